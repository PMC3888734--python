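"""Mechanical systems of dihedral angles.

A chain is a set of torsion (dihedral) angles with diagonal rotational
inertia and a per-angle potential.  Angles are plain real numbers in
radians (no 2*pi wrapping); energies are in units of kB*T with kB*T = 1 by
default.

Conventions
-----------
The harmonic spring evaluates ``V(theta) = k * theta**2`` — no factor of
one half.  The half convention ``V = 0.5 * k * theta**2`` is available via
the explicit ``half_k=True`` flag and is never a silent default.

The cusp germ is ``S(s) = s**4/4 + a*s**2/2 + b*s`` (linear term in ``s``).
A variant with a constant offset ``+ b`` instead of the linear term exists
behind the explicit ``constant_offset=True`` flag; constant offsets do not
affect criticality.
"""

from __future__ import annotations

import abc
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .errors import ValidationError

__all__ = [
    "Potential",
    "HarmonicSpring",
    "AsymmetricSpring",
    "CuspPotential",
    "CompositePotential",
    "ExpressionPotential",
    "ScheduledPotential",
    "CuspGerm",
    "TorsionChain",
    "POTENTIAL_KINDS",
    "potential_from_spec",
    "build_chain",
    "evaluate_potential",
    "asymmetric_spring_energy",
    "cusp_action_value",
]

POTENTIAL_KINDS = (
    "harmonic_spring",
    "asymmetric_spring",
    "cusp",
    "composite",
    "custom",
    "free",
)


class Potential(abc.ABC):
    """Scalar potential of a single angle, optionally time dependent."""

    time_dependent: bool = False

    @abc.abstractmethod
    def value(self, theta, t=0.0):
        """Potential energy V(theta, t)."""

    @abc.abstractmethod
    def deriv(self, theta, t=0.0):
        """dV/dtheta."""

    @abc.abstractmethod
    def deriv2(self, theta, t=0.0):
        """d^2 V / dtheta^2."""

    def with_schedule(self, schedule) -> "ScheduledPotential":
        """Multiply this potential by a time schedule g(t)."""
        return ScheduledPotential(self, schedule)


@dataclass(frozen=True)
class FreePotential(Potential):
    """V = 0: free rotation."""

    def value(self, theta, t=0.0):
        return np.zeros_like(np.asarray(theta, dtype=float))

    def deriv(self, theta, t=0.0):
        return np.zeros_like(np.asarray(theta, dtype=float))

    def deriv2(self, theta, t=0.0):
        return np.zeros_like(np.asarray(theta, dtype=float))


@dataclass(frozen=True)
class HarmonicSpring(Potential):
    """Angular spring V = k*theta**2 (or 0.5*k*theta**2 with half_k).

    ``k`` may be negative, which gives the inverted spring used for
    no-conjugate-point tests.
    """

    k: float
    half_k: bool = False

    @property
    def _c(self) -> float:
        return 0.5 * self.k if self.half_k else self.k

    def value(self, theta, t=0.0):
        return self._c * np.asarray(theta, dtype=float) ** 2

    def deriv(self, theta, t=0.0):
        return 2.0 * self._c * np.asarray(theta, dtype=float)

    def deriv2(self, theta, t=0.0):
        return np.full_like(np.asarray(theta, dtype=float), 2.0 * self._c)


@dataclass(frozen=True)
class AsymmetricSpring(Potential):
    """Direction-dependent spring: stiffness depends on the side of theta_ref.

    V = k_plus*(theta-theta_ref)**2 for theta >= theta_ref, else
    k_minus*(theta-theta_ref)**2.  C^1 at theta_ref; V'' jumps there and is
    evaluated one-sidedly (the theta >= theta_ref branch wins at the kink).
    """

    k_plus: float
    k_minus: float
    theta_ref: float = 0.0

    def __post_init__(self):
        if self.k_plus < 0 or self.k_minus < 0:
            raise ValidationError(
                "asymmetric_spring stiffnesses must be >= 0, got "
                f"k_plus={self.k_plus}, k_minus={self.k_minus}"
            )

    def _k(self, theta):
        return np.where(np.asarray(theta, dtype=float) >= self.theta_ref,
                        self.k_plus, self.k_minus)

    def value(self, theta, t=0.0):
        d = np.asarray(theta, dtype=float) - self.theta_ref
        return self._k(theta) * d ** 2

    def deriv(self, theta, t=0.0):
        d = np.asarray(theta, dtype=float) - self.theta_ref
        return 2.0 * self._k(theta) * d

    def deriv2(self, theta, t=0.0):
        return 2.0 * self._k(theta) * np.ones_like(np.asarray(theta, dtype=float))


@dataclass(frozen=True)
class CuspPotential(Potential):
    """Quartic two-control potential V = theta**4/4 + a*theta**2/2 + b*theta."""

    a: float
    b: float

    def value(self, theta, t=0.0):
        th = np.asarray(theta, dtype=float)
        return 0.25 * th ** 4 + 0.5 * self.a * th ** 2 + self.b * th

    def deriv(self, theta, t=0.0):
        th = np.asarray(theta, dtype=float)
        return th ** 3 + self.a * th + self.b

    def deriv2(self, theta, t=0.0):
        th = np.asarray(theta, dtype=float)
        return 3.0 * th ** 2 + self.a


@dataclass(frozen=True)
class CompositePotential(Potential):
    """Sum of component potentials."""

    parts: tuple[Potential, ...]

    def __post_init__(self):
        if not self.parts:
            raise ValidationError("composite potential needs at least one part")

    @property
    def time_dependent(self):  # type: ignore[override]
        return any(p.time_dependent for p in self.parts)

    def value(self, theta, t=0.0):
        return sum(p.value(theta, t) for p in self.parts)

    def deriv(self, theta, t=0.0):
        return sum(p.deriv(theta, t) for p in self.parts)

    def deriv2(self, theta, t=0.0):
        return sum(p.deriv2(theta, t) for p in self.parts)


class ExpressionPotential(Potential):
    """Potential given as a symbolic expression in ``theta`` (and optionally ``t``).

    Derivatives are taken symbolically, so finite-difference consistency is
    automatic.
    """

    def __init__(self, expression: str):
        import sympy as sp

        theta, t = sp.symbols("theta t")
        expr = sp.sympify(expression)
        bad = expr.free_symbols - {theta, t}
        if bad:
            raise ValidationError(
                f"custom potential may only use 'theta' and 't'; got {sorted(map(str, bad))}"
            )
        self.expression = expression
        self.time_dependent = t in expr.free_symbols
        self._f = sp.lambdify((theta, t), expr, modules="numpy")
        self._fp = sp.lambdify((theta, t), sp.diff(expr, theta), modules="numpy")
        self._fpp = sp.lambdify((theta, t), sp.diff(expr, theta, 2), modules="numpy")

    def _eval(self, fn, theta, t):
        th = np.asarray(theta, dtype=float)
        out = fn(th, t)
        return np.broadcast_to(np.asarray(out, dtype=float), th.shape).copy() \
            if np.ndim(out) != np.ndim(th) else np.asarray(out, dtype=float)

    def value(self, theta, t=0.0):
        return self._eval(self._f, theta, t)

    def deriv(self, theta, t=0.0):
        return self._eval(self._fp, theta, t)

    def deriv2(self, theta, t=0.0):
        return self._eval(self._fpp, theta, t)

    def __repr__(self):
        return f"ExpressionPotential({self.expression!r})"


class ScheduledPotential(Potential):
    """Base potential multiplied by a time schedule g(t)."""

    time_dependent = True

    def __init__(self, base: Potential, schedule):
        self.base = base
        if callable(schedule):
            self._g = schedule
            self.schedule = schedule
        else:
            import sympy as sp

            t = sp.symbols("t")
            expr = sp.sympify(schedule)
            if expr.free_symbols - {t}:
                raise ValidationError("time schedule may only depend on 't'")
            self._g = sp.lambdify(t, expr, modules="numpy")
            self.schedule = schedule

    def value(self, theta, t=0.0):
        return float(self._g(t)) * self.base.value(theta, t)

    def deriv(self, theta, t=0.0):
        return float(self._g(t)) * self.base.deriv(theta, t)

    def deriv2(self, theta, t=0.0):
        return float(self._g(t)) * self.base.deriv2(theta, t)


@dataclass(frozen=True)
class CuspGerm:
    """The cusp germ S(s) = s**4/4 + a*s**2/2 + b*s.

    ``constant_offset=True`` selects the variant with a constant ``+ b`` in
    place of the linear ``b*s`` term; the offset shifts values but not
    derivatives.
    """

    a: float
    b: float
    constant_offset: bool = False

    def value(self, s):
        s = np.asarray(s, dtype=float)
        quart = 0.25 * s ** 4 + 0.5 * self.a * s ** 2
        if self.constant_offset:
            return quart + self.b
        return quart + self.b * s

    def deriv(self, s):
        s = np.asarray(s, dtype=float)
        d = s ** 3 + self.a * s
        if self.constant_offset:
            return d
        return d + self.b

    def deriv2(self, s):
        s = np.asarray(s, dtype=float)
        return 3.0 * s ** 2 + self.a

    def critical_points(self) -> np.ndarray:
        """Real roots of S'(s), sorted ascending."""
        b_lin = 0.0 if self.constant_offset else self.b
        roots = np.roots([1.0, 0.0, self.a, b_lin])
        real = roots[np.abs(roots.imag) < 1e-9 * (1.0 + np.abs(roots.real))].real
        return np.sort(np.unique(np.round(real, 12)))

    def discriminant(self) -> float:
        """4*a**3 + 27*b**2; negative inside the three-critical-point region."""
        b_lin = 0.0 if self.constant_offset else self.b
        return 4.0 * self.a ** 3 + 27.0 * b_lin ** 2


def cusp_action_value(germ: CuspGerm, s):
    """Value of the cusp germ at state ``s`` (see also germ.deriv/deriv2)."""
    return germ.value(s)


def asymmetric_spring_energy(theta, k_plus: float, k_minus: float, theta_ref: float = 0.0):
    """One-sided quadratic spring energy (functional form of AsymmetricSpring)."""
    return AsymmetricSpring(k_plus=k_plus, k_minus=k_minus, theta_ref=theta_ref).value(theta)


def potential_from_spec(spec: Mapping | Potential) -> Potential:
    """Build a Potential from a plain mapping (the [potential] config section)."""
    if isinstance(spec, Potential):
        return spec
    if not isinstance(spec, Mapping):
        raise ValidationError(f"potential spec must be a mapping, got {type(spec).__name__}")
    spec = dict(spec)
    kind = spec.pop("kind", None)
    schedule = spec.pop("schedule", None)
    if kind not in POTENTIAL_KINDS:
        raise ValidationError(
            f"unknown potential kind {kind!r}; allowed kinds: {', '.join(POTENTIAL_KINDS)}"
        )
    if kind == "harmonic_spring":
        pot = _build(HarmonicSpring, spec, required=("k",), optional=("half_k",))
    elif kind == "asymmetric_spring":
        pot = _build(AsymmetricSpring, spec,
                     required=("k_plus", "k_minus"), optional=("theta_ref",))
    elif kind == "cusp":
        pot = _build(CuspPotential, spec, required=("a", "b"), optional=())
    elif kind == "free":
        if spec:
            raise ValidationError(f"free potential takes no parameters, got {sorted(spec)}")
        pot = FreePotential()
    elif kind == "custom":
        pot = _build(ExpressionPotential, spec, required=("expression",), optional=())
    else:  # composite
        parts = spec.pop("parts", None)
        if spec:
            raise ValidationError(f"unknown keys in composite potential spec: {sorted(spec)}")
        if not isinstance(parts, Sequence) or not parts:
            raise ValidationError("composite potential needs a non-empty 'parts' list")
        pot = CompositePotential(tuple(potential_from_spec(p) for p in parts))
    if schedule is not None:
        pot = pot.with_schedule(schedule)
    return pot


def _build(cls, spec: dict, required: tuple, optional: tuple) -> Potential:
    missing = [k for k in required if k not in spec]
    if missing:
        raise ValidationError(f"potential spec missing required keys: {missing}")
    unknown = sorted(set(spec) - set(required) - set(optional))
    if unknown:
        raise ValidationError(f"unknown keys in potential spec: {unknown}")
    return cls(**spec)


@dataclass(frozen=True)
class TorsionChain:
    """A chain of dihedral angles with diagonal inertia.

    Kinetic energy is T = 0.5 * sum_i I_i * omega_i**2; the potential is a
    per-angle scalar potential summed over angles (one potential broadcast
    to all angles, or one per angle).
    """

    n_angles: int
    inertias: np.ndarray
    potentials: tuple[Potential, ...]
    label: str = ""

    def __post_init__(self):
        if not isinstance(self.n_angles, (int, np.integer)) or self.n_angles < 1:
            raise ValidationError(f"n_angles must be a positive integer, got {self.n_angles!r}")
        inert = np.atleast_1d(np.asarray(self.inertias, dtype=float))
        if inert.size == 1:
            inert = np.full(self.n_angles, float(inert[0]))
        if inert.shape != (self.n_angles,):
            raise ValidationError(
                f"inertias must broadcast to length n_angles={self.n_angles}, "
                f"got shape {inert.shape}"
            )
        if not np.all(np.isfinite(inert)) or np.any(inert <= 0):
            raise ValidationError(f"inertias must be finite and > 0, got {inert.tolist()}")
        object.__setattr__(self, "inertias", inert)
        pots = self.potentials
        if isinstance(pots, Potential):
            pots = (pots,)
        pots = tuple(pots)
        if len(pots) == 1:
            pots = pots * self.n_angles
        if len(pots) != self.n_angles:
            raise ValidationError(
                f"need 1 or n_angles={self.n_angles} potentials, got {len(pots)}"
            )
        object.__setattr__(self, "potentials", pots)

    @property
    def time_dependent(self) -> bool:
        return any(p.time_dependent for p in self.potentials)

    def _check_q(self, q) -> np.ndarray:
        q = np.asarray(q, dtype=float)
        if q.shape != (self.n_angles,):
            raise ValidationError(
                f"angle vector has shape {q.shape}, expected ({self.n_angles},)"
            )
        return q

    def kinetic_energy(self, v) -> float:
        v = self._check_q(v)
        return float(0.5 * np.dot(self.inertias, v ** 2))

    def potential_energy(self, q, t: float = 0.0) -> float:
        q = self._check_q(q)
        return float(sum(p.value(qi, t) for p, qi in zip(self.potentials, q)))

    def potential_grad(self, q, t: float = 0.0) -> np.ndarray:
        q = self._check_q(q)
        return np.array([float(p.deriv(qi, t)) for p, qi in zip(self.potentials, q)])

    def potential_hess(self, q, t: float = 0.0) -> np.ndarray:
        """Hessian of V at q.  Per-angle potentials are separable -> diagonal."""
        q = self._check_q(q)
        return np.diag([float(p.deriv2(qi, t)) for p, qi in zip(self.potentials, q)])

    def acceleration(self, q, t: float = 0.0) -> np.ndarray:
        return -self.potential_grad(q, t) / self.inertias

    def total_energy(self, q, v, t: float = 0.0) -> float:
        return self.kinetic_energy(v) + self.potential_energy(q, t)

    def lagrangian(self, q, v, t: float = 0.0) -> float:
        return self.kinetic_energy(v) - self.potential_energy(q, t)


_CHAIN_KEYS = {"n_angles", "inertias", "potential", "label"}


def build_chain(config: Mapping) -> TorsionChain:
    """Build a validated TorsionChain from a configuration mapping.

    Expects keys ``n_angles``, ``inertias`` (scalar broadcast allowed) and
    ``potential`` (a potential spec mapping, or a list of them, one per
    angle).
    """
    if not isinstance(config, Mapping):
        raise ValidationError("chain config must be a mapping")
    unknown = sorted(set(config) - _CHAIN_KEYS)
    if unknown:
        raise ValidationError(f"unknown keys in chain config: {unknown}")
    missing = sorted(_CHAIN_KEYS - {"label"} - set(config))
    if missing:
        raise ValidationError(f"chain config missing required keys: {missing}")
    n = config["n_angles"]
    if isinstance(n, bool) or not isinstance(n, (int, np.integer)):
        raise ValidationError(f"n_angles must be an integer, got {n!r}")
    pspec = config["potential"]
    if isinstance(pspec, Sequence) and not isinstance(pspec, (str, bytes, Mapping)):
        pots = tuple(potential_from_spec(p) for p in pspec)
    else:
        pots = (potential_from_spec(pspec),)
    return TorsionChain(
        n_angles=int(n),
        inertias=np.asarray(config["inertias"], dtype=float),
        potentials=pots,
        label=str(config.get("label", "")),
    )


def evaluate_potential(chain: TorsionChain, angles, t: float = 0.0) -> float:
    """Total potential energy of the chain at the given angle vector."""
    return chain.potential_energy(angles, t)
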