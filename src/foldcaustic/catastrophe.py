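"""The seven elementary normal forms: registry, classification, stability,
and Boltzmann moment statistics of catastrophe potentials.

"Shape unchanged" under perturbation is operationalized as preservation of
the critical-point count and Morse indices inside a state-space window;
right-equivalence up to diffeomorphism is not decidable numerically.
Classification matches a fitted polynomial jet (degree <= 6) against the
registry germs after scaling normalization; rotations of the 2-state-variable
frame are not searched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import quad
from scipy.optimize import least_squares

from .errors import IntegrabilityError, OptimizationError, ValidationError
from .torsion_model import CuspPotential

__all__ = [
    "NormalFormEntry",
    "ClassificationResult",
    "StabilityReport",
    "CuspControlEstimate",
    "normal_form_registry",
    "classify_germ",
    "perturbation_stability_test",
    "boltzmann_moments",
    "recover_cusp_controls",
]


@dataclass(frozen=True)
class NormalFormEntry:
    """One of the seven structurally stable germs with its universal unfolding."""

    name: str
    corank: int          # number of degenerate state variables (1 or 2)
    control_dim: int     # codimension of the universal unfolding
    germ_degree: int     # polynomial degree of the germ
    _value: Callable = field(repr=False, compare=False)
    _grad: Callable = field(repr=False, compare=False)
    _hess: Callable = field(repr=False, compare=False)
    germ_expr: str = ""

    @property
    def state_dim(self) -> int:
        return self.corank

    def _controls(self, controls):
        if controls is None:
            controls = (0.0,) * self.control_dim
        controls = tuple(float(c) for c in controls)
        if len(controls) != self.control_dim:
            raise ValidationError(
                f"{self.name} takes {self.control_dim} controls, got {len(controls)}")
        return controls

    def value(self, *state, controls=None):
        return self._value(*state, *self._controls(controls))

    def grad(self, *state, controls=None) -> np.ndarray:
        return np.asarray(
            self._grad(*state, *self._controls(controls)), dtype=float).ravel()

    def hess(self, *state, controls=None) -> np.ndarray:
        return np.atleast_2d(np.asarray(
            self._hess(*state, *self._controls(controls)), dtype=float))

    def unfolding_coefficients(self, controls=None) -> np.ndarray:
        """Coefficients c[k] of s**k for 1-state-variable forms."""
        if self.corank != 1:
            raise ValidationError(
                f"{self.name} has corank 2; no univariate coefficient form")
        controls = self._controls(controls)
        c = np.zeros(self.germ_degree + 1)
        if self.name == "fold":
            c[3] = 1.0
            c[1] = controls[0]
        elif self.name == "cusp":
            c[4] = 0.25
            c[2] = 0.5 * controls[0]
            c[1] = controls[1]
        elif self.name == "swallowtail":
            c[5] = 1.0
            c[3], c[2], c[1] = controls
        else:  # butterfly
            c[6] = 1.0
            c[4], c[3], c[2], c[1] = controls
        return c


def _make_entry(name, corank, control_dim, degree, expr_str, state_syms, ctrl_syms):
    import sympy as sp

    expr = sp.sympify(expr_str)
    syms = state_syms + ctrl_syms
    grad = sp.Matrix([sp.diff(expr, s) for s in state_syms])
    hess = sp.Matrix([[sp.diff(expr, a, b) for b in state_syms] for a in state_syms])
    return NormalFormEntry(
        name=name, corank=corank, control_dim=control_dim, germ_degree=degree,
        _value=sp.lambdify(syms, expr, modules="numpy"),
        _grad=sp.lambdify(syms, grad, modules="numpy"),
        _hess=sp.lambdify(syms, hess, modules="numpy"),
        germ_expr=expr_str,
    )


@lru_cache(maxsize=1)
def _registry() -> tuple[NormalFormEntry, ...]:
    import sympy as sp

    s, s1, s2 = sp.symbols("s s1 s2")
    a, b, c, d = sp.symbols("a b c d")
    return (
        _make_entry("fold", 1, 1, 3, "s**3 + a*s", (s,), (a,)),
        _make_entry("cusp", 1, 2, 4, "s**4/4 + a*s**2/2 + b*s", (s,), (a, b)),
        _make_entry("swallowtail", 1, 3, 5,
                    "s**5 + a*s**3 + b*s**2 + c*s", (s,), (a, b, c)),
        _make_entry("butterfly", 1, 4, 6,
                    "s**6 + a*s**4 + b*s**3 + c*s**2 + d*s", (s,), (a, b, c, d)),
        _make_entry("hyperbolic_umbilic", 2, 3, 3,
                    "s1**3 + s2**3 + a*s1*s2 + b*s1 + c*s2", (s1, s2), (a, b, c)),
        _make_entry("elliptic_umbilic", 2, 3, 3,
                    "s1**3 - 3*s1*s2**2 + a*(s1**2 + s2**2) + b*s1 + c*s2",
                    (s1, s2), (a, b, c)),
        _make_entry("parabolic_umbilic", 2, 4, 4,
                    "s2**4 + s1**2*s2 + a*s1**2 + b*s2**2 + c*s1 + d*s2",
                    (s1, s2), (a, b, c, d)),
    )


def normal_form_registry() -> list[NormalFormEntry]:
    """The fixed list of the seven elementary normal forms."""
    return list(_registry())


def registry_entry(name: str) -> NormalFormEntry:
    for entry in _registry():
        if entry.name == name:
            return entry
    raise ValidationError(
        f"unknown normal form {name!r}; known forms: "
        f"{', '.join(e.name for e in _registry())}")


# -------------------------------------------------------------- classification


@dataclass(frozen=True)
class ClassificationResult:
    match: str                  # registry name, "morse", or "unclassified"
    corank: int
    controls: tuple
    residual: float
    morse_index: int | None = None


def _fit_jet_1d(s: np.ndarray, f: np.ndarray, degree: int = 6):
    A = np.vander(s, degree + 1, increasing=True)
    coef, res, *_ = np.linalg.lstsq(A, f, rcond=None)
    fit_res = float(np.sqrt(res[0])) if res.size else 0.0
    return coef, fit_res


def _fit_jet_2d(s1: np.ndarray, s2: np.ndarray, F: np.ndarray, degree: int = 6):
    S1, S2 = np.meshgrid(s1, s2, indexing="ij")
    terms = [(i, j) for i in range(degree + 1) for j in range(degree + 1)
             if i + j <= degree]
    A = np.stack([(S1 ** i * S2 ** j).ravel() for i, j in terms], axis=1)
    coef, res, *_ = np.linalg.lstsq(A, F.ravel(), rcond=None)
    fit_res = float(np.sqrt(res[0])) if res.size else 0.0
    return dict(zip(terms, coef)), fit_res


_HESS_ZERO_RTOL = 1e-6


def classify_germ(samples, state_dim: int | None = None,
                  grad_tol: float = 1e-6,
                  residual_tol: float = 1e-3) -> ClassificationResult:
    """Classify a sampled scalar function around a critical point at the origin.

    ``samples`` is ``(s, f)`` for one state variable or ``(s1, s2, F)`` for
    two; grids must straddle the origin.  A degree-6 jet is fitted by least
    squares; corank comes from the Hessian spectrum; the reduced jet is
    matched to a registry germ after scaling normalization.
    """
    samples = tuple(np.asarray(a, dtype=float) for a in samples)
    if state_dim is None:
        state_dim = len(samples) - 1
    if state_dim not in (1, 2):
        raise ValidationError(f"state_dim must be 1 or 2, got {state_dim}")
    if state_dim == 1:
        return _classify_1d(samples, grad_tol, residual_tol)
    return _classify_2d(samples, grad_tol, residual_tol)


def _classify_1d(samples, grad_tol, residual_tol) -> ClassificationResult:
    s, f = samples
    coef, fit_res = _fit_jet_1d(s, f)
    scale = max(float(np.max(np.abs(f))), 1e-300)
    span = max(float(np.max(np.abs(s))), 1e-300)
    cn = coef / scale * span ** np.arange(coef.size)  # dimensionless coefficients
    if abs(cn[1]) > grad_tol:
        raise ValidationError(
            f"center is not a critical point: |gradient| = {abs(coef[1]):.3e}")
    if abs(cn[2]) > _HESS_ZERO_RTOL * max(np.max(np.abs(cn[2:])), 1e-300):
        idx = 1 if coef[2] < 0 else 0
        return ClassificationResult(match="morse", corank=0, controls=(),
                                    residual=fit_res / scale, morse_index=idx)
    # degenerate: find the leading reduced-jet coefficient
    lead = None
    for k in (3, 4, 5, 6):
        if abs(cn[k]) > 1e-8 * max(np.max(np.abs(cn[3:])), 1e-300):
            lead = k
            break
    if lead is None:
        return ClassificationResult(match="unclassified", corank=1, controls=(),
                                    residual=fit_res / scale)
    name = {3: "fold", 4: "cusp", 5: "swallowtail", 6: "butterfly"}[lead]
    target = {3: 1.0, 4: 0.25, 5: 1.0, 6: 1.0}[lead]
    lam = (target / abs(coef[lead])) ** (1.0 / lead)
    cs = coef * lam ** np.arange(coef.size)  # coefficients after s -> s/lam
    if name == "fold":
        controls = (float(cs[1]),)
        leftover = [cs[2], cs[4] if cs.size > 4 else 0.0,
                    cs[5] if cs.size > 5 else 0.0, cs[6] if cs.size > 6 else 0.0]
    elif name == "cusp":
        controls = (float(2.0 * cs[2]), float(cs[1]))
        leftover = [cs[3], cs[5], cs[6]]
    elif name == "swallowtail":
        controls = (float(cs[3]), float(cs[2]), float(cs[1]))
        leftover = [cs[4], cs[6]]
    else:
        controls = (float(cs[4]), float(cs[3]), float(cs[2]), float(cs[1]))
        leftover = [cs[5]]
    residual = fit_res / scale + float(np.linalg.norm(leftover)) / max(
        abs(cs[lead]), 1e-300)
    if residual > residual_tol:
        return ClassificationResult(match="unclassified", corank=1,
                                    controls=controls, residual=residual)
    return ClassificationResult(match=name, corank=1, controls=controls,
                                residual=residual)


def _classify_2d(samples, grad_tol, residual_tol) -> ClassificationResult:
    s1, s2, F = samples
    coef, fit_res = _fit_jet_2d(s1, s2, F)
    scale = max(float(np.max(np.abs(F))), 1e-300)
    g = np.array([coef[(1, 0)], coef[(0, 1)]])
    if np.linalg.norm(g) > grad_tol * scale:
        raise ValidationError(
            f"center is not a critical point: |gradient| = {np.linalg.norm(g):.3e}")
    H = np.array([[2 * coef[(2, 0)], coef[(1, 1)]],
                  [coef[(1, 1)], 2 * coef[(0, 2)]]])
    w = np.linalg.eigvalsh(H)
    wmax = max(float(np.max(np.abs(w))), 1e-300)
    corank = int(np.sum(np.abs(w) < _HESS_ZERO_RTOL * wmax))
    if float(np.max(np.abs(w))) < 1e-10 * scale:
        corank = 2
    if corank == 0:
        return ClassificationResult(match="morse", corank=0, controls=(),
                                    residual=fit_res / scale,
                                    morse_index=int(np.sum(w < 0)))
    if corank == 1:
        # one soft direction: reduce along the eigenvector -- only handled
        # when the frame is already aligned with the axes
        return ClassificationResult(match="unclassified", corank=1, controls=(),
                                    residual=fit_res / scale)
    # corank 2: discriminate by the binary cubic a*s1^3+b*s1^2 s2+c*s1 s2^2+d*s2^3
    a, b = coef[(3, 0)], coef[(2, 1)]
    c, d = coef[(1, 2)], coef[(0, 3)]
    cubic_scale = max(float(np.max(np.abs([a, b, c, d]))), 1e-300)
    disc = (18 * a * b * c * d - 4 * b ** 3 * d + b ** 2 * c ** 2
            - 4 * a * c ** 3 - 27 * a ** 2 * d ** 2)
    if disc > 1e-8 * cubic_scale ** 4:
        name = "elliptic_umbilic"
    elif disc < -1e-8 * cubic_scale ** 4:
        name = "hyperbolic_umbilic"
    else:
        name = "parabolic_umbilic"
    residual = fit_res / scale
    if name == "parabolic_umbilic":
        if abs(coef[(0, 4)]) < 1e-8 * scale or abs(b) < 1e-8 * cubic_scale:
            return ClassificationResult(match="unclassified", corank=2,
                                        controls=(), residual=residual)
    if residual > residual_tol:
        return ClassificationResult(match="unclassified", corank=2, controls=(),
                                    residual=residual)
    return ClassificationResult(match=name, corank=2, controls=(),
                                residual=residual)


# ------------------------------------------------------- perturbation testing


@dataclass(frozen=True)
class StabilityReport:
    trials: int
    preserved: int
    form: str
    controls: tuple
    window: float
    degree_min: int
    degree_max: int
    amplitude: float
    seed: int

    @property
    def preserved_fraction(self) -> float:
        return self.preserved / self.trials if self.trials else 1.0


def _critical_structure(coeffs: np.ndarray, window: float):
    """(sorted critical points, Morse indices) of a polynomial inside |s|<=window."""
    dcoef = coeffs[1:] * np.arange(1, coeffs.size)
    roots = np.polynomial.polynomial.polyroots(dcoef)
    real = roots[np.abs(roots.imag) < 1e-8 * (1.0 + np.abs(roots.real))].real
    real = np.sort(real[np.abs(real) <= window])
    # collapse numerically coincident roots
    keep = []
    for r in real:
        if not keep or r - keep[-1] > 1e-8 * max(1.0, window):
            keep.append(float(r))
    d2coef = dcoef[1:] * np.arange(1, dcoef.size)
    indices = [1 if np.polynomial.polynomial.polyval(r, d2coef) < 0 else 0
               for r in keep]
    return keep, indices


def perturbation_stability_test(
    form,
    controls,
    window: float,
    degree_min: int,
    degree_max: int,
    amplitude: float,
    trials: int,
    seed: int,
) -> StabilityReport:
    """Monte-Carlo structural-stability check for a corank-1 germ.

    Adds random polynomials (degrees degree_min..degree_max, coefficients
    uniform in [-amplitude, amplitude]) to the unfolded germ and counts the
    trials in which the critical points inside the window keep their number
    and Morse indices.
    """
    if isinstance(form, str):
        form = registry_entry(form)
    if form.corank != 1:
        raise ValidationError(
            "perturbation_stability_test supports the corank-1 forms "
            "(fold, cusp, swallowtail, butterfly)")
    if degree_min <= form.germ_degree:
        raise ValidationError(
            f"perturbations must be higher order than the germ: need "
            f"degree_min > {form.germ_degree}, got {degree_min}")
    if degree_max < degree_min:
        raise ValidationError("degree_max must be >= degree_min")
    if amplitude < 0:
        raise ValidationError("amplitude must be >= 0")

    base = form.unfolding_coefficients(controls)
    ref_pts, ref_idx = _critical_structure(base, window)
    rng = np.random.default_rng(seed)
    preserved = 0
    for _ in range(trials):
        pert = np.zeros(degree_max + 1)
        pert[degree_min:degree_max + 1] = rng.uniform(
            -amplitude, amplitude, degree_max - degree_min + 1)
        total = np.zeros(max(base.size, pert.size))
        total[:base.size] += base
        total[:pert.size] += pert
        pts, idx = _critical_structure(total, window)
        if len(pts) == len(ref_pts) and idx == ref_idx:
            preserved += 1
    return StabilityReport(
        trials=trials, preserved=preserved, form=form.name,
        controls=tuple(np.atleast_1d(controls).tolist()) if controls is not None else (),
        window=window, degree_min=degree_min, degree_max=degree_max,
        amplitude=amplitude, seed=seed,
    )


# ------------------------------------------------------------------- moments

_LOG_CUTOFF = -np.log(1e-16)  # weight threshold relative to its max


def _potential_callable(potential):
    if callable(potential) and not hasattr(potential, "value"):
        return potential
    return potential.value


def _integration_window(V, kBT: float):
    """Symmetric-search window where the Boltzmann weight exceeds 1e-16."""
    grid = np.linspace(-30.0, 30.0, 4001)
    try:
        vals = np.asarray(V(grid), dtype=float)
        if vals.shape != grid.shape:
            raise TypeError
    except (TypeError, ValueError):
        vals = np.array([float(V(g)) for g in grid])
    i_min = int(np.argmin(vals))
    v_min = float(vals[i_min])
    threshold = v_min + _LOG_CUTOFF * kBT

    lo = float(grid[i_min])
    while V(lo) < threshold:
        lo -= 0.5
        if lo < -1e4:
            raise IntegrabilityError(
                "potential is not confining on the left tail "
                "(Boltzmann weight does not decay)")
    hi = float(grid[i_min])
    while V(hi) < threshold:
        hi += 0.5
        if hi > 1e4:
            raise IntegrabilityError(
                "potential is not confining on the right tail "
                "(Boltzmann weight does not decay)")
    # tail test: the weight must keep decaying beyond the window
    if V(lo - 1.0) < V(lo) or V(hi + 1.0) < V(hi):
        raise IntegrabilityError("potential decreases beyond the integration "
                                 "window; exp(-V/kBT) is not integrable")
    return lo, hi, v_min


def boltzmann_moments(potential, kBT: float = 1.0,
                      orders: Sequence[int] = (1, 2)) -> dict[int, float]:
    """Moments <theta**k> under the Boltzmann weight exp(-V(theta)/kBT)."""
    if kBT <= 0:
        raise ValidationError(f"kBT must be > 0, got {kBT}")
    V = _potential_callable(potential)
    lo, hi, v_min = _integration_window(V, kBT)

    def weight(th, k=0):
        return th ** k * np.exp(-(V(th) - v_min) / kBT)

    Z, _ = quad(weight, lo, hi, limit=200)
    if not np.isfinite(Z) or Z <= 0:
        raise IntegrabilityError("partition integral did not converge")
    out = {}
    for k in orders:
        num, _ = quad(weight, lo, hi, args=(int(k),), limit=200)
        out[int(k)] = float(num / Z)
    return out


@dataclass(frozen=True)
class CuspControlEstimate:
    a: float
    b: float
    residual: float


def recover_cusp_controls(moments: Sequence[float], kBT: float = 1.0,
                          x0: Sequence[float] = (1.0, 0.0)) -> CuspControlEstimate:
    """Invert boltzmann_moments for the cusp potential: (m1, m2, m3) -> (a, b)."""
    m_obs = np.asarray(moments, dtype=float)
    if m_obs.size != 3:
        raise ValidationError("need the first three moments (m1, m2, m3)")

    def resid(p):
        m = boltzmann_moments(CuspPotential(a=p[0], b=p[1]), kBT=kBT,
                              orders=(1, 2, 3))
        return np.array([m[1], m[2], m[3]]) - m_obs

    sol = least_squares(resid, x0=np.asarray(x0, dtype=float),
                        xtol=1e-12, ftol=1e-12)
    if not sol.success:
        raise OptimizationError(
            f"cusp control recovery failed: {sol.message}", diagnostics=sol)
    return CuspControlEstimate(a=float(sol.x[0]), b=float(sol.x[1]),
                               residual=float(np.linalg.norm(sol.fun)))
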