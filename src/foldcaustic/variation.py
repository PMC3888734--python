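"""Action evaluation, stationarity checks, second variation, conjugate points.

The second variation of the action about a stationary path x0(t) is the
quadratic form

    d2S/de2 = int [ xidot^T M xidot - xi^T HessV(x0(t)) xi ] dt

over variations xi with pinned endpoints.  It is discretized with
piecewise-linear finite elements and mass-lumped quadrature, which makes
the form matrix block-tridiagonal (tridiagonal per angle for separable
potentials) and lets the sliding-endpoint scan stay cheap.

Conjugate points are located two independent ways: by the smallest
eigenvalue of the endpoint-restricted form crossing zero, and by zeros of
det Y(t) for the matrix Jacobi field Y solving M Ydd = -HessV(x0(t)) Y,
Y(t0) = 0, Yd(t0) = I.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import simpson
from scipy.linalg import eigh, eigh_tridiagonal
from scipy.optimize import brentq

from .dynamics import Trajectory
from .errors import NonStationaryTrajectoryError, ValidationError
from .torsion_model import TorsionChain

__all__ = [
    "VariationFunction",
    "SecondVariationForm",
    "ConjugatePoint",
    "action_integral",
    "el_residual",
    "second_variation_form",
    "find_conjugate_points",
    "jacobi_conjugate_points",
]

DEFAULT_STATIONARITY_TOL = 1e-3


@dataclass(frozen=True)
class VariationFunction:
    """A variation xi(t) on a trajectory grid with xi(t0) = xi(t1) = 0."""

    t: np.ndarray
    xi: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        xi = np.asarray(self.xi, dtype=float)
        if xi.ndim == 1:
            xi = xi[:, None]
        if xi.shape[0] != t.size:
            raise ValidationError("xi must have one row per time grid point")
        if np.any(xi[0] != 0.0) or np.any(xi[-1] != 0.0):
            raise ValidationError("variation endpoints must be exactly zero")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "xi", xi)


@dataclass(frozen=True)
class ConjugatePoint:
    """First times at which the sliding-endpoint second variation vanishes."""

    t_star: float
    multiplicity: int
    method: str


def action_integral(chain: TorsionChain, traj: Trajectory) -> float:
    """Action S = int (T - V) dt along the trajectory, by Simpson's rule."""
    if traj.n_steps < 2:
        raise ValidationError("grid too short for Simpson quadrature (need N >= 2)")
    return float(simpson(traj.lagrangian_values(), x=traj.t))


def el_residual(chain: TorsionChain, traj: Trajectory) -> float:
    """Max-norm of the discretized Euler-Lagrange operator at interior points.

    Residual_i = M (q_{i+1} - 2 q_i + q_{i-1}) / h^2 + gradV(q_i, t_i).
    """
    h = traj.h
    q = traj.q
    acc = (q[2:] - 2.0 * q[1:-1] + q[:-2]) / (h * h)
    grad = np.array([
        chain.potential_grad(q[i], traj.t[i]) for i in range(1, traj.t.size - 1)
    ])
    res = chain.inertias[None, :] * acc + grad
    return float(np.max(np.abs(res))) if res.size else 0.0


def _hessians_along(chain: TorsionChain, traj: Trajectory) -> np.ndarray:
    return np.array([
        chain.potential_hess(traj.q[i], traj.t[i]) for i in range(traj.t.size)
    ])


@dataclass
class SecondVariationForm:
    """Discretized second-variation quadratic form on a stationary trajectory.

    Piecewise-linear xi, interior nodes 1..N-1; the matrix decomposes into
    stiffness (exact for piecewise-linear xi) minus a mass-lumped Hessian
    term.
    """

    traj: Trajectory
    chain: TorsionChain
    hessians: np.ndarray  # (N+1, n, n), HessV along the trajectory

    _matrix: np.ndarray | None = None
    _eigenvalues: np.ndarray | None = None

    # ---------------------------------------------------------- assembly

    @property
    def h(self) -> float:
        return self.traj.h

    @property
    def n_angles(self) -> int:
        return self.chain.n_angles

    @property
    def separable(self) -> bool:
        off = self.hessians - np.einsum(
            "tij,ij->tij", self.hessians, np.eye(self.n_angles)
        )
        return bool(np.all(off == 0.0))

    def _assemble(self, n_nodes: int, last_h: float | None = None) -> np.ndarray:
        """Dense matrix over interior nodes 1..n_nodes (inclusive).

        With ``last_h`` set, the final element (from node n_nodes to the
        movable endpoint) has that length instead of h; the lumped weight of
        the last interior node becomes (h + last_h)/2.
        """
        n, h = self.n_angles, self.h
        hl = h if last_h is None else last_h
        m = self.chain.inertias
        dim = n_nodes * n
        Q = np.zeros((dim, dim))
        for i in range(n_nodes):
            s = i * n
            w = h if i < n_nodes - 1 else 0.5 * (h + hl)
            stiff = m / h + (m / hl if i == n_nodes - 1 else m / h)
            Q[s:s + n, s:s + n] = np.diag(stiff) - w * self.hessians[i + 1]
            if i + 1 < n_nodes:
                Q[s:s + n, s + n:s + 2 * n] = -np.diag(m / h)
                Q[s + n:s + 2 * n, s:s + n] = -np.diag(m / h)
        return Q

    @property
    def matrix(self) -> np.ndarray:
        if self._matrix is None:
            self._matrix = self._assemble(self.traj.n_steps - 1)
        return self._matrix

    @property
    def eigenvalues(self) -> np.ndarray:
        if self._eigenvalues is None:
            self._eigenvalues = np.sort(np.linalg.eigvalsh(self.matrix))
        return self._eigenvalues

    # ------------------------------------------------------- evaluation

    def form_value(self, xi) -> float:
        """Quadratic form value for a variation given on the full grid."""
        if isinstance(xi, VariationFunction):
            xi = xi.xi
        xi = np.asarray(xi, dtype=float)
        if xi.ndim == 1:
            xi = xi[:, None]
        if xi.shape != self.traj.q.shape:
            raise ValidationError(
                f"variation shape {xi.shape} does not match trajectory {self.traj.q.shape}"
            )
        if np.any(xi[0] != 0.0) or np.any(xi[-1] != 0.0):
            raise ValidationError("variation endpoints must be exactly zero")
        h = self.h
        m = self.chain.inertias
        dxi = np.diff(xi, axis=0) / h
        stiffness = float(np.sum(m[None, :] * dxi ** 2) * h)
        pot = float(sum(
            h * xi[i] @ self.hessians[i] @ xi[i] for i in range(1, xi.shape[0] - 1)
        ))
        return stiffness - pot

    # --------------------------------------------- sliding-endpoint scan

    def _tridiag(self, n_nodes: int, last_h: float | None = None):
        """Diagonal/off-diagonal of the restricted form (single-angle case)."""
        h = self.h
        hl = h if last_h is None else last_h
        m = float(self.chain.inertias[0])
        H = self.hessians[1:n_nodes + 1, 0, 0]
        d = np.full(n_nodes, 2.0 * m / h) - h * H
        if n_nodes >= 1:
            d[-1] = m / h + m / hl - 0.5 * (h + hl) * H[-1]
        e = np.full(max(n_nodes - 1, 0), -m / h)
        return d, e

    def restricted_eigenvalue(self, n_nodes: int, index: int = 0,
                              last_h: float | None = None) -> float:
        """index-th smallest eigenvalue of the form restricted to n_nodes."""
        if n_nodes * self.n_angles <= index:
            raise ValidationError("eigenvalue index out of range for restriction")
        if self.n_angles == 1:
            d, e = self._tridiag(n_nodes, last_h)
            if n_nodes == 1:
                return float(d[0])
            vals = eigh_tridiagonal(d, e, select="i",
                                    select_range=(index, index), eigvals_only=True)
            return float(vals[0])
        Q = self._assemble(n_nodes, last_h)
        vals = eigh(Q, eigvals_only=True, subset_by_index=[index, index])
        return float(vals[0])

    def negative_count(self, n_nodes: int, tol: float = 0.0,
                       last_h: float | None = None) -> int:
        """Number of eigenvalues below -tol for the restricted form."""
        if self.n_angles == 1:
            d, e = self._tridiag(n_nodes, last_h)
            if n_nodes == 1:
                return int(d[0] < -tol)
            vals = eigh_tridiagonal(d, e, eigvals_only=True)
        else:
            vals = np.linalg.eigvalsh(self._assemble(n_nodes, last_h))
        return int(np.sum(vals < -tol))

    def negative_counts_by_endpoint(self, tol: float = 0.0) -> np.ndarray:
        """Negative-eigenvalue counts of the restricted form for every endpoint.

        Entry ``j - 2`` is the count for the movable endpoint at grid time
        t_j, j = 2..N.  Computed in one block-LDL sweep: restricted forms
        are leading principal submatrices, and inertia is additive over the
        Schur-complement blocks.
        """
        n, h = self.n_angles, self.h
        m = self.chain.inertias
        N = self.traj.n_steps
        B = -np.diag(m / h)
        counts = np.empty(N - 1, dtype=int)
        neg = 0
        D_prev_inv = None
        for i in range(1, N):
            A = np.diag(2.0 * m / h) - h * self.hessians[i]
            D = A if D_prev_inv is None else A - B @ D_prev_inv @ B
            w, V = np.linalg.eigh(D)
            neg += int(np.sum(w < -tol))
            guard = 1e-13 * max(2.0 * float(np.max(m)) / h, float(np.max(np.abs(w))))
            w_safe = np.where(np.abs(w) < guard, guard, w)
            D_prev_inv = (V / w_safe) @ V.T
            counts[i - 1] = neg
        return counts

    def morse_index(self, tol: float | None = None) -> int:
        """Number of negative eigenvalues of the full-interval form."""
        if tol is None:
            tol = self.zero_tolerance()
        return int(self.negative_counts_by_endpoint(tol=tol)[-1])

    def zero_tolerance(self) -> float:
        """Eigenvalues within this of zero count as vanishing (round-off guard)."""
        return 1e-9 * 2.0 * float(np.max(self.chain.inertias)) / self.h


def second_variation_form(
    chain: TorsionChain,
    traj: Trajectory,
    stationarity_tol: float = DEFAULT_STATIONARITY_TOL,
) -> SecondVariationForm:
    """Assemble the discretized second variation about a stationary path."""
    res = el_residual(chain, traj)
    if res > stationarity_tol:
        raise NonStationaryTrajectoryError(
            f"trajectory is not stationary: Euler-Lagrange residual {res:.3e} "
            f"exceeds threshold {stationarity_tol:.3e}; the second variation "
            "is only defined about solutions of the equations of motion",
            residual=res,
        )
    return SecondVariationForm(traj=traj, chain=chain,
                               hessians=_hessians_along(chain, traj))


def find_conjugate_points(
    chain: TorsionChain,
    traj: Trajectory,
    stationarity_tol: float = DEFAULT_STATIONARITY_TOL,
    refine_tol: float | None = None,
) -> list[ConjugatePoint]:
    """Conjugate points via the sliding-endpoint eigenvalue scan.

    The movable endpoint advances along the grid; every time the number of
    negative eigenvalues of the restricted form increases, the crossing time
    is refined by bisection (default tolerance h/100).
    """
    form = second_variation_form(chain, traj, stationarity_tol)
    h = traj.h
    if refine_tol is None:
        refine_tol = h / 100.0
    tol = form.zero_tolerance()
    points: list[ConjugatePoint] = []
    prev_neg = 0
    N = traj.n_steps
    counts = form.negative_counts_by_endpoint(tol=tol)
    for j in range(2, N + 1):  # endpoint at t_j, interior nodes 1..j-1
        neg = int(counts[j - 2])
        if neg > prev_neg:
            mult = neg - prev_neg
            t_lo, t_hi = float(traj.t[j - 1]), float(traj.t[j])

            def g(tau: float) -> float:
                k = int(np.searchsorted(traj.t, tau, side="right")) - 1
                k = min(k, N - 1)
                last_h = tau - float(traj.t[k])
                if last_h < 1e-12 * h:
                    k, last_h = k - 1, h
                return form.restricted_eigenvalue(k, index=prev_neg, last_h=last_h)

            t_star = _bisect_sign_change(g, t_lo, t_hi, refine_tol)
            points.append(ConjugatePoint(t_star=t_star, multiplicity=mult,
                                         method="eigenvalue"))
            prev_neg = neg
    return points


def _bisect_sign_change(g, t_lo: float, t_hi: float, tol: float) -> float:
    g_lo, g_hi = g(t_lo), g(t_hi)
    if g_lo <= 0.0:
        return t_lo
    if g_hi > 0.0:
        return t_hi
    while t_hi - t_lo > tol:
        mid = 0.5 * (t_lo + t_hi)
        if g(mid) > 0.0:
            t_lo = mid
        else:
            t_hi = mid
    return 0.5 * (t_lo + t_hi)


# --------------------------------------------------------------- Jacobi route


class _JacobiField:
    """Matrix Jacobi field Y(t): M Ydd = -H(t) Y, Y(t0) = 0, Yd(t0) = I.

    One RK4 pass over the trajectory grid caches (Y, Yd) at every node;
    evaluation at off-grid times restarts from the cached bracketing node.
    H(t) is interpolated linearly between grid nodes.
    """

    def __init__(self, chain: TorsionChain, traj: Trajectory,
                 hessians: np.ndarray, substeps: int = 2):
        self.chain = chain
        self.traj = traj
        self.hessians = hessians
        self.substeps = substeps
        self._Minv = 1.0 / chain.inertias
        n = chain.n_angles
        Npts = traj.t.size
        self.Y = np.empty((Npts, n, n))
        self.Yd = np.empty((Npts, n, n))
        self.Y[0] = np.zeros((n, n))
        self.Yd[0] = np.eye(n)
        for i in range(Npts - 1):
            self.Y[i + 1], self.Yd[i + 1] = self._advance(
                self.Y[i], self.Yd[i], float(traj.t[i]), float(traj.t[i + 1]))
        self.dets = np.array([np.linalg.det(Y) for Y in self.Y])

    def _H_at(self, t: float) -> np.ndarray:
        grid = self.traj.t
        s = (t - grid[0]) / self.traj.h
        k = int(np.clip(np.floor(s), 0, grid.size - 2))
        w = s - k
        return (1.0 - w) * self.hessians[k] + w * self.hessians[k + 1]

    def _advance(self, Y, Yd, t_from: float, t_to: float):
        def rhs(t, Y, Yd):
            return Yd, -(self._Minv[:, None] * (self._H_at(t) @ Y))

        step = self.traj.h / self.substeps
        t = t_from
        while t < t_to - 1e-15 * max(1.0, abs(t_to)):
            dt = min(step, t_to - t)
            k1Y, k1V = rhs(t, Y, Yd)
            k2Y, k2V = rhs(t + dt / 2, Y + dt / 2 * k1Y, Yd + dt / 2 * k1V)
            k3Y, k3V = rhs(t + dt / 2, Y + dt / 2 * k2Y, Yd + dt / 2 * k2V)
            k4Y, k4V = rhs(t + dt, Y + dt * k3Y, Yd + dt * k3V)
            Y = Y + dt / 6 * (k1Y + 2 * k2Y + 2 * k3Y + k4Y)
            Yd = Yd + dt / 6 * (k1V + 2 * k2V + 2 * k3V + k4V)
            t += dt
        return Y, Yd

    def value(self, tau: float) -> np.ndarray:
        grid = self.traj.t
        k = int(np.clip(np.searchsorted(grid, tau, side="right") - 1,
                        0, grid.size - 1))
        if abs(tau - grid[k]) < 1e-15 * max(1.0, abs(tau)):
            return self.Y[k]
        Y, _ = self._advance(self.Y[k], self.Yd[k], float(grid[k]), tau)
        return Y

    def det(self, tau: float) -> float:
        return float(np.linalg.det(self.value(tau)))


def jacobi_conjugate_points(
    chain: TorsionChain,
    traj: Trajectory,
    stationarity_tol: float = DEFAULT_STATIONARITY_TOL,
    refine_tol: float | None = None,
) -> list[ConjugatePoint]:
    """Conjugate points as zeros of det Y(t) for the matrix Jacobi field.

    Independent oracle for :func:`find_conjugate_points`: same definition,
    different numerics (initial-value integration instead of eigenvalue
    scans).
    """
    res = el_residual(chain, traj)
    if res > stationarity_tol:
        raise NonStationaryTrajectoryError(
            f"trajectory is not stationary (residual {res:.3e})", residual=res)
    hessians = _hessians_along(chain, traj)
    h = traj.h
    if refine_tol is None:
        refine_tol = h / 100.0

    field = _JacobiField(chain, traj, hessians)
    dets = field.dets[1:]  # skip the trivial zero at t0
    t_nodes = traj.t[1:]
    scale = np.maximum.accumulate(np.abs(dets))
    scale[scale == 0.0] = 1.0

    points: list[ConjugatePoint] = []
    for i in range(len(dets) - 1):
        t_a, t_b = float(t_nodes[i]), float(t_nodes[i + 1])
        if dets[i] == 0.0 and i > 0:
            points.append(_jacobi_point(field, t_a))
        elif dets[i] * dets[i + 1] < 0.0:
            t_star = brentq(field.det, t_a, t_b, xtol=refine_tol)
            points.append(_jacobi_point(field, float(t_star)))
        elif (0 < i < len(dets) - 1
              and abs(dets[i]) < 1e-10 * scale[i]
              and abs(dets[i]) <= abs(dets[i - 1])
              and abs(dets[i]) <= abs(dets[i + 1])):
            # even-multiplicity zero: |det| dips to ~0 without a sign change
            points.append(_jacobi_point(field, t_a))
    return points


def _jacobi_point(field: _JacobiField, t_star: float) -> ConjugatePoint:
    sv = np.linalg.svd(field.value(t_star), compute_uv=False)
    top = sv[0] if sv[0] > 0 else 1.0
    mult = max(1, int(np.sum(sv < 1e-6 * top)))
    return ConjugatePoint(t_star=t_star, multiplicity=mult, method="jacobi")
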