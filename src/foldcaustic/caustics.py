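"""Family action surfaces, caustic detection, envelopes, Hessian scans.

A family of stationary trajectories indexed by a scalar parameter u carries
an action surface S(u, .): either S tabulated along members against time
(with the member positions x(u, t) recorded), or an analytic S given as a
function of u and control parameters.  Caustics are located where dS/du and
d2S/du2 vanish together; envelopes are found purely geometrically from the
member position field; the saddle beyond a caustic is confirmed by an
inertia flip.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import cumulative_simpson

from .dynamics import Trajectory, TrajectoryFamily
from .errors import ValidationError
from .torsion_model import TorsionChain
from .variation import el_residual, second_variation_form

__all__ = [
    "FamilyActionSurface",
    "CausticPoint",
    "CausticSet",
    "EnvelopePoint",
    "family_action_surface",
    "analytic_action_surface",
    "detect_caustic",
    "envelope_points",
    "hessian_determinant_scan",
    "saddle_check_beyond",
]

_MIN_U_SAMPLES = 5


@dataclass(frozen=True)
class CausticPoint:
    """A point satisfying dS/du = 0 and d2S/du2 = 0 within tolerances."""

    x: tuple
    u: float
    t: float | None = None
    kind: str = "fold"


@dataclass(frozen=True)
class CausticSet:
    points: tuple[CausticPoint, ...]
    tol_first: float
    tol_second: float

    def __len__(self):
        return len(self.points)

    def __iter__(self):
        return iter(self.points)


@dataclass(frozen=True)
class EnvelopePoint:
    t: float
    x: tuple
    u: float


@dataclass(frozen=True)
class FamilyActionSurface:
    """S over a (u, time) grid of family members, or over (u, controls).

    Family mode: ``t`` and ``x`` are set; S[i, j] is the action of member i
    accumulated from t0 to t_j and x[i, j] its position there.
    Analytic mode: ``controls`` holds the control-parameter axes and S has
    shape (n_u, *control_shape).
    """

    u: np.ndarray
    S: np.ndarray
    t: np.ndarray | None = None
    x: np.ndarray | None = None
    controls: tuple[np.ndarray, ...] | None = None
    control_names: tuple[str, ...] = ()
    family: TrajectoryFamily | None = None
    chain: TorsionChain | None = None

    def __post_init__(self):
        u = np.asarray(self.u, dtype=float)
        if u.size < _MIN_U_SAMPLES:
            raise ValidationError(
                f"need at least {_MIN_U_SAMPLES} u-samples for derivative stencils, "
                f"got {u.size}"
            )
        if not np.all(np.isfinite(self.S)):
            raise ValidationError("S must be finite on the declared grid")
        object.__setattr__(self, "u", u)

    @property
    def mode(self) -> str:
        return "family" if self.t is not None else "analytic"

    @property
    def du(self) -> float:
        return float(self.u[1] - self.u[0])

    @property
    def dS_du(self) -> np.ndarray:
        """Centered first derivative in u; edge rows are NaN (no stencil)."""
        out = np.full_like(self.S, np.nan)
        out[1:-1] = (self.S[2:] - self.S[:-2]) / (2.0 * self.du)
        return out

    @property
    def d2S_du2(self) -> np.ndarray:
        """Centered second derivative in u; edge rows are NaN."""
        out = np.full_like(self.S, np.nan)
        out[1:-1] = (self.S[2:] - 2.0 * self.S[1:-1] + self.S[:-2]) / self.du ** 2
        return out


def family_action_surface(
    family: TrajectoryFamily,
    chain: TorsionChain,
    stationarity_tol: float = 1e-3,
) -> FamilyActionSurface:
    """Tabulate the running action S(u, t) and positions x(u, t) of a family."""
    if family.u.size < _MIN_U_SAMPLES:
        raise ValidationError(
            f"need at least {_MIN_U_SAMPLES} family members, got {family.u.size}")
    for u, traj in zip(family.u, family.trajectories):
        res = el_residual(chain, traj)
        if res > stationarity_tol:
            raise ValidationError(
                f"family member u={u:.6g} is not stationary (residual {res:.3e})")
    L = np.stack([traj.lagrangian_values() for traj in family.trajectories])
    S = cumulative_simpson(L, x=family.t, axis=1, initial=0.0)
    return FamilyActionSurface(
        u=family.u, S=S, t=family.t.copy(), x=family.positions(),
        family=family, chain=chain,
    )


def analytic_action_surface(
    func: Callable,
    u_grid,
    control_grids: Sequence,
    control_names: Sequence[str] = (),
) -> FamilyActionSurface:
    """Sample an analytic S(u, c1, c2, ...) on a tensor grid."""
    u = np.asarray(u_grid, dtype=float)
    ctrls = tuple(np.asarray(c, dtype=float) for c in control_grids)
    mesh = np.meshgrid(u, *ctrls, indexing="ij")
    S = np.asarray(func(*mesh), dtype=float)
    names = tuple(control_names) or tuple(f"c{i}" for i in range(len(ctrls)))
    return FamilyActionSurface(u=u, S=S, controls=ctrls, control_names=names)


# ----------------------------------------------------------------- detection


def _zero_crossings(y: np.ndarray, x: np.ndarray):
    """(x*, linear-interp index weights) for each sign change of y over x."""
    out = []
    for i in range(len(y) - 1):
        a, b = y[i], y[i + 1]
        if not (np.isfinite(a) and np.isfinite(b)):
            continue
        if a == 0.0:
            out.append((float(x[i]), i, 0.0))
        elif a * b < 0.0:
            w = a / (a - b)
            out.append((float(x[i] + w * (x[i + 1] - x[i])), i, float(w)))
    return out


def _interp_along(arr, i, w):
    return (1.0 - w) * arr[i] + w * arr[i + 1]


def detect_caustic(
    surface: FamilyActionSurface,
    tol_first: float | None = None,
    tol_second: float | None = None,
) -> CausticSet:
    """Grid cells where dS/du and d2S/du2 vanish together, refined locally.

    Default tolerances: tol_first = 1e-6 * range(S),
    tol_second = 1e-4 * median |d2S/du2|.
    """
    Su = surface.dS_du
    Suu = surface.d2S_du2
    if tol_first is None:
        tol_first = 1e-6 * float(np.ptp(surface.S))
    if tol_second is None:
        tol_second = 1e-4 * float(np.nanmedian(np.abs(Suu)))

    if surface.mode == "family":
        points = _detect_family(surface, Su, Suu, tol_first, tol_second)
    else:
        points = _detect_analytic(surface, Su, Suu, tol_first, tol_second)
    return CausticSet(points=tuple(points), tol_first=tol_first,
                      tol_second=tol_second)


# columns this close to t0 are skipped: S(u, t) -> 0 as t -> t0 for every
# member, so the start of the family is trivially (and spuriously) degenerate
_SKIP_INITIAL_COLS = 3


def _detect_family(surface, Su, Suu, tol_first, tol_second) -> list[CausticPoint]:
    t = surface.t
    u = surface.u
    x = surface.x
    raw = []  # (t, u, x-tuple)
    # per time column: stationary u (zero of Su), with Suu there
    col_roots: list[list[tuple[float, float]]] = []
    for j in range(t.size):
        roots = []
        if j >= _SKIP_INITIAL_COLS:
            for u_star, i, w in _zero_crossings(Su[:, j], u):
                suu = float(_interp_along(Suu[:, j], i, w))
                if np.isfinite(suu):
                    roots.append((u_star, suu))
        col_roots.append(roots)
    for j in range(t.size):
        for u_star, suu in col_roots[j]:
            # sub-tolerance at this cell
            if abs(suu) < tol_second:
                raw.append(_family_point(surface, u_star, float(t[j])))
                continue
            # sign change of Suu at the stationary u between adjacent columns
            if j + 1 < t.size and col_roots[j + 1]:
                u_next, suu_next = min(
                    col_roots[j + 1], key=lambda r: abs(r[0] - u_star))
                if abs(u_next - u_star) <= 2.0 * surface.du and suu * suu_next < 0.0:
                    w = suu / (suu - suu_next)
                    t_star = float(t[j] + w * (t[j + 1] - t[j]))
                    u_ref = float((1 - w) * u_star + w * u_next)
                    raw.append(_family_point(surface, u_ref, t_star))
    merged = _merge_points(raw, dt=float(t[1] - t[0]), du=surface.du)
    return _classify_extent(merged, surface)


def _family_point(surface, u_star: float, t_star: float):
    t = surface.t
    u = surface.u
    j = int(np.clip(np.searchsorted(t, t_star) - 1, 0, t.size - 2))
    wt = (t_star - t[j]) / (t[j + 1] - t[j])
    i = int(np.clip(np.searchsorted(u, u_star) - 1, 0, u.size - 2))
    wu = (u_star - u[i]) / (u[i + 1] - u[i])
    xt = (1 - wt) * surface.x[:, j] + wt * surface.x[:, j + 1]  # (Nu, n)
    x_star = (1 - wu) * xt[i] + wu * xt[i + 1]
    return (t_star, u_star, tuple(float(v) for v in x_star))


def _merge_points(raw, dt: float, du: float):
    """Cluster raw detections closer than ~2 cells in (t, u)."""
    merged: list[list] = []
    for t_star, u_star, x_star in sorted(raw):
        for cluster in merged:
            if (abs(cluster[0][0] - t_star) <= 2 * dt
                    and abs(cluster[0][1] - u_star) <= 2 * du):
                cluster.append((t_star, u_star, x_star))
                break
        else:
            merged.append([(t_star, u_star, x_star)])
    out = []
    for cluster in merged:
        ts = float(np.mean([c[0] for c in cluster]))
        us = float(np.mean([c[1] for c in cluster]))
        xs = tuple(np.mean([c[2] for c in cluster], axis=0).tolist())
        out.append((ts, us, xs))
    return out


def _classify_extent(points, surface) -> list[CausticPoint]:
    if not points:
        return []
    x_all = np.array([p[2] for p in points])
    cell = float(np.ptp(surface.x)) / max(surface.u.size, surface.t.size)
    extent = float(np.max(np.ptp(x_all, axis=0))) if len(points) > 1 else 0.0
    kind = "focus" if extent < 2.0 * max(cell, 1e-12) else "fold"
    return [CausticPoint(x=p[2], u=p[1], t=p[0], kind=kind) for p in points]


def _detect_analytic(surface, Su, Suu, tol_first, tol_second) -> list[CausticPoint]:
    ctrls = surface.controls
    shape = surface.S.shape[1:]
    pts = []
    for idx in itertools.product(*(range(s) for s in shape)):
        col = (slice(None),) + idx
        for u_star, i, w in _zero_crossings(Suu[col], surface.u):
            su = float(_interp_along(Su[col], i, w))
            if np.isfinite(su) and abs(su) < tol_first:
                coords = tuple(float(ctrls[d][idx[d]]) for d in range(len(ctrls)))
                pts.append((coords, float(u_star)))
    if not pts:
        return []
    coords_all = np.array([p[0] for p in pts])
    cells = np.array([
        (c[1] - c[0]) if c.size > 1 else 1.0 for c in ctrls])
    extent = (np.ptp(coords_all, axis=0) / cells) if len(pts) > 1 else np.zeros(len(ctrls))
    kind = "focus" if float(np.max(extent)) < 2.0 else "fold"
    return [CausticPoint(x=c, u=u, t=None, kind=kind) for c, u in pts]


# ------------------------------------------------------------------ envelope


def envelope_points(family: TrajectoryFamily) -> list[EnvelopePoint]:
    """Geometric envelope: where neighbouring members become tangent.

    For one angle this is the zero set of dx/du(u, t); for two angles, of
    det[dx/du, xdot]; for more, a dip of the smallest singular value of
    [dx/du, xdot] below round-off scale.
    """
    if family.u.size < _MIN_U_SAMPLES:
        raise ValidationError(
            f"need at least {_MIN_U_SAMPLES} members, got {family.u.size}")
    u = family.u
    t = family.t
    x = family.positions()  # (Nu, Nt, n)
    v = np.stack([traj.v for traj in family.trajectories])
    dxdu = np.gradient(x, u, axis=0)
    n = x.shape[2]
    if n == 1:
        D = dxdu[:, :, 0]
    elif n == 2:
        D = dxdu[:, :, 0] * v[:, :, 1] - dxdu[:, :, 1] * v[:, :, 0]
    else:
        J = np.concatenate([dxdu[..., None], v[..., None]], axis=-1)
        sv = np.linalg.svd(J, compute_uv=False)
        D = sv[..., -1] - 1e-8 * np.maximum(sv[..., 0], 1e-300)

    out = []
    dt = float(t[1] - t[0])
    t_min = float(t[0]) + _SKIP_INITIAL_COLS * dt  # start-point degeneracy
    # crossings along t at fixed u
    for i in range(u.size):
        for t_star, j, w in _zero_crossings(D[i, :], t):
            if t_star < t_min:
                continue
            x_star = _interp_along(x[i], j, w)
            out.append(EnvelopePoint(t=t_star, x=tuple(map(float, x_star)),
                                     u=float(u[i])))
    # crossings along u at fixed t
    for j in range(_SKIP_INITIAL_COLS, t.size):
        for u_star, i, w in _zero_crossings(D[:, j], u):
            x_star = _interp_along(x[:, j], i, w)
            out.append(EnvelopePoint(t=float(t[j]), x=tuple(map(float, x_star)),
                                     u=u_star))
    return out


# ------------------------------------------------------- Hessian determinant


def hessian_determinant_scan(
    action_field: Callable,
    axes: Sequence,
    tol: float = 1e-3,
) -> list[dict]:
    """Near-zero points of det Hess S over a tensor grid of scan parameters.

    ``action_field`` maps d scalar coordinates to the action value;
    ``axes`` is one 1-D grid per scan dimension (each needs >= 5 points for
    the centered stencils).  A point is reported when |det H| < tol * scale
    with scale the median |det H| over the region.
    """
    axes = [np.asarray(a, dtype=float) for a in axes]
    if not axes:
        raise ValidationError("need at least one scan axis")
    for a in axes:
        if a.size < 5:
            raise ValidationError(
                f"grid too coarse for Hessian stencil: axis with {a.size} < 5 points")
    mesh = np.meshgrid(*axes, indexing="ij")
    S = np.asarray(action_field(*mesh), dtype=float)
    d = len(axes)
    grads = np.gradient(S, *axes) if d > 1 else [np.gradient(S, axes[0])]
    H = np.empty(S.shape + (d, d))
    for i in range(d):
        gi = np.gradient(grads[i], *axes) if d > 1 else [np.gradient(grads[i], axes[0])]
        for j in range(d):
            H[..., i, j] = gi[j]
    det = np.linalg.det(H)
    interior = tuple(slice(2, -2) for _ in range(d))
    det_in = det[interior]
    scale = float(np.median(np.abs(det_in)))
    if scale == 0.0:
        scale = float(np.max(np.abs(det_in))) or 1.0
    hits = np.argwhere(np.abs(det_in) < tol * scale)
    out = []
    for idx in hits:
        full_idx = tuple(int(i) + 2 for i in idx)
        point = tuple(float(axes[k][full_idx[k]]) for k in range(d))
        out.append({"point": point, "det": float(det[full_idx]),
                    "index": full_idx})
    return out


# -------------------------------------------------------------- saddle check


def saddle_check_beyond(
    surface: FamilyActionSurface,
    caustics: CausticSet,
    offset: float | None = None,
) -> list[dict]:
    """Inertia of the action just before and just after each caustic.

    Family mode: Morse index (negative-eigenvalue count) of the second
    variation of the member through the caustic, with the endpoint slid to
    t* -/+ offset.  Analytic mode: signs of d2S/du2 over the stationary
    points of S(u) at control points one cell to either side.  A caustic is
    confirmed when the signature goes positive-definite -> indefinite.
    """
    reports = []
    for cp in caustics:
        if surface.mode == "family":
            reports.append(_saddle_family(surface, cp, offset))
        else:
            reports.append(_saddle_analytic(surface, cp))
    return reports


def _truncate(traj: Trajectory, t_end: float) -> Trajectory:
    k = int(np.searchsorted(traj.t, t_end, side="right"))
    k = max(k, 3)
    return Trajectory(t=traj.t[:k], q=traj.q[:k], v=traj.v[:k],
                      chain=traj.chain, integrator=traj.integrator)


def _saddle_family(surface, cp: CausticPoint, offset) -> dict:
    family = surface.family
    chain = surface.chain
    dt = float(surface.t[1] - surface.t[0])
    if offset is None:
        offset = 5.0 * dt
    member = family.member_nearest(cp.u)
    t_before = cp.t - offset
    t_after = cp.t + offset
    if t_after > float(surface.t[-1]) or t_before <= float(surface.t[0]) + 2 * dt:
        return {"caustic": cp, "status": "unconfirmable",
                "reason": "caustic at the boundary of the scanned region"}
    form_b = second_variation_form(chain, _truncate(member, t_before))
    form_a = second_variation_form(chain, _truncate(member, t_after))
    n_neg_b, n_neg_a = form_b.morse_index(), form_a.morse_index()
    dim_b, dim_a = form_b.matrix.shape[0], form_a.matrix.shape[0]
    status = "confirmed" if (n_neg_b == 0 and n_neg_a >= 1) else "no_transition"
    return {
        "caustic": cp, "status": status,
        "before": {"n_pos": dim_b - n_neg_b, "n_neg": n_neg_b},
        "after": {"n_pos": dim_a - n_neg_a, "n_neg": n_neg_a},
    }


def _stationary_signature(surface, col_idx) -> dict:
    col = (slice(None),) + col_idx
    Su = surface.dS_du[col]
    Suu = surface.d2S_du2[col]
    n_pos = n_neg = 0
    for _, i, w in _zero_crossings(Su, surface.u):
        suu = float(_interp_along(Suu, i, w))
        if suu > 0:
            n_pos += 1
        elif suu < 0:
            n_neg += 1
    return {"n_pos": n_pos, "n_neg": n_neg}


def _saddle_analytic(surface, cp: CausticPoint) -> dict:
    ctrls = surface.controls
    idx = tuple(int(np.argmin(np.abs(ctrls[d] - cp.x[d])))
                for d in range(len(ctrls)))
    for d in range(len(ctrls)):
        if not (1 <= idx[d] < ctrls[d].size - 1):
            return {"caustic": cp, "status": "unconfirmable",
                    "reason": "caustic at the boundary of the scanned region"}
        lo = idx[:d] + (idx[d] - 1,) + idx[d + 1:]
        hi = idx[:d] + (idx[d] + 1,) + idx[d + 1:]
        sig_lo = _stationary_signature(surface, lo)
        sig_hi = _stationary_signature(surface, hi)
        if (sig_lo["n_neg"], sig_lo["n_pos"]) != (sig_hi["n_neg"], sig_hi["n_pos"]):
            return {"caustic": cp, "status": "confirmed", "axis": d,
                    "before": sig_lo, "after": sig_hi}
    return {"caustic": cp, "status": "no_transition",
            "before": _stationary_signature(surface, idx),
            "after": _stationary_signature(surface, idx)}
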