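"""Equation-of-motion integration and trajectory families.

Velocity Verlet (symplectic, order 2) is the default integrator; classic
RK4 is available and is selected automatically for time-dependent
potentials.  Steps are uniform and fixed so that trajectory grids align
across a family and with the second-variation discretization.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import FamilyIntegrationError, IntegrationBlowupError, ValidationError
from .torsion_model import TorsionChain

__all__ = [
    "Trajectory",
    "TrajectoryFamily",
    "integrate_trajectory",
    "shoot_family",
]

_UNIFORM_RTOL = 1e-12


@dataclass(frozen=True)
class Trajectory:
    """A discretized path in angle space on a uniform time grid.

    Arrays have shapes t: (N+1,), q: (N+1, n_angles), v: (N+1, n_angles).
    """

    t: np.ndarray
    q: np.ndarray
    v: np.ndarray
    chain: TorsionChain
    integrator: str = "verlet"

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        q = np.asarray(self.q, dtype=float)
        v = np.asarray(self.v, dtype=float)
        if t.ndim != 1 or t.size < 2:
            raise ValidationError("time grid needs at least 2 points")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValidationError("time grid must be strictly increasing")
        h = dt[0]
        if np.any(np.abs(dt - h) > _UNIFORM_RTOL * max(abs(t[0]), abs(t[-1]), 1.0)):
            raise ValidationError("time grid must be uniform to relative tolerance 1e-12")
        n = self.chain.n_angles
        if q.ndim == 1:
            q = q[:, None]
        if v.ndim == 1:
            v = v[:, None]
        if q.shape != (t.size, n) or v.shape != (t.size, n):
            raise ValidationError(
                f"positions/velocities must have shape ({t.size}, {n}); "
                f"got {q.shape} and {v.shape}"
            )
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "v", v)

    @property
    def h(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def n_steps(self) -> int:
        return self.t.size - 1

    @property
    def t0(self) -> float:
        return float(self.t[0])

    @property
    def t1(self) -> float:
        return float(self.t[-1])

    def energies(self) -> np.ndarray:
        """Total energy T + V at each grid point."""
        return np.array([
            self.chain.total_energy(self.q[i], self.v[i], self.t[i])
            for i in range(self.t.size)
        ])

    def lagrangian_values(self) -> np.ndarray:
        """L = T - V at each grid point."""
        return np.array([
            self.chain.lagrangian(self.q[i], self.v[i], self.t[i])
            for i in range(self.t.size)
        ])

    # ------------------------------------------------------------------ I/O

    def to_frame(self) -> pd.DataFrame:
        n = self.chain.n_angles
        data = {"t": self.t}
        for j in range(n):
            data[f"theta_{j}"] = self.q[:, j]
        for j in range(n):
            data[f"omega_{j}"] = self.v[:, j]
        return pd.DataFrame(data)

    def write_csv(self, path, metadata: dict | None = None) -> None:
        """Write t, theta_*, omega_* columns plus a JSON metadata sidecar."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False, float_format="%.17g")
        meta = {
            "n_angles": int(self.chain.n_angles),
            "integrator": self.integrator,
            "h": self.h,
            "t0": self.t0,
            "t1": self.t1,
            "content_sha256": hashlib.sha256(path.read_bytes()).hexdigest(),
        }
        if metadata:
            meta.update(metadata)
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(meta, indent=2, sort_keys=True) + "\n"
        )

    @classmethod
    def read_csv(cls, path, chain: TorsionChain, integrator: str = "unknown") -> "Trajectory":
        df = pd.read_csv(path)
        n = chain.n_angles
        cols = ["t"] + [f"theta_{j}" for j in range(n)] + [f"omega_{j}" for j in range(n)]
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValidationError(f"trajectory CSV missing columns: {missing}")
        q = df[[f"theta_{j}" for j in range(n)]].to_numpy()
        v = df[[f"omega_{j}" for j in range(n)]].to_numpy()
        return cls(t=df["t"].to_numpy(), q=q, v=v, chain=chain, integrator=integrator)


@dataclass(frozen=True)
class TrajectoryFamily:
    """One trajectory per value of a scalar family parameter u.

    All members share the same time grid; the initial-manifold descriptor
    records how (q0, v0) depend on u.
    """

    u: np.ndarray
    trajectories: tuple[Trajectory, ...]
    initial_curve: str = ""

    def __post_init__(self):
        u = np.asarray(self.u, dtype=float)
        if u.ndim != 1 or u.size < 3:
            raise ValidationError("family parameter grid needs at least 3 values")
        if np.any(np.diff(u) <= 0):
            raise ValidationError("family parameter grid must be strictly increasing")
        if len(self.trajectories) != u.size:
            raise ValidationError("one trajectory required per u value")
        t0 = self.trajectories[0].t
        for traj in self.trajectories[1:]:
            if traj.t.shape != t0.shape or not np.allclose(traj.t, t0, rtol=0, atol=1e-12):
                raise ValidationError("all family members must share the same time grid")
        object.__setattr__(self, "u", u)

    @property
    def t(self) -> np.ndarray:
        return self.trajectories[0].t

    @property
    def chain(self) -> TorsionChain:
        return self.trajectories[0].chain

    def positions(self) -> np.ndarray:
        """Member positions stacked as an array of shape (n_u, N+1, n_angles)."""
        return np.stack([traj.q for traj in self.trajectories])

    def member_nearest(self, u_value: float) -> Trajectory:
        return self.trajectories[int(np.argmin(np.abs(self.u - u_value)))]


def _step_verlet(chain: TorsionChain, q, v, a, t, h):
    q_new = q + h * v + 0.5 * h * h * a
    a_new = chain.acceleration(q_new, t + h)
    v_new = v + 0.5 * h * (a + a_new)
    return q_new, v_new, a_new


def _step_rk4(chain: TorsionChain, q, v, t, h):
    def f(qq, vv, tt):
        return vv, chain.acceleration(qq, tt)

    k1q, k1v = f(q, v, t)
    k2q, k2v = f(q + 0.5 * h * k1q, v + 0.5 * h * k1v, t + 0.5 * h)
    k3q, k3v = f(q + 0.5 * h * k2q, v + 0.5 * h * k2v, t + 0.5 * h)
    k4q, k4v = f(q + h * k3q, v + h * k3v, t + h)
    q_new = q + (h / 6.0) * (k1q + 2 * k2q + 2 * k3q + k4q)
    v_new = v + (h / 6.0) * (k1v + 2 * k2v + 2 * k3v + k4v)
    return q_new, v_new


def integrate_trajectory(
    chain: TorsionChain,
    q0,
    v0,
    t0: float,
    t1: float,
    n_steps: int,
    method: str = "auto",
) -> Trajectory:
    """Integrate the Euler-Lagrange equations of motion on a uniform grid.

    ``method`` is one of "auto", "verlet", "rk4".  "auto" picks velocity
    Verlet for time-independent potentials and RK4 otherwise.
    """
    if t1 <= t0:
        raise ValidationError(f"need t1 > t0, got t0={t0}, t1={t1}")
    if n_steps < 8:
        raise ValidationError(f"n_steps must be >= 8, got {n_steps}")
    if method not in ("auto", "verlet", "rk4"):
        raise ValidationError(f"unknown integrator {method!r}; use verlet, rk4 or auto")
    if method == "auto":
        method = "rk4" if chain.time_dependent else "verlet"

    n = chain.n_angles
    q0 = np.broadcast_to(np.atleast_1d(np.asarray(q0, dtype=float)), (n,)).astype(float)
    v0 = np.broadcast_to(np.atleast_1d(np.asarray(v0, dtype=float)), (n,)).astype(float)
    t = t0 + (t1 - t0) * np.arange(n_steps + 1) / n_steps
    h = (t1 - t0) / n_steps
    q = np.empty((n_steps + 1, n))
    v = np.empty((n_steps + 1, n))
    q[0], v[0] = q0, v0

    if method == "verlet":
        a = chain.acceleration(q0, t0)
        for i in range(n_steps):
            q[i + 1], v[i + 1], a = _step_verlet(chain, q[i], v[i], a, t[i], h)
            if not (np.all(np.isfinite(q[i + 1])) and np.all(np.isfinite(v[i + 1]))):
                raise IntegrationBlowupError(
                    f"non-finite state at t={t[i + 1]:.6g}", t_reached=float(t[i])
                )
    else:
        for i in range(n_steps):
            q[i + 1], v[i + 1] = _step_rk4(chain, q[i], v[i], t[i], h)
            if not (np.all(np.isfinite(q[i + 1])) and np.all(np.isfinite(v[i + 1]))):
                raise IntegrationBlowupError(
                    f"non-finite state at t={t[i + 1]:.6g}", t_reached=float(t[i])
                )

    return Trajectory(t=t, q=q, v=v, chain=chain, integrator=method)


def shoot_family(
    chain: TorsionChain,
    initial_curve: Callable[[float], tuple],
    u_grid,
    t0: float,
    t1: float,
    n_steps: int,
    method: str = "auto",
    label: str = "",
) -> TrajectoryFamily:
    """Integrate one trajectory per family parameter u.

    ``initial_curve(u)`` returns the start state (q0, v0) for parameter u.
    """
    u_grid = np.asarray(u_grid, dtype=float)
    if u_grid.ndim != 1 or u_grid.size < 3:
        raise ValidationError("u_grid needs at least 3 values")
    members = []
    for u in u_grid:
        try:
            q0, v0 = initial_curve(float(u))
            members.append(
                integrate_trajectory(chain, q0, v0, t0, t1, n_steps, method=method)
            )
        except (IntegrationBlowupError, ValidationError) as exc:
            raise FamilyIntegrationError(
                f"family member at u={u:.6g} failed: {exc}", u=float(u)
            ) from exc
    return TrajectoryFamily(u=u_grid, trajectories=tuple(members),
                            initial_curve=label)
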