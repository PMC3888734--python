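"""Seeded generators for every synthetic input the test surface needs.

Each fixture writes plain-text artifacts (YAML config, CSV tables) plus a
manifest JSON recording the spec, seed, content hashes, and the analytic
ground truth, so tests compare against the manifest instead of hard-coding
numbers twice.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .catastrophe import boltzmann_moments, normal_form_registry
from .dynamics import shoot_family
from .errors import ValidationError
from .torsion_model import CuspGerm, CuspPotential, build_chain

__all__ = ["FixtureSpec", "FIXTURE_CATALOG", "generate_fixture"]

FIXTURE_CATALOG = (
    "free_particle",
    "harmonic_focus",
    "inverted_harmonic",
    "cusp_family",
    "zeeman_toy",
    "germ_samples",
    "noisy_moments",
)

_FLOAT_FMT = "%.17g"


@dataclass(frozen=True)
class FixtureSpec:
    name: str
    parameters: dict = dc_field(default_factory=dict)
    seed: int = 0


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def _write_yaml(obj: dict, path: Path) -> None:
    path.write_text(yaml.safe_dump(obj, sort_keys=True))


def _family_frame(family) -> pd.DataFrame:
    rows = []
    n = family.chain.n_angles
    for u, traj in zip(family.u, family.trajectories):
        df = traj.to_frame()
        df.insert(0, "u", u)
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


def generate_fixture(spec: FixtureSpec, out_dir) -> dict:
    """Write the named fixture into out_dir; return its manifest."""
    if spec.name not in FIXTURE_CATALOG:
        raise ValidationError(
            f"unknown fixture {spec.name!r}; catalog: {', '.join(FIXTURE_CATALOG)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    builder = globals()[f"_fixture_{spec.name}"]
    files, truth, params = builder(spec, out)
    manifest = {
        "name": spec.name,
        "parameters": params,
        "seed": spec.seed,
        "files": {f.name: _sha256(f) for f in files},
        "truth": truth,
    }
    mpath = out / f"{spec.name}.manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


# ------------------------------------------------------------------ builders


def _scenario_config(chain_cfg, integrator, family, seed) -> dict:
    return {
        "chain": chain_cfg,
        "integrator": integrator,
        "family": family,
        "detection": {"stationarity_tol": 1.0e-3},
        "output": {"dir": "out"},
        "seed": seed,
        "log_level": "INFO",
    }


def _fixture_free_particle(spec: FixtureSpec, out: Path):
    p = {"inertia": 1.0, "v0": 0.5, "u_min": -1.0, "u_max": 1.0, "n_u": 9,
         "t0": 0.0, "t1": 2.0, "n_steps": 200, **spec.parameters}
    chain_cfg = {"n_angles": 1, "inertias": p["inertia"],
                 "potential": {"kind": "free"}}
    cfg = _scenario_config(
        chain_cfg,
        {"method": "verlet", "t0": p["t0"], "t1": p["t1"], "n_steps": p["n_steps"]},
        {"q0": "u", "v0": str(p["v0"]), "u_min": p["u_min"],
         "u_max": p["u_max"], "n_u": p["n_u"]},
        spec.seed)
    chain = build_chain(chain_cfg)
    family = shoot_family(
        chain, lambda u: (u, p["v0"]), np.linspace(p["u_min"], p["u_max"], p["n_u"]),
        p["t0"], p["t1"], p["n_steps"], label="q0=u, v0 fixed")
    cfg_path, fam_path = out / "free_particle.config.yaml", out / "free_particle.family.csv"
    _write_yaml(cfg, cfg_path)
    _write_csv(_family_frame(family), fam_path)
    truth = {"caustic": None, "conjugate_points": [],
             "envelope": None}
    return [cfg_path, fam_path], truth, p


def _fixture_harmonic_focus(spec: FixtureSpec, out: Path):
    p = {"theta0": 1.0, "u_min": -2.0, "u_max": 2.0, "n_u": 21,
         "t0": 0.0, "t1": 4.0, "n_steps": 800, **spec.parameters}
    chain_cfg = {"n_angles": 1, "inertias": 1.0,
                 "potential": {"kind": "harmonic_spring", "k": 1.0, "half_k": True}}
    cfg = _scenario_config(
        chain_cfg,
        {"method": "verlet", "t0": p["t0"], "t1": p["t1"], "n_steps": p["n_steps"]},
        {"q0": str(p["theta0"]), "v0": "u", "u_min": p["u_min"],
         "u_max": p["u_max"], "n_u": p["n_u"]},
        spec.seed)
    chain = build_chain(chain_cfg)
    family = shoot_family(
        chain, lambda u: (p["theta0"], u),
        np.linspace(p["u_min"], p["u_max"], p["n_u"]),
        p["t0"], p["t1"], p["n_steps"], label="q0 fixed, v0=u")
    cfg_path = out / "harmonic_focus.config.yaml"
    fam_path = out / "harmonic_focus.family.csv"
    _write_yaml(cfg, cfg_path)
    _write_csv(_family_frame(family), fam_path)
    truth = {
        "focus_t": float(np.pi),
        "focus_x": -p["theta0"],
        "conjugate_t": float(np.pi),
        "member_closed_form": "theta(t) = theta0*cos(t) + u*sin(t)",
    }
    return [cfg_path, fam_path], truth, p


def _fixture_inverted_harmonic(spec: FixtureSpec, out: Path):
    p = {"q0": 0.5, "v0": 0.25, "t0": 0.0, "t1": 3.0, "n_steps": 600,
         **spec.parameters}
    chain_cfg = {"n_angles": 1, "inertias": 1.0,
                 "potential": {"kind": "harmonic_spring", "k": -1.0, "half_k": True}}
    cfg = _scenario_config(
        chain_cfg,
        {"method": "verlet", "t0": p["t0"], "t1": p["t1"], "n_steps": p["n_steps"]},
        {"q0": str(p["q0"]), "v0": "u", "u_min": p["v0"] - 1.0,
         "u_max": p["v0"] + 1.0, "n_u": 9},
        spec.seed)
    from .dynamics import integrate_trajectory

    chain = build_chain(chain_cfg)
    traj = integrate_trajectory(chain, p["q0"], p["v0"], p["t0"], p["t1"],
                                p["n_steps"])
    cfg_path = out / "inverted_harmonic.config.yaml"
    traj_path = out / "inverted_harmonic.traj.csv"
    _write_yaml(cfg, cfg_path)
    _write_csv(traj.to_frame(), traj_path)
    truth = {"conjugate_points": [],
             "jacobi_solution": "xi(t) ~ sinh(t), no zeros for t > 0"}
    return [cfg_path, traj_path], truth, p


def _fixture_cusp_family(spec: FixtureSpec, out: Path):
    p = {"n_u": 61, "u_lim": 1.5, "x1_min": -1.2, "x1_max": -0.2, "n_x1": 11,
         "x2_lim": 0.8, "n_x2": 21, **spec.parameters}
    u = np.linspace(-p["u_lim"], p["u_lim"], p["n_u"])
    x1 = np.linspace(p["x1_min"], p["x1_max"], p["n_x1"])
    x2 = np.linspace(-p["x2_lim"], p["x2_lim"], p["n_x2"])
    U, X1, X2 = np.meshgrid(u, x1, x2, indexing="ij")
    S = 0.25 * U ** 4 + 0.5 * X1 * U ** 2 + X2 * U
    df = pd.DataFrame({"u": U.ravel(), "x1": X1.ravel(), "x2": X2.ravel(),
                       "S": S.ravel()})
    path = out / "cusp_family.surface.csv"
    _write_csv(df, path)
    truth = {
        "surface": "S(u; x1, x2) = u^4/4 + x1*u^2/2 + x2*u",
        "discriminant": "4*x1^3 + 27*x2^2 = 0",
        "grid": {"u": [float(u[0]), float(u[-1]), int(u.size)],
                 "x1": [float(x1[0]), float(x1[-1]), int(x1.size)],
                 "x2": [float(x2[0]), float(x2[-1]), int(x2.size)]},
    }
    return [path], truth, p


def _fixture_zeeman_toy(spec: FixtureSpec, out: Path):
    p = {"a": -1.0, "b": 0.0, "s_lim": 2.0, "n_s": 401, **spec.parameters}
    chain_cfg = {"n_angles": 1, "inertias": 1.0,
                 "potential": {"kind": "cusp", "a": p["a"], "b": p["b"]}}
    cfg_path = out / "zeeman_toy.config.yaml"
    _write_yaml({"chain": chain_cfg}, cfg_path)
    s = np.linspace(-p["s_lim"], p["s_lim"], p["n_s"])
    germ_lin = CuspGerm(a=p["a"], b=p["b"])
    germ_off = CuspGerm(a=p["a"], b=p["b"], constant_offset=True)
    df = pd.DataFrame({"theta": s, "S_linear_term": germ_lin.value(s),
                       "S_constant_offset": germ_off.value(s)})
    tab_path = out / "zeeman_toy.action.csv"
    _write_csv(df, tab_path)
    truth = {
        "critical_points": [float(r) for r in germ_lin.critical_points()],
        "discriminant": germ_lin.discriminant(),
    }
    return [cfg_path, tab_path], truth, p


def _fixture_germ_samples(spec: FixtureSpec, out: Path):
    p = {"radius": 0.5, "n_1d": 101, "n_2d": 41, **spec.parameters}
    files = []
    truth = {}
    r = p["radius"]
    s = np.linspace(-r, r, p["n_1d"])
    for entry in normal_form_registry():
        path = out / f"germ_{entry.name}.csv"
        if entry.corank == 1:
            vals = np.array([float(entry.value(si)) for si in s])
            _write_csv(pd.DataFrame({"s": s, "value": vals}), path)
        else:
            g = np.linspace(-r, r, p["n_2d"])
            G1, G2 = np.meshgrid(g, g, indexing="ij")
            vals = np.array([[float(entry.value(a, b)) for b in g] for a in g])
            _write_csv(pd.DataFrame({"s1": G1.ravel(), "s2": G2.ravel(),
                                     "value": vals.ravel()}), path)
        truth[entry.name] = {"corank": entry.corank,
                             "control_dim": entry.control_dim}
        files.append(path)
    return files, truth, p


def _fixture_noisy_moments(spec: FixtureSpec, out: Path):
    p = {"a": 2.0, "b": 0.0, "kBT": 1.0, "replicates": 100, "noise": 0.01,
         **spec.parameters}
    exact = boltzmann_moments(CuspPotential(a=p["a"], b=p["b"]), kBT=p["kBT"],
                              orders=(1, 2, 3))
    rng = np.random.default_rng(spec.seed)
    base = np.array([exact[1], exact[2], exact[3]])
    noisy = base[None, :] * (1.0 + p["noise"] * rng.standard_normal(
        (p["replicates"], 3)))
    df = pd.DataFrame(noisy, columns=["m1", "m2", "m3"])
    df.insert(0, "replicate", np.arange(p["replicates"]))
    path = out / "noisy_moments.csv"
    _write_csv(df, path)
    truth = {"a": p["a"], "b": p["b"], "kBT": p["kBT"],
             "exact_moments": [float(v) for v in base]}
    return [path], truth, p
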