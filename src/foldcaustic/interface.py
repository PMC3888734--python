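"""Run configuration, scenario pipeline, and structured logging.

A scenario config is a YAML file with sections [chain], [integrator],
[family], [detection], [output] plus top-level ``seed`` and ``log_level``.
Unknown keys are rejected.  ``run_scenario`` executes
shoot_family -> family_action_surface -> detect_caustic ->
saddle_check_beyond (-> classify_germ around caustics, opt-in) and writes a
versioned JSON report.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .caustics import detect_caustic, family_action_surface, saddle_check_beyond
from .catastrophe import classify_germ
from .dynamics import shoot_family
from .errors import FoldCausticError, ValidationError
from .torsion_model import build_chain

__all__ = ["RunConfig", "load_config", "run_scenario", "setup_logging"]

REPORT_SCHEMA_VERSION = 1

log = logging.getLogger("foldcaustic")


def setup_logging(level: str = "INFO") -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter(
        "level=%(levelname)s stage=%(name)s msg=%(message)s"))
    root = logging.getLogger("foldcaustic")
    root.handlers[:] = [handler]
    root.setLevel(getattr(logging, str(level).upper(), logging.INFO))


_SECTION_KEYS = {
    "chain": None,  # validated by build_chain
    "integrator": {"method", "t0", "t1", "n_steps"},
    "family": {"q0", "v0", "u_min", "u_max", "n_u"},
    "detection": {"tol_first", "tol_second", "stationarity_tol", "classify"},
    "output": {"dir"},
}
_TOP_KEYS = set(_SECTION_KEYS) | {"seed", "log_level"}


@dataclass(frozen=True)
class RunConfig:
    chain: dict
    integrator: dict
    family: dict
    detection: dict = field(default_factory=dict)
    output: dict = field(default_factory=lambda: {"dir": "out"})
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def _validate_section(name: str, section, required=()) -> dict:
    if section is None:
        raise ValidationError(f"config missing required [{name}] section")
    if not isinstance(section, dict):
        raise ValidationError(f"[{name}] section must be a mapping")
    allowed = _SECTION_KEYS[name]
    if allowed is not None:
        unknown = sorted(set(section) - allowed)
        if unknown:
            raise ValidationError(f"unknown keys in [{name}] section: {unknown}")
        missing = sorted(set(required) - set(section))
        if missing:
            raise ValidationError(f"[{name}] section missing keys: {missing}")
    return dict(section)


def parse_config(data: dict) -> RunConfig:
    if not isinstance(data, dict):
        raise ValidationError("config root must be a mapping")
    unknown = sorted(set(data) - _TOP_KEYS)
    if unknown:
        raise ValidationError(f"unknown top-level config keys: {unknown}")
    return RunConfig(
        chain=_validate_section("chain", data.get("chain")),
        integrator=_validate_section("integrator", data.get("integrator"),
                                     required=("t0", "t1", "n_steps")),
        family=_validate_section("family", data.get("family"),
                                 required=("q0", "v0", "u_min", "u_max", "n_u")),
        detection=_validate_section("detection", data.get("detection", {})),
        output=_validate_section("output", data.get("output", {"dir": "out"})),
        seed=int(data.get("seed", 0)),
        log_level=str(data.get("log_level", "INFO")),
    )


def load_config(path) -> RunConfig:
    """Parse and validate a scenario config file (YAML key-value sections)."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    cfg = parse_config(data)
    # losslessness check: the config must round-trip through its dict form
    if parse_config(cfg.to_dict()) != cfg:
        raise ValidationError("config does not round-trip losslessly")
    return cfg


def _curve_from_exprs(q0_spec, v0_spec, n_angles: int):
    """Build u -> (q0, v0) from expression strings (or lists of them) in u."""
    import sympy as sp

    u = sp.symbols("u")

    def compile_one(spec):
        exprs = spec if isinstance(spec, (list, tuple)) else [spec] * n_angles
        if len(exprs) != n_angles:
            raise ValidationError(
                f"initial-curve expression list must have length {n_angles}")
        fns = []
        for e in exprs:
            expr = sp.sympify(e)
            if expr.free_symbols - {u}:
                raise ValidationError(
                    f"initial-curve expression {e!r} may only depend on 'u'")
            fns.append(sp.lambdify(u, expr, modules="numpy"))
        return fns

    qf, vf = compile_one(q0_spec), compile_one(v0_spec)

    def curve(uv: float):
        return (np.array([float(f(uv)) for f in qf]),
                np.array([float(f(uv)) for f in vf]))

    return curve


def run_scenario(config: RunConfig, out_dir=None) -> dict:
    """Execute the full pipeline described by the config; write report JSON."""
    out = Path(out_dir if out_dir is not None else config.output.get("dir", "out"))
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "tool_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": [],
    }
    report_path = out / "report.json"

    def fail(stage: str, exc: Exception):
        report["failed_stage"] = stage
        report["error"] = str(exc)
        report_path.write_text(json.dumps(report, indent=2, default=str) + "\n")
        raise FoldCausticError(f"stage {stage!r} failed: {exc}") from exc

    stage = "build_chain"
    try:
        chain = build_chain(config.chain)
        report["stages"].append(stage)
        log.info("stage=%s n_angles=%d", stage, chain.n_angles)

        stage = "shoot_family"
        fam = config.family
        u_grid = np.linspace(float(fam["u_min"]), float(fam["u_max"]),
                             int(fam["n_u"]))
        curve = _curve_from_exprs(fam["q0"], fam["v0"], chain.n_angles)
        integ = config.integrator
        family = shoot_family(
            chain, curve, u_grid, float(integ["t0"]), float(integ["t1"]),
            int(integ["n_steps"]), method=integ.get("method", "auto"),
            label=f"q0={fam['q0']!r} v0={fam['v0']!r}")
        report["stages"].append(stage)
        log.info("stage=%s n_members=%d", stage, u_grid.size)

        stage = "family_action_surface"
        det = config.detection
        surface = family_action_surface(
            family, chain,
            stationarity_tol=float(det.get("stationarity_tol", 1e-3)))
        report["stages"].append(stage)

        stage = "detect_caustic"
        caustics = detect_caustic(surface,
                                  tol_first=det.get("tol_first"),
                                  tol_second=det.get("tol_second"))
        report["stages"].append(stage)
        report["caustics"] = [
            {"t": cp.t, "x": list(cp.x), "u": cp.u, "type": cp.kind}
            for cp in caustics
        ]
        report["no_caustic_detected"] = len(caustics) == 0
        log.info("stage=%s n_caustics=%d", stage, len(caustics))

        stage = "saddle_check_beyond"
        checks = saddle_check_beyond(surface, caustics)
        report["stages"].append(stage)
        report["saddle_checks"] = [
            {k: v for k, v in chk.items() if k != "caustic"} for chk in checks
        ]

        if det.get("classify"):
            stage = "classify_germ"
            report["classifications"] = _classify_caustics(surface, caustics)
            report["stages"].append(stage)
    except FoldCausticError as exc:
        fail(stage, exc)
    except Exception as exc:  # pragma: no cover - defensive
        fail(stage, exc)

    report_path.write_text(json.dumps(report, indent=2, default=str) + "\n")
    log.info("stage=done report=%s", report_path)
    return report


def _classify_caustics(surface, caustics) -> list[dict]:
    out = []
    for cp in caustics:
        j = int(np.argmin(np.abs(surface.t - cp.t)))
        i = int(np.argmin(np.abs(surface.u - cp.u)))
        lo, hi = max(i - 5, 0), min(i + 6, surface.u.size)
        s = surface.u[lo:hi] - surface.u[i]
        f = surface.S[lo:hi, j] - surface.S[i, j]
        try:
            res = classify_germ((s, f), state_dim=1, grad_tol=1e-2,
                                residual_tol=1e-2)
            out.append({"t": cp.t, "u": cp.u, "match": res.match,
                        "residual": res.residual})
        except ValidationError as exc:
            out.append({"t": cp.t, "u": cp.u, "match": "unclassified",
                        "reason": str(exc)})
    return out
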