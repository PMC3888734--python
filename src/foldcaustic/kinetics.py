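"""Barrier-crossing rate law, denaturant chevron curves, contact-order scaling.

rate = gamma * exp(-dG_ts / kBT).  The chevron substitutes a transition-state
free energy linear in denaturant concentration, dG_ts(C) = dG0_ts * C, so
log(rate) is exactly linear in C with slope -dG0_ts/kBT.  The contact-order
hook makes the folding time proportional to contact order: the effective
prefactor is gamma_scale / CO**exponent with exponent 1 by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "RateModel",
    "folding_rate",
    "chevron_curve",
    "rate_vs_contact_order",
]


@dataclass(frozen=True)
class RateModel:
    """Transition-state rate parameters (energies in units of kBT by default)."""

    gamma: float
    dG_ts: float = 0.0
    kBT: float = 1.0
    dG0_ts: float = 0.0

    def __post_init__(self):
        if self.gamma <= 0:
            raise ValidationError(f"gamma must be > 0, got {self.gamma}")
        if self.kBT <= 0:
            raise ValidationError(f"kBT must be > 0, got {self.kBT}")


def folding_rate(model: RateModel, dG_ts: float | None = None) -> float:
    """rate = gamma * exp(-dG_ts / kBT)."""
    dg = model.dG_ts if dG_ts is None else dG_ts
    return float(model.gamma * np.exp(-dg / model.kBT))


def chevron_curve(model: RateModel, concentrations) -> pd.DataFrame:
    """Folding-arm chevron: columns C, rate, log_rate with dG_ts = dG0_ts * C."""
    C = np.asarray(concentrations, dtype=float)
    if C.ndim != 1 or C.size == 0:
        raise ValidationError("concentrations must be a non-empty 1-D array")
    if np.any(C < 0):
        raise ValidationError("concentrations must be nonnegative")
    if np.any(np.diff(C) < 0):
        raise ValidationError("concentrations must be sorted ascending")
    log_rate = np.log(model.gamma) - model.dG0_ts * C / model.kBT
    return pd.DataFrame({"C": C, "rate": np.exp(log_rate), "log_rate": log_rate})


def rate_vs_contact_order(
    gamma_scale: float,
    contact_orders,
    dG_ts: float = 0.0,
    kBT: float = 1.0,
    exponent: float = 1.0,
) -> pd.DataFrame:
    """Rates with prefactor gamma_scale / CO**exponent (folding time ~ CO)."""
    co = np.asarray(contact_orders, dtype=float)
    if np.any(co <= 0):
        raise ValidationError("contact orders must be > 0")
    if gamma_scale <= 0:
        raise ValidationError(f"gamma_scale must be > 0, got {gamma_scale}")
    gamma = gamma_scale / co ** exponent
    rate = gamma * np.exp(-dG_ts / kBT)
    return pd.DataFrame({"contact_order": co, "gamma": gamma, "rate": rate,
                         "folding_time": 1.0 / rate})
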