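"""Derived homeostatic quantities and the Ki67-only residence approximation.

From the fitted rates (mu, rho, beta) the biologically interpretable scales
follow in closed form: mean residence time 1/delta with delta = rho + mu,
mean interdivision time 1/rho, daily replacement 100*mu (%/day) and the
clonal half-life ln(2)/(delta - rho) — the time for a labelled cohort and its
descendants to halve in number.  When loss does not outpace self-renewal
(delta <= rho) a cohort does not decay and the half-life is undefined.

A model-light consistency check: at steady state, the observed Ki67-high
frequency k and the replacement rate mu alone bound the residence time,
depending on whether immigrants arrive Ki67-low (quiescent) or Ki67-high
(division-linked).  Solving the equilibrium Ki67 balance
``k = (mu*h + 2*rho) / (beta + 2*rho + mu)`` for rho at h = 0 and h = 1:

    rho_quiescent       = k * (beta + mu) / (2 * (1 - k))
    rho_division_linked = max(0, (k*beta - mu*(1-k)) / (2 * (1 - k)))

and the residence bounds are 1/(rho_q + mu) (lower) and 1/(rho_d + mu)
(upper).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DerivedEstimates",
    "clonal_half_life",
    "ki67_residence_bounds",
    "DEFAULT_BETA",
]

#: fallback Ki67-high reversion rate when no fitted value is available:
#: Ki67 stays high for ~3-4 days after division, midpoint 3.5 days.
DEFAULT_BETA = 1.0 / 3.5


def clonal_half_life(rho: float, delta: float) -> float:
    """Time (days) for a labelled cohort and its progeny to halve: ln2/(delta-rho).

    Returns ``math.inf`` when delta <= rho (non-decaying cohort).
    """
    if rho < 0:
        raise ValueError("rho must be >= 0")
    if delta <= 0:
        raise ValueError("delta must be > 0")
    if delta <= rho:
        return math.inf
    return math.log(2.0) / (delta - rho)


@dataclass(frozen=True)
class DerivedEstimates:
    """Interpretable scales implied by one (mu, rho) rate pair."""

    residence_days: float
    interdivision_days: float
    replacement_pct_per_day: float
    clonal_half_life_days: float
    non_decaying: bool

    @classmethod
    def from_rates(cls, mu: float, rho: float) -> "DerivedEstimates":
        if mu < 0 or rho < 0:
            raise ValueError("rates must be non-negative")
        delta = mu + rho
        if delta <= 0:
            raise ValueError("mu + rho must be positive")
        hl = clonal_half_life(rho, delta)
        return cls(
            residence_days=1.0 / delta,
            interdivision_days=(1.0 / rho) if rho > 0 else math.inf,
            replacement_pct_per_day=100.0 * mu,
            clonal_half_life_days=hl,
            non_decaying=not math.isfinite(hl),
        )


def ki67_residence_bounds(k: float, mu: float, beta: float = DEFAULT_BETA):
    """Bounds (lower_days, upper_days) on mean residence time from Ki67 alone.

    Parameters
    ----------
    k : float
        Observed steady-state Ki67-high fraction of the target, in (0, 1).
    mu : float
        Daily fractional replacement rate (day^-1), >= 0.
    beta : float
        Ki67-high reversion rate (day^-1); defaults to 1/3.5.

    The lower bound assumes quiescent immigrants (all tissue Ki67 comes from
    local division, so division must be fast); the upper bound assumes
    division-linked immigrants (immigration supplies Ki67-high cells, so local
    division can be slow).  When even rho = 0 cannot bring the division-linked
    balance down to k, that branch is floored at rho = 0 and the upper bound
    becomes 1/mu.
    """
    if not 0.0 < k < 1.0:
        raise ValueError("k must lie strictly inside (0, 1)")
    if mu < 0:
        raise ValueError("mu must be >= 0")
    if beta <= 0:
        raise ValueError("beta must be > 0")
    rho_q = k * (beta + mu) / (2.0 * (1.0 - k))
    rho_d = max(0.0, (k * beta - mu * (1.0 - k)) / (2.0 * (1.0 - k)))
    lower = 1.0 / (rho_q + mu)
    upper = 1.0 / (rho_d + mu) if (rho_d + mu) > 0 else math.inf
    return lower, upper


def summarize_derived(mu_draws, rho_draws, beta_draws=None) -> dict:
    """Posterior summaries (median, 2.5%, 97.5%) of the derived scales."""
    mu = np.asarray(mu_draws, dtype=float)
    rho = np.asarray(rho_draws, dtype=float)
    delta = mu + rho
    out = {
        "residence_days": 1.0 / delta,
        "interdivision_days": np.where(rho > 0, 1.0 / np.maximum(rho, 1e-300), np.inf),
        "replacement_pct_per_day": 100.0 * mu,
        "clonal_half_life_days": np.where(mu > 0, np.log(2.0) / np.maximum(mu, 1e-300), np.inf),
    }
    if beta_draws is not None:
        out["ki67hi_duration_days"] = 1.0 / np.asarray(beta_draws, dtype=float)
    summary = {}
    for name, draws in out.items():
        finite = draws[np.isfinite(draws)]
        summary[name] = {
            "median": float(np.median(finite)) if finite.size else math.nan,
            "lo95": float(np.percentile(finite, 2.5)) if finite.size else math.nan,
            "hi95": float(np.percentile(finite, 97.5)) if finite.size else math.nan,
            "n_non_decaying": int(np.sum(~np.isfinite(draws))),
        }
    return summary
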