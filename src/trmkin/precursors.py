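"""Empirical descriptors of precursor label frequencies over time.

The candidate precursors of tissue CD4 T_RM (lymph-node naive, central- and
effector-memory cells, and the local CD69- compartment) are not modelled
mechanistically; their YFP+ and mTom+ frequencies act as boundary conditions
for the target's label kinetics.  Each curve is a single-exponential
relaxation on the log-odds scale,

    f(t) = expit(a + b * exp(-c * (t - t0))),

which is bounded in (0, 1), monotone whenever b*c != 0, and covers both the
observed patterns: mTom frequencies that decline several-fold over a year
(b > 0, c > 0) and YFP frequencies that stay essentially flat (b ~ 0).  The
descriptor parameters are estimated jointly with the target model so their
uncertainty propagates into the kinetic estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = ["PrecursorDescriptor", "eval_precursor"]

DEFAULT_T0 = 5.0  # days post-tamoxifen at which analysis starts


@dataclass(frozen=True)
class PrecursorDescriptor:
    """One precursor label curve: ``expit(a + b * exp(-c * (t - t0)))``.

    ``a`` is the asymptotic log-odds, ``a + b`` the log-odds at ``t0`` and
    ``c`` (day^-1) the relaxation rate towards the asymptote.
    """

    a: float
    b: float
    c: float
    label: str = "mTom"  # "YFP" or "mTom"
    population: str = ""
    t0: float = DEFAULT_T0

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"descriptor parameter {name} must be finite")
        if self.c < 0:
            raise ValueError(f"relaxation rate c must be >= 0, got {self.c}")
        if self.label not in ("YFP", "mTom"):
            raise ValueError(f"label must be 'YFP' or 'mTom', got {self.label!r}")

    def __call__(self, t):
        return eval_precursor(self, t)


def eval_precursor(desc: PrecursorDescriptor, t):
    """Evaluate the descriptor at time(s) ``t`` (days, >= t0)."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < desc.t0):
        raise ValueError(f"descriptor evaluated before its time origin t0={desc.t0}")
    val = expit(desc.a + desc.b * np.exp(-desc.c * (t_arr - desc.t0)))
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(val)
    return val
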