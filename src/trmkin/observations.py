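"""Observation schema and binomial likelihood for fate-reporter count data.

Each record is one flow-cytometry readout from one mouse at one time point:
``n_pos`` label-positive cells among ``n_total`` sampled cells of a given
tissue/subset, for one of four channels.  The mTom channel exists only in the
CD4-reporter strain (Cd4FR); the YFP and conditional-Ki67 channels only in the
division-reporter strain (Ki67DIVN).  Counts are modelled as binomial draws
around the model-predicted fraction, which both captures the sample-size
dependent noise of flow data and yields the per-record log-likelihood terms
needed for PSIS-LOO model comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "STRAINS",
    "TISSUES",
    "SUBSETS",
    "CHANNELS",
    "COLUMNS",
    "ObservationRecord",
    "pointwise_loglik",
    "binomial_loglik",
    "filter_fit_window",
    "validate_table",
    "read_observation_table",
    "write_observation_table",
]

logger = logging.getLogger(__name__)

STRAINS = ("Cd4FR", "Ki67DIVN")
TISSUES = ("skin", "LP", "LN")
SUBSETS = ("EM", "Trm69pos", "CD69neg", "naive", "CM", "TEM")
CHANNELS = (
    "mtom_pos",
    "yfp_pos",
    "ki67hi_given_yfp_pos",
    "ki67hi_given_yfp_neg",
)
#: channels observable in each reporter strain
STRAIN_CHANNELS = {
    "Cd4FR": ("mtom_pos",),
    "Ki67DIVN": ("yfp_pos", "ki67hi_given_yfp_pos", "ki67hi_given_yfp_neg"),
}
#: default chase windows (days post-tamoxifen) per strain
CHASE_WINDOWS = {"Ki67DIVN": 63.0, "Cd4FR": 399.0}

COLUMNS = ["mouse_id", "strain", "t_days", "tissue", "subset", "channel", "n_pos", "n_total"]

#: probability clamp for the binomial likelihood (0/1 predictions stay finite)
LIK_EPS = 1e-6

FIT_WINDOW_START = 5.0  # reporter induction completes by day 5; earlier data unused


@dataclass(frozen=True)
class ObservationRecord:
    """One per-mouse count observation."""

    mouse_id: str
    strain: str
    t_days: float
    tissue: str
    subset: str
    channel: str
    n_pos: int
    n_total: int

    def __post_init__(self) -> None:
        if self.strain not in STRAINS:
            raise ValueError(f"unknown strain {self.strain!r}")
        if self.tissue not in TISSUES:
            raise ValueError(f"unknown tissue {self.tissue!r}")
        if self.subset not in SUBSETS:
            raise ValueError(f"unknown subset {self.subset!r}")
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.channel not in STRAIN_CHANNELS[self.strain]:
            raise ValueError(
                f"channel {self.channel!r} is not observable in strain {self.strain!r}"
            )
        if self.t_days < 0:
            raise ValueError("t_days must be >= 0")
        if self.n_total <= 0:
            raise ValueError("n_total must be a positive integer")
        if not 0 <= self.n_pos <= self.n_total:
            raise ValueError("n_pos must satisfy 0 <= n_pos <= n_total")


def binomial_loglik(n_pos, n_total, p, eps: float = LIK_EPS):
    """Binomial log-pmf with the success probability clamped to [eps, 1-eps].

    Vectorised over all arguments; always finite for valid counts.
    """
    n_pos = np.asarray(n_pos, dtype=float)
    n_total = np.asarray(n_total, dtype=float)
    p = np.clip(np.asarray(p, dtype=float), eps, 1.0 - eps)
    if np.any(n_total <= 0):
        raise ValueError("n_total must be positive")
    if np.any((n_pos < 0) | (n_pos > n_total)):
        raise ValueError("n_pos must lie in [0, n_total]")
    return (
        gammaln(n_total + 1.0)
        - gammaln(n_pos + 1.0)
        - gammaln(n_total - n_pos + 1.0)
        + n_pos * np.log(p)
        + (n_total - n_pos) * np.log1p(-p)
    )


def pointwise_loglik(record: ObservationRecord, predicted_fraction: float) -> float:
    """Log-likelihood contribution of one record at the model-predicted fraction."""
    if not 0.0 <= predicted_fraction <= 1.0:
        raise ValueError("predicted_fraction must lie in [0, 1]")
    return float(binomial_loglik(record.n_pos, record.n_total, predicted_fraction))


def filter_fit_window(records, t_min: float = FIT_WINDOW_START):
    """Drop observations taken before the analysis window opens (default day 5).

    Reporter expression is still being induced before day 5 post-tamoxifen, so
    those points do not reflect cellular dynamics.  Accepts and returns either
    a DataFrame or a list of :class:`ObservationRecord`, preserving order.
    """
    if isinstance(records, pd.DataFrame):
        kept = records[records["t_days"] >= t_min]
        n_removed = len(records) - len(kept)
        if n_removed:
            logger.info("filter_fit_window: removed %d records before day %g", n_removed, t_min)
        return kept.reset_index(drop=True)
    kept_list = [r for r in records if r.t_days >= t_min]
    n_removed = len(records) - len(kept_list)
    if n_removed:
        logger.info("filter_fit_window: removed %d records before day %g", n_removed, t_min)
    return kept_list


def validate_table(df: pd.DataFrame, chase_windows=CHASE_WINDOWS) -> list[tuple[int, str]]:
    """Schema-check a tidy observation table; return (row, message) violations."""
    problems: list[tuple[int, str]] = []
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        return [(-1, f"missing columns: {missing}")]
    for i, row in df.iterrows():
        if row["strain"] not in STRAINS:
            problems.append((i, f"unknown strain {row['strain']!r}"))
            continue
        if row["tissue"] not in TISSUES:
            problems.append((i, f"unknown tissue {row['tissue']!r}"))
        if row["subset"] not in SUBSETS:
            problems.append((i, f"unknown subset {row['subset']!r}"))
        if row["channel"] not in CHANNELS:
            problems.append((i, f"unknown channel {row['channel']!r}"))
        elif row["channel"] not in STRAIN_CHANNELS[row["strain"]]:
            problems.append(
                (i, f"channel {row['channel']!r} not observable in strain {row['strain']!r}")
            )
        if row["t_days"] < 0:
            problems.append((i, "t_days < 0"))
        elif row["t_days"] > chase_windows.get(row["strain"], np.inf):
            problems.append((i, f"t_days beyond {row['strain']} chase window"))
        if row["n_total"] <= 0:
            problems.append((i, "n_total must be positive"))
        elif not 0 <= row["n_pos"] <= row["n_total"]:
            problems.append((i, "n_pos outside [0, n_total]"))
    return problems


def read_observation_table(path, validate: bool = True) -> pd.DataFrame:
    """Read a tidy observation CSV; optionally reject schema violations."""
    df = pd.read_csv(path, dtype={"mouse_id": str})
    if validate:
        problems = validate_table(df)
        if problems:
            msg = "; ".join(f"row {i}: {m}" for i, m in problems[:20])
            raise ValueError(f"invalid observation table {path}: {msg}")
    return df


def write_observation_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=COLUMNS)
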