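"""Synthetic fate-reporter datasets with the structure of the real study.

The experiment this emulates: a single tamoxifen pulse at day 0 marks cohorts
of cells in two reporter strains; mice are then sacrificed at staggered times
(analysis starting at day 5, once reporter induction is complete) and label
frequencies are measured by flow cytometry in tissue targets and candidate
precursors.  The division-reporter (Ki67DIVN) cohort is chased for 9 weeks,
the CD4-reporter (Cd4FR) cohort for 57 weeks.  Populations are assumed to be
at steady state throughout.

For each mouse and channel, a sampled-cell count is drawn LogNormal around
~2000 cells (floored at 20) and the label-positive count is binomial at the
model-predicted fraction, so sampling noise has the size-dependent structure
of real flow data.  The generating parameters ("truth") are serialised next
to every dataset to support parameter-recovery studies.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.special import logit

from .kinetics import (
    KineticParameters,
    LabelStateVector,
    RecruitmentMode,
    solve_label_trajectories,
)
from .observations import COLUMNS
from .precursors import PrecursorDescriptor, DEFAULT_T0

__all__ = ["StudyDesign", "TruthRecord", "generate_dataset", "default_truths"]


@dataclass(frozen=True)
class StudyDesign:
    """Mouse numbers, chase windows and sampling depths of one experiment."""

    n_mice_ki67divn: int = 31
    n_mice_cd4fr: int = 36
    window_ki67divn: tuple[float, float] = (DEFAULT_T0, 63.0)
    window_cd4fr: tuple[float, float] = (DEFAULT_T0, 399.0)
    mice_per_timepoint: int = 3  # quasi-uniform schedule, 2-4 mice per point
    cells_logmean: float = math.log(2000.0)
    cells_logsd: float = 0.5
    min_cells: int = 20

    def schedule(self, strain: str) -> np.ndarray:
        """Integer-day sacrifice times, one entry per mouse, quasi-uniform."""
        if strain == "Ki67DIVN":
            n, (lo, hi) = self.n_mice_ki67divn, self.window_ki67divn
        elif strain == "Cd4FR":
            n, (lo, hi) = self.n_mice_cd4fr, self.window_cd4fr
        else:
            raise ValueError(f"unknown strain {strain!r}")
        if n == 0:
            return np.array([], dtype=float)
        n_points = max(1, int(np.ceil(n / self.mice_per_timepoint)))
        days = np.unique(np.round(np.linspace(lo, hi, n_points)))
        return days[np.arange(n) % days.size]


@dataclass
class TruthRecord:
    """Generating parameters of one synthetic dataset."""

    name: str
    params: KineticParameters
    initial: LabelStateVector
    precursor_yfp: PrecursorDescriptor
    precursor_mtom: PrecursorDescriptor
    target_tissue: str = "skin"
    target_subset: str = "Trm69pos"
    precursor_tissue: str = "skin"
    precursor_subset: str = "CD69neg"

    def to_json(self) -> str:
        d = {
            "name": self.name,
            "params": {
                "mu": self.params.mu,
                "rho": self.params.rho,
                "beta": self.params.beta,
                "mode": self.params.mode.value,
                "precursor_ki67": self.params.precursor_ki67,
            },
            "initial": asdict(self.initial),
            "precursor_yfp": asdict(self.precursor_yfp),
            "precursor_mtom": asdict(self.precursor_mtom),
            "target_tissue": self.target_tissue,
            "target_subset": self.target_subset,
            "precursor_tissue": self.precursor_tissue,
            "precursor_subset": self.precursor_subset,
        }
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthRecord":
        d = json.loads(text)
        return cls(
            name=d["name"],
            params=KineticParameters(**d["params"]),
            initial=LabelStateVector(**d["initial"]),
            precursor_yfp=PrecursorDescriptor(**d["precursor_yfp"]),
            precursor_mtom=PrecursorDescriptor(**d["precursor_mtom"]),
            target_tissue=d["target_tissue"],
            target_subset=d["target_subset"],
            precursor_tissue=d["precursor_tissue"],
            precursor_subset=d["precursor_subset"],
        )


def default_truths() -> dict[str, TruthRecord]:
    """Presets encoding the favoured models of skin and LP CD69+ T_RM.

    ``skin_trm``: replaced at 2%/day via a division-linked transition from the
    local CD69- compartment, dividing every 7 weeks -> residence ~24.5 days.
    ``lp_trm``: replaced at 5.5%/day from lymph-node effector-memory cells
    entering quiescent, dividing every 9 weeks -> residence ~14 days.
    Precursor YFP curves are flat; mTom curves decline ~8-fold over a year.
    """
    t0 = DEFAULT_T0
    mtom_desc = lambda pop, hi, lo: PrecursorDescriptor(  # noqa: E731
        a=float(logit(lo)), b=float(logit(hi) - logit(lo)), c=0.012,
        label="mTom", population=pop, t0=t0,
    )
    yfp_flat = lambda pop, level: PrecursorDescriptor(  # noqa: E731
        a=float(logit(level)), b=0.0, c=0.01, label="YFP", population=pop, t0=t0,
    )
    skin = TruthRecord(
        name="skin_trm",
        params=KineticParameters(
            mu=0.02, rho=1.0 / 49.0, beta=1.0 / 3.0,
            mode=RecruitmentMode.DIVISION_LINKED,
        ),
        initial=LabelStateVector.from_marginals(
            yfp=0.20, ki67_in_yfp_pos=0.55, ki67_in_yfp_neg=0.12, mtom=0.55
        ),
        precursor_yfp=yfp_flat("CD69neg-skin", 0.35),
        precursor_mtom=mtom_desc("CD69neg-skin", 0.45, 0.055),
        target_tissue="skin",
        precursor_tissue="skin",
        precursor_subset="CD69neg",
    )
    lp = TruthRecord(
        name="lp_trm",
        params=KineticParameters(
            mu=0.055, rho=1.0 / 63.0, beta=1.0 / 3.0,
            mode=RecruitmentMode.QUIESCENT,
        ),
        initial=LabelStateVector.from_marginals(
            yfp=0.20, ki67_in_yfp_pos=0.50, ki67_in_yfp_neg=0.08, mtom=0.60
        ),
        precursor_yfp=yfp_flat("TEM-LN", 0.35),
        precursor_mtom=mtom_desc("TEM-LN", 0.50, 0.06),
        target_tissue="LP",
        target_subset="Trm69pos",
        precursor_tissue="LN",
        precursor_subset="TEM",
    )
    return {"skin_trm": skin, "lp_trm": lp}


def _draw_counts(rng: np.random.Generator, n: int, design: StudyDesign) -> np.ndarray:
    raw = rng.lognormal(design.cells_logmean, design.cells_logsd, size=n)
    return np.maximum(np.round(raw), design.min_cells).astype(int)


def generate_dataset(
    truth: TruthRecord, design: StudyDesign, seed: int
) -> pd.DataFrame:
    """Simulate one two-strain study; returns a tidy observation table.

    Deterministic given (truth, design, seed).
    """
    rng = np.random.default_rng(seed)
    rows: list[dict] = []

    # --- division-reporter cohort: YFP and conditional Ki67 channels -------
    days_kd = design.schedule("Ki67DIVN")
    if days_kd.size:
        times = np.unique(days_kd)
        traj = solve_label_trajectories(
            truth.params,
            truth.precursor_yfp,
            truth.precursor_mtom,
            None,
            truth.initial,
            np.concatenate(([DEFAULT_T0], times)) if times[0] != DEFAULT_T0 else times,
        )
        keep = np.isin(traj.times, times)
        t_idx = {t: i for i, t in enumerate(traj.times[keep])}
        yfp = traj.yfp[keep]
        kp = traj.ki67hi_given_yfp_pos[keep]
        kn = traj.ki67hi_given_yfp_neg[keep]
        prec_yfp = truth.precursor_yfp(times)
        for j, day in enumerate(days_kd):
            i = t_idx[day]
            mouse = f"KD{j + 1:03d}"
            specs = [
                (truth.target_tissue, truth.target_subset, "yfp_pos", yfp[i]),
                (truth.target_tissue, truth.target_subset, "ki67hi_given_yfp_pos", kp[i]),
                (truth.target_tissue, truth.target_subset, "ki67hi_given_yfp_neg", kn[i]),
                (truth.precursor_tissue, truth.precursor_subset, "yfp_pos",
                 np.atleast_1d(prec_yfp)[np.searchsorted(times, day)]),
            ]
            n_tot = _draw_counts(rng, len(specs), design)
            for (tissue, subset, channel, p), nt in zip(specs, n_tot):
                rows.append(
                    dict(
                        mouse_id=mouse, strain="Ki67DIVN", t_days=float(day),
                        tissue=tissue, subset=subset, channel=channel,
                        n_pos=int(rng.binomial(nt, float(p))), n_total=int(nt),
                    )
                )

    # --- CD4-reporter cohort: mTom channel ---------------------------------
    days_cf = design.schedule("Cd4FR")
    if days_cf.size:
        times = np.unique(days_cf)
        traj = solve_label_trajectories(
            truth.params,
            truth.precursor_yfp,
            truth.precursor_mtom,
            None,
            truth.initial,
            np.concatenate(([DEFAULT_T0], times)) if times[0] != DEFAULT_T0 else times,
        )
        keep = np.isin(traj.times, times)
        t_idx = {t: i for i, t in enumerate(traj.times[keep])}
        mtom = traj.mtom[keep]
        prec_mtom = truth.precursor_mtom(times)
        for j, day in enumerate(days_cf):
            i = t_idx[day]
            mouse = f"CF{j + 1:03d}"
            specs = [
                (truth.target_tissue, truth.target_subset, "mtom_pos", mtom[i]),
                (truth.precursor_tissue, truth.precursor_subset, "mtom_pos",
                 np.atleast_1d(prec_mtom)[np.searchsorted(times, day)]),
            ]
            n_tot = _draw_counts(rng, len(specs), design)
            for (tissue, subset, channel, p), nt in zip(specs, n_tot):
                rows.append(
                    dict(
                        mouse_id=mouse, strain="Cd4FR", t_days=float(day),
                        tissue=tissue, subset=subset, channel=channel,
                        n_pos=int(rng.binomial(nt, float(p))), n_total=int(nt),
                    )
                )

    return pd.DataFrame(rows, columns=COLUMNS)
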