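"""Ranking candidate (precursor x recruitment-mode) models by PSIS-LOO.

Each candidate fit of one target population is scored by its leave-one-out
expected log predictive density (elpd), estimated with Pareto-smoothed
importance sampling over the stored per-record log-likelihoods, and the
candidates' relative support is summarised as weights that sum to one.
Following the definition of the weights as a summary of out-of-sample
prediction error *of the target's label kinetics*, only the target
population's channels enter the pointwise terms; precursor-descriptor records
are excluded because candidates share precursor data unequally.

Weights default to stacking of predictive distributions; pseudo-BMA+ with a
Bayesian bootstrap is available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import arviz as az

from .inference import FitResult

__all__ = ["LooResult", "compute_loo", "model_weights", "compare_candidates"]

PARETO_K_WARN = 0.7


@dataclass(frozen=True)
class LooResult:
    elpd: float
    se: float
    pareto_k: np.ndarray
    n_high_k: int
    n_records: int


def _idata_from_matrix(ll: np.ndarray) -> az.InferenceData:
    """Wrap a (chains, draws, records) or (draws, records) matrix for arviz."""
    ll = np.asarray(ll, dtype=float)
    if ll.ndim == 2:
        ll = ll[None, :, :]
    if ll.ndim != 3:
        raise ValueError("log-likelihood matrix must be 2- or 3-dimensional")
    return az.from_dict(log_likelihood={"obs": ll})


def _elpd_data(idata: az.InferenceData):
    """az.loo on an InferenceData; relative efficiency 1 when only a
    log-likelihood group is present (e.g. raw matrices)."""
    reff = None if hasattr(idata, "posterior") else 1.0
    return az.loo(idata, pointwise=True, reff=reff)


def loo_from_matrix(ll: np.ndarray) -> LooResult:
    """PSIS-LOO elpd from a pointwise log-likelihood matrix."""
    if ll.shape[-1] < 2:
        raise ValueError("need at least 2 records for LOO")
    res = _elpd_data(_idata_from_matrix(ll))
    k = np.asarray(res.pareto_k)
    return LooResult(
        elpd=float(res.elpd_loo),
        se=float(res.se),
        pareto_k=k,
        n_high_k=int(np.sum(k > PARETO_K_WARN)),
        n_records=int(ll.shape[-1]),
    )


def compute_loo(fit: FitResult, target_only: bool = True) -> LooResult:
    """PSIS-LOO for one fit, restricted by default to target-channel records."""
    ll = fit.pointwise_loglik
    if target_only:
        ll = ll[:, :, fit.records["is_target"].to_numpy()]
    return loo_from_matrix(ll)


def model_weights(
    candidates: dict[str, FitResult | np.ndarray],
    method: str = "stacking",
    target_only: bool = True,
    seed: int | None = None,
) -> pd.Series:
    """Normalised support for >= 2 candidate models of the same records.

    ``method`` is ``"stacking"`` (default) or ``"pseudo-bma+"``.
    """
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidates to compute weights")
    idatas = {}
    n_records = None
    for name, cand in candidates.items():
        if isinstance(cand, FitResult):
            idatas[name] = cand.to_inferencedata(target_only=target_only)
        else:
            idatas[name] = _idata_from_matrix(np.asarray(cand))
        n = idatas[name].log_likelihood["obs"].shape[-1]
        if n_records is None:
            n_records = n
        elif n != n_records:
            raise ValueError(
                f"candidate {name!r} scores {n} records, others score {n_records}"
            )
    az_method = {"stacking": "stacking", "pseudo-bma+": "BB-pseudo-BMA"}[method]
    elpds = {name: _elpd_data(idata) for name, idata in idatas.items()}
    cmp = az.compare(elpds, ic="loo", method=az_method, seed=seed)
    w = cmp["weight"].reindex(list(candidates))
    return w / w.sum()


def compare_candidates(
    candidates: dict[str, FitResult],
    method: str = "stacking",
    seed: int | None = None,
) -> pd.DataFrame:
    """Full comparison report: per-candidate elpd, se, Pareto-k count, weight."""
    weights = model_weights(candidates, method=method, seed=seed)
    rows = []
    for name, fit in candidates.items():
        loo = compute_loo(fit)
        rows.append(
            dict(
                candidate_id=name,
                elpd=loo.elpd,
                se=loo.se,
                n_high_pareto_k=loo.n_high_k,
                weight=float(weights[name]),
            )
        )
    return pd.DataFrame(rows).set_index("candidate_id")
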