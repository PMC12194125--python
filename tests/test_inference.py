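"""Joint-fit behaviour: reproducibility, recovery, summaries, errors."""

import numpy as np
import pytest
from dataclasses import replace

from trmkin import (
    McmcSettings,
    StudyDesign,
    default_truths,
    fit_model,
    generate_dataset,
    summarize_posterior,
)
from trmkin.inference import ConfigurationError, ModelConfig, Priors, _Likelihood
from trmkin.recovery import config_for_truth, run_recover


def test_identical_seed_and_config_reproduce_fit(truths, small_skin_data, short_mcmc):
    cfg = config_for_truth(truths["skin_trm"], short_mcmc)
    fit1 = fit_model(small_skin_data, cfg)
    fit2 = fit_model(small_skin_data, cfg)
    np.testing.assert_array_equal(fit1.chain, fit2.chain)
    np.testing.assert_array_equal(fit1.pointwise_loglik, fit2.pointwise_loglik)
    assert summarize_posterior(fit1).equals(summarize_posterior(fit2))


def test_missing_required_channel_raises_named_error(truths, small_skin_data, short_mcmc):
    cfg = config_for_truth(truths["skin_trm"], short_mcmc)
    broken = small_skin_data[small_skin_data["channel"] != "ki67hi_given_yfp_pos"]
    with pytest.raises(ConfigurationError, match="ki67hi_given_yfp_pos"):
        fit_model(broken, cfg)


def test_unknown_precursor_rejected(short_mcmc):
    with pytest.raises(ConfigurationError, match="precursor"):
        ModelConfig(
            target_tissue="skin", target_subset="Trm69pos",
            precursor_subset="Treg", precursor_tissue="skin",
            mode="quiescent", mcmc=short_mcmc,
        )
    with pytest.raises(ConfigurationError, match="precursor_ki67"):
        ModelConfig(
            target_tissue="skin", target_subset="Trm69pos",
            precursor_subset="CD69neg", precursor_tissue="skin",
            mode="neutral", mcmc=short_mcmc,
        )


def test_near_noiseless_fit_recovers_truth_within_ten_percent(truths):
    """Deep sampling (1e5 cells/channel) and dense timepoints pin the rates."""
    truth = truths["skin_trm"]
    design = StudyDesign(
        n_mice_ki67divn=24, n_mice_cd4fr=24,
        mice_per_timepoint=2,
        cells_logmean=np.log(1e5), cells_logsd=0.05,
    )
    data = generate_dataset(truth, design, seed=21)
    fit = fit_model(
        data,
        config_for_truth(truth, McmcSettings(seed=22, walkers=32, steps=1500, warmup=900, thin=4)),
    )
    d = fit.draws()
    for name, true_val in (
        ("mu", truth.params.mu), ("rho", truth.params.rho), ("beta", truth.params.beta),
    ):
        med = float(np.median(d[name]))
        assert abs(med - true_val) / true_val < 0.10, (name, med, true_val)


def test_posterior_draw_domains_and_prior_predictive(truths, small_skin_data, short_mcmc):
    """Rates positive by construction; prior-predictive channel fractions in [0,1]."""
    cfg = config_for_truth(truths["skin_trm"], short_mcmc)
    fit = fit_model(small_skin_data, cfg)
    d = fit.draws()
    assert (d[["mu", "rho", "beta", "cY", "cM"]] > 0).all().all()
    frac = d[["y0", "kp0", "kn0", "m0"]].to_numpy()
    assert np.all((frac > 0) & (frac < 1))

    lik = _Likelihood(small_skin_data, cfg)
    rng = np.random.default_rng(0)
    X = lik._prior_mean + lik._prior_sd * rng.standard_normal((60, len(lik._prior_mean)))
    pred = lik.predicted_fractions(X)
    assert np.all(pred >= 0.0) and np.all(pred <= 1.0)


def test_summary_quantiles_match_direct_recomputation(truths, small_skin_data, short_mcmc):
    cfg = config_for_truth(truths["skin_trm"], short_mcmc)
    fit = fit_model(small_skin_data, cfg)
    s = summarize_posterior(fit)
    d = fit.draws()
    mu = d["mu"].to_numpy()
    rho = d["rho"].to_numpy()
    assert abs(s.loc["mu", "median"] - np.median(mu)) < 1e-12
    assert abs(s.loc["mu", "lo95"] - np.percentile(mu, 2.5)) < 1e-12
    res = 1.0 / (mu + rho)
    assert abs(s.loc["residence_days", "median"] - np.median(res)) < 1e-9
    repl = 100.0 * mu
    assert abs(s.loc["replacement_pct_per_day", "hi95"] - np.percentile(repl, 97.5)) < 1e-9
    # derived-at-MAP consistency
    map_row = fit.map_draw()
    assert abs(s.loc["residence_days", "map"] - 1.0 / (map_row["mu"] + map_row["rho"])) < 1e-12


def test_pointwise_matrix_shape_matches_records(truths, small_skin_data, short_mcmc):
    cfg = config_for_truth(truths["skin_trm"], short_mcmc)
    fit = fit_model(small_skin_data, cfg)
    nw, nd, nr = fit.pointwise_loglik.shape
    assert nr == len(fit.records)
    assert nw * nd == fit.n_draws
    assert np.all(np.isfinite(fit.pointwise_loglik))
    # likelihood stored for retained draws equals a direct recomputation
    lik = _Likelihood(small_skin_data, cfg)
    flat = fit.chain.reshape(-1, fit.chain.shape[-1])
    np.testing.assert_allclose(
        fit.flat_pointwise()[:5], lik.pointwise(flat[:5]), rtol=1e-12
    )


def test_recovery_study_scaled_down(truths):
    """simulate -> fit -> summarise on a reduced design: small bias, CIs cover."""
    report = run_recover(
        "skin_trm",
        replicates=5,
        seed=314,
        design=StudyDesign(n_mice_ki67divn=12, n_mice_cd4fr=12),
        mcmc=McmcSettings(seed=0, walkers=28, steps=900, warmup=550, thin=5),
    )
    assert len(report) == 5 * 3
    summary = report.attrs["summary"]
    assert set(summary.index) == {"mu", "rho", "beta"}
    # truth inside the 95% interval in at least 4 of 5 replicates per rate
    cov = report.groupby("parameter")["covered"].sum()
    assert (cov >= 4).all(), cov.to_dict()
    assert summary["mean_relative_bias"].abs().max() < 0.2


def test_recovery_with_zero_replicates_is_empty_success():
    report = run_recover("lp_trm", replicates=0, seed=1)
    assert len(report) == 0
    assert report.attrs["passed"] is True
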