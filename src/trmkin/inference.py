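"""Joint Bayesian estimation of target kinetics and precursor descriptors.

One fit couples six timecourses: within the target population, the YFP+ and
mTom+ frequencies and the Ki67-high fractions among YFP+ and YFP- cells; and
within the chosen precursor, the YFP+ and mTom+ frequencies.  The unknowns
are the three kinetic rates (mu, rho, beta), the target's label composition
at the day-5 time origin, and the two precursor descriptor curves — all
estimated in a single posterior so that precursor uncertainty propagates into
the kinetic estimates.

Rates are sampled on the log scale with log-normal priors; fractions on the
logit scale with uniform priors on the fraction.  The posterior is explored
with an affine-invariant ensemble sampler (emcee); walkers are treated as
chains for split-R-hat and effective-sample-size diagnostics, and the
per-record binomial log-likelihoods of the retained draws are stored for
PSIS-LOO model comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import emcee
import arviz as az

from . import _fast
from .kinetics import RecruitmentMode
from .observations import filter_fit_window
from .derived import summarize_derived

__all__ = [
    "Priors",
    "McmcSettings",
    "ModelConfig",
    "FitResult",
    "fit_model",
    "summarize_posterior",
]

#: sampled-parameter names, in vector order
PARAM_NAMES = [
    "ln_mu", "ln_rho", "ln_beta",
    "logit_y0", "logit_kp0", "logit_kn0", "logit_m0",
    "aY", "bY", "ln_cY",
    "aM", "bM", "ln_cM",
]
NDIM = len(PARAM_NAMES)

#: natural-scale names reported to users
NATURAL_NAMES = [
    "mu", "rho", "beta", "y0", "kp0", "kn0", "m0",
    "aY", "bY", "cY", "aM", "bM", "cM",
]

TARGET_CHANNELS = ("yfp_pos", "ki67hi_given_yfp_pos", "ki67hi_given_yfp_neg", "mtom_pos")
PRECURSOR_CHANNELS = ("yfp_pos", "mtom_pos")

ALLOWED_PRECURSORS = {"naive", "CM", "TEM", "EM", "CD69neg"}


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class Priors:
    """Weakly informative priors on the sampled scales.

    The Ki67 reversion rate beta is the only moderately informed one: Ki67
    stays high for roughly 3-4 days after division, hence a log-normal
    centred on 1/3.5 per day with narrow spread.
    """

    mu_logmean: float = math.log(0.03)
    mu_logsd: float = 1.0
    rho_logmean: float = math.log(0.015)
    rho_logsd: float = 1.0
    beta_logmean: float = math.log(1.0 / 3.5)
    beta_logsd: float = 0.3
    desc_ab_sd: float = 2.5
    c_logmean: float = math.log(0.02)
    c_logsd: float = 1.0


@dataclass(frozen=True)
class McmcSettings:
    """Ensemble-sampler budget.  ``seed`` is mandatory (no implicit seeding)."""

    seed: int
    walkers: int = 40
    steps: int = 2500
    warmup: int = 1250
    thin: int = 5

    def __post_init__(self) -> None:
        if self.walkers < 2 * NDIM + 2:
            raise ValueError(f"need at least {2 * NDIM + 2} walkers for {NDIM} parameters")
        if not 0 < self.warmup < self.steps:
            raise ValueError("warmup must lie in (0, steps)")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_draws(self) -> int:
        return ((self.steps - self.warmup) // self.thin) * self.walkers


@dataclass(frozen=True)
class ModelConfig:
    """Everything defining one candidate fit."""

    target_tissue: str
    target_subset: str
    precursor_subset: str
    precursor_tissue: str
    mode: RecruitmentMode
    mcmc: McmcSettings
    priors: Priors = Priors()
    t0: float = 5.0
    precursor_ki67: float | None = None  # constant immigrant Ki67 for neutral mode
    grid_dt: float = 0.5

    def __post_init__(self) -> None:
        object.__setattr__(self, "mode", RecruitmentMode(self.mode))
        if self.precursor_subset not in ALLOWED_PRECURSORS:
            raise ConfigurationError(
                f"unknown precursor {self.precursor_subset!r}; expected one of {sorted(ALLOWED_PRECURSORS)}"
            )
        if self.mode is RecruitmentMode.NEUTRAL and self.precursor_ki67 is None:
            raise ConfigurationError("neutral recruitment requires precursor_ki67")

    @property
    def immigrant_ki67(self) -> float:
        if self.mode is RecruitmentMode.QUIESCENT:
            return 0.0
        if self.mode is RecruitmentMode.DIVISION_LINKED:
            return 1.0
        return float(self.precursor_ki67)


def _expit(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


class _Likelihood:
    """Pre-indexed data and vectorised log-probability for one fit."""

    def __init__(self, data: pd.DataFrame, config: ModelConfig):
        df = filter_fit_window(data, config.t0)
        is_target = (
            (df["tissue"] == config.target_tissue)
            & (df["subset"] == config.target_subset)
            & df["channel"].isin(TARGET_CHANNELS)
        )
        is_prec = (
            (df["tissue"] == config.precursor_tissue)
            & (df["subset"] == config.precursor_subset)
            & df["channel"].isin(PRECURSOR_CHANNELS)
        )
        df = df[is_target | is_prec].reset_index(drop=True)
        df["is_target"] = (
            (df["tissue"] == config.target_tissue)
            & (df["subset"] == config.target_subset)
        )
        for ch in TARGET_CHANNELS:
            if not ((df["is_target"]) & (df["channel"] == ch)).any():
                raise ConfigurationError(f"no target observations for required channel {ch!r}")
        for ch in PRECURSOR_CHANNELS:
            if not ((~df["is_target"]) & (df["channel"] == ch)).any():
                raise ConfigurationError(f"no precursor observations for required channel {ch!r}")

        self.records = df
        self.config = config
        self.n_records = len(df)

        obs_t = df.loc[df["is_target"], "t_days"].to_numpy()
        self.grid, out_idx = _fast.build_grid(config.t0, obs_t, dt=config.grid_dt)
        uniq_t = self.grid[out_idx]
        self.out_idx = out_idx

        # per-channel record indices and time positions within uniq_t
        self.channel_rows: dict[str, np.ndarray] = {}
        self.channel_tpos: dict[str, np.ndarray] = {}
        for ch in TARGET_CHANNELS:
            rows = np.flatnonzero((df["is_target"] & (df["channel"] == ch)).to_numpy())
            self.channel_rows[ch] = rows
            self.channel_tpos[ch] = np.searchsorted(uniq_t, df.loc[rows, "t_days"].to_numpy())
        for ch, key in (("yfp_pos", "prec_yfp"), ("mtom_pos", "prec_mtom")):
            rows = np.flatnonzero(((~df["is_target"]) & (df["channel"] == ch)).to_numpy())
            self.channel_rows[key] = rows
            self.channel_tpos[key] = df.loc[rows, "t_days"].to_numpy()  # raw times

        self.n_pos = df["n_pos"].to_numpy(dtype=float)
        self.n_total = df["n_total"].to_numpy(dtype=float)
        from scipy.special import gammaln

        self.log_binom_coef = (
            gammaln(self.n_total + 1.0)
            - gammaln(self.n_pos + 1.0)
            - gammaln(self.n_total - self.n_pos + 1.0)
        )
        self.h_const = config.immigrant_ki67
        self.priors = config.priors
        self._prior_mean = np.array(
            [self.priors.mu_logmean, self.priors.rho_logmean, self.priors.beta_logmean,
             0, 0, 0, 0, 0, 0, self.priors.c_logmean, 0, 0, self.priors.c_logmean]
        )
        self._prior_sd = np.array(
            [self.priors.mu_logsd, self.priors.rho_logsd, self.priors.beta_logsd,
             1, 1, 1, 1,
             self.priors.desc_ab_sd, self.priors.desc_ab_sd, self.priors.c_logsd,
             self.priors.desc_ab_sd, self.priors.desc_ab_sd, self.priors.c_logsd]
        )

    # -- priors -------------------------------------------------------------
    def log_prior(self, X: np.ndarray) -> np.ndarray:
        lp = np.zeros(X.shape[0])
        norm_idx = [0, 1, 2, 7, 8, 9, 10, 11, 12]
        z = (X[:, norm_idx] - self._prior_mean[norm_idx]) / self._prior_sd[norm_idx]
        lp -= 0.5 * np.sum(z**2, axis=1)
        # uniform prior on each initial fraction -> logistic density on the logit
        logits = X[:, 3:7]
        lp += np.sum(logits - 2.0 * np.logaddexp(0.0, logits), axis=1)
        return lp

    # -- predictions --------------------------------------------------------
    def predicted_fractions(self, X: np.ndarray) -> np.ndarray:
        """Model-predicted fraction for every record; shape (K, n_records)."""
        K = X.shape[0]
        mu = np.exp(X[:, 0])
        rho = np.exp(X[:, 1])
        beta = np.exp(X[:, 2])
        y0 = _expit(X[:, 3])
        kp0 = _expit(X[:, 4])
        kn0 = _expit(X[:, 5])
        m0 = _expit(X[:, 6])
        aY, bY, cY = X[:, 7], X[:, 8], np.exp(X[:, 9])
        aM, bM, cM = X[:, 10], X[:, 11], np.exp(X[:, 12])
        x0 = np.column_stack(
            [y0 * kp0, y0 * (1 - kp0), (1 - y0) * kn0, (1 - y0) * (1 - kn0), m0]
        )
        h = np.full(K, self.h_const)
        states = _fast.integrate_batch(
            mu, rho, beta, h, aY, bY, cY, aM, bM, cM, x0, self.grid, self.out_idx
        )
        a, b = states[..., 0], states[..., 1]
        c, d = states[..., 2], states[..., 3]
        yfp = a + b
        kp = a / np.maximum(yfp, 1e-12)
        kn = c / np.maximum(c + d, 1e-12)
        mtom = states[..., 4]

        pred = np.empty((K, self.n_records))
        per_channel = {
            "yfp_pos": yfp,
            "ki67hi_given_yfp_pos": kp,
            "ki67hi_given_yfp_neg": kn,
            "mtom_pos": mtom,
        }
        for ch, series in per_channel.items():
            rows = self.channel_rows[ch]
            pred[:, rows] = series[:, self.channel_tpos[ch]]
        t0 = self.config.t0
        for key, (av, bv, cv) in (
            ("prec_yfp", (aY, bY, cY)),
            ("prec_mtom", (aM, bM, cM)),
        ):
            rows = self.channel_rows[key]
            tt = self.channel_tpos[key]
            pred[:, rows] = _expit(
                av[:, None] + bv[:, None] * np.exp(-cv[:, None] * (tt[None, :] - t0))
            )
        return np.clip(pred, 0.0, 1.0)

    def pointwise(self, X: np.ndarray) -> np.ndarray:
        """Per-record binomial log-likelihoods; shape (K, n_records)."""
        p = np.clip(self.predicted_fractions(X), 1e-6, 1.0 - 1e-6)
        return (
            self.log_binom_coef[None, :]
            + self.n_pos[None, :] * np.log(p)
            + (self.n_total[None, :] - self.n_pos[None, :]) * np.log1p(-p)
        )

    def log_prob(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        ok = np.all(np.abs(X) < 40.0, axis=1)
        out = np.full(X.shape[0], -np.inf)
        if ok.any():
            Xv = X[ok]
            val = self.log_prior(Xv) + self.pointwise(Xv).sum(axis=1)
            # extreme rate proposals can overflow the fixed-step integrator;
            # treat any non-finite likelihood as zero posterior mass
            val[~np.isfinite(val)] = -np.inf
            out[ok] = val
        return out


@dataclass
class FitResult:
    """Posterior draws, likelihood matrix and diagnostics of one fit."""

    config: ModelConfig
    param_names: list[str]
    chain: np.ndarray  # (walkers, draws, ndim) on the sampled scale
    log_post: np.ndarray  # (walkers, draws)
    pointwise_loglik: np.ndarray  # (walkers, draws, n_records)
    records: pd.DataFrame
    rhat: dict[str, float]
    ess: dict[str, float]

    @property
    def converged(self) -> bool:
        return max(self.rhat.values()) <= 1.01

    @property
    def n_draws(self) -> int:
        return self.chain.shape[0] * self.chain.shape[1]

    def draws(self) -> pd.DataFrame:
        """Flat natural-scale posterior draws."""
        flat = self.chain.reshape(-1, self.chain.shape[-1])
        out = pd.DataFrame(
            {
                "mu": np.exp(flat[:, 0]),
                "rho": np.exp(flat[:, 1]),
                "beta": np.exp(flat[:, 2]),
                "y0": _expit(flat[:, 3]),
                "kp0": _expit(flat[:, 4]),
                "kn0": _expit(flat[:, 5]),
                "m0": _expit(flat[:, 6]),
                "aY": flat[:, 7],
                "bY": flat[:, 8],
                "cY": np.exp(flat[:, 9]),
                "aM": flat[:, 10],
                "bM": flat[:, 11],
                "cM": np.exp(flat[:, 12]),
            }
        )
        out["log_post"] = self.log_post.reshape(-1)
        return out

    def map_draw(self) -> pd.Series:
        """Natural-scale parameters of the highest-posterior retained draw."""
        d = self.draws()
        return d.iloc[int(d["log_post"].to_numpy().argmax())]

    def flat_pointwise(self, target_only: bool = False) -> np.ndarray:
        ll = self.pointwise_loglik.reshape(-1, self.pointwise_loglik.shape[-1])
        if target_only:
            ll = ll[:, self.records["is_target"].to_numpy()]
        return ll

    def to_inferencedata(self, target_only: bool = True) -> az.InferenceData:
        """arviz container with posterior and per-record log-likelihood.

        ``target_only`` restricts the likelihood group to the target
        population's channels, the unit at which candidate models are
        compared (candidates share precursor data unequally, so precursor
        terms are excluded from model weights).
        """
        nat = self.draws().drop(columns="log_post")
        nw, nd = self.chain.shape[:2]
        posterior = {
            name: nat[name].to_numpy().reshape(nw, nd) for name in nat.columns
        }
        ll = self.pointwise_loglik
        if target_only:
            ll = ll[:, :, self.records["is_target"].to_numpy()]
        return az.from_dict(posterior=posterior, log_likelihood={"obs": ll})


def _posterior_mode(lik: _Likelihood, rng: np.random.Generator) -> np.ndarray:
    """Locate the posterior mode with L-BFGS and batched numerical gradients.

    Several restarts (prior centre plus prior-dispersed points) guard against
    a poor basin; the best optimum is returned.
    """
    from scipy.optimize import minimize

    def negf(x: np.ndarray) -> float:
        return -float(lik.log_prob(x[None, :])[0])

    def neggrad(x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
        X = np.repeat(x[None, :], 2 * NDIM, axis=0)
        for i in range(NDIM):
            X[2 * i, i] += eps
            X[2 * i + 1, i] -= eps
        v = lik.log_prob(X)
        return -(v[0::2] - v[1::2]) / (2.0 * eps)

    starts = [lik._prior_mean.copy()]
    for _ in range(2):
        starts.append(lik._prior_mean + 0.5 * lik._prior_sd * rng.standard_normal(NDIM))
    best_x, best_f = None, np.inf
    for x0 in starts:
        if not np.isfinite(lik.log_prob(x0[None, :])[0]):
            continue
        res = minimize(negf, x0, jac=neggrad, method="L-BFGS-B")
        if res.fun < best_f and np.isfinite(res.fun):
            best_x, best_f = res.x, res.fun
    if best_x is None:  # pragma: no cover - all starts infeasible
        raise RuntimeError("posterior-mode search failed from every start point")
    return best_x


def _initial_walkers(
    lik: _Likelihood, settings: McmcSettings, rng: np.random.Generator
) -> np.ndarray:
    """Start walkers scattered around the posterior mode, all finite."""
    centre = _posterior_mode(lik, rng)
    sd = np.maximum(0.05 * lik._prior_sd, 1e-3)
    X0 = np.empty((settings.walkers, NDIM))
    n_ok = 0
    while n_ok < settings.walkers:
        cand = centre + sd * rng.standard_normal((settings.walkers, NDIM))
        good = np.isfinite(lik.log_prob(cand))
        take = min(settings.walkers - n_ok, int(good.sum()))
        X0[n_ok : n_ok + take] = cand[good][:take]
        n_ok += take
    return X0


def fit_model(data: pd.DataFrame, config: ModelConfig) -> FitResult:
    """Sample the joint posterior of one candidate model.

    A short L-BFGS search locates the posterior mode; the ensemble starts in
    a ball around it and explores with differential-evolution moves, which
    handle the correlated rate/descriptor posterior better than the default
    stretch move.  Reproducible given (data, config): all randomness derives
    from ``config.mcmc.seed``.
    """
    lik = _Likelihood(data, config)
    settings = config.mcmc
    rng = np.random.default_rng(settings.seed)
    X0 = _initial_walkers(lik, settings, rng)

    sampler = emcee.EnsembleSampler(
        settings.walkers,
        NDIM,
        lik.log_prob,
        vectorize=True,
        moves=[(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)],
    )
    sampler.random_state = np.random.RandomState(settings.seed).get_state()
    sampler.run_mcmc(X0, settings.steps, progress=False)

    chain = sampler.get_chain(discard=settings.warmup, thin=settings.thin)
    logp = sampler.get_log_prob(discard=settings.warmup, thin=settings.thin)
    # (steps, walkers, ndim) -> (walkers, steps, ndim): walkers act as chains
    chain = np.transpose(chain, (1, 0, 2))
    logp = logp.T

    nw, nd, _ = chain.shape
    pointwise = np.empty((nw, nd, lik.n_records))
    flat = chain.reshape(-1, NDIM)
    batch = 512
    for i in range(0, flat.shape[0], batch):
        pointwise.reshape(-1, lik.n_records)[i : i + batch] = lik.pointwise(
            flat[i : i + batch]
        )

    post = {
        name: chain[:, :, i] for i, name in enumerate(PARAM_NAMES)
    }
    idata = az.from_dict(posterior=post)
    rhat_ds = az.rhat(idata)
    ess_ds = az.ess(idata)
    rhat = {name: float(rhat_ds[name].values) for name in PARAM_NAMES}
    ess = {name: float(ess_ds[name].values) for name in PARAM_NAMES}

    return FitResult(
        config=config,
        param_names=list(PARAM_NAMES),
        chain=chain,
        log_post=logp,
        pointwise_loglik=pointwise,
        records=lik.records,
        rhat=rhat,
        ess=ess,
    )


def summarize_posterior(fit: FitResult) -> pd.DataFrame:
    """MAP, posterior median and central 95% interval for every parameter and
    derived quantity (residence, interdivision, replacement, clonal half-life,
    Ki67-high duration)."""
    d = fit.draws()
    map_row = fit.map_draw()
    rows = []
    for name in NATURAL_NAMES:
        x = d[name].to_numpy()
        rows.append(
            dict(
                quantity=name,
                map=float(map_row[name]),
                median=float(np.median(x)),
                lo95=float(np.percentile(x, 2.5)),
                hi95=float(np.percentile(x, 97.5)),
                n_flagged=0,
            )
        )
    mu, rho, beta = (d[c].to_numpy() for c in ("mu", "rho", "beta"))
    derived = summarize_derived(mu, rho, beta)
    map_mu, map_rho, map_beta = (float(map_row[c]) for c in ("mu", "rho", "beta"))
    delta = mu + rho
    rows.append(
        dict(
            quantity="delta", map=map_mu + map_rho, median=float(np.median(delta)),
            lo95=float(np.percentile(delta, 2.5)), hi95=float(np.percentile(delta, 97.5)),
            n_flagged=0,
        )
    )
    map_vals = {
        "residence_days": 1.0 / (map_mu + map_rho),
        "interdivision_days": (1.0 / map_rho) if map_rho > 0 else math.inf,
        "replacement_pct_per_day": 100.0 * map_mu,
        "clonal_half_life_days": (math.log(2) / map_mu) if map_mu > 0 else math.inf,
        "ki67hi_duration_days": 1.0 / map_beta,
    }
    for name, s in derived.items():
        rows.append(
            dict(
                quantity=name,
                map=map_vals[name],
                median=s["median"],
                lo95=s["lo95"],
                hi95=s["hi95"],
                n_flagged=s["n_non_decaying"],
            )
        )
    return pd.DataFrame(rows).set_index("quantity")
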