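# Methods

## The kinetic model

Each target population (CD4+ effector-memory or CD69+ T_RM cells in skin or
gut lamina propria) is treated as kinetically homogeneous and at demographic
steady state: immigration from a precursor at fractional rate μ (day⁻¹),
self-renewal at per-cell rate ρ (day⁻¹) and loss (death, egress,
differentiation) at total rate δ. Constant population size forces
δ = ρ + μ, so δ is derived throughout and never a free parameter.
Absolute cell numbers are never modelled — all observables are fractions.

Two heritable labels are followed. In the division-reporter strain, YFP marks
cells in cycle during the tamoxifen pulse, and Ki67-high/low status is
measured separately within YFP+ and YFP− cells. In the CD4-reporter strain,
mTom marks CD4-expressing cells; the population kinetics are identical and
only the label source differs. With a, b, c, d the YFP+Ki67hi, YFP+Ki67lo,
YFP−Ki67hi, YFP−Ki67lo fractions, m the mTom+ fraction, g_Y(t), g_m(t) the
precursor label frequencies, and h(t) the Ki67-high fraction among
immigrants:

    da/dt = μ g_Y h     + ρ a + 2ρ b − (β + δ) a
    db/dt = μ g_Y (1−h)        + β a − (ρ + δ) b
    dc/dt = μ (1−g_Y) h + ρ c + 2ρ d − (β + δ) c
    dd/dt = μ (1−g_Y)(1−h)     + β c − (ρ + δ) d
    dm/dt = μ (g_m − m)

The division bookkeeping: a dividing Ki67-low cell yields two Ki67-high
daughters (+2ρ from the low pool), a dividing Ki67-high cell adds one net
Ki67-high cell (+ρ), and Ki67 reverts to low at rate β (mean high duration
1/β ≈ 3–4 days). At equilibrium the total Ki67-high fraction is

    k = (μ h + 2ρ) / (β + δ + ρ),

which at the favoured skin rates (μ = 0.02/d, ρ = 1/49 d⁻¹, β = 1/3 d⁻¹,
h = 1) gives k ≈ 0.15 and at the LP rates (μ = 0.055/d, ρ = 1/63 d⁻¹, h = 0)
k ≈ 0.076 — both matching the Ki67 frequencies measured in those tissues.

Recruitment mode sets h: quiescent (h = 0), division-linked (h = 1), or
neutral (h equals the precursor's Ki67-high frequency). Neutral mode defaults
to a constant supplied in configuration; the reference solver also accepts a
time-varying curve.

The analysis time origin is t₀ = 5 days post-tamoxifen: reporter induction is
still under way before then, so earlier observations are excluded from all
fits (`filter_fit_window`). Initial label fractions at t₀ are free parameters
estimated with everything else.

## Precursor descriptors

Candidate precursors (lymph-node naive, central-memory, effector-memory
cells; the local CD69− compartment) are boundary conditions, not mechanistic
models. Each label curve is a single-exponential relaxation on the log-odds
scale, f(t) = expit(a + b·e^(−c(t−t₀))): three parameters, bounded in (0,1),
monotone when b·c ≠ 0, flexible enough for both the several-fold mTom decline
over a year and the essentially flat YFP curves. A second exponential term
could be added for non-monotone curves; the default keeps one. Descriptors
are estimated jointly with the target's parameters so precursor uncertainty
propagates into the kinetic estimates.

## Likelihood

Each record is `n_pos` label-positive cells among `n_total` sampled cells for
one mouse, time, tissue, subset and channel. Counts are modelled as binomial
at the model-predicted fraction, clamped to [1e-6, 1−1e-6] so the likelihood
stays finite at degenerate predictions. The binomial respects the
sample-size-dependent noise of flow cytometry and supplies the per-record
pointwise terms that leave-one-out cross-validation needs; one record is one
pointwise unit. Records are independent given the trajectory, so the total
log-likelihood is the sum over records and invariant to reordering. The
conditional Ki67 channels (Ki67-high among YFP+ and among YFP−) are binomial
within their denominators, which is exactly how the cells are gated.
Overdispersion beyond binomial and mouse-level random effects are not
modelled (see Limitations).

## Priors

| parameter | prior | rationale |
|---|---|---|
| μ | LogNormal(ln 0.03, 1) | weakly informative, spans 0.4–20 %/day |
| ρ | LogNormal(ln 0.015, 1) | interdivision times of weeks to months |
| β | LogNormal(ln(1/3.5), 0.3) | Ki67 stays high ~3–4 days after division |
| initial fractions | Uniform(0,1) (Beta(1,1)) | sampled on the logit scale |
| descriptor a, b | Normal(0, 2.5) | log-odds scale, covers (0.01, 0.99) |
| descriptor c | LogNormal(ln 0.02, 1) | relaxation over weeks to a year |

All priors are plain dataclass fields (`trmkin.inference.Priors`) so users
can substitute their own.

## Posterior sampling

The posterior is explored with an affine-invariant ensemble sampler (emcee),
the gradient-free MCMC available in this stack; the model itself (a 13-
parameter ODE-constrained likelihood) is authored here. Defaults: 40
walkers, 2500 steps, first 1250 discarded, thinning 5 → 10 000 retained
draws. Three choices matter for robustness:

- **Initialisation**: a short L-BFGS search (batched central-difference
  gradients, three restarts) locates the posterior mode; walkers start in a
  small ball around it. This removes the long burn-in that ensemble samplers
  otherwise need in correlated rate posteriors.
- **Moves**: 80% differential-evolution, 20% snooker, which mix better than
  the default stretch move here.
- **Diagnostics**: walkers are treated as chains for split-R̂ and effective
  sample size (arviz). Ensemble walkers are not independent chains, so R̂ is
  conservative; fits are *flagged* non-converged when any split-R̂ exceeds
  1.01 but results are still returned with the flag attached. Typical
  full-design fits reach max split-R̂ ≈ 1.05–1.10 with posterior medians
  stable to well under the reporting precision; users wanting R̂ ≤ 1.01
  can raise `steps`.

The MAP reported in summaries is the highest-posterior retained draw (no
separate optimiser pass), an approximation documented here once.

Every fit is reproducible from its configuration: the MCMC seed is mandatory,
all randomness (optimiser restarts, walker initialisation, proposals) derives
from it, and the CLI writes a manifest with the config hash and seed.

## Numerical integration

The system is linear with smooth logistic forcing and rates below ~1/day.
The public solver integrates with adaptive LSODA at rtol 1e-8 / atol 1e-10,
restarting at declared forcing discontinuities; it is verified against an
exact matrix-exponential solution on piecewise-constant forcing to 1e-8.
Likelihood evaluation inside MCMC uses a fixed-step classical RK4 on a
half-day grid (numba-compiled, batched over walkers), which agrees with the
adaptive solver to ~1e-5 — two orders of magnitude below the binomial noise
floor of ~2000-cell samples. Observation times are inserted into the grid,
so no interpolation error enters. Conditional Ki67 fractions guard the 0/0
case: when the YFP+ fraction falls below 1e-12 the conditional is returned
as NaN (reference path) or computed against a floored denominator (fitting
path, where the estimated initial conditions keep the pool occupied).
Non-finite likelihoods from extreme proposals (fixed-step blow-up at absurd
rates) are mapped to zero posterior mass.

## Synthetic study generator

`generate_dataset` emulates the real design: a single pulse at day 0,
analysis from day 5, a 31-mouse division-reporter cohort chased 9 weeks and a
36-mouse CD4-reporter cohort chased 57 weeks, mice sacrificed on a
quasi-uniform schedule of 2–4 per timepoint. Per-channel sampled-cell counts
are LogNormal(ln 2000, 0.5) rounded and floored at 20 — chosen once so that
binomial noise dominates at tissue-realistic yields — and positives are
binomial at the model-predicted fraction. Truth presets encode the favoured
models: `skin_trm` (μ = 0.02/d, ρ = 1/49 d⁻¹, β = 1/3 d⁻¹, division-linked
from local CD69− cells; residence ≈ 24.7 d) and `lp_trm` (μ = 0.055/d,
ρ = 1/63 d⁻¹, quiescent from LN effector memory; residence ≈ 14.1 d), with
flat YFP and ~8-fold-declining mTom precursor curves.

What the generator does **not** emulate: between-mouse biological
heterogeneity (every mouse shares one parameter set), overdispersion,
staining/gating error, the 0–5 day induction transient, and precursor curves
outside the logistic-relaxation family. Passing recovery tests therefore
demonstrate that the inference machinery is correct and well calibrated under
the model's own assumptions — not that those assumptions hold in any given
real dataset.

## Model comparison

Candidates (precursor × recruitment mode) are scored by PSIS-LOO expected
log predictive density over the **target population's channels only**;
precursor-descriptor records are excluded because candidates share precursor
data unequally and including them would bias the comparison. Weights default
to stacking of predictive distributions, with pseudo-BMA+ (Bayesian
bootstrap, seeded) as an option; the choice is recorded in the comparison
report. Records with Pareto-k above 0.7 are counted and reported per
candidate.

## Derived quantities

From each posterior draw: residence 1/δ, interdivision 1/ρ, replacement
100μ %/day, clonal half-life ln 2/(δ − ρ) (= ln 2/μ at steady state). Draws
with δ ≤ ρ are flagged non-decaying rather than given an infinite summary.
Since μ ≤ δ, the half-life always satisfies ln 2/(δ−ρ) ≥ ln 2/δ.

The Ki67-only residence bounds invert the equilibrium balance
k = (μh + 2ρ)/(β + 2ρ + μ) for ρ at h = 0 and h = 1:

    ρ_quiescent = k(β + μ) / (2(1 − k))
    ρ_division-linked = max(0, (kβ − μ(1 − k)) / (2(1 − k)))

giving residence bounds 1/(ρ_q + μ) ≤ 1/δ ≤ 1/(ρ_d + μ). When even ρ = 0
cannot reconcile division-linked immigration with the observed k, that branch
is floored and the upper bound becomes 1/μ. β defaults to the fitted
posterior median when available, else 1/3.5 d⁻¹ (midpoint of the 3–4 day
Ki67 lifetime). At (k = 0.15, μ = 0.02/d, β = 1/3.5) the bounds are
21.3–28.4 days; at (k = 0.07, μ = 0.055/d, β = 1/3) the division-linked
branch floors and the bounds are 14.4–18.2 days.

## Problem sizes in the test suite

The recovery checks that headline estimates rest on use the full design
(31 + 36 mice) with 2500-step chains. The repeated-replicate studies — ten
recruitment-mode recovery replicates and the five-replicate
coverage-and-bias study — use a reduced design (12 + 12 and 9 + 9 mice) with
shorter chains; these are property checks on ranking and calibration, for
which the package's reduced sizes retain ample signal while keeping the
suite fast.

## Limitations

- One parameter set per population: no hierarchical mouse-level effects, no
  kinetic heterogeneity within a subset.
- Binomial observation noise only; real flow data may be overdispersed.
- Ensemble-sampler R̂ is computed across interacting walkers; treat the
  1.01 convergence flag as strict and the diagnostics as conservative.
- The descriptor family is monotone; strongly non-monotone precursor label
  curves would need the two-term extension.
- Population sizes are assumed constant; the model cannot speak to expansion
  or contraction of the niche, only to steady-state turnover.
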