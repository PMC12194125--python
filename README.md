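# trmkin — homeostatic kinetics of tissue-resident memory CD4 T cells

Tissue-resident memory T cells (T_RM) guard barrier sites such as skin and
the gut lamina propria (LP). How long an individual cell resides in the
tissue, how often it divides, and how fast the population is replenished from
circulating precursors together determine how durable — and how plastic —
local immune memory is. These rates cannot be read off a single measurement;
`trmkin` estimates them jointly from genetic fate-reporter timecourses.

The package is aimed at quantitative immunologists analysing pulse-chase
fate-mapping experiments: two reporter strains, one marking cells in cycle
during a tamoxifen pulse (YFP, with Ki67-high/low status tracked within YFP+
and YFP− cells), one marking CD4-expressing cells (mTom). After the pulse,
the labelled fractions drift towards the label content of the upstream
precursor, at speeds set by the population's turnover.

## Model

A target population of constant size N receives immigrants at rate θ from a
precursor with label frequencies g_Y(t), g_m(t), self-renews at per-cell rate
ρ and is lost at total rate δ. Steady state enforces δ = ρ + μ with
μ = θ/N the fractional daily replacement. Writing a, b, c, d for the
YFP+Ki67hi, YFP+Ki67lo, YFP−Ki67hi, YFP−Ki67lo fractions and m for the mTom+
fraction:

    da/dt = μ g_Y h     + ρ a + 2ρ b − (β + δ) a
    db/dt = μ g_Y (1−h)        + β a − (ρ + δ) b
    dc/dt = μ (1−g_Y) h + ρ c + 2ρ d − (β + δ) c
    dd/dt = μ (1−g_Y)(1−h)     + β c − (ρ + δ) d
    dm/dt = μ (g_m − m)

β is the Ki67-high → low reversion rate (Ki67 stays high ~3–4 days after
division) and h is the Ki67 status of immigrants: 0 ("quiescent"), 1
("division-linked") or the precursor's own Ki67 frequency ("neutral").
Precursor curves are three-parameter logistic relaxations fitted jointly with
the target so their uncertainty propagates. Counts are binomial around the
model-predicted fractions; the joint posterior is sampled with an
affine-invariant ensemble (emcee) and candidate (precursor × mode) models are
weighed by PSIS-LOO stacking (arviz).

Derived scales: residence time 1/δ, interdivision time 1/ρ, daily
replacement 100μ %/day, and the clonal half-life ln 2/(δ − ρ) — the time for
a labelled cohort and its descendants to halve.

## Worked example

```python
import numpy as np
from trmkin import (StudyDesign, McmcSettings, default_truths,
                    generate_dataset, fit_model, summarize_posterior)
from trmkin.recovery import config_for_truth

truth = default_truths()["skin_trm"]          # 2%/day, 7-week interdivision
data = generate_dataset(truth, StudyDesign(), seed=1)   # 31 + 36 mice
fit = fit_model(data, config_for_truth(truth, McmcSettings(seed=11)))
print(summarize_posterior(fit).loc[
    ["replacement_pct_per_day", "residence_days", "ki67hi_duration_days"],
    ["median", "lo95", "hi95"]].round(2))
```

prints

```
                         median   lo95   hi95
quantity
replacement_pct_per_day    1.94   1.86   2.02
residence_days            25.49  23.80  27.18
ki67hi_duration_days       3.10   2.85   3.34
```

i.e. the fit recovers the generating skin-T_RM kinetics: about 2% of cells
replaced per day, a mean tissue residence of ~24–25 days, and Ki67 staying
high for ~3 days after division. The same machinery run on the LP preset
returns ~14-day residence maintained by ~5.5%/day replacement.

The numbered drivers under `analysis/` run the full narrative — simulate the
two cohorts, fit both, rank recruitment-mode candidates (the generating
division-linked mode wins with stacking weight 1.0), and tabulate clonal
half-lives (~5 weeks skin, ~2 weeks LP) and Ki67-only residence bounds.

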