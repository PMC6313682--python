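# Methods

## Model

`kosem` implements a microenvironmental, time-activity-based model of daily
PM2.5 exposure. A day is divided into 144 ten-minute slots; a person's
location in each slot is one of three microenvironments — residential
indoor, transportation, or "other" (workplaces, schools, restaurants,
streets: everything that is neither the own home nor a vehicle/walk). Each
(slot, microenvironment) pair is a grid cell carrying the PM2.5
concentration observed there, pooled over all campaign days into one
diurnal pattern.

Daily personal exposure is the time-weighted average concentration

    E = (1 / n_used) * sum_t C_t(m_t),

where `m_t` is the diary's microenvironment in slot `t` and `C_t(m)` the
cell concentration. The model has two readings of `C_t(m)`, kept as
explicit modes that are never mixed silently:

* **mean mode** (deterministic): `C_t(m)` is the arithmetic mean of the
  corrected 1-min measurements in the cell. One exposure per person-day.
* **distribution mode** (Monte-Carlo): `C_t(m)` is a draw from the cell's
  fitted concentration distribution; each trial redraws every cell and
  applies the same equation. Summaries pool all person-day × trial values.

Cells with fewer than `min_obs_per_cell` observations (default 5) are
*unavailable*: slots falling on them are excluded and the denominator
shrinks accordingly, e.g. 20 min of early-morning transit on unmeasured
transportation cells gives a 1420-min rather than 1440-min base. The same
exclusion rule applies in both modes, and the affected fraction of diaries
is reported. The minimum-count rule is this package's mechanism for "no
usable data in the cell"; any campaign will leave some cells empty simply
because nobody was measured there at that hour.

## Measurement processing

Input is 1-min PM2.5 records tagged with microenvironment, minute-of-day
and a measurement-run identifier. A gravimetric correction factor
(typically ≈ 1.1 for light-scattering instruments referenced against filter
weights) multiplies each record; factors may be per-run or one global
value. Negative concentrations are rejected at read time rather than
clipped — instrument output is non-negative, so a negative value signals a
parse error. Multi-day campaigns pool into a single 24-h grid with no date
stratification.

## Distribution fitting

Each available cell is fitted by maximum likelihood with four candidate
right-skewed, non-negative families — lognormal, gamma, Weibull, and a
normal truncated at zero — and the family minimizing AIC is selected (the
Kolmogorov–Smirnov statistic is selectable via `criterion="ks"`). These
four families cover the observed behaviour of indoor/outdoor PM samples,
whose daily exposures are themselves close to lognormal. Zero-variance
cells collapse to a point mass at the common value with a warning. Every
fitted distribution samples non-negative values by construction (support
[0, ∞) for all four families). The truncated-normal likelihood is
maximized over (μ, log σ) with Nelder–Mead from moment starting values;
the lognormal MLE is closed-form on log data; gamma and Weibull use the
profile MLE with the location pinned at zero.

## Monte-Carlo simulation

The default draw scope is `shared_per_cell`: within a trial, one
concentration is drawn per cell and shared by everyone occupying it — a
trial is one realized day of microenvironment conditions. The alternative
`independent_per_subject` gives every subject independent draws; both
scopes agree in expectation and are exposed because the choice is a
genuine modelling ambiguity. Default 10,000 trials.

Randomness: a single top-level seed spawns one `SeedSequence` substream
per cell (shared scope) or per trial (independent scope), in canonical
slot-major cell order, and each substream draws its whole vector at once.
Which diaries use a cell therefore never perturbs the draws of other
cells, and runs are bit-reproducible given the seed. Extreme draws are not
truncated; heavy-tailed fitted cells can produce large simulated maxima.

Exposure summaries report arithmetic mean/SD, median, 95th/99th
percentiles (linear-interpolation definition), the fraction exceeding a
24-h standard (default 35 µg/m³, the Korean PM2.5 ambient standard),
geometric mean and GSD, and a log-normality statistic (the correlation
coefficient of the normal probability plot of log values). On samples
above one million values the probability-plot statistic is computed on an
evenly strided subsample of ~500k values; the other statistics always use
the full sample.

## High-exposure-group analysis

The high group is the top 5% of the exposure distribution:
`ceil(0.05 N)` subjects (8072 diaries give a 404/7668 split), ties at the
threshold broken deterministically by subject id after a stable sort.

Categorical covariates are tested with Fisher's exact test of
independence under the probability-ordering two-sided convention (sum of
fixed-margin table probabilities not exceeding the observed table's, with
a 1e-7 relative tolerance). r×c tables are enumerated exactly when the
number of fixed-margin tables is within a budget (default 500,000);
beyond it, a seeded Monte-Carlo estimate using the Patefield sampler is
returned with its standard error. Continuous covariates use Welch's
unequal-variance t-test — the safer reading of "t-test" given a 404 vs
7668 group-size imbalance. Variables with p strictly below 0.1 enter the
multivariate model.

Collinearity screening computes variance inflation factors on the
dummy-coded design and drops columns above the threshold (default 10)
iteratively, highest first; exact-collinearity ties drop the later-ordered
column. The "stepwise" stage is screen → VIF pruning → a single
multivariate fit, not iterative add/drop elimination: a classical stepwise
would evict the non-significant terms that characteristically remain in
this kind of exposure model (sex, education, income, house size), so the
screen-then-fit reading is the one consistent with reporting them.

The logistic model is a maximum-likelihood fit of high vs low with dummy
coding against fixed reference levels (weekday, male, married,
middle-school-or-below, primary/secondary industry, office worker,
<$2000, owns house/car). Respondents whose industry/job is
`not_applicable` (not working) are excluded from contingency tables of
those variables and from the multivariate fit (complete-case): a model
containing industry, job and working hours is only defined on the employed
subpopulation. Per-variable p-values are drop-one likelihood-ratio tests
(χ² with one df per dummy column removed); effect sizes are odds ratios
`exp(β)` with 95% Wald intervals `exp(β ± 1.96·SE)`, so `ci_low ≤ OR ≤
ci_high` holds by construction. Fewer than ~10 events per parameter
triggers a warning; non-convergence and complete separation raise. Report
tables round half-up: one decimal for percentages, three for model terms.

Day-type comparisons of time budgets use classical one-way ANOVA plus
Scheffé's simultaneous pairwise contrasts, F_ij = (x̄_i − x̄_j)² /
[(k−1)·MSW·(1/n_i + 1/n_j)] on F(k−1, N−k) — conservative relative to
unadjusted contrasts by construction.

## Synthetic data generator

The generator produces campaigns and diary populations with the structure
the model assumes, so the whole pipeline is testable without external
data.

**Campaign.** Per-cell 1-min concentrations are lognormal with an
arithmetic-mean diurnal profile and a per-microenvironment GSD. Defaults:
residential indoor mean 23.7 µg/m³ with a 1.5× lunch-hour bump;
transportation 24.2 µg/m³, flat; "other" 34.7 µg/m³ with a 2× elevation
over 18:00–22:59 (restaurants and bars). GSDs are set so the lognormal
CV matches the observed mean/SD ratios of the three microenvironments
(≈2.3, 2.2, 3.3) — the "other" category's SD far exceeding its mean is
what motivates lognormal noise; other noise families are not generated.
Default observation counts per cell (229/37/150) mirror a campaign of
roughly 59,000 minutes split ~33k/5.3k/21.7k across microenvironments.
Twenty-three night/early-morning transportation cells (02:10–05:59) are
blanked by default, leaving 409 of 432 cells available and making the
04:00–05:59 window the source of reduced-denominator diaries.

**Population.** Day types are sampled at the survey mix
(4849:1608:1618 weekday:Saturday:Sunday). Schedules are block-structured —
sleep at home, morning commute, a daytime block in "other", evening
commute, evening at home — rather than slot-i.i.d., which reproduces
morning/evening transit peaks. Residential and transportation budgets are
drawn from day-type-specific normals (weekday 13.95 ± 4.77 h and
2.03 ± 1.68 h; Saturday 15.02 ± 5.09 and 2.02 ± 1.72; Sunday 17.01 ± 5.40
and 1.76 ± 1.86), clipped to feasible ranges; "other" takes the
remainder, so every budget sums to exactly 24 h. Covariates are sampled
from marginals patterned on the surveyed population (46.5% male, ~54%
employed, etc.); the joint covariate distribution is *not* matched — only
marginal structure plus controllable effects.

Effects are log-odds-scale tilts attached to covariate indicators or
centered continuous covariates; a subject's summed tilt `z` moves up to
`effect_scale_hours · (2·sigmoid(z) − 1)` hours (default scale 3 h) from
residential time into the late-day "other" block, pushing tilted subjects
toward the top of the exposure distribution. A configurable fraction of
subjects (default 511/8072 ≈ 6.3%) is forced into 04:00–04:19 transit,
exercising the reduced-denominator rule; subjects whose schedules
organically place a commute before 06:00 add to that fraction, so the
realized reduced-denominator share (~10% at defaults) exceeds the forced
fraction.

What passing tests on this generator do **not** show: fidelity to any real
joint covariate distribution, indoor-source physics (the model has no
mass-balance component by design), day-to-day correlation within persons
(diaries are single person-days), or behaviour under high-pollution
episodes (the default profiles describe a low-ambient-concentration
summer).

## Numerical choices and degenerate inputs

* Slots are 1-based (t = 1…144) over half-open minute ranges
  [10(t−1), 10t); minutes are 0-based.
* Exposure is asserted (in tests) to be a convex combination of the used
  cell means.
* ANOVA on groups that are all constant and equal returns F = 0, p = 1;
  constant but unequal groups return F = ∞, p = 0.
* Fisher tests reject degenerate tables (an all-zero row or column).
* `label_top_fraction` requires 0 < fraction < 1 and breaks exposure ties
  by subject id, making the labeling seed-free and deterministic.
* Logistic fits cap iterations at 200 and surface statsmodels'
  separation/convergence failures as errors with diagnostics.
* Report rounding is half-up (ties away from zero), not banker's.

## Problem sizes

The test suite runs campaigns of 8–30 observations per cell, populations
of 120–4000 diaries and simulations of 10–10,000 trials; the acceptance
script runs the full survey-scale study (59,053 campaign minutes, 8072
diaries, 10,000 shared-scope trials, ~2 GB peak memory). These sizes are
the package's default validation scale; all of them are configurable.

## Known limitations

* Single-day exposure only: no chronic/multi-day aggregation, no dose
  (inhalation-rate) modelling, no spatial interpolation of ambient data.
* The three-microenvironment scheme is coarse; the finer seven-category
  survey scheme is accepted only through a fixed mapping onto the three.
* Fisher Monte-Carlo p-values carry sampling error (reported as `mc_se`).
* The shared-per-cell draw scope understates between-subject variance
  within a trial relative to independent draws; both are available.
* Survey weights are not modelled — diaries are an unweighted population.
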