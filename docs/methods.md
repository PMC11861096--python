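# Methods

## Thermal time

A day's degree contribution is `max(0, (T'max + T'min)/2 − T_base)` with the
daily maximum capped at a ceiling. Two capping rules are offered:

* `cap_max_floor_min` (default): additionally floor the daily minimum at the
  base before averaging. This is the common agronomic convention and the one
  consistent with a mild site showing zero SDD: a cold night cannot cancel
  heat accumulated in the afternoon.
* `cap_max_only`: cap the maximum only, letting cold nights drag the daily
  mean down (never below zero for the day).

Stress Degree Days are defined as a difference of two GDD runs,
`SDD = GDD(ceiling = t_stress_ceiling) − GDD(ceiling = t_growth_ceiling)`.
Because the stress ceiling (50 °C) dominates the growth ceiling (30 °C)
day-by-day, SDD is non-negative for any weather series. Defaults (base
10 °C, ceilings 30/50 °C) are the chickpea conventions; all three are
configurable through `ThermalConfig`, which enforces
`t_base < t_growth_ceiling < t_stress_ceiling`.

**Stage windows.** Stages are inclusive, disjoint date windows: vegetative
= [sowing, flowering − 1 day], reproductive = [flowering, maturity], full
season = [sowing, maturity]. `age_days` is the inclusive calendar-day count
of the window, which makes the three stages exactly additive for GDD, SDD,
grow days and age, and guarantees `0 ≤ grow_days ≤ age_days` (grow days =
days with positive degree contribution; "days whose mean lies strictly
inside the base/ceiling band" would be an alternative reading, but the
positive-contribution definition is the one consistent with the additivity
and bounding invariants). A flowering date equal to sowing yields an empty
vegetative stage of all zeros.

**Missing weather.** A date gap inside a requested window is an error naming
the first missing date, never silently interpolated — gap-filling corrupts
cumulative sums. Sub-daily station records are assumed pre-collapsed to
daily min/max before entering the package.

## Synthetic trial generator

The generator emulates a two-location, two-sowing-time heat-stress trial of
148 genotypes (10 desi, 138 kabuli; origins 129/10/9 Syria/India/Australia)
in 2-replicate RCBDs on 8 m² plots. It is the package's stated study
condition, not a tuning surface.

**Weather.** Daily mean = seasonal sinusoid + N(0, σ) noise; tmax/tmin sit
half a diurnal range either side. Southern-hemisphere phasing (annual
minimum 1 July). Defaults:

| site | mean (°C) | amplitude | diurnal range | noise sd | character |
|---|---|---|---|---|---|
| hotsite | 28.5 | 2.5 | 14 | 1.5 | hot, stable, "ideal" (irrigated) |
| tempsite | 17.5 | 9.0 | 12 | 2.5 | temperate, variable, rainfed |

Sowing: both sites mid-May (commercial window); the delayed sowing is +1
month at the hot site and +2 months at the temperate site, pushing
reproduction into the warming spring.

**Phenology.** Each genotype carries GDD requirements (flowering ≈ N(450,
35²), maturity ≈ flowering + N(550, 45²) °C·day); a stage date is the first
day cumulative GDD from sowing meets the requirement, so overshoot is less
than one day's contribution. The hot site therefore flowers in ~30 days
against ~90–140 at the temperate site. An unreachable requirement within
the weather horizon is an error.

**Trait response.** Yield (g/plot) is multiplicative in stress:

```
yield = (μ + site_offset + g_i + e_j + ge_ij + block + ε)
        × max(0, 1 − h_i · m_loc · SDD_j)
```

with genotype heat sensitivities `h_i ~ U(0, 0.02)` (fraction of yield lost
per SDD unit) and a site stress-moderation factor `m_loc` (0.2 at the
irrigated hot site, 1 elsewhere): an irrigated canopy cools itself by
transpiration, so its large SDD burden costs far less yield per unit than
the same heat would cost a rainfed crop. The mean effective response —
roughly 1 %/SDD rainfed, 0.2 %/SDD irrigated — is conservative relative to
realized field responses at rainfed sites. HSW (g) is additive and
genotype-dominated: genotype sd 5 g against environment/G×E sds of
0.5/0.4 g and a 0.002 g per SDD unit penalty. Variance defaults (yield:
genotype 200, environment 60, G×E 110, block 40, residual 250 g) were
chosen once to give within-environment heritabilities in the realistic
0.5–0.9 (yield) and ≈0.95 (HSW) ranges and are not adjusted thereafter.

One seeded random stream drives a run, consumed in a fixed order (weather
per location in name order, then genotype/environment/G×E/block effects,
then plot noise), so identical seeds give byte-identical outputs and any
stage can be regenerated independently.

**What the generator does not emulate:** spatial field trend (rows/ranges),
photoperiod and vernalization responses, water-balance dynamics (moderation
is a static site factor), genotype-specific base temperatures, and
measurement error in phenology scoring. Passing tests therefore demonstrate
the estimators recover *designed* effects under clean RCBD assumptions —
not that field data of this shape are free of the confounders above.

## Predicted means and summaries

Predicted means per genotype × environment are block-adjusted replicate
means (observation minus its block's deviation from the environment mean,
then averaged). Under a balanced RCBD this equals the plain replicate mean
and is the expectation-equivalent stand-in for the REML/spatial mixed-model
fits used with proprietary software in designed-trial practice; no
row/range adjustment is attempted. Environments are location × sowing-time
combinations, except for stability runs, which follow the convention of
treating the two sowing times within one location as the environments (one
run per location).

Yield is stored in grams per plot with plot area; t/ha = g / m² × 0.01 is a
derived display unit.

**Relative difference.** All "X % larger/faster/variation" comparisons use
`(max − min)/max × 100` — symmetric, bounded in [0, 100) for positive
inputs. This is deliberately *not* the more common `(max − min)/min`
convention; it is the one under which the package's worked-example
percentage statistics are mutually consistent, so it is applied uniformly.
Table dispersions ("±") are sample standard deviations.

## Stability and GGE

Cultivar superiority uses the standard Lin & Binns form
`P_i = Σ_j (X_ij − M_j)²/(2n)`; static stability is the sample variance
(ddof = 1) across environments. Ranks are ascending (1 = lowest
coefficient) with ties broken by genotype id for reproducibility.

The GGE decomposition centers each environment column by its mean (removing
the environment main effect, keeping G and G×E) and takes the SVD. PC
percentages are `σ_k²/Σσ²·100` over the full spectrum, so they sum to 100.
SVD sign indeterminacy is fixed by making the largest-magnitude genotype
loading on each axis positive. Scalings: symmetric (both sides √σ, the
common GGE display and the default), genotype-focused (UΣ, V),
environment-focused (U, VΣ). A centered matrix that is exactly zero is
flagged degenerate with zero scores rather than an error.

## Heritability

Within one environment, balanced-RCBD method-of-moments components:
`s_e² = MS_error`, `s_g² = max(0, (MS_genotype − MS_error)/r)`, and
`H² = s_g²/(s_g² + s_e²/r)` on the genotype-mean basis. The estimator is
unbiased before truncation and is cross-checked against an independent OLS
ANOVA in the test suite. Unbalanced data are rejected rather than
approximated; negative genetic-variance estimates truncate to zero because
variance components are non-negative by definition. One model per
environment ("within-environment" heritability). The error sum of squares
is floored at zero to absorb floating-point round-off in exact-fit cases.

## Associations

Spearman's rho is the Pearson correlation of mid-ranked data with a
two-sided t-approximation p-value on n − 2 df (delegated to
`scipy.stats.spearmanr`; an independent rank-then-correlate oracle guards
it in the tests). Constant input vectors make the correlation undefined:
the low-level function raises, while the correlation-grid builder reports
NaN with tier "ns" — a mild site can legitimately have an all-zero
vegetative SDD column. Significance tiers are p < 0.05 and p < 0.001, with
no multiple-testing correction across the grid (matching standard practice
for this table layout). Correlations are computed on genotype × environment
predicted means, pooling sowing times within a location.

Exponential yield trends `y = a·e^{bx}` are fitted by least squares on
(x, ln y); R² is reported on the log scale where the model is linear
(configurable to the original scale — the choice is not standardized in the
field). Non-positive responses are a domain error rather than silently
dropped.

## Problem sizes and numerical choices

The default scenario (148 genotypes × 2 locations × 2 sowing times × 2
replicates = 1184 plots, ~400-day weather series) simulates in ~2 s;
per-plot thermal profiles use per-location prefix sums so accumulation is
O(days + plots). Test-suite simulation studies use 200 replicate trials for
variance-component recovery at full panel size, and 20 seeds × 60 genotypes
for the zero-penalty null calibration of the correlation tiers — sizes
chosen to make Monte-Carlo error comfortably smaller than the 5-percentage
point recovery tolerance. Hypothesis property tests run derandomized.

Dates are ISO-8601 calendar dates throughout; weather series must be
gap-free over any window they serve; CSV floats are read with round-trip
precision so write-then-read is exact.

## Known limitations

* The balanced estimators (block-adjusted means, EMS variance components)
  require complete, equal-replication layouts; real trials with missing
  plots need a mixed-model engine outside this package's scope.
* SDD is a purely meteorological statistic: it cannot distinguish heat that
  a well-watered canopy shrugs off from damaging heat, which is why the
  response model needs an explicit site moderation factor.
* Superiority/stability and GGE results depend on the environment grouping
  chosen; with only two environments per stability run the static-stability
  variance has one degree of freedom and ranks accordingly coarse meaning.
* The exponential trend fit weights observations on the log scale; with
  heteroscedastic yields a nonlinear fit would weight large yields more.
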