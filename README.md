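# thermalgxe

Thermal-time and genotype-by-environment (G×E) analysis of heat stress in
chickpea multi-environment field trials.

Plant breeders evaluating many genotypes across contrasting sites and sowing
times need to separate how much of a trait — grain yield, seed size — is
under genetic control and how much is driven by the environment,
particularly by heat. Calendar days are a poor currency for this: the same
genotype may need 60 days to flower at a hot tropical site and 180 at a
temperate one. `thermalgxe` works in thermal time instead, and layers the
standard G×E toolkit of quantitative genetics on top.

## The statistics at its core

**Growing Degree Days (GDD)** accumulate the capped daily mean temperature
above a crop base temperature:

```
GDD = Σ_days max(0, (T'max + T'min)/2 − T_base)
```

with `T'max = min(Tmax, T_ceiling)` and, under the default capping rule,
`T'min = max(Tmin, T_base)`. Defaults for chickpea: base 10 °C, growth
ceiling 30 °C.

**Stress Degree Days (SDD)** isolate supra-optimal heat by differencing two
GDD runs, one with the ceiling lifted to a stress ceiling (50 °C, above any
temperature the crop experiences):

```
SDD = GDD(ceiling = 50 °C) − GDD(ceiling = 30 °C)    (always ≥ 0)
```

On genotype × environment tables of predicted means `X_ij` the package
computes:

* **Cultivar superiority** (Lin & Binns) `P_i = Σ_j (X_ij − M_j)² / 2n`,
  where `M_j` is the best genotype in environment `j` — low values mark
  broadly superior genotypes;
* **Static stability** `S_i² = Var_j(X_ij)` — low values mark
  environment-insensitive genotypes;
* **GGE biplots**: SVD of the environment-centered table, so PC1/PC2
  partition genotype-plus-G×E variance;
* **Broad-sense heritability** from balanced RCBD variance components,
  `H² = s_g² / (s_g² + s_e²/r)`;
* **Spearman rank correlations** of GDD/SDD per growth period (vegetative =
  sowing→flowering, reproductive = flowering→maturity) with yield and
  100-seed weight (HSW), and exponential yield–degree-day trend fits
  `y = a·e^{bx}`.

A fully specified synthetic trial generator (two contrasting sites, two
sowing times, 148 genotypes in 2-replicate RCBDs, thermal-time-driven
phenology, SDD-sensitive yield vs genotype-dominated seed weight) makes the
whole pipeline testable without field data.

## Worked example

```python
import thermalgxe as tg

panel = tg.default_panel(seed=7)
plots, weather = tg.simulate_trial(panel, seed=7)
profiles = tg.profiles_table(plots, weather)

summary = tg.environment_summary(plots, profiles, "full_season")
print(summary[["location", "tos", "age_days_mean", "gdd_mean", "sdd_mean",
               "yield_t_ha_mean", "hsw_g_mean"]].round(1).to_string(index=False))
```

```
location  tos  age_days_mean  gdd_mean  sdd_mean  yield_t_ha_mean  hsw_g_mean
 hotsite    1           68.8     997.8     105.1              2.6        38.0
 hotsite    2           68.1     998.8     113.4              2.5        38.1
tempsite    1          185.2     997.7       8.2              2.4        35.5
tempsite    2          135.2     997.4      15.7              2.2        35.7
```

The hot site matures in ~69 days against ~135–185 at the temperate site —
same thermal requirement, delivered faster — and carries roughly ten times
the seasonal heat load (SDD ≈ 105–113 vs 8–16). The delayed sowing (TOS 2)
raises SDD at both sites and trims temperate yield from 2.4 to 2.2 t/ha.

```python
for res in tg.heritability_by_environment(plots)[:2]:
    print(res.summary())
for trait in ("yield_g", "hsw_g"):
    print(tg.gge_decompose(tg.predicted_means(plots, trait)).summary())
```

```
yield_g @ hotsite-tos1: s_g²=1.194e+05, s_e²=3.001e+04, r=2, H²=0.888
hsw_g @ hotsite-tos1: s_g²=25.75, s_e²=2.45, r=2, H²=0.955
GGE biplot — yield_g (symmetric scaling)
  PC1: 75.10%  PC2: 11.44%  (sum 86.54%)
  148 genotypes × 4 environments
GGE biplot — hsw_g (symmetric scaling)
  PC1: 96.76%  PC2: 1.26%  (sum 98.02%)
  148 genotypes × 4 environments
```

Seed weight is more heritable than yield in every environment and
concentrates more variance on PC1 — the signature of a genotype-dominated
trait — whereas yield spreads into the G×E axes. The designed heat penalty
surfaces as a negative SDD–yield rank correlation at the rainfed temperate
site (`rho = −0.17, p < 0.05` in this run; the hot, irrigated site buffers
its heat load and shows no significant association).

The same pipeline runs from the shell:

```
thermalgxe simulate --seed 7 --out trial/
thermalgxe run --seed 7 --out results/
thermalgxe gge --plots-csv trial/plots.csv --trait hsw_g --figure biplot.png
```

All inputs and outputs are headered CSV (weather: `date,tmin,tmax`; plots:
design, phenology dates, yield in grams, HSW in grams); `run` writes every
analysis table plus a `manifest.json` that fully determines the run.

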