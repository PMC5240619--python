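# divcarbon

Multi-scale analysis of tree diversity and aboveground live-carbon stocks
in tropical forest inventory plots.

Old-growth tropical forests store enormous amounts of carbon in live
biomass and hold most of the world's tree species, and conservation policy
often assumes the two co-vary. Testing that assumption requires taking
stem-level inventory tables (every stem ≥ 10 cm diameter in 1 ha plots,
identified taxonomically) all the way to diversity–carbon inference at
several spatial scales. `divcarbon` implements that pipeline for
ecologists working with standardised plot networks, together with a
synthetic-inventory generator with known ground truth so that every
inferential step can be validated by parameter recovery.

## What it computes

**Carbon.** Each stem's aboveground biomass follows the moist-forest
allometry AGB = 0.0673 (ρD²H)^0.976 (kg), with wood density ρ resolved by
taxonomic fallback (species → genus → family → plot mean), height H from
regional Weibull height–diameter models H = a(1 − e^(−bD^c)), and carbon
= 0.471 × AGB. Per-unit-area aggregation also yields basal area,
basal-area-weighted wood density, stem density and the Gini coefficient of
stem basal areas.

**Alpha diversity.** Taxon richness (with a correction for unidentified
stems), exact individual-based rarefaction E[S_n] = Σᵢ [1 − C(N−Nᵢ,n)/C(N,n)],
Fisher's log-series α solving S = α ln(1 + N/α), Shannon entropy and
Gini–Simpson diversity, at plot (1 ha) and subplot (0.04 ha) scale.

**Beta diversity.** Pairwise Sørensen similarity 2a/(2a+b+c) against
great-circle distance, fitted as ln(similarity) = α + β·distance with a
binomial log-link GLM and plot-level bootstrap envelopes, plus a
gamma-diversity null model of the similarity expected from random
species-pool draws.

**Stand scale.** Bivariate Kendall τ screens with a Fisher-z power
analysis of the minimum detectable effect; all-subsets OLS of ln(carbon)
on diversity, climate (CWD, MAT, MAP) and soil (TEB, C:N, texture) with
AICc model averaging over the 95% confidence set; a maximum-likelihood
simultaneous autoregressive (SAR) error model for spatially
autocorrelated residuals; continental means with bootstrap CIs and
ANOVA/Tukey letters.

**Within plots.** Per-plot OLS of ln(subplot carbon) on ln(richness) plus
a second-order polynomial in ln(stem count); cross-plot slope summary
(bootstrap CI, Wilcoxon signed-rank, sign counts, percent carbon change
per richness doubling = (2^β − 1)·100); and a random-coefficients mixed
model across all plots.

**Mechanisms.** Community-weighted trait means, wood-density dispersion
and functional dispersion regressed on carbon; exact hypergeometric (and
frequency-weighted Monte-Carlo) null curves for the probability that a
community of S species contains a potentially large (max diameter ≥ 70 cm)
or densely wooded (ρ ≥ 0.8 g cm⁻³) species; binomial mixed models of
observed occurrence versus richness.

## Worked example

Simulate a 40-plot network with a true within-subplot diversity→carbon
coupling of β = 0.096, then recover it:

```python
from divcarbon.config import SimConfig
from divcarbon import synthgen, carbon, alpha, within, stand

cfg = SimConfig(n_plots_per_continent=40, continents=("SouthAmerica",),
                beta_true=0.096, seed=42)
data = synthgen.generate(cfg)

stems = carbon.resolve_wood_density(data.stems, data.traits)
stems = carbon.add_height_and_agb(stems, data.plots)
csub = carbon.aggregate_carbon(stems, data.plots, scale="subplot")
dsub = alpha.diversity_profiles(data.stems, scale="subplot")
tab = csub.merge(dsub[["plot_id", "subplot_id", "richness"]],
                 on=["plot_id", "subplot_id"], how="left")

slopes = within.fit_all_plot_slopes(tab)
print(within.summarize_slopes(slopes, n_boot=10000, seed=42).summary())
p = stand.detectable_effect(40)
print(f"detectable r at n=40: {p.r_min:.2f}, tau: {p.tau_min:.2f}")
```

prints

```
Within-plot richness-carbon slopes across 40 plots
  mean beta = 0.1768 +/- 0.0950 SE, 95% bootstrap CI [-0.0084, 0.3611] (10000 resamples)
  Wilcoxon signed-rank vs 0: P = 0.06027
  positive slopes: 27 (67.5%), negative: 13
  doubling richness changes carbon by +13.0%

detectable r at n=40: 0.43, tau: 0.28
```

The mean slope estimate (0.18 ± 0.10 SE) brackets the generating value
0.096 — at 40 plots the sampling error is large, which is exactly what the
power analysis on the last line quantifies: with 40 plots only
correlations of |r| ≥ 0.43 are detectable with 80% power. The doubling
percentage converts the mean slope to the percent change in carbon
expected when subplot species richness doubles.

The same pipeline runs end to end from the shell:

```sh
divcarbon run-all --out demo_run --seed 42
divcarbon simulate --out data_dir --seed 1
divcarbon carbon --stems data_dir/stems.csv --plots data_dir/plots.csv \
    --traits data_dir/traits.csv --scale subplot
```

## Layout

- `src/divcarbon/synthgen.py` — synthetic inventories with known truth
- `src/divcarbon/carbon.py` — allometry and carbon aggregation
- `src/divcarbon/alpha.py`, `beta.py` — diversity metrics, distance decay
- `src/divcarbon/stand.py`, `within.py` — among-plot and within-plot inference
- `src/divcarbon/mechanisms.py` — selection-effect diagnostics
- `src/divcarbon/workflow.py`, `cli.py` — validation, orchestration, CLI
- `docs/methods.md` — modelling assumptions and design choices
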