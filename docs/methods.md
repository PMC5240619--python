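# Methods

This note records the models behind each pipeline stage, the parameters
that matter, what the synthetic-data generator does and does not emulate,
and the numerical and design choices made where more than one reasonable
option existed.

## Carbon from stems

Aboveground biomass per stem is AGB = 0.0673 (ρD²H)^0.976 in kg, with
diameter D in cm (census threshold 10 cm), wood density ρ in g cm⁻³ and
height H in m. Height comes from regional Weibull models
H = a(1 − exp(−bD^c)); the shipped coefficients (asymptotes 42.6 m South
America, 50.5 m Africa, 57.1 m Asia) are plausible regional values and are
overridable — for synthetic-data work only internal consistency matters,
since the generator and the analysis use the same model. Carbon is 47.1%
of biomass (mean carbon fraction of tropical angiosperm wood). Aggregation
divides by unit area in hectares, so a 0.96 ha plot's totals are scaled by
1/0.96.

Wood density resolves by species match, then genus mean, then family mean,
then the mean of the plot's already-resolved stems; the provenance is kept
per stem. Uncertainty in the allometry itself is not propagated. Stem size
inequality is the Gini coefficient of stem basal areas — a bounded [0, 1]
summary of how strongly a few large stems dominate the stand's
cross-sectional area.

## Alpha diversity

* Richness correction: unidentified stems are assumed to add new
  species-level taxa at the unit's observed taxa-per-identified-stem rate,
  S = S_obs + round(U·S_obs/N_id). Stems identified only to genus or
  family neither add species-level taxa nor enter the correction. The
  correction is switchable (`correct_richness=False`).
* Rarefaction uses the exact hypergeometric form with log-gamma
  arithmetic; units with fewer individuals than the rarefaction size give
  missing values — the curve is never extrapolated.
* Fisher's α is the bracketed Brent root of S = α ln(1 + N/α) (relative
  tolerance 1e-12), solved on species-level taxa and stems; S = N returns
  +inf. Simpson diversity is reported in Gini–Simpson form (1 − Σp²).

## Beta diversity and distance decay

Sørensen similarity is computed on species-level taxa only (genus- and
family-level stems excluded), between plot pairs within a continent, with
great-circle distances (Earth radius 6371.0088 km). The decay model
ln(similarity) = α + βd is a binomial-family GLM with log link fitted to
raw pairs; pairs are not binned. Because pairwise rows sharing a plot are
dependent, confidence envelopes bootstrap *plots* (default 10,000
resamples) and rebuild the pair table per resample, dropping self-pairs of
duplicated plots. The analysis restricts to plots with > 90% of stems
identified to species (configurable). The gamma-diversity null model
reports the similarity expected when each plot's observed richness is
drawn at random from the continental pool, either uniformly (closed-form
expected shared count S_aS_b/G, plus Monte-Carlo) or weighted by relative
occurrence frequency (exact weighted sampling without replacement via the
Gumbel top-k race).

## Stand-scale inference

* Kendall τ-b with asymptotic two-sided p-values screens bivariate
  diversity–carbon association; the companion power analysis inverts the
  Fisher-z test, r_min = tanh((z_{1−α/2} + z_{power})/√(n−3)), and maps r
  to τ through the bivariate-normal relation τ = (2/π) arcsin(r). A
  Monte-Carlo routine (`simulated_power`) verifies the nominal 80% power.
* All-subsets regression fits every subset of the seven predictors
  (diversity + CWD, MAT, MAP, TEB, C:N, texture; 128 models) by OLS on
  z-scored predictors. AICc = AIC + 2K(K+1)/(n−K−1) with K counting the
  intercept, slopes and error variance. Averaging uses the top models
  whose cumulative Akaike weight reaches 0.95, with full-model (zero
  substitution) averaging and unconditional standard errors; per-predictor
  summed weights are over all 128 candidates. Ties in the AICc ordering
  break by fewer parameters, then term names. Conditional averaging was
  the alternative; full-model averaging was chosen because the quantity of
  interest is the marginal effect of diversity, and shrinkage toward zero
  for weakly supported predictors is the appropriate behaviour for that
  question.
* The SAR error model y = Xβ + u, u = λWu + ε is fitted by maximum
  likelihood with the log-determinant expressed through the eigenvalues of
  the symmetrised, row-standardised k-nearest-neighbour weight matrix
  (default k = 8; the row-standardised matrix is similar to a symmetric
  one, so its spectrum is real). λ is profiled out by bounded scalar
  optimisation; λ = 0 reproduces OLS exactly, which the tests assert to
  1e-8. No spatial-econometrics dependency is used.
* Continental summaries bootstrap the group mean on the original scale
  (percentile CIs) while the ANOVA/Tukey comparison runs on the
  transformed scale (carbon log-transformed, Fisher's α square-root
  transformed); compact letter displays are built from the pairwise Tukey
  decisions.

## Within-plot analysis

Subplots are the 25 contiguous 20 m × 20 m cells of a 1 ha plot (24 cells
for 0.96 ha). Per plot, ln(carbon) is regressed on ln(richness) and a
second-order polynomial in within-plot-centred ln(stem count) (the
saturating density control); subplots with zero carbon or zero richness
are dropped with a warning, and at least five usable subplots and
non-constant richness are required. Subplot richness is raw observed
species-level taxa — rarefaction to 300 stems is meaningless at ~20 stems.
The cross-plot summary reports the mean slope, its SE, a plot-level
percentile bootstrap CI, a two-sided one-sample Wilcoxon signed-rank test
against zero, sign counts and the doubling conversion
(2^mean − 1)·100%. The one-stage alternative is a random-coefficients
mixed model (random intercept and richness slope by plot, ML); if the
random-slope covariance fails to converge it falls back to a
random-intercept model and says so.

## Selection-effect diagnostics

Community-weighted means weight by basal area (the dominance-weighted
reading of the biomass-ratio hypothesis; stem-count weighting was the
alternative). Functional dispersion is the basal-area-weighted mean
distance of species to the weighted centroid in z-scored (wood density,
ln max diameter) space, standardised over the full trait table. The null
sampling curve P(community of S contains a qualifying species) is exact in
uniform mode, 1 − C(G−K,S)/C(G,S), and Monte-Carlo in frequency mode.
Occurrence models are variational-Bayes binomial mixed models (plot random
intercept); a constant outcome (every unit already contains a potentially
large species) is reported as saturated rather than fitted. Default
thresholds: maximum diameter ≥ 70 cm, wood density ≥ 0.8 g cm⁻³, both
configurable.

## The synthetic-inventory generator

The generator defines the study conditions for all recovery tests.

* **Pools.** Per-species abundances are log-series draws with the
  configured Fisher α (defaults 120 South America, 35 Africa, 130 Asia,
  reproducing the characteristic low African alpha diversity), sorted into
  rank order and normalised. Wood density is truncated-normal (mean 0.60,
  SD 0.15, bounds 0.20–1.15 g cm⁻³); ln(max diameter) is normal with
  median 40 cm and SD 0.45, so roughly a tenth of species are potentially
  large (≥ 70 cm) and a tenth densely wooded (≥ 0.8 g cm⁻³) — minorities,
  as selection-effect logic presumes. Pool size defaults to 1000 species
  per continent, far above per-plot richness, as in real continental
  floras.
* **Occupancy and turnover.** Species occupancy follows a power law of
  pool frequency, q ∝ f^0.4, capped at 0.9 and scaled so expected plot
  richness matches the continental target (150/75/160 species ha⁻¹).
  Presence/absence across plots is a Gaussian-copula threshold field: the
  latent pairwise correlation is obtained by tetrachoric inversion (Owen's
  T orthant formula, interpolated and eigenvalue-repaired to a valid
  correlation matrix) so that the expected pairwise Sørensen similarity
  equals s₀·exp(−decay_rate·d) *by construction*, where s₀ is set by the
  near-distance correlation parameter (default 0.5) and the decay rate
  defaults to 0.001 km⁻¹. The exponential law holds until it reaches the
  chance-overlap floor Σq²/Σq of independent communities, after which
  similarity flattens; with the default pool the floor sits beyond the
  default 500 km × 500 km domain.
* **Stems.** Plot totals are uniform in 400–700 stems ha⁻¹; every present
  species receives one stem and the rest are multinomial in pool
  frequency; subplot membership is uniform over the 25 cells; diameters
  are truncated-Pareto (shape 2.2, minimum 10 cm, capped at the species
  maximum), so large stems dominate biomass. Identification is masked per
  plot (species-level fraction Beta-distributed around 0.90; the remainder
  split genus/family/unidentified 70/15/15), emulating real identification
  levels.
* **Environment.** Each covariate is a Gaussian random field with
  exponential spatial covariance (default range 300 km) sampled at plot
  locations and clipped to the humid lowland domain (MAT ≥ 20 °C,
  MAP ≥ 1300 mm, CWD ≤ 0).
* **Carbon coupling.** Subplot stem diameters are rescaled through
  D → 10 + f(D − 10) (which preserves the census threshold), with f solved
  by Brent root-finding per subplot so that pipeline-computed subplot
  carbon equals exp(a₀ + plot effect + env effects + β_true ln S +
  γ(ln n − plot mean ln n) + noise). β_true defaults to 0.096 (≈ 6.9%
  carbon per richness doubling); γ = 1; lognormal noise SD 0.25;
  between-plot SD 0.30; baseline 165 Mg C ha⁻¹ at 15 subplot species; a
  CWD effect of 0.15 per SD is on by default. The stem-count term is
  centred *within* plots so that in a β_true = 0 world plot-level carbon
  is independent of plot-level diversity — without the centring, the
  sampling correlation between richness and stem count would leak a
  spurious stand-scale diversity effect and the null world would not be
  null.

**What the generator does not emulate:** demographic dynamics (growth,
mortality, recruitment), within-plot spatial clustering of conspecifics,
measurement error in diameters, phylogenetic trait conservatism, and
environmental control of *diversity* (environment affects carbon only).
Recovery tests therefore demonstrate that the estimators are consistent
and calibrated under a known data-generating process — not that tropical
forests obey that process.

## Numerical choices and degenerate inputs

Bracketed root-finding throughout (Fisher's α, occupancy scaling,
diameter rescaling) with explicit bracket growth; log-gamma arithmetic
for all binomial coefficients; percentile bootstrap everywhere a CI is
reported (default 10,000 resamples, reduced in the demo pipeline);
empty subplots carry zero carbon and an `empty_unit` flag; saturated
binary outcomes, constant predictors and all-identical slope sets are
reported as degenerate rather than silently fitted. All randomness flows
from a single integer seed through named substreams, and the full
pipeline is bit-reproducible under a fixed configuration.

## Problem sizes in the validation suite

Recovery checks use 200-plot single-continent worlds for the within-plot
slope (the scale at which the ±2 SE criterion is meaningful), 50 plots
for distance decay, n = 150 for SAR recovery, and 200 null worlds of 35
plots for the false-positive calibration; these sizes give Monte-Carlo
error comfortably inside the stated tolerances.
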