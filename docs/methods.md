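# Methods

`paleofd` implements a continental-scale analysis of how Last Glacial
Maximum (LGM, ~21,000 yr BP) climate legacies shape present-day plant
functional diversity (FD), together with a synthetic study system that
makes every stage runnable and testable without external data. This note
records the models, the defaults, the numerical choices, and what the
synthetic system does and does not capture.

## The analysis

### Trait preparation and multiple imputation

Four continuous ecomorphological traits are used: specific leaf area
(cm² g⁻¹), seed mass (mg), maximum stem height (m) and stem/wood density
(kg m⁻³), plus a categorical growth form (fern, graminoid, forb, shrub,
tree, climber). All four are approximately lognormal, so every analysis
runs on log10-transformed values z-scored to mean 0, SD 1 (population SD,
computed over observed entries; the transform is stored and exactly
invertible).

Compiled trait databases are heavily incomplete (≈40–55% missing per
trait). Gaps are filled by a constrained chained-equations procedure
(MICE):

* each incomplete trait is regressed (OLS) on the other three traits at
  their current filled values, growth-form indicator variables (the
  ecological constraint), and the genus-level mean of the target trait
  computed from observed values (the evolutionary constraint);
* genera with no observed value of a trait fall back to the growth-form
  mean, then the overall mean — this handles monotypic genera, for which
  per-genus fixed effects would be unidentifiable (the reason the genus
  signal enters as a mean covariate rather than fixed effects);
* regression coefficients are perturbed by a draw from their sampling
  distribution (proper imputation), and missing entries are imputed by
  predictive mean matching (PMM) with k = 5 donors, so imputations are
  always observed values and never leave the observed support;
* a chain sweeps all incomplete traits until the mean absolute change of
  imputed values falls below 1e−3 (standardized scale) or 20 sweeps.

The procedure runs m = 10 independent chains, giving 10 complete trait
tables. All downstream quantities are computed per replicate and pooled
(mean and range / percentile interval), which propagates imputation
uncertainty into the final inference. Observed cells are never altered.

Note on accuracy: a single PMM replicate imputes a *draw* from the
conditional distribution, whose RMSE against the truth is ≈ √2 × the
conditional SD — deliberately so, to keep between-replicate variance
honest. The accurate point estimate is the across-replicate mean, whose
RMSE is ≈ the conditional SD and clearly beats column-mean imputation
when traits are correlated; quality checks compare the pooled estimate.

### Functional diversity and the null model

Per grid cell (species assemblage), on the standardized log-trait space:

* **functional richness** F_Rich — the convex-hull volume of the
  assemblage's trait points (units: standardized trait units⁴). Cells
  with fewer than d+1 = 5 species, or affinely degenerate point sets, get
  an *undefined* (NaN) value rather than zero: degeneracy is not a tiny
  hull, and silently joggling the points would trade reproducibility for
  an arbitrary volume. Undefined cells are dropped from regressions.
* **functional dispersion** F_Disp — the mean Euclidean distance of trait
  points to their unweighted centroid; 0 for a single species.
* univariate range (max − min) and dispersion (population SD) per trait.
  The population SD is a descriptive statistic of the assemblage, not an
  estimate of a superpopulation parameter.

The null model redraws each cell's members uniformly without replacement
from the full species pool, preserving the cell's observed species
richness exactly (row sums are invariant). Uniform species weights are
the literal reading of a richness-constrained null; frequency-preserving
swap algorithms are a well-known stricter alternative and are noted here
as a possible extension, not implemented. Standardized effect sizes are
SES = (observed − null mean) / null SD with the n−1 SD; under its own
null the SES is approximately standard normal (calibration is tested).
Presence–absence data only; no abundance weighting.

### Historical predictors

Both historical predictors are built from paired present-day and LGM
climate surfaces, after ensemble-averaging across climate models and
change-factor downscaling of coarse model output onto the fine
present-day baseline (additive anomalies for temperature, multiplicative
ratios for precipitation with the coarse present floored at 0.1 mm and
results clipped at 0; a spatially constant change factor survives the
bilinear interpolation exactly).

**Climate velocity** (km·decade⁻¹) is the ratio of the temporal trend to
the local spatial gradient: trend = |present − LGM| / 2100 decades;
gradient = slope magnitude of the 3×3 plane fit to the present-day
surface (Horn's method — the neighborhood size is prescribed, the
estimator is our documented choice), floored at 1e−5 units·km⁻¹ so flat
surfaces give large-but-finite velocities (flagged), standard practice in
the velocity literature. Edge cells reuse their nearest interior
neighbors (edge replication). Velocity is reported raw and as log10.
Velocity is invariant to adding a constant to both epochs and scales
linearly in the anomaly. Only the two endpoints enter; millennial-scale
dynamics between them (e.g. late-glacial oscillations) are outside the
estimator by construction.

**Accessibility to LGM refugia** (km⁻¹): refugial cells are those
climatically suitable for cool-temperate trees at the LGM — growing
degree-days ≥ 800 °C·day (5 °C base, monthly means × days per month,
non-leap calendar), coldest-month mean ≥ −15 °C, and June–August
precipitation ≥ 50 mm, boundaries inclusive. The coldest-month threshold
is stated as "≥15 °C" in parts of the source literature; +15 °C would
exclude virtually all temperate land and contradicts the cold-*tolerance*
reading of the criterion, so the default is −15 °C and the value is
configurable. Summer = JJA is the Northern-Hemisphere convention.
Accessibility of cell i is Σ_j 1/d_ij over all refugial cells j,
Euclidean centroid distances on the projected equal-area plane; a
refugial focal cell contributes a self-term with d = cell_size/2.
Summation is per refugial *cell*, the literal reading; summing over
contiguous refugial regions would be an alternative aggregation.

### Spatial-error regression and multimodel inference

FD–environment relations are estimated with simultaneous autoregressive
error (SAR-error) models, y = Xβ + u, u = λWu + ε, ε ~ N(0, σ²I), which
keep type-I error control under residual spatial autocorrelation. W links
each cell to its first nearest neighbor, symmetrized (i~j if either is
the other's nearest, so no isolates) and row-standardized; rook/queen
contiguity would be reasonable alternatives on a lattice, and the
symmetrized-kNN reading is the package default.

Maximum likelihood uses the concentrated likelihood: for fixed λ, β̂ and
σ̂² are OLS on the filtered system (I−λW)y, (I−λW)X; the Jacobian
log|I−λW| comes from the eigenvalues of D^{-1/2}BD^{-1/2} (real, since W
is similar to a symmetric matrix), computed once per weights matrix and
shared across all models; a sparse-LU evaluation is kept as a
cross-check. λ is searched on (−0.999, 0.999) by bounded scalar
optimization (xatol 1e−6); estimates at the boundary are flagged. AIC
counts k = p + 2 parameters (coefficients including intercept, plus λ and
σ²) so models of different size are comparable. Response and predictors
are z-scored before fitting, making all coefficients standardized.

Every predictor may enter a model as absent, linear, or unimodal (linear
+ quadratic of the standardized predictor; quadratic never alone,
without orthogonalization — collinearity between x and x² is tolerated
by the exhaustive-AIC design). The model set is the full 3^p factorial
(with an optional cap on the number of included predictors). For p = 12
predictors this is 531,441 models; a published count of 28,672 for the
same description is not reproducible from any obvious truncation rule,
so the factorial rule is implemented and the enumeration is configurable.
Summaries:

* Akaike weights w_i = exp(−Δ_i/2)/Σ exp(−Δ_j/2);
* variable importance W = Σ w_i over models containing the predictor;
* model-averaged standardized coefficients, *conditional* form
  (Σ w_i β_i / Σ w_i over containing models — the literal "weighted by
  the w of the model that contained it"); terms with containing weight
  < 0.1 are flagged low-support. Zero-filled full-set averaging is the
  documented alternative;
* explained variance per predictor: Nagelkerke pseudo-R² of the
  single-predictor unimodal model against the intercept-only SAR-error
  fit (not OLS), which isolates the predictor's contribution from the
  spatial structure: R²_CS = 1 − exp(−(2/n)(L₁−L₀)) normalized by
  1 − exp((2/n)L₀), clipped to [0, 1);
* partial residuals r + b·x for effect displays, r being the fitted
  model's response-scale residuals. The exact slope identity holds in
  the model's own (spatially filtered) metric.

Everything is computed per imputation replicate; pooled summaries report
the replicate mean with the empirical 2.5–97.5 percentile interval.
Rubin's rules are not used because the pooled quantities are summary
scores (importance, R²), not coefficient/SE pairs.

**Spatially corrected correlations** between predictors use Dutilleul's
modified t-test: distance-class Moran autocorrelation estimates for both
variables (13 equal-width classes by default) build estimated correlation
matrices R̂x, R̂y; with the centering projector B, the effective sample
size is n* = 1 + tr(BR̂xB)·tr(BR̂yB)/tr(BR̂xB·BR̂yB) (capped at n), and
the t-test uses n*−2 degrees of freedom. On strongly autocorrelated
independent surfaces this holds the nominal 5% level (measured ≈5–6%)
where the naive test rejects ~45% of the time.

## The synthetic study system

Defaults define the reference conditions and are fixed once:

| parameter | default | rationale |
|---|---|---|
| grid | 20×20 cells of 50 km | desk-scale analogue of a ~50 km continental atlas grid |
| species / genera | 300 / 40 | enough for 4-D hulls at all richness levels; real atlas ~2700 |
| trait correlation | 0.5 off-diagonal (log scale) | mid-strength allometric coupling |
| missingness | SLA 50%, height 53%, seed mass 50%, density 42% | the completeness profile of compiled trait databases |
| richness range | 10–150 | gradient wide enough to expose richness-mediated effects |
| SAR λ | 0.3 | moderate residual autocorrelation |
| planted effects | accessibility 0.5, GDD 0.3 (standardized) | historical effect comparable to contemporary, as in the motivating system |
| noise SD | 1.0 | unit-variance innovations; standardized effect sizes read directly |

Traits are lognormal with the configured inter-trait correlation applied
to *both* the genus-level intercepts and the species-level deviations
(genus share 30% of log-scale variance), so the total log-scale
correlation equals the configured matrix exactly regardless of the
variance split. Growth form is assigned per genus. Missingness is MCAR —
the simplest mechanism under which chained equations are unbiased; real
trait databases are likely missing-not-at-random (rarer, smaller species
are less measured), which the generator does not emulate, so imputation
tests here certify the machinery, not robustness to MNAR.

Climate surfaces combine a south–north temperature gradient, a seasonal
cycle with spatially varying (continentality) amplitude, an independent
smooth "orography" surface driving precipitation, and LGM anomalies
(everywhere-colder, strongest at high latitude) and glacial-aridity
factors with their own smooth textures. The textures are low-frequency
random-phase sinusoid sums, seeded from the config. They exist so that
the six derived predictors — accessibility, temperature and precipitation
velocity, GDD, annual precipitation, coldest-month temperature — are only
weakly cross-correlated (max |r| ≈ 0.7, between GDD and winter
temperature, which are intrinsically coupled), matching the
near-orthogonal predictor sets of real continental analyses; with a
single latitude gradient every predictor would be collinear and no
inference test could attribute effects. Glacial aridity is strong enough
that the summer-moisture criterion co-limits the refugia (≈16% of cells
refugial), giving refugial geography a pattern of its own.

Occurrences: per-cell richness is a deterministic monotone (min–max)
rescaling of accessibility into the richness range; membership is drawn
without replacement with Gaussian inclusion weights on the standardized
SLA axis, with the niche optimum tracking the standardized GDD and the
niche width shrinking where GDD is extreme. This produces the two
couplings the recovery tests need — richness follows the historical
predictor, and trait space narrows (negative SES) under environmental
filtering — by a mechanism chosen for transparency, not realism.

Response vectors for recovery experiments come from the exact SAR
process: ε is drawn i.i.d. normal, and u solves (I − λW)u = ε by sparse
LU, not by truncated series, so generated data satisfy the model
identity to machine precision.

What the synthetic system does **not** emulate: real geography and
coastlines, taxonomic structure beyond genus, inter-model spread of
paleoclimate ensembles (the ensemble-mean operation is exercised on
synthetic member lists), MNAR missingness, frequency-structured species
pools (null-model tests use the uniform pool), and observation error in
occurrences. Passing tests therefore certify the estimators and their
calibration under the stated data-generating processes, not performance
on any particular real atlas.

## Numerical choices and degenerate inputs

* Convex hulls: Qhull without joggling; degeneracy → NaN.
* Zero null SD, fewer than two finite nulls → SES undefined (NaN).
* Constant trait column or non-positive observed trait value → error
  naming the trait (and species).
* Duplicate cell coordinates → error (nearest neighbor ill-defined).
* λ search bounded at ±0.999 (|I−λW| > 0 for row-standardized W);
  boundary estimates flagged, σ² floored at 1e−300 in the likelihood for
  the exact-fit limit.
* Log10-transformed predictors (velocities, annual precipitation,
  elevation-heterogeneity analogues) are floored at one tenth of their
  smallest positive value before the transform.
* Cells whose response is undefined in any imputation replicate are
  dropped from all replicates and the weights matrix is rebuilt, keeping
  the model sets comparable across replicates.
* All randomness flows from explicit integer seeds through
  `numpy.random.Generator`; reruns are byte-identical.

## Problem sizes

Default test and acceptance runs use the 20×20 grid (400 cells), 300
species, 3⁶ = 729-model enumerations, 100-seed SAR recovery batches,
500-draw null models and 500-seed type-I-error simulations. These sizes
were chosen so the full property suite demonstrates calibration at
comfortable desk scale; all of them are configuration, not code limits.

## Known limitations

* The SAR fit reports ML point estimates; no coefficient standard errors
  or Wald tests (the inferential currency here is AIC weighting, as in
  the analysis the package implements).
* Conditional model averaging is biased away from zero for weakly
  supported terms; the support column and low-support flag must be read
  together with the coefficient.
* PMM with k = 5 donors cannot extrapolate beyond the observed trait
  range; under strong range truncation it compresses tails.
* The Dutilleul correction's distance classes use equal-width bins; very
  irregular point configurations may warrant user-chosen class edges.
* `fd_pipeline` recomputes null hulls per imputation replicate; with
  n_null = 1000 and thousands of cells this is the dominant cost and is
  best run with a reduced n_null first.
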