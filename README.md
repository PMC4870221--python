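# paleofd

**Paleoclimatic legacies in plant functional diversity**: a tested,
reusable pipeline linking the functional diversity (FD) of gridded plant
assemblages to historical (glacial) and contemporary environmental
predictors.

Continental floras still carry the imprint of the Last Glacial Maximum
(LGM, ~21,000 yr BP): assemblages far from glacial refugia, or in regions
where climate moved fast since the LGM, occupy less trait space than
contemporary conditions alone would predict. Testing that idea requires a
chain of methods that this package implements end to end:

1. **Trait imputation** — species×trait tables (specific leaf area, seed
   mass, maximum height, stem/wood density, growth form) are ~40–55%
   incomplete; gaps are filled by a genus- and growth-form-constrained
   chained-equations procedure (MICE with predictive mean matching),
   repeated m = 10 times to propagate imputation uncertainty.
2. **Functional diversity** — per grid cell, on log10-transformed
   z-scored traits: functional richness *F*<sub>Rich</sub> (convex-hull
   volume of the assemblage's trait points) and functional dispersion
   *F*<sub>Disp</sub> (mean distance to the trait centroid), univariate
   trait ranges/SDs, and standardized effect sizes
   SES = (obs − null mean)/null SD under a null model that redraws each
   cell's species uniformly while preserving its richness exactly.
3. **Historical predictors** — from paired present/LGM climate surfaces
   (ensemble-averaged, change-factor downscaled): climate velocity
   (temporal anomaly / local 3×3 spatial gradient, km·decade⁻¹) and
   accessibility to LGM refugia (Σ 1/d to all cells meeting
   GDD ≥ 800 °C·day, coldest month ≥ −15 °C, summer precip ≥ 50 mm).
4. **Spatial multimodel inference** — SAR-error regressions
   y = Xβ + u, u = λWu + ε (W: symmetrized first-nearest-neighbor,
   row-standardized; maximum likelihood via the concentrated likelihood
   with an eigenvalue log-determinant), enumerated exhaustively over all
   3^p combinations of absent/linear/unimodal responses per predictor,
   and summarized by Akaike weights, variable importance
   *W*<sub>AIC</sub>, conditional model-averaged standardized
   coefficients, single-predictor Nagelkerke pseudo-R², and partial
   residuals. Dutilleul's modified t-test provides spatially honest
   predictor correlations.

A first-class **synthetic study system** (`paleofd.synthetic`) generates
every input — correlated lognormal traits with genus structure, realistic
missingness, paired present/LGM climate surfaces, occurrence matrices
with richness gradients and trait filtering, and exact SAR-process
responses — so the full pipeline runs, and is tested, with no external
data. See `docs/methods.md` for models, defaults, and limitations.

## Worked example

```python
import paleofd as p
from paleofd.pipeline import RunConfig
from paleofd.synthetic import SyntheticConfig

cfg = RunConfig(
    synthetic=SyntheticConfig(grid_nrows=10, grid_ncols=10, n_species=150,
                              n_genera=25, richness_range=(10, 80), seed=42),
    m_imputations=3, n_null=50, out_dir="readme_run",
)
res = p.run_all(cfg)
print(res.inference["f_rich"].importance.round(3))
```

```
         predictor  importance_mean  importance_lo  importance_hi
0    accessibility            1.000          1.000          1.000
1    temp_velocity            0.445          0.342          0.624
2  precip_velocity            0.448          0.347          0.598
3              gdd            0.740          0.446          0.982
4    annual_precip            0.465          0.361          0.563
5        tmin_cold            0.411          0.392          0.425
```

The synthetic study plants a standardized accessibility effect of 0.5 and
a GDD effect of 0.3 on the assemblage process; the inference recovers
accessibility with full support (*W*<sub>AIC</sub> = 1.0 across all three
imputation replicates, interval zero-width) while the no-effect
predictors sit near the 0.4–0.5 baseline that exhaustive enumeration
assigns to uninformative variables. The averaged-coefficient table shows
the effect size and shape:

```
             term  coefficient_mean  support_mean  low_support
  accessibility:b             0.950         1.000        False
 accessibility:b2            -0.094         0.664        False
  temp_velocity:b            -0.028         0.445        False
```

— a strong positive linear accessibility response (standardized 0.95;
the planted 0.5 plus the indirect richness-mediated pathway, since
richness itself follows accessibility in the generator). Single-predictor
explained variance (Nagelkerke pseudo-R² against the intercept-only
SAR-error fit) tells the same story: accessibility 0.86, GDD 0.44,
temperature velocity 0.21. Per-cell FD tables carry richness,
*F*<sub>Rich</sub>, *F*<sub>Disp</sub> and their SES; with the
generator's trait filtering on, SES *F*<sub>Rich</sub> is negative where
filtering is strong (mean ≈ −0.4 in the run above).

The same stages are available from the shell:

```bash
paleofd run-all --out run_dir            # full synthetic pipeline
paleofd simulate --out sim --seed 1      # traits with missingness
paleofd impute --traits sim/traits.csv --out imp -m 10
paleofd climate velocity --present p.asc --lgm l.asc --out v.asc
paleofd infer --predictors pred.csv --fd fd.csv --out inf
```

Rasters are plain-text ESRI ASCII grids; tables are CSV; every run writes
a manifest with its config digest and seeds, and reruns are
byte-identical.

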