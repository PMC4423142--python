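# tyroqsar

QSAR modelling toolkit for L-tyrosine scaffold MMP-2 inhibitors.

MMP-2 (gelatinase A) is a zinc metalloproteinase central to tumor invasion.
A published series of 30 L-tyrosine derivatives, varying in three substituent
positions (R1/R2/R3), spans pIC50 ≈ 4.1–7.9 against MMP-2. This package
implements the full descriptor-based activity-modelling workflow used to
analyse that series, for medicinal chemists and chemometricians who want a
reproducible, tested version of each stage:

* **3D molecular descriptors** computed from structures (SDF V2000 / XYZ):
  first-order information content (IC1), 3D-MoRSE signals, radial
  distribution function (RDF) values, Geary autocorrelations (GATS), WHIM
  directional indices, GETAWAY leverage autocorrelations (HATS/R/Rmax),
  Randic-style shape profiles, and PM3-derived quantum indices
  (η, S, χ, ω, dipole components).
* **Matrix cleanup**: near-constant removal and a collinearity filter that,
  in every descriptor pair with |r| > 0.9, keeps the member more correlated
  with the activity.
* **Stepwise MLR via CDFS** (combined data splitting–feature selection):
  ten seeded 24/6 splits, a stepwise model per split, retention at
  R²_c > 0.95, pooled descriptor union, and a general model selected by
  leave-one-out Q².
* **GA-PLS**: genetic-algorithm descriptor selection with partial-least-
  squares fitness (cross-validated Q² minus a sparsity penalty).
* **Validation and applicability domain**: Q²_LOO/RMS_CV, Y-randomization,
  and the Williams plot (leverage vs standardized residual) with warning
  leverage h\* = 3(k+1)/n.
* **Published equations** as ready predictors, e.g. the general MLR model

  pIC50 = −13.428 + 5.965·IC1 + 1.464·Mor24m − 0.187·RDF115m + 0.307·SP20 + 1.284·Mor15e

  (N = 24, R²_c = 0.958, Q²_LOO = 0.921), its GA-PLS counterpart, and the
  packaged 30-compound reference table.

Because the original descriptor matrices are not public, the package ships a
first-class synthetic-data module that emulates the study's dimensions
(30 compounds × 291 post-filter descriptors, sparse activity signal,
correlated descriptor blocks, 24/6 split) with a known generating truth, so
every pipeline stage is testable end to end.

## Worked example

`examples/` contains one short script per capability. Recovering a known
5-descriptor truth with CDFS on the synthetic bundle
(`python examples/03_cdfs_stepwise_mlr.py`) prints:

```
pooled descriptor union: 14 descriptors
general model: Mor29u, RDF010e, RDF020v, RDF040p, RDF095e
  R2_c = 0.996, S.E = 0.515, Q2_LOO = 0.993, RMS_CV = 0.597, R2_p = 0.965
generating truth: Mor29u, RDF010e, RDF020v, RDF040p, RDF095e
recovered exactly: True
```

The ten per-split rows above it mirror the usual model-report layout
(descriptors used, R²_c, S.E, R²_p, Q²_LOO, RMS_CV). R²_c is the calibration
fit, Q²_LOO the leave-one-out predictive fit (Q² ≤ R² always), and R²_p the
squared correlation between predicted and observed activities on the held-out
validation compounds. Evaluating the published general equation with all
descriptors zero returns its intercept, −13.428
(`python examples/06_published_predictions.py`).

A thin CLI mirrors the library stages:

```bash
tyroqsar simulate --preset qsar30 --seed 7 --out bundle/
tyroqsar filter --desc bundle/X.csv --activity bundle/y.csv --out filtered.csv
tyroqsar mlr-cdfs --desc filtered.csv --activity bundle/y.csv --seed 7 \
    --out-model model.json --out-report report.csv
tyroqsar predict --model eq1 --desc descriptors.csv --out predictions.csv
```

## Documentation

`docs/methods.md` describes the models, the numerical choices, the
synthetic-data design and the known limitations.
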