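# Methods

## Scope and data model

The package models MMP-2 inhibitory activity (pIC50) of small molecules as a
linear function of named molecular descriptors. A molecule is an ordered atom
list with 3D coordinates in Å plus an undirected bond graph; descriptors are
deterministic functions of that structure (and, for the electronic ones, of a
per-molecule quantum record carrying E_HOMO, E_LUMO in eV and the dipole
vector in Debye). Geometry optimization and quantum-chemistry calculations
are out of scope: coordinates and orbital energies are inputs.

## Descriptors

All 3D descriptors use carbon-scaled atomic weights w_i =
property(element)/property(C) with schemes u (ones), m (mass), e (Sanderson
electronegativity), p (polarizability), v (van der Waals volume). The
property table packages CRC atomic masses, Sanderson electronegativities,
atomic polarizabilities, Bondi-radius-derived van der Waals volumes and
Cordero covalent radii, and is versioned with the package so results are
reproducible.

* **IC1** — atoms are partitioned by (atomic number, degree, multiset of
  neighbor (atomic number, bond order)); IC1 is the Shannon entropy
  −Σ (n_g/n) log₂(n_g/n) of the partition, in bits. Range [0, log₂ n].
* **3D-MoRSE** — Mor(s) = Σ_{i<j} w_i w_j sin(s·r_ij)/(s·r_ij), with
  signal k ↔ s = k−1 Å⁻¹ over the 32-signal catalogue (so signal 1 is the
  weighted pair count; sin(0)/0 ≡ 1).
* **RDF** — RDF(R) = Σ_{i<j} w_i w_j exp(−B(R−r_ij)²). Names encode the
  radius in tenths of an Å on the 1.0…15.5 grid (RDF115 ↔ 11.5 Å). The
  smoothing B defaults to 100 Å⁻² and is configurable; it is not printed in
  the source material, so the default follows the standard parameterization.
* **GATS** — the standard Geary spatial-autocorrelation estimator at a
  topological lag: c = [(n−1) Σ_{d_ij=lag}(w_i−w_j)²] / [2Δ Σ_i(w_i−w̄)²],
  sums and Δ over ordered pairs. For i.i.d. weights its expectation is ≈ 1,
  which the test suite verifies by Monte-Carlo. Zero weight variance or an
  empty lag yields NaN, never a silent zero.
* **GETAWAY** — atomic leverages h are the diagonal of the molecular
  influence matrix M(MᵀM)⁻¹Mᵀ of centered coordinates (pseudo-inverse, so
  Σh equals the coordinate rank: 3, 2 or 1). Over unordered pairs at a lag:
  HATS = Σ (w_i√h_i)(w_j√h_j), R = Σ (√(h_i h_j)/r_ij) w_i w_j, and Rmax is
  the largest single R summand (name suffix "0", e.g. R7e0).
* **WHIM** — eigen-decomposition of the weighted covariance of centered
  coordinates (weights normalized to sum 1). L_m are the eigenvalues
  (size), E_m = L_m²·n/Σ_i t_im⁴ an inverse-kurtosis accessibility index of
  the axis scores, and the symmetry index G_m = [1 − ((n_s/n)log₂(n_s/n) +
  (n_a/n)log₂(1/n))]⁻¹ with n_s the atoms possessing a mirror counterpart at
  −t (or lying on the plane) within a relative tolerance of 1e-4 of the
  score scale. G_m = 1 exactly for full symmetry. Published WHIM variants
  differ in the symmetry tolerance convention; this formula is fixed here
  and validated by property tests (rotation invariance, exact symmetry),
  not by matching any external implementation's values.
* **Shape profiles** — SP_k = [(2/(n(n−1))) Σ_{i<j} r_ij^k]/k!, the k-th
  average distance moment with a factorial scale that keeps high orders
  (SP20) in a sane numeric range. Shape-profile variants also differ across
  published sources; the moment form above is the package's fixed choice.
* **Quantum indices** — hardness η = ½(E_HOMO+E_LUMO), softness S = 1/η,
  electronegativity χ = ½(E_HOMO−E_LUMO), electrophilicity ω = χ²/(2η), as
  used by the source analysis. These are the sign-swap of the conventional
  definitions; `convention="textbook"` switches to η = ½(E_LUMO−E_HOMO),
  χ = −½(E_HOMO+E_LUMO). η = 0 makes S and ω NaN.

Hydrogens are kept by default (3D descriptors are conventionally computed on
H-included structures); every table-building call accepts
`hydrogens=False`. Undefined descriptor values propagate as NaN and the
near-constant filter removes such columns, so model selection never sees
fabricated zeros.

The 26-descriptor preset is the union of every descriptor appearing in the
reported models: the 22 of the ten split models plus RDF035v, RDF135m,
HATS7e and Mor32e.

## Preprocessing

Near-constant removal drops columns with any missing values, sd < 1e-8, or a
most-frequent value covering > 90% of rows (no threshold is standard; these
defaults are stated and configurable). The collinearity filter visits pairs
with |Pearson r| > 0.9 in descending |r| and drops the member less
|correlated| with the activity (ties keep the earlier column), which
guarantees no surviving pair exceeds the cutoff. Splitting is uniform random
without replacement (seeded); an activity-sorted systematic mode exists for
deterministic reproducibility studies. No scaling or imputation: the models
use raw descriptor values, as linear equations with physical coefficients
imply.

## Stepwise MLR and CDFS

`fit_ols` solves least squares with intercept and reports coefficient
standard errors, R², and the residual standard error sqrt(RSS/(n−p−1)).
Stepwise selection is classic forward-entry/backward-removal on partial-F
p-values with the common defaults p_enter = 0.05, p_remove = 0.10 and a term
cap of round(n/5). Entry p-values for all candidates are computed at once by
projecting the response and candidates out of the current design (QR), which
is algebraically identical to the add-one t-test. Note that with many
candidates the per-candidate 0.05 entry threshold admits chance descriptors
at the usual multiple-testing rate; the CDFS layer, not the threshold, is
the guard against such noise.

CDFS makes 10 seeded 24/6 splits, runs stepwise on each calibration set, and
retains models with R²_c > 0.95 (a flag switches the criterion to R). The
retained models' descriptors form the pooled union. A final stepwise run
restricted to the pool on a designated fresh split produces a path of nested
candidate models; every candidate the procedure has visited — that path plus
the retained per-split models, all subsets of the pool — is scored by
leave-one-out Q² on the designated calibration, and the maximizer wins (ties
go to fewer descriptors). Scoring the retained models as well as the final
path makes the selection robust to a single unlucky greedy run on the
designated split; all candidates remain subsets of the pooled union, so the
CDFS containment invariant holds. Q²_LOO uses the exact hat-matrix shortcut
(deleted residual e_i/(1−h_ii)), proven equal to the n-refit loop in the
test suite.

## GA-PLS

Chromosomes are binary descriptor-inclusion vectors. Fitness is the
leave-n-out cross-validated Q² of a PLS model on the encoded subset — with
the component count chosen internally by the same cross-validation up to
min(5, k, n−2) — minus a sparsity penalty of 0.005 per selected descriptor,
implementing the stated preference for the smallest subsets with the highest
fitness. Operators: tournament selection (size 2), single-point crossover
(p = 0.9), per-gene mutation (default 1/pool), elitism 2, and a sparse
initial population (gene-on probability 0.1 by default). The population size
is validated against the 80–125 band used in the original runs unless
explicitly overridden for small problems. The all-zero chromosome has
fitness −∞. Runs are bit-reproducible for a fixed seed, and elitism makes
the best-ever fitness non-decreasing (asserted every run in the tests). PLS
itself is scikit-learn's NIPALS implementation, exposed both in latent form
and as collapsed original-space coefficients; with full components it
reproduces OLS, which the tests verify.

## Validation and applicability domain

Q²_LOO = 1 − PRESS/Σ(y−ȳ)² and RMS_CV = √(PRESS/n). Y-randomization refits
the fixed descriptor subset on seeded permutations of the activity (identity
permutations are redrawn) and flags whether every permuted R² and Q² falls
below the true model's. The Williams table computes leverage
h_q = x_qᵀ(X_cᵀX_c)⁻¹x_q on the intercept-augmented calibration matrix of
the model's own descriptors (matching the per-model domain plots), and
standardized residuals divided by the calibration residual standard error
(a per-point deleted variant is switchable). Flags: |std residual| > 2 and
h > h\* = 3(k+1)/n. h\* is always computed from the actual descriptor count
k; for a 4-descriptor model at n = 24 this gives 0.625, not the 0.5 that a
3-parameter count would give — a discrepancy the source material leaves
ambiguous and which this package resolves in favor of the formula.

## Synthetic data

`make_regression_dataset` emulates the post-filter study matrix: n = 30 rows
(compounds), p = 291 standard-normal descriptor columns with QSAR-style
names, of which 5 blocks of 4 columns share a latent factor (pairwise
correlation ≈ 0.95) to exercise the collinearity filter. The activity is
intercept + X[:, support]·β + N(0, σ²) with the true support drawn outside
the blocks, σ = sd(signal)/SNR and SNR = 10 by default. Coefficient
magnitudes follow a geometric cascade from 5.0 down to 1.0 (each true
descriptor explains roughly half the signal variance left after the ones
before it), with random signs. This dominance structure mirrors real QSAR
series, where one lead descriptor (here the size/branching index IC1 in
every reported model) carries most of the activity variance and the rest
refine it; it is also what makes greedy forward selection a sensible
estimator for the problem. What the generator does **not** emulate: real
descriptor marginal distributions, non-linear structure-activity relations,
activity measurement heteroscedasticity, and between-descriptor correlations
beyond the explicit blocks — so passing recovery tests demonstrate the
pipeline's statistical machinery, not chemical validity on new series.
`make_point_cloud_molecule` provides descriptor test substrates: uniform
random coordinates in a box joined by a random spanning tree, so every
topological lag exists and all graphs are connected. Every generator is
byte-reproducible from its seed.

The default test and example problem sizes (40 seeded bundles for CDFS
recovery, 20 GA runs on a 30-descriptor pool, leave-6/leave-10 folds for GA
fitness) were chosen to make the statistical assertions sharp while keeping
a full run of the suite inside a few minutes on one CPU.

## Numerical choices and degenerate inputs

Rank-deficient OLS designs raise; leverages use the pseudo-inverse; a
leave-one-out fold with leverage 1 raises rather than dividing by zero.
Equal-|correlation| ties in the collinearity filter and equal p-value ties
in stepwise resolve to the earlier column, making every pipeline stage
deterministic given a seed. Coincident atoms make the influence matrix and
WHIM undefined (error); a pair of bonded atoms at zero distance makes the
GETAWAY R sum undefined (error). Descriptor invariance under rigid motion
and atom renumbering holds to 1e-8 relative tolerance and is asserted on
random pseudo-molecules.

## Known limitations

* The published equations are shipped with their printed coefficients; the
  original DRAGON/PM3 descriptor values are unavailable, so the package does
  not recompute the original calibration statistics or Table-level predicted
  values from structures, and descriptor implementations are validated by
  mathematical properties and independent oracles rather than by matching a
  proprietary implementation's outputs.
* Stepwise and GA searches are heuristics; exact support recovery on
  synthetic data is a statistical statement (≥95% / ≥90% over seeds), not a
  guarantee per run.
* Only the descriptor families appearing in the reported models are
  implemented; the wider descriptor catalogue (BCUT, Galvez, walk counts,
  …) is out of scope.
* Bond perception from XYZ uses a covalent-radius distance rule (1.15 ×
  r_i + r_j, configurable); no aromaticity perception beyond what input
  files encode.
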