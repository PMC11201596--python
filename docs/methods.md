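# Methods

This note documents the statistical model behind each stage, the defaults
and why they are what they are, what the synthetic-data generator does and
does not emulate, and the numerical choices that matter when reproducing or
extending results.

## Severity index

The behavioral target is the first principal component of a battery of m
alcohol-consumption measures (default m = 15), computed on the
**correlation** matrix: each measure is z-scored, so variance explained is
exactly 100·λ₁/m. This convention is identified by the arithmetic of the
reference battery (λ₁ = 7.42 over 15 measures ⇔ 49.47%); covariance-matrix
PCA would not satisfy that identity. Scores are the projection onto the
leading eigenvector, standardized to unit variance.

Two conventions the eigendecomposition cannot fix are made explicit
arguments:

- **flip set** — measures whose natural direction is protective (e.g.,
  abstinence counts) are sign-inverted before PCA. Which measures need
  flipping is a property of the instrument, not of the data, so it is user
  input; the simulator records its own flip set in the ground truth and the
  pipeline applies it automatically for simulated cohorts.
- **anchor** — an eigenvector's global sign is arbitrary, so PC1 is
  oriented to correlate non-negatively with a named severity-aligned
  measure (default: the first column; the pipeline picks the first
  unflipped measure for simulated cohorts).

Subjects with any missing measure are excluded at table construction and
recorded; no imputation is attempted. A constant measure column is an
error naming the column.

## Connectivity

Edges are pairwise Pearson correlations over the concatenated frames of
one condition's blocks. Defaults and their rationale:

- `lag_frames = 0`: raw block time courses; a lag is exposed for
  sensitivity analyses of hemodynamic delay, with windows checked to stay
  inside the run and not overlap after shifting.
- Fixation/baseline frames are never concatenated into task connectivity;
  the short inter-block baselines carry over task dynamics.
- Blocks are concatenated across runs first and correlated once
  (concatenate-then-correlate), rather than averaging per-block
  correlation matrices.
- Pearson r is the default CPM feature; Fisher z (atanh, diagonal set to 0)
  is a flag.
- A constant node column is an error by default; the `"missing"` policy
  instead NaNs that node's edges and logs, for cohorts with dropped-out
  parcels.

Extraction from a 4-D image with an integer label atlas computes the mean
voxel time course per label, labels ordered 1..max, with empty labels
producing a warning and an all-NaN column rather than silently renumbering
nodes.

## CPM

Edge selection uses the **partial Pearson correlation** between each edge
and the severity score controlling age and sex, implemented as a QR
projection of both sides onto the orthogonal complement of
[1, covariates] (numerically identical to residualize-then-correlate);
two-tailed p from t = r·√(df/(1−r²)) with df = n − 2 − q. The alternative
`method="residualized"` correlates raw edges with covariate-residualized
behavior only. Covariates enter selection but not the predictive model,
matching common CPM practice; the predictive model is OLS of behavior on
the network strengths (one predictor for a single polarity, two for
`combined`).

Defaults: `p_threshold = 0.01` (the conventional CPM default), LOOCV, and
for k-fold a fresh random partition per repeat with `repeats` configurable
(1 by default; per-repeat r values are retained and the headline r is their
mean). The **consensus mask** reported from a run contains edges selected
in 100% of folds (fraction configurable); an edge that ever switches sign
across folds is excluded from the negative consensus to keep the sets
disjoint.

Degenerate training folds (no edges selected, or constant strength) fall
back to an intercept-only model, are counted, and logged. Note a LOOCV
pathology worth knowing: if *every* fold is intercept-only, predictions are
leave-one-out training means, which anti-correlate perfectly with the
held-out values (r = −1); this is the expected behavior of the estimator,
not a defect, and disappears as soon as any signal is selected.

The permutation test permutes behavior labels across subjects while
keeping covariates bound to their subjects — the null hypothesis is "no
behavior–connectome association", not "no covariate structure" — and
re-runs the full cross-validation per permutation, selection included.
p = (1 + #{r_perm ≥ r_obs})/(1 + n_perm), so the attainable floor is
1/(n_perm + 1).

### Calibration oracle

`netfingerprint.calibration` links generator knobs to attainable
prediction performance. Over F i.i.d. frames a sample correlation around
ρ has SD ≈ (1−ρ²)/√(F−1); a planted edge's across-subject correlation with
severity is effect/√(effect² + sd²); and a polarity's strength sum of m
planted edges plus the ≈ (α/2)·E_null spuriously selected null edges has
correlation m·effect/√(m²·effect² + (m+k)·sd²) with severity. The combined
two-predictor ceiling is the root-sum-square of the two polarities'
correlations, and `effect_for_prediction_r` inverts it by bisection.

Two empirical facts the closed form deliberately brackets rather than
models exactly (both verified by Monte-Carlo in the test suite and during
design): (1) spuriously selected edges retain their in-cohort correlation
out-of-fold under LOOCV (held-out subjects belong to the same cohort
selection saw), which adds an optimism of roughly +0.02 to observed r at
the default threshold and, more importantly, adds seed-to-seed variance
that grows with the number of testable edges; (2) observed cross-validated
r therefore has an irreducible spread of ≈ 0.06–0.14 SD across cohorts at
n = 500 depending on atlas size. Studies reporting a single cross-validated
r should expect that spread.

## Anatomy

Degrees are incident-edge counts per polarity; "highest-degree nodes" are
reported as the complete argmax set, with ties kept together rather than
broken arbitrarily. Canonical-network matrices count mask edges by the
unordered pair of endpoint networks over the ten macroscale systems; the
upper triangle (diagonal included) sums to the mask size, a conservation
law the tests enforce. Edge fraction uses the unordered-pair denominator
C(n,2) — for a 268-node atlas, 35,778 — under which a 39-edge mask is
0.109% of all possible connections and a 44-edge mask 0.123%.

The 268-node annotation shipped for tests (`synthetic_atlas_annotation`)
is a deterministic synthetic stand-in: macro-regions, networks, and
coordinates are arbitrary but fixed. Real annotation tables load through
`anatomy.read_atlas` in the same format.

## Molecular profiling

The regional GLM regresses each region's contrast value on
[1, severity, age, sex]; T is the severity coefficient over its standard
error with df = n − 4. This parcel-level GLM is a deliberate approximation
of a voxelwise map-then-parcellate pipeline: the downstream spatial
correlation consumes only regional values, and at matched regions the two
routes agree up to within-parcel averaging. Perfect fits (zero residual
variance) return a large finite T (±10⁶) and are flagged per region
rather than returning infinities.

Spatial correlation is Pearson across gray-matter regions (white matter
and CSF excluded by tissue class), matched **by region label** — joins are
order-independent, verified by a shuffle test. Receptor maps are affinely
rescaled to [0, 100] (correlation-invariant; the extreme regions land on
exactly 0 and 100 by computing the ratio before the scale factor). The
default inference is the parametric two-tailed p at α = 0.05 per map with
no correction across maps, matching field practice for this analysis;
Benjamini–Hochberg across maps is available (`correction="fdr"`). No
spatial-autocorrelation (spin) correction is offered: the package consumes
region-keyed tables without geometry, and a defensible spin test needs the
parcel coordinates.

## Synthetic cohorts

What the generator emulates, per stage:

- **Battery**: measure_j = λ·latent + √(1−λ²)·ε_j with λ = 0.677 by
  default, chosen so PC1's expected variance share (1 + (m−1)λ²)/m ≈ 49.5%
  matches the reference battery; a configurable subset of measures is
  sign-flipped. Age is Normal with a sex-shifted mean (men 27.9 ± 3.6 y,
  women 29.6 ± 3.6 y), reproducing the "women older" covariate structure.
- **Time series**: for each subject and condition, frames are i.i.d. draws
  from a zero-mean multivariate normal whose correlation matrix is the
  identity except at planted edges, set to base ± effect·severity
  (positive-list edges strengthen with severity, negative-list weaken;
  base 0.2 by default). Config validation enforces
  |base| + 3·|effect| < 1 so matrices stay valid three SDs out; per-subject
  values are clipped at ±0.999 and repaired to positive definite by
  eigenvalue clipping (floor 1e-6) alternated with unit-diagonal rescaling
  until both constraints hold; a repair that moves any entry by more than
  0.05 aborts naming the offending edges.
- **Receptor atlases**: a standard-normal target map over gray regions,
  and per named system a map r·target + √(1−r²)·noise with r planted (0
  when absent), rescaled to [0, 100]; optional extra regions labeled
  white/CSF. With `sample_exact=True` the noise is orthogonalized to the
  target in-sample so the realized gray-matter correlation equals the
  planted value exactly — including exactly 0 for unplanted maps — which
  is the mode to use when a test needs "no association" to mean the map
  cannot be flagged, as opposed to the default population mode where null
  maps still carry the α-level parametric false-positive rate.

What it does **not** emulate, and hence what passing tests do not show
about real data: temporal autocorrelation and hemodynamics (frames are
i.i.d., so frame counts translate to effective sample sizes optimistically),
motion and scanner artifacts, spatial autocorrelation of regional maps
(receptor-map p-values on real parcellations are anti-conservative without
a spin test), heavy-tailed behavioral distributions, and any nonlinearity
in the severity–connectivity coupling (severity enters edge strength
linearly by design, matching the linear detection model of CPM so that
parameter recovery is interpretable).

## Reproducibility plumbing

Every stochastic stage takes an explicit seed; the pipeline derives stage
seeds from the run seed through a fixed `SeedSequence` spawn order, so a
config reproduces all outputs bit-identically (tested). The manifest
records the config, its SHA-256 hash, the derived seeds, package version,
and per-stage wall times. CLI exit codes: 2 parameter/config, 3 data, 4
simulation.

## Problem sizes used in the shipped checks

The test suite and acceptance script run at desk scale, chosen as the
smallest sizes at which each statistical claim is meaningfully testable:
batteries at n = 2000; null permutation calibration on 100 cohorts of
n = 300 subjects × 60 nodes with 5-fold CV and 99 permutations; planted
recovery at n = 500 subjects on a 12-node atlas with one planted edge per
polarity, calibrated to a prediction ceiling of 0.25; receptor recovery on
119-region atlases with 27 maps. Full-scale cohorts (≈10³ subjects × 268
nodes) run through the same code paths unchanged.

## Known limitations

- LOOCV optimism: selected-edge strength sums retain in-cohort spurious
  correlation; at liberal thresholds the headline r is biased upward by a
  few hundredths and noisier across cohorts than the naive ceiling
  suggests. k-fold with repeats is the more conservative scheme.
- The permutation test re-runs the full CV per permutation and is the
  pipeline's dominant cost; the implementation is vectorized per fold but
  still O(n_perm · folds · n · edges).
- `network_strength` sums raw r values; no binarized or weighted-degree
  variants.
- The parcel GLM assumes homoscedastic Gaussian residuals per region; no
  robust or mixed-effects options.
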