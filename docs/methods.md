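# Methods

## Model

`hierfc` estimates functional connectivity at two orders simultaneously
from a sequence of windowed correlation networks, separately inside each
functional sub-network and across sub-networks.

For one subject, the ROI signal matrix **X** ∈ ℝ^{M×N} (M time points, N
ROIs) is divided along the ROI axis by a partition {Ω₁ … Ω_U} of the N
ROIs into U named sub-networks. Within sub-network u (N_u ROIs), a window
of width l_w sliding in steps of l_s yields

    K = ⌊(M − l_w)/l_s⌋ + 1

segments, and the Pearson correlation matrix of each segment gives a
sequence of symmetric connectivity matrices W_u¹ … W_u^K (unit diagonal,
entries in [−1, 1]). The sequence is modelled as i.i.d. draws from a
matrix-variate normal

    W_u^k ~ MN(M_u, C_u, C_u),   i.e.  vec(W) ~ N(vec(M_u), C_u ⊗ C_u),

where the Kronecker decomposition of the N_u²×N_u² covariance into two
equal N_u×N_u factors is legitimate because W is symmetric (row and column
covariance coincide). **M_u** is the *low-order* estimate — the average
pairwise connectivity — and **C_u** is the *high-order* estimate — the
covariance of whole connectivity patterns across windows, capturing
co-fluctuation structure that involves more than two ROIs.

The same construction applied to the U *mean time series* (each Ω_u's
ROI-averaged signal) gives the inter-sub-network low/high-order estimates,
recovering connectivity information that the partition severs.

The point of the hierarchy is sample efficiency: a windowed connectivity
matrix is one sample of dimension N², and with N = 116 and M = 170 the
dimension-to-sample ratio is 116²/170 ≈ 79.15, hopeless for covariance
estimation; the largest bundled sub-network (26 ROIs) brings it down to
26²/170 ≈ 3.98. `dimension_report` computes exactly these diagnostics.

## Maximum-likelihood fitting

The mean MLE is the elementwise average of the K matrices. The factor MLE
solves the fixed point

    C = (1/(K·N)) Σ_k (W_k − M) C⁻¹ (W_k − M)ᵀ.

Iterating this equation *simultaneously* (replacing C on both sides at
once) is numerically unusable: scaling C by a maps the iterate to C/a, so
any scale error oscillates with period 2 and the likelihood bounces
between two values instead of converging. `fit_factor` therefore runs the
classical flip-flop algorithm on the two-factor parameterization MN(M, U,
V): alternately set U to the exact conditional maximizer given V and vice
versa. Each half-step is an exact conditional maximization, so the
recorded log-likelihood trace is non-decreasing by construction (checked
to 1e-8 in the tests). On symmetric samples the factors converge to
proportional matrices; they are collapsed into the single symmetric C via
the scale balance C = U·√(tr V / tr U), which leaves U ⊗ V = C ⊗ C
unchanged and satisfies the symmetric fixed-point equation above.

Numerical choices:

* **Initialization** U = V = I. Scale-free; the first iterate is the
  average squared-residual matrix.
* **Convergence** relative Frobenius change of the balanced C below
  `tol` (default 1e-6), `max_iter` 100.
* **Ridge** when a factor's condition number exceeds 1e12, its inverse is
  taken after adding `ridge`·tr(C)/N·I (default ridge 1e-6, recorded in
  the fit). Rank deficiency is *expected*, not exceptional: K can be
  smaller than N_u (e.g. 28 windows for 26 ROIs).
* **Degenerate data** K = 1, or all windows identical, makes every
  residual zero; the factor MLE is the zero matrix, returned exactly when
  a ridge is configured and raised as an error otherwise.
* **Symmetrization** of every iterate, and a trace-positivity convention,
  make repeated fits bit-identical (the fixed point is unique only up to
  sign).
* Zero-variance columns inside a window get correlation 0 (with a
  warning) rather than NaN, keeping the fit well-posed.

## Features, normalization, classification

Four blocks per subject, fused in the order (intra-high, intra-low,
inter-high, inter-low): low-order matrices are vectorized as strict lower
triangles (the diagonal is identically 1); high-order factors include the
diagonal, which carries variance information. Traversal is row-major over
(i > j) resp. (i ≥ j), so feature indices are stable and invertible
(`unvec_lower`). For the bundled six-network division the widths are
1107 + 1223 + 15 + 21 = 2366.

Min–max normalization is per block. `minmax_normalize` rescales a single
block vector by its own extrema. Inside cross-validation the per-block
min/max are computed from **training subjects only** (pooled over the
block's entries) and applied, unclipped, to test subjects — this prevents
any test-set statistic from influencing selection; a `global_norm` flag
reproduces whole-cohort normalization for comparison.

Selection and classification: a two-sample t-test filter (keep p <
threshold; features with zero variance in both groups have no defined
p-value and are dropped), then LASSO

    min_w ½ Σ_l (I^l − f_lᵀ w)² + λ‖w‖₁

with labels I ∈ {+1 (patient), −1 (control)} and no intercept, keeping the
nonzero-coefficient features; then a linear soft-margin SVM. Scikit-learn
provides the LASSO solver (`alpha = λ/L`), the SVM, and the stratified
splits. If selection empties the feature set, prediction falls back to the
training majority class with a warning so cross-validation never crashes.

Nested stratified k-fold CV (default 5×5): the inner loop grid-searches
(p, λ, cost) by mean inner accuracy, ties resolved toward the simpler
model (larger p, larger λ, smaller cost); the winner is refit on the full
outer-training set — normalization and selection included — and scored on
the held-out fold. `repeats` reshuffles folds with fresh sub-seeds.
Summaries are reported both over all folds and over repeat means, since
either convention is defensible. Default grids: p ∈ {0.01 … 0.10},
λ ∈ {0.1 … 0.9}, cost ∈ {2⁻⁴ … 2⁴}.

Provenance tracing: each selected feature maps back to its block and
(sub-network, ROI-pair) or network-pair origin. Contribution rates credit
an intra feature's network with 1 and each endpoint of an inter feature
with ½, normalized to sum to 1. Top edges rank low-order ROI-pair features
by the number of repeats in which they were selected, ties broken
lexicographically.

## Bundled partition

The package ships a six-network division of the 116 AAL regions —
sensorimotor (18), visual (14), execution/attention (17), default mode
(22), subcortical (19), cerebellum+vermis (26). The group *sizes* are the
published ones; the region membership is this package's reconstruction
from standard functional-anatomy assignments consistent with those sizes.
The odd sizes force one asymmetry: the superior temporal pole pair is
split (left → subcortical group, right → execution/attention). Analyses
that only depend on group sizes (dimension diagnostics, feature widths)
are insensitive to membership; edge-level reports name the regions and
inherit this reconstruction's uncertainty. A k-means alternative
(`partition_by_kmeans`) clusters each ROI's z-scored, subject-averaged
time series with Euclidean k-means++ — one concrete reading of
"clustering the ROI time series"; it is order-invariant across subjects
and deterministic given its seed.

## Synthetic cohort generator

`generate_cohort` emulates a two-group resting-state cohort. Defaults
match a typical single-site study — 45 patients + 47 controls, 170
time points, the bundled six-network partition — with correlation levels
chosen once as plausible resting-state values: within-network coupling
0.5, between-network 0.1, patient-group shift of −0.15 on the
default-mode within-network correlations (reduced default-mode coupling
is the expected disease direction), two connectivity states alternating
every 45 time points with within-block jitter up to ±0.15, and additive
measurement noise of SD 0.5 on unit-variance signal. Each segment is
drawn from a multivariate normal with the state's block correlation
matrix; shifted matrices are projected back to positive-definite
correlations by eigenvalue clipping (floor 1e-6) and diagonal
renormalization. Per-subject seed sequences make cohorts bit-reproducible
and independent of generation order.

What the generator does *not* emulate: hemodynamics and autocorrelated
BOLD noise, site/scanner heterogeneity, motion artefacts, and
subject-level variability in the connectivity structure beyond sampling
noise. Passing the pipeline's recovery tests on this generator shows the
estimator and classifier behave correctly *under the model's own
assumptions*; it does not certify accuracy figures on real cohorts, which
is why the validation emphasizes calibration (chance-level accuracy when
no effect exists) and recovery (the injected network ranks first) rather
than absolute accuracy values.

## Validation problem sizes

The statistical validation suite runs at desk scale, chosen once: the
matrix-normal recovery check uses 500 draws from a known 4×4 factor
(scale-aligned relative Frobenius error < 10%); likelihood monotonicity is
checked on 100 random instances; the matrix-normal log-density is checked
against the Kronecker-vectorized multivariate normal on 2×2 instances to
1e-8. Classifier calibration uses a null cohort (no group effect) of
2×30 subjects, 16 ROIs in four networks, 120 time points, window 40/10,
with 20 fold reshuffles — mean accuracy must stay inside the 95% binomial
band around 0.5 for n = 60 (repeat means of the same subjects are
correlated, so the band uses the subject count, not repeats × subjects).
Power uses the same geometry with a −0.4 default-mode shift over 10
replicate cohorts: accuracy must exceed the chance band and the
default-mode network must rank first in the contribution trace in ≥ 9/10
replicates. Reduced hyperparameter grids (p ∈ {0.05, 0.2}, λ ∈ {0.2,
0.5}, cost = 1) are used in these loops; the full default grids remain
available and are exercised by the unit tests.

## Known limitations

* Only the symmetric equal-factor matrix normal is implemented — the
  general rectangular case with distinct row/column factors is out of
  scope.
* The LASSO objective has no intercept (matching the selection model's
  definition); with min–max-normalized features and ±1 labels this is a
  deliberate, documented choice rather than an oversight.
* High-order features cannot be traced to individual ROI pairs — the
  factor's entries couple whole rows of the connectivity matrix — so edge
  reports cover low-order features only.
* The bundled partition's membership reconstruction (above) is the main
  caveat for anatomical interpretation of edge-level output.
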