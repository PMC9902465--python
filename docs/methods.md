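# Methods

## Scope and data model

The package implements a complete resting-state fMRI comparison study at
desk scale: per-subject ROI time series (T×N, default T = 370 timepoints at
TR = 0.8 s, N ROIs named after the AAL atlas convention) feed six FC
estimators; optional 4D voxel volumes feed ALFF/fALFF/ReHo; a subject table
carries the label and the nuisance covariates (sex, scanner manufacturer,
site, a scalar head-motion summary). Real cohorts load from a TSV manifest;
the synthetic generator produces statistically matched stand-ins with known
ground truth.

## Synthetic cohorts

Signals are stationary Gaussian processes: AR(1) innovations (coefficient
0.3 by default — a mild temporal autocorrelation typical of fast-TR rsfMRI
after preprocessing) mapped through the Cholesky factor of a target
correlation matrix. The two groups share a random well-conditioned base
correlation matrix and differ only at `n_effect_edges` planted edges, whose
correlations are shifted by `effect_delta`; if the shift breaks positive
definiteness the matrix is repaired by eigenvalue clipping at 1e-6 and
re-normalization to unit diagonal, with the planted entries re-imposed so
the groups differ at exactly the planted edges. The default demo condition
is 20 ROIs, 60+60 subjects, 8 edges at shift 0.4, T = 370 — strong enough
that the pipeline should recover the planted edges, which is what the
recovery tests check.

Dynamic scenarios draw piecewise-stationary segments from per-state
covariances with geometric dwell times (mean 40 timepoints; memoryless,
one parameter). Voxel scenarios plant either a band-limited (0.01–0.1 Hz)
amplitude boost (targets ALFF/fALFF) or a shared latent signal mixed into a
neighborhood (targets ReHo; mixing weight 1 makes the series identical and
ReHo exactly 1). Covariates are sampled per group with configurable
imbalance; head motion is log-normal, optionally shifted in the case group
to emulate motion confounding.

What the generator does **not** emulate: spatial autocorrelation of real
BOLD, scanner drifts and physiological noise spectra, heavy-tailed motion
artifacts, site batch effects beyond a categorical label, or realistic
effect topographies. Passing tests therefore demonstrate the pipeline's
correctness and statistical calibration under a known model, not clinical
effect sizes; the real-data analogue of the demo AUC is expected to be far
lower.

## Voxel measures

Spectra are single-taper periodograms of the demeaned series; amplitude is
√power per bin. ALFF averages amplitude over the 0.01–0.1 Hz bins; fALFF
divides the in-band amplitude sum by the sum over all positive frequencies
up to Nyquist (DC excluded) and is computed on unfiltered data. ReHo is
Kendall's W over the voxel and its in-mask neighbors (7/19/27-voxel
neighborhoods); boundary voxels use partial neighborhoods rather than NaN,
and voxels with fewer than two in-mask series are 0 and flagged. Band-pass
is an ideal DFT-domain mask (exact on bin-aligned sinusoids, which is what
makes the analytic tests sharp); smoothing is Gaussian with
σ = FWHM/(2√(2 ln 2)) per axis in voxel units, renormalized by the smoothed
mask at edges; nuisance regression is OLS with intercept and linear trend
always included and rank-deficient columns dropped with a warning. The
pipeline driver enforces the order: regression → smoothing (except ReHo) →
band-pass (except fALFF) → measure. ALFF maps are not z-standardized by
default — standardization is not part of the measure definition here, and
group-level covariate effects are removed by feature residualization
instead.

## High-order FC

tHOFC(i,j) is the Pearson correlation of the LOFC profiles of ROIs i and j
over the indices k ∉ {i, j}; the diagonal is set to 1 by convention, and a
zero-variance profile yields 0 with a flag (never silent NaN). dHOFC uses
rectangular, contiguous sliding windows (length L, step s; Θ = ⌊(T−L)/s⌋+1)
over all P = N(N−1)/2 pairs in row-major upper-triangle order, Ward
minimum-variance clustering (scipy linkage, deterministic) of the P window
series into K clusters, unweighted cluster-mean series, and a K×K matrix of
their correlations. Degenerate (zero-variance) correlations anywhere in the
package are set to 0 and flagged.

## Sparse-representation estimators

All four objectives constrain diag(W) = 0: without it the printed SR/SLR
objectives admit the trivial minimizer W = I, and the group formulations
exclude ROI i from its own design explicitly. Columns are standardized to
zero mean and unit ℓ2 norm so the λ grid [0.01…0.1] is comparable across
instances.

- SR: per-column lasso by monotone FISTA (MFISTA); the analytic null
  threshold λ_max = max_j ‖X₋ⱼᵀxⱼ‖_∞ zeroes the solution exactly.
- SLR: consensus ADMM with two copies of W — one carrying the ℓ1 prox plus
  the diagonal projection, one the singular-value soft-threshold — and a
  ridge W-update; the returned matrix is the best-objective Z₁ iterate, so
  the reported objective sequence is non-increasing.
- GSR: per-ROI row-group (ℓ2,1) MFISTA across subjects; row support is
  jointly zero or jointly free by construction of the group prox.
- SSGSR: exact change of variables w̃ = b ⊙ w (valid since
  b = e^(−w0²) > 0), which turns the weighted ℓ2,1 into a standard one and
  leaves the similarity term as a smooth quadratic (graph-Laplacian form);
  the Lipschitz constant of the smooth part is estimated by power iteration.

Stopping: relative objective change below `tol` (default 1e-8) for three
consecutive iterations, `max_iter` 5000 by default. The test suite verifies
each solver against an algorithmically independent oracle: a generic smooth
reformulation (positive/negative splitting for ℓ1; ε-smoothed group and
nuclear norms with ε chosen so the objective bias is ≤ 1e-8) minimized by
L-BFGS-B. Feature extraction uses the symmetrized matrix (W+Wᵀ)/2, upper
triangle, since reported biomarkers are undirected connections.

## Classification protocol

Nested stratified CV: outer 10-fold (configurable) for generalization,
inner 5-fold AUC grid search for hyperparameters, Boruta selection on the
outer-training rows only. Stratification is the defensible default given
near-balanced groups and AUC reporting. All fold assignments, Boruta
permutations and tree seeds derive from the single global seed, which makes
the run reproducible and lets the poisoning test verify the leakage
contract exactly: corrupting outer-test rows changes no selection or tuning
decision. If Boruta accepts nothing in a fold, all features are kept for
that fold and the fallback is recorded — under a true null this leaves the
AUC at chance rather than crashing the fold.

Boruta internals: shuffled shadow copy per still-undecided feature each
round, random-forest importances (default 300 trees, depth 5), a hit when a
real feature beats the best shadow, and two-sided binomial decisions at
α = 0.05 with Bonferroni correction over the undecided features (from round
5 onward); undecided features at `max_rounds` (default 100) are rejected —
the conservative choice. The classifier zoo is the standard nine-family
set behind a uniform fit/score interface, backed by scikit-learn; the
hyperparameter grids are small package defaults recorded in
`make_classifier_specs`.

Metrics are computed from the confusion counts by their definitions
(ACC, precision, recall, F1); zero denominators report 0 with a flag.
AUC is the trapezoidal ROC area with midpoint tie handling (all-tied scores
give exactly 0.5).

Parameter sensitivity deliberately uses the simpler protocol — plain
stratified 10-fold with a fixed RBF SVM (C = 1.0) — separate from the
nested evaluation, returning the mean-AUC surface and its argmax (ties go
to the smallest parameter values).

## Fusion

Early fusion concatenates per-modality (selected) feature tables. MKL
builds one Gram per modality — RBF with the median-heuristic bandwidth on
standardized features (default) or linear — centered and trace-normalized
to S; test-vs-train kernels are centered with the training statistics so
training-set predictions are exact. Weights are centered-kernel alignment
with the label kernel, clipped at zero and normalized to the simplex
(deterministic and convex); the final classifier is an SVM on the
precomputed combined Gram. Alignment weighting is recorded as a swappable
strategy: it is not a claim about which MKL variant any particular study
used. The spec'd linear-kernel identity contract (orthonormal rows → unit
Gram) is exposed via `center=False`.

## Biomarkers

ROI-wise: candidates are the intersection of the outer-fold Boruta
selections; each gets a pooled-variance two-sample t-test (Welch by flag)
and BH FDR across the candidate set; directions are the sign of the group
mean difference. Reporting rules by modality: top 20 by p for SLR-type,
all significant for SSGSR-type, and for dHOFC the 10 clusters with the most
appearances among significant cluster-pairs (ties to the lower cluster id).

Voxel-wise: a pooled-variance t-map on the common mask, two-tailed voxel
threshold at p < 0.001, 26-connected clusters per sign, and a
max-cluster-extent null from label permutations (≥100 permutations;
clusters above the 95th null percentile are reported with peak t, location,
size and sign). The permutation null replaces parametric random-field
cluster inference deliberately: it is exact by construction at the stated
thresholds and has no smoothness-estimation settings. Because the null
takes the max over both signs, family-wise error is controlled jointly
across tails.

## Problem sizes used in tests and the acceptance script

Solver-oracle checks run on 20 tiny instances (N ≤ 6, T ≤ 40, S ≤ 4) where
the generic oracle is reliable. The demo discriminability check runs the
full nested CV once on the 60+60 cohort; the permutation-null and
planted-edge-recovery checks use reduced protocol settings (5 outer folds /
smaller Boruta forests, 10–20 replicates) chosen once as the package's demo
protocol; empirical error control uses 200 null runs (feature FDR) and 50
null runs × 100 permutations (cluster FWE). These sizes are the package's
own demo conditions; the statistical thresholds they are checked against
(AUC ≥ 0.80, 0.5 ± 0.08 null band, 0.05 + 2·MC-SE error rates, ≥80%
recovery) are fixed properties of the design.

## Known limitations

- The voxel ReHo loop is Python-level per voxel; fine for the small grids
  used here, slow for whole-brain masks.
- SSGSR's inter-subject quadratic couples all subjects per ROI; cost grows
  with S² in the similarity term.
- The Boruta implementation is a faithful shadow-feature procedure but not
  a byte-for-byte port of any particular package; decisions can differ near
  the significance boundary.
- MKL is alignment-based; margin-based joint weight/classifier optimization
  is out of scope.
- No DICOM/BIDS ingestion; NIfTI and TSV manifests only.
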