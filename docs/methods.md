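# Methods

This note documents the models implemented in `nirchem`, the defaults and
why they were chosen, the numerical decisions, and the limits of what the
synthetic experiments demonstrate.

## Data model and protocol

A dataset is an `n × p` absorbance matrix on a strictly increasing
wavelength grid (nm) with unique sample ids and optional per-sample origin
labels and reference lipid contents (%). The on-disk form is a wide CSV
(first column id, optional `origin`/`lipid`, numeric wavelength headers);
replicate rows sharing an id are averaged on read, mirroring the practice
of reading each sample several times on the instrument.

Every modelling run uses the same protocol: a random calibration /
prediction split with fixed sizes (80/40 by default for 120 samples),
five-fold cross-validation on the calibration set for an exhaustive grid
search, a final refit on the full calibration set, and scoring on the
untouched prediction set. Splits, folds, Monte-Carlo subsets and the
generator all draw from `numpy.random.default_rng(seed)` with explicit
seeds, so identical configurations reproduce byte-identical reports.
Stratified splitting is available but off by default (plain random
sampling is the baseline protocol). Fold sizes differ by at most one and
each fold is held out exactly once.

**Leakage policy.** All data-dependent stages (PCA, UVE/MCUVE/SPA
selection, variance filters) are refitted inside each cross-validation
training fold and merely applied to the held-out fold. Where the original
protocol for a comparable study is ambiguous on this point, inside-fold
fitting is the safe choice: a canary test confirms that selecting
variables on the full data before CV visibly inflates apparent skill on
pure noise, while the pipeline's CV does not. SNV and the wavelet
compressor are strictly row-wise (per-spectrum), so they cannot leak by
construction.

## SNV

Each spectrum is centered and scaled to unit **sample** (n−1) standard
deviation — the dominant chemometrics convention; the alternative
population scaling differs only by a constant factor that later
mean-centering absorbs. A constant spectrum has no defined SNV transform
and raises an error naming the offending sample. No derivative, MSC or
Savitzky–Golay pretreatments are provided; SNV is the only pretreatment
the implemented schemes use.

## Wavelet engine

The multilevel DWT/IDWT is delegated to PyWavelets; the thresholding
logic, noise estimation, and the compression/distortion accounting are
implemented here.

* **Depth and filters.** Default depth J = 3 with any PyWavelets filter;
  the four filters exercised throughout are db9, bior4.4, sym8, coif4.
* **Boundary extension.** Half-point symmetric by default — the common
  choice for spectra, avoiding wrap-around artifacts at the grid edges.
  `periodization` is available and is used wherever exact energy
  bookkeeping matters: for orthogonal filters under periodization the
  transform is an orthogonal map, so coefficient energy equals signal
  energy and PRD is provably nondecreasing in the threshold. Neither
  holds exactly for the biorthogonal bior4.4, and the tests deliberately
  do not assert them for it.
* **Noise level.** σ = median(|d₁|)/0.6745 from the finest detail level
  only, shared across levels — the standard robust estimator under the
  i.i.d. Gaussian noise model.
* **Strategies.**
  * *Universal hard ("Donoho")*: λ = σ√(2 ln N) with keep-or-kill
    shrinkage; retained coefficients are unbiased, so reconstruction
    fidelity is best at a given zero-count.
  * *Universal soft*: same λ, survivors shrunk by λ; slightly higher
    distortion at the same threshold, as the paired test verifies.
  * *SURE*: per-level soft threshold minimizing Stein's unbiased risk
    estimate, scanned exhaustively over the candidate set {0} ∪ {|dⱼₖ|}
    (an O(n log n) cumulative-sum scan; verified against a brute-force
    risk loop).
  * *Birgé–Massart*: with M the approximation length and sparsity
    parameter α (default 1.5, the compression regime), detail level j
    (j = 1 coarsest) keeps its nⱼ = round(M/(2+j)^α) largest-magnitude
    coefficients; implemented as the hard threshold equal to the
    (nⱼ+1)-th largest magnitude, which retains exactly nⱼ coefficients
    in the absence of ties (ties have probability zero for continuous
    data).
* **Diagnostics.** Compression rate is defined as the percentage of all
  coefficients (details + approximation) exactly zero after thresholding
  — the approximation is never thresholded, so with J = 3 the rate is
  bounded by ~87.5%, matching the 80–87% range observed on NIR-like
  signals. PRD = 100·√(Σ(x−x̂)²/Σx²) is scale-invariant and zero iff the
  reconstruction is exact.

## Feature selection

* **PCA** is a thin wrapper over scikit-learn's full-SVD solver, exposed
  as an orthonormal projection object; scores are test-verified against a
  dense eigendecomposition of the covariance.
* **MCUVE** defaults: 500 Monte-Carlo runs, 80% subset fraction drawn
  without replacement, and a PLS depth chosen once by five-fold RMSECV on
  the full input (scanned over 1–10). These counts are explicit design
  choices: 500 runs stabilize the mean/std ratio at ~1% Monte-Carlo error
  while keeping a fit under a couple of seconds on ~80 × 550 inputs.
  Ranking ties break by ascending variable index. A coefficient with zero
  spread across runs gets a signed-infinity stability (it is maximally
  stable); the special case mean = std = 0 — typical for wavelet
  coefficient columns zeroed in every sample — gets stability 0 so dead
  columns can never be selected.
* **UVE** appends p uniform-noise columns scaled to 1e−10 of max|X|
  (numerically inert, statistically null), computes leave-one-out
  stabilities, and keeps real variables whose |s| beats every noise
  variable. On pipelines the selector falls back to the top-stability
  variable if the cutoff empties the selection, so downstream fits remain
  defined.
* **SPA** grows a candidate chain from **every** start column by
  repeatedly adding the column with the largest projection onto the
  orthogonal complement of the chain (duplicates project to zero and are
  never co-selected); each (start, k) subset is scored by five-fold
  RMSECV of an ordinary least-squares fit and the global minimizer wins.

## PLS models

NIPALS with mean-centering only (autoscaling available behind a flag but
off: SNV/wavelet steps precede the model). Per component: unit weight
vector w, scores t = Xw, loadings p = Xᵀt/tᵀt and q = Yᵀt/tᵀt, inner
coefficient b = uᵀt/tᵀt, then deflation of both blocks. Prediction uses
the composite regression vector R = W(PᵀW)⁻¹, coef = RQᵀ, so new samples
need only centering. For univariate y the inner loop converges in one
pass; for multivariate Y it iterates to a 1e−9 relative tolerance.
Numerical guarantees exercised by tests: successive scores orthogonal to
1e−8; at full rank, fitted values equal the least-squares solution to
1e−6; predictions agree with an independent reference implementation.

PLS-DA one-hot encodes classes in order of first appearance and applies
an argmax rule to the predicted response, ties resolving to the lowest
class index. PCR regresses y on the first PCA scores.

**R² convention.** The default is the standard coefficient of
determination 1 − SSres/SStot. The alternative `paper_eq14` returns the
raw ratio Σ(ŷ−y)²/Σ(ŷ−ȳ)² as some sources print it; note that ratio is 0,
not 1, for perfect predictions — reported R² values in the comparison
literature behave like the standard convention, which is why it is the
default.

**Classification metrics.** Precision and recall are macro-averaged over
classes (the convention chosen here; micro-averaging is the main
alternative and would equal accuracy for single-label problems), and F1
is computed from the macro values as 2PR/(P+R). Accuracy is the fraction
correct, also reportable ×100.

**Grid search** is exhaustive and deterministic: pooled five-fold RMSECV
(regression, minimized) or pooled CV accuracy (classification,
maximized), ties keeping the earliest grid point. Pipeline stages before
the first grid-referenced stage are fitted once per fold and their
transforms reused — with MCUVE inside a pipeline this avoids re-running
500 Monte-Carlo fits for every candidate component count, since the
selection does not depend on the downstream model's depth.

## Synthetic study

The generator emulates the study conditions end to end: 3 origin classes
× 40 samples, 511 bands over 900–1700 nm, and per-class lipid contents
drawn from truncated normals matched to gravimetric reference statistics
(class means 60.90/63.01/61.17%, SDs 0.76/0.27/0.52, all values inside
59.7–63.4%). Each spectrum is a sum of six Gaussian absorption bands; the
bands near 1210 and 1390 nm (second C–H overtone and C–H combination
regions, where lipid absorbs) have amplitudes linear in lipid content
(0.012 and 0.009 absorbance per % lipid), and two further bands carry
small class-specific offsets. Degradations: multiplicative scatter
(SD 0.05), a random linear baseline (slope SD 0.02), and white noise
(SD 0.002 absorbance, i.e. per-band SNR of order 10²–10³ against signals
of 0.3–1.0) — levels typical of a well-maintained diode-array instrument
on powdered samples.

Two generator design points deserve note:

* The two non-reference class-offset patterns act on *different* bands,
  so the three class centroids form a triangle in PCA space rather than a
  line. With collinear centroids, one-hot linear regression suffers the
  classic masking of the middle class and no amount of separation fixes
  it; the triangular layout reproduces the completely separated 2-D score
  plot that the emulated study design calls for (silhouette ≈ 0.7,
  prediction accuracies 95–100% across seeds).
* With noise, scatter, baseline and class offsets all zero, the centered
  spectra are exactly rank one in lipid, so a single PLS component
  recovers lipid with R² = 1 to machine precision — an analytic anchor
  the tests assert. (After SNV the relation is no longer exactly rank
  one, because each row's standard deviation itself depends on lipid;
  R² > 0.999 still holds.)

What the synthetic study does **not** establish: real NIR spectra have
correlated, wavelength-dependent noise, nonlinear detector effects,
water-band interference and temperature drift, none of which are
simulated. Passing tests demonstrate that the algorithms are implemented
correctly and that the pipelines behave sensibly under the stated
conditions — not that these exact accuracies transfer to measured
spectra. Published figures from comparable measured-data studies (e.g.
~84.7% compression at 0.21% PRD, 98.75/97.50% accuracies, RMSECV/RMSEP of
0.0098/0.0390) are reproduced *structurally*, not numerically.

## Problem sizes and tolerances

The default experiments use the full 120 × 511 study: classification and
regression runs take seconds; the complete test suite runs in well under
a minute on one CPU. Reconstruction is asserted to 1e−8, orthogonality to
1e−8–1e−10, oracle equivalences to 1e−6–1e−10, and stochastic properties
(MCUVE separation, scheme accuracies, SPA recovery) under fixed seeds at
the thresholds stated in the tests. The grid-length guard rejects
decompositions deeper than ⌊log₂ n⌋; PyWavelets may still warn about
boundary effects for short signals with long filters (e.g. length 100
with db9 at J = 3) — reconstruction remains exact, which is what the
tests require.

## Known limitations

* `WT-PLS` reports as its feature count the number of coefficient columns
  that are nonzero in at least one calibration sample (a variance filter
  fitted on calibration data); per-sample thresholding means the zero
  pattern varies across samples.
* Birgé–Massart keep-counts use the approximation length as M; other
  parameterizations exist and α, M are exposed as knobs.
* UVE's leave-one-out loop is O(n) PLS fits on a doubled feature set and
  becomes the slowest selector on wide inputs.
* PLS-DA inherits indicator-regression pathologies (class masking for
  collinear class layouts); for such geometries a different classifier
  head would be needed.
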