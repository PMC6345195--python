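# Methods

This note records the models, conventions and numerical choices behind
`spiraldct`, and what the synthetic validation does and does not show.

## Signal model and the residue construction

A spiral drawing is a pair of coordinate streams sampled at a nominal
100 Hz. Drawings of different lengths are made comparable by linear
interpolation onto a common grid of 4096 sample-index positions; the
effective sampling rate is rescaled by `4096 / original_length` and carried
with the sequence, so spectral features refer to true physical frequency.
Linear interpolation is the default (robust for strokes that are not
band-limited); it is exact on affine segments and preserves the endpoints.

The DCT-II/DCT-III pair is used in its orthonormal convention (the scaling
`c_k` appears in both the forward and inverse sums), implemented via
`scipy.fft.dct/idct(norm="ortho")`. Under this convention Parseval holds
coefficient-for-coefficient, which gives the useful identity
`‖x − x̃_L‖² = Σ_{k≥L} X_k²`: residue energy is a monotonically
non-increasing function of the reconstruction order `L`. `L` counts
coefficients from k = 0 inclusive, so the DC term is always inside the
reconstruction (and outside the residue) for `L ≥ 1`. Residues are computed
per axis and then combined pointwise into the residue-distance sequence;
they are never computed on the radius.

Coordinates are centered (per-axis mean removed) before the radius method,
because the polar radius is origin-dependent and tablet coordinates are
absolute; they are not centered before the residue method, where the
discarded DC coefficient absorbs any translation. Both behaviours are
configurable.

A caveat worth knowing when interpreting spectra: `rd_n` is a *magnitude*.
For a sinusoidal tremor at frequency f the per-axis residues oscillate at
f, but their pointwise norm is approximately a rectified sinusoid, whose
spectrum carries a slow envelope plus a line at 2f rather than a line at f.
Frequency content of the tremor is therefore best read from the per-axis
residues; the rd sequence is a time-domain irregularity measure, which is
exactly how its feature bank uses it.

## Feature bank (35 values)

Temporal features follow their textbook formulas with the N−1 denominator
for VAR/STD/AAC. Conventions fixed here:

* **SENT** — sample entropy with embedding dimension m = 3, Chebyshev
  distance, self-matches excluded, tolerance r = 0.2 × the sample (N−1)
  standard deviation. Degenerate cases (constant input, no template
  matches) return 0 with a warning. The pair-counting kernel is
  numba-compiled; a literal Python-loop implementation is kept in the test
  suite as the oracle.
* **FD** — Higuchi's estimator with k_max = 5; mean curve lengths at scales
  1..k_max are fitted by least squares in log–log. Smooth signals score
  near 1, white noise near 2.
* **LOG, MFL** — natural logarithm; |x| floored at 1e−12 inside LOG.
* **ZC** — crossings of the signal mean; exact zeros take the sign of the
  following sample. **SSC** — strict sign changes of consecutive nonzero
  first differences.
* **WAMP** — count of |X_i − X_{i+1}| > ε with ε equal to the signal mean,
  taken literally. Note that on non-negative sequences (radius,
  residue-distance) the mean exceeds every sample-to-sample step, so WAMP
  is identically 0 there; it is retained for completeness and receives zero
  relevance weight automatically.
* **AR1–AR4** — Yule–Walker solution with biased autocovariance
  (statsmodels `yule_walker(method="mle")`), reported as the prediction
  coefficients without the leading 1.
* **MYO** — percentage (0–100) of samples exceeding twice the mean.

Spectral features are read from the Welch periodogram (density scaling):
Hamming window, 256-sample segments, 50% overlap — standard defaults, all
exposed in `FeatureParams` since reasonable alternatives exist. STDp uses
the N−1 denominator; KUR is the non-excess (Pearson) kurtosis of the PSD
values; MDF is the smallest frequency at which cumulative power reaches
half the total. Auto1–3 are the lag-1..3 normalized autocorrelations of the
*time* sequence (not of the periodogram), the conventional reading of
"first autocorrelation coefficients". The sampling rate entering the
frequency axis is the post-resampling effective rate stored in the
sequence.

The bank enumerates 35 scalars (20 temporal + 15 spectral); intra-vector
identities (VAR = STD², IEMG = N·MAV, SSI = N·RMS², MFL = log WL) are
verified on every extraction in the tests.

## ReliefF and selection

Binary ReliefF iterates over *all* samples (no stochastic subsampling): for
each sample the 10 nearest hits and 10 nearest misses under Manhattan
distance on range-normalized features update each feature's weight by
(mean miss difference − mean hit difference). Range normalization makes
weights invariant to affine rescaling of any feature; zero-range features
get weight exactly 0. Distance ties are broken by sample index via a stable
sort, so rankings are fully deterministic. The published 5-feature subsets
for both methods ship as named constants and can be evaluated without
re-ranking.

## Classification protocol

* Feature columns are scaled to unit Euclidean norm. GLOBAL mode fits the
  scale on the whole cohort (mirroring the original study's description);
  TRAINFOLD fits it on each training fold only (leakage-safe). Likewise
  ReliefF selection can be global or re-run inside each training fold; the
  leakage-safe nested mode is the recommended protocol for new data, the
  global mode reproduces the historical procedure.
* LDA uses pooled covariance with empirical class priors
  (scikit-learn's implementation, SVD solver, robust to singular pooled
  covariance).
* k-NN uses Euclidean distance and majority vote; any voting tie (even k or
  equidistant neighbors) is decided by the single nearest neighbor's label,
  deterministically.
* SVM-RBF uses `K(u,v) = exp(−‖u−v‖²/s²)` with box constraint C — the
  MATLAB "KernelScale" parameterization. This matters: with scikit-learn's
  `gamma` convention the equivalent setting is `gamma = 1/s²`; other
  conventions shift the scale grid.
* Leave-one-out is the headline protocol; stratified seed-deterministic
  10-fold is available for parity. Hyperparameter grids default to the
  study's printed values (L ∈ {10,…,50}, odd k ∈ 1..33, cost 10⁻⁵..10⁴,
  scale 0.1..1.1); off-grid values are allowed with a warning.

## Synthetic cohorts

The generator emulates tablet recordings of the spiral test: base
trajectory `x = pθcosθ, y = pθsinθ` with pitch p = 3 length units/radian,
3 turns over 15 s at 100 Hz. The angular speed is trapezoidal by default —
cosine ramps over the first and last 15% of the record, constant in
between — because a pen starts and stops at rest; this also keeps the
tremor-free template spectrally compact (≥ 99.9% of each axis's variance in
the first 17 DCT coefficients, the premise that makes an order-17 residue a
tremor isolator). A constant-speed profile is available but is less
compact (nonzero boundary velocity slows the DCT coefficient decay).

Disturbances: a sinusoidal kinetic tremor with frequency uniform in
4–12 Hz, injected perpendicular to the instantaneous pen path (kinetic
tremor acts across the stroke; a radial mode exists for radius-method
studies); low-pass-filtered drift (cutoff 0.5 Hz, RMS 0.1 p) for posture
wander; and white jitter (SD 0.05 p) for sensor noise. Cohort presets draw
ET tremor amplitudes from U(0.4 p, 1.2 p) and control amplitudes from
U(0.02 p, 0.08 p) — disjoint ranges whose ratio at the nearest edges is 5.
Controls are not tremor-free: everyone has some physiological oscillation;
the class difference is amplitude, as in the clinical picture. All
per-sample parameters derive from a single cohort seed and are written to a
manifest kept separate from the drawings.

What the simulator does *not* model: pen pressure and grip dynamics,
pen-up excursions, stroke corrections, amplitude-variable or multi-component
tremor, and the within-class heterogeneity of real patients. Passing the
end-to-end surrogate therefore shows that the pipeline's machinery is
correct and sensitive to amplitude-separated 4–12 Hz tremor at realistic
noise levels — it does not certify clinical accuracy on real drawings,
which in the original study was established on a private clinical database.

## Problem sizes and determinism

The default validation scale — cohorts of 24 ET + 27 controls, 4096-point
sequences, 20 seeded repetitions for the end-to-end surrogate, 10×11 SVM
grid under LOO — runs in a few minutes on one CPU and matches the clinical
study's cohort geometry. All randomness flows from explicit integer seeds
(numpy `default_rng`); repeated runs are bit-identical. Degenerate inputs
(constant sequences, zero-norm feature columns, too-short drawings) are
either guarded with warnings and neutral values or rejected with typed
errors, as documented per function.

## Known limitations

* WAMP is uninformative on non-negative sequences under the literal
  mean-threshold convention (see above).
* The residue-distance spectrum reads tremor frequency at 2f (magnitude
  rectification); per-axis residues should be used for frequency estimates.
* GLOBAL normalization and GLOBAL ReliefF selection leak information into
  LOO estimates; they exist for fidelity to the original protocol, and the
  nested alternatives quantify the difference on new data.
* The synthetic amplitude presets are calibrated to the study's separability
  premise (ET ≥ 5× control at the range edges), not to measured drawing
  amplitudes of any clinical population.
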