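# Methods

This note documents the models, estimators, numerical choices, and known
limitations of `v1iso`.  It states no empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## The scientific question

Simple cells and double-opponent (DO) cells in V1 both have spatially
opponent receptive fields (RFs): two adjacent subfields preferring opposite
stimuli (bright/dark for simple cells; opposite cone-opponent colors for DO
cells).  The question the pipeline operationalizes is whether such neurons
combine signals **linearly across subfields**: under linearity, excitation
delivered to one subfield can be exactly canceled by the anti-preferred
stimulus on the other, at a fixed ratio, over the whole contrast range —
the isoresponse contour in the two-subfield contrast plane is a straight
line.  Departures (asymmetric rectification of subfield drives, energy-model
squaring) bend the contour and let a quadratic spike-prediction model beat
a linear one.

## Display model and color spaces

The display is a linearized three-primary monitor: intensities live in
[0, 1] per channel (gamma assumed already corrected — hardware calibration
is out of scope), the background is mid-gray (0.5, 0.5, 0.5).  Cone
excitation is the inner product of (spectrum × intensity) with a cone
fundamental, summed over primaries; cone contrast is Weber contrast per
cone class, ΔE/E_background.  A linear neuron's phosphor-space color
weighting `v` is converted to cone weights via `w = C^{-T} v`, where `C` is
the 3×3 intensity→cone-contrast matrix, then L1-normalized
(|l|+|m|+|s| = 1).

Bundled spectra are synthetic: Gaussian phosphor bumps (610/530/465 nm,
SD 30 nm) and Gaussian L/M/S fundamentals (565/535/440 nm) on a 380–780 nm,
5-nm grid.  They are colorimetrically plausible but are *not* measured
data; the luminance direction used by the luminance tuning index is the
regression of a synthetic L+M luminosity onto these fundamentals.  The
genuine CVRL tables (Judd/Vos luminosity, Stockman–MacLeod–Johnson 2°
fundamentals) could not be obtained in the build environment (no network);
the luminance regression is therefore verified on synthetic spectra, where
OLS without intercept recovers exact linear combinations, and the
acceptance check against the printed coefficients (0.83, 0.55, 0.03)
remains unsatisfied until the four small CSV tables are dropped into
`src/v1iso/data/`.

## Synthetic model neurons (the ground truth)

Each neuron is a subunit cascade over a 10×10 pixel grid (0.2°/pixel):

* one separable 15-frame filter per subfield —
  `gain · temporal ⊗ spatial ⊗ color` with a unit-norm biphasic temporal
  kernel peaking 3 frames (≈40 ms) before the spike bin, uniform spatial
  weights over a 2×3-pixel subfield, and a unit color vector;
* a pointwise subunit nonlinearity: identity (`simple_linear`,
  `do_linear`), asymmetric half-rectification with gains
  (gain_pos, gain_neg) = (1, 0.25) (`rectified_subunit`), or squaring
  (`energy`);
* a signed sum across subunits and a logistic output:
  per-frame Bernoulli spiking with p = logistic(g + c) during white noise
  (one 13.33-ms bin per frame), and Poisson counts with rate
  `R_max·logistic(g + c) + baseline` for 300-ms static-image trials, where
  the trial drive uses only the peak temporal slice of the filter scaled by
  `trial_gain` (temporal integration of a static stimulus is a fixed
  scalar).

Defaults and why: `gain = 6` and `c = −2.5` put Phase-1 spiking near 0.12
per frame with peak-frame pixel z-scores ≈ 8 at 5×10³ spikes (the automatic
yoking needs every subfield pixel to clear the p < 0.05 z-test), and
Phase-2 spiking near 0.24.  The energy preset uses `gain = 2`, `c = −3`
(its drive is a sum of squares).  `R_max = 100` sp/s, `baseline = 10` sp/s,
`trial_gain = 2` place the isoresponse contour of the default targets
(~35–40 ips) mid-gamut, so that 8–10 of 16 staircase directions terminate
for a linear cell; Phase-3 directions are offset half a step from 0 so none
coincides with a linear cell's null axis, where the target is unreachable
by construction.  The color vectors are generated from target cone weights
((0.5, −0.5, 0) opponent; (0.5, 0.45, 0.05) non-opponent), so cone-weight
recovery has an exact ground truth.

The cascade answers both open-loop (movie → spike train) and closed-loop
(image → trial count) queries, and `analytic_isoresponse` inverts it in
closed form / by bracketed root search to provide ground-truth contour
radii for staircase validation.

What the generator does **not** emulate: eye movements (stimulus jitter),
spike-history effects and refractoriness, adaptation/non-stationarity
across the session, correlated noise, and spike-sorting errors.  A green
test therefore establishes estimator correctness under the model's
idealizations, not robustness to these nuisances — notably, the
isoresponse NLI's sensitivity to slow rate drift (flagged in the original
protocol as a caveat) is untested here.

## Estimators

**STA and significance.**  The STA averages the 15 background-subtracted
frames preceding each spike (spike-count weighted).  The peak-frame
statistic is `n_spikes · Σ(element/σ)²` with the known truncated-Gaussian
noise SD, referred to a χ² with one degree of freedom per element; pixel
tests are per-phosphor z-tests at p < 0.05, uncorrected (as in the original
on-line screening).  Significant pixels are grouped into components that
are 8-connected *and* chromatically coherent (adjacent pixels connect only
if their peak-frame RGB cosine is positive); plain 8-connectivity would
fuse abutting opposite-color subfields into one blob.  The two largest
components with distinct mean color (cosine < 0.9) become the hyperpixels;
fewer than two raises the "passed over" screening error.  The energy
preset's expected STA is exactly zero (even nonlinearity), so its subfields
cannot be found this way; `use_true_map=True` supplies the generating map,
standing in for manual yoking.

**SVD decomposition.**  The peak hyperpixel-STA frame and its flanks are
averaged with weights ∝ per-frame energy; the 3×2 color×space matrix's
first singular pair gives the color and spatial weighting functions
(sign-fixed: the color vector's largest-magnitude entry is positive);
variance explained is σ₁²/Σσᵢ² (≥ 0.5 by construction for a 3×2 matrix).

**PC1 permutation test.**  Spike-triggering 15×2×3 segments are vectorized,
the sample STA direction projected out, and the top eigenvalue of the
(mean-centered) covariance computed.  The null redoes the *entire*
computation — STA, projection, covariance, eigenvalue — after circularly
shifting the spike train by a uniform offset ≥ 15 frames (1000 shifts);
significance means exceeding the empirical 95th percentile.  Circular
shifts preserve spike count and autostructure.

**GLM/GQM and NLIs.**  Logistic fits are unpenalized maximum likelihood
(lbfgs); complete separation (detected as a separating margin on the
training data) falls back to a documented tiny ridge (1e-6) and is
flagged.  Classification error is 1 − AUC with midrank tie handling.
Folds are stratified on the spike label (spikes are rare; unstratified
folds can lose a class) and synchronized across the two hyperpixels in the
within-subfield analysis; the across-subfield analysis sums errors over
subfields before forming the GLM/GQM ratio.  The NLI is
log10(median over folds of the error ratio); its spread is the standard
delete-one jackknife over per-fold log-ratios.  Non-finite fold ratios
(a zero held-out error) are excluded from the jackknife.

**Staircase.**  Updates are multiplicative (additive in log radius): up
log 1.35 when the count is below target, down log 0.65 otherwise (a count
equal to target is treated as "not below", so the procedure always makes
progress); each reversal shrinks the step by 25%; a run halts at 7
reversals ("terminated", termination radius = final trial's radius — the
protocol's own estimate) or on crossing the per-direction gamut limit
("out of gamut", excluded from fits).  The initial radius is 25% of the
gamut limit.  Directions are interleaved in random pairs, alternating
trial-by-trial.  Note the terminal quantization of this schedule: the last
step magnitude is 0.75⁶·|log 0.65| ≈ 0.077 in log radius, so individual
termination points can sit up to ~8% from the true isoresponse radius even
with a noiseless oracle; averaging across directions, not per-point
accuracy, is what the contour fits rely on.

**Robust polar fits.**  Residuals are log r_obs − log r_pred (radial error
in log contrast, matching the multiplicative staircase).  The loss is
Tukey bisquare with tuning constant 4.685 (95% Gaussian efficiency),
standardized by a MAD scale.  Because gross outliers at high-leverage
directions can corrupt both a least-squares seed and its MAD scale, the
seed and scale come from a high-breakdown subsample search (best-of-60
exact minimal-subset fits by least median of squares), followed by
multi-start Nelder–Mead and one re-scaled polish.  Quadratic predictions
take the smallest positive root of the conic in r; directions with no
positive root incur a large fixed penalty (1e3·scale²).  The linear model
is exactly the quadratic with (A, B, C) = 0, and the two parameterizations
give identical objectives on shared data (tested).  The isoresponse NLI
uses leave-one-out refits warm-started from the full-data fits.

## Numerical and design choices

* Truncated-Gaussian noise is sampled by rejection (resample until
  in-gamut), not clipping — clipping would put point masses at the gamut
  edges; significance tests use the analytic truncated-normal SD.
* Stimulus frames are 0-based; a segment "ending at frame t" spans
  [t−14, t]; frames before index 14 never spike.
* Out-of-gamut edge stimuli are flagged, not rejected (the staircase needs
  to know, the display model does not forbid asking).
* `isoresponse_nli` requires ≥ 8 terminated points and ≥ 6 valid LOO
  folds; degenerate folds are dropped and logged in the result.
* Target rates are the smallest multiple of 5 ips strictly above the 95th
  percentile of baseline rates (≥ 20 baseline trials).
* All simulations take explicit integer seeds; a fixed `ExperimentConfig`
  reproduces a `CellReport` byte-for-byte.

## Known limitations

* The per-point staircase quantization (~8% worst case) exceeds the ~5%
  level one might hope for from 7 reversals; estimating terminations from
  the final two trials would halve it but would depart from the protocol's
  stated termination point, so it is not done.
* The Tukey line fit at n = 16, σ = 0.1 with 2 gross outliers has ~2% of
  draws whose *global* robust optimum still misses the generating (A, B)
  by more than 10% — an estimator property, not an optimizer failure (the
  optimizer is checked against a grid-search oracle).
* Cone weights are meaningful only for chromatically linear cells; the
  pipeline (like the protocol it implements) reports them for OSO cells
  only alongside the PC1 flag that marks them as unreliable.
* The within-subfield analysis conditions on a single latency frame and
  treats the other subfield's influence as additive noise; both
  assumptions are inherited from the protocol.
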