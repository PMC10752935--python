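# Methods

## The model

Cortical activity in the high-gamma band (70–200 Hz) contains a component
that is time-locked to the fine structure of continuous speech.  The analysis
models a source-localized response `y(t)` (a 3-component current-dipole
vector per voxel) as a sum of convolutions of stimulus feature time series
with temporal response functions (TRFs):

    y(t) = Σ_τ Σ_p x_p(t − τ) h_p(τ) + n(t)

with lags τ from −40 to 210 ms.  Two features are used per speech stream:

* **carrier** — the stimulus waveform resampled to 500 Hz and bandpassed to
  70–200 Hz (temporal fine structure; for a low-pitched voice the fundamental
  frequency itself lies in this band);
* **envelope modulations** — a cochlear-style filterbank spectrogram is
  computed, the envelopes of the 300–4,000 Hz bands are each bandpassed to
  70–200 Hz, averaged across bands, resampled to 500 Hz, and standardized
  (F0-rate amplitude modulation of the harmonics).

The single-speaker design uses the two predictors of one voice; the
cocktail-party design uses four (carrier + envelope for attended and ignored
streams simultaneously).

## Estimation

TRFs are estimated by coordinate-descent boosting with cross-validated early
stopping, independently for each voxel and each of the three dipole
components.  Kernels are parameterized on overlapping 4 ms Hamming windows,
one per lag sample of the 500 Hz grid (125 lags over [−40, 210) ms), so
estimates vary smoothly.  Each step evaluates every (predictor, window, ±δ)
candidate — δ = 0.005 × sd(response component) per channel, with predictors
at unit sd — and applies the one that most reduces training error.  Time is
split into 4 contiguous folds; training stops when the held-out segment's
error has not improved for 10 consecutive steps (rolling back to the best
validation state) or when no step reduces training error.  The final kernel
is the fold average.  Because all coordinates of all predictors are swept
before each step, correlated predictors compete for variance and the
predictor ordering has no effect (verified bit-exact in the tests).  Exact
ties in error reduction resolve to the lowest (predictor, window) index and
+δ before −δ; tie events are counted in the fit diagnostics.

The inner loop runs on sufficient statistics: per-fold Gram matrices of the
lagged design and residual–design correlation vectors, updated incrementally
after each step.  All channels (voxels × components × subjects × conditions)
that share a predictor set are fitted in one vectorized batch against a
single precomputed design, which is what makes cohort-scale simulation
studies tractable on one CPU.

Prediction accuracy is the per-voxel Pearson correlation between measured
and predicted responses, computed per component and averaged (a
`concatenated` reduction is available in config).  By default predictions
are cross-validated: each fold's held-out segment is predicted by the kernel
trained without it.  Note the validation segment used for early stopping is
the same held-out segment, so accuracies retain a small optimistic bias even
for unrelated predictors — exactly why accuracies are always compared
against circular-shift null models rather than zero.

## Null models and statistics

Each fitted model is accompanied by three null fits in which all predictors
are coherently rotated by 1/4, 2/4, 3/4 of their duration (preserving
marginal distribution, autocorrelation and cross-predictor structure while
destroying stimulus alignment), using the identical estimator configuration.
The mean null amplitude (L2 norm of the kernel vector over components) is
the noise floor; it is subtracted from the true amplitude before extracting
each subject's peak amplitude and latency in the 20–50 ms window (averaged
over the voxel set first).

Group inference uses one-tailed paired-t maps enhanced with threshold-free
cluster enhancement (TFCE; E = 0.5, H = 2, dh = max(t)/100) and max-statistic
sign-flip permutation distributions: over lags (chain adjacency) for
amplitude-vs-null tests, and over voxels (6-connectivity on the 7-mm grid,
after Gaussian smoothing of accuracies with 5 mm sd) for accuracy-vs-null
tests.  All 2^n sign patterns are enumerated when feasible (n ≤ ~13 at the
default permutation budget), otherwise Monte Carlo sampling includes the
identity flip so p ≥ 1/n_permutations.  The attended-vs-ignored peak
comparison is a two-sided Wilcoxon signed-rank test per predictor kind, with
the statistic reported as the rank sum of negative differences (exact null
distribution for n ≤ 25 without ties).

A deliberately independent brute-force TFCE (per-threshold breadth-first
component search over an explicit edge list) ships alongside the fast
implementation (scipy.ndimage labeling) and the two are compared on random
1-D and 3-D maps in the tests.

## Synthetic data

The generator emulates the study conditions so every stage has a
parameter-recovery oracle:

* **Stimuli** — 18 s harmonic complexes; male voice F0 ≈ 95 Hz (long-run sd
  8 Hz), female ≈ 168 Hz (sd 10 Hz), F0 drifting as a mean-reverting Gaussian
  walk (0.5 s time constant, clipped at ±3 sd); 1 s alternation of voiced
  segments and white-noise bursts (75% voiced); 40 harmonics (23 for the
  female voice) at 16 kHz.  Each harmonic carries a slow independent phase
  drift (OU, sd 1.5 rad, 0.25 s time constant): natural voices are not
  phase-locked across harmonics, and without this dispersion the carrier and
  envelope-modulation predictors of one voice become nearly collinear
  (r ≈ 0.95) instead of the moderate correlation (r ≈ 0.1–0.3) real speech
  produces.
* **Kernels** — per subject and voxel, a current dipole whose vector norm
  over lags is a Gaussian bump (peak 40 ms, sd 5 ms) and whose direction
  rotates in a random plane at 135 Hz.  The rotation keeps the kernel's
  energy inside the measurement band: with stimuli and responses band-limited
  to 70–200 Hz, out-of-band kernel content can neither drive a response nor
  be identified, so a static low-pass bump would make "recover the kernel"
  an ill-posed target (a static variant remains available via
  `carrier_freq_hz=0`).
* **Responses** — gain-weighted predictor ⊛ kernel sums plus Gaussian noise
  bandpassed to 70–200 Hz, sd 16 per component.  Attention scales the male
  envelope pathway (gain 1.5 attended vs. 1.0 ignored by default); the
  carrier pathway gain is 1.0 in both conditions; female-speech kernels are
  scaled by 0.1 (a near-null response, matching the empirical absence of
  responses to high-pitched voices).  Subject-level lognormal gain jitter
  (sd 20%) multiplies each pathway, preserving each subject's attend/ignore
  ratio.  All subjects of a cohort share one stimulus pair; kernels,
  orientations and noise are per-subject, all seeded deterministically from
  the master seed.

The default noise level was set so that, at desk scale (one 18 s stimulus
pair, 22 subjects, a 32-voxel grid), the male-speech amplitude tests are
significant around the true 40 ms peak, the 10×-weaker female response is
not, and cross-validated accuracies land at a few hundredths.  Real
recordings sit at far lower single-trial SNR (accuracies near 0.01) and
compensate with hours of data; the generator trades that regime for runtime,
so passing tests demonstrate correctness and calibration of the machinery,
not field-strength effect sizes.  What the generator does not emulate:
sensor-level noise structure and preprocessing, inverse-operator leakage and
cross-voxel correlation, phonetic/articulatory stimulus structure,
subject-specific latency differences, or attention effects on the carrier
pathway.

## Problem sizes and numerical choices

Simulation studies in the tests and acceptance script use reduced problem
sizes chosen for single-CPU runtimes: 4–8-voxel grids, 12 s stimuli for
cohort replicates (36 s for single-subject kernel recovery), 20 replicate
cohorts, and 100–500 permutations (full 2^8 enumeration for n = 8 cohorts).
Peak-based attention comparisons are insensitive to grid size because peaks
are taken on voxel-averaged amplitudes.

Degenerate inputs are handled explicitly: constant series standardize to
zeros with a flag; zero-variance response components yield zero kernels and
a flag; zero-variance predictions define accuracy 0; paired-t with zero
difference variance is capped at ±1e6 with a degeneracy flag; all-zero
Wilcoxon differences return a no-test result.  Filtering is linear-phase FIR
(Hamming design, 3.3/N transition rule) applied with group-delay
compensation, so a symmetric pulse stays symmetric and TRF latencies are not
biased; resampling interpolates after the anti-aliasing filter confines
energy ~40× below the original Nyquist.  Per-bin auditory filters are
order-4 Butterworth bandpasses whose half-power bandwidth cf/5.196 gives
Q10dB = 3 exactly for the Butterworth magnitude; envelopes are half-wave
rectified and smoothed to a 1 kHz frame rate before the high-gamma filter,
then resampled to 500 Hz (the alternative — filtering after resampling —
would alias the 300–4,000 Hz envelope content and is not offered).

## Known limitations

* The attended/ignored distinction collapses the original "attend language"
  vs. "attend arithmetic" sub-conditions into one attended stream per
  speaker.
* Mixed-effects modeling of peak amplitudes is intentionally out of scope;
  the peak table is exported as tidy TSV for external statistical tools, and
  only the Wilcoxon comparison is built in.
* The boosting step size, patience, fold count and tie-break rules follow
  the estimation tradition for this family of deconvolution methods and are
  exposed in config, but no claim is made that they are optimal.
* Trial boundaries inside concatenated predictors are not masked during
  fitting.
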