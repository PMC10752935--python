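# hgtrf

High-gamma temporal response functions for continuous speech.

Auditory cortex tracks the fine structure of running speech at surprisingly
high frequencies: responses in the 70–200 Hz ("high-gamma") band follow the
fundamental frequency of a low-pitched voice and the F0-rate amplitude
modulation of its harmonics.  `hgtrf` is a pipeline for estimating and
testing these responses in source-localized MEG-style data — and for anyone
who wants to validate such an analysis end to end on synthetic data with
known ground truth before trusting it on real recordings.

## The model

A vector dipole response `y(t)` (3 components per voxel) is modeled as a sum
of convolutions with temporal response functions (TRFs) over lags −40–210 ms:

    y(t) = Σ_τ Σ_p x_p(t−τ) h_p(τ) + n(t)

The predictors `x_p` are, per speech stream, the **carrier** (waveform
bandpassed to 70–200 Hz) and the **envelope modulations** (average of
auditory-spectrogram band envelopes, 300–4,000 Hz, each bandpassed to
70–200 Hz); both standardized at 500 Hz.  The single-speaker model uses two
predictors, the cocktail-party (two concurrent voices, one attended) model
uses four, estimated jointly by coordinate-descent **boosting** with
cross-validated early stopping on a 4 ms Hamming-window lag basis, so
correlated predictors compete for variance and ordering is irrelevant.

Estimates are tested against **circular-shift null models** (predictors
rotated by 1/4, 2/4, 3/4 of their duration, refitted identically).  The mean
null amplitude is the noise floor; group tests are one-tailed paired-t maps
with threshold-free cluster enhancement (TFCE) and max-statistic sign-flip
permutations, over lags (TRF amplitude vs. null) and over voxels (prediction
accuracy vs. null, smoothed with a 5 mm Gaussian).  Attended vs. ignored
peak amplitudes (noise-floor-corrected, 20–50 ms) are compared with a
Wilcoxon signed-rank test per predictor kind.

The package includes a first-class synthetic-data module: speech-like
harmonic stimuli with controlled F0 (male ≈ 95 Hz, female ≈ 168 Hz), a 7-mm
voxel grid of rotating-dipole ground-truth kernels peaking at 40 ms, band
noise, and an attention gain on the envelope pathway.  See
`docs/methods.md` for the full model description and design choices.

## Worked example

Simulate and analyze a small cocktail-party cohort from the shell:

```sh
hgtrf run-cocktail --seed 7 --n-subjects 8 --grid 2,2,1 --out runs/demo
hgtrf report --run-dir runs/demo
```

which prints (abridged):

```
scenario: cocktail_party  subjects: 8  config: 89041cf59e657e8b
  accuracy[attend_female]: 0.0807 (null 0.0231)
  accuracy[attend_male]: 0.1041 (null 0.0235)
  amplitude[attend_male:male_envelope]: t_max=7.866  22-28 ms, 36-46 ms, 50-56 ms
  amplitude[attend_male:male_carrier]: t_max=7.010  24-28 ms, 36-44 ms, 50-58 ms
  amplitude[attend_male:female_envelope]: t_max=None  n.s.
  amplitude[attend_female:male_envelope]: t_max=7.659  26-26 ms, 34-44 ms, 52-56 ms
  wilcoxon[envelope]: W=0.0 p=0.0078125
  wilcoxon[carrier]: W=14.0 p=0.640625
```

Reading this: the TRF model predicts the responses far better than its
circular-shift null (0.104 vs. 0.023); the male-speech TRFs have significant
time-locked responses clustered around the true 40 ms peak in both attention
conditions, while female-speech TRFs (simulated at 10% gain) stay at the
noise floor; and the attended-vs-ignored peak comparison is significant for
the envelope pathway (every subject's attended peak is larger, W = 0) but
not for the carrier, whose simulated gain does not depend on attention.
The same analyses are available as library calls
(`hgtrf.pipeline.run_single_speaker` / `run_cocktail_party`) and as stagewise
subcommands (`simulate`, `predictors`, `fit`, `null`, `stats`) operating on
saved intermediates.

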