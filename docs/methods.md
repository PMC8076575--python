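# Methods

This note documents the models, parameter choices and limitations behind
`crydetect`, in the order the pipeline runs.

## Signal representation and epoching

All audio is reduced to mono (channel averaging) float64 in [-1, 1] at a
canonical 16 kHz — a standard rate for speech-band analysis that covers
the cry fundamental (300–600 Hz) and its first dozen harmonics with
margin. Arbitrary input rates are converted by polyphase resampling.
Peak normalization is applied only when a sample exceeds full scale, so
relative level information is preserved otherwise.

Epochs are non-overlapping 5-s windows, 0-based, half-open in time
([start, start+5)); a trailing remainder shorter than one epoch is
discarded rather than padded, because every downstream count (cry epochs,
sequence durations) assumes whole epochs. A signal shorter than one epoch
yields an empty grid with a warning, not an error, so batch runs survive
stub files.

## Acoustic features

Per epoch, frames of 25 ms with a 10 ms hop (Hamming window, 498 frames
per epoch) produce 42 low-level descriptors:

| LLD | count | notes |
|---|---|---|
| MFCC 1–12 | 12 | DCT-II (ortho) of the 26 log mel energies; coefficient 0 excluded, so MFCCs are exactly gain-invariant |
| log mel-band energy | 26 | triangular filters, 20–8000 Hz, floored at 1e-10 before the log |
| RMS energy | 1 | unwindowed frame RMS |
| zero-crossing rate | 1 | sign changes per second; invariant to positive gain |
| F0 | 1 | Hz; 0 when unvoiced |
| voicing probability | 1 | normalized autocorrelation peak, lags 75–600 Hz |

Pitch/voicing details: frames are mean-removed, the autocorrelation is
computed by FFT and normalized by lag-0 with an unbiased (1 − k/N) taper
so long lags are not penalized. Because the autocorrelation of a periodic
signal also peaks at period multiples, F0 is taken from the earliest
*local* peak within 90% of the global peak — the global argmax would
systematically halve or third the pitch. Frames whose peak falls below a
voicing threshold of 0.45 get F0 = 0; frames with vanishing energy
(r0 ≤ 1e-30, including denormals from filtered silence) are treated as
silent outright.

Each LLD's frame series is summarized by 13 functionals: mean, population
SD, min, max, range, percentiles 1/25/50/75/99 (type-7 linear
interpolation), IQR, skewness and excess kurtosis, with skewness and
kurtosis of a zero-variance series defined as 0. Population SD and type-7
percentiles are fixed conventions, chosen once for reproducibility. The
registry of 42 × 13 = 546 ordered names is the contract shared by
screening, training and prediction; extraction is bitwise deterministic.

This registry deliberately does **not** reproduce any particular
large-scale feature-extraction toolkit configuration: it covers the LLD
families that matter for cry detection (spectral envelope, mel energies,
voicing) with a documented, testable surface.

## Feature screening

Re-recordings of identical audio under different ambient conditions
should produce identical feature distributions. The screen makes the
stability judgment explicit: for each feature and condition it computes
the standardized mean difference |μ_c − μ_ref| / √((σ_ref² + σ_c²)/2)
and the SD ratio σ_c/σ_ref (population SDs), and excludes the feature if
*any* condition exceeds SMD 0.5 or leaves the SD-ratio band [0.5, 2].
Worst-case (any-condition) exclusion matches the requirement that a
feature be robust under all deployment conditions, not on average.
Zero-variance corner cases: a constant feature that moves between
conditions is excluded (maximally fragile); one that stays put is
retained. Both thresholds are exposed; exclusion is monotone in the SMD
threshold. The default screening conditions are 6 dB attenuation
(distance), a 4 kHz low-pass (physical barrier) and added white
background at 10 dB SNR (ambient noise).

## Classification

Three families are compared: random forest, L2 logistic regression and
Gaussian naive Bayes. Logistic regression and naive Bayes see z-scored
features (scaler fit on training folds only, inside the CV loop); the
forest sees raw features. Default grids are small and documented:
forest {trees 100/300/500 × depth ∅/10/20 × min leaf 1/5}, logistic
{C ∈ 0.01, 0.1, 1, 10}, naive Bayes {variance smoothing 1e-9, 1e-6}.

"Optimize for sensitivity" is formalized as: the grid winner maximizes
mean cross-validated sensitivity, ties broken by mean MCC, remaining ties
by grid order — the simplest deterministic reading of a
sensitivity-first protocol. Folds are stratified (the deployment class
balance is heavily skewed toward non-cry) and seeded; identical inputs
and seed give identical results. The final model is the family with the
highest mean CV MCC, refit on all rows, with family order
(forest, logistic, naive Bayes) as the deterministic tie-break. The
decision threshold on the cry probability is fixed at 0.5, with the
boundary labeled cry.

The metric suite (accuracy, MCC, sensitivity, specificity, PPV, NPV) has
a single implementation shared by CV and evaluation. Zero-denominator
metrics return 0 with a flag instead of NaN so single-class stretches in
per-subject evaluation never crash a pipeline; real-valued confusion
counts are allowed so pooled metrics can be reconstructed from published
rates and class totals. Percent formatting rounds half away from zero to
one decimal.

## Cry sequences

On the 5-s grid, a cry sequence opens at the first cry epoch of the
earliest 12-epoch window containing ≥ 6 cry epochs, and closes at the
last cry epoch before the first run of ≥ 60 consecutive non-cry epochs
(or end of series). Readings fixed here, since several are open:

* "within 1 minute" means any sliding 12-epoch window, not clock-aligned
  minutes — alignment-free and strictly more sensitive; windows at the
  series tail are truncated (≥ 6 cries within *fewer* than 12 trailing
  epochs still triggers).
* the sequence starts at crying, not at the triggering window's first
  epoch, and ends at the last cry: internal pauses shorter than the stop
  gap are bridged into the duration, but the terminating silence itself
  is never counted.
* sub-threshold crying between sequences belongs to no sequence.

The implementation is a linear scan over prefix sums and zero-run
lengths; the test suite proves it equal to an independently written
brute-force scan on *all* binary series up to length 20 (scaled
parameters 2/4/5) and on 1,000 random hour-long series at the deployment
parameters 6/12/60.

Cohort summaries report type-7 medians and IQRs of annotated sequence
counts, |Δcount| and |Δduration| (the latter restricted to subjects with
at least one annotated sequence), plus per-group medians of total cry
duration (cry epochs × 5/60 min). Note that published IQRs of this kind
of table are sensitive to the quantile convention; medians are stable
across conventions and are what the acceptance checks use.

## Synthetic data

The generator defines the study conditions for every test:

* **Cry**: an additive harmonic stack (8 harmonics, 1/k decay) driven by
  a rising–falling F0 contour (base 450 Hz, excursion +100 Hz) with 2%
  smooth multiplicative jitter, shaped into ~1 s expiratory phrases with
  ~0.4 s pauses and a rise–fall envelope. This is a source model with the
  right gross spectro-temporal structure, not perceptual resynthesis.
* **Non-cry**: white noise, pink noise, tones (100–1000 Hz), speech-like
  babble (alternating weak voiced segments at 120–250 Hz and noise) and
  impulsive knocks — spectrally distinct stand-ins for domestic sounds.
* **Corpus**: labeled 5-s clips, 300 cry / 400 non-cry by default; every
  clip is mixed with mild room tone (white background at a random SNR of
  10–30 dB). Re-recorded audio is never digitally silent — in particular
  the pauses inside a cry contain ambient noise — and training on
  digitally clean clips was observed to fail exactly there: a forest
  trained on clean cries rejects session epochs whose pauses carry
  background. The room tone is a property of the emulated recording
  process, not a tuning knob.
* **Sessions**: continuous background with cry bouts mixed at a stated
  SNR (default 10 dB) on a labeled epoch grid. The robustness session is
  348 epochs (29 min) with 200 cry epochs (~16.7 min of crying). The
  default *monitoring* session prevalence is ~3% cry epochs, matching a
  realistic day-long class imbalance.
* **Perturbations**: attenuation (10^(−dB/20) gain), zero-phase 6th-order
  Butterworth low-pass, and background mixing at a stated SNR — the
  software analogues of distance, barriers and ambient noise.

All generators are pure functions of (parameters, seed).

What passing tests on this data do and do not show: the synthetic classes
are controllably separable, so near-ceiling benchmark metrics demonstrate
that the pipeline machinery (features → screen → CV → selection →
sequences) is correct and leak-free, not that real-world cry detection is
solved. Real recordings add reverberation, overlapping sources,
cry-like fussing and annotator ambiguity, none of which the generator
emulates; published validation-scale sensitivity (~0.83) should be
expected to be harder than the benchmark suggests.

## Robustness analysis

Cumulative cry-count curves (prefix sums of epoch labels) are compared
across runs: per run, the final-count delta against the reference, the
maximum pointwise deviation and its epoch. Because the software pipeline
is deterministic, repeated runs on identical input must coincide exactly
— the software analogue of intra-device repeatability; hardware-induced
variability between devices cannot be reproduced here and is emulated
only as perturbation conditions. For the attenuation series
(0/−6/−12 dB) the acceptance tolerance of ±15% on the final count is an
artifact-level choice for the distance analogue, not an external claim.

## Problem sizes and numerical choices

The standard benchmark (700 clips × 4 extraction passes, three CV grid
searches) runs in ~2 minutes on one CPU; the exhaustive sequence oracle
(~2.1 M series) in ~20 s. Sizes were chosen so the full suite and the
reproduction script each stay comfortably within a coffee break.
Numerical conventions collected in one place: log floor 1e-10 for mel
energies; silence threshold 1e-30 on lag-0 autocorrelation; voicing
threshold 0.45; decision threshold 0.5 with ≥ labeling cry; type-7
quantiles; population SDs; rounding half away from zero at one decimal
in percent reporting only.

## Known limitations

* The feature set is a compact 546-dimensional reconstruction of the
  relevant LLD families, not any specific industrial configuration;
  absolute feature values are not comparable to other toolkits.
* The screening rule replaces human visual judgment of distribution
  plots with an SMD/SD-ratio criterion; threshold defaults are sensible
  but not canonical.
* Cry-type discrimination (pathological vs normal cries), streaming
  capture and non-WAV codecs are out of scope.
* The grid search covers hyperparameters only; feature-subset search
  beyond the robustness screen is not implemented.
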