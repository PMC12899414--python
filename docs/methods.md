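# Methods

This note documents the models, conventions and design choices behind
`nbackeeg`, in the order data flows through the package.

## Signal model and the synthetic generator

The generator does not attempt physiological realism; it reproduces the
*statistical structure the analysis assumes*, which is what makes the
chain testable. Each channel is

    x(t) = sigma * sum_b sqrt(f_b) * n_b(t) + blinks(t),

where `n_b` is unit-variance Gaussian noise confined to band `b` and
`f_b` are the target band fractions (a point on the 5-simplex per
channel). Band confinement uses brick-wall FFT masks over exactly the
half-open `[low, high)` frequency bins that the feature extractor later
sums, so the target fraction and the measured relative power agree by
construction; measured over the full recording the error is near zero,
and over a 10-s epoch it is estimation noise of a few percent.

- `sigma` (`eeg_rms_uv`, default 20 uV) sets the background scale;
  relative powers are scale-free, so it only matters relative to blink
  amplitude.
- Condition effects enter through the per-channel fraction vectors.
  Built-in specs reproduce the published group-mean relative powers per
  task and time of day (e.g. T6 theta 24.1% a.m. vs 35.4% p.m. in the
  2-back task), renormalized to sum to 1.
- Inter-participant variability is one 6-vector per participant, drawn
  N(0, `subject_sd`) and added on the logit of each fraction before
  renormalizing. The logit scale keeps fractions in (0, 1) where an
  additive offset could go negative. The same offset applies to both
  conditions, making subject identity a nuisance factor orthogonal to
  the condition contrast. Default `subject_sd = 0.3` gives moderate,
  clearly visible subject differences; 1.5 is used to emulate the
  "strong chronotype heterogeneity" regime.
- Blinks are raised-cosine pulses, 300-500 ms wide, 120-180 uV, on
  Fp1/Fp2 only (Fp2 scaled 0.85-1.0), arriving as a Poisson process at
  `blink_rate_hz` (default 0.1/s). A pulse of width w has its spectral
  content at DC and near 1/w = 2-3.3 Hz, so the 2-50 Hz band-pass
  removes much but not all of it - which is the realistic situation
  that motivates the ICA/excision stage.
- Behavioral tables are 20 Bernoulli trials per session with
  per-condition correct rates defaulting to the bundled table's group
  means (2-back 0.80/0.885, 3-back 0.68/0.74) and log-normal response
  times (median ~770 ms).
- Study defaults mirror the emulated design: 5 participants, 2 sessions
  per condition, 250 Hz, 16 s per recording (enough to cover the 3-15 s
  analysis range with margin). All randomness flows from a single seed;
  identical inputs reproduce identical recordings bitwise.

What the generator does *not* model - and what green simulation tests
therefore do not establish about real EEG: 1/f background spectra,
evoked responses, non-stationarity across a session, channel
correlations beyond shared band structure, muscle/line artifacts, and
any genuine circadian physiology. The generator answers "does the
pipeline behave correctly on data with the assumed structure?", not
"would the published effect replicate?".

## Preprocessing

Fixed order: per-channel normalization, then band-pass, then artifact
cleaning.

- Normalization brings each channel to mean 0 and variance 1 using the
  population (1/N) variance convention; with two samples [1, 3] the
  result is exactly [-1, 1]. Per-channel (not whole-montage) scaling is
  the natural reading and keeps channels comparable.
- The band-pass is a 4th-order Butterworth applied forward-backward
  (`sosfiltfilt`), giving zero phase. Measured response: <1 dB ripple
  across 4-40 Hz, half power at the 2 and 50 Hz corners, >=20 dB
  attenuation at 0.5 and 80 Hz. The upper shoulder (45-50 Hz) rolls off
  by ~2 dB; pushing it inside 1 dB would need roughly a 10th-order
  design, which was not considered worth the numerical risk.
- Blink handling replaces an operator's visual excision with an
  automated, reproducible rule. FastICA (fixed seed, 8 components)
  decomposes the conditioned signal; components correlating with the
  frontal (Fp1+Fp2) mean at |r| > 0.8 are zeroed before reconstruction.
  Samples where a cleaned frontal channel exceeds 4 channel-SDs are
  marked excised, padded by 200 ms and merged; excision is metadata
  that downstream windowing honors - samples are never deleted. On
  near-Gaussian sources (typical of the synthetic band mixtures) FastICA
  legitimately fails to converge; the signal then passes through with no
  components removed and the amplitude rule still applies. The 4-SD rule
  has a small false-positive rate on clean Gaussian data (about 0.25
  samples per frontal channel per 16-s recording), which simply drops a
  handful of windows.

## Features

- Band powers come from the untapered FFT of each window, summed over
  half-open `[low, high)` bins so shared edges (4, 8, 12, 15, 30 Hz)
  are counted once. The periodogram is scaled (one-sided doubling,
  DC/Nyquist-aware, 1/N) so all bins sum to the time-domain energy;
  relative powers are invariant to this calibration.
- The compacted waveform splits 250 samples into 10 blocks of 25, each
  block into segments of (4,4,4,4,4,5) samples - the odd 5-sample
  segment sits last by convention (config-exposed) - and averages
  segment means across blocks. The map is linear; a ramp 0..249
  compacts to (114.0, 118.0, 122.0, 126.0, 130.0, 134.5).
- Windows are anchored to the session's task start, 1 s long, sliding
  at 0.1 s from 3.0 to 14.0 s (111 per recording); a window is dropped
  when its open interval intersects an excised interval. The long
  10-s epoch (5-15 s) serves condition-level band-power tables.

## Classifier

Input is the 8x6 feature matrix, oriented as 6 positions x 8 channels.
A kernel-1 1-D convolution with 128 filters mixes the 8 channels at
each position (no temporal receptive field - the convolution is
position-equivariant), then ReLU, flatten (768), a linear 32-unit dense
layer, and a 2-class softmax: 25,826 trainable parameters
((8x128+128) + (768x32+32) + (32x2+2)). ReLU is applied after the
convolution for both representations for symmetry. The protocol names
no optimizer or loss; Adam (lr 1e-3) on categorical cross-entropy is
the de-facto standard and both are config-exposed. Training runs a
fixed number of epochs (default 1000) with no early stopping; 30% of
the training data is held out as a per-epoch validation monitor only.
Weights use Glorot-uniform initialization; training is bit-reproducible
given (seed, data). The network is implemented directly in numpy - at
this size an explicit forward/backward trains in seconds on one CPU.

Relative-power inputs are used as-is (already in [0, 1]); compacted
waveforms inherit the z-scored microvolt scale.

## Evaluation

- Accuracy is (TP+TN)/total with class 1 ("pm"/"high") as positive and
  argmax ties resolved to class 0.
- Pooled evaluation repeats a *window-level* random 70:30 split ten
  times (fresh split and fresh model per repeat, seeds seed+r) and
  reports mean +/- SEM (n-1 SD over repeats). Window-level splitting is
  deliberate fidelity to the emulated protocol and is optimistic:
  windows 0.1 s apart share 90% of their samples, so test windows are
  highly correlated with training windows from the same recording.
  Measured consequence: with *identical* condition specs the pooled
  test accuracy sits near 0.73 rather than 0.5 - the network memorizes
  recording identity, whose label is coherent under the null. Two
  controls localize this to the protocol rather than the code: permuting
  labels at the window level (which breaks per-recording coherence)
  yields chance accuracy, and LOOCV under the null is at chance.
- LOOCV holds out each participant in turn, trains on the rest
  (id-disjointness asserted), and summarizes each fold over repeated
  trainings; the grand mean is the subject-level generalization
  estimate. With strong subject offsets (subject_sd 1.5) LOOCV
  collapses toward chance while pooled accuracy stays above 0.8 -
  the generalization-gap pattern.
- The high/low score task labels, per participant and task, the
  sessions with the highest and lowest correct-answer rate; rate ties
  break by mean response time (shortest -> high, longest -> low), then
  by session order (flagged). Windows from non-selected sessions are
  excluded.

Simulation scale: evaluations in the test suite and the acceptance
script train for 100 epochs (loss and accuracy plateau well before
that for this model and data size) with 10 pooled repeats and 3 LOOCV
repeats per fold.

## Exact statistics

Signed-rank: differences are ranked by |d| with midranks for ties after
dropping zeros (Wilcoxon's convention; Pratt's signed-zero variant is
available). W+ is the rank sum of positive differences; the two-sided p
is P(min(W+, W-) <= observed min) over all 2^n sign assignments,
conditional on the observed ranks. Rank-sum: the exact distribution of
the first group's midrank sum over all C(n+m, n) assignments, with both
tails at least as far from the null mean as observed. Summing both
tails (rather than doubling one) stays correct when ties skew the
distribution. The distributions are built by a generating-function
recursion over doubled (integer) midranks - algebraically the same
enumeration at polynomial cost; tests compare it against literal
itertools enumeration. Enumeration is refused beyond n = 25 (paired)
or n + m = 22 (independent). No multiple-comparison correction is
applied anywhere, by design.

A convention note: on the bundled behavioral table, the 3-back
trial-level morning/afternoon comparison gives p = 0.2617 under this
procedure. Classical no-ties tables evaluated at the truncated
statistic give 0.25, and participant-mean pairing gives different
values again (the 2-back comparison only reproduces its published
p = 0.13 at participant level, 0.125). The package defaults to
trial-level pairing and midrank-exact enumeration and reports whatever
that computes; the alternatives are one argument away.

## Bundled reference tables

`study_tables.py` carries the five-participant behavioral score table
(40 scores with the printed high/low markings) and the group-mean
relative powers per task and time of day. Mean response times were not
published; the bundled `rt_ms` values are synthetic, constructed only
to be consistent with the printed markings under the selection rule
(three cells genuinely need the RT tiebreak). One low-score cell
(participant 4, 3-back, tied at 65%) is not decidable from rates alone
and follows the synthetic RTs.

## Known limitations

- The published classification accuracies cannot be reproduced: the
  original recordings are unreleased. Simulations reproduce the
  qualitative structure (effect detectability, representation ordering,
  LOOCV collapse), not the printed percentages.
- The pooled protocol's window-level leakage (above) means its numbers
  measure within-recording decodability, not deployment accuracy.
- FastICA on synthetic Gaussian mixtures usually reduces to a no-op;
  the ICA path is exercised meaningfully only on data with
  non-Gaussian artifact components.
- The OpenBCI reader targets the GUI v5/v6 TXT dialect; other export
  formats (EDF/BDF, BrainVision) are out of scope.
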