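# nbackeeg

Can scalp EEG recorded during a working-memory task tell *when* the task
was performed, and *how well*? `nbackeeg` is a reusable Python
implementation of an analysis chain for that question, built around a
five-participant pilot design: 8-channel EEG (Fp1, Fp2, C3, C4, T5, T6,
O1, O2 in the 10-20 system, 250 Hz, OpenBCI-style TXT exports) recorded
while participants answered 20-question 2-back and 3-back sessions in
the morning (8-9 a.m.) and afternoon (3-4 p.m.).

It is a library first: the importable API plus the short scripts in
`examples/` are the interface. It targets researchers who want to
re-run, stress-test, or extend this kind of small-N EEG classification
study - including on simulated data, since the original recordings are
not publicly released.

## What it computes

**Features.** Signals are conditioned (per-channel z-scoring, 2-50 Hz
zero-phase Butterworth band-pass, ICA-based blink handling with
automated excision of residual frontal artifacts), then summarized per
1-s window (250 samples) in two 8x6 representations:

- *relative power*: FFT band powers over delta (2-4), theta (4-8),
  alpha (8-12), beta1 (12-15), beta2 (15-30) and gamma (30-50 Hz),
  normalized per channel so that rel_b = P_b / sum_k P_k;
- *compacted waveform*: the window split into 10 blocks of 25 samples,
  each block into six segments of (4,4,4,4,4,5) samples, segment means
  averaged across blocks.

Windows slide at 0.1-s steps from 3 to 15 s after task onset (111 per
clean recording).

**Classifier.** A channel-wise convolutional network: a kernel-1 1-D
convolution with 128 filters mixes the 8 channel values at each of the
6 feature positions, followed by ReLU, a 32-unit dense layer, and a
2-class softmax - 25,826 trainable parameters, trained with Adam on
cross-entropy. Accuracy is (TP + TN) / (TP + TN + FP + FN). Evaluation
is both *pooled* (ten repeated 70:30 window-level splits, mean +/- SEM)
and *leave-one-participant-out* (train on all other subjects, test on
the held-out one). The pooled protocol deliberately mirrors the pilot
design, including its optimism: overlapping windows from one recording
can land in both train and test.

**Statistics.** Because n is small, behavioral and band-power
comparisons use exact Wilcoxon signed-rank and rank-sum tests: p-values
come from full enumeration of the permutation null (midranks for ties,
both tails summed), not normal approximations.

**Synthetic studies.** A generator produces band-structured EEG with
per-channel target band fractions per condition, per-participant
logit-scale offsets, frontal blink artifacts, and 20-trial behavioral
tables - so the entire chain is testable end to end and study-level
properties (effect detectability, null behavior, subject-level
generalization) can be measured by simulation.

## Worked example

`examples/03_behavioral_statistics.py` scores the bundled behavioral
table (five participants, both tasks, two sessions per time of day):

```
correct-answer rate, mean +/- SEM over the 10 trial-level scores:
  2-back am: 80.0 +/- 3.0 %
  2-back pm: 88.5 +/- 1.8 %
  3-back am: 68.0 +/- 3.8 %
  3-back pm: 74.0 +/- 4.1 %
3-back a.m. vs p.m.: W+ = 12.5, exact two-sided p = 0.2617 (n = 9 non-zero pairs)
high/low selection: 10 participant x task cells, 3 needed the response-time tiebreak
```

Performance differs only modestly between morning and afternoon - the
exact test finds no significant difference - which is what makes the
EEG route interesting. `examples/04_train_time_of_day_classifier.py`
then simulates a study whose morning/afternoon band structure follows
the published group means (e.g. T6 theta 24.1% a.m. vs 35.4% p.m.) and
trains the CNN on relative-power windows:

```
2068 windows from 20 recordings (111 per recording minus artifact-excised windows)
model: 25826 trainable parameters
pooled 70:30 split, 10 repeats: train 93.0 +/- 0.3 %, test 87.9 +/- 0.5 %
```

The time of day is decodable from single 1-s windows well above chance.
`examples/05_generalization_gap.py` adds strong inter-participant
variability and contrasts the pooled number (82.6%) with
leave-one-participant-out accuracy (63.1% grand mean, with individual
subjects at chance) - the gap measures how much of what the network
learned is subject-specific rather than portable.

## Layout

- `src/nbackeeg/core.py` - montage, band definitions, recording container
- `src/nbackeeg/synthetic.py` - band-structured EEG and behavior generator
- `src/nbackeeg/io_formats.py` - OpenBCI TXT dialect, manifests, YAML config
- `src/nbackeeg/preprocess.py` - normalize, band-pass, ICA/excision
- `src/nbackeeg/features.py` - band powers, compaction, sliding windows
- `src/nbackeeg/classifier.py` - the channel-wise CNN (numpy)
- `src/nbackeeg/evaluation.py` - pooled and LOOCV evaluation, pipeline
- `src/nbackeeg/behavior.py` - session scoring, high/low selection
- `src/nbackeeg/exact_stats.py` - exact Wilcoxon tests
- `src/nbackeeg/study_tables.py` - bundled reference tables
- `docs/methods.md` - model, assumptions, and design choices
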