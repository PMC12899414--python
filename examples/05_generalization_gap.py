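"""Pooled vs leave-one-participant-out accuracy.

When participants differ strongly in their individual band structure,
a window-level pooled split still scores high (it sees every subject
during training, and overlapping windows leak between train and test),
while leave-one-participant-out evaluation - the honest test of
subject-level generalization - collapses toward chance.
"""

from nbackeeg import CNNConfig, StudySpec, generate_study, table2_condition_specs
from nbackeeg.evaluation import loocv_eval, pooled_eval
from nbackeeg.features import build_dataset
from nbackeeg.preprocess import preprocess_chain

am, pm = table2_condition_specs(task_n=2)
study = generate_study(am, pm, StudySpec(seed=0, subject_sd=1.5), task_n=2)
examples = build_dataset(
    [preprocess_chain(r) for r in study.recordings], "relative_power"
)

cfg = CNNConfig(epochs=100)
pooled = pooled_eval(examples, cfg, n_repeats=10, seed=1)
loocv = loocv_eval(examples, cfg, seed=1, n_repeats=3)

print(f"pooled 70:30 test accuracy: {100 * pooled.test_mean:.1f} %")
print(f"LOOCV accuracy by held-out participant:")
for pid, (mean, sem) in loocv.per_participant.items():
    print(f"  {pid}: {100 * mean:.1f} +/- {100 * sem:.1f} %")
print(f"LOOCV grand mean: {100 * loocv.grand_mean:.1f} %")
# The gap between the two numbers is the subject-specific share of what
# the network learned: a model intended for unseen users must be judged
# by the LOOCV number, not the pooled one.
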