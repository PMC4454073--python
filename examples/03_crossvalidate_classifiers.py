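"""Compare the SVM and profile-HMM classifiers by cross-validation.

Runs stratified 5-fold cross-validation of both classifiers on a small
synthetic benchmark and prints per-fold and mean metrics (accuracy and
the percent-better-than-random score S).

Uses a reduced benchmark (n=15 per family) so it finishes in well under
a minute; the full shipped benchmark (n=60) is what the acceptance
script evaluates.

Run:  python examples/03_crossvalidate_classifiers.py
"""

from ampyscan.metrics import HMMTrainer, SVMTrainer, crossvalidate
from ampyscan.synth import default_benchmark

dataset = default_benchmark(seed=1, n=15)
labels = [dataset.labels[r.id] for r in dataset.records]
print(f"{len(dataset.records)} sequences in {len(set(labels))} families\n")

for name, trainer in (
    ("hybrid k-mer SVM", SVMTrainer(ks=(1, 2, 4), C=0.01)),
    ("profile HMM", HMMTrainer(seed=1)),
):
    result = crossvalidate(dataset.records, labels, trainer, folds=5, seed=1)
    print(f"{name}:")
    for report in result.fold_reports:
        print(f"  fold {report.fold}: accuracy {100 * report.overall_acc:6.2f}%"
              f"  S {report.s_score:6.1f}  macro-MCC {report.macro.mcc:.3f}")
    print(f"  mean: accuracy {100 * result.mean_accuracy:.2f}%  "
          f"S {result.mean_s:.1f}\n")
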