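"""Train the bag-of-features tern-vs-foam classifier and evaluate it.

Builds a visual vocabulary from dense gradient-orientation descriptors on
labelled synthetic chips, trains a linear SVM on the occurrence histograms,
and prints the per-class and macro validation accuracy — the figure of merit
for separating birds from drifting foam before tracking.
"""

from wakewatch.bof_classifier import (DescriptorSpec, build_vocabulary,
                                      compute_descriptors, encode,
                                      encode_chips, evaluate, train_classifier)
from wakewatch.synthetic_data import generate_chip_dataset

train_chips, train_labels = generate_chip_dataset(200, seed=1)
val_chips, val_labels = generate_chip_dataset(200, seed=2)

spec = DescriptorSpec()
descriptors = [compute_descriptors(c, spec) for c in train_chips]
vocab = build_vocabulary(descriptors, k=100, seed=1)
model = train_classifier([encode(d, vocab) for d in descriptors],
                         train_labels, vocab, seed=1)

report = evaluate(model, encode_chips(val_chips, vocab), val_labels)
print(f"validation chips: {report.n_validation}")
for cls, acc in report.per_class_accuracy.items():
    print(f"  {cls}: {acc:.1f}% correct")
print(f"macro average accuracy: {report.average_accuracy:.1f}%")
print("confusion (rows true foam/tern, cols predicted):")
print(report.confusion)
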