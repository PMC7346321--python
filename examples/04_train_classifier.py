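"""Train the EnDCNN CVD classifier on (mention, label) units.

Each extracted mention is packed into a unit of 7 cells (6 surface
characters + 1 label token); the region embedding with k=7 covers exactly
one unit. This example uses gold mentions and the reduced model (32
feature maps, 3 blocks) on the planted-rule task. Takes a couple of
minutes on one CPU.
"""

import numpy as np

from endcnn import (
    SynthConfig,
    build_vocab,
    classification_metrics,
    mentions_to_units,
    train_classifier,
    unit_vocabulary,
)
from endcnn.classifier import reduced_synthetic_config
from endcnn.synth import sample_documents

SEED = 13
docs = sample_documents(SynthConfig(seed=SEED), 700)
train, test = docs[:500], docs[500:]

uvocab = unit_vocabulary(build_vocab([d.sentence.chars for d in train]))
to_units = lambda d: mentions_to_units(list(d.mentions), uvocab)  # noqa: E731
ds_train = [(to_units(d), d.document.label) for d in train if d.mentions]
ds_test = [(to_units(d), d.document.label) for d in test if d.mentions]
print(f"train {len(ds_train)} docs, test {len(ds_test)} docs, "
      f"unit vocabulary {len(uvocab)} tokens")

model, losses = train_classifier(
    ds_train, reduced_synthetic_config(), vocab_size=len(uvocab), seed=SEED
)
print(f"mean cross-entropy: epoch 1 {losses[0]:.3f} -> final {losses[-1]:.3f}")

pred = [int(np.argmax(model.forward(u))) for u, _ in ds_test]
m = classification_metrics([label for _, label in ds_test], pred)
print(f"held-out: accuracy={m.accuracy:.4f} precision={m.precision:.4f} "
      f"recall={m.recall:.4f} F={m.f_score:.4f}")
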