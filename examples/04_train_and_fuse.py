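"""Train classifiers for two ECG channels, evaluate, and fuse their votes.

Uses a reduced benchmark dataset (4 subjects, 1600 one-second segments) so
the example finishes in about a minute on one CPU. Prints each modality's
confusion matrix in count + percent-of-test-set style with Total margins,
then the majority-vote fusion accuracy for the channel pair.
"""

import numpy as np

from emochart import pipeline, synthgen, trainer
from emochart.fusion import VoteTable, majority_vote

shape = synthgen.fixture_shape(n_subjects=4)  # 4 x 16 trials x 25 s = 1600 segments
sigs = synthgen.high_separability_signatures()
segs = pipeline.preprocess_dataset(shape, sigs, seed=1, modalities=("ECG_L", "ECG_R"))

cfg = trainer.TrainConfig(epochs=10, seed=1)
split = trainer.random_split(len(segs["ECG_L"]), cfg.split_fraction, cfg.seed)
print(f"{len(split[0])} training / {len(split[1])} test segments "
      f"(70/30 random split)\n")

results = {}
for m in ("ECG_L", "ECG_R"):
    results[m] = pipeline.train_modality(segs[m], cfg, split)
    print(f"{m}: test accuracy {results[m].accuracy_pct:.1f}% "
          f"(loss {results[m].loss_curve[0]:.2f} -> {results[m].loss_curve[-1]:.2f})")
    print(results[m].confusion.to_frame().to_string(), "\n")

targets = segs["ECG_L"].labels[split[1]]
table = VoteTable(
    votes={m: r.predictions["predicted"].to_numpy() for m, r in results.items()},
    probs={m: r.predictions[[f"p_{q}" for q in trainer.QUADRANTS]].to_numpy()
           for m, r in results.items()},
    targets=targets,
)
fused, acc = majority_vote(table)
print(f"majority-vote fusion (ECG_L + ECG_R): {100 * acc:.1f}% "
      f"(ties broken by summed softmax confidence)")
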