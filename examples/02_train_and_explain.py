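"""Train a small classifier and visualize what it looks at.

Trains the tiny CNN with plain cross-entropy on the fake-vs-real task, then
computes a Grad-CAM heatmap for one test image.  The heatmap is an
input-sized nonnegative map; larger values mark pixels that push the
pre-softmax score of the chosen class up.
"""

import numpy as np

from xleaf import (LossSpec, NetworkSpec, SceneConfig, TrainConfig,
                   build_dataset, build_network, evaluate_accuracy,
                   gradcam_explain, train)

cfg = SceneConfig(image_size=(64, 64))
ds = build_dataset("fake_vs_real", cfg, n_samples=500, seed=1)
spec = NetworkSpec(variant="tiny", n_classes=2, input_size=(64, 64, 3))

model = build_network(spec, seed=1)
model, history = train(model, ds, LossSpec(lambda_weight=0.0),
                       TrainConfig(epochs=15, seed=1))
print(f"train loss {history[0]['closs']:.3f} -> {history[-1]['closs']:.3f}; "
      f"test accuracy {evaluate_accuracy(model, ds, 'test'):.2f}")

i = next(j for j in ds.splits["test"] if ds.samples[j].label == 1)
sample = ds.samples[i]
e = gradcam_explain(model, sample.image, c=sample.label)
r, c = np.unravel_index(e.heatmap.argmax(), e.heatmap.shape)
inside = sample.assessment[r, c] == 1
print(f"sample label {ds.class_names[sample.label]}: heatmap peak at "
      f"({r}, {c}), which is {'inside' if inside else 'outside'} the "
      f"ground-truth useful region; heatmap max {e.heatmap.max():.4f}")
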