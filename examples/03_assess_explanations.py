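"""Compare a baseline and a guided model on accuracy and explanation quality.

Runs the full four-step framework on the fake-vs-real task: train a baseline,
retrain from the same initialization with the balanced right-reasons loss
(annotation matrices mark the pixels outside the injected circles as useless),
and assess both with RMSE, cosine similarity and PIP against the circle
regions.  Lower RMSE and higher CosineS / PIP mean the heatmaps sit closer to
the pixels that truly decide the class.
"""

from xleaf import ExperimentConfig, SceneConfig, run_framework

cfg = ExperimentConfig(task="fake_vs_real",
                       scene=SceneConfig(image_size=(64, 64)),
                       n_samples=300, epochs=10, seed=3)
report = run_framework(cfg)

print(report.to_frame().to_string(index=False))
print("\ndeltas (rrr - baseline):")
for k, v in report.deltas().items():
    print(f"  {k:>14}: {v:+.4f}")
print("\naccuracy is in percent; rmse/cosines in [0,1]; pip columns are the "
      "percentage of top-k% heatmap pixels falling inside the reference mask."
      "\nNote: at this miniature scale, penalizing the broad outside-circle "
      "region usually costs the small model accuracy and heatmap alignment; "
      "see docs/methods.md for when guidance helps (narrow spurious regions, "
      "as in example 04) and when it does not")
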