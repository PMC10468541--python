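"""Grad-CAM saliency for a degraded photograph.

Trains a quick model, then renders where the network looks when it predicts
each defect explanation for one blurry, badly lit image — the panel mirrors
how attention maps are presented next to the original photograph.
"""

from pathlib import Path

from dermaqx import (
    EXPLANATIONS,
    ModelConfig,
    QUALITY_CLASSES,
    build_model,
    compute_class_weights,
    generate_dataset,
    grad_cam,
    render_panel,
    split_dataset,
    train,
)
from dermaqx.synthgen import DegradationSpec, SceneSpec, apply_degradation, generate_base_image
from dermaqx.train_eval import TrainConfig

records = generate_dataset({c: 80 for c in QUALITY_CLASSES},
                           {e: 0.35 for e in EXPLANATIONS}, seed=0)
train_set, val_set = split_dataset(records, 0.25, seed=0)
weights = compute_class_weights(
    {c: n for c, n in train_set.class_counts().items() if n > 0})
model = build_model(ModelConfig(input_size=64), seed=0)
train(model, train_set, val_set, weights, TrainConfig(epochs=10, lr=1e-3, seed=0))

# one fresh test image: a centred lesion, then blurred and over-exposed
scene = SceneSpec("lesion", (64, 64), lesion_center=(32.0, 32.0),
                  lesion_radii=(12.0, 9.0))
rec, truth = generate_base_image(scene, seed=123)
rec, truth = apply_degradation(
    rec, truth,
    [DegradationSpec("blurry", 0.8), DegradationSpec("bad_light", 0.7)],
    seed=123)
print("ground truth:", truth.quality_class, truth.explanation_tags())

targets = ["bad_light", "blurry", "low_resolution"]
maps = [grad_cam(model, rec.pixels, t) for t in targets]
out = Path("scratch/gradcam_panel.png")
out.parent.mkdir(parents=True, exist_ok=True)
render_panel(rec.pixels, maps, out)
for m in maps:
    print(f"{m.target_output:<16} peak saliency at {m.max_activation()}"
          f"{'  (all-zero map)' if m.is_empty else ''}")
print(f"wrote {out} (original + one overlay per target)")
# Each overlay highlights the pixels that drove that explanation's score;
# the peak coordinate is what the JSON sidecar of the CLI reports.
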