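"""Train the quality/explanation network on synthetic data and score it.

A deliberately small run (400 images, 10 epochs) so it finishes in well
under a minute on a laptop CPU; the full-scale recovery study (2,000 images,
20 epochs) lives in `dermaqx.train_eval.synthetic_recovery_experiment`.
"""

from dermaqx import (
    EXPLANATIONS,
    ModelConfig,
    QUALITY_CLASSES,
    build_model,
    compute_class_weights,
    evaluate,
    generate_dataset,
    split_dataset,
    train,
)
from dermaqx.train_eval import TrainConfig

records = generate_dataset({c: 100 for c in QUALITY_CLASSES},
                           {e: 0.35 for e in EXPLANATIONS}, seed=0)
train_set, val_set = split_dataset(records, val_fraction=0.25, seed=0)
weights = compute_class_weights(
    {c: n for c, n in train_set.class_counts().items() if n > 0})

model = build_model(ModelConfig(backbone="tiny_cnn", input_size=64), seed=0)
summary = train(model, train_set, val_set, weights,
                TrainConfig(epochs=10, lr=1e-3, seed=0))

print(f"loss: {summary.loss_trajectory[0].total:.3f} (epoch 1) -> "
      f"{summary.loss_trajectory[-1].total:.3f} (epoch {len(summary.loss_trajectory)})")
report = evaluate(model, val_set)
print("\nimage quality (held-out):")
print(report.quality.to_table())
print("\npoor-quality explanations (held-out):")
print(report.explanations.to_table())
print(f"\nflagged for retake: {report.retake_count}/{report.n_images}")
# The quality table mirrors the CLASS / SENSITIVITY / SPECIFICITY / F1-SCORE
# layout used to report this kind of model; "flagged for retake" counts
# held-out images the model would bounce back (predicted poor quality or
# no skin) before they ever reach a dermatologist.
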