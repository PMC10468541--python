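"""Generate a small labelled synthetic dataset and inspect its ground truth.

Renders 40 skin-like photographs (10 per quality class), applies strong
degradations to the poor-quality ones, and prints the class balance and the
per-explanation prevalence. The manifest written alongside the PNGs allows
bit-exact regeneration.
"""

from collections import Counter
from pathlib import Path

from dermaqx import EXPLANATIONS, QUALITY_CLASSES, generate_dataset
from dermaqx.synthgen import write_images, write_manifest

out_dir = Path("scratch/example_dataset")
records = generate_dataset(
    counts={c: 10 for c in QUALITY_CLASSES},
    degradation_mix={e: 0.35 for e in EXPLANATIONS},
    seed=0,
    image_size=(64, 64),
    severity_range=(0.6, 1.0),
)
write_images(records, out_dir / "images")
write_manifest(records, out_dir / "manifest.jsonl")

classes = Counter(truth.quality_class for _, truth in records)
print("class balance:", dict(classes))
tags = Counter(tag for _, t in records for tag in t.explanation_tags())
print("explanation prevalence among poor-quality images:")
for e in EXPLANATIONS:
    print(f"  {e:<16} {tags.get(e, 0):>2} / {classes['poor_quality']}")
print(f"wrote images + manifest under {out_dir}/")
# Each poor-quality image carries >= 1 defect tag; the counts above show how
# often each degradation operator was sampled at probability 0.35 each.
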