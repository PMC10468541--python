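"""Label taxonomy for teledermatological image-quality triage.

Every photograph receives one of four quality verdicts. Images judged
undiagnosable (``poor_quality``) additionally carry one or more of five
defect explanations describing *why* the photo cannot be assessed.
"""

from __future__ import annotations

import re

#: Four-way quality verdict, in canonical order (most to least frequent in
#: a typical teledermatology stream is lesion >> poor_quality > healthy_skin
#: > no_skin, but the order here is fixed for reporting, not by frequency).
QUALITY_CLASSES: tuple[str, ...] = (
    "lesion",
    "no_skin",
    "healthy_skin",
    "poor_quality",
)

#: Five poor-quality explanations, in canonical order.
EXPLANATIONS: tuple[str, ...] = (
    "bad_framing",
    "bad_light",
    "blurry",
    "low_resolution",
    "too_far_away",
)

#: The three verdict tokens an annotator may emit besides an ICD-10 code.
NON_LESION_LABELS: frozenset[str] = frozenset(
    {"poor_quality", "healthy_skin", "no_skin"}
)

#: Tie-break priority for plurality fusion: when vote counts tie, prefer the
#: verdict that withholds the image from diagnosis (conservative triage).
TIEBREAK_PRIORITY: tuple[str, ...] = (
    "poor_quality",
    "no_skin",
    "healthy_skin",
    "lesion",
)

# Syntactic shape of an ICD-10 code: a letter, two digits, optional
# dotted extension (e.g. "L20.9", "Z99", "C43.9").
ICD10_PATTERN = re.compile(r"^[A-Z][0-9]{2}(?:\.[0-9A-Z]{1,4})?$")

#: Placeholder ICD-10 codes emitted by the rater simulator for lesion
#: verdicts; their only role is to exercise the collapse-to-lesion rule.
PLACEHOLDER_ICD10_CODES: tuple[str, ...] = (
    "L20.9",  # atopic dermatitis, unspecified
    "L30.9",  # dermatitis, unspecified
    "L70.0",  # acne vulgaris
    "B07",    # viral warts
    "D22.9",  # melanocytic naevus, unspecified
    "C43.9",  # malignant melanoma, unspecified
)

CLASS_INDEX: dict[str, int] = {c: i for i, c in enumerate(QUALITY_CLASSES)}
EXPLANATION_INDEX: dict[str, int] = {e: i for i, e in enumerate(EXPLANATIONS)}
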