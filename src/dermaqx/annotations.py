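"""Multi-rater annotation parsing and reference-standard construction.

Annotators either diagnose a photograph with an ICD-10 code or discard it
with one of three non-lesion verdicts (``poor_quality``, ``healthy_skin``,
``no_skin``); poor-quality verdicts carry defect explanation tags. The
reference standard per image is built by

* collapsing every ICD-10 code to the ``lesion`` class,
* plurality fusion of the collapsed verdicts (fixed tie-break priority
  ``poor_quality > no_skin > healthy_skin > lesion``), and
* union fusion of explanations: a defect tag is in the reference standard
  if at least one rater discarded the image with that tag.

Class weights for imbalance-aware training are inverse-frequency weights
``w_c = min(n_max / n_c, clip)`` computed from the training split only.
"""

from __future__ import annotations

import json
from collections import Counter
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .taxonomy import (
    EXPLANATION_INDEX,
    EXPLANATIONS,
    ICD10_PATTERN,
    NON_LESION_LABELS,
    QUALITY_CLASSES,
    TIEBREAK_PRIORITY,
)

__all__ = [
    "RaterEvaluation",
    "FusedLabel",
    "ClassWeights",
    "ReferenceStandard",
    "VerdictParseError",
    "DuplicateEvaluationError",
    "collapse_verdict",
    "fuse_quality",
    "fuse_explanations",
    "compute_class_weights",
    "build_reference_standard",
    "label_distribution_table",
    "read_evaluations",
    "write_evaluations",
    "write_fused_labels",
]


class VerdictParseError(ValueError):
    """A verdict token is neither a plausible ICD-10 code nor a known label."""


class DuplicateEvaluationError(ValueError):
    """The same rater evaluated the same image more than once."""


@dataclass(frozen=True)
class RaterEvaluation:
    """One annotator's verdict on one image."""

    rater_id: str
    image_id: str
    verdict: str
    explanations: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "explanations", tuple(self.explanations))
        for e in self.explanations:
            if e not in EXPLANATIONS:
                raise VerdictParseError(
                    f"unknown explanation tag {e!r} "
                    f"(rater={self.rater_id}, image={self.image_id})"
                )
        if self.explanations and self.verdict != "poor_quality":
            raise VerdictParseError(
                "explanations are only valid with a poor_quality verdict "
                f"(rater={self.rater_id}, image={self.image_id}, "
                f"verdict={self.verdict!r})"
            )

    def explanation_bits(self) -> np.ndarray:
        bits = np.zeros(len(EXPLANATIONS), dtype=np.int8)
        for e in self.explanations:
            bits[EXPLANATION_INDEX[e]] = 1
        return bits


@dataclass
class FusedLabel:
    """Reference-standard label for one image."""

    image_id: str
    quality_class: str
    explanations: np.ndarray  # (5,) int8
    vote_counts: dict[str, int]
    n_raters: int

    def to_dict(self) -> dict:
        return {
            "image_id": self.image_id,
            "quality_class": self.quality_class,
            "explanations": [int(b) for b in self.explanations],
            "vote_counts": dict(self.vote_counts),
            "n_raters": self.n_raters,
        }


@dataclass
class ClassWeights:
    """Inverse-frequency class weights, clipped, modal class pinned at 1."""

    weights: dict[str, float]
    clip: float
    counts: dict[str, int]

    def as_array(self, classes: Sequence[str] = QUALITY_CLASSES) -> np.ndarray:
        """Weights in the given class order; classes absent from the counts
        (never seen in training) default to 1.0."""
        return np.array([self.weights.get(c, 1.0) for c in classes],
                        dtype=np.float64)

    def rounded(self, ndigits: int = 2) -> dict[str, float]:
        """Display rounding; internal arithmetic stays full precision."""
        return {c: round(w, ndigits) for c, w in self.weights.items()}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"weights": self.weights, "clip": self.clip, "counts": self.counts},
            indent=2))


def collapse_verdict(verdict: str) -> str:
    """Map a raw verdict to one of the four quality classes.

    Any syntactically plausible ICD-10 code (letter + two digits, optional
    dotted extension) collapses to ``lesion``; the three non-lesion labels
    map to themselves; anything else raises :class:`VerdictParseError`.
    """
    if verdict in NON_LESION_LABELS:
        return verdict
    if ICD10_PATTERN.match(verdict):
        return "lesion"
    raise VerdictParseError(
        f"verdict {verdict!r} is neither an ICD-10 code nor one of "
        f"{sorted(NON_LESION_LABELS)}"
    )


def fuse_quality(evals: Sequence[RaterEvaluation]) -> FusedLabel:
    """Plurality fusion of one image's verdicts.

    The fused class is the collapsed verdict chosen by the most raters; ties
    are broken by the fixed priority ``poor_quality > no_skin >
    healthy_skin > lesion`` (prefer withholding a contested image from
    diagnosis).
    """
    if not evals:
        raise ValueError("fuse_quality requires at least one evaluation")
    image_id = evals[0].image_id
    votes = Counter(collapse_verdict(e.verdict) for e in evals)
    top = max(votes.values())
    winner = next(c for c in TIEBREAK_PRIORITY if votes.get(c, 0) == top)
    return FusedLabel(
        image_id=image_id,
        quality_class=winner,
        explanations=fuse_explanations(evals),
        vote_counts={c: votes.get(c, 0) for c in QUALITY_CLASSES},
        n_raters=len(evals),
    )


def fuse_explanations(evals: Sequence[RaterEvaluation]) -> np.ndarray:
    """Union fusion: bit e is set iff some rater discarded the image as
    poor quality with explanation e. Independent of the fused class."""
    if not evals:
        raise ValueError("fuse_explanations requires at least one evaluation")
    bits = np.zeros(len(EXPLANATIONS), dtype=np.int8)
    for e in evals:
        if e.verdict == "poor_quality":
            bits |= e.explanation_bits()
    return bits


def compute_class_weights(train_counts: Mapping[str, int],
                          clip: float = 10.0) -> ClassWeights:
    """Inverse-frequency weights ``w_c = min(n_max / n_c, clip)``.

    ``n_max`` is the largest class count, so the most frequent class always
    receives weight exactly 1.0. Counts must all be positive (a zero count
    leaves the weight undefined) and are taken from the training split only.
    """
    if clip <= 0:
        raise ValueError("clip must be positive")
    counts = {c: int(n) for c, n in train_counts.items()}
    if not counts:
        raise ValueError("train_counts must be non-empty")
    for c, n in counts.items():
        if n <= 0:
            raise ValueError(f"class {c!r} has count {n}; weights require > 0")
    n_max = max(counts.values())
    weights = {c: min(n_max / n, float(clip)) for c, n in counts.items()}
    return ClassWeights(weights=weights, clip=float(clip), counts=counts)


@dataclass
class ReferenceStandard:
    """Fused labels plus the count tables needed for weighting/reporting."""

    labels: list[FusedLabel]
    class_counts: dict[str, int]
    explanation_counts: dict[str, int]

    def by_image(self) -> dict[str, FusedLabel]:
        return {l.image_id: l for l in self.labels}


def build_reference_standard(
    all_evals: Iterable[RaterEvaluation],
) -> ReferenceStandard:
    """Fuse every image's panel; error on duplicate (rater, image) pairs.

    Explanation counts use the union rule per image and are tallied over all
    images regardless of the fused class (the union rule is unconditional;
    training decides how bits on non-poor images are used).
    """
    by_image: dict[str, list[RaterEvaluation]] = {}
    seen: set[tuple[str, str]] = set()
    for ev in all_evals:
        key = (ev.rater_id, ev.image_id)
        if key in seen:
            raise DuplicateEvaluationError(
                f"rater {ev.rater_id!r} evaluated image {ev.image_id!r} twice"
            )
        seen.add(key)
        by_image.setdefault(ev.image_id, []).append(ev)

    labels = [fuse_quality(evs) for evs in by_image.values()]
    class_counts = Counter(l.quality_class for l in labels)
    expl_counts: Counter = Counter()
    for l in labels:
        for e, b in zip(EXPLANATIONS, l.explanations):
            if b:
                expl_counts[e] += 1
    return ReferenceStandard(
        labels=labels,
        class_counts={c: class_counts.get(c, 0) for c in QUALITY_CLASSES},
        explanation_counts={e: expl_counts.get(e, 0) for e in EXPLANATIONS},
    )


def label_distribution_table(train_counts: Mapping[str, int],
                             test_counts: Mapping[str, int],
                             order: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-class count table with ``total`` and ``mean`` summary rows.

    Mirrors the standard dataset-distribution table of a labelling campaign:
    one row per class, a column per split, plus the column sums and the
    arithmetic mean over classes.
    """
    order = list(order) if order is not None else [
        c for c in QUALITY_CLASSES if c in train_counts or c in test_counts
    ]
    df = pd.DataFrame(
        {"train": [train_counts.get(c, 0) for c in order],
         "test": [test_counts.get(c, 0) for c in order]},
        index=order, dtype=float,
    )
    body = df.copy()
    df.loc["total"] = body.sum()
    df.loc["mean"] = body.mean()
    df["all"] = df["train"] + df["test"]
    return df


# --------------------------------------------------------------------------
# IO: evaluations as JSONL or CSV, fused labels as JSONL


def _eval_from_row(rater_id, image_id, verdict, explanations) -> RaterEvaluation:
    if isinstance(explanations, str):
        tags = tuple(t for t in explanations.split(";") if t)
    elif explanations is None or (isinstance(explanations, float) and pd.isna(explanations)):
        tags = ()
    else:
        tags = tuple(explanations)
    return RaterEvaluation(str(rater_id), str(image_id), str(verdict), tags)


def read_evaluations(path: str | Path) -> list[RaterEvaluation]:
    """Read evaluation records from JSONL (one object per line) or CSV
    (columns rater_id, image_id, verdict, explanations as ';'-joined tags);
    the format is chosen by file extension."""
    path = Path(path)
    out: list[RaterEvaluation] = []
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        for row in df.itertuples(index=False):
            out.append(_eval_from_row(row.rater_id, row.image_id, row.verdict,
                                      getattr(row, "explanations", "")))
    else:
        with path.open() as fh:
            for line in fh:
                if not line.strip():
                    continue
                d = json.loads(line)
                out.append(_eval_from_row(d["rater_id"], d["image_id"],
                                          d["verdict"], d.get("explanations", ())))
    return out


def write_evaluations(evals: Sequence[RaterEvaluation], path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        pd.DataFrame(
            {"rater_id": [e.rater_id for e in evals],
             "image_id": [e.image_id for e in evals],
             "verdict": [e.verdict for e in evals],
             "explanations": [";".join(e.explanations) for e in evals]}
        ).to_csv(path, index=False)
    else:
        with path.open("w") as fh:
            for e in evals:
                fh.write(json.dumps(
                    {"rater_id": e.rater_id, "image_id": e.image_id,
                     "verdict": e.verdict,
                     "explanations": list(e.explanations)}) + "\n")


def write_fused_labels(labels: Sequence[FusedLabel], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for l in labels:
            fh.write(json.dumps(l.to_dict()) + "\n")
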