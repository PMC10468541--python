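"""Evaluation statistics: per-class sensitivity/specificity/F1, macro means,
and pairwise inter-rater F1.

All metrics are one-vs-rest. Degenerate 0/0 ratios (no positives in either
prediction or reference) return 0.0 by convention and are flagged in the
report rather than propagating NaN.

Pairwise inter-rater F1 treats, for each unordered pair of raters, one
rater as the reference standard and the other as the prediction on the
images both rated; F1 is symmetric under swapping false positives and false
negatives, so the orientation of the pair is irrelevant. The mean and
standard deviation are taken over pairs.
"""

from __future__ import annotations

import itertools
import json
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .annotations import RaterEvaluation, collapse_verdict
from .taxonomy import EXPLANATIONS, QUALITY_CLASSES

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion_counts",
    "sensitivity",
    "specificity",
    "f1",
    "macro_f1",
    "classification_report",
    "pairwise_interrater_f1",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest confusion counts for a single positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_counts(pred: Sequence, ref: Sequence, positive_class) -> ConfusionCounts:
    """Count TP/FP/FN/TN for ``positive_class``; ``pred`` and ``ref`` must be
    aligned item-for-item."""
    if len(pred) != len(ref):
        raise ValueError(f"length mismatch: {len(pred)} predictions vs {len(ref)} references")
    if len(ref) == 0:
        raise ValueError("confusion_counts requires at least one item")
    p = np.asarray([x == positive_class for x in pred])
    r = np.asarray([x == positive_class for x in ref])
    return ConfusionCounts(
        tp=int(np.sum(p & r)),
        fp=int(np.sum(p & ~r)),
        fn=int(np.sum(~p & r)),
        tn=int(np.sum(~p & ~r)),
    )


def sensitivity(c: ConfusionCounts) -> float:
    """TP / (TP + FN); 0.0 when the class never occurs in the reference."""
    d = c.tp + c.fn
    return c.tp / d if d else 0.0


def specificity(c: ConfusionCounts) -> float:
    """TN / (TN + FP); 0.0 when the class covers the whole reference."""
    d = c.tn + c.fp
    return c.tn / d if d else 0.0


def f1(c: ConfusionCounts) -> float:
    """2TP / (2TP + FP + FN); 0.0 when the class is absent from both sides."""
    d = 2 * c.tp + c.fp + c.fn
    return 2 * c.tp / d if d else 0.0


def macro_f1(per_class_f1: Mapping) -> float:
    """Unweighted arithmetic mean of per-class F1 scores."""
    if not per_class_f1:
        raise ValueError("macro_f1 requires at least one class")
    return float(np.mean(list(per_class_f1.values())))


_METRIC_KEYS = ("sensitivity", "specificity", "f1")


@dataclass
class MetricsReport:
    """Per-class and macro sensitivity/specificity/F1, with optional
    dispersion (std over training runs or rater pairs) per cell."""

    per_class: dict[str, dict[str, float]]
    macro: dict[str, float]
    dispersion: dict[str, dict[str, float]] | None = None
    notes: list[str] = field(default_factory=list)

    @classmethod
    def from_labels(cls, pred: Sequence, ref: Sequence,
                    classes: Sequence[str]) -> "MetricsReport":
        per_class: dict[str, dict[str, float]] = {}
        notes: list[str] = []
        for c in classes:
            cc = confusion_counts(pred, ref, c)
            per_class[c] = {"sensitivity": sensitivity(cc),
                            "specificity": specificity(cc),
                            "f1": f1(cc)}
            if cc.tp + cc.fn == 0:
                notes.append(f"class {c!r}: absent from reference (0/0 -> 0)")
        macro = {k: float(np.mean([v[k] for v in per_class.values()]))
                 for k in _METRIC_KEYS}
        return cls(per_class=per_class, macro=macro, notes=notes)

    @classmethod
    def aggregate(cls, reports: Sequence["MetricsReport"]) -> "MetricsReport":
        """Cell-wise mean +/- std (population) over several reports."""
        if not reports:
            raise ValueError("aggregate requires at least one report")
        classes = list(reports[0].per_class)
        per, disp = {}, {}
        for c in classes:
            per[c] = {k: float(np.mean([r.per_class[c][k] for r in reports]))
                      for k in _METRIC_KEYS}
            disp[c] = {k: float(np.std([r.per_class[c][k] for r in reports]))
                       for k in _METRIC_KEYS}
        macro = {k: float(np.mean([v[k] for v in per.values()])) for k in _METRIC_KEYS}
        disp["macro"] = {k: float(np.mean([disp[c][k] for c in classes]))
                         for k in _METRIC_KEYS}
        return cls(per_class=per, macro=macro, dispersion=disp)

    def to_dict(self) -> dict:
        d = {"per_class": self.per_class, "macro": self.macro}
        if self.dispersion is not None:
            d["dispersion"] = self.dispersion
        if self.notes:
            d["notes"] = self.notes
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def to_table(self) -> str:
        """Plain-text table: CLASS / SENSITIVITY / SPECIFICITY / F1-SCORE."""
        rows = [f"{'CLASS':<16}{'SENSITIVITY':>14}{'SPECIFICITY':>14}{'F1-SCORE':>12}"]

        def cell(c, k):
            v = (self.per_class.get(c, self.macro)[k] if c != "mean"
                 else self.macro[k])
            if self.dispersion is not None:
                key = "macro" if c == "mean" else c
                return f"{v:.2f} ± {self.dispersion[key][k]:.2f}"
            return f"{v:.2f}"

        for c in list(self.per_class) + ["mean"]:
            rows.append(f"{c:<16}{cell(c, 'sensitivity'):>14}"
                        f"{cell(c, 'specificity'):>14}{cell(c, 'f1'):>12}")
        return "\n".join(rows)


def classification_report(pred: Sequence[str], ref: Sequence[str],
                          classes: Sequence[str] = QUALITY_CLASSES) -> MetricsReport:
    return MetricsReport.from_labels(pred, ref, classes)


def pairwise_interrater_f1(
    evals: Sequence[RaterEvaluation],
    targets: str = "quality",
    min_overlap: int = 10,
) -> tuple[dict[str, tuple[float, float]], dict]:
    """Mean +/- std of per-class F1 over all unordered rater pairs.

    ``targets='quality'`` compares collapsed four-way verdicts;
    ``targets='explanations'`` compares the five defect bits (a rater's bits
    are all-zero unless their verdict was poor quality). Pairs sharing fewer
    than ``min_overlap`` images are excluded and reported in the info dict.
    """
    if targets not in ("quality", "explanations"):
        raise ValueError(f"unknown targets {targets!r}")
    by_rater: dict[str, dict[str, RaterEvaluation]] = {}
    for e in evals:
        by_rater.setdefault(e.rater_id, {})[e.image_id] = e

    if targets == "quality":
        names = list(QUALITY_CLASSES)

        def labels_for(e: RaterEvaluation, name: str) -> bool:
            return collapse_verdict(e.verdict) == name
    else:
        names = list(EXPLANATIONS)

        def labels_for(e: RaterEvaluation, name: str) -> bool:
            return e.verdict == "poor_quality" and name in e.explanations

    per_pair: dict[str, list[float]] = {n: [] for n in names}
    used, excluded = [], []
    for ra, rb in itertools.combinations(sorted(by_rater), 2):
        shared = sorted(set(by_rater[ra]) & set(by_rater[rb]))
        if len(shared) < min_overlap:
            excluded.append((ra, rb, len(shared)))
            continue
        used.append((ra, rb, len(shared)))
        for name in names:
            a = [labels_for(by_rater[ra][i], name) for i in shared]
            b = [labels_for(by_rater[rb][i], name) for i in shared]
            per_pair[name].append(f1(confusion_counts(b, a, True)))
    if not used:
        raise ValueError(
            f"no rater pair shares at least min_overlap={min_overlap} images"
        )
    result = {n: (float(np.mean(v)), float(np.std(v))) for n, v in per_pair.items()}
    info = {"pairs_used": used, "pairs_excluded": excluded}
    return result, info
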