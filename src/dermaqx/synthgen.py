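"""Synthetic skin-photograph generator with controllable quality degradations.

Real teledermatology photographs cannot be redistributed, so this module
renders procedural stand-ins with fully known ground truth: a skin-tone base
with low-frequency mottling and grain, an optional pigmented elliptical
lesion, or a clearly non-dermatological background texture. Five degradation
operators emulate the defects annotators tag in practice — bad framing, bad
lighting, blur, low resolution, and excessive camera distance — each driven
by a single severity in [0, 1] where severity 0 is the identity transform.

A companion rater simulator draws annotation panels (up to 12 raters per
image) from per-rater confusion matrices, so label-fusion and agreement
statistics can be exercised end to end without clinical data.
"""

from __future__ import annotations

import dataclasses
import json
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.transform import resize

from .annotations import RaterEvaluation
from .taxonomy import (
    EXPLANATION_INDEX,
    EXPLANATIONS,
    PLACEHOLDER_ICD10_CODES,
    QUALITY_CLASSES,
)

__all__ = [
    "SceneSpec",
    "DegradationSpec",
    "GroundTruth",
    "ImageRecord",
    "RaterProfile",
    "InvalidSceneError",
    "generate_base_image",
    "apply_degradation",
    "generate_dataset",
    "write_manifest",
    "regenerate_from_manifest",
    "write_images",
    "simulate_raters",
    "identity_profile",
    "symmetric_profile",
    "DEFAULT_DEGRADATION_MIX",
    "DEFAULT_DIAGNOSABILITY_THRESHOLD",
]


class InvalidSceneError(ValueError):
    """Scene geometry or degradation parameters violate a precondition."""


#: Severity above which an operator is considered to make the image
#: undiagnosable, i.e. the explanation bit enters the ground truth.
DEFAULT_DIAGNOSABILITY_THRESHOLD = 0.3

#: Default per-operator inclusion probabilities for poor-quality images.
#: Relative prevalences of the five defect tags in a large teledermatology
#: annotation campaign, normalised so one tag is expected per image before
#: conditioning on at least one being present.
DEFAULT_DEGRADATION_MIX: dict[str, float] = {
    "bad_framing": 0.111,
    "bad_light": 0.294,
    "blurry": 0.314,
    "low_resolution": 0.227,
    "too_far_away": 0.054,
}

# A few plausible skin tones (RGB, 8-bit) spanning light to dark.
_SKIN_TONES: tuple[tuple[int, int, int], ...] = (
    (234, 192, 168),
    (222, 171, 138),
    (198, 140, 105),
    (161, 102, 72),
    (120, 74, 52),
    (84, 51, 38),
)

_BASE_CLASSES = ("lesion", "healthy_skin", "no_skin")


@dataclass(frozen=True)
class SceneSpec:
    """Geometry and appearance of one synthetic photograph before degradation."""

    class_intent: str
    image_size: tuple[int, int] = (64, 64)
    skin_tone: tuple[int, int, int] = _SKIN_TONES[1]
    lesion_center: tuple[float, float] | None = None  # (row, col) pixels
    lesion_radii: tuple[float, float] | None = None   # (row, col) semi-axes
    texture_seed: int = 0
    frame_margin: float = 0.05  # ellipse must stay this fraction from edges

    def __post_init__(self):
        if self.class_intent not in _BASE_CLASSES:
            raise InvalidSceneError(
                f"class_intent must be one of {_BASE_CLASSES}, got {self.class_intent!r}"
            )
        has_lesion = self.lesion_center is not None and self.lesion_radii is not None
        if (self.class_intent == "lesion") != has_lesion:
            raise InvalidSceneError(
                "lesion_center/lesion_radii must be present iff class_intent='lesion'"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["image_size"] = list(self.image_size)
        d["skin_tone"] = list(self.skin_tone)
        if self.lesion_center is not None:
            d["lesion_center"] = list(self.lesion_center)
            d["lesion_radii"] = list(self.lesion_radii)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SceneSpec":
        d = dict(d)
        d["image_size"] = tuple(d["image_size"])
        d["skin_tone"] = tuple(d["skin_tone"])
        if d.get("lesion_center") is not None:
            d["lesion_center"] = tuple(d["lesion_center"])
            d["lesion_radii"] = tuple(d["lesion_radii"])
        return cls(**d)


@dataclass(frozen=True)
class DegradationSpec:
    """One degradation operator at a given severity.

    ``operator_params`` maps parameter names to values; unresolved stochastic
    parameters (e.g. the framing displacement angle) are drawn once when the
    spec is resolved and stored, so re-applying a resolved spec is exact.
    """

    operator: str
    severity: float
    operator_params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.operator not in EXPLANATIONS:
            raise InvalidSceneError(
                f"unknown degradation operator {self.operator!r}; "
                f"expected one of {EXPLANATIONS}"
            )
        if not 0.0 <= self.severity <= 1.0:
            raise InvalidSceneError(
                f"severity must lie in [0, 1], got {self.severity}"
            )

    def to_dict(self) -> dict:
        return {
            "operator": self.operator,
            "severity": self.severity,
            "operator_params": dict(self.operator_params),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "DegradationSpec":
        return cls(d["operator"], d["severity"], dict(d.get("operator_params", {})))


@dataclass
class GroundTruth:
    """Reference label of a synthetic image: quality class, defect bits, mask."""

    quality_class: str
    explanations: np.ndarray  # (5,) int8, order of EXPLANATIONS
    lesion_mask: np.ndarray   # (H, W) bool

    def __post_init__(self):
        self.explanations = np.asarray(self.explanations, dtype=np.int8)
        if self.quality_class not in QUALITY_CLASSES:
            raise InvalidSceneError(f"unknown quality class {self.quality_class!r}")
        if self.explanations.any() and self.quality_class != "poor_quality":
            raise InvalidSceneError(
                "explanation bits set on a non-poor-quality ground truth"
            )

    def explanation_tags(self) -> tuple[str, ...]:
        return tuple(e for e, b in zip(EXPLANATIONS, self.explanations) if b)


@dataclass
class ImageRecord:
    """An RGB photograph plus the scene descriptor that produced it."""

    image_id: str
    pixels: np.ndarray  # (H, W, 3) uint8
    scene: SceneSpec | None = None
    degradations: tuple[DegradationSpec, ...] = ()
    seed: int | None = None


# --------------------------------------------------------------------------
# Base-scene rendering


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int],
                  cell: int, amplitude: float) -> np.ndarray:
    """Low-frequency value noise: coarse Gaussian grid upsampled bilinearly."""
    h, w = shape
    coarse = rng.normal(0.0, 1.0, size=(max(2, h // cell), max(2, w // cell)))
    return amplitude * resize(coarse, shape, order=1, mode="edge",
                              anti_aliasing=False)


def _render_skin(rng: np.random.Generator, shape: tuple[int, int],
                 tone: tuple[int, int, int]) -> np.ndarray:
    h, w = shape
    img = np.empty((h, w, 3), dtype=np.float64)
    mottle = _smooth_noise(rng, shape, cell=8, amplitude=7.0)
    grain = rng.normal(0.0, 2.5, size=(h, w))
    for ch in range(3):
        img[:, :, ch] = tone[ch] + mottle * (1.0 - 0.15 * ch) + grain
    return img


def _render_non_skin(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """A clearly non-dermatological background: cool-toned striped fabric."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    angle = rng.uniform(0, np.pi)
    period = rng.uniform(6.0, 14.0)
    stripes = np.sin(2 * np.pi * (np.cos(angle) * xx + np.sin(angle) * yy) / period)
    base = np.array([rng.uniform(60, 120), rng.uniform(90, 140), rng.uniform(130, 190)])
    img = np.empty((h, w, 3), dtype=np.float64)
    mottle = _smooth_noise(rng, shape, cell=10, amplitude=10.0)
    for ch in range(3):
        img[:, :, ch] = base[ch] + 25.0 * stripes + mottle + rng.normal(0, 2.0, (h, w))
    return img


def _ellipse_mask(shape: tuple[int, int], center: tuple[float, float],
                  radii: tuple[float, float]) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(np.float64)
    d = ((yy - center[0]) / radii[0]) ** 2 + ((xx - center[1]) / radii[1]) ** 2
    return d <= 1.0


def generate_base_image(spec: SceneSpec, seed: int) -> tuple[ImageRecord, GroundTruth]:
    """Render one undegraded scene; deterministic given ``(spec, seed)``.

    Lesion scenes place a pigmented ellipse, darker than the surrounding
    skin, with soft edges and internal texture; the returned
    :class:`GroundTruth` carries the exact ellipse mask.
    """
    h, w = spec.image_size
    if h < 32 or w < 32:
        raise InvalidSceneError(f"image_size must be at least 32x32, got {h}x{w}")
    rng = np.random.default_rng([seed & 0x7FFFFFFF, spec.texture_seed & 0x7FFFFFFF])

    mask = np.zeros((h, w), dtype=bool)
    if spec.class_intent == "no_skin":
        img = _render_non_skin(rng, (h, w))
    else:
        img = _render_skin(rng, (h, w), spec.skin_tone)
        if spec.class_intent == "lesion":
            cy, cx = spec.lesion_center
            ry, rx = spec.lesion_radii
            m = spec.frame_margin * min(h, w)
            if (cy - ry < m or cy + ry > h - m or cx - rx < m or cx + rx > w - m):
                raise InvalidSceneError(
                    "lesion ellipse extends beyond the frame margin: "
                    f"center={spec.lesion_center} radii={spec.lesion_radii} "
                    f"size={spec.image_size} margin={m:.1f}px"
                )
            yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
            d = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2
            mask = d <= 1.0
            # soft-edged pigmented ellipse, darker and redder than the skin
            alpha = np.clip((1.15 - d) / 0.3, 0.0, 1.0)
            lesion_tone = np.array(spec.skin_tone, dtype=np.float64) * 0.45
            lesion_tone[0] *= 1.25  # keep a reddish-brown cast
            inner = _smooth_noise(rng, (h, w), cell=4, amplitude=9.0)
            for ch in range(3):
                target = lesion_tone[ch] + inner
                img[:, :, ch] = (1 - alpha) * img[:, :, ch] + alpha * target

    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    record = ImageRecord(image_id=f"{spec.class_intent}-{seed}", pixels=pixels,
                         scene=spec, seed=seed)
    truth = GroundTruth(
        quality_class="healthy_skin" if spec.class_intent == "healthy_skin"
        else spec.class_intent,
        explanations=np.zeros(len(EXPLANATIONS), dtype=np.int8),
        lesion_mask=mask,
    )
    return record, truth


# --------------------------------------------------------------------------
# Degradation operators
#
# Each operator maps (img float64 HxWx3, mask bool, severity, params) to a new
# (img, mask). Severity 0 is skipped entirely upstream, guaranteeing exact
# identity. Physical parameters are non-decreasing in severity.


def _op_blurry(img, mask, severity, params):
    sigma = params.get("sigma", severity * params.get("max_sigma", 4.0))
    if sigma <= 0:
        return img, mask
    out = ndimage.gaussian_filter(img, sigma=(sigma, sigma, 0.0), mode="nearest")
    return out, mask


def _op_low_resolution(img, mask, severity, params):
    max_factor = params.get("max_factor", 8)
    factor = int(params.get("factor", 1 + round(severity * (max_factor - 1))))
    if factor <= 1:
        return img, mask
    h, w = img.shape[:2]
    small = resize(img, (max(1, h // factor), max(1, w // factor), 3),
                   order=1, mode="edge", anti_aliasing=True)
    out = resize(small, (h, w, 3), order=0, mode="edge", anti_aliasing=False)
    return out, mask


def _op_bad_light(img, mask, severity, params):
    direction = params.get("direction", 1.0)  # +1 overexposed, -1 underexposed
    max_log2 = params.get("max_log2_gain", 2.0)
    gain = 2.0 ** (direction * severity * max_log2)
    if gain == 1.0:
        return img, mask
    return img * gain, mask


def _op_bad_framing(img, mask, severity, params):
    # Displace the lesion centroid to lie OUTSIDE the central 50% window:
    # its dominant displacement component from the image centre is
    # (0.25 + 0.2*severity) * min(H, W), i.e. just past the window edge at
    # low severity and deep into the border at severity 1. Partial
    # truncation of the lesion at the frame edge is allowed.
    if severity == 0.0 and "offset_fraction" not in params:
        return img, mask
    h, w = img.shape[:2]
    s = min(h, w)
    angle = params.get("angle", 0.0)
    frac = params.get("offset_fraction", 0.25 + 0.2 * severity)
    u = np.array([np.sin(angle), np.cos(angle)])
    dom = max(abs(u[0]), abs(u[1]), 1e-9)
    if mask.any():
        cy, cx = ndimage.center_of_mass(mask)
    else:
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    ty = (h - 1) / 2.0 + u[0] * frac * s / dom
    tx = (w - 1) / 2.0 + u[1] * frac * s / dom
    dy, dx = ty - cy, tx - cx
    out = ndimage.shift(img, (dy, dx, 0.0), order=0, mode="nearest")
    mshift = ndimage.shift(mask.astype(np.float64), (dy, dx), order=0,
                           mode="constant", cval=0.0)
    return out, mshift > 0.5


def _op_too_far_away(img, mask, severity, params):
    max_zoom = params.get("max_zoom", 4.0)
    zoom = params.get("zoom", 1.0 + severity * (max_zoom - 1.0))
    if zoom <= 1.0:
        return img, mask
    h, w = img.shape[:2]
    h2, w2 = max(4, int(round(h / zoom))), max(4, int(round(w / zoom)))
    small = resize(img, (h2, w2, 3), order=1, mode="edge", anti_aliasing=True)
    border = np.concatenate([img[0], img[-1], img[:, 0], img[:, -1]])
    canvas = np.broadcast_to(np.median(border, axis=0), (h, w, 3)).copy()
    top, left = (h - h2) // 2, (w - w2) // 2
    canvas[top : top + h2, left : left + w2] = small
    msmall = resize(mask.astype(np.float64), (h2, w2), order=0,
                    anti_aliasing=False) > 0.5
    mcanvas = np.zeros((h, w), dtype=bool)
    mcanvas[top : top + h2, left : left + w2] = msmall
    return canvas, mcanvas


_OPERATORS = {
    "blurry": _op_blurry,
    "low_resolution": _op_low_resolution,
    "bad_light": _op_bad_light,
    "bad_framing": _op_bad_framing,
    "too_far_away": _op_too_far_away,
}

#: Ordering bucket: geometric operators rearrange content and are applied
#: before photometric ones when a dataset is generated (physical image
#: formation: the scene is framed before the sensor degrades it).
GEOMETRIC_OPERATORS = ("bad_framing", "too_far_away")


def resolve_specs(specs: Sequence[DegradationSpec],
                  rng: np.random.Generator) -> list[DegradationSpec]:
    """Draw any unresolved stochastic operator parameters and freeze them."""
    resolved = []
    for s in specs:
        params = dict(s.operator_params)
        if s.operator == "bad_framing" and "angle" not in params:
            params["angle"] = float(rng.uniform(0.0, 2 * np.pi))
        if s.operator == "bad_light" and "direction" not in params:
            params["direction"] = float(rng.choice([-1.0, 1.0]))
        resolved.append(DegradationSpec(s.operator, s.severity, params))
    return resolved


def apply_degradation(
    image: ImageRecord,
    truth: GroundTruth,
    specs: Sequence[DegradationSpec],
    seed: int,
    diagnosability_thresholds: Mapping[str, float] | float | None = None,
) -> tuple[ImageRecord, GroundTruth]:
    """Apply degradation operators in the order given.

    The quality class flips to ``poor_quality`` exactly when at least one
    operator's severity exceeds its diagnosability threshold (default 0.3),
    and those operators' explanation bits are set. Geometric operators
    transform the lesion mask consistently.
    """
    if not specs:
        raise InvalidSceneError("specs must be non-empty")
    specs = [s if isinstance(s, DegradationSpec) else DegradationSpec(**s)
             for s in specs]
    if diagnosability_thresholds is None:
        thresholds = {op: DEFAULT_DIAGNOSABILITY_THRESHOLD for op in EXPLANATIONS}
    elif isinstance(diagnosability_thresholds, (int, float)):
        thresholds = {op: float(diagnosability_thresholds) for op in EXPLANATIONS}
    else:
        thresholds = {op: diagnosability_thresholds.get(
            op, DEFAULT_DIAGNOSABILITY_THRESHOLD) for op in EXPLANATIONS}

    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    specs = resolve_specs(specs, rng)

    img = image.pixels.astype(np.float64)
    mask = truth.lesion_mask.copy()
    touched = False
    for s in specs:
        if s.severity == 0.0 and not s.operator_params:
            continue  # exact identity
        img2, mask = _OPERATORS[s.operator](img, mask, s.severity, s.operator_params)
        if img2 is not img:
            touched = True
        img = img2

    bits = truth.explanations.copy()
    for s in specs:
        if s.severity > thresholds[s.operator]:
            bits[EXPLANATION_INDEX[s.operator]] = 1
    quality = "poor_quality" if bits.any() else truth.quality_class

    pixels = (np.clip(np.rint(img), 0, 255).astype(np.uint8)
              if touched else image.pixels.copy())
    rec = ImageRecord(image_id=image.image_id, pixels=pixels, scene=image.scene,
                      degradations=tuple(specs), seed=image.seed)
    return rec, GroundTruth(quality, bits, mask)


# --------------------------------------------------------------------------
# Dataset generation


def _sample_scene(class_intent: str, rng: np.random.Generator,
                  image_size: tuple[int, int]) -> SceneSpec:
    h, w = image_size
    tone = _SKIN_TONES[rng.integers(0, len(_SKIN_TONES))]
    texture_seed = int(rng.integers(0, 2**31 - 1))
    if class_intent != "lesion":
        return SceneSpec(class_intent, image_size, tone,
                         texture_seed=texture_seed)
    s = min(h, w)
    ry = float(rng.uniform(0.10, 0.22) * s)
    rx = float(rng.uniform(0.10, 0.22) * s)
    # A diagnosable photograph is framed on the lesion: the centre stays
    # well inside the central 50% window (bad framing is a degradation).
    cy = float(rng.uniform(0.38 * h, 0.62 * h))
    cx = float(rng.uniform(0.38 * w, 0.62 * w))
    return SceneSpec("lesion", image_size, tone, (cy, cx), (ry, rx),
                     texture_seed=texture_seed)


def _sample_operators(mix: Mapping[str, float], rng: np.random.Generator,
                      severity_range: tuple[float, float]) -> list[DegradationSpec]:
    ops = [op for op in EXPLANATIONS if mix.get(op, 0.0) > 0.0]
    if not ops:
        raise InvalidSceneError("degradation mix selects no operator")
    # independent inclusion, rejected until at least one operator is present
    while True:
        chosen = [op for op in ops if rng.random() < mix[op]]
        if chosen:
            break
    lo, hi = severity_range
    specs = [DegradationSpec(op, float(rng.uniform(lo, hi))) for op in chosen]
    specs.sort(key=lambda s: (s.operator not in GEOMETRIC_OPERATORS,
                              EXPLANATION_INDEX[s.operator]))
    return specs


def generate_dataset(
    counts: Mapping[str, int],
    degradation_mix: Mapping[str, float] | None = None,
    seed: int = 0,
    *,
    image_size: tuple[int, int] = (64, 64),
    severity_range: tuple[float, float] = (0.6, 1.0),
    diagnosability_thresholds: Mapping[str, float] | float | None = None,
) -> list[tuple[ImageRecord, GroundTruth]]:
    """Generate a labelled synthetic dataset with exact per-class counts.

    ``counts`` maps quality classes to the number of images requested;
    poor-quality images start from a lesion scene and receive at least one
    degradation operator, sampled independently per operator with the
    inclusion probabilities in ``degradation_mix``. Severities are drawn
    uniformly from ``severity_range``; with the default range every sampled
    operator exceeds the diagnosability threshold, so the sampled class is
    always realised.
    """
    counts = {c: int(n) for c, n in counts.items()}
    for c in counts:
        if c not in QUALITY_CLASSES:
            raise InvalidSceneError(f"unknown quality class in counts: {c!r}")
        if counts[c] < 0:
            raise InvalidSceneError("counts must be non-negative")
    if sum(counts.values()) == 0:
        raise InvalidSceneError("counts must request at least one image")
    mix = dict(DEFAULT_DEGRADATION_MIX if degradation_mix is None
               else degradation_mix)
    for op, p in mix.items():
        if op not in EXPLANATIONS or not 0.0 <= p <= 1.0:
            raise InvalidSceneError(f"invalid mix entry {op!r}: {p}")

    master = np.random.default_rng(seed & 0x7FFFFFFF)
    out: list[tuple[ImageRecord, GroundTruth]] = []
    idx = 0
    for cls in QUALITY_CLASSES:
        for _ in range(counts.get(cls, 0)):
            image_seed = int(master.integers(0, 2**31 - 1))
            rng = np.random.default_rng(image_seed)
            base_cls = "lesion" if cls == "poor_quality" else cls
            spec = _sample_scene(base_cls, rng, image_size)
            rec, truth = generate_base_image(spec, image_seed)
            if cls == "poor_quality":
                specs = _sample_operators(mix, rng, severity_range)
                specs = resolve_specs(specs, rng)
                rec, truth = apply_degradation(
                    rec, truth, specs, image_seed,
                    diagnosability_thresholds=diagnosability_thresholds)
                if truth.quality_class != "poor_quality":
                    raise InvalidSceneError(
                        "sampled severities fell below every diagnosability "
                        "threshold; raise severity_range or lower thresholds")
            rec.image_id = f"img{idx:05d}"
            out.append((rec, truth))
            idx += 1
    return out


def write_manifest(records: Sequence[tuple[ImageRecord, GroundTruth]],
                   path: str | Path) -> None:
    """Write a JSONL manifest from which the dataset regenerates bit-exactly."""
    path = Path(path)
    with path.open("w") as fh:
        for rec, truth in records:
            row = {
                "image_id": rec.image_id,
                "seed": rec.seed,
                "scene": rec.scene.to_dict(),
                "degradations": [d.to_dict() for d in rec.degradations],
                "quality_class": truth.quality_class,
                "explanations": [int(b) for b in truth.explanations],
            }
            fh.write(json.dumps(row) + "\n")


def regenerate_from_manifest(
    path: str | Path,
    diagnosability_thresholds: Mapping[str, float] | float | None = None,
) -> list[tuple[ImageRecord, GroundTruth]]:
    out = []
    with Path(path).open() as fh:
        for line in fh:
            row = json.loads(line)
            spec = SceneSpec.from_dict(row["scene"])
            rec, truth = generate_base_image(spec, row["seed"])
            degr = [DegradationSpec.from_dict(d) for d in row["degradations"]]
            if degr:
                rec, truth = apply_degradation(
                    rec, truth, degr, row["seed"],
                    diagnosability_thresholds=diagnosability_thresholds)
            rec.image_id = row["image_id"]
            out.append((rec, truth))
    return out


def write_images(records: Sequence[tuple[ImageRecord, GroundTruth]],
                 out_dir: str | Path) -> list[Path]:
    """Save each record as an 8-bit RGB PNG named by its image id."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for rec, _ in records:
        p = out_dir / f"{rec.image_id}.png"
        Image.fromarray(rec.pixels, mode="RGB").save(p)
        paths.append(p)
    return paths


# --------------------------------------------------------------------------
# Rater-panel simulation


@dataclass(frozen=True)
class RaterProfile:
    """Stochastic annotator model.

    ``quality_confusion`` is a 4x4 row-stochastic matrix over the canonical
    class order (row = true class, column = emitted class). When the rater
    emits ``poor_quality``, each truly present explanation is reported with
    probability ``explanation_sensitivity`` and each absent one with
    probability ``explanation_false_alarm``.
    """

    rater_id: str
    quality_confusion: tuple  # 4x4 nested tuples
    explanation_sensitivity: tuple  # 5 probabilities
    explanation_false_alarm: tuple  # 5 probabilities

    def __post_init__(self):
        m = np.asarray(self.quality_confusion, dtype=np.float64)
        if m.shape != (len(QUALITY_CLASSES),) * 2:
            raise InvalidSceneError("quality_confusion must be 4x4")
        if np.any(m < 0) or np.any(np.abs(m.sum(axis=1) - 1.0) > 1e-9):
            raise InvalidSceneError("confusion rows must be stochastic (sum to 1)")
        for v in (self.explanation_sensitivity, self.explanation_false_alarm):
            a = np.asarray(v, dtype=np.float64)
            if a.shape != (len(EXPLANATIONS),) or np.any((a < 0) | (a > 1)):
                raise InvalidSceneError("explanation probabilities must be 5 values in [0,1]")

    @property
    def confusion(self) -> np.ndarray:
        return np.asarray(self.quality_confusion, dtype=np.float64)


def identity_profile(rater_id: str) -> RaterProfile:
    """A perfectly accurate rater (noiseless limit)."""
    eye = tuple(tuple(float(x) for x in row) for row in np.eye(len(QUALITY_CLASSES)))
    return RaterProfile(rater_id, eye, (1.0,) * 5, (0.0,) * 5)


def symmetric_profile(rater_id: str, accuracy: float = 0.8,
                      sensitivity: float = 0.8,
                      false_alarm: float = 0.05) -> RaterProfile:
    """A rater who is correct with ``accuracy`` and errs uniformly otherwise."""
    k = len(QUALITY_CLASSES)
    off = (1.0 - accuracy) / (k - 1)
    m = tuple(tuple(accuracy if i == j else off for j in range(k)) for i in range(k))
    return RaterProfile(rater_id, m, (sensitivity,) * 5, (false_alarm,) * 5)


def simulate_raters(
    truths: Sequence[tuple] | Mapping[str, GroundTruth],
    profiles: Sequence[RaterProfile],
    raters_per_image: int,
    seed: int,
) -> list[RaterEvaluation]:
    """Draw an annotation panel for every image.

    ``truths`` may be a mapping ``image_id -> GroundTruth`` or the
    ``(ImageRecord, GroundTruth)`` pairs returned by
    :func:`generate_dataset`. Each image is rated by ``raters_per_image``
    distinct raters sampled from ``profiles``; emitted lesion verdicts carry
    a placeholder ICD-10 code so downstream parsing is exercised.
    """
    if not profiles:
        raise InvalidSceneError("profiles must be non-empty")
    if not 1 <= raters_per_image <= len(profiles):
        raise InvalidSceneError(
            f"raters_per_image must be in [1, {len(profiles)}], got {raters_per_image}"
        )
    if len(profiles) > 12:
        raise InvalidSceneError("at most 12 rater profiles are supported")

    if isinstance(truths, Mapping):
        items = list(truths.items())
    else:
        items = [(t[0].image_id, t[1]) if isinstance(t[0], ImageRecord) else tuple(t)
                 for t in truths]

    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    n_classes = len(QUALITY_CLASSES)
    evals: list[RaterEvaluation] = []
    for image_id, truth in items:
        true_idx = QUALITY_CLASSES.index(truth.quality_class)
        chosen = (range(len(profiles)) if raters_per_image == len(profiles)
                  else rng.choice(len(profiles), size=raters_per_image,
                                  replace=False))
        for pi in chosen:
            prof = profiles[pi]
            emitted = int(rng.choice(n_classes, p=prof.confusion[true_idx]))
            cls = QUALITY_CLASSES[emitted]
            tags: tuple[str, ...] = ()
            if cls == "lesion":
                verdict = str(rng.choice(PLACEHOLDER_ICD10_CODES))
            else:
                verdict = cls
                if cls == "poor_quality":
                    sens = np.asarray(prof.explanation_sensitivity)
                    fa = np.asarray(prof.explanation_false_alarm)
                    p = np.where(truth.explanations > 0, sens, fa)
                    bits = rng.random(len(EXPLANATIONS)) < p
                    tags = tuple(e for e, b in zip(EXPLANATIONS, bits) if b)
            evals.append(RaterEvaluation(rater_id=prof.rater_id,
                                         image_id=image_id,
                                         verdict=verdict,
                                         explanations=tags))
    return evals
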