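"""Grad-CAM saliency for any of the nine network outputs.

For a chosen output score (one of the four quality classes or five
poor-quality explanations, taken pre-softmax / pre-sigmoid to avoid
saturation), the gradient of the score is backpropagated to a convolutional
stage; channel importances are the spatially averaged gradients, and the
saliency map is the rectified importance-weighted sum of that stage's
activations, upsampled to the image grid and min-max normalised. An
all-zero rectified map is preserved as-is and flagged rather than
renormalised, to avoid inventing saliency.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib
import numpy as np
from PIL import Image
from skimage.transform import resize

from .model import Prediction, QualityExplainerNet, preprocess_images
from .taxonomy import CLASS_INDEX, EXPLANATION_INDEX

__all__ = ["SaliencyMap", "grad_cam", "overlay", "render_panel"]


@dataclass
class SaliencyMap:
    target_output: str
    values: np.ndarray  # (H, W) in [0, 1]
    source_layer: str
    is_empty: bool = False  # rectified map was all-zero before normalisation

    def max_activation(self) -> tuple[int, int]:
        """(row, col) of the strongest saliency."""
        return tuple(int(v) for v in np.unravel_index(np.argmax(self.values),
                                                      self.values.shape))


def grad_cam(
    model: QualityExplainerNet,
    image: np.ndarray,
    target_output: str,
    layer: str | None = None,
) -> SaliencyMap:
    """Compute the saliency map of ``target_output`` for one image.

    ``layer`` names a convolutional stage of the backbone (``stage1`` ...);
    the default is the last stage, whose coarse map carries the most
    class-specific semantics. Deterministic in evaluation mode.
    """
    if layer is None:
        layer = model.stage_names[-1]
    if layer not in model.stage_names:
        raise ValueError(
            f"{layer!r} is not a convolutional stage; expected one of "
            f"{model.stage_names}")
    si = model.stage_names.index(layer)

    h, w = np.asarray(image).shape[:2]
    x = preprocess_images([image], model.cfg.input_size)
    out = model.forward(x, train=False)

    d_q = np.zeros_like(out.quality_logits)
    d_e = np.zeros_like(out.explanation_logits)
    if target_output in CLASS_INDEX:
        d_q[0, CLASS_INDEX[target_output]] = 1.0
    elif target_output in EXPLANATION_INDEX:
        d_e[0, EXPLANATION_INDEX[target_output]] = 1.0
    else:
        raise ValueError(f"undefined target name {target_output!r}")
    model.backward(d_q.astype(np.float32), d_e.astype(np.float32),
                   capture_stage_grads=True)

    acts = model.stage_activations[si][0]   # (C, h', w')
    grads = model.stage_gradients[si][0]
    alpha = grads.mean(axis=(1, 2))          # channel importances
    cam = np.maximum((alpha[:, None, None] * acts).sum(axis=0), 0.0)

    cam = resize(cam.astype(np.float64), (h, w), order=1, mode="edge",
                 anti_aliasing=False)
    peak = cam.max()
    if peak <= 0.0:
        return SaliencyMap(target_output, np.zeros((h, w)), layer, is_empty=True)
    return SaliencyMap(target_output, cam / peak, layer)


def overlay(image: np.ndarray, smap: SaliencyMap | np.ndarray,
            colormap_name: str = "jet", alpha: float = 0.5) -> np.ndarray:
    """Alpha-blend a heat rendering of the map over the photograph.

    The blend weight at each pixel is ``alpha`` scaled by the local saliency,
    so an all-zero map returns the photograph unchanged.
    """
    values = smap.values if isinstance(smap, SaliencyMap) else np.asarray(smap)
    image = np.asarray(image)
    if values.shape != image.shape[:2]:
        raise ValueError(
            f"map shape {values.shape} does not match image {image.shape[:2]}")
    cmap = matplotlib.colormaps[colormap_name]
    heat = (cmap(values)[:, :, :3] * 255.0)
    weight = (alpha * values)[:, :, None]
    blended = (1.0 - weight) * image.astype(np.float64) + weight * heat
    return np.clip(np.rint(blended), 0, 255).astype(np.uint8)


def render_panel(
    image: np.ndarray,
    maps: list[SaliencyMap],
    out_path: str | Path | None = None,
    colormap_name: str = "jet",
    pad: int = 4,
) -> np.ndarray:
    """Side-by-side panel: the original photograph followed by one overlay
    per target, saved as PNG when ``out_path`` is given."""
    tiles = [np.asarray(image)] + [overlay(image, m, colormap_name) for m in maps]
    h = tiles[0].shape[0]
    gap = np.full((h, pad, 3), 255, dtype=np.uint8)
    row = tiles[0]
    for t in tiles[1:]:
        row = np.concatenate([row, gap, t], axis=1)
    if out_path is not None:
        Image.fromarray(row, mode="RGB").save(Path(out_path))
    return row
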