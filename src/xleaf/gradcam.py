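"""Gradient-weighted class activation mapping (Grad-CAM).

For a trained network M, input X and class c, the channel weights are the
spatially averaged gradients of the pre-softmax class score with respect to
the last convolutional feature maps A^k,

    w_k^c = (1 / (P*Q)) * sum_ij d y^c / d A^k_ij,

and the explanation is the ReLU of their linear combination, upsampled to the
input resolution:

    G(M, X, c) = Trans(ReLU(sum_k w_k^c A^k)).

Gradients are taken on the pre-softmax score; ``Trans`` is corner-aligned
bilinear interpolation.  Heatmaps are returned unnormalized (assessment
metrics normalize internally).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import autodiff as ad
from .autodiff import Tensor

__all__ = ["Explanation", "gradcam_weights", "gradcam_explain", "upsample",
           "save_explanation", "load_explanation", "render_preview"]


@dataclass
class Explanation:
    """A nonnegative saliency heatmap at input resolution."""

    heatmap: np.ndarray  # (U, V) float32, >= 0
    class_index: int
    model_id: str = ""


def _to_nchw(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float32)
    if x.ndim == 3:  # HWC single image
        return x.transpose(2, 0, 1)[None]
    if x.ndim == 4:
        return x
    raise ValueError(f"expected an HWC image or NCHW batch, got shape {x.shape}")


def _features_and_class_grad(model, x: np.ndarray, c: int):
    xb = _to_nchw(x)
    if xb.shape[0] != 1:
        raise ValueError("Grad-CAM operates on one image at a time")
    feats, logits = model.forward_with_features(Tensor(xb))
    n_classes = logits.shape[-1]
    if not (0 <= c < n_classes):
        raise ValueError(f"class index {c} out of range [0, {n_classes})")
    yc = ad.tsum(ad.mul(logits, Tensor(
        np.eye(n_classes, dtype=np.float32)[c][None, :])))
    (ga,) = ad.grad(yc, [feats])
    return feats.data[0], ga.data[0]  # (K, P, Q) each


def gradcam_weights(model, x: np.ndarray, c: int) -> np.ndarray:
    """Channel weights w_k^c: global average pooling of dy^c/dA^k."""
    _, ga = _features_and_class_grad(model, x, c)
    return ga.mean(axis=(1, 2))  # (K,)


def gradcam_explain(model, x: np.ndarray, c: int,
                    model_id: str = "") -> Explanation:
    """Grad-CAM heatmap for class ``c`` at input resolution."""
    feats, ga = _features_and_class_grad(model, x, c)
    w = ga.mean(axis=(1, 2))
    cam = np.maximum((w[:, None, None] * feats).sum(axis=0), 0.0)
    U, V = np.asarray(x).shape[:2] if np.asarray(x).ndim == 3 \
        else np.asarray(x).shape[2:]
    heat = upsample(cam, (U, V))
    return Explanation(heatmap=heat.astype(np.float32), class_index=int(c),
                       model_id=model_id)


def upsample(arr: np.ndarray, target: tuple[int, int]) -> np.ndarray:
    """Corner-aligned bilinear interpolation of a P x Q map to U x V.

    Exact on constant maps; output values stay within [min, max] of the
    input (order-1 interpolation cannot overshoot).
    """
    U, V = target
    if U < 1 or V < 1:
        raise ValueError(f"target size must be at least 1x1, got {target}")
    arr = np.asarray(arr, dtype=np.float64)
    P, Q = arr.shape
    if (P, Q) == (U, V):
        return arr.astype(np.float32)
    rows = np.linspace(0.0, P - 1.0, U) if P > 1 else np.zeros(U)
    cols = np.linspace(0.0, Q - 1.0, V) if Q > 1 else np.zeros(V)
    grid = np.meshgrid(rows, cols, indexing="ij")
    out = ndimage.map_coordinates(arr, grid, order=1, mode="nearest")
    return out.astype(np.float32)


# -- persistence --------------------------------------------------------------

def save_explanation(e: Explanation, path: str | Path) -> None:
    """Lossless float32 raster (.npz) with a JSON sidecar."""
    path = Path(path)
    np.savez(path, heatmap=e.heatmap.astype(np.float32))
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps({"class_index": e.class_index,
                                   "model_id": e.model_id,
                                   "shape": list(e.heatmap.shape)}))


def load_explanation(path: str | Path) -> Explanation:
    path = Path(path)
    with np.load(path.with_suffix(".npz")) as z:
        heat = z["heatmap"]
    meta = json.loads(path.with_suffix(".json").read_text())
    return Explanation(heatmap=heat, class_index=meta["class_index"],
                       model_id=meta.get("model_id", ""))


def render_preview(e: Explanation, path: str | Path,
                   cmap: str = "jet") -> None:
    """Colour-mapped PNG preview of a heatmap (max-normalized for display)."""
    import matplotlib
    from PIL import Image

    h = e.heatmap
    hmax = h.max()
    disp = h / hmax if hmax > 0 else h
    rgba = (matplotlib.colormaps[cmap](disp) * 255).astype(np.uint8)
    Image.fromarray(rgba[:, :, :3], mode="RGB").save(path)
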