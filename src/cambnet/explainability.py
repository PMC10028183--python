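"""Feature-map grids and Grad-CAM class-activation maps.

Grad-CAM: the gradient of the target-class logit with respect to a
convolutional stage's feature map is spatially averaged per channel to
give importance weights; the weighted sum of the activations, rectified,
bilinearly upsampled to the input size and min-max normalised, highlights
the image regions that drove the prediction.  The default stage is the
last convolutional stage of the deep feature extraction module
("Conv4_5").  A quantitative localisation score — the fraction of total
saliency falling inside the tumor contour — turns "the model looks at the
tumor" into a measurable property.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

from .model import CAMBNet
from .preprocessing import ROIPatch

DEFAULT_GRADCAM_LAYER = "Conv4_5"

#: stages displayed in the feature grid, in network order
FEATURE_GRID_STAGES = (
    "Pre_layer", "SFEpath", "LTTpath1", "LTTpath2", "Fuse", "Conv4_5",
)


@dataclass
class SaliencyMap:
    data: np.ndarray  # (side, side) in [0, 1]
    target_class: int
    source_layer: str

    def __post_init__(self):
        if self.data.min() < 0 or self.data.max() > 1:
            raise ValueError("saliency values must lie in [0, 1]")


class UnknownLayerError(KeyError):
    """Raised for a layer tag that names no hookable stage."""


def gradcam(model: CAMBNet, patch: ROIPatch | np.ndarray, target_class: int,
            layer_tag: str = DEFAULT_GRADCAM_LAYER) -> SaliencyMap:
    """Gradient-weighted class-activation map for one patch.

    The patch is (side, side, C) HWC (an :class:`ROIPatch` or bare array).
    If the pre-normalisation map is identically zero (e.g. the target
    logit does not depend on the input), the all-zero map is returned
    rather than dividing by zero.
    """
    data = patch.data if isinstance(patch, ROIPatch) else np.asarray(patch)
    side = data.shape[0]
    x = np.transpose(data, (2, 0, 1))[None].astype(np.float32)
    model.eval()
    logits = model(x)
    if layer_tag not in model.stages:
        raise UnknownLayerError(
            f"unknown layer tag {layer_tag!r}; valid tags: "
            f"{sorted(model.stages)}"
        )
    feat = model.stages[layer_tag]
    if feat.ndim != 4:
        raise UnknownLayerError(f"stage {layer_tag!r} is not a spatial feature map")
    model.zero_grad()
    seed = np.zeros_like(logits.data)
    seed[0, target_class] = 1.0
    logits.backward(seed)
    if feat.grad is None:
        weights = np.zeros(feat.shape[1], dtype=np.float32)
    else:
        weights = feat.grad[0].mean(axis=(1, 2))  # GAP of the gradients
    cam = np.maximum((weights[:, None, None] * feat.data[0]).sum(axis=0), 0.0)
    cam = _sk_resize(cam, (side, side), order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    cam = np.maximum(cam, 0.0)
    peak = cam.max()
    if peak > 0:
        cam = (cam - cam.min()) / (peak - cam.min())
    else:
        cam = np.zeros_like(cam)
    return SaliencyMap(data=cam.astype(np.float32), target_class=target_class,
                       source_layer=layer_tag)


def feature_grid(model: CAMBNet, patch: ROIPatch | np.ndarray,
                 mode: str = "mean",
                 stages: tuple[str, ...] = FEATURE_GRID_STAGES
                 ) -> dict[str, np.ndarray]:
    """Per-stage display images (channel mean or per-channel stack).

    ``mode="mean"`` returns one min-max-scaled image per stage;
    ``mode="channels"`` returns the (C, H, W) stack scaled jointly.
    """
    from .nn import tensor as T

    data = patch.data if isinstance(patch, ROIPatch) else np.asarray(patch)
    x = np.transpose(data, (2, 0, 1))[None].astype(np.float32)
    model.eval()
    with T.no_grad():
        model(x)
    grid = {}
    for tag in stages:
        feat = model.stages[tag].data[0]
        img = feat.mean(axis=0) if mode == "mean" else feat
        lo, hi = img.min(), img.max()
        grid[tag] = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
    return grid


def localization_score(saliency: SaliencyMap | np.ndarray,
                       mask: np.ndarray) -> float:
    """Fraction of total saliency falling inside the (resized) tumor mask."""
    sal = saliency.data if isinstance(saliency, SaliencyMap) else np.asarray(saliency)
    mask = np.asarray(mask).astype(bool)
    if mask.shape != sal.shape:
        raise ValueError(f"mask shape {mask.shape} != saliency shape {sal.shape}")
    if not mask.any():
        raise ValueError("empty mask")
    total = sal.sum()
    if total == 0:
        return 0.0
    return float(sal[mask].sum() / total)


def save_overlay(patch: ROIPatch | np.ndarray, saliency: SaliencyMap, path,
                 channel: int = -1) -> None:
    """Write the patch with the saliency map blended on top."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = patch.data if isinstance(patch, ROIPatch) else np.asarray(patch)
    base = data[..., channel]
    lo, hi = base.min(), base.max()
    base = (base - lo) / (hi - lo) if hi > lo else np.zeros_like(base)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(base, cmap="gray")
    ax.imshow(saliency.data, cmap="jet", alpha=0.4)
    ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


__all__ = [
    "DEFAULT_GRADCAM_LAYER",
    "FEATURE_GRID_STAGES",
    "SaliencyMap",
    "UnknownLayerError",
    "gradcam",
    "feature_grid",
    "localization_score",
    "save_overlay",
]
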