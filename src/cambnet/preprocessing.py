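"""ROI extraction: contour extremes -> margin -> crop -> resize -> normalize.

From each physician-contoured (here: phantom) mask the minimum axis-aligned
box covering the tumor is taken from the extreme contour points in the four
directions, expanded by a fixed margin (default 10 px, clipped at the image
frame), cropped from every channel, resized to 64x64 with bilinear
interpolation (half-pixel-centre sampling, no corner alignment) and
normalised per channel as (x - mu) / sigma after scaling intensities to
[0, 1].  The rectangular crop is resized directly to the square target; the
aspect ratio is not preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

DEFAULT_MARGIN = 10
DEFAULT_SIDE = 64
DEFAULT_MEAN = 0.5
DEFAULT_STD = 0.5


class EmptyMaskError(ValueError):
    """Raised when a contour mask has no positive pixel (no visible ROI)."""


@dataclass(frozen=True)
class BoundingBox:
    """Inclusive, 0-based pixel box."""

    row_min: int
    row_max: int
    col_min: int
    col_max: int

    def __post_init__(self):
        if self.row_min > self.row_max or self.col_min > self.col_max:
            raise ValueError(f"degenerate bounding box {self}")

    @property
    def height(self) -> int:
        return self.row_max - self.row_min + 1

    @property
    def width(self) -> int:
        return self.col_max - self.col_min + 1


@dataclass
class ROIPatch:
    """Normalised 64x64 multi-channel tumor patch with its label."""

    data: np.ndarray  # (side, side, C) float32
    label: str
    patient_id: str
    label4: str | None = None

    def __post_init__(self):
        if self.data.ndim != 3:
            raise ValueError("patch data must be (H, W, C)")
        if not np.isfinite(self.data).all():
            raise ValueError("patch contains non-finite values")


def extract_bounding_box(mask: np.ndarray, margin: int = DEFAULT_MARGIN) -> BoundingBox:
    """Minimum box covering the mask, expanded by ``margin`` px per side.

    The expansion is clipped to the image frame.  Raises
    :class:`EmptyMaskError` on an all-zero mask, mirroring the exclusion of
    cases with no visible region of interest.
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    if margin < 0:
        raise ValueError("margin must be >= 0")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        raise EmptyMaskError("mask has no positive pixel (no visible ROI)")
    h, w = mask.shape
    return BoundingBox(
        row_min=max(int(rows[0]) - margin, 0),
        row_max=min(int(rows[-1]) + margin, h - 1),
        col_min=max(int(cols[0]) - margin, 0),
        col_max=min(int(cols[-1]) + margin, w - 1),
    )


def crop_resize(images, box: BoundingBox, side: int = DEFAULT_SIDE) -> np.ndarray:
    """Crop ``box`` from each channel and bilinearly resize to side x side.

    ``images`` is a list of (H, W) arrays or a single (H, W, C) array.
    Returns (side, side, C) float32.  Bilinear interpolation uses
    half-pixel-centre sampling with edge clamping, so constant images stay
    exactly constant and an identity-size crop is returned unchanged.
    """
    if isinstance(images, np.ndarray) and images.ndim == 3:
        channels = [images[..., c] for c in range(images.shape[-1])]
    else:
        channels = list(images)
    if box.height < 1 or box.width < 1:
        raise ValueError(f"degenerate crop box {box}")
    out = np.empty((side, side, len(channels)), dtype=np.float32)
    for c, img in enumerate(channels):
        img = np.asarray(img, dtype=np.float32)
        if box.row_max >= img.shape[0] or box.col_max >= img.shape[1]:
            raise ValueError(f"box {box} exceeds image shape {img.shape}")
        crop = img[box.row_min : box.row_max + 1, box.col_min : box.col_max + 1]
        if crop.shape == (side, side):
            out[..., c] = crop
        else:
            out[..., c] = _sk_resize(
                crop, (side, side), order=1, mode="edge",
                anti_aliasing=False, preserve_range=True,
            ).astype(np.float32)
    return out


def normalize(patch: np.ndarray, mean=DEFAULT_MEAN, std=DEFAULT_STD) -> np.ndarray:
    """Per-channel affine normalisation (x - mu_c) / sigma_c."""
    patch = np.asarray(patch, dtype=np.float32)
    c = patch.shape[-1]
    mean = np.broadcast_to(np.asarray(mean, dtype=np.float32), (c,))
    std = np.broadcast_to(np.asarray(std, dtype=np.float32), (c,))
    if np.any(std == 0):
        raise ValueError("normalization std must be nonzero for every channel")
    return (patch - mean) / std


def denormalize(patch: np.ndarray, mean=DEFAULT_MEAN, std=DEFAULT_STD) -> np.ndarray:
    """Inverse of :func:`normalize` given the same constants."""
    patch = np.asarray(patch, dtype=np.float32)
    c = patch.shape[-1]
    mean = np.broadcast_to(np.asarray(mean, dtype=np.float32), (c,))
    std = np.broadcast_to(np.asarray(std, dtype=np.float32), (c,))
    return patch * std + mean


def preprocess_case(case, margin: int = DEFAULT_MARGIN, side: int = DEFAULT_SIDE,
                    mean=DEFAULT_MEAN, std=DEFAULT_STD) -> ROIPatch:
    """Full pipeline for one contoured case -> normalised ROI patch."""
    box = extract_bounding_box(case.mask, margin=margin)
    patch = crop_resize(case.images, box, side=side)
    patch = normalize(patch, mean=mean, std=std)
    return ROIPatch(
        data=patch,
        label=case.subtype_label,
        patient_id=case.patient_id,
        label4=getattr(case, "subtype_label4", None),
    )


def preprocess_cohort(cases, margin: int = DEFAULT_MARGIN, side: int = DEFAULT_SIDE,
                      mean=DEFAULT_MEAN, std=DEFAULT_STD) -> list[ROIPatch]:
    return [preprocess_case(c, margin=margin, side=side, mean=mean, std=std)
            for c in cases]


def resize_mask(mask: np.ndarray, box: BoundingBox, side: int = DEFAULT_SIDE
                ) -> np.ndarray:
    """Carry a contour mask through the same crop/resize, re-binarised."""
    m = crop_resize([np.asarray(mask, dtype=np.float32)], box, side=side)[..., 0]
    return m > 0.5


__all__ = [
    "DEFAULT_MARGIN",
    "DEFAULT_SIDE",
    "DEFAULT_MEAN",
    "DEFAULT_STD",
    "BoundingBox",
    "ROIPatch",
    "EmptyMaskError",
    "extract_bounding_box",
    "crop_resize",
    "normalize",
    "denormalize",
    "preprocess_case",
    "preprocess_cohort",
    "resize_mask",
]
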