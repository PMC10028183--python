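"""Phantom DCE-MRI-like cohorts for the subtype-classification pipeline.

Real inputs to the pipeline are per-patient MR series with a physician
contour of the tumor and clinical covariates (age at menarche, tumor
size).  Such clinical data is not redistributable, so this module renders
two-class lesion phantoms carrying the same structure:

* "luminal" lesions: elliptical masses whose boundary is perturbed by
  radial sinusoidal spiculation — irregular, burr-edged margins;
* "non_luminal" lesions: smooth discs with a brighter enhancing ring
  (annular enhancement), the morphology described for triple-negative
  disease.

Each case has three image channels (standing for T1WI / T2WI / DCE phase
3) rendered as correlated views of the same lesion with different
contrast, a binary contour mask, and per-patient metadata so that the
menarche-age and tumor-size subgroup analyses are mechanically
exercisable.  Generation is a pure function of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull

CLASS_LABELS = ("luminal", "non_luminal")
SUBTYPES = ("luminalA", "luminalB", "HER2", "TN")

#: mm per pixel used to convert lesion diameters to tumor_size_mm.  At the
#: default radius range this places lesions on both sides of the 20 mm
#: grouping threshold.
PIXEL_SPACING_MM = 0.5

#: per-channel lesion contrast gains emulating T1WI / T2WI / DCE phase 3
CHANNEL_GAINS = (0.9, 0.7, 1.2)


class InvalidClassError(ValueError):
    """Raised for a class label outside the supported set."""


@dataclass(frozen=True)
class PhantomSpec:
    """Rendering parameters of the phantom generator."""

    image_side: int = 256
    n_channels: int = 3
    lesion_radius_range: tuple[float, float] = (12.0, 30.0)
    spiculation_amplitude: float = 0.35
    ring_contrast: float = 0.35
    background_noise_scale: float = 0.06
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.lesion_radius_range
        if lo < 4:
            raise ValueError("lesion_radius_range min must be >= 4 px")
        if hi >= self.image_side / 2:
            raise ValueError("lesion_radius_range max must be < image_side/2")
        if not 0.0 <= self.spiculation_amplitude < 1.0:
            raise ValueError("spiculation_amplitude must lie in [0, 1)")
        if self.ring_contrast < 0:
            raise ValueError("ring_contrast must be >= 0")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")


@dataclass
class ContouredCase:
    """One patient record: images, contour mask and clinical covariates."""

    patient_id: str
    images: list[np.ndarray]  # one (H, W) float array in [0,1] per channel
    mask: np.ndarray          # (H, W) bool, True inside the tumor contour
    subtype_label: str        # "luminal" / "non_luminal"
    subtype_label4: str       # one of SUBTYPES
    menarche_age: int
    tumor_size: float         # maximum lesion diameter, mm
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.mask.any():
            raise ValueError(f"case {self.patient_id}: mask has no positive pixel")
        for img in self.images:
            if img.shape != self.mask.shape:
                raise ValueError(
                    f"case {self.patient_id}: image {img.shape} vs mask "
                    f"{self.mask.shape}"
                )
        if self.tumor_size <= 0:
            raise ValueError("tumor_size must be positive")
        if self.menarche_age <= 0:
            raise ValueError("menarche_age must be positive")


# -- geometry helpers ------------------------------------------------------

def _smooth_noise(rng: np.random.Generator, side: int, sigma: float = 6.0) -> np.ndarray:
    """Zero-mean, unit-std spatially smoothed Gaussian field."""
    raw = rng.normal(size=(side, side))
    sm = ndimage.gaussian_filter(raw, sigma)
    return (sm - sm.mean()) / max(sm.std(), 1e-9)


def _ellipse_radius(theta: np.ndarray, a: float, b: float, phi: float) -> np.ndarray:
    """Polar radius of an ellipse with semi-axes a, b rotated by phi."""
    t = theta - phi
    return (a * b) / np.sqrt((b * np.cos(t)) ** 2 + (a * np.sin(t)) ** 2)


def _largest_4connected(mask: np.ndarray, cy: float, cx: float) -> np.ndarray:
    labels, n = ndimage.label(mask)  # default structure = 4-connectivity
    if n <= 1:
        return mask
    centre_label = labels[int(round(cy)), int(round(cx))]
    if centre_label == 0:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        centre_label = 1 + int(np.argmax(sizes))
    return labels == centre_label


def max_diameter_px(mask: np.ndarray) -> float:
    """Maximum pairwise distance between mask pixels (convex hull based)."""
    pts = np.argwhere(mask).astype(float)
    if len(pts) == 1:
        return 1.0
    if len(pts) <= 3 or np.linalg.matrix_rank(pts - pts.mean(0)) < 2:
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        return float(d.max()) + 1.0
    hull = pts[ConvexHull(pts).vertices]
    d = np.sqrt(((hull[:, None] - hull[None]) ** 2).sum(-1))
    # +1 px: pixels are unit squares, centres underestimate the support
    return float(d.max()) + 1.0


def boundary_roughness(mask: np.ndarray) -> float:
    """Isoperimetric ratio perimeter^2 / (4 pi area); 1 for a disc."""
    from skimage.measure import perimeter_crofton

    area = float(mask.sum())
    per = float(perimeter_crofton(mask, directions=4))
    return per ** 2 / (4.0 * math.pi * area)


def ring_intensity_contrast(case: ContouredCase, channel: int = -1) -> float:
    """Mean intensity in the lesion's outer band minus its core.

    Positive and large for ring-enhanced lesions; near zero for lesions
    with flat interior intensity.  Computed on the DCE-like channel by
    default.
    """
    img = case.images[channel]
    dist = ndimage.distance_transform_edt(case.mask)
    dmax = dist.max()
    outer = case.mask & (dist <= 0.35 * dmax)
    core = dist > 0.6 * dmax
    if not outer.any() or not core.any():
        return 0.0
    return float(img[outer].mean() - img[core].mean())


# -- phantom rendering -----------------------------------------------------

def generate_phantom(class_label: str, spec: PhantomSpec,
                     rng: np.random.Generator,
                     patient_id: str = "P0000") -> ContouredCase:
    """Render one contoured phantom case of the requested class."""
    if class_label not in CLASS_LABELS:
        raise InvalidClassError(
            f"unknown class label {class_label!r}; expected one of {CLASS_LABELS}"
        )
    side = spec.image_side
    lo, hi = spec.lesion_radius_range
    r = float(rng.uniform(lo, hi))
    cy = float(rng.uniform(0.32 * side, 0.68 * side))
    cx = float(rng.uniform(0.32 * side, 0.68 * side))

    yy, xx = np.mgrid[0:side, 0:side].astype(float)
    dy, dx = yy - cy, xx - cx
    dist = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)

    prov: dict = {"radius": r, "center": (cy, cx), "class": class_label}
    if class_label == "luminal":
        ecc = float(rng.uniform(0.12, 0.3))
        phi = float(rng.uniform(0, math.pi))
        a, b = r * (1 + ecc), r * (1 - ecc)
        base = _ellipse_radius(theta, a, b, phi)
        freqs = rng.choice(np.arange(6, 13), size=3, replace=False)
        phases = rng.uniform(0, 2 * math.pi, size=3)
        amps = rng.uniform(0.5, 1.0, size=3)
        s = np.zeros_like(theta)
        for f, p, w in zip(freqs, phases, amps):
            s += w * np.sin(f * theta + p)
        smax = np.abs(s).max()
        if smax > 0:
            s /= smax
        rho = base * (1.0 + spec.spiculation_amplitude * s)
        prov.update(axes=(a, b), orientation=phi,
                    spiculation=spec.spiculation_amplitude)
    else:
        rho = np.full_like(theta, r)
        prov.update(ring_contrast=spec.ring_contrast)

    mask = dist <= rho
    mask = _largest_4connected(mask, cy, cx)
    mask = ndimage.binary_fill_holes(mask)

    # intensity model: textured background + lesion contrast per channel
    interior = ndimage.gaussian_filter(mask.astype(float), 1.0)
    images: list[np.ndarray] = []
    if class_label == "non_luminal":
        ring_band = mask & (dist >= 0.7 * r)
        ring = ndimage.gaussian_filter(ring_band.astype(float), 1.0)
    else:
        ring = None
    for c in range(spec.n_channels):
        gain = CHANNEL_GAINS[c % len(CHANNEL_GAINS)]
        img = 0.35 + spec.background_noise_scale * _smooth_noise(rng, side)
        img = img + 0.18 * gain * interior
        if ring is not None:
            img = img + spec.ring_contrast * gain * ring
        img = img + 0.01 * rng.normal(size=img.shape)  # acquisition noise
        images.append(np.clip(img, 0.0, 1.0).astype(np.float32))

    tumor_size = max_diameter_px(mask) * PIXEL_SPACING_MM
    menarche_age = int(rng.integers(11, 18))  # both sides of the 14 y threshold

    if class_label == "luminal":
        label4 = "luminalA" if rng.random() < 38 / 85 else "luminalB"
    else:
        label4 = "HER2" if rng.random() < 47 / 75 else "TN"

    return ContouredCase(
        patient_id=patient_id,
        images=images,
        mask=mask,
        subtype_label=class_label,
        subtype_label4=label4,
        menarche_age=menarche_age,
        tumor_size=tumor_size,
        provenance=prov,
    )


def generate_cohort(n_cases: int = 160, class_balance: float = 84 / 160,
                    spec: PhantomSpec | None = None,
                    seed: int | None = None
                    ) -> tuple[list[ContouredCase], pd.DataFrame]:
    """Generate a phantom cohort and its metadata table.

    ``class_balance`` is the luminal fraction; the default reproduces the
    84 luminal : 76 non-luminal composition of a 160-case clinical cohort.
    Returns the cases and a DataFrame with one row per patient.
    """
    if n_cases < 2:
        raise ValueError("n_cases must be >= 2")
    spec = spec or PhantomSpec()
    if seed is None:
        seed = spec.seed
    n_luminal = int(round(n_cases * class_balance))
    n_luminal = min(max(n_luminal, 1), n_cases - 1)  # at least one per class
    labels = ["luminal"] * n_luminal + ["non_luminal"] * (n_cases - n_luminal)

    rng = np.random.default_rng(seed)
    cases = []
    for i, lab in enumerate(labels):
        cases.append(generate_phantom(lab, spec, rng, patient_id=f"P{i:04d}"))
    meta = cohort_metadata(cases)
    return cases, meta


def cohort_metadata(cases: list[ContouredCase]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [c.patient_id for c in cases],
            "label": [c.subtype_label for c in cases],
            "label4": [c.subtype_label4 for c in cases],
            "menarche_age": [c.menarche_age for c in cases],
            "tumor_size_mm": [round(c.tumor_size, 2) for c in cases],
        }
    )


# -- disk round trip -------------------------------------------------------

def save_cohort(cases: list[ContouredCase], meta: pd.DataFrame, outdir) -> None:
    """Write per-channel PNGs, mask PNGs and the metadata CSV."""
    from pathlib import Path

    from PIL import Image

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for case in cases:
        for c, img in enumerate(case.images):
            arr = np.clip(img * 255.0, 0, 255).astype(np.uint8)
            Image.fromarray(arr).save(outdir / f"{case.patient_id}_ch{c}.png")
        Image.fromarray((case.mask * 255).astype(np.uint8)).save(
            outdir / f"{case.patient_id}_mask.png"
        )
    meta.to_csv(outdir / "metadata.csv", index=False)


def load_cohort(indir) -> tuple[list[ContouredCase], pd.DataFrame]:
    """Read a cohort written by :func:`save_cohort`."""
    from pathlib import Path

    from PIL import Image

    indir = Path(indir)
    meta = pd.read_csv(indir / "metadata.csv")
    cases = []
    for row in meta.itertuples():
        pid = row.patient_id
        images = []
        c = 0
        while (indir / f"{pid}_ch{c}.png").exists():
            images.append(
                np.asarray(Image.open(indir / f"{pid}_ch{c}.png"), dtype=np.float32)
                / 255.0
            )
            c += 1
        mask_path = indir / f"{pid}_mask.png"
        if not mask_path.exists():
            raise FileNotFoundError(f"missing mask for case {pid}: {mask_path}")
        mask = np.asarray(Image.open(mask_path)) > 127
        if not mask.any():
            raise ValueError(f"corrupt mask for case {pid}: no positive pixel")
        cases.append(
            ContouredCase(
                patient_id=pid,
                images=images,
                mask=mask,
                subtype_label=row.label,
                subtype_label4=row.label4,
                menarche_age=int(row.menarche_age),
                tumor_size=float(row.tumor_size_mm),
            )
        )
    return cases, meta


__all__ = [
    "CLASS_LABELS",
    "SUBTYPES",
    "PIXEL_SPACING_MM",
    "PhantomSpec",
    "ContouredCase",
    "InvalidClassError",
    "generate_phantom",
    "generate_cohort",
    "cohort_metadata",
    "boundary_roughness",
    "ring_intensity_contrast",
    "max_diameter_px",
    "save_cohort",
    "load_cohort",
]
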