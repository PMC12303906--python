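"""Synthetic B-mode-like carotid plaque phantoms with exact ground truth.

Each phantom holds one elliptical plaque on a darker vessel background.
The rendering pipeline emulates the properties that make clinical carotid
ultrasound hard to segment: low plaque/background contrast (a small
intensity offset), blurred edges (Gaussian blur), intense multiplicative
speckle (unit-mean Gamma field with ``looks`` L, variance 1/L), and an
occasional hypoechoic shadow band below the plaque mimicking calcification
shadowing.  Ground-truth diameters are the full ellipse axes (2a, 2b) in
mm, known analytically — regression targets carry no measurement noise.

Generation is a pure function of (config.seed, sample_index), so a whole
dataset is reproducible from its config alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image
from scipy import ndimage

from .manifest import COLUMNS, DatasetManifest, ManifestError

__all__ = [
    "PhantomConfig",
    "PhantomSample",
    "GenerationError",
    "generate_sample",
    "generate_dataset",
    "apply_speckle",
    "write_dataset",
]

#: multiplicative attenuation inside an acoustic shadow band
SHADOW_FACTOR = 0.3
#: rows over which the shadow ramps from none to full attenuation
SHADOW_FEATHER_ROWS = 6
#: columns of linear lateral feathering at the shadow edges
SHADOW_FEATHER_COLS = 3
#: base echo intensity of the vessel background
BACKGROUND_LEVEL = 0.35


class GenerationError(ValueError):
    pass


@dataclass
class PhantomConfig:
    """Geometry, noise and artifact settings of the phantom generator.

    ``plaque_long_axis_range_mm`` bounds the *semi*-axis a; the recorded
    long diameter is 2a.  ``speckle_looks`` is the Gamma shape L (smaller =
    noisier; variance of the speckle field is 1/L); ``math.inf`` disables
    speckle entirely.
    """

    image_height_px: int = 256
    image_width_px: int = 256
    pixel_spacing_mm: float = 0.1
    plaque_long_axis_range_mm: tuple[float, float] = (2.0, 10.0)
    plaque_aspect_ratio_range: tuple[float, float] = (0.4, 0.8)
    plaque_contrast: float = 0.25
    speckle_looks: float = 4.0
    edge_blur_sigma_px: float = 1.5
    shadow_probability: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height_px <= 0 or self.image_width_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel spacing must be positive")
        for name in ("plaque_long_axis_range_mm", "plaque_aspect_ratio_range"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name}: min must not exceed max")
        lo, hi = self.plaque_aspect_ratio_range
        if not (0 < lo and hi <= 1):
            raise ValueError("aspect ratios must lie in (0, 1]")
        if self.plaque_long_axis_range_mm[0] <= 0:
            raise ValueError("plaque axes must be positive")
        if not 0 < self.plaque_contrast <= 1:
            raise ValueError("plaque_contrast must lie in (0, 1]")
        if self.speckle_looks <= 0:
            raise ValueError("speckle_looks must be positive")
        if self.edge_blur_sigma_px < 0:
            raise ValueError("edge_blur_sigma_px must be nonnegative")
        if not 0 <= self.shadow_probability <= 1:
            raise ValueError("shadow_probability must lie in [0, 1]")


@dataclass
class PhantomSample:
    """One phantom: image, label mask and analytic ground truth."""

    image: np.ndarray  # (H, W) float in [0, 1]
    mask: np.ndarray  # (H, W) uint8 in {0, 1}
    long_diameter_mm: float
    short_diameter_mm: float
    pixel_spacing_mm: float
    sample_id: str

    def __post_init__(self) -> None:
        if not self.long_diameter_mm >= self.short_diameter_mm > 0:
            raise ValueError("require long >= short > 0")
        if not (self.mask != 0).any():
            raise ValueError("mask contains no plaque pixel")


def apply_speckle(image: np.ndarray, looks: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Multiply by an i.i.d. unit-mean Gamma(L, 1/L) speckle field.

    ``looks == inf`` disables speckle (the field degenerates to 1).  The
    result is clipped back to [0, 1].
    """
    if not looks > 0:
        raise ValueError("looks must be positive")
    if math.isinf(looks):
        return image.copy()
    s = rng.gamma(shape=looks, scale=1.0 / looks, size=image.shape)
    return np.clip(image * s, 0.0, 1.0)


def _sample_rng(config: PhantomConfig, sample_index: int) -> np.random.Generator:
    return np.random.default_rng([config.seed & 0x7FFFFFFF, sample_index])


def generate_sample(config: PhantomConfig, sample_index: int) -> PhantomSample:
    """Render one phantom; deterministic for fixed (config.seed, index)."""
    if sample_index < 0:
        raise ValueError("sample_index must be >= 0")
    rng = _sample_rng(config, sample_index)
    h, w = config.image_height_px, config.image_width_px
    s = config.pixel_spacing_mm

    a_mm = rng.uniform(*config.plaque_long_axis_range_mm)
    aspect = rng.uniform(*config.plaque_aspect_ratio_range)
    b_mm = a_mm * aspect
    theta = rng.uniform(0.0, math.pi)
    a_px, b_px = a_mm / s, b_mm / s

    # axis-aligned half extents of the rotated ellipse
    ex = math.hypot(a_px * math.cos(theta), b_px * math.sin(theta))
    ey = math.hypot(a_px * math.sin(theta), b_px * math.cos(theta))
    margin = 2.0
    if 2 * ex + 2 * margin > w or 2 * ey + 2 * margin > h:
        raise GenerationError(
            f"plaque long axis {2 * a_mm:.2f} mm does not fit a "
            f"{h}x{w} image at {s} mm/px")
    cx = rng.uniform(ex + margin, w - 1 - ex - margin)
    cy = rng.uniform(ey + margin, h - 1 - ey - margin)

    yy, xx = np.mgrid[0:h, 0:w]
    xr = (xx - cx) * math.cos(theta) + (yy - cy) * math.sin(theta)
    yr = -(xx - cx) * math.sin(theta) + (yy - cy) * math.cos(theta)
    mask = ((xr / a_px) ** 2 + (yr / b_px) ** 2 <= 1.0).astype(np.uint8)

    img = np.full((h, w), BACKGROUND_LEVEL, dtype=np.float64)
    img[mask == 1] += config.plaque_contrast

    shadow = rng.uniform() < config.shadow_probability
    if config.edge_blur_sigma_px > 0:
        img = ndimage.gaussian_filter(img, config.edge_blur_sigma_px)
    img = apply_speckle(img, config.speckle_looks, rng)
    if shadow:
        img = _apply_shadow(img, mask)
    img = np.clip(img, 0.0, 1.0)

    return PhantomSample(
        image=img.astype(np.float64),
        mask=mask,
        long_diameter_mm=2 * a_mm,
        short_diameter_mm=2 * b_mm,
        pixel_spacing_mm=s,
        sample_id=f"phantom_{sample_index:05d}",
    )


def _apply_shadow(img: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Hypoechoic vertical band below the plaque with linear feathering."""
    rows, cols = np.nonzero(mask)
    r0 = rows.max()
    c0, c1 = cols.min(), cols.max()
    h, w = img.shape
    if r0 + 1 >= h:
        return img
    depth = np.arange(1, h - r0, dtype=float)
    ramp = 1.0 - (1.0 - SHADOW_FACTOR) * np.minimum(depth / SHADOW_FEATHER_ROWS, 1.0)
    # shadow strength across columns: full inside the plaque's span,
    # linear feather just outside it
    strength = np.zeros(w)
    strength[c0:c1 + 1] = 1.0
    for k in range(1, SHADOW_FEATHER_COLS + 1):
        frac = 1.0 - k / (SHADOW_FEATHER_COLS + 1)
        for c in (c0 - k, c1 + k):
            if 0 <= c < w:
                strength[c] = max(strength[c], frac)
    atten = 1.0 - strength[None, :] * (1.0 - ramp[:, None])
    out = img.copy()
    out[r0 + 1:, :] *= atten
    return out


def generate_dataset(config: PhantomConfig, n_samples: int) -> list[PhantomSample]:
    """The full dataset is a pure function of (config, n_samples)."""
    return [generate_sample(config, i) for i in range(n_samples)]


def write_dataset(samples: Sequence[PhantomSample], directory,
                  provenance: str = "") -> DatasetManifest:
    """Write 8-bit PNG images/masks plus a CSV+JSON manifest.

    Mask PNGs store labels 0/1 verbatim, so the round trip is exact; image
    intensities survive to within 8-bit quantization.
    """
    import pandas as pd

    directory = Path(directory)
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ManifestError("duplicate sample_id in dataset")
    (directory / "images").mkdir(parents=True, exist_ok=True)
    (directory / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for smp in samples:
        img8 = np.round(np.clip(smp.image, 0, 1) * 255).astype(np.uint8)
        ipath = Path("images") / f"{smp.sample_id}.png"
        mpath = Path("masks") / f"{smp.sample_id}.png"
        Image.fromarray(img8, mode="L").save(directory / ipath)
        Image.fromarray(smp.mask.astype(np.uint8), mode="L").save(directory / mpath)
        rows.append({
            "sample_id": smp.sample_id,
            "image_path": str(ipath),
            "mask_path": str(mpath),
            "long_mm": smp.long_diameter_mm,
            "short_mm": smp.short_diameter_mm,
            "spacing_mm_per_px": smp.pixel_spacing_mm,
            "split": "unassigned",
        })
    df = pd.DataFrame(rows, columns=COLUMNS)
    man = DatasetManifest(rows=df, root=directory, provenance=provenance)
    man.write(directory)
    return man
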