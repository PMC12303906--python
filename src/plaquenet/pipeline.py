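"""Dataset preparation: the 7:1:2 split, preprocessing, and augmentation.

The split uses a seeded random permutation with floor rounding for train
and validation and the remainder to test — with 287 images at 7:1:2 this
yields (200, 28, 59).  Training images are expanded by random elastic
deformation, rotation, scaling and flipping; the default plan emits 7
variants per image, an 8-fold training set.  Augmented samples re-measure
their diameters from the transformed mask, so even deformations with no
closed-form diameter law stay consistent with the measurement oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from skimage import exposure

from . import morphometry
from .manifest import COLUMNS, DatasetManifest, ManifestError
from .phantom import PhantomSample

__all__ = [
    "SplitSpec",
    "AugmentationPlan",
    "SplitError",
    "AugmentationError",
    "split_manifest",
    "preprocess_image",
    "elastic_deform",
    "rotate_sample",
    "scale_sample",
    "flip_sample",
    "augment_manifest",
]

OPERATIONS = ("elastic", "rotate", "scale", "flip_h", "flip_v")


class SplitError(ValueError):
    pass


class AugmentationError(RuntimeError):
    pass


@dataclass
class SplitSpec:
    ratios: tuple[int, int, int] = (7, 1, 2)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.ratios) or sum(self.ratios) <= 0:
            raise ValueError("ratios must be nonnegative with positive sum")


@dataclass
class AugmentationPlan:
    """What to generate per training image and from which parameter ranges.

    ``variants_per_image = 7`` gives the 8-fold expansion (original + 7).
    Rotation is in degrees, scale is a multiplicative factor, elastic
    (alpha, sigma) are displacement amplitude and smoothing in pixels.
    """

    variants_per_image: int = 7
    operations: tuple[str, ...] = OPERATIONS
    rotation_deg: tuple[float, float] = (-15.0, 15.0)
    scale_range: tuple[float, float] = (0.9, 1.1)
    elastic_alpha: float = 30.0
    elastic_sigma: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variants_per_image < 0:
            raise ValueError("variants_per_image must be >= 0")
        bad = set(self.operations) - set(OPERATIONS)
        if bad:
            raise ValueError(f"unknown operations: {sorted(bad)}")
        if self.variants_per_image > 0 and not self.operations:
            raise ValueError("need at least one operation to generate variants")


def split_manifest(manifest: DatasetManifest, spec: SplitSpec) -> DatasetManifest:
    """Randomly partition unassigned rows into train/val/test.

    Counts are ``floor(n * r/sum)`` for train and val; test takes the
    remainder.  Deterministic for a fixed seed.
    """
    rows = manifest.rows
    if (rows["split"] != "unassigned").any():
        raise SplitError("manifest already contains split assignments")
    n = len(rows)
    nonzero_parts = sum(1 for r in spec.ratios if r > 0)
    if n < nonzero_parts:
        raise SplitError(f"cannot split {n} rows into {nonzero_parts} nonempty parts")
    total = sum(spec.ratios)
    n_train = int(np.floor(n * spec.ratios[0] / total))
    n_val = int(np.floor(n * spec.ratios[1] / total))
    perm = np.random.default_rng(spec.seed).permutation(n)
    split = np.empty(n, dtype=object)
    split[perm[:n_train]] = "train"
    split[perm[n_train:n_train + n_val]] = "val"
    split[perm[n_train + n_val:]] = "test"
    out = rows.copy()
    out["split"] = split
    return DatasetManifest(rows=out, root=manifest.root,
                           provenance=manifest.provenance
                           + f" | split ratios={spec.ratios} seed={spec.seed}")


def preprocess_image(image: np.ndarray, method: str = "clahe") -> np.ndarray:
    """Min-max normalize to [0, 1], then enhance contrast.

    A constant image maps to all zeros (no division by zero).  ``method``
    is ``"clahe"`` (contrast-limited adaptive histogram equalization, the
    default), ``"hist"`` (plain histogram equalization) or ``"none"``.
    """
    if method not in ("clahe", "hist", "none"):
        raise ValueError(f"unknown contrast method {method!r}")
    image = np.asarray(image, dtype=np.float64)
    if image.size == 0:
        raise ValueError("empty image")
    lo, hi = image.min(), image.max()
    if hi == lo:
        return np.zeros_like(image)
    x = (image - lo) / (hi - lo)
    if method == "clahe":
        x = exposure.equalize_adapthist(x, clip_limit=0.02)
    elif method == "hist":
        x = exposure.equalize_hist(x)
    return np.clip(x, 0.0, 1.0)


def _remeasure(sample: PhantomSample, image: np.ndarray,
               mask: np.ndarray, suffix: str) -> PhantomSample:
    if not (mask != 0).any():
        raise AugmentationError("transform removed the plaque from the frame")
    pair = morphometry.measure_diameters(mask, sample.pixel_spacing_mm)
    return PhantomSample(
        image=np.clip(image, 0.0, 1.0),
        mask=(mask != 0).astype(np.uint8),
        long_diameter_mm=pair.long_mm,
        short_diameter_mm=pair.short_mm,
        pixel_spacing_mm=sample.pixel_spacing_mm,
        sample_id=sample.sample_id + suffix,
    )


def elastic_deform(sample: PhantomSample, alpha: float, sigma: float,
                   rng: np.random.Generator) -> PhantomSample:
    """Warp image and mask by one smooth random displacement field.

    The field is i.i.d. uniform noise smoothed with a Gaussian of width
    ``sigma`` px and scaled to amplitude ``alpha`` px; images interpolate
    linearly, masks by nearest neighbor (labels stay binary).  Diameters
    are re-measured from the warped mask.  ``alpha = 0`` is the identity.
    """
    if alpha < 0 or sigma <= 0:
        raise ValueError("require alpha >= 0 and sigma > 0")
    if alpha == 0:
        return replace(sample)  # zero displacement: exact identity
    h, w = sample.mask.shape
    dy = ndimage.gaussian_filter(rng.uniform(-1, 1, (h, w)), sigma) * alpha
    dx = ndimage.gaussian_filter(rng.uniform(-1, 1, (h, w)), sigma) * alpha
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    coords = np.array([yy + dy, xx + dx])
    img = ndimage.map_coordinates(sample.image, coords, order=1, mode="reflect")
    msk = ndimage.map_coordinates(sample.mask, coords, order=0, mode="constant", cval=0)
    return _remeasure(sample, img, msk, "_elastic")


def rotate_sample(sample: PhantomSample, degrees: float) -> PhantomSample:
    """Rotate about the image center (linear/nearest, constant padding)."""
    img = ndimage.rotate(sample.image, degrees, reshape=False, order=1,
                         mode="constant", cval=float(sample.image.min()))
    msk = ndimage.rotate(sample.mask, degrees, reshape=False, order=0,
                         mode="constant", cval=0)
    return _remeasure(sample, img, msk, "_rot")


def scale_sample(sample: PhantomSample, factor: float) -> PhantomSample:
    """Zoom about the image center; true diameters scale by ``factor``."""
    if factor <= 0:
        raise ValueError("scale factor must be positive")
    if factor == 1.0:
        return replace(sample)
    h, w = sample.mask.shape
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    matrix = np.eye(2) / factor
    offset = center - matrix @ center
    img = ndimage.affine_transform(sample.image, matrix, offset=offset, order=1,
                                   mode="constant", cval=float(sample.image.min()))
    msk = ndimage.affine_transform(sample.mask, matrix, offset=offset, order=0,
                                   mode="constant", cval=0)
    return _remeasure(sample, img, msk, "_scale")


def flip_sample(sample: PhantomSample, axis: str) -> PhantomSample:
    """Mirror horizontally or vertically; diameters are invariant."""
    if axis == "horizontal":
        img, msk = sample.image[:, ::-1], sample.mask[:, ::-1]
    elif axis == "vertical":
        img, msk = sample.image[::-1, :], sample.mask[::-1, :]
    else:
        raise ValueError("axis must be 'horizontal' or 'vertical'")
    return _remeasure(sample, img.copy(), msk.copy(), "_flip")


def _apply_random_op(sample: PhantomSample, plan: AugmentationPlan,
                     rng: np.random.Generator) -> PhantomSample:
    op = plan.operations[int(rng.integers(len(plan.operations)))]
    if op == "elastic":
        return elastic_deform(sample, plan.elastic_alpha, plan.elastic_sigma, rng)
    if op == "rotate":
        return rotate_sample(sample, float(rng.uniform(*plan.rotation_deg)))
    if op == "scale":
        return scale_sample(sample, float(rng.uniform(*plan.scale_range)))
    if op == "flip_h":
        return flip_sample(sample, "horizontal")
    return flip_sample(sample, "vertical")


def augment_manifest(manifest: DatasetManifest, plan: AugmentationPlan,
                     splits: tuple[str, ...] = ("train",)) -> DatasetManifest:
    """Expand each training row into the original + N augmented variants.

    Augmented PNGs are written next to the originals; validation and test
    rows pass through untouched.  Only the training split may be augmented
    (augmenting evaluation data would leak the protocol).
    """
    if set(splits) != {"train"}:
        raise ManifestError("augmentation may only touch the train split")
    rng = np.random.default_rng(plan.seed)
    new_rows = []
    for row in manifest.rows.itertuples(index=False):
        new_rows.append(row._asdict())
        if row.split != "train" or plan.variants_per_image == 0:
            continue
        base = PhantomSample(
            image=manifest.load_image(row),
            mask=manifest.load_mask(row),
            long_diameter_mm=row.long_mm,
            short_diameter_mm=row.short_mm,
            pixel_spacing_mm=row.spacing_mm_per_px,
            sample_id=row.sample_id,
        )
        for k in range(plan.variants_per_image):
            var = None
            for _attempt in range(5):
                try:
                    var = _apply_random_op(base, plan, rng)
                    break
                except AugmentationError:
                    continue
            if var is None:  # fall back to a flip, which cannot fail
                var = flip_sample(base, "horizontal")
            sid = f"{row.sample_id}_aug{k}"
            ipath = Path("images") / f"{sid}.png"
            mpath = Path("masks") / f"{sid}.png"
            img8 = np.round(np.clip(var.image, 0, 1) * 255).astype(np.uint8)
            Image.fromarray(img8, mode="L").save(manifest.root / ipath)
            Image.fromarray(var.mask, mode="L").save(manifest.root / mpath)
            new_rows.append({
                "sample_id": sid,
                "image_path": str(ipath),
                "mask_path": str(mpath),
                "long_mm": var.long_diameter_mm,
                "short_mm": var.short_diameter_mm,
                "spacing_mm_per_px": var.pixel_spacing_mm,
                "split": "train",
            })
    df = pd.DataFrame(new_rows, columns=COLUMNS)
    return DatasetManifest(rows=df, root=manifest.root,
                           provenance=manifest.provenance
                           + f" | augmented x{plan.variants_per_image + 1} seed={plan.seed}")
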