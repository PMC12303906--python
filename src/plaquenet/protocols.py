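"""Canned experiment protocols at desk (CPU) scale.

Two ready-made studies over the phantom generator:

* :func:`smoke_experiment` — generate a phantom dataset, split it 7:1:2,
  train the dual-branch network and report test segmentation and
  size-regression metrics.
* :func:`joint_vs_baseline` — paired comparison, on identical heavy-speckle
  data, of the joint regression branch against the segment-then-measure
  baseline for diameter prediction.

Problem sizes here are deliberately small (64x64 images, an 8-channel
trunk, ~160 phantoms, a dozen epochs) so a full study runs in minutes on
one CPU core; every knob is a parameter for larger runs.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass
from pathlib import Path

from .harness import (
    EvalReport,
    TrainConfig,
    baseline_unet_measure,
    evaluate,
    train_once,
)
from .manifest import DatasetManifest
from .model_core import ModelConfig
from .objective import LossWeights
from .phantom import PhantomConfig, generate_dataset, write_dataset
from .pipeline import AugmentationPlan, SplitSpec, augment_manifest, split_manifest

__all__ = [
    "smoke_phantom_config",
    "smoke_train_config",
    "build_smoke_dataset",
    "smoke_experiment",
    "joint_vs_baseline",
]


def smoke_phantom_config(seed: int, speckle_looks: float = 4.0) -> PhantomConfig:
    """64x64 phantoms with plaque diameters of 2-5.2 mm at 0.12 mm/px."""
    return PhantomConfig(
        image_height_px=64,
        image_width_px=64,
        pixel_spacing_mm=0.12,
        plaque_long_axis_range_mm=(1.0, 2.6),
        plaque_aspect_ratio_range=(0.45, 0.85),
        plaque_contrast=0.25,
        speckle_looks=speckle_looks,
        edge_blur_sigma_px=1.0,
        shadow_probability=0.25,
        seed=seed,
    )


def smoke_train_config(seed: int, epochs: int = 12) -> TrainConfig:
    """Adam lr 0.001, batch 16, small dual-branch trunk (depth 3, base 8)."""
    return TrainConfig(
        learning_rate=1e-3,
        batch_size=16,
        epochs=epochs,
        early_stopping_patience=15,
        repetitions=1,
        seed=seed,
        loss=LossWeights(alpha=1.0, beta=1.0, mode="fixed"),
        model=ModelConfig(depth=3, base_channels=8, regression_hidden_units=32,
                          eca_conv_layers=2, eca_kernel_size="adaptive"),
        input_size=(64, 64),
        contrast_method="clahe",
        standardize_targets=True,
    )


def build_smoke_dataset(directory, seed: int, n: int = 160,
                        speckle_looks: float = 4.0,
                        augment_variants: int = 2) -> DatasetManifest:
    """Generate, write, 7:1:2-split and augment a phantom dataset.

    ``augment_variants`` extra variants per training image regularize the
    small training split (the full-scale protocol uses 7, an 8-fold set).
    """
    cfg = smoke_phantom_config(seed, speckle_looks)
    man = write_dataset(generate_dataset(cfg, n), directory,
                        provenance=f"smoke dataset n={n} seed={seed} "
                                   f"looks={speckle_looks}")
    man = split_manifest(man, SplitSpec(ratios=(7, 1, 2), seed=seed))
    if augment_variants > 0:
        man = augment_manifest(
            man, AugmentationPlan(variants_per_image=augment_variants,
                                  seed=seed))
    man.write(directory)
    return man


def smoke_experiment(seed: int, work_dir=None, epochs: int = 10,
                     n: int = 160, speckle_looks: float = 4.0,
                     augment_variants: int = 2) -> EvalReport:
    """Train once on a fresh phantom dataset and evaluate on its test split."""
    ctx = tempfile.TemporaryDirectory() if work_dir is None else None
    root = Path(ctx.name) if ctx else Path(work_dir)
    try:
        man = build_smoke_dataset(root, seed, n=n, speckle_looks=speckle_looks,
                                  augment_variants=augment_variants)
        cfg = smoke_train_config(seed, epochs=epochs)
        result = train_once(man, cfg)
        return evaluate(result, man, cfg, split="test")
    finally:
        if ctx:
            ctx.cleanup()


@dataclass
class PairedReplicate:
    joint_mae: float
    baseline_mae: float
    baseline_missing: int


def joint_vs_baseline(seed: int, replicates: int = 3,
                      speckle_looks: float = 1.0,
                      epochs: int = 8, n: int = 160,
                      augment_variants: int = 1) -> list[PairedReplicate]:
    """Paired heavy-speckle replicates of joint vs. segment-then-measure.

    Each replicate draws its own dataset and weight initialization (offset
    seeds); both arms see identical data.  The reported MAE is the mean of
    the long- and short-diameter MAEs on the test split.
    """
    out = []
    for r in range(replicates):
        rep_seed = seed + 101 * r
        with tempfile.TemporaryDirectory() as d:
            man = build_smoke_dataset(Path(d), rep_seed, n=n,
                                      speckle_looks=speckle_looks,
                                      augment_variants=augment_variants)
            cfg = smoke_train_config(rep_seed, epochs=epochs)
            joint = evaluate(train_once(man, cfg), man, cfg, split="test")
            base = baseline_unet_measure(man, cfg)
        joint_mae = 0.5 * (joint.reg_long.mae + joint.reg_short.mae)
        if base.reg_long is None:
            base_mae = float("inf")  # baseline produced no measurable masks
        else:
            base_mae = 0.5 * (base.reg_long.mae + base.reg_short.mae)
        out.append(PairedReplicate(joint_mae=joint_mae, baseline_mae=base_mae,
                                   baseline_missing=base.n_missing))
    return out
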