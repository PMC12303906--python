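"""Experiment orchestration: training, checkpointing, repeated evaluation.

Protocol: Adam at the configured learning rate, mini-batches drawn in a
seeded random order, per-epoch validation of the total loss, best-on-
validation checkpointing with early stopping, and N independent
repetitions (fixed data split, re-initialized weights) aggregated as
mean +/- standard deviation (n-1 denominator).  A segment-then-measure
baseline — the same trunk without attention or a regression branch, its
diameters read off the predicted mask by morphometry — supports the joint
vs. pipelined size-prediction comparison.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.transform import resize
from threadpoolctl import threadpool_limits

from . import morphometry
from .manifest import DatasetManifest
from .metrics import (
    RegMetrics,
    SegMetrics,
    confusion,
    regression_metrics,
    seg_metrics,
)
from .model_core import DualPlaqueNet, ModelConfig, build_model
from .nn import Adam
from .objective import LossWeights, UncertaintyBalancer, joint_loss, segmentation_loss
from .pipeline import preprocess_image

__all__ = [
    "TrainConfig",
    "TrainResult",
    "EvalReport",
    "RunReport",
    "load_split_arrays",
    "train_once",
    "evaluate",
    "evaluate_predictions",
    "run_experiment",
    "baseline_unet_measure",
    "check_no_leakage",
    "save_result",
    "load_result",
]


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 16
    epochs: int = 100
    early_stopping_patience: float = 15
    repetitions: int = 10
    seed: int = 0
    loss: LossWeights = field(default_factory=LossWeights)
    model: ModelConfig = field(default_factory=ModelConfig)
    input_size: tuple[int, int] = (96, 96)
    contrast_method: str = "clahe"
    standardize_targets: bool = True

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.batch_size, self.epochs,
               self.repetitions) <= 0:
            raise ValueError("learning rate, batch size, epochs, repetitions "
                             "must be positive")
        if self.early_stopping_patience <= 0:
            raise ValueError("patience must be positive (math.inf disables)")
        step = 2 ** self.model.depth
        if self.input_size[0] % step or self.input_size[1] % step:
            raise ValueError(f"input_size must be divisible by 2^depth={step}")


@dataclass
class TrainResult:
    state: dict
    model_config: ModelConfig
    curves: pd.DataFrame
    target_mu: np.ndarray
    target_sd: np.ndarray
    best_epoch: int
    best_val_loss: float
    epochs_run: int


@dataclass
class EvalReport:
    seg: SegMetrics
    reg_long: RegMetrics | None
    reg_short: RegMetrics | None
    n_images: int
    n_missing: int = 0


@dataclass
class RunReport:
    per_repetition: list[dict]
    aggregate: dict[str, tuple[float, float]]  # name -> (mean, std)
    notes: str = ""


def check_no_leakage(manifest: DatasetManifest) -> None:
    """Assert no augmented row descends from a val/test sample."""
    rows = manifest.rows
    aug = rows[rows["sample_id"].str.contains("_aug")]
    parents = aug["sample_id"].str.replace(r"_aug\d+$", "", regex=True)
    split_of = dict(zip(rows["sample_id"], rows["split"]))
    for pid, s in zip(parents, aug["split"]):
        if split_of.get(pid) in ("val", "test") or s != "train":
            raise AssertionError(f"augmented sample leaks from {pid} ({split_of.get(pid)})")


def load_split_arrays(manifest: DatasetManifest, split: str,
                      config: TrainConfig):
    """Images (preprocessed, resized), masks, diameters, effective spacing.

    Returns ``(X, Y, D, S)`` with X (N,1,H,W) float32 in [0,1], Y (N,H,W)
    uint8, D (N,2) mm as (long, short), and S (N,) mm/px in the resized
    pixel grid (original spacing scaled by the resize ratio).
    """
    rows = manifest.subset(split)
    h, w = config.input_size
    xs, ys, ds, ss = [], [], [], []
    for row in rows.itertuples(index=False):
        img = manifest.load_image(row)
        msk = manifest.load_mask(row)
        ratio = 0.5 * (img.shape[0] / h + img.shape[1] / w)
        if img.shape != (h, w):
            img = resize(img, (h, w), order=1, preserve_range=True,
                         anti_aliasing=True)
            msk = resize(msk, (h, w), order=0, preserve_range=True,
                         anti_aliasing=False).astype(np.uint8)
        img = preprocess_image(img, config.contrast_method)
        xs.append(img.astype(np.float32))
        ys.append(msk)
        ds.append((row.long_mm, row.short_mm))
        ss.append(row.spacing_mm_per_px * ratio)
    if not xs:
        raise ValueError(f"split {split!r} is empty")
    X = np.stack(xs)[:, None]
    return X, np.stack(ys), np.asarray(ds, float), np.asarray(ss, float)


def _epoch_loss(model: DualPlaqueNet, X, Y, D, weights: LossWeights,
                batch: int) -> tuple[float, float, float]:
    """Mean (total, seg, size) loss over a split in inference mode."""
    segs, sizes, ns = [], [], []
    for i in range(0, len(X), batch):
        out = model.forward(X[i:i + batch], train=False)
        seg = segmentation_loss(out.segmentation_scores, Y[i:i + batch])
        if model.fc1 is not None:
            size = float(np.mean((out.diameter_predictions - D[i:i + batch]) ** 2))
        else:
            size = 0.0
        segs.append(seg)
        sizes.append(size)
        ns.append(len(X[i:i + batch]))
    n = sum(ns)
    seg = sum(s * k for s, k in zip(segs, ns)) / n
    size = sum(s * k for s, k in zip(sizes, ns)) / n
    return weights.alpha * seg + weights.beta * size, seg, size


def train_once(manifest: DatasetManifest, config: TrainConfig,
               repetition_index: int = 0) -> TrainResult:
    """One seeded training session with best-on-validation checkpointing."""
    with threadpool_limits(limits=1):
        return _train_once(manifest, config, repetition_index)


def _train_once(manifest: DatasetManifest, config: TrainConfig,
                repetition_index: int = 0) -> TrainResult:
    check_no_leakage(manifest)
    rep_seed = config.seed + repetition_index
    rng = np.random.default_rng(rep_seed)
    Xtr, Ytr, Dtr, _ = load_split_arrays(manifest, "train", config)
    Xva, Yva, Dva, _ = load_split_arrays(manifest, "val", config)

    mu = np.zeros(2)
    sd = np.ones(2)
    if config.standardize_targets and config.model.regression_branch:
        mu = Dtr.mean(axis=0)
        sd = np.where(Dtr.std(axis=0) > 0, Dtr.std(axis=0), 1.0)
    Ztr = (Dtr - mu) / sd
    Zva = (Dva - mu) / sd

    model = build_model(config.model, seed=rep_seed)
    opt = Adam(model.params(), lr=config.learning_rate)
    balancer = UncertaintyBalancer() if config.loss.mode == "auto" else None

    curves = []
    best_state, best_val, best_epoch = None, math.inf, -1
    bad_epochs = 0
    n = len(Xtr)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        tr_tot = tr_seg = tr_size = 0.0
        nb = 0
        for i in range(0, n, config.batch_size):
            idx = order[i:i + config.batch_size]
            out = model.forward(Xtr[idx], train=True)
            weights = balancer.weights if balancer else config.loss
            if model.fc1 is not None:
                bd, dseg, dsize = joint_loss(
                    out.segmentation_scores, Ytr[idx],
                    out.diameter_predictions, Ztr[idx],
                    weights, return_grads=True)
                model.backward(dseg, dsize)
            else:
                seg, dseg = segmentation_loss(out.segmentation_scores, Ytr[idx],
                                              return_grad=True)
                from .objective import LossBreakdown
                bd = LossBreakdown(weights.alpha * seg, seg, 0.0,
                                   weights.alpha, weights.beta)
                model.backward(weights.alpha * dseg, None)
            if not math.isfinite(bd.total):
                raise RuntimeError(
                    f"divergent loss at epoch {epoch}: total={bd.total}")
            # the reported breakdown must recompose exactly
            assert abs(bd.total - (bd.alpha_used * bd.seg_term
                                   + bd.beta_used * bd.size_term)) < 1e-9
            opt.step()
            opt.zero_grad()
            if balancer is not None:
                balancer.step(bd.seg_term, bd.size_term)
            tr_tot += bd.total
            tr_seg += bd.seg_term
            tr_size += bd.size_term
            nb += 1
        weights = balancer.weights if balancer else config.loss
        va_tot, va_seg, va_size = _epoch_loss(model, Xva, Yva, Zva, weights,
                                              config.batch_size)
        curves.append({
            "epoch": epoch, "train_total": tr_tot / nb, "train_seg": tr_seg / nb,
            "train_size": tr_size / nb, "val_total": va_tot, "val_seg": va_seg,
            "val_size": va_size, "alpha": weights.alpha, "beta": weights.beta,
        })
        if va_tot < best_val:
            best_val, best_epoch = va_tot, epoch
            best_state = model.get_state()
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= config.early_stopping_patience:
                break
    model.set_state(best_state)
    return TrainResult(state=best_state, model_config=config.model,
                       curves=pd.DataFrame(curves), target_mu=mu, target_sd=sd,
                       best_epoch=best_epoch, best_val_loss=best_val,
                       epochs_run=len(curves))


def save_result(result: TrainResult, config: TrainConfig, path) -> None:
    """Checkpoint: weights, target standardization, config, curves."""
    from dataclasses import asdict

    meta = {"train_config": asdict(config),
            "best_epoch": result.best_epoch,
            "best_val_loss": result.best_val_loss,
            "epochs_run": result.epochs_run}
    np.savez(path,
             _meta_json=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             _curves_json=np.frombuffer(
                 result.curves.to_json(orient="records").encode(), dtype=np.uint8),
             _target_mu=result.target_mu, _target_sd=result.target_sd,
             **result.state)


def load_result(path) -> tuple[TrainResult, TrainConfig]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["_meta_json"].tobytes()).decode())
        curves = pd.read_json(
            __import__("io").StringIO(
                bytes(data["_curves_json"].tobytes()).decode()),
            orient="records")
        mu = data["_target_mu"]
        sd = data["_target_sd"]
        state = {k: data[k] for k in data.files if not k.startswith("_")}
    tc = meta["train_config"]
    tc["model"] = ModelConfig(**tc["model"])
    tc["loss"] = LossWeights(**tc["loss"])
    tc["input_size"] = tuple(tc["input_size"])
    config = TrainConfig(**tc)
    result = TrainResult(state=state, model_config=config.model,
                         curves=curves, target_mu=mu, target_sd=sd,
                         best_epoch=meta["best_epoch"],
                         best_val_loss=meta["best_val_loss"],
                         epochs_run=meta["epochs_run"])
    return result, config


def _predict(model: DualPlaqueNet, X: np.ndarray, batch: int):
    masks, diams = [], []
    with threadpool_limits(limits=1):
        return _predict_impl(model, X, batch)


def _predict_impl(model: DualPlaqueNet, X: np.ndarray, batch: int):
    masks, diams = [], []
    for i in range(0, len(X), batch):
        out = model.forward(X[i:i + batch], train=False)
        masks.append(out.segmentation_scores.argmax(axis=1).astype(np.uint8))
        diams.append(out.diameter_predictions)
    return np.concatenate(masks), np.concatenate(diams)


def evaluate_predictions(pred_masks, true_masks, pred_diams=None,
                         true_diams=None, average: str = "micro") -> EvalReport:
    """Score predicted masks (and optionally diameters) against truth.

    ``average="micro"`` pools confusion counts over all pixels of all
    images before computing metrics; ``"macro"`` averages per-image metric
    values instead.
    """
    n = len(pred_masks)
    counts = [confusion(p, t) for p, t in zip(pred_masks, true_masks)]
    if average == "micro":
        pooled = counts[0]
        for c in counts[1:]:
            pooled = pooled + c
        seg = seg_metrics(pooled)
    elif average == "macro":
        per = [seg_metrics(c) for c in counts]
        seg = SegMetrics(*(float(np.mean([getattr(m, f) for m in per]))
                           for f in ("accuracy_pct", "miou_pct",
                                     "iou_fg_pct", "dice_pct")))
    else:
        raise ValueError("average must be 'micro' or 'macro'")
    reg_long = reg_short = None
    if pred_diams is not None:
        pred_diams = np.asarray(pred_diams, float)
        true_diams = np.asarray(true_diams, float)
        reg_long = regression_metrics(pred_diams[:, 0], true_diams[:, 0])
        reg_short = regression_metrics(pred_diams[:, 1], true_diams[:, 1])
    return EvalReport(seg=seg, reg_long=reg_long, reg_short=reg_short,
                      n_images=n)


def evaluate(result: TrainResult, manifest: DatasetManifest,
             config: TrainConfig, split: str = "test",
             average: str = "micro") -> EvalReport:
    """Run inference on a split and compute the full metric suite."""
    X, Y, D, _ = load_split_arrays(manifest, split, config)
    model = build_model(result.model_config)
    model.set_state(result.state)
    pred_masks, z = _predict(model, X, config.batch_size)
    if result.model_config.regression_branch:
        diams = z * result.target_sd + result.target_mu
        return evaluate_predictions(pred_masks, Y, diams, D, average=average)
    return evaluate_predictions(pred_masks, Y, average=average)


def _flatten(report: EvalReport) -> dict[str, float]:
    out = {
        "accuracy_pct": report.seg.accuracy_pct,
        "miou_pct": report.seg.miou_pct,
        "iou_fg_pct": report.seg.iou_fg_pct,
        "dice_pct": report.seg.dice_pct,
    }
    for name, reg in (("long", report.reg_long), ("short", report.reg_short)):
        if reg is not None:
            out[f"{name}_mse"] = reg.mse
            out[f"{name}_mae"] = reg.mae
            if reg.r2 is not None:
                out[f"{name}_r2"] = reg.r2
    return out


def run_experiment(manifest: DatasetManifest, config: TrainConfig,
                   out_dir=None) -> RunReport:
    """Repeat train+evaluate; aggregate each metric as mean +/- std."""
    per_rep = []
    ckpt_dir = Path(out_dir) if out_dir is not None else None
    if ckpt_dir is not None:
        ckpt_dir.mkdir(parents=True, exist_ok=True)
    for rep in range(config.repetitions):
        result = train_once(manifest, config, repetition_index=rep)
        report = evaluate(result, manifest, config, split="test")
        row = {"repetition": rep, "epochs_run": result.epochs_run,
               "best_epoch": result.best_epoch, **_flatten(report)}
        if ckpt_dir is not None:
            ckpt = ckpt_dir / f"checkpoint_rep{rep}.npz"
            save_result(result, config, ckpt)
            result.curves.to_csv(ckpt_dir / f"curves_rep{rep}.csv", index=False)
            row["checkpoint"] = str(ckpt)
        per_rep.append(row)
    names = [k for k in per_rep[0]
             if k not in ("repetition", "checkpoint")]
    agg = {}
    for k in names:
        vals = np.array([r[k] for r in per_rep], float)
        std = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        agg[k] = (float(vals.mean()), std)
    notes = "" if config.repetitions > 1 else "single repetition: std reported as 0"
    report = RunReport(per_repetition=per_rep, aggregate=agg, notes=notes)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(per_rep).to_csv(out_dir / "per_repetition.csv", index=False)
        (out_dir / "report.json").write_text(json.dumps({
            "aggregate": {k: {"mean": v[0], "std": v[1]} for k, v in agg.items()},
            "per_repetition": per_rep,
            "notes": notes,
        }, indent=1))
    return report


def baseline_unet_measure(manifest: DatasetManifest, config: TrainConfig,
                          repetition_index: int = 0):
    """Segment-then-measure baseline for diameter prediction.

    Trains the same trunk without channel attention and without the
    regression branch (segmentation loss only), then derives diameters
    from each predicted mask by caliper morphometry.  Images whose
    predicted mask is empty are excluded and counted.
    """
    base_cfg = replace(config,
                       model=replace(config.model, attention=False,
                                     regression_branch=False),
                       loss=LossWeights(alpha=1.0, beta=0.0, mode="fixed"))
    result = train_once(manifest, base_cfg, repetition_index=repetition_index)
    X, Y, D, S = load_split_arrays(manifest, "test", base_cfg)
    model = build_model(result.model_config)
    model.set_state(result.state)
    pred_masks, _ = _predict(model, X, base_cfg.batch_size)
    meas, truth = [], []
    n_missing = 0
    for pm, d, s in zip(pred_masks, D, S):
        try:
            pair = morphometry.measure_diameters(pm, s)
        except morphometry.EmptyMaskError:
            n_missing += 1
            continue
        meas.append((pair.long_mm, pair.short_mm))
        truth.append(d)
    seg_report = evaluate_predictions(pred_masks, Y)
    if meas:
        meas = np.asarray(meas)
        truth = np.asarray(truth)
        reg_long = regression_metrics(meas[:, 0], truth[:, 0])
        reg_short = regression_metrics(meas[:, 1], truth[:, 1])
    else:
        reg_long = reg_short = None
    return EvalReport(seg=seg_report.seg, reg_long=reg_long,
                      reg_short=reg_short, n_images=len(X),
                      n_missing=n_missing)
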