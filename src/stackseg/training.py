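"""Loss, schedules, splitting, and the two-phase training loop.

Training follows the regimen the loading-code methodology was designed
around: a class-weighted cross-entropy loss (background down-weighted to
0.5 to bias against false-positive pixels), a 1-cycle learning-rate
schedule, and two phases — a short warm-up with the encoder frozen, then
the full network with discriminative per-group learning rates spread
geometrically from the earliest encoder stage to the decoder head.
Defaults are the full-scale regimen (5 + 100 epochs, peak LR 2e-4 in
phase 1 and 2e-6 -> 1e-4 across groups in phase 2); desk-scale runs
override the sizes, never the structure.

Loading-code randomness (random channel choice, channel/merge dropout) is
re-rolled per sample per epoch from a seed stream derived from
``(run_seed, epoch, sample)``, so runs are exactly reproducible while
dropout still acts as an augmentation.  Validation applies only the
deterministic square-crop-and-resize transform; its loading-code
randomness uses a fixed per-(epoch, sample) stream so accuracies are
comparable across models, and the dropout rate seen at validation can be
overridden for robustness sweeps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .augmentation import AugmentParams, augment_pair, validation_transform
from .loading_codes import LoadingCode, assemble_subimage, set_dropout_rates
from .model import UNet, logits_to_mask
from .nn import Adam, SGD
from .stack_io import DatasetManifest, read_hyperstack, read_mask


class TrainingError(RuntimeError):
    pass


@dataclass(frozen=True)
class ClassWeights:
    """Per-class loss weights; background < cell biases against
    false-positive pixels."""

    cell: float = 1.0
    background: float = 0.5

    def __post_init__(self):
        if self.cell <= 0 or self.background <= 0:
            raise ValueError("class weights must be strictly positive")

    def as_array(self) -> np.ndarray:
        # index 0 = background, 1 = cell
        return np.array([self.background, self.cell], dtype=np.float64)


def weighted_cross_entropy(logits: np.ndarray, target: np.ndarray,
                           weights: ClassWeights | np.ndarray,
                           return_grad: bool = False,
                           reduction: str = "weighted_mean"):
    """Two-class weighted cross entropy.

    Per pixel, with ``cls`` the target class there,
    ``loss = weight[cls] * (-x[cls] + log(sum_j exp(x[j])))``.
    With ``reduction="weighted_mean"`` (default) pixels are aggregated by
    sum of weighted losses over sum of weights, so the class weighting
    does not change the loss scale; ``reduction="none"`` returns the
    per-pixel weighted losses.  Log-sum-exp is max-stabilized.
    """
    w = weights.as_array() if isinstance(weights, ClassWeights) else \
        np.asarray(weights, dtype=np.float64)
    x = np.asarray(logits, dtype=np.float64)
    t = np.asarray(target)
    if x.ndim == 3:
        x = x[None]
    if t.ndim == 2:
        t = t[None]
    if x.shape[0] != t.shape[0] or x.shape[2:] != t.shape[1:]:
        raise ValueError(f"logits {x.shape} and target {t.shape} mismatch")
    if not np.isin(np.unique(t), [0, 1]).all():
        raise ValueError("target mask must be binary {0, 1}")
    t = t.astype(np.int64)
    m = x.max(axis=1, keepdims=True)
    lse = m[:, 0] + np.log(np.exp(x - m).sum(axis=1))
    x_cls = np.take_along_axis(x, t[:, None], axis=1)[:, 0]
    w_px = w[t]
    losses = w_px * (lse - x_cls)
    if reduction == "none":
        if return_grad:
            raise ValueError("gradients are only provided for the reduced loss")
        return losses
    if reduction != "weighted_mean":
        raise ValueError(f"unknown reduction {reduction!r}")
    total_w = w_px.sum()
    loss = float(losses.sum() / total_w)
    if not return_grad:
        return loss
    p = np.exp(x - lse[:, None])
    onehot = np.stack([(t == 0), (t == 1)], axis=1).astype(np.float64)
    grad = w_px[:, None] * (p - onehot) / total_w
    return loss, grad


def split_dataset(manifest: DatasetManifest, fraction: float = 0.8,
                  split_seed: int = 0) -> tuple[DatasetManifest, DatasetManifest]:
    """Randomized train/validation partition: disjoint and exhaustive,
    ``round(fraction * N)`` rows on the training side, reproducible from
    ``split_seed``."""
    n = len(manifest)
    if n == 0:
        raise ValueError("manifest is empty")
    n_train = int(round(fraction * n))
    if n_train == 0 or n_train == n:
        raise ValueError(
            f"fraction {fraction} leaves an empty side for N={n}")
    rng = np.random.default_rng(split_seed)
    order = rng.permutation(n)
    return manifest.subset(np.sort(order[:n_train])), \
        manifest.subset(np.sort(order[n_train:]))


def one_cycle_schedule(max_lr: float, total_iters: int,
                       warmup_frac: float = 0.25, div: float = 25.0,
                       final_div: float = 1e4) -> np.ndarray:
    """Cosine 1-cycle: ``max_lr/div`` -> ``max_lr`` -> ``max_lr/final_div``.

    The peak of the returned sequence equals ``max_lr`` exactly.
    """
    if max_lr <= 0:
        raise ValueError("max_lr must be positive")
    if total_iters < 2:
        raise ValueError("total_iters must be >= 2")
    peak = max(1, min(total_iters - 2, int(round(warmup_frac * (total_iters - 1)))))
    lrs = np.empty(total_iters, dtype=np.float64)
    start, end = max_lr / div, max_lr / final_div
    for i in range(total_iters):
        if i <= peak:
            pct = i / peak
            lrs[i] = start + (max_lr - start) * (1 - math.cos(math.pi * pct)) / 2
        else:
            pct = (i - peak) / (total_iters - 1 - peak)
            lrs[i] = max_lr + (end - max_lr) * (1 - math.cos(math.pi * pct)) / 2
    lrs[peak] = max_lr
    return lrs


def group_peak_lrs(low: float, high: float, n_groups: int) -> np.ndarray:
    """Geometric interpolation of peak LRs across parameter groups."""
    if low <= 0 or high <= 0:
        raise ValueError("learning rates must be positive")
    if n_groups == 1:
        return np.array([high])
    return np.array([low * (high / low) ** (g / (n_groups - 1))
                     for g in range(n_groups)])


@dataclass(frozen=True)
class TrainConfig:
    frozen_epochs: int = 5
    unfrozen_epochs: int = 100
    max_lr_phase1: float = 2e-4
    lr_range_phase2: tuple[float, float] = (2e-6, 1e-4)
    batch_size: int = 8
    split_fraction: float = 0.8
    split_seed: int = 0
    run_seed: int = 0
    class_weights: ClassWeights = field(default_factory=ClassWeights)
    augment: AugmentParams = field(default_factory=AugmentParams)
    target_size: int | None = None          # defaults to augment.target_size
    absence_policy: str = "strict"
    merge_renormalize: bool = False
    val_dropout_override: float | None = None  # freeze validation dropout
    val_dropout_param: str = "merge"
    weight_decay: float = 0.0
    grad_clip: float | None = None          # global-norm gradient clipping
    bn_refresh_batches: int = 3             # precise-BN batches before eval
    deterministic: bool = True

    def __post_init__(self):
        if self.frozen_epochs < 0 or self.unfrozen_epochs < 0 \
                or self.frozen_epochs + self.unfrozen_epochs < 1:
            raise ValueError("need at least one training epoch")
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must be in (0, 1)")
        lo, hi = self.lr_range_phase2
        if self.max_lr_phase1 <= 0 or lo <= 0 or hi <= 0:
            raise ValueError("learning rates must be positive")

    @property
    def total_epochs(self) -> int:
        return self.frozen_epochs + self.unfrozen_epochs

    @property
    def resolved_target_size(self) -> int:
        return self.target_size or self.augment.target_size


@dataclass
class TrainingHistory:
    train_loss: list = field(default_factory=list)     # per epoch
    val_accuracy: list = field(default_factory=list)   # per epoch
    lr_trace: list = field(default_factory=list)       # per iteration

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"epoch": np.arange(1, len(self.train_loss) + 1),
                             "train_loss": self.train_loss,
                             "val_accuracy": self.val_accuracy})


class StackDataset:
    """In-memory dataset: preloaded hyper-stacks and masks of a manifest."""

    def __init__(self, manifest: DatasetManifest):
        self.manifest = manifest
        self.stacks = [read_hyperstack(manifest.image_path(i))
                       for i in range(len(manifest))]
        self.masks = [read_mask(manifest.mask_path(i))
                      for i in range(len(manifest))]

    def __len__(self) -> int:
        return len(self.stacks)


def _sample_rng(run_seed: int, epoch: int, index: int, salt: int = 0):
    return np.random.default_rng(
        np.random.SeedSequence([run_seed & 0x7FFFFFFF, salt, epoch, index]))


def _load_train_sample(data: StackDataset, idx: int, code: LoadingCode,
                       config: TrainConfig, epoch: int):
    rng = _sample_rng(config.run_seed, epoch, idx, salt=1)
    sub = assemble_subimage(data.stacks[idx], code, rng,
                            absence_policy=config.absence_policy,
                            merge_renormalize=config.merge_renormalize)
    aug = replace(config.augment, target_size=config.resolved_target_size)
    img, mask = augment_pair(sub.pixels, data.masks[idx], aug, rng)
    return img, mask.pixels


def _load_val_sample(data: StackDataset, idx: int, code: LoadingCode,
                     config: TrainConfig, epoch: int):
    rng = _sample_rng(config.run_seed, epoch, idx, salt=2)
    if config.val_dropout_override is not None:
        code = set_dropout_rates(code, config.val_dropout_override,
                                 param=config.val_dropout_param)
    sub = assemble_subimage(data.stacks[idx], code, rng,
                            absence_policy=config.absence_policy,
                            merge_renormalize=config.merge_renormalize)
    img, mask = validation_transform(sub.pixels, data.masks[idx],
                                     config.resolved_target_size)
    return img, mask.pixels


def evaluate_model(model: UNet, val_data: StackDataset, code: LoadingCode,
                   config: TrainConfig, epoch: int = 0) -> float:
    """Mean per-image pixel accuracy on the validation side."""
    was_training = model.training
    model.set_training(False)
    accs = []
    bs = max(1, config.batch_size)
    samples = [_load_val_sample(val_data, i, code, config, epoch)
               for i in range(len(val_data))]
    for start in range(0, len(samples), bs):
        chunk = samples[start:start + bs]
        x = np.stack([c[0] for c in chunk])
        t = np.stack([c[1] for c in chunk])
        pred = logits_to_mask(model.forward(x))
        accs.extend((pred[i] == t[i]).mean() for i in range(len(chunk)))
    model.set_training(was_training)
    return float(np.mean(accs))


def refresh_bn_stats(model: UNet, batches) -> None:
    """Re-estimate batch-norm running statistics from training batches.

    With only a handful of iterations per epoch the EMA of batch
    statistics lags the fast-moving weights, which makes eval-mode
    predictions erratic; recomputing the statistics with frozen weights
    over a few batches right before validation (the "precise BN" device)
    removes that lag.  Frozen batch-norm layers are untouched.
    """
    from .model import _batchnorms

    bns = [bn for bn in _batchnorms(model) if bn.trainable]
    if not bns or not batches:
        return
    saved = [(bn.momentum) for bn in bns]
    was_training = model.training
    model.set_training(True)
    for i, x in enumerate(batches):
        for bn in bns:
            bn.momentum = 1.0 / (i + 1)   # cumulative moving average
        model.forward(x)
    for bn, m in zip(bns, saved):
        bn.momentum = m
    model.set_training(was_training)


def clip_gradients(model: UNet, max_norm: float) -> float:
    """Scale all trainable gradients so their global L2 norm <= max_norm."""
    params = [p for p in model.parameters() if p.trainable]
    total = math.sqrt(sum(float((p.grad ** 2).sum()) for p in params))
    if total > max_norm > 0:
        scale = max_norm / (total + 1e-12)
        for p in params:
            p.grad *= scale
    return total


def _run_phase(model: UNet, opt, train_data: StackDataset,
               val_data: StackDataset, code: LoadingCode,
               config: TrainConfig, n_epochs: int, peak_lrs: np.ndarray,
               history: TrainingHistory, epoch_offset: int) -> None:
    n = len(train_data)
    bs = max(1, min(config.batch_size, n))
    iters_per_epoch = math.ceil(n / bs)
    total_iters = max(2, n_epochs * iters_per_epoch)
    shape = one_cycle_schedule(1.0, total_iters)
    it = 0
    for epoch in range(n_epochs):
        ep = epoch_offset + epoch
        order = _sample_rng(config.run_seed, ep, 0, salt=3).permutation(n)
        losses = []
        recent_batches = []
        for start in range(0, n, bs):
            idxs = order[start:start + bs]
            batch = [_load_train_sample(train_data, int(i), code, config, ep)
                     for i in idxs]
            x = np.stack([b[0] for b in batch])
            t = np.stack([b[1] for b in batch])
            logits = model.forward(x)
            loss, grad = weighted_cross_entropy(
                logits, t, config.class_weights, return_grad=True)
            if not math.isfinite(loss):
                raise TrainingError(
                    f"training diverged (non-finite loss) at epoch {ep + 1}, "
                    f"iteration {it + 1}")
            model.zero_grad()
            model.backward(grad)
            if config.grad_clip is not None:
                clip_gradients(model, config.grad_clip)
            lrs = shape[min(it, total_iters - 1)] * peak_lrs
            opt.step(lrs)
            history.lr_trace.append(float(lrs.max()))
            losses.append(loss)
            it += 1
            recent_batches.append(x)
            if len(recent_batches) > config.bn_refresh_batches:
                recent_batches.pop(0)
        history.train_loss.append(float(np.mean(losses)))
        if config.bn_refresh_batches:
            refresh_bn_stats(model, recent_batches)
        history.val_accuracy.append(
            evaluate_model(model, val_data, code, config, epoch=ep))


def train(model: UNet, dataset, config: TrainConfig,
          code: LoadingCode) -> tuple[UNet, TrainingHistory]:
    """Two-phase training.

    ``dataset`` is a DatasetManifest or a (train, val) pair of
    StackDatasets.  Phase 1 freezes the encoder and trains
    ``frozen_epochs`` at ``max_lr_phase1``; phase 2 unfreezes everything
    and trains ``unfrozen_epochs`` with per-group peak LRs spread
    geometrically over ``lr_range_phase2``.
    """
    if isinstance(dataset, DatasetManifest):
        train_man, val_man = split_dataset(dataset, config.split_fraction,
                                           config.split_seed)
        train_data, val_data = StackDataset(train_man), StackDataset(val_man)
    else:
        train_data, val_data = dataset
    if len(train_data) == 0 or len(val_data) == 0:
        raise ValueError("both split sides must be nonempty")
    history = TrainingHistory()
    groups = model.parameter_groups()
    opt = Adam(groups, weight_decay=config.weight_decay)
    model.set_training(True)

    if config.frozen_epochs > 0:
        model.freeze_encoder()
        peak = np.full(len(groups), config.max_lr_phase1)
        _run_phase(model, opt, train_data, val_data, code, config,
                   config.frozen_epochs, peak, history, epoch_offset=0)
    model.unfreeze_encoder()
    if config.unfrozen_epochs > 0:
        low, high = config.lr_range_phase2
        peak = group_peak_lrs(low, high, len(groups))
        _run_phase(model, opt, train_data, val_data, code, config,
                   config.unfrozen_epochs, peak, history,
                   epoch_offset=config.frozen_epochs)
    return model, history


# ---------------------------------------------------------------------------
# Learning-rate finder
# ---------------------------------------------------------------------------

def lr_ramp(min_lr: float, max_lr: float, n_iters: int) -> np.ndarray:
    """Geometric LR ramp with exact endpoints ``min_lr`` and ``max_lr``."""
    if min_lr <= 0 or max_lr <= min_lr or n_iters < 2:
        raise ValueError("need 0 < min_lr < max_lr and n_iters >= 2")
    return min_lr * (max_lr / min_lr) ** (np.arange(n_iters) / (n_iters - 1))


def lr_scan(step_fn, lrs, divergence_factor: float = 4.0,
            smooth_beta: float = 0.98):
    """Drive ``step_fn(lr) -> loss`` over an LR ramp with early abort.

    Records (lr, smoothed_loss) pairs using bias-corrected exponential
    smoothing; aborts once the smoothed loss exceeds
    ``divergence_factor`` x the best smoothed loss seen, or on a
    non-finite loss.
    """
    records = []
    avg = 0.0
    best = math.inf
    for i, lr in enumerate(lrs):
        loss = step_fn(float(lr))
        if not math.isfinite(loss):
            if i == 0:
                raise TrainingError(
                    f"loss is non-finite at the first lr {lr:.3g}")
            break
        avg = smooth_beta * avg + (1 - smooth_beta) * loss
        smoothed = avg / (1 - smooth_beta ** (i + 1))
        records.append((float(lr), float(smoothed)))
        best = min(best, smoothed)
        if smoothed > divergence_factor * best:
            break
    return records


def lr_find(model: UNet, train_data: StackDataset, code: LoadingCode,
            config: TrainConfig, min_lr: float = 1e-7, max_lr: float = 1e-1,
            n_iters: int = 100, divergence_factor: float = 4.0,
            smooth_beta: float = 0.98, optimizer: str = "adam"):
    """Geometric LR ramp recording exponentially smoothed training loss.

    Returns ``(records, suggestion)`` where ``records`` is a list of
    (lr, smoothed_loss) pairs and ``suggestion`` is the lr at the steepest
    negative slope of the smoothed loss before divergence (loss exceeding
    ``divergence_factor`` x the best smoothed loss), or None with a
    warning when the loss never falls (e.g. zero gradients).
    """
    import warnings

    if len(train_data) == 0:
        raise ValueError("lr_find needs a nonempty dataset")
    groups = model.parameter_groups()
    opt = Adam(groups) if optimizer == "adam" else SGD(groups)
    model.set_training(True)
    n = len(train_data)
    bs = max(1, min(config.batch_size, n))
    counter = {"i": 0}

    def step(lr: float) -> float:
        i = counter["i"]
        counter["i"] += 1
        idxs = [(i * bs + j) % n for j in range(bs)]
        batch = [_load_train_sample(train_data, idx, code, config, epoch=i)
                 for idx in idxs]
        x = np.stack([b[0] for b in batch])
        t = np.stack([b[1] for b in batch])
        logits = model.forward(x)
        loss, grad = weighted_cross_entropy(logits, t, config.class_weights,
                                            return_grad=True)
        if math.isfinite(loss):
            model.zero_grad()
            model.backward(grad)
            opt.step(lr)
        return loss

    records = lr_scan(step, lr_ramp(min_lr, max_lr, n_iters),
                      divergence_factor, smooth_beta)
    suggestion = suggest_lr(records)
    if suggestion is None:
        warnings.warn("lr_find: smoothed loss never decreased; no suggestion")
    return records, suggestion


def suggest_lr(records) -> float | None:
    """LR at the steepest negative slope of smoothed loss (None if flat)."""
    if len(records) < 3:
        return None
    lrs = np.array([r[0] for r in records])
    losses = np.array([r[1] for r in records])
    slopes = np.gradient(losses, np.log(lrs))
    if slopes.min() >= -1e-12:
        return None
    return float(lrs[int(np.argmin(slopes))])
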