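"""Metrics, strategy comparison, and train x validate dropout sweeps.

Pixel accuracy is the primary metric (fraction of pixels whose predicted
class matches the single-cell ground truth), pooled per image and then
averaged over images.  A model's reported accuracy is the rolling mean of
its validation accuracy over the final training epochs, which smooths
epoch-to-epoch jitter.  Strategy comparisons use a paired design — within
each replicate every loading code shares the same train/validation split
and the same weight initialization — and are tested with a paired t-test
against a reference code.  Robustness is quantified by training models at
a grid of dropout rates and validating each across the full grid,
yielding an accuracy matrix whose rows are training rates and columns
validation rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .loading_codes import LoadingCode, LoadingCodeError, set_dropout_rates
from .model import ModelConfig, build_model
from .stack_io import DatasetManifest, MaskLabel
from .training import (
    StackDataset,
    TrainConfig,
    TrainingHistory,
    evaluate_model,
    split_dataset,
    train,
)


class DegenerateComparisonError(ValueError):
    """Paired differences have zero variance; a t-test is undefined."""


def _as_binary(arr) -> np.ndarray:
    a = arr.pixels if isinstance(arr, MaskLabel) else np.asarray(arr)
    if not np.isin(np.unique(a), [0, 1]).all():
        raise ValueError("masks must be binary {0, 1}")
    return a.astype(np.uint8)


def pixel_accuracy(pred, truth) -> float:
    """Fraction of agreeing pixels."""
    p, t = _as_binary(pred), _as_binary(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    return float((p == t).mean())


def confusion_counts(pred, truth) -> tuple[int, int, int, int]:
    """Pixelwise (TP, FP, FN, TN) with cell = positive class."""
    p, t = _as_binary(pred), _as_binary(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    tp = int(((p == 1) & (t == 1)).sum())
    fp = int(((p == 1) & (t == 0)).sum())
    fn = int(((p == 0) & (t == 1)).sum())
    tn = int(((p == 0) & (t == 0)).sum())
    return tp, fp, fn, tn


def rolling_final_accuracy(history: TrainingHistory | list, window: int = 10) -> float:
    """Mean validation accuracy over the final ``window`` epochs."""
    accs = history.val_accuracy if isinstance(history, TrainingHistory) else list(history)
    if window < 1:
        raise ValueError("window must be >= 1")
    if len(accs) < window:
        raise ValueError(f"history has {len(accs)} epochs < window {window}")
    return float(np.mean(accs[-window:]))


def paired_t_test(a, b) -> float:
    """Two-sided paired t-test p-value.

    Raises :class:`DegenerateComparisonError` when the paired differences
    have zero variance (including a == b), where the statistic is
    undefined.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-D arrays")
    if a.size < 2:
        raise ValueError("need at least two pairs")
    d = a - b
    if np.ptp(d) == 0.0:
        raise DegenerateComparisonError(
            "paired differences have zero variance; t-test undefined")
    return float(stats.ttest_rel(a, b).pvalue)


@dataclass
class ComparisonTable:
    """Per-code replicate accuracies with paired statistics."""

    frame: pd.DataFrame              # code, mean, sem, n, p_vs_reference
    replicate_accuracies: dict       # code -> list of per-replicate values
    reference: str
    histories: dict = field(default_factory=dict)


def _replicate_seeds(base_seed: int, n: int) -> list[tuple[int, int]]:
    """(split_seed, run_seed) per replicate, distinct by construction."""
    seeds = [(int(base_seed + 1000 * k), int(base_seed + 1000 * k + 500))
             for k in range(n)]
    flat = [s for pair in seeds for s in pair]
    if len(set(flat)) != len(flat):
        raise ValueError("replicate seeds collide")
    return seeds


def compare_strategies(codes: list[LoadingCode], manifest: DatasetManifest,
                       model_config: ModelConfig, train_config: TrainConfig,
                       n_replicates: int = 3, reference: str = "brightfield",
                       window: int = 10, base_seed: int = 0,
                       keep_histories: bool = False) -> ComparisonTable:
    """Train one model per code per replicate and tabulate final accuracies.

    Paired design: within a replicate all codes share the split seed and
    the initialization seed, so differences reflect the loading codes
    alone.  Each code's mean final accuracy is compared against the
    ``reference`` code by a paired t-test across replicates.
    """
    if len(codes) < 2:
        raise ValueError("need at least two codes to compare")
    names = [c.name for c in codes]
    if len(set(names)) != len(names):
        raise ValueError(f"code names must be unique within a run: {names}")
    if reference not in names:
        raise ValueError(f"reference {reference!r} not among codes {names}")
    seeds = _replicate_seeds(base_seed, n_replicates)
    accs: dict[str, list[float]] = {n: [] for n in names}
    histories: dict[str, list[TrainingHistory]] = {n: [] for n in names}
    for split_seed, run_seed in seeds:
        cfg = replace(train_config, split_seed=split_seed, run_seed=run_seed)
        train_man, val_man = split_dataset(manifest, cfg.split_fraction,
                                           split_seed)
        data = (StackDataset(train_man), StackDataset(val_man))
        for code in codes:
            model = build_model(model_config, seed=run_seed)
            model, history = train(model, data, cfg, code)
            accs[code.name].append(
                rolling_final_accuracy(history,
                                       min(window, len(history.val_accuracy))))
            if keep_histories:
                histories[code.name].append(history)
    rows = []
    ref = np.array(accs[reference])
    for name in names:
        vals = np.array(accs[name])
        if name == reference or len(vals) < 2:
            p = np.nan
        else:
            try:
                p = paired_t_test(vals, ref)
            except DegenerateComparisonError:
                p = np.nan
        rows.append({"code": name,
                     "mean_accuracy": float(vals.mean()),
                     "sem": float(vals.std(ddof=1) / np.sqrt(len(vals)))
                     if len(vals) > 1 else 0.0,
                     "n": len(vals),
                     "p_vs_reference": p})
    return ComparisonTable(frame=pd.DataFrame(rows),
                           replicate_accuracies=accs, reference=reference,
                           histories=histories if keep_histories else {})


@dataclass
class SweepResult:
    """Accuracy grid over (training dropout rate x validation dropout rate)."""

    train_rates: list
    val_rates: list
    accuracy_grid: np.ndarray        # (|train_rates|, |val_rates|)
    n_replicates: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.accuracy_grid,
                            index=pd.Index(self.train_rates, name="train_rate"),
                            columns=pd.Index(self.val_rates, name="val_rate"))

    def robustness_range(self, train_rate) -> float:
        """max - min accuracy across validation rates for one trained model."""
        i = list(self.train_rates).index(train_rate)
        row = self.accuracy_grid[i]
        return float(row.max() - row.min())


def dropout_sweep(code_template: LoadingCode, manifest: DatasetManifest,
                  model_config: ModelConfig, train_config: TrainConfig,
                  train_rates, val_rates, n_replicates: int = 1,
                  param: str = "merge", base_seed: int = 0) -> SweepResult:
    """Train at each training dropout rate; validate across all val rates.

    For every training rate the template's dropout knob is set to that
    rate; the trained model is then evaluated with the validation loader
    overridden to each validation rate in turn.  Grid entries are mean
    pixel accuracies over replicates.
    """
    train_rates = list(train_rates)
    val_rates = list(val_rates)
    for r in train_rates + val_rates:
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"dropout rate out of [0, 1]: {r}")
    if sorted(train_rates) != train_rates or sorted(val_rates) != val_rates:
        raise ValueError("rates must be sorted ascending")
    # validates that the template actually bears the dropout parameter
    set_dropout_rates(code_template, 0.0, param=param)

    grid = np.zeros((len(train_rates), len(val_rates)))
    seeds = _replicate_seeds(base_seed, n_replicates)
    for split_seed, run_seed in seeds:
        cfg = replace(train_config, split_seed=split_seed, run_seed=run_seed)
        train_man, val_man = split_dataset(manifest, cfg.split_fraction,
                                           split_seed)
        data = (StackDataset(train_man), StackDataset(val_man))
        for i, tr in enumerate(train_rates):
            code = set_dropout_rates(code_template, tr, param=param)
            model = build_model(model_config, seed=run_seed)
            model, history = train(model, data, cfg, code)
            for j, vr in enumerate(val_rates):
                eval_cfg = replace(cfg, val_dropout_override=vr,
                                   val_dropout_param=param)
                grid[i, j] += evaluate_model(
                    model, data[1], code, eval_cfg,
                    epoch=cfg.total_epochs)
    grid /= n_replicates
    return SweepResult(train_rates=train_rates, val_rates=val_rates,
                       accuracy_grid=grid, n_replicates=n_replicates)


# ---------------------------------------------------------------------------
# Rendering: every figure has a CSV twin so no result is figure-only
# ---------------------------------------------------------------------------

def save_sweep(result: SweepResult, out_dir, stem: str = "sweep") -> None:
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.to_frame().to_csv(out / f"{stem}.csv")
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        im = ax.imshow(result.accuracy_grid, origin="upper", cmap="viridis",
                       aspect="auto")
        ax.set_xticks(range(len(result.val_rates)),
                      [f"{v:.0%}" for v in result.val_rates])
        ax.set_yticks(range(len(result.train_rates)),
                      [f"{v:.0%}" for v in result.train_rates])
        ax.set_xlabel("validation dropout rate")
        ax.set_ylabel("training dropout rate")
        fig.colorbar(im, ax=ax, label="pixel accuracy")
        fig.tight_layout()
        fig.savefig(out / f"{stem}.png", dpi=120)
        plt.close(fig)
    except ImportError:  # pragma: no cover
        pass


def save_comparison(table: ComparisonTable, out_dir,
                    stem: str = "comparison") -> None:
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.frame.to_csv(out / f"{stem}.csv", index=False)
    pd.DataFrame(table.replicate_accuracies).to_csv(
        out / f"{stem}_replicates.csv", index=False)


def plot_history(histories: dict, out_path, window: int = 10) -> None:
    """Line plot of validation accuracy with a rolling mean per model."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for name, history in histories.items():
        acc = np.asarray(history.val_accuracy, dtype=float)
        smooth = pd.Series(acc).rolling(window, min_periods=1).mean()
        ax.plot(np.arange(1, len(acc) + 1), smooth, label=name)
    ax.set_xlabel("epoch")
    ax.set_ylabel(f"validation pixel accuracy ({window}-pt rolling mean)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
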