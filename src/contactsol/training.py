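"""Training loop, cross-validation protocol, ensembles and metrics.

The network is trained to minimize mean squared error between predicted and
measured solubility (the same minimizer as RMSE, which is what is reported)
with the Adam optimizer, accumulating per-protein gradients over small
batches — mathematically identical to per-graph evaluation. Evaluation
follows the fivefold cross-validation protocol repeated over several random
fold seeds, ensembles average the member model outputs, and the metric
suite reports RMSE, the coefficient of determination R², and the
threshold-0.5 classification metrics (accuracy, precision, recall, F1, AUC)
obtained by calling a protein soluble when its score is at least the
threshold.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import r2_score, roc_auc_score, roc_curve, precision_recall_curve

from .graphs import ProteinGraph, normalize_adjacency
from .model import (
    ModelConfig,
    ModelParameters,
    backward,
    forward,
    init_parameters,
)

__all__ = [
    "SolubilityDataset",
    "TrainConfig",
    "MetricsReport",
    "CVResult",
    "train",
    "split_dataset",
    "cross_validate",
    "ensemble_predict",
    "predict_dataset",
    "compute_metrics",
    "threshold_sweep",
]


@dataclass
class SolubilityDataset:
    """Protein graphs with measured solubility targets in [0, 1]."""

    records: list[tuple[ProteinGraph, float, str]]

    def __post_init__(self) -> None:
        ids = [rid for _, _, rid in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate identifiers in dataset")
        for _, y, rid in self.records:
            if not (0.0 <= y <= 1.0):
                raise ValueError(f"target for {rid!r} outside [0,1]: {y}")

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, indices) -> "SolubilityDataset":
        return SolubilityDataset([self.records[i] for i in indices])

    @property
    def targets(self) -> np.ndarray:
        return np.array([y for _, y, _ in self.records])

    @property
    def identifiers(self) -> list[str]:
        return [rid for _, _, rid in self.records]


@dataclass
class TrainConfig:
    """Optimization settings (Adam)."""

    learning_rate: float = 1e-3
    epochs: int = 100
    seed: int = 0
    batch_size: int = 8
    patience: int = 10  # early stopping on validation R²; 0 disables
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


class _Adam:
    def __init__(self, shapes, cfg: TrainConfig):
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0
        self.cfg = cfg

    def step(self, arrays, grads):
        c = self.cfg
        self.t += 1
        bc1 = 1 - c.adam_beta1**self.t
        bc2 = 1 - c.adam_beta2**self.t
        for a, g, m, v in zip(arrays, grads, self.m, self.v):
            m *= c.adam_beta1
            m += (1 - c.adam_beta1) * g
            v *= c.adam_beta2
            v += (1 - c.adam_beta2) * g * g
            a -= c.learning_rate * (m / bc1) / (np.sqrt(v / bc2) + c.adam_eps)


def _prepared(dataset: SolubilityDataset):
    """Precompute the normalized adjacency of every graph once."""
    out = []
    for graph, y, rid in dataset.records:
        out.append((graph.features.X, normalize_adjacency(graph.A), y, rid))
    return out


def train(
    dataset: SolubilityDataset,
    mconfig: ModelConfig,
    tconfig: TrainConfig,
    val_dataset: SolubilityDataset | None = None,
    log: list | None = None,
    log_path=None,
) -> ModelParameters:
    """Fit model parameters by MSE/Adam; returns the trained parameters.

    With a validation set and ``patience > 0``, training stops once the
    validation R² has not improved for ``patience`` epochs and the best
    parameters seen are returned. The per-epoch loss (and validation R²)
    is appended to ``log`` and, if given, written as line-delimited JSON
    to ``log_path``.
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    params = init_parameters(mconfig, seed=tconfig.seed)
    if tconfig.epochs == 0:
        return params
    prep = _prepared(dataset)
    val_prep = _prepared(val_dataset) if val_dataset is not None else None
    arrays = params.to_flat_list()
    opt = _Adam([a.shape for a in arrays], tconfig)
    rng = np.random.default_rng(tconfig.seed)
    best_r2 = -np.inf
    best_params = None
    stale = 0
    log_fh = open(log_path, "w") if log_path is not None else None
    try:
        for epoch in range(tconfig.epochs):
            order = rng.permutation(len(prep))
            sq_sum = 0.0
            for start in range(0, len(order), tconfig.batch_size):
                batch = order[start:start + tconfig.batch_size]
                grad_accum = None
                for idx in batch:
                    X, A_hat, y, _ = prep[idx]
                    S, _, cache = forward(X, A_hat, params, mconfig, keep_cache=True)
                    if not np.isfinite(S):
                        raise FloatingPointError(
                            f"non-finite prediction at epoch {epoch}"
                        )
                    sq_sum += (S - y) ** 2
                    g = backward(2.0 * (S - y) / len(batch), params, mconfig, cache)
                    flat = g.to_flat_list()
                    if grad_accum is None:
                        grad_accum = flat
                    else:
                        for acc, gi in zip(grad_accum, flat):
                            acc += gi
                opt.step(arrays, grad_accum)
            rmse = float(np.sqrt(sq_sum / len(prep)))
            if not np.isfinite(rmse):
                raise FloatingPointError(f"NaN loss at epoch {epoch}")
            entry = {"epoch": epoch, "train_rmse": rmse}
            if val_prep is not None:
                preds = np.array(
                    [forward(X, A, params, mconfig)[0] for X, A, _, _ in val_prep]
                )
                ys = np.array([y for _, _, y, _ in val_prep])
                # single-record validation: fall back to negative RMSE as
                # the early-stopping score (R² needs >= 2 observations)
                if ys.size >= 2 and np.ptp(ys) > 0:
                    val_r2 = float(r2_score(ys, preds))
                else:
                    val_r2 = -float(np.sqrt(np.mean((preds - ys) ** 2)))
                entry["val_r2"] = val_r2
                if tconfig.patience > 0:
                    if val_r2 > best_r2 + 1e-6:
                        best_r2 = val_r2
                        best_params = params.copy()
                        stale = 0
                    else:
                        stale += 1
                        if stale >= tconfig.patience:
                            if log is not None:
                                log.append(entry)
                            if log_fh:
                                log_fh.write(json.dumps(entry) + "\n")
                            break
            if log is not None:
                log.append(entry)
            if log_fh:
                log_fh.write(json.dumps(entry) + "\n")
    finally:
        if log_fh:
            log_fh.close()
    if best_params is not None:
        return best_params
    return params


def predict_dataset(params: ModelParameters, mconfig: ModelConfig,
                    dataset: SolubilityDataset) -> np.ndarray:
    return np.array(
        [forward(g.features.X, normalize_adjacency(g.A), params, mconfig)[0]
         for g, _, _ in dataset.records]
    )


def split_dataset(dataset: SolubilityDataset, train_fraction: float,
                  seed: int = 0) -> tuple[SolubilityDataset, SolubilityDataset]:
    """Seeded random split; train gets ``floor(fraction * n)`` records."""
    n = len(dataset)
    if n == 0:
        raise ValueError("cannot split an empty dataset")
    if not (0 < train_fraction <= 1):
        raise ValueError("train_fraction must be in (0, 1]")
    n_train = int(np.floor(train_fraction * n))
    perm = np.random.default_rng(seed).permutation(n)
    return dataset.subset(perm[:n_train]), dataset.subset(perm[n_train:])


def _fold_indices(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Seeded shuffle, then contiguous chunks; sizes differ by at most 1
    (the remainder goes to the first ``n mod k`` folds)."""
    perm = np.random.default_rng(seed).permutation(n)
    base, rem = divmod(n, k)
    folds, start = [], 0
    for i in range(k):
        size = base + (1 if i < rem else 0)
        folds.append(perm[start:start + size])
        start += size
    return folds


@dataclass
class CVResult:
    """Cross-validation outcome: per-(seed, fold) metrics and trained models."""

    table: pd.DataFrame  # one row per seed x fold
    models: list[tuple[int, int, ModelParameters]]  # (seed, fold, params)
    mconfig: ModelConfig

    def aggregate(self) -> pd.DataFrame:
        """Mean ± std over all seed x fold runs, plus the per-seed means
        (averaging folds first, then seeds) for both aggregation orders."""
        numeric = self.table.drop(columns=["seed", "fold"])
        overall = pd.DataFrame({"mean": numeric.mean(), "std": numeric.std(ddof=0)})
        by_seed = self.table.groupby("seed").mean().drop(columns=["fold"])
        overall["mean_of_seed_means"] = by_seed.mean()
        return overall


def cross_validate(
    dataset: SolubilityDataset,
    mconfig: ModelConfig,
    tconfig: TrainConfig,
    k: int = 5,
    n_seed_repeats: int = 5,
    base_seed: int = 0,
) -> CVResult:
    """k-fold cross-validation repeated over ``n_seed_repeats`` fold seeds.

    Every fold serves once as validation per seed, so ``k * n_seed_repeats``
    models are trained in total.
    """
    n = len(dataset)
    if n < k:
        raise ValueError(f"need at least k={k} records, got {n}")
    rows, models = [], []
    for rep in range(n_seed_repeats):
        seed = base_seed + rep
        folds = _fold_indices(n, k, seed)
        for fi, val_idx in enumerate(folds):
            train_idx = np.concatenate([f for j, f in enumerate(folds) if j != fi])
            train_ds, val_ds = dataset.subset(train_idx), dataset.subset(val_idx)
            fold_tcfg = TrainConfig(**{**tconfig.__dict__, "seed": tconfig.seed + rep})
            params = train(train_ds, mconfig, fold_tcfg, val_dataset=val_ds)
            preds = predict_dataset(params, mconfig, val_ds)
            if len(val_ds) >= 2:
                row = compute_metrics(preds, val_ds.targets).to_dict()
            else:
                # leave-one-out boundary: only the error is defined
                row = {"rmse": float(np.abs(preds[0] - val_ds.targets[0])),
                       "r2": np.nan}
            rows.append({"seed": seed, "fold": fi, **row})
            models.append((seed, fi, params))
    return CVResult(table=pd.DataFrame(rows), models=models, mconfig=mconfig)


def ensemble_predict(models: list[ModelParameters], graph: ProteinGraph,
                     mconfig: ModelConfig) -> float:
    """Arithmetic mean of the member model predictions; stays in (0, 1)."""
    if not models:
        raise ValueError("ensemble needs at least one model")
    p = graph.features.X.shape[1]
    for m in models:
        if m.gcn_weights[0].shape[0] != p:
            raise ValueError("ensemble member does not match graph feature width")
    A_hat = normalize_adjacency(graph.A)
    preds = [forward(graph.features.X, A_hat, m, mconfig)[0] for m in models]
    return float(np.mean(preds))


# ---------------------------------------------------------------------------
# metrics


@dataclass
class MetricsReport:
    """Regression and threshold-based classification metrics."""

    rmse: float
    r2: float
    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "rmse", "r2", "threshold", "tp", "fp", "tn", "fn",
            "accuracy", "precision", "recall", "f1", "auc")}


def compute_metrics(predicted, actual, threshold: float = 0.5) -> MetricsReport:
    """RMSE, R² and threshold classification metrics.

    Both vectors are thresholded at ``threshold`` (``>=`` counts as
    soluble). Degenerate denominators (no predicted positives, no actual
    positives, constant actuals, single-class actuals for AUC) produce a
    warning and a 0 (or NaN R²/AUC for undefined cases).
    """
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if predicted.shape != actual.shape or predicted.ndim != 1:
        raise ValueError("predicted and actual must be 1-D of equal length")
    if predicted.size < 2:
        raise ValueError("need at least 2 observations")
    rmse = float(np.sqrt(np.mean((predicted - actual) ** 2)))
    if np.ptp(actual) == 0:
        warnings.warn("actual values have zero variance; R² undefined")
        r2 = float("nan")
    else:
        r2 = float(r2_score(actual, predicted))
    pred_pos = predicted >= threshold
    act_pos = actual >= threshold
    tp = int(np.sum(pred_pos & act_pos))
    fp = int(np.sum(pred_pos & ~act_pos))
    tn = int(np.sum(~pred_pos & ~act_pos))
    fn = int(np.sum(~pred_pos & act_pos))
    accuracy = (tp + tn) / predicted.size
    if tp + fp == 0:
        warnings.warn("no predicted positives; precision reported as 0")
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        warnings.warn("no actual positives; recall reported as 0")
        recall = 0.0
    else:
        recall = tp / (tp + fn)
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    if len(np.unique(act_pos)) < 2:
        warnings.warn("single-class actuals; AUC undefined, reported as NaN")
        auc = float("nan")
    else:
        auc = float(roc_auc_score(act_pos, predicted))
    return MetricsReport(rmse, r2, threshold, tp, fp, tn, fn,
                         accuracy, precision, recall, f1, auc)


def threshold_sweep(predicted, actual, grid) -> dict:
    """Metrics at every threshold in ``grid``, plus ROC / PR coordinates.

    Returns a dict with a ``table`` DataFrame (one MetricsReport row per
    threshold), and ``roc`` / ``pr`` coordinate arrays for plotting.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size and (grid.min() < 0 or grid.max() > 1):
        raise ValueError("thresholds must lie in [0, 1]")
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    rows = [compute_metrics(predicted, actual, threshold=t).to_dict() for t in grid]
    act_pos = actual >= 0.5
    roc = pr = None
    if len(np.unique(act_pos)) == 2:
        fpr, tpr, roc_thr = roc_curve(act_pos, predicted)
        prec, rec, pr_thr = precision_recall_curve(act_pos, predicted)
        roc = {"fpr": fpr, "tpr": tpr, "thresholds": roc_thr}
        pr = {"precision": prec, "recall": rec, "thresholds": pr_thr}
    return {"table": pd.DataFrame(rows), "roc": roc, "pr": pr}
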