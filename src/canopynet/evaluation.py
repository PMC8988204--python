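"""Evaluation metrics and the model-comparison matrix.

Metrics follow the standard regression definitions:

* ``R^2   = 1 - sum (y_i - yhat_i)^2 / sum (y_i - ybar)^2``
* ``RMSE  = sqrt(mean (y_i - yhat_i)^2)``
* ``rRMSE = RMSE / ybar * 100%``

Predictions are denormalized with the training-time min-max parameters
before metrics are computed, so RMSE is in kg/ha for yield and in percent
points for GPC.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (ConfigurationError, DegenerateRangeError,
                     InvalidArgumentError)
from .models import ModelSpec
from .prep import TARGETS, PreparedDataset
from .training import TrainConfig, TrainedModel, train


def _check_pair(y_true, y_pred, min_n: int) -> tuple[np.ndarray, np.ndarray]:
    yt = np.asarray(y_true, dtype=float).ravel()
    yp = np.asarray(y_pred, dtype=float).ravel()
    if yt.shape != yp.shape:
        raise InvalidArgumentError("y_true and y_pred lengths differ")
    if yt.size < min_n:
        raise InvalidArgumentError(f"need at least {min_n} observations, got {yt.size}")
    return yt, yp


def r_squared(y_true, y_pred) -> float:
    """Coefficient of determination; can be negative for poor predictors."""
    yt, yp = _check_pair(y_true, y_pred, min_n=2)
    ss_tot = float(np.sum((yt - yt.mean()) ** 2))
    if ss_tot == 0.0:
        raise DegenerateRangeError("R^2 undefined: y_true is constant")
    return 1.0 - float(np.sum((yt - yp) ** 2)) / ss_tot


def rmse(y_true, y_pred) -> float:
    yt, yp = _check_pair(y_true, y_pred, min_n=1)
    return float(np.sqrt(np.mean((yt - yp) ** 2)))


def rrmse(y_true, y_pred) -> float:
    """Relative RMSE in percent of the observed mean."""
    yt, yp = _check_pair(y_true, y_pred, min_n=1)
    ybar = float(yt.mean())
    if ybar == 0.0:
        raise DegenerateRangeError("rRMSE undefined: mean of y_true is zero")
    return rmse(yt, yp) / ybar * 100.0


@dataclass(frozen=True)
class EvalReport:
    """Per-target test metrics of one trained model."""

    metrics: dict[str, dict[str, float]]  # target -> {r2, rmse, rrmse}
    n: int
    split: str
    spec: ModelSpec

    def to_rows(self) -> list[dict]:
        return [{"topology": self.spec.topology, "extractor": self.spec.extractor,
                 "input_traits": "+".join(self.spec.input_traits),
                 "target": t, "split": self.split, "n": self.n, **m}
                for t, m in self.metrics.items()]


def evaluate(trained: TrainedModel, dataset: PreparedDataset,
             split: str = "test") -> EvalReport:
    """Denormalize predictions and compute R^2 / RMSE / rRMSE per head."""
    if trained.norm_params is None:
        raise ConfigurationError("trained model carries no normalization parameters")
    idx = dataset.split_indices(split)
    if idx.size == 0:
        raise InvalidArgumentError(f"split {split!r} is empty")
    preds_norm = trained.predict_norm(dataset, idx)
    metrics = {}
    for target in trained.spec.output_targets:
        col = TARGETS.index(target)
        y_true = trained.norm_params.denormalize(dataset.y_norm[idx, col], target)
        y_pred = trained.norm_params.denormalize(preds_norm[target], target)
        metrics[target] = {"r2": r_squared(y_true, y_pred),
                           "rmse": rmse(y_true, y_pred),
                           "rrmse": rrmse(y_true, y_pred)}
    return EvalReport(metrics=metrics, n=int(idx.size), split=split,
                      spec=trained.spec)


def predictions_frame(trained: TrainedModel, dataset: PreparedDataset,
                      split: str = "test") -> pd.DataFrame:
    """Per-example observed/predicted values (raw scale) for scatter plots."""
    idx = dataset.split_indices(split)
    preds_norm = trained.predict_norm(dataset, idx)
    out = {"plot_id": [dataset.ids[i] for i in idx]}
    for target in trained.spec.output_targets:
        col = TARGETS.index(target)
        out[f"{target}_true"] = trained.norm_params.denormalize(
            dataset.y_norm[idx, col], target)
        out[f"{target}_pred"] = trained.norm_params.denormalize(
            preds_norm[target], target)
    return pd.DataFrame(out)


def compare_models(specs: Sequence[ModelSpec], dataset: PreparedDataset,
                   n_seeds: int = 5, train_config: TrainConfig | None = None,
                   base_seed: int = 0, split: str = "test") -> pd.DataFrame:
    """Train every spec ``n_seeds`` times and tabulate mean +/- sd metrics.

    One row per (spec, target); configurations are ranked per target by
    mean R^2 (rank 1 = best). Training failures are annotated in an
    ``error`` column rather than aborting the whole comparison.
    """
    base = train_config or TrainConfig()
    rows = []
    # seeds are shared across specs so configurations are compared paired
    seeds = [int(np.random.SeedSequence([base_seed, s]).generate_state(1)[0]
                 % 2**31) for s in range(n_seeds)]
    for spec in specs:
        per_target: dict[str, dict[str, list[float]]] = {
            t: {"r2": [], "rmse": [], "rrmse": []} for t in spec.output_targets}
        error = None
        for s in seeds:
            cfg = TrainConfig(learning_rate=base.learning_rate,
                              batch_size=base.batch_size,
                              dropout_rate=base.dropout_rate,
                              max_epochs=base.max_epochs,
                              early_stop_patience=base.early_stop_patience,
                              seed=s)
            try:
                trained = train(spec, dataset, cfg)
                report = evaluate(trained, dataset, split=split)
            except Exception as exc:  # annotate, keep comparing
                error = f"{type(exc).__name__}: {exc}"
                break
            for t, m in report.metrics.items():
                for k, v in m.items():
                    per_target[t][k].append(v)
        for target, acc in per_target.items():
            row = {"topology": spec.topology, "extractor": spec.extractor,
                   "input_traits": "+".join(spec.input_traits),
                   "loss_weights": f"{spec.loss_weights[0]:g}:{spec.loss_weights[1]:g}",
                   "target": target, "n_seeds": len(acc["r2"]), "error": error}
            for k in ("r2", "rmse", "rrmse"):
                vals = np.array(acc[k])
                row[f"{k}_mean"] = float(vals.mean()) if vals.size else np.nan
                row[f"{k}_sd"] = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
            rows.append(row)
    table = pd.DataFrame(rows)
    table["rank"] = table.groupby("target")["r2_mean"].rank(
        ascending=False, method="min")
    return table
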