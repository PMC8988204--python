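"""Training protocol: Adam on weighted MAE with early stopping.

Mirrors a standard small-network regression protocol: batch size 32, Adam
at learning rate 1e-3, dropout 0.1, validation-loss early stopping with
best-weight restoration. Loss is computed on the normalized target scale;
evaluation metrics are reported on the raw scale by the evaluation module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DivergenceError
from .models import Model, ModelSpec, build_model, mae_loss, multitask_loss
from .nn.optim import Adam
from .prep import PreparedDataset


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.001
    batch_size: int = 32
    dropout_rate: float | None = None  # None -> use the model spec's rate
    max_epochs: int = 500
    early_stop_patience: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")
        if self.early_stop_patience < 1:
            raise ConfigurationError("early_stop_patience must be >= 1")
        if self.max_epochs < 1:
            raise ConfigurationError("max_epochs must be >= 1")


@dataclass
class TrainedModel:
    """A fitted model with its training history and normalization context."""

    spec: ModelSpec
    model: Model
    history: pd.DataFrame  # columns: epoch, train_loss, val_loss
    norm_params: object    # prep.NormParams of the training dataset
    seed: int
    best_epoch: int

    def predict_norm(self, dataset: PreparedDataset, idx=None) -> dict[str, np.ndarray]:
        inputs = dataset.inputs_for(self.spec.input_traits, idx)
        return self.model.predict(inputs)


def _batch_loss(model: Model, preds, targets):
    spec = model.spec
    if spec.n_outputs == 2:
        lam_gpc, lam_yield = spec.loss_weights
        return multitask_loss(preds["yield"], preds["gpc"],
                              targets["yield"], targets["gpc"],
                              lam_gpc=lam_gpc, lam_yield=lam_yield)
    t = spec.output_targets[0]
    return mae_loss(preds[t], targets[t])


def _epoch_loss(model: Model, dataset: PreparedDataset, idx: np.ndarray) -> float:
    inputs = dataset.inputs_for(model.spec.input_traits, idx)
    targets = dataset.targets_for(model.spec.output_targets, idx)
    preds, _ = model.forward(inputs, training=False)
    return float(_batch_loss(model, preds, targets).data)


def train(model: Model | ModelSpec, dataset: PreparedDataset,
          config: TrainConfig | None = None) -> TrainedModel:
    """Fit a model on the dataset's train split, monitoring the val split.

    Stops once the validation loss has not improved for
    ``early_stop_patience`` epochs and restores the best-validation
    weights. Bit-reproducible for fixed (model seed, config seed, data).
    """
    config = config or TrainConfig()
    if isinstance(model, ModelSpec):
        model = build_model(model, seed=config.seed)
    spec = model.spec
    for trait in spec.input_traits:
        dataset.trait_index(trait)  # raises if the dataset lacks the trait
    if dataset.splits is None or dataset.y_norm is None:
        raise ConfigurationError("train() needs a normalized, split dataset")
    train_idx = dataset.split_indices("train")
    val_idx = dataset.split_indices("val")
    if train_idx.size == 0 or val_idx.size == 0:
        raise ConfigurationError("train and val splits must be nonempty")

    rng = np.random.default_rng([config.seed, 23])
    params = model.parameters()
    opt = Adam(params, learning_rate=config.learning_rate)
    history = []
    best_val = np.inf
    best_weights = model.get_weights()
    best_epoch = 0
    since_best = 0
    bs = config.batch_size

    for epoch in range(config.max_epochs):
        order = rng.permutation(train_idx)
        total, count = 0.0, 0
        for start in range(0, order.size, bs):
            batch = order[start:start + bs]
            inputs = dataset.inputs_for(spec.input_traits, batch)
            targets = dataset.targets_for(spec.output_targets, batch)
            preds, _ = model.forward(inputs, training=True, rng=rng,
                                     dropout_rate=config.dropout_rate)
            loss = _batch_loss(model, preds, targets)
            if not np.isfinite(loss.data):
                raise DivergenceError(f"non-finite loss at epoch {epoch}", epoch)
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += float(loss.data) * batch.size
            count += batch.size
        train_loss = total / count
        val_loss = _epoch_loss(model, dataset, val_idx)
        if not np.isfinite(val_loss):
            raise DivergenceError(f"non-finite validation loss at epoch {epoch}", epoch)
        history.append((epoch, train_loss, val_loss))
        if val_loss < best_val:
            best_val = val_loss
            best_weights = model.get_weights()
            best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.early_stop_patience:
                break

    model.set_weights(best_weights)
    hist = pd.DataFrame(history, columns=["epoch", "train_loss", "val_loss"])
    return TrainedModel(spec=spec, model=model, history=hist,
                        norm_params=dataset.norm, seed=config.seed,
                        best_epoch=best_epoch)
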