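"""Network zoo for yield/GPC prediction from 89-day trait vectors.

Four topologies, named by (number of input traits)-to-(number of targets):

* ``one_to_one``  — single trait in, one target out (yield *or* GPC);
* ``one_to_two``  — single trait in, both targets out (multitask);
* ``two_to_one``  — two traits fused at feature level, one target out;
* ``two_to_two``  — feature-level fusion *and* multitask heads.

Single-input models stack three hidden layers of 16 units; dual-input
models encode each trait branch to 16 units, concatenate to 32, and pass
one more 16-unit hidden layer. The first encoding stage (the "extractor")
is interchangeable: FC (dense), vanilla RNN, LSTM, 1-D CNN, or a
temporal-attention module. Heads are single linear units on the normalized
target scale.

The multitask loss is a convex combination of per-task mean absolute
errors: ``lambda_gpc * MAE_gpc + lambda_yield * MAE_yield``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, InvalidArgumentError, ShapeError
from .nn import autodiff as ad
from .nn.autodiff import Tensor
from .nn.layers import LSTM, Conv1D, Dense, Dropout, SimpleRNN
from .synthetic import N_DAYS

TOPOLOGIES = ("one_to_one", "one_to_two", "two_to_one", "two_to_two")
EXTRACTORS = ("FC", "RNN", "LSTM", "CNN1D", "ATTENTION")
ATTENTION_CHANNELS = 5


@dataclass(frozen=True)
class ModelSpec:
    """Topology + extractor + loss-weight configuration.

    ``loss_weights`` is (lambda_gpc, lambda_yield); both default to 0.5.
    ``target`` selects the predicted variable for single-output topologies
    and is ignored (both heads built) for two-output ones.
    """

    topology: str
    extractor: str = "FC"
    input_traits: tuple[str, ...] = ("Hmean",)
    target: str | None = None
    hidden_width: int = 16
    input_length: int = N_DAYS
    loss_weights: tuple[float, float] = (0.5, 0.5)
    dropout_rate: float = 0.1
    softmax_attention: bool = True

    def __post_init__(self):
        if self.topology not in TOPOLOGIES:
            raise ConfigurationError(f"unknown topology {self.topology!r}")
        if self.extractor not in EXTRACTORS:
            raise ConfigurationError(f"unknown extractor {self.extractor!r}")
        n_in = 2 if self.topology.startswith("two") else 1
        if len(self.input_traits) != n_in:
            raise ConfigurationError(
                f"{self.topology} takes {n_in} input trait(s), got {self.input_traits}")
        if self.n_outputs == 1:
            if self.target not in ("yield", "gpc"):
                raise ConfigurationError(
                    f"{self.topology} needs target 'yield' or 'gpc', got {self.target!r}")
        lam1, lam2 = self.loss_weights
        if not (0.0 <= lam1 <= 1.0 and 0.0 <= lam2 <= 1.0):
            raise ConfigurationError("loss weights must lie in [0, 1]")
        if self.n_outputs == 2 and abs(lam1 + lam2 - 1.0) > 1e-9:
            raise ConfigurationError("loss weights must sum to 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigurationError("dropout_rate must be in [0, 1)")
        if self.hidden_width < 1 or self.input_length < 1:
            raise ConfigurationError("hidden_width and input_length must be >= 1")

    @property
    def n_inputs(self) -> int:
        return 2 if self.topology.startswith("two") else 1

    @property
    def n_outputs(self) -> int:
        return 2 if self.topology.endswith("two") else 1

    @property
    def output_targets(self) -> tuple[str, ...]:
        return ("yield", "gpc") if self.n_outputs == 2 else (self.target,)

    def to_dict(self) -> dict:
        return {"topology": self.topology, "extractor": self.extractor,
                "input_traits": list(self.input_traits), "target": self.target,
                "hidden_width": self.hidden_width, "input_length": self.input_length,
                "loss_weights": list(self.loss_weights),
                "dropout_rate": self.dropout_rate,
                "softmax_attention": self.softmax_attention}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        d = dict(d)
        d["input_traits"] = tuple(d["input_traits"])
        d["loss_weights"] = tuple(d["loss_weights"])
        return cls(**d)


# ---------------------------------------------------------------------------
# attention module

class AttentionCore:
    """Temporal-attention feature extractor.

    An LSTM with 5 units (returning full sequences) lifts the 89-day input
    to an 89 x 5 feature matrix. A parallel line transposes to channels x
    time, applies a per-channel dense map over the time axis, normalizes
    with a softmax along time, transposes back, and multiplies the two
    lines elementwise. The softmax weights, averaged over the 5 channels,
    are the per-day importance this module exposes.
    """

    def __init__(self, rng: np.random.Generator, input_length: int = N_DAYS,
                 channels: int = ATTENTION_CHANNELS, use_softmax: bool = True):
        self.input_length = input_length
        self.channels = channels
        self.use_softmax = use_softmax
        self.lstm = LSTM(1, channels, rng, return_sequences=True)
        from .nn.layers import glorot_uniform
        self.att_w = Tensor(glorot_uniform(rng, (channels, input_length, input_length),
                                           input_length, input_length),
                            requires_grad=True)
        self.att_b = Tensor(np.zeros((channels, input_length)), requires_grad=True)

    def __call__(self, x: Tensor) -> tuple[Tensor, Tensor]:
        """x: (batch, T, 1) -> (features (batch, T, C), attention (batch, T))."""
        B, T, _ = x.data.shape
        if T != self.input_length:
            raise ShapeError(f"attention extractor expects length {self.input_length}, got {T}")
        feats = self.lstm(x)                       # (B, T, C)
        per_channel = []
        for c in range(self.channels):
            logits = ad.add(ad.matmul(feats[:, :, c], self.att_w[c]), self.att_b[c])
            per_channel.append(ad.reshape(logits, (B, 1, T)))
        logits = ad.concat(per_channel, axis=1)    # (B, C, T)
        weights = ad.softmax(logits, axis=2) if self.use_softmax else ad.sigmoid(logits)
        weights_t = ad.transpose(weights, (0, 2, 1))  # (B, T, C)
        out = ad.mul(feats, weights_t)
        attention = ad.mean(weights, axis=1)       # (B, T), channel-averaged
        return out, attention

    def params(self):
        return self.lstm.params() + [self.att_w, self.att_b]


def extract_features_attention(x, core: AttentionCore | None = None,
                               seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Run the attention module on a (batch, 89, 1) array.

    Returns (features (batch, 89, 5), attention (batch, 89)); the attention
    row of each example is nonnegative and sums to one. A fresh
    seed-initialized module is built when ``core`` is not given.
    """
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 3 or arr.shape[2] != 1:
        raise ShapeError(f"expected (batch, T, 1) input, got {arr.shape}")
    core = core or AttentionCore(np.random.default_rng(seed),
                                 input_length=arr.shape[1])
    feats, att = core(Tensor(arr))
    return feats.data, att.data


# ---------------------------------------------------------------------------
# branch extractors

class _Branch:
    """One input branch: time-series extractor -> 16-unit encoding."""

    def __init__(self, kind: str, width: int, length: int,
                 rng: np.random.Generator, softmax_attention: bool = True):
        self.kind = kind
        self.attention_core: AttentionCore | None = None
        if kind == "FC":
            self.net = Dense(length, width, rng, activation="relu")
        elif kind == "RNN":
            self.net = SimpleRNN(1, width, rng)
        elif kind == "LSTM":
            self.net = LSTM(1, width, rng)
        elif kind == "CNN1D":
            self.conv = Conv1D(1, width, 3, rng, activation="relu")
        elif kind == "ATTENTION":
            self.attention_core = AttentionCore(rng, input_length=length,
                                                use_softmax=softmax_attention)
            self.proj = Dense(length * ATTENTION_CHANNELS, width, rng, activation="relu")
        else:
            raise ConfigurationError(f"unknown extractor {kind!r}")
        self.length = length

    def __call__(self, x: Tensor) -> tuple[Tensor, Tensor | None]:
        """x: (batch, length) -> ((batch, width) encoding, attention or None)."""
        B = x.data.shape[0]
        if self.kind == "FC":
            return self.net(x), None
        seq = ad.reshape(x, (B, self.length, 1))
        if self.kind in ("RNN", "LSTM"):
            return self.net(seq), None
        if self.kind == "CNN1D":
            return ad.mean(self.conv(seq), axis=1), None  # global average pool
        feats, att = self.attention_core(seq)
        flat = ad.reshape(feats, (B, self.length * ATTENTION_CHANNELS))
        return self.proj(flat), att

    def params(self):
        if self.kind == "FC" or self.kind in ("RNN", "LSTM"):
            return self.net.params()
        if self.kind == "CNN1D":
            return self.conv.params()
        return self.attention_core.params() + self.proj.params()


def build_extractor(kind: str, width: int = 16, length: int = N_DAYS,
                    seed: int = 0) -> _Branch:
    """Standalone branch extractor (mostly for inspection and tests)."""
    return _Branch(kind, width, length, np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# full model

class Model:
    """An untrained (or trained-in-place) network instance."""

    def __init__(self, spec: ModelSpec, seed: int = 0):
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng([seed, 11])
        w, L = spec.hidden_width, spec.input_length
        self.branches = [_Branch(spec.extractor, w, L, rng, spec.softmax_attention)
                         for _ in range(spec.n_inputs)]
        self.trunk: list[Dense] = []
        if spec.n_inputs == 1:
            # extractor is hidden layer 1; two more 16-unit hidden layers
            self.trunk = [Dense(w, w, rng, activation="relu"),
                          Dense(w, w, rng, activation="relu")]
            head_in = w
        else:
            # branch encodings concatenate to 32, one more 16-unit hidden layer
            self.trunk = [Dense(2 * w, w, rng, activation="relu")]
            head_in = w
        self.heads = {t: Dense(head_in, 1, rng) for t in spec.output_targets}
        self.dropout = Dropout(spec.dropout_rate)

    def parameters(self) -> list[Tensor]:
        ps: list[Tensor] = []
        for b in self.branches:
            ps.extend(b.params())
        for layer in self.trunk:
            ps.extend(layer.params())
        for head in self.heads.values():
            ps.extend(head.params())
        return ps

    def parameter_count(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def forward(self, inputs: Sequence[np.ndarray], training: bool = False,
                rng: np.random.Generator | None = None,
                dropout_rate: float | None = None
                ) -> tuple[dict[str, Tensor], list[np.ndarray]]:
        """Run a batch through the network.

        ``inputs`` holds one (batch, input_length) array per input trait.
        Returns per-target (batch,) prediction tensors and, for attention
        extractors, the per-branch (batch, 89) daily attention weights.
        """
        if len(inputs) != self.spec.n_inputs:
            raise ConfigurationError(
                f"{self.spec.topology} expects {self.spec.n_inputs} inputs, got {len(inputs)}")
        drop = self.dropout if dropout_rate is None else Dropout(dropout_rate)
        xs = []
        for arr in inputs:
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != self.spec.input_length:
                raise ShapeError(
                    f"each input must be (batch, {self.spec.input_length}), got {arr.shape}")
            xs.append(Tensor(arr))
        encodings, attentions = [], []
        for branch, x in zip(self.branches, xs):
            enc, att = branch(x)
            encodings.append(drop(enc, training, rng))
            if att is not None:
                attentions.append(att.data)
        h = encodings[0] if len(encodings) == 1 else ad.concat(encodings, axis=1)
        for layer in self.trunk:
            h = drop(layer(h), training, rng)
        preds = {t: ad.reshape(head(h), (-1,)) for t, head in self.heads.items()}
        return preds, attentions

    def predict(self, inputs: Sequence[np.ndarray]) -> dict[str, np.ndarray]:
        preds, _ = self.forward(inputs, training=False)
        return {t: p.data for t, p in preds.items()}

    def get_weights(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        params = self.parameters()
        if len(weights) != len(params):
            raise ConfigurationError("weight list length mismatch")
        for p, w in zip(params, weights):
            if p.data.shape != w.shape:
                raise ConfigurationError("weight shape mismatch")
            p.data = w.copy()


def build_model(spec: ModelSpec, seed: int = 0) -> Model:
    """Instantiate a network with seed-deterministic initial weights."""
    return Model(spec, seed=seed)


# ---------------------------------------------------------------------------
# loss

def multitask_loss(pred_yield, pred_gpc, true_yield, true_gpc,
                   lam_gpc: float = 0.5, lam_yield: float = 0.5):
    """Weighted multitask MAE: ``lam_gpc * MAE_gpc + lam_yield * MAE_yield``.

    Computed on the normalized target scale. Accepts arrays (returns a
    float) or autodiff tensors (returns a scalar tensor).
    """
    if lam_gpc < 0 or lam_yield < 0:
        raise InvalidArgumentError("loss weights must be nonnegative")
    tensors = any(isinstance(v, Tensor)
                  for v in (pred_yield, pred_gpc, true_yield, true_gpc))
    py, pg = ad.as_tensor(pred_yield), ad.as_tensor(pred_gpc)
    ty, tg = ad.as_tensor(true_yield), ad.as_tensor(true_gpc)
    if py.data.shape != ty.data.shape or pg.data.shape != tg.data.shape:
        raise InvalidArgumentError("prediction/truth length mismatch")
    total = ad.add(ad.mul(ad.mean(ad.absolute(pg - tg)), lam_gpc),
                   ad.mul(ad.mean(ad.absolute(py - ty)), lam_yield))
    return total if tensors else float(total.data)


def mae_loss(pred, true):
    """Plain MAE for single-target models (normalized scale)."""
    p, t = ad.as_tensor(pred), ad.as_tensor(true)
    if p.data.shape != t.data.shape:
        raise InvalidArgumentError("prediction/truth length mismatch")
    return ad.mean(ad.absolute(p - t))


# ---------------------------------------------------------------------------
# persistence

def save_model(model: Model, path: str | Path) -> Path:
    """Save weights (.npz) plus a JSON manifest of the spec and seed."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {f"p{i:03d}": p.data for i, p in enumerate(model.parameters())}
    np.savez_compressed(path, **arrays)
    manifest = {"spec": model.spec.to_dict(), "seed": model.seed}
    path.with_suffix(".json").write_text(json.dumps(manifest))
    return path


def load_model(path: str | Path) -> Model:
    path = Path(path)
    manifest = json.loads(path.with_suffix(".json").read_text())
    model = Model(ModelSpec.from_dict(manifest["spec"]), seed=manifest["seed"])
    arrays = np.load(path)
    model.set_weights([arrays[k] for k in sorted(arrays.files)])
    return model
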