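"""Dataset preparation: fixed-length vectors, interpolation, augmentation,
normalization and train/val/test splitting.

Each plot contributes an 8 x 89 feature matrix (traits x days after sowing
107..195). Gaps in the observed days are filled by piecewise-linear
interpolation (constant fill at the window edges). Targets — and by default
the trait features too — are min-max normalized to [0, 1] using statistics
of the *original* (non-augmented) examples only. Augmentation draws from
three time-series recipes (jitter, scale, resample) and perturbs both
normalized targets by a truncated Normal on [-0.05, 0.05].
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import truncnorm

from .errors import (ConfigurationError, DegenerateRangeError,
                     InsufficientDataError, InvalidArgumentError)
from .synthetic import (DAS_END, DAS_START, N_DAYS, TRAITS, PlotRecord,
                        TraitSeries)

TARGETS = ("yield", "gpc")
AUGMENT_METHODS = ("jitter", "scale", "resample")


@dataclass
class FeatureVector:
    """One trait's 89-day vector for one plot."""

    trait: str
    values: np.ndarray        # (89,), NaN where unobserved before interpolation
    observed_mask: np.ndarray  # (89,) bool

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.observed_mask = np.asarray(self.observed_mask, dtype=bool)
        if self.values.shape != (N_DAYS,) or self.observed_mask.shape != (N_DAYS,):
            raise InvalidArgumentError(f"feature vectors have length {N_DAYS}")


@dataclass(frozen=True)
class NormParams:
    """Min-max parameters for targets (and optionally per-trait features)."""

    targets: dict[str, tuple[float, float]]
    features: dict[str, tuple[float, float]] | None = None

    def normalize(self, values, target: str) -> np.ndarray:
        lo, hi = self.targets[target]
        return (np.asarray(values, float) - lo) / (hi - lo)

    def denormalize(self, values, target: str) -> np.ndarray:
        lo, hi = self.targets[target]
        return np.asarray(values, float) * (hi - lo) + lo

    def to_dict(self) -> dict:
        return {"targets": {k: list(v) for k, v in self.targets.items()},
                "features": None if self.features is None else
                {k: list(v) for k, v in self.features.items()}}

    @classmethod
    def from_dict(cls, d: dict) -> "NormParams":
        return cls(targets={k: tuple(v) for k, v in d["targets"].items()},
                   features=None if d.get("features") is None else
                   {k: tuple(v) for k, v in d["features"].items()})


def denormalize(values, params: NormParams, target: str) -> np.ndarray:
    """Map normalized target values back to their raw scale."""
    return params.denormalize(values, target)


@dataclass(frozen=True)
class PrepConfig:
    """Knobs of the preparation stage (all augmentation magnitudes are
    relative to normalized features)."""

    target_count: int = 1000
    methods: tuple[str, ...] = AUGMENT_METHODS
    jitter_frac: float = 0.03          # noise sd as fraction of per-trait sd
    scale_range: tuple[float, float] = (0.9, 1.1)
    resample_keep_frac: float = 0.6    # fraction of days kept before re-interpolation
    target_perturb: str = "truncnorm"  # or "uniform" on [-0.05, 0.05]
    target_perturb_limit: float = 0.05
    normalize_features: bool = True
    split_ratios: tuple[float, float, float] = (0.8, 0.1, 0.1)
    force_originals_in_test: bool = False


@dataclass
class PreparedDataset:
    """Model-ready tensors plus provenance and normalization metadata."""

    X: np.ndarray                     # (n, 8, 89)
    y_raw: np.ndarray                 # (n, 2), columns (yield, gpc)
    ids: list[str]
    provenance: np.ndarray            # (n,) of {"original", "augmented"}
    source_index: np.ndarray          # (n,) index of the source original
    traits: tuple[str, ...] = TRAITS
    y_norm: np.ndarray | None = None  # (n, 2) after normalize_targets
    norm: NormParams | None = None
    splits: dict[str, np.ndarray] | None = None
    seed: int | None = None

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def n_original(self) -> int:
        return int((self.provenance == "original").sum())

    def trait_index(self, trait: str) -> int:
        try:
            return self.traits.index(trait)
        except ValueError:
            raise InvalidArgumentError(f"trait {trait!r} not in dataset") from None

    def inputs_for(self, traits: Sequence[str], idx=None) -> list[np.ndarray]:
        """Per-branch (n, 89) input arrays for the given traits."""
        idx = slice(None) if idx is None else idx
        return [self.X[idx, self.trait_index(t), :] for t in traits]

    def targets_for(self, targets: Sequence[str], idx=None) -> dict[str, np.ndarray]:
        if self.y_norm is None:
            raise ConfigurationError("dataset targets are not normalized yet")
        idx = slice(None) if idx is None else idx
        return {t: self.y_norm[idx, TARGETS.index(t)] for t in targets}

    def split_indices(self, split: str) -> np.ndarray:
        if self.splits is None:
            raise ConfigurationError("dataset has no splits; call split() first")
        if split not in self.splits:
            raise InvalidArgumentError(f"unknown split {split!r}")
        return self.splits[split]


# ---------------------------------------------------------------------------
# vectorization & interpolation

def vectorize(series: TraitSeries) -> FeatureVector:
    """Place observations on the 89-day grid; unobserved entries are NaN."""
    values = np.full(N_DAYS, np.nan)
    mask = np.zeros(N_DAYS, dtype=bool)
    for das, value in series.observations.items():
        if not DAS_START <= das <= DAS_END:
            raise InvalidArgumentError(
                f"observation at DAS {das} outside [{DAS_START}, {DAS_END}]")
        values[das - DAS_START] = value
        mask[das - DAS_START] = True
    return FeatureVector(trait=series.trait, values=values, observed_mask=mask)


def interpolate_missing(vec: FeatureVector) -> FeatureVector:
    """Fill gaps by piecewise-linear interpolation between observed days.

    Leading/trailing gaps take the nearest observed value (constant fill),
    so the operation never extrapolates a trend. Observed entries are left
    untouched, which makes the operation idempotent.
    """
    obs = np.flatnonzero(vec.observed_mask)
    if obs.size < 2:
        raise InsufficientDataError(
            f"interpolation needs >= 2 observed days, got {obs.size}")
    filled = np.interp(np.arange(N_DAYS), obs, vec.values[obs])
    filled[obs] = vec.values[obs]
    return FeatureVector(trait=vec.trait, values=filled,
                         observed_mask=vec.observed_mask.copy())


def build_examples(plots: Sequence[PlotRecord],
                   series: Iterable[TraitSeries]) -> PreparedDataset:
    """Assemble interpolated 8 x 89 matrices and raw targets per plot."""
    by_plot: dict[str, dict[str, TraitSeries]] = {}
    for s in series:
        by_plot.setdefault(s.plot_id, {})[s.trait] = s
    n = len(plots)
    X = np.empty((n, len(TRAITS), N_DAYS))
    y = np.empty((n, 2))
    ids = []
    for i, plot in enumerate(plots):
        if plot.yield_true is None or plot.gpc_true is None:
            raise InvalidArgumentError(f"plot {plot.plot_id} has no targets")
        traits_here = by_plot.get(plot.plot_id, {})
        for j, trait in enumerate(TRAITS):
            if trait not in traits_here:
                raise InvalidArgumentError(
                    f"plot {plot.plot_id} is missing trait {trait}")
            X[i, j] = interpolate_missing(vectorize(traits_here[trait])).values
        y[i] = (plot.yield_true, plot.gpc_true)
        ids.append(plot.plot_id)
    return PreparedDataset(X=X, y_raw=y, ids=ids,
                           provenance=np.array(["original"] * n),
                           source_index=np.arange(n))


# ---------------------------------------------------------------------------
# normalization

def _minmax(values: np.ndarray, what: str) -> tuple[float, float]:
    lo, hi = float(np.min(values)), float(np.max(values))
    if hi <= lo:
        raise DegenerateRangeError(f"{what} has zero range ({lo}); cannot min-max normalize")
    return lo, hi


def normalize_targets(dataset: PreparedDataset) -> tuple[PreparedDataset, NormParams]:
    """Min-max normalize yield and GPC to [0, 1] over original examples."""
    orig = dataset.provenance == "original"
    targets = {}
    for k, name in enumerate(TARGETS):
        vals = dataset.y_raw[orig, k]
        if np.unique(vals).size < 2:
            raise DegenerateRangeError(f"target {name!r} is constant")
        targets[name] = _minmax(vals, f"target {name!r}")
    params = NormParams(targets=targets, features=dataset.norm.features
                        if dataset.norm else None)
    y_norm = np.column_stack([params.normalize(dataset.y_raw[:, k], name)
                              for k, name in enumerate(TARGETS)])
    out = dataclasses.replace(dataset, y_norm=y_norm, norm=params)
    return out, params


def normalize_features(dataset: PreparedDataset) -> PreparedDataset:
    """Min-max normalize each trait channel over original examples."""
    orig = dataset.provenance == "original"
    feats = {}
    X = dataset.X.copy()
    for j, trait in enumerate(dataset.traits):
        lo, hi = _minmax(dataset.X[orig, j, :], f"trait {trait!r}")
        feats[trait] = (lo, hi)
        X[:, j, :] = (X[:, j, :] - lo) / (hi - lo)
    norm = NormParams(targets=dataset.norm.targets if dataset.norm else {},
                      features=feats)
    return dataclasses.replace(dataset, X=X, norm=norm)


# ---------------------------------------------------------------------------
# augmentation

def _resample_row(row: np.ndarray, keep_idx: np.ndarray) -> np.ndarray:
    out = np.interp(np.arange(N_DAYS), keep_idx, row[keep_idx])
    out[keep_idx] = row[keep_idx]
    return out


def augment(dataset: PreparedDataset, target_count: int | None = None,
            methods: Sequence[str] | None = None, seed: int = 0,
            config: PrepConfig | None = None) -> PreparedDataset:
    """Grow the dataset to ``target_count`` examples with randomized copies.

    Each new example copies a random *original* example, applies one random
    method (jitter / scale / resample) to its feature matrix, and perturbs
    both normalized targets by a truncated Normal(0, (limit/3)^2) restricted
    to [-limit, limit]. Deterministic given ``seed``.
    """
    config = config or PrepConfig()
    target_count = config.target_count if target_count is None else target_count
    methods = tuple(config.methods if methods is None else methods)
    if not methods or any(m not in AUGMENT_METHODS for m in methods):
        raise InvalidArgumentError(
            f"methods must be a nonempty subset of {AUGMENT_METHODS}, got {methods}")
    n = len(dataset)
    if target_count < n:
        raise InvalidArgumentError(
            f"target_count={target_count} below current size {n}")
    if target_count == n:
        return dataset
    if dataset.y_norm is None:
        raise ConfigurationError("augment() requires normalized targets")
    rng = np.random.default_rng(seed)
    orig_idx = np.flatnonzero(dataset.provenance == "original")
    limit = config.target_perturb_limit
    n_keep = max(2, int(round(config.resample_keep_frac * N_DAYS)))

    new_X, new_y, new_ids, new_src = [], [], [], []
    for k in range(target_count - n):
        src = int(orig_idx[rng.integers(len(orig_idx))])
        method = methods[rng.integers(len(methods))]
        mat = dataset.X[src].copy()
        if method == "jitter":
            sds = mat.std(axis=1, keepdims=True)
            mat = mat + rng.normal(0.0, 1.0, mat.shape) * (config.jitter_frac * sds)
        elif method == "scale":
            mat = mat * rng.uniform(*config.scale_range)
        else:  # resample
            keep = np.sort(rng.choice(N_DAYS, size=n_keep, replace=False))
            mat = np.apply_along_axis(_resample_row, 1, mat, keep)
        if limit == 0.0:
            delta = np.zeros(2)
        elif config.target_perturb == "uniform":
            delta = rng.uniform(-limit, limit, size=2)
        else:
            delta = truncnorm.rvs(-3.0, 3.0, scale=limit / 3.0, size=2,
                                  random_state=rng)
        new_X.append(mat)
        new_y.append(dataset.y_norm[src] + delta)
        new_ids.append(f"{dataset.ids[src]}-aug{k:04d}")
        new_src.append(src)

    X = np.concatenate([dataset.X, np.stack(new_X)], axis=0)
    y_norm = np.concatenate([dataset.y_norm, np.stack(new_y)], axis=0)
    y_raw_new = np.column_stack([
        dataset.norm.denormalize(np.stack(new_y)[:, k], name)
        for k, name in enumerate(TARGETS)]) if dataset.norm else np.stack(new_y)
    y_raw = np.concatenate([dataset.y_raw, y_raw_new], axis=0)
    return dataclasses.replace(
        dataset,
        X=X, y_raw=y_raw, y_norm=y_norm,
        ids=dataset.ids + new_ids,
        provenance=np.concatenate([dataset.provenance,
                                   np.array(["augmented"] * len(new_ids))]),
        source_index=np.concatenate([dataset.source_index, np.array(new_src)]),
    )


# ---------------------------------------------------------------------------
# splitting

def split(dataset: PreparedDataset,
          ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
          seed: int = 0, force_originals_in_test: bool = False) -> PreparedDataset:
    """Random disjoint exhaustive train/val/test assignment.

    Val and test get floor allocations; the remainder goes to train.
    ``force_originals_in_test`` restricts the test split to original
    (non-augmented) examples, avoiding augmented-copy leakage.
    """
    ratios = tuple(float(r) for r in ratios)
    if len(ratios) != 3 or any(r <= 0 for r in ratios):
        raise InvalidArgumentError(f"ratios must be three positive numbers, got {ratios}")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise InvalidArgumentError(f"ratios must sum to 1, got sum={sum(ratios)}")
    n = len(dataset)
    n_val = int(np.floor(ratios[1] * n))
    n_test = int(np.floor(ratios[2] * n))
    rng = np.random.default_rng(seed)
    if force_originals_in_test:
        orig = np.flatnonzero(dataset.provenance == "original")
        if n_test > orig.size:
            raise InvalidArgumentError(
                f"test split of {n_test} exceeds {orig.size} original examples")
        test = rng.permutation(orig)[:n_test]
        rest = rng.permutation(np.setdiff1d(np.arange(n), test))
        val, train = rest[:n_val], rest[n_val:]
    else:
        perm = rng.permutation(n)
        test, val, train = perm[:n_test], perm[n_test:n_test + n_val], perm[n_test + n_val:]
    splits = {"train": np.sort(train), "val": np.sort(val), "test": np.sort(test)}
    return dataclasses.replace(dataset, splits=splits)


# ---------------------------------------------------------------------------
# one-shot pipeline & persistence

def prepare_dataset(plots: Sequence[PlotRecord], series: Iterable[TraitSeries],
                    config: PrepConfig | None = None, seed: int = 0) -> PreparedDataset:
    """Full preparation: assemble, normalize, augment, split."""
    config = config or PrepConfig()
    ds = build_examples(plots, series)
    ds, _ = normalize_targets(ds)
    if config.normalize_features:
        ds = normalize_features(ds)
    ds = augment(ds, config.target_count, config.methods,
                 seed=_subseed(seed, 1), config=config)
    ds = split(ds, config.split_ratios, seed=_subseed(seed, 2),
               force_originals_in_test=config.force_originals_in_test)
    return dataclasses.replace(ds, seed=seed)


def _subseed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2 ** 31))


def save_prepared(dataset: PreparedDataset, path: str | Path) -> Path:
    """Save tensors as .npz with a JSON sidecar of metadata."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {"X": dataset.X, "y_raw": dataset.y_raw,
              "source_index": dataset.source_index}
    if dataset.y_norm is not None:
        arrays["y_norm"] = dataset.y_norm
    if dataset.splits is not None:
        for k, v in dataset.splits.items():
            arrays[f"split_{k}"] = v
    np.savez_compressed(path, **arrays)
    meta = {"ids": dataset.ids, "provenance": dataset.provenance.tolist(),
            "traits": list(dataset.traits), "seed": dataset.seed,
            "norm": dataset.norm.to_dict() if dataset.norm else None}
    path.with_suffix(".json").write_text(json.dumps(meta))
    return path


def load_prepared(path: str | Path) -> PreparedDataset:
    path = Path(path)
    arrays = np.load(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    splits = {k.removeprefix("split_"): arrays[k]
              for k in arrays.files if k.startswith("split_")} or None
    return PreparedDataset(
        X=arrays["X"], y_raw=arrays["y_raw"], ids=list(meta["ids"]),
        provenance=np.array(meta["provenance"]),
        source_index=arrays["source_index"], traits=tuple(meta["traits"]),
        y_norm=arrays["y_norm"] if "y_norm" in arrays.files else None,
        norm=NormParams.from_dict(meta["norm"]) if meta["norm"] else None,
        splits=splits, seed=meta["seed"])
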