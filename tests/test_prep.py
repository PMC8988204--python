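"""Vectorization, interpolation, augmentation, normalization, splitting."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from canopynet.errors import (DegenerateRangeError, InsufficientDataError,
                              InvalidArgumentError)
from canopynet.prep import (FeatureVector, NormParams, PrepConfig,
                            PreparedDataset, augment, build_examples,
                            denormalize, interpolate_missing, load_prepared,
                            normalize_targets, prepare_dataset, save_prepared,
                            split, vectorize)
from canopynet.synthetic import (N_DAYS, TraitSeries, simulate_dataset)
from _oracles import interpolate_scalar


def make_series(obs, trait="Hmean"):
    return TraitSeries(plot_id="P0001", trait=trait, observations=obs)


# -- vectorize ---------------------------------------------------------------

def test_vectorize_places_observations_and_mask():
    full = make_series({d: float(d) for d in range(107, 196)})
    vec = vectorize(full)
    assert vec.observed_mask.all()
    assert vec.values[0] == 107 and vec.values[-1] == 195
    partial = make_series({107: 1.0, 150: 2.0, 195: 3.0})
    vec = vectorize(partial)
    assert vec.observed_mask.sum() == 3
    assert np.isnan(vec.values[1])


def test_vectorize_rejects_out_of_window_observation():
    with pytest.raises(InvalidArgumentError):
        make_series({200: 1.0})  # construction already enforces the window


# -- interpolation -----------------------------------------------------------

def test_linear_interpolation_midpoint_and_identity():
    vec = vectorize(make_series({107: 1.0, 109: 3.0}))
    out = interpolate_missing(vec)
    assert out.values[1] == pytest.approx(2.0)
    full = vectorize(make_series({d: float(d) % 7 for d in range(107, 196)}))
    np.testing.assert_array_equal(interpolate_missing(full).values, full.values)


def test_leading_and_trailing_gaps_take_nearest_value():
    vec = vectorize(make_series({110: 5.0, 190: 7.0}))
    out = interpolate_missing(vec)
    assert np.all(out.values[:3] == 5.0)
    assert np.all(out.values[-5:] == 7.0)


def test_interpolation_requires_two_observations():
    with pytest.raises(InsufficientDataError):
        interpolate_missing(vectorize(make_series({150: 1.0})))


def test_interpolation_is_idempotent():
    rng = np.random.default_rng(3)
    obs = {int(d): float(v) for d, v in
           zip(np.sort(rng.choice(np.arange(107, 196), 20, replace=False)),
               rng.normal(size=20))}
    once = interpolate_missing(vectorize(make_series(obs)))
    twice = interpolate_missing(once)
    np.testing.assert_array_equal(once.values, twice.values)


@given(st.integers(0, 10_000))
def test_interpolation_matches_scalar_oracle(seed):
    rng = np.random.default_rng(seed)
    mask = np.zeros(N_DAYS, dtype=bool)
    mask[rng.choice(N_DAYS, size=int(rng.integers(2, 40)), replace=False)] = True
    values = np.where(mask, rng.normal(size=N_DAYS), np.nan)
    vec = FeatureVector(trait="CVI", values=values, observed_mask=mask)
    expected = interpolate_scalar([0.0 if np.isnan(v) else v for v in values],
                                  list(mask))
    np.testing.assert_allclose(interpolate_missing(vec).values, expected,
                               atol=1e-12)


# -- normalization -----------------------------------------------------------

def _dataset(y, n_traits_value=0.5):
    n = len(y)
    return PreparedDataset(
        X=np.full((n, 8, N_DAYS), n_traits_value),
        y_raw=np.asarray(y, dtype=float),
        ids=[f"P{i:04d}" for i in range(n)],
        provenance=np.array(["original"] * n),
        source_index=np.arange(n))


def test_minmax_normalization_endpoints_and_round_trip(rng):
    ds = _dataset([[2000.0, 9.0], [4000.0, 11.0], [6000.0, 15.0]])
    out, params = normalize_targets(ds)
    np.testing.assert_allclose(out.y_norm[:, 0], [0.0, 0.5, 1.0])
    raw = rng.uniform(2000, 6000, size=100)
    back = denormalize(params.normalize(raw, "yield"), params, "yield")
    assert np.max(np.abs(back - raw)) < 1e-12


def test_constant_target_rejected():
    with pytest.raises(DegenerateRangeError):
        normalize_targets(_dataset([[2000.0, 12.0], [4000.0, 12.0]]))


# -- augmentation ------------------------------------------------------------

@pytest.fixture(scope="module")
def tiny_prepared():
    plots, series = simulate_dataset(seed=3, n_varieties=12, n_nitrogen=2,
                                     n_reps=2)
    ds = build_examples(plots, series)
    ds, _ = normalize_targets(ds)
    return ds


def test_augment_reaches_target_count_and_flags(tiny_prepared):
    out = augment(tiny_prepared, target_count=100, seed=5)
    assert len(out) == 100
    assert (out.provenance == "augmented").sum() == 100 - len(tiny_prepared)
    # originals appear unchanged, in place
    np.testing.assert_array_equal(out.X[:len(tiny_prepared)], tiny_prepared.X)
    assert (out.y_norm[(out.provenance == "augmented")] >= -0.05 - 1e-12).all()
    assert (out.y_norm[(out.provenance == "augmented")] <= 1.05 + 1e-12).all()


def test_augment_noop_and_validation(tiny_prepared):
    assert augment(tiny_prepared, target_count=len(tiny_prepared), seed=1) \
        is tiny_prepared
    with pytest.raises(InvalidArgumentError):
        augment(tiny_prepared, target_count=3, seed=1)
    with pytest.raises(InvalidArgumentError):
        augment(tiny_prepared, target_count=100, methods=("warp",), seed=1)


def test_degenerate_augmentation_copies_source(tiny_prepared):
    cfg = PrepConfig(jitter_frac=0.0, scale_range=(1.0, 1.0),
                     target_perturb_limit=0.0)
    out = augment(tiny_prepared, target_count=len(tiny_prepared) + 5,
                  methods=("jitter", "scale"), seed=5, config=cfg)
    for i in range(len(tiny_prepared), len(out)):
        src = out.source_index[i]
        np.testing.assert_array_equal(out.X[i], out.X[src])
        np.testing.assert_array_equal(out.y_norm[i], out.y_norm[src])


def test_augment_deterministic(tiny_prepared):
    a = augment(tiny_prepared, target_count=80, seed=9)
    b = augment(tiny_prepared, target_count=80, seed=9)
    np.testing.assert_array_equal(a.X, b.X)
    assert a.ids == b.ids


# -- splitting ---------------------------------------------------------------

def test_split_sizes_floor_with_remainder_to_train():
    ds = _dataset(np.column_stack([np.linspace(2000, 9000, 1000),
                                   np.linspace(8, 16, 1000)]))
    out = split(ds, (0.8, 0.1, 0.1), seed=0)
    assert {k: v.size for k, v in out.splits.items()} == \
        {"train": 800, "val": 100, "test": 100}
    small = split(_dataset(np.column_stack([np.arange(10), np.arange(10)])),
                  (0.8, 0.1, 0.1), seed=0)
    assert {k: v.size for k, v in small.splits.items()} == \
        {"train": 8, "val": 1, "test": 1}


def test_split_disjoint_exhaustive_deterministic():
    ds = _dataset(np.column_stack([np.arange(57.0), np.arange(57.0)]))
    a = split(ds, (0.6, 0.2, 0.2), seed=4)
    b = split(ds, (0.6, 0.2, 0.2), seed=4)
    union = np.concatenate(list(a.splits.values()))
    assert np.array_equal(np.sort(union), np.arange(57))
    for k in a.splits:
        np.testing.assert_array_equal(a.splits[k], b.splits[k])


def test_split_rejects_bad_ratios():
    ds = _dataset(np.column_stack([np.arange(10.0), np.arange(10.0)]))
    with pytest.raises(InvalidArgumentError):
        split(ds, (0.5, 0.5, 0.5), seed=0)
    with pytest.raises(InvalidArgumentError):
        split(ds, (0.9, 0.2, -0.1), seed=0)


def test_force_originals_in_test(tiny_prepared):
    ds = augment(tiny_prepared, target_count=100, seed=5)
    out = split(ds, (0.8, 0.1, 0.1), seed=2, force_originals_in_test=True)
    assert all(ds.provenance[i] == "original" for i in out.splits["test"])


# -- persistence -------------------------------------------------------------

def test_prepared_dataset_round_trip(tmp_path, tiny_prepared):
    ds = augment(tiny_prepared, target_count=60, seed=1)
    ds = split(ds, (0.8, 0.1, 0.1), seed=1)
    path = save_prepared(ds, tmp_path / "prepared.npz")
    back = load_prepared(path)
    np.testing.assert_array_equal(back.X, ds.X)
    np.testing.assert_array_equal(back.y_norm, ds.y_norm)
    assert back.ids == ds.ids
    assert back.norm.targets == ds.norm.targets
    for k in ds.splits:
        np.testing.assert_array_equal(back.splits[k], ds.splits[k])
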