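"""Generator contracts: design factorial, latent draws, curves, targets."""

import dataclasses

import numpy as np
import pytest

from canopynet.errors import InvalidArgumentError
from canopynet.synthetic import (DAS_END, DAS_START, GeneratorConfig, TRAITS,
                                 apply_missingness, planted_postanthesis_config,
                                 read_dataset, simulate_dataset, simulate_design,
                                 simulate_latent, simulate_targets,
                                 simulate_trait_series, trait_curve,
                                 write_dataset)

ZERO_VAR = GeneratorConfig(
    h_max=(0.9, 0.0), growth_rate=(0.12, 0.0), t_mid=(135.0, 0.0),
    t_anthesis=(160.0, 0.0), senescence_rate=(0.08, 0.0), vigor=(1.0, 0.0),
    vigor_plot_sd=0.0, n_effect_control=(1.0, 0.0), n_effect_deficient=(0.7, 0.0),
    yield_noise_sd=0.0, gpc_noise_sd=0.0, noise_frac=0.0)


# -- design ------------------------------------------------------------------

@pytest.mark.parametrize("nv,nn,nr,expected", [(120, 2, 2, 480), (1, 1, 1, 1),
                                               (3, 2, 2, 12)])
def test_design_is_full_factorial(nv, nn, nr, expected):
    records = simulate_design(nv, nn, nr, seed=7)
    assert len(records) == expected
    combos = {(r.variety_id, r.nitrogen_level, r.replication) for r in records}
    assert len(combos) == expected  # each combination exactly once
    assert len({r.plot_id for r in records}) == expected


def test_design_rejects_nonpositive_counts():
    with pytest.raises(InvalidArgumentError):
        simulate_design(0, 2, 2)
    with pytest.raises(InvalidArgumentError):
        simulate_design(5, -1, 2)


# -- latent states -----------------------------------------------------------

def test_latent_deterministic_and_ordered():
    rec = simulate_design(5, 2, 2)[3]
    s1 = simulate_latent(rec, seed=11)
    s2 = simulate_latent(rec, seed=11)
    assert s1 == s2
    assert DAS_START < s1.t_mid < s1.t_anthesis < DAS_END


def test_zero_variance_config_collapses_to_means():
    rec = simulate_design(1, 2, 2)[0]
    state = simulate_latent(rec, ZERO_VAR, seed=5)
    assert state.h_max == 0.9
    assert state.growth_rate == 0.12
    assert state.t_mid == 135.0
    assert state.t_anthesis == 160.0
    assert state.vigor == 1.0
    assert state.n_effect == 1.0


def test_nitrogen_effect_higher_under_control():
    records = simulate_design(1, 2, 1)
    control, deficient = records[0], records[1]
    c = [simulate_latent(control, seed=s).n_effect for s in range(1000)]
    d = [simulate_latent(deficient, seed=s).n_effect for s in range(1000)]
    assert np.mean(c) > np.mean(d)


# -- trait curves ------------------------------------------------------------

def test_structural_curve_rises_to_plateau():
    state = simulate_latent(simulate_design(1, 1, 1)[0], seed=3)
    series = simulate_trait_series(state, "Hmean", noise_sd=0.0)
    values = [series.observations[d] for d in range(DAS_START, DAS_END + 1)]
    assert values[-1] >= values[0]
    assert np.all(np.diff(values) >= 0)  # noiseless logistic is nondecreasing


def test_spectral_peak_between_midgrowth_and_anthesis():
    state = simulate_latent(simulate_design(1, 1, 1)[0], seed=3)
    das = np.arange(DAS_START, DAS_END + 1)
    curve = trait_curve(state, "GNDVI", das)
    peak_das = das[np.argmax(curve)]
    assert state.t_mid <= peak_das <= state.t_anthesis + 5


def test_trait_series_deterministic_and_unknown_trait_rejected():
    state = simulate_latent(simulate_design(1, 1, 1)[0], seed=3)
    a = simulate_trait_series(state, "CVI", noise_sd=0.1, seed=9)
    b = simulate_trait_series(state, "CVI", noise_sd=0.1, seed=9)
    assert a.observations == b.observations
    with pytest.raises(InvalidArgumentError):
        simulate_trait_series(state, "NDVI")


# -- targets -----------------------------------------------------------------

def test_noiseless_targets_match_closed_form():
    cfg = ZERO_VAR
    rec = simulate_design(1, 1, 1)[0]
    state = simulate_latent(rec, cfg, seed=0)
    yld, gpc = simulate_targets(state, cfg, seed=0)
    expected_yield = cfg.a0 + cfg.a1 * 0.9 * 1.0 + cfg.a2 * 1.0 * (195 - 160)
    assert yld == pytest.approx(expected_yield, abs=1e-9)
    z = (expected_yield - cfg.yield_center) / cfg.yield_scale
    assert gpc == pytest.approx(cfg.b0 + cfg.b1 * 1.0 - cfg.b2 * z, abs=1e-9)


def test_yield_gpc_tradeoff_within_nitrogen_level():
    """Within each N level the yield-GPC correlation is negative
    (permutation test, 999 shuffles, p < 0.05)."""
    plots, _ = simulate_dataset(seed=4, missingness=False, noise=False)
    y = np.array([(p.yield_true, p.gpc_true) for p in plots])
    levels = np.array([p.nitrogen_level for p in plots])
    rng = np.random.default_rng(0)
    for level in (240.0, 0.0):
        m = levels == level
        r_obs = np.corrcoef(y[m, 0], y[m, 1])[0, 1]
        assert r_obs < 0
        perm = [np.corrcoef(y[m, 0], rng.permutation(y[m, 1]))[0, 1]
                for _ in range(999)]
        p_val = (1 + sum(r <= r_obs for r in perm)) / (1 + 999)
        assert p_val < 0.05


def test_positive_b1_raises_control_gpc_when_tradeoff_removed():
    cfg = GeneratorConfig(b2=0.0)
    records = simulate_design(1, 2, 1)
    gpc_c = [simulate_targets(simulate_latent(records[0], cfg, seed=s), cfg,
                              seed=s)[1] for s in range(1000)]
    gpc_d = [simulate_targets(simulate_latent(records[1], cfg, seed=s), cfg,
                              seed=s)[1] for s in range(1000)]
    assert np.mean(gpc_c) > np.mean(gpc_d)


def test_planted_signal_recoverable_by_regression():
    """With vigor/anthesis variance off and no noise, OLS of yield on
    h_max*n_effect recovers the generator coefficient a1 to 1e-6."""
    cfg = dataclasses.replace(
        GeneratorConfig(), vigor=(1.0, 0.0), vigor_plot_sd=0.0,
        t_anthesis=(160.0, 0.0), yield_noise_sd=0.0, gpc_noise_sd=0.0)
    plots = simulate_design(60, 2, 1)
    x, y = [], []
    for i, rec in enumerate(plots):
        state = simulate_latent(rec, cfg, seed=2)
        yld, _ = simulate_targets(state, cfg, seed=i)
        x.append(state.h_max * state.n_effect)
        y.append(yld)
    slope = np.polyfit(x, y, 1)[0]
    assert slope == pytest.approx(cfg.a1, abs=1e-6)


def test_planted_postanthesis_config_freezes_preanthesis_dynamics():
    plots, series = simulate_dataset(planted_postanthesis_config(), seed=5,
                                     n_varieties=4, n_nitrogen=1, n_reps=1,
                                     noise=False, missingness=False)
    gndvi = [s for s in series if s.trait == "GNDVI"]
    pre = [[s.observations[d] for d in range(DAS_START, 141)] for s in gndvi]
    assert np.allclose(pre[0], pre[1]) and np.allclose(pre[0], pre[2])
    yields = [p.yield_true for p in plots]
    assert np.std(yields) > 0  # targets still vary through anthesis timing


# -- missingness -------------------------------------------------------------

def test_missingness_keeps_endpoints_and_count():
    state = simulate_latent(simulate_design(1, 1, 1)[0], seed=3)
    full = simulate_trait_series(state, "PLA")
    assert apply_missingness(full, 89, seed=0).observations == full.observations
    sub = apply_missingness(full, 53, seed=0)
    assert len(sub.observations) == 53
    assert DAS_START in sub.observations and DAS_END in sub.observations
    only_ends = apply_missingness(full, 2, seed=0)
    assert sorted(only_ends.observations) == [DAS_START, DAS_END]
    with pytest.raises(InvalidArgumentError):
        apply_missingness(full, 1, seed=0)
    with pytest.raises(InvalidArgumentError):
        apply_missingness(full, 90, seed=0)


# -- I/O ---------------------------------------------------------------------

def test_dataset_round_trip_and_row_count(tmp_path):
    cfg = GeneratorConfig(n_observed_cycle=(53,))
    plots, series = simulate_dataset(cfg, seed=9, n_varieties=5, n_nitrogen=2,
                                     n_reps=2)
    assert sum(len(s.observations) for s in series) == 20 * 8 * 53
    write_dataset(plots, series, tmp_path)
    plots2, series2 = read_dataset(tmp_path)
    assert plots2 == plots
    assert {(s.plot_id, s.trait): s.observations for s in series2} == \
           {(s.plot_id, s.trait): s.observations for s in series}


def test_write_empty_dataset_gives_header_only(tmp_path):
    plots_path, traits_path = write_dataset([], [], tmp_path)
    assert plots_path.read_text().strip() == \
        "plot_id,variety_id,nitrogen_level,replication,block,yield,gpc"
    assert traits_path.read_text().strip() == "plot_id,das,trait,value"
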