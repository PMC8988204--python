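"""Synthetic field-trial generator.

Emulates a winter-wheat phenotyping trial: a full-factorial split-plot
design (varieties x nitrogen levels x replications), per-plot latent growth
states, eight canopy trait time series sampled near-daily over the sensing
window (days after sowing 107..195), and plot-level grain yield and grain
protein content (GPC) targets.

The statistical structure the downstream models rely on is planted
explicitly:

* structural traits (Hmean, H99, PLA, Volume) follow a logistic rise to a
  plateau proportional to ``h_max * n_effect * vigor``;
* spectral indices (GNDVI, CVI, NCPI, MCARI) rise logistically and decline
  exponentially after anthesis at ``senescence_rate``;
* yield is linear in ``h_max * n_effect`` and in the grain-filling window
  ``vigor * (195 - t_anthesis)``;
* GPC rises with nitrogen supply and trades off against standardized yield,
  giving the familiar negative yield-protein correlation within a nitrogen
  level.

Every function is deterministic for a given (inputs, seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError

DAS_START = 107
DAS_END = 195
N_DAYS = DAS_END - DAS_START + 1  # 89-day sensing window

SPECTRAL_TRAITS = ("GNDVI", "CVI", "NCPI", "MCARI")
STRUCTURAL_TRAITS = ("Hmean", "H99", "PLA", "Volume")
TRAITS = SPECTRAL_TRAITS + STRUCTURAL_TRAITS

NITROGEN_CONTROL = 240.0  # kg/ha
NITROGEN_DEFICIENT = 0.0

# Seasonal curve shape per trait: structural plateaus are per unit of
# h_max * n_effect * vigor (h_max in m); spectral amplitudes scale as
# n_effect * sqrt(vigor). `range` is the nominal dynamic range used to set
# the default observation-noise scale.
TRAIT_CURVES: dict[str, dict] = {
    "Hmean":  {"kind": "structural", "scale": 720.0,  "floor": 0.0,  "range": 650.0},
    "H99":    {"kind": "structural", "scale": 1110.0, "floor": 0.0,  "range": 1000.0},
    "PLA":    {"kind": "structural", "scale": 1.25,   "floor": 0.0,  "range": 1.1},
    "Volume": {"kind": "structural", "scale": 0.55,   "floor": 0.0,  "range": 0.45},
    "GNDVI":  {"kind": "spectral",   "scale": 0.65,   "floor": 0.15, "range": 0.65},
    "CVI":    {"kind": "spectral",   "scale": 3.2,    "floor": 1.2,  "range": 3.2},
    "NCPI":   {"kind": "spectral",   "scale": 0.30,   "floor": 0.05, "range": 0.30},
    "MCARI":  {"kind": "spectral",   "scale": 0.95,   "floor": 0.10, "range": 0.95},
}

SeedLike = int | Sequence[int]


@dataclass(frozen=True)
class PlotRecord:
    """One experimental plot of the trial design."""

    plot_id: str
    variety_id: int
    nitrogen_level: float  # kg/ha applied N (240 control, 0 deficient)
    replication: int
    block: int
    yield_true: float | None = None  # kg/ha
    gpc_true: float | None = None    # percent


@dataclass(frozen=True)
class LatentPlotState:
    """Latent growth parameters that drive one plot's traits and targets."""

    h_max: float            # maximum canopy height, m
    growth_rate: float      # logistic growth rate, 1/day
    t_mid: float            # DAS of fastest growth
    t_anthesis: float       # DAS of anthesis (flowering)
    senescence_rate: float  # post-anthesis decay rate of spectral signal, 1/day
    vigor: float            # dimensionless canopy-density scalar
    n_effect: float         # dimensionless nitrogen multiplier

    def __post_init__(self):
        if not (DAS_START < self.t_mid < self.t_anthesis < DAS_END):
            raise InvalidArgumentError(
                f"need {DAS_START} < t_mid < t_anthesis < {DAS_END}, got "
                f"t_mid={self.t_mid}, t_anthesis={self.t_anthesis}")
        if self.h_max <= 0 or self.growth_rate <= 0 or self.senescence_rate <= 0:
            raise InvalidArgumentError("h_max and rates must be positive")


@dataclass
class TraitSeries:
    """One trait's DAS-indexed values for one plot (gaps allowed)."""

    plot_id: str
    trait: str
    observations: dict[int, float]

    def __post_init__(self):
        if not all(DAS_START <= d <= DAS_END for d in self.observations):
            raise InvalidArgumentError(
                f"all DAS must lie in [{DAS_START}, {DAS_END}]")
        if not 1 <= len(self.observations) <= N_DAYS:
            raise InvalidArgumentError("series must hold 1..89 observations")


@dataclass(frozen=True)
class GeneratorConfig:
    """Distributions and coefficients of the synthetic trial.

    Latent-parameter entries are (mean, sd) of a Normal draw; plot-level
    nitrogen multipliers are drawn per plot, everything else per variety.
    """

    h_max: tuple[float, float] = (0.9, 0.1)               # m
    growth_rate: tuple[float, float] = (0.12, 0.02)       # 1/day
    t_mid: tuple[float, float] = (135.0, 5.0)             # DAS
    t_anthesis: tuple[float, float] = (160.0, 3.0)        # DAS
    senescence_rate: tuple[float, float] = (0.08, 0.02)   # 1/day
    vigor: tuple[float, float] = (1.0, 0.15)
    vigor_plot_sd: float = 0.05        # relative plot-to-plot vigor jitter
    n_effect_control: tuple[float, float] = (1.0, 0.08)
    n_effect_deficient: tuple[float, float] = (0.7, 0.08)
    # yield = a0 + a1*h_max*n_effect + a2*vigor*(195 - t_anthesis) + eps
    a0: float = 300.0      # kg/ha intercept
    a1: float = 5500.0     # kg/ha per (m * n_effect)
    a2: float = 30.0       # kg/ha per (vigor * day of grain filling)
    yield_noise_sd: float = 250.0   # kg/ha
    # gpc = b0 + b1*n_effect - b2*(yield - yield_center)/yield_scale + eps
    b0: float = 5.5        # percent intercept
    b1: float = 8.0        # percent per unit n_effect
    b2: float = 1.5        # percent per standardized-yield unit (trade-off)
    yield_center: float = 5400.0
    yield_scale: float = 1500.0
    gpc_noise_sd: float = 0.3       # percent
    noise_frac: float = 0.03        # trait noise sd as fraction of trait range
    n_observed_cycle: tuple[int, ...] = (51, 53)  # observed days, alternating

    def trait_noise_sd(self, trait: str) -> float:
        return self.noise_frac * TRAIT_CURVES[trait]["range"]

    def replace(self, **kwargs) -> "GeneratorConfig":
        return dataclasses.replace(self, **kwargs)


def planted_postanthesis_config() -> GeneratorConfig:
    """A probe configuration whose target signal is only visible after anthesis.

    All latent parameters are frozen at their means except the anthesis date,
    so every plot's trait curves are identical before anthesis; yield and GPC
    vary only through ``t_anthesis``, which spectral indices reveal through
    the onset of their post-anthesis decline. Used to test that the attention
    extractor concentrates importance on the post-anthesis days.
    """
    return GeneratorConfig(
        h_max=(0.9, 0.0), growth_rate=(0.12, 0.0), t_mid=(135.0, 0.0),
        t_anthesis=(160.0, 6.0), senescence_rate=(0.10, 0.0),
        vigor=(1.0, 0.0), vigor_plot_sd=0.0,
        n_effect_control=(1.0, 0.0), n_effect_deficient=(0.7, 0.0),
        yield_noise_sd=30.0, gpc_noise_sd=0.03, noise_frac=0.005,
    )


# ---------------------------------------------------------------------------
# design & latent state

def simulate_design(n_varieties: int, n_nitrogen: int, n_reps: int,
                    seed: int = 0) -> list[PlotRecord]:
    """Full-factorial split-plot design: every (variety, N, rep) once.

    Nitrogen levels are 240 kg/ha (control) and 0 kg/ha (deficient) for the
    standard two-level trial; other counts space levels evenly in between.
    """
    for name, v in (("n_varieties", n_varieties), ("n_nitrogen", n_nitrogen),
                    ("n_reps", n_reps)):
        if not isinstance(v, (int, np.integer)) or v < 1:
            raise InvalidArgumentError(f"{name} must be a positive integer, got {v!r}")
    levels = np.linspace(NITROGEN_CONTROL, NITROGEN_DEFICIENT, n_nitrogen) \
        if n_nitrogen > 1 else np.array([NITROGEN_CONTROL])
    records = []
    i = 0
    for variety in range(1, n_varieties + 1):
        for n_idx, level in enumerate(levels):
            for rep in range(1, n_reps + 1):
                i += 1
                records.append(PlotRecord(
                    plot_id=f"P{i:04d}",
                    variety_id=variety,
                    nitrogen_level=float(level),
                    replication=rep,
                    block=n_idx * n_reps + rep,
                ))
    return records


def _draw(rng: np.random.Generator, dist: tuple[float, float]) -> float:
    mean, sd = dist
    return float(rng.normal(mean, sd)) if sd > 0 else float(mean)


def simulate_latent(record: PlotRecord, config: GeneratorConfig | None = None,
                    seed: int = 0) -> LatentPlotState:
    """Draw a plot's latent growth state, deterministic in (record, seed).

    Variety-level parameters (height, phenology, vigor) are shared between
    replications of the same variety; the nitrogen multiplier and a small
    vigor jitter are plot-level.
    """
    config = config or GeneratorConfig()
    v_rng = np.random.default_rng([seed, 1_000_003, record.variety_id])
    p_rng = np.random.default_rng(
        [seed, record.variety_id, int(record.nitrogen_level), record.replication])
    h_max = max(_draw(v_rng, config.h_max), 0.05)
    growth_rate = max(_draw(v_rng, config.growth_rate), 1e-3)
    t_mid = float(np.clip(_draw(v_rng, config.t_mid), DAS_START + 1.0, DAS_END - 10.0))
    t_anthesis = float(np.clip(_draw(v_rng, config.t_anthesis),
                               t_mid + 2.0, DAS_END - 1.0))
    senescence_rate = max(_draw(v_rng, config.senescence_rate), 1e-3)
    vigor = max(_draw(v_rng, config.vigor), 0.05)
    if config.vigor_plot_sd > 0:
        vigor *= max(1.0 + p_rng.normal(0.0, config.vigor_plot_sd), 0.05)
    n_dist = (config.n_effect_control
              if record.nitrogen_level >= NITROGEN_CONTROL / 2
              else config.n_effect_deficient)
    n_effect = max(_draw(p_rng, n_dist), 0.01)
    return LatentPlotState(h_max=h_max, growth_rate=growth_rate, t_mid=t_mid,
                           t_anthesis=t_anthesis, senescence_rate=senescence_rate,
                           vigor=vigor, n_effect=n_effect)


# ---------------------------------------------------------------------------
# trait curves & targets

def trait_curve(state: LatentPlotState, trait: str,
                das: np.ndarray | None = None) -> np.ndarray:
    """Noiseless seasonal curve of one trait on the DAS grid."""
    if trait not in TRAIT_CURVES:
        raise InvalidArgumentError(f"unknown trait {trait!r}; expected one of {TRAITS}")
    das = np.arange(DAS_START, DAS_END + 1, dtype=float) if das is None else np.asarray(das, float)
    spec = TRAIT_CURVES[trait]
    rise = 1.0 / (1.0 + np.exp(-state.growth_rate * (das - state.t_mid)))
    if spec["kind"] == "structural":
        return spec["scale"] * state.h_max * state.n_effect * state.vigor * rise
    decay = np.exp(-state.senescence_rate * np.maximum(0.0, das - state.t_anthesis))
    # chlorophyll-driven indices respond ~linearly to nitrogen status
    amp = spec["scale"] * state.n_effect * np.sqrt(state.vigor)
    return spec["floor"] + amp * rise * decay


def simulate_trait_series(state: LatentPlotState, trait: str,
                          noise_sd: float = 0.0, seed: int = 0,
                          plot_id: str = "P0000") -> TraitSeries:
    """Emit all 89 days of one trait with multiplicative+additive noise.

    ``noise_sd`` is the additive Gaussian sd in trait units; the
    multiplicative component's relative sd is ``noise_sd / trait range`` so
    one knob controls both, and ``noise_sd=0`` gives the closed-form curve.
    Structural traits are clipped at zero (physical nonnegativity).
    """
    values = trait_curve(state, trait)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        rel_sd = noise_sd / TRAIT_CURVES[trait]["range"]
        values = values * (1.0 + rng.normal(0.0, rel_sd, size=values.shape))
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    if TRAIT_CURVES[trait]["kind"] == "structural":
        values = np.maximum(values, 0.0)
    das = np.arange(DAS_START, DAS_END + 1)
    return TraitSeries(plot_id=plot_id, trait=trait,
                       observations={int(d): float(v) for d, v in zip(das, values)})


def simulate_targets(state: LatentPlotState, config: GeneratorConfig | None = None,
                     seed: int = 0) -> tuple[float, float]:
    """Yield (kg/ha) and GPC (%) from the latent state.

    GPC trades off against standardized yield (coefficient ``b2``), which
    induces the negative within-nitrogen yield-protein correlation wheat
    agronomy expects.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    yld = (config.a0
           + config.a1 * state.h_max * state.n_effect
           + config.a2 * state.vigor * (DAS_END - state.t_anthesis))
    if config.yield_noise_sd > 0:
        yld += rng.normal(0.0, config.yield_noise_sd)
    yld = max(yld, 100.0)
    z = (yld - config.yield_center) / config.yield_scale
    gpc = config.b0 + config.b1 * state.n_effect - config.b2 * z
    if config.gpc_noise_sd > 0:
        gpc += rng.normal(0.0, config.gpc_noise_sd)
    gpc = float(np.clip(gpc, 5.05, 24.95))
    return float(yld), gpc


def apply_missingness(series: TraitSeries, n_observed: int,
                      seed: int = 0) -> TraitSeries:
    """Keep ``n_observed`` days, always retaining the first and last DAS.

    Retaining the window endpoints means later interpolation never has to
    extrapolate. Deterministic given ``seed``.
    """
    if not 2 <= n_observed <= N_DAYS:
        raise InvalidArgumentError(f"n_observed must be in [2, {N_DAYS}], got {n_observed}")
    days = sorted(series.observations)
    if n_observed > len(days):
        raise InvalidArgumentError(
            f"n_observed={n_observed} exceeds available {len(days)} observations")
    if n_observed == len(days):
        return TraitSeries(series.plot_id, series.trait, dict(series.observations))
    first, last = days[0], days[-1]
    middle = np.array(days[1:-1])
    rng = np.random.default_rng(seed)
    keep = rng.choice(middle, size=n_observed - 2, replace=False)
    kept = sorted([first, last] + [int(d) for d in keep])
    return TraitSeries(series.plot_id, series.trait,
                       {d: series.observations[d] for d in kept})


# ---------------------------------------------------------------------------
# whole-trial simulation & I/O

def simulate_dataset(config: GeneratorConfig | None = None, seed: int = 0,
                     n_varieties: int = 120, n_nitrogen: int = 2, n_reps: int = 2,
                     noise: bool = True, missingness: bool = True,
                     ) -> tuple[list[PlotRecord], list[TraitSeries]]:
    """Simulate the full trial: design, targets, and all trait series.

    Defaults reproduce the emulated trial layout: 120 varieties x 2 nitrogen
    levels x 2 replications = 480 plots, 51/53 observed days alternating per
    plot.
    """
    config = config or GeneratorConfig()
    design = simulate_design(n_varieties, n_nitrogen, n_reps, seed=seed)
    plots: list[PlotRecord] = []
    series: list[TraitSeries] = []
    for i, rec in enumerate(design):
        state = simulate_latent(rec, config, seed=seed)
        yld, gpc = simulate_targets(state, config,
                                    seed=[seed, 2_000_003, i])  # type: ignore[arg-type]
        plots.append(dataclasses.replace(rec, yield_true=yld, gpc_true=gpc))
        for j, trait in enumerate(TRAITS):
            noise_sd = config.trait_noise_sd(trait) if noise else 0.0
            ts = simulate_trait_series(
                state, trait, noise_sd=noise_sd,
                seed=[seed, 3_000_017, i, j],  # type: ignore[arg-type]
                plot_id=rec.plot_id)
            if missingness:
                n_obs = config.n_observed_cycle[i % len(config.n_observed_cycle)]
                ts = apply_missingness(ts, n_obs, seed=[seed, 4_000_037, i, j])  # type: ignore[arg-type]
            series.append(ts)
    return plots, series


PLOTS_COLUMNS = ["plot_id", "variety_id", "nitrogen_level", "replication",
                 "block", "yield", "gpc"]
TRAITS_COLUMNS = ["plot_id", "das", "trait", "value"]


def plots_to_frame(plots: Iterable[PlotRecord]) -> pd.DataFrame:
    rows = [(p.plot_id, p.variety_id, p.nitrogen_level, p.replication, p.block,
             p.yield_true, p.gpc_true) for p in plots]
    return pd.DataFrame(rows, columns=PLOTS_COLUMNS)


def series_to_frame(series: Iterable[TraitSeries]) -> pd.DataFrame:
    rows = [(s.plot_id, das, s.trait, value)
            for s in series for das, value in sorted(s.observations.items())]
    return pd.DataFrame(rows, columns=TRAITS_COLUMNS)


def frame_to_plots(frame: pd.DataFrame) -> list[PlotRecord]:
    return [PlotRecord(plot_id=str(r.plot_id), variety_id=int(r.variety_id),
                       nitrogen_level=float(r.nitrogen_level),
                       replication=int(r.replication), block=int(r.block),
                       yield_true=None if pd.isna(r[5]) else float(r[5]),
                       gpc_true=None if pd.isna(r[6]) else float(r[6]))
            for r in frame.itertuples(index=False)]


def frame_to_series(frame: pd.DataFrame) -> list[TraitSeries]:
    out = []
    for (plot_id, trait), grp in frame.groupby(["plot_id", "trait"], sort=False):
        obs = {int(d): float(v) for d, v in zip(grp["das"], grp["value"])}
        out.append(TraitSeries(plot_id=str(plot_id), trait=str(trait), observations=obs))
    return out


def write_dataset(plots: Sequence[PlotRecord], series: Sequence[TraitSeries],
                  out_dir: str | Path) -> tuple[Path, Path]:
    """Write ``plots.csv`` and ``traits.csv`` (long format) to a directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    plots_path = out_dir / "plots.csv"
    traits_path = out_dir / "traits.csv"
    plots_to_frame(plots).to_csv(plots_path, index=False, float_format="%.17g")
    series_to_frame(series).to_csv(traits_path, index=False, float_format="%.17g")
    return plots_path, traits_path


def read_dataset(in_dir: str | Path) -> tuple[list[PlotRecord], list[TraitSeries]]:
    in_dir = Path(in_dir)
    plots = pd.read_csv(in_dir / "plots.csv", float_precision="round_trip")
    traits = pd.read_csv(in_dir / "traits.csv", float_precision="round_trip")
    return frame_to_plots(plots), frame_to_series(traits)
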