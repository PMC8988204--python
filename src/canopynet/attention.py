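"""Daily temporal-importance analysis from a trained attention model.

The attention extractor assigns each of the 89 sensing days a softmax
weight; averaged over examples and expressed in percent, a trait's profile
says how much each day contributed to the fused prediction. Splitting the
profile at anthesis gives the pre-/post-anthesis stage comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, EmptyInputError, InvalidArgumentError
from .prep import PreparedDataset
from .synthetic import DAS_END, DAS_START, N_DAYS
from .training import TrainedModel

DEFAULT_ANTHESIS_DAS = 160


@dataclass(frozen=True)
class AttentionProfile:
    """Per-day importance (percent) of one input trait."""

    input_trait: str
    daily_importance: np.ndarray  # (89,), percent per day, sums to 100
    n_examples_averaged: int

    def __post_init__(self):
        arr = np.asarray(self.daily_importance, dtype=float)
        if arr.shape != (N_DAYS,):
            raise InvalidArgumentError(f"profile must have length {N_DAYS}")
        object.__setattr__(self, "daily_importance", arr)

    @property
    def das(self) -> np.ndarray:
        return np.arange(DAS_START, DAS_END + 1)


def extract_attention_profile(trained: TrainedModel, dataset: PreparedDataset,
                              split: str = "test") -> list[AttentionProfile]:
    """One profile per input trait of a two_to_two attention model.

    Softmax weights are channel-averaged per example inside the model;
    here they are averaged over the split's examples and scaled to percent.
    """
    spec = trained.spec
    if spec.topology != "two_to_two" or spec.extractor != "ATTENTION":
        raise ConfigurationError(
            "attention profiles need a two_to_two model with the ATTENTION "
            f"extractor, got {spec.topology}/{spec.extractor}")
    idx = dataset.split_indices(split)
    if idx.size == 0:
        raise InvalidArgumentError(f"split {split!r} is empty")
    inputs = dataset.inputs_for(spec.input_traits, idx)
    _, attentions = trained.model.forward(inputs, training=False)
    profiles = []
    for trait, att in zip(spec.input_traits, attentions):
        daily = att.mean(axis=0) * 100.0
        profiles.append(AttentionProfile(input_trait=trait,
                                         daily_importance=daily,
                                         n_examples_averaged=int(idx.size)))
    return profiles


def stage_importance(profile: AttentionProfile,
                     anthesis_das: int = DEFAULT_ANTHESIS_DAS
                     ) -> tuple[float, float]:
    """(pre-anthesis, post-anthesis) mean importance in percent/day.

    Pre-anthesis covers DAS < anthesis; post-anthesis covers DAS >= anthesis.
    """
    if not DAS_START < anthesis_das < DAS_END:
        raise InvalidArgumentError(
            f"anthesis_das must lie strictly inside ({DAS_START}, {DAS_END})")
    das = profile.das
    pre = profile.daily_importance[das < anthesis_das]
    post = profile.daily_importance[das >= anthesis_das]
    return float(pre.mean()), float(post.mean())


def profiles_frame(profiles: Sequence[AttentionProfile]) -> pd.DataFrame:
    rows = [(p.input_trait, int(d), float(v))
            for p in profiles for d, v in zip(p.das, p.daily_importance)]
    return pd.DataFrame(rows, columns=["trait", "das", "importance_pct"])


def export_profile_plot(profiles: Sequence[AttentionProfile], path: str | Path,
                        anthesis_das: int = DEFAULT_ANTHESIS_DAS) -> Path:
    """Bar plot of daily attention values, one panel per trait."""
    if not profiles:
        raise EmptyInputError("no attention profiles to plot")
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(profiles)
    fig, axes = plt.subplots(n, 1, figsize=(9, 2.8 * n), squeeze=False)
    for ax, profile in zip(axes[:, 0], profiles):
        ax.bar(profile.das, profile.daily_importance, width=0.9,
               color="#4c72b0")
        ax.axvline(anthesis_das, color="#c44e52", linestyle="--",
                   label=f"anthesis (DAS {anthesis_das})")
        ax.set_ylabel("importance (%/day)")
        ax.set_title(profile.input_trait)
        ax.legend(loc="upper left", fontsize=8)
    axes[-1, 0].set_xlabel("days after sowing")
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
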