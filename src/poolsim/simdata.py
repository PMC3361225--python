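"""Synthetic two-class omics data with Gaussian biology and technical noise.

Each feature of an individual sample has a latent biological value
``z ~ N(0, sigma2)`` for controls and ``z ~ N(gamma_f, sigma2)`` for cases,
where ``gamma_f`` is nonzero only for marker features and is drawn once per
dataset family from ``U(gamma_low, gamma_high)``.  The measured value is
``y = z + eps`` with technical noise ``eps ~ N(0, tech_variance)``.  Values
live on the natural-log scale throughout, which is what makes the
exp-average-log pooling transform (see :mod:`poolsim.pooling`) meaningful.

Two presets mimic typical study designs: a "human" cohort (90 samples per
class, biological variance 0.2) and an "animal" experiment (30 per class,
variance 0.1, reflecting in-bred homogeneity).  Both use 1000 features and
technical variance 0.2**2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CONTROL",
    "CASE",
    "ScenarioConfig",
    "OmicsDataset",
    "scenario_preset",
    "human_scenario",
    "animal_scenario",
    "draw_gammas",
    "simulate_individuals",
    "simulate_test_set",
]

#: Integer class labels: control is the negative class, case the positive one.
CONTROL: int = -1
CASE: int = 1

_LABEL_NAMES = {CONTROL: "control", CASE: "case"}


@dataclass(frozen=True)
class ScenarioConfig:
    """Generative parameters of one simulation scenario.

    Parameters
    ----------
    n_features
        Number of features ``a`` per sample.
    n_per_class
        Number of individual training samples per class.
    bio_variance
        Between-subject (biological) variance ``sigma2`` of every feature.
    tech_variance
        Variance of the additive technical (measurement) noise; one noise
        draw per performed measurement, individual or pooled.
    n_markers
        Number of discriminating features (case mean shifted by ``gamma``).
    gamma_low, gamma_high
        Bounds of the uniform distribution the per-marker effect sizes are
        drawn from.
    label
        Free-text scenario name; ``"human"`` / ``"animal"`` for the presets.
    """

    n_features: int = 1000
    n_per_class: int = 90
    bio_variance: float = 0.2
    tech_variance: float = 0.2 ** 2
    n_markers: int = 10
    gamma_low: float = 0.3
    gamma_high: float = 0.4
    label: str = "custom"

    def __post_init__(self) -> None:
        if self.n_features < 1:
            raise ValueError("n_features must be a positive integer")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be a positive integer")
        if not 0 <= self.n_markers <= self.n_features:
            raise ValueError(
                f"n_markers must lie in [0, n_features]; got {self.n_markers}"
            )
        if not 0 <= self.gamma_low <= self.gamma_high:
            raise ValueError("require 0 <= gamma_low <= gamma_high")
        if self.bio_variance <= 0:
            raise ValueError("bio_variance must be > 0")
        if self.tech_variance < 0:
            raise ValueError("tech_variance must be >= 0")


_PRESETS = {
    "human": dict(n_features=1000, n_per_class=90, bio_variance=0.2, label="human"),
    "animal": dict(n_features=1000, n_per_class=30, bio_variance=0.1, label="animal"),
}


def scenario_preset(name: str, **overrides) -> ScenarioConfig:
    """Return a named preset, with any field overridable by keyword."""
    try:
        base = dict(_PRESETS[name])
    except KeyError:
        raise ValueError(
            f"unknown scenario preset {name!r}; choose from {sorted(_PRESETS)}"
        ) from None
    base.update(overrides)
    return ScenarioConfig(**base)


def human_scenario(**overrides) -> ScenarioConfig:
    """Human-cohort preset: 90/class, sigma2 = 0.2, 1000 features."""
    return scenario_preset("human", **overrides)


def animal_scenario(**overrides) -> ScenarioConfig:
    """Animal-experiment preset: 30/class, sigma2 = 0.1, 1000 features."""
    return scenario_preset("animal", **overrides)


@dataclass
class OmicsDataset:
    """A labelled samples-by-features matrix with marker bookkeeping.

    ``values`` holds the measured data ``y = z + eps``; ``bio_values`` keeps
    the latent biological component ``z`` separately because pooling operates
    on ``z`` and adds its own fresh technical noise afterwards.
    """

    values: np.ndarray
    bio_values: np.ndarray
    labels: np.ndarray
    marker_indices: np.ndarray
    gamma_values: np.ndarray
    pool_size: int = 1
    scenario: ScenarioConfig | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.bio_values = np.asarray(self.bio_values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.marker_indices = np.asarray(self.marker_indices, dtype=int)
        self.gamma_values = np.asarray(self.gamma_values, dtype=float)
        if self.values.shape != self.bio_values.shape:
            raise ValueError("values and bio_values must have the same shape")
        if self.labels.shape != (self.values.shape[0],):
            raise ValueError("labels must have one entry per sample")
        if not np.isin(self.labels, [CONTROL, CASE]).all():
            raise ValueError("labels must be dichotomous (control/case)")
        if self.marker_indices.shape != self.gamma_values.shape:
            raise ValueError("one gamma per marker index is required")
        if self.pool_size < 1:
            raise ValueError("pool_size must be a positive integer")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def class_indices(self, label: int) -> np.ndarray:
        """Row indices of all samples with the given class label."""
        return np.flatnonzero(self.labels == label)

    def to_frame(self) -> pd.DataFrame:
        """Measured values as a DataFrame with feature columns plus a final
        ``class`` column of label names (for dumping/inspection)."""
        cols = [f"f{j}" for j in range(self.n_features)]
        frame = pd.DataFrame(self.values, columns=cols)
        frame["class"] = [_LABEL_NAMES[c] for c in self.labels]
        return frame

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def draw_gammas(config: ScenarioConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw one effect size per marker from ``U(gamma_low, gamma_high)``."""
    return rng.uniform(config.gamma_low, config.gamma_high, size=config.n_markers)


def _simulate(
    config: ScenarioConfig,
    gammas: Sequence[float],
    n_control: int,
    n_case: int,
    rng: np.random.Generator,
) -> OmicsDataset:
    gammas = np.asarray(gammas, dtype=float)
    if gammas.shape != (config.n_markers,):
        raise ValueError(
            f"expected {config.n_markers} gammas, got {gammas.shape}"
        )
    n = n_control + n_case
    a = config.n_features
    mean = np.zeros((n, a))
    # markers occupy the leading feature indices; positions carry no meaning
    mean[n_control:, : config.n_markers] = gammas
    z = mean + rng.normal(0.0, np.sqrt(config.bio_variance), size=(n, a))
    eps = rng.normal(0.0, np.sqrt(config.tech_variance), size=(n, a))
    labels = np.concatenate(
        [np.full(n_control, CONTROL), np.full(n_case, CASE)]
    )
    return OmicsDataset(
        values=z + eps,
        bio_values=z,
        labels=labels,
        marker_indices=np.arange(config.n_markers),
        gamma_values=gammas,
        pool_size=1,
        scenario=config,
    )


def simulate_individuals(
    config: ScenarioConfig,
    gammas: Sequence[float],
    rng: np.random.Generator,
) -> OmicsDataset:
    """Simulate a balanced individual-sample training set (2 * n_per_class rows)."""
    return _simulate(config, gammas, config.n_per_class, config.n_per_class, rng)


def simulate_test_set(
    config: ScenarioConfig,
    gammas: Sequence[float],
    n_test: int,
    rng: np.random.Generator,
) -> OmicsDataset:
    """Simulate ``n_test`` individual test samples from the same generative
    model (balanced classes; markers shared with the paired training set)."""
    if n_test <= 0:
        raise ValueError("n_test must be a positive integer")
    n_control = n_test // 2
    return _simulate(config, gammas, n_control, n_test - n_control, rng)
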