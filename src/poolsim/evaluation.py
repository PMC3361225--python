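"""Experiment orchestration: simulate, pool, rank, tune, train, test, repeat.

One replication draws fresh marker effect sizes, simulates an individual
training set and an individual test set, pools the training set at each
requested pool size (size 1 passes through untouched), ranks features by
t-test on the (pooled) training data, and for every (classifier, top-k)
cell tunes hyperparameters by class-stratified internal cross-validation on
the training data before scoring misclassification on the individual test
set.  Model evaluation never uses pooled samples: future subjects cannot be
pooled, so k-fold CV on pooled data would not estimate the error that
matters.

Randomness is organized around a single master seed: every consumer of
random numbers (gamma draw, training/test simulation, pool assignment and
noise, CV folds, stochastic learners) gets its own ``SeedSequence`` child
keyed by replication index and role, so any replication — and any cell
within it — is reproducible in isolation and independent of which other
cells run.
"""

from __future__ import annotations

import json
import time
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import ranksums
from sklearn.model_selection import StratifiedKFold

from . import classifiers as clf
from .classifiers import ClassifierSpec, default_specs, grid_points
from .feature_selection import rank_by_ttest, select_top
from .pooling import make_pooling_plan, pool_dataset
from .simdata import OmicsDataset, ScenarioConfig, draw_gammas, human_scenario
from .simdata import simulate_individuals, simulate_test_set

__all__ = [
    "ExperimentConfig",
    "ReplicateResult",
    "ExperimentSummary",
    "tune_by_internal_cv",
    "run_replication",
    "summarize",
    "run_experiment",
]

logger = logging.getLogger(__name__)

# seed-tree roles: SeedSequence(master_seed, spawn_key=(rep, ROLE, ...))
_ROLE_GAMMA, _ROLE_TRAIN, _ROLE_TEST, _ROLE_POOL, _ROLE_TUNE, _ROLE_FIT = range(6)


def _rng(master_seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=key))


@dataclass(frozen=True)
class ExperimentConfig:
    """Full specification of one pooling experiment.

    Defaults mirror the benchmark design: pool sizes 1/2/3/5, top-k
    10/100/1000, 300 replications, a 450-sample individual test set and
    3-fold internal CV.  ``cells`` optionally restricts evaluation to a
    subset of (classifier, pool_size, top_k) combinations; ``None`` means
    the full cross product.
    """

    scenario: ScenarioConfig = field(default_factory=human_scenario)
    pool_sizes: tuple[int, ...] = (1, 2, 3, 5)
    top_ks: tuple[int, ...] = (10, 100, 1000)
    classifier_specs: tuple[ClassifierSpec, ...] = field(
        default_factory=lambda: tuple(default_specs())
    )
    n_reps: int = 300
    n_test: int = 450
    cv_folds: int = 3
    master_seed: int = 0
    cells: frozenset[tuple[str, int, int]] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "pool_sizes", tuple(self.pool_sizes))
        object.__setattr__(self, "top_ks", tuple(self.top_ks))
        object.__setattr__(self, "classifier_specs", tuple(self.classifier_specs))
        if self.cells is not None:
            object.__setattr__(self, "cells", frozenset(self.cells))
        if self.n_reps < 1 or self.n_test < 1:
            raise ValueError("n_reps and n_test must be positive")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be at least 2")
        for p in self.pool_sizes:
            if p < 1 or self.scenario.n_per_class % p:
                raise ValueError(
                    f"pool size {p} does not divide n_per_class="
                    f"{self.scenario.n_per_class} (designs require n = p*m)"
                )
        for k in self.top_ks:
            if not 1 <= k <= self.scenario.n_features:
                raise ValueError(f"top-k {k} outside [1, n_features]")

    def iter_cells(self) -> Iterable[tuple[ClassifierSpec, int, int]]:
        for p in self.pool_sizes:
            for k in self.top_ks:
                for spec in self.classifier_specs:
                    if self.cells is None or (spec.name, p, k) in self.cells:
                        yield spec, p, k


@dataclass
class ReplicateResult:
    """Misclassification rate and chosen hyperparameters per evaluated cell
    of one replication."""

    rep_index: int
    rates: dict[tuple[str, int, int], float]
    chosen_params: dict[tuple[str, int, int], dict]
    master_seed: int


@dataclass
class ExperimentSummary:
    """Aggregates across replications.

    ``cell_stats`` has one row per (classifier, pool_size, top_k) with the
    mean rate and a normal-approximation 95% confidence interval of the
    mean; the two Wilcoxon tables hold two-sided rank-sum p-values between
    pool sizes (per classifier and top-k) and between top-k settings (per
    classifier and pool size).
    """

    cell_stats: pd.DataFrame
    pool_size_wilcoxon: pd.DataFrame
    top_k_wilcoxon: pd.DataFrame
    n_reps: int

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.cell_stats.to_csv(out / "summary.csv", index=False)
        wilcoxon = pd.concat(
            [
                self.pool_size_wilcoxon.assign(comparison="pool_size"),
                self.top_k_wilcoxon.assign(comparison="top_k"),
            ],
            ignore_index=True,
        )
        wilcoxon.to_csv(out / "wilcoxon.csv", index=False)


def _cv_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(2**31 - 1))


def tune_by_internal_cv(
    spec: ClassifierSpec,
    train_data: OmicsDataset,
    features: Sequence[int],
    folds: int,
    rng: np.random.Generator,
) -> dict:
    """Choose grid parameters by class-stratified internal CV on the
    training set only.

    The winner is the grid point with the smallest mean CV misclassification
    count; ties go to the earliest point in grid order (each parameter's
    candidate list defines its natural order, later grid keys varying
    fastest), so tuning is deterministic given the folds.  k-NN is tuned
    with a single neighbor-sort per fold and a cumulative-vote sweep over
    all k.
    """
    features = np.asarray(features, dtype=int)
    X = train_data.values[:, features]
    y = train_data.labels
    class_counts = np.unique(y, return_counts=True)[1]
    if len(class_counts) < 2 or class_counts.min() < folds:
        raise ValueError(
            "too few samples per class for class-stratified "
            f"{folds}-fold internal CV"
        )
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=_cv_seed(rng))
    splits = list(splitter.split(X, y))
    min_fit = min(len(tr) for tr, _ in splits)

    if spec.name == "knn" and spec.grid.get("k") is None:
        k_max = min(features.size, min_fit)
        if k_max != min(features.size, len(y)):
            logger.debug(
                "knn grid capped at %d by the CV fold size", k_max
            )
        k_values = list(range(1, k_max + 1))
        errors = np.zeros(len(k_values))
        for tr, va in splits:
            errors += clf.knn_error_curve(X[tr], y[tr], X[va], y[va], k_values)
        return {"k": k_values[int(np.argmin(errors))]}

    points = grid_points(spec, n_features=features.size, n_train=min_fit)
    if len(points) == 1:
        return dict(points[0])
    errors = np.zeros(len(points))
    for tr, va in splits:
        for i, params in enumerate(points):
            state = clf._fit_raw(spec, params, X[tr], y[tr], rng)
            errors[i] += np.sum(state.predict(X[va]) != y[va])
    return dict(points[int(np.argmin(errors))])


def _evaluate_cell(
    spec: ClassifierSpec,
    train_set: OmicsDataset,
    test_set: OmicsDataset,
    features: np.ndarray,
    folds: int,
    tune_rng: np.random.Generator,
    fit_rng: np.random.Generator,
) -> tuple[float, dict]:
    params = tune_by_internal_cv(spec, train_set, features, folds, tune_rng)
    model = clf.train(spec, params, train_set, features, fit_rng)
    pred = clf.predict(model, test_set)
    rate = float(np.mean(pred != test_set.labels))
    return rate, params


def run_replication(config: ExperimentConfig, rep_index: int) -> ReplicateResult:
    """Run one full simulate → pool → rank → tune → train → test cycle.

    Marker effect sizes are re-drawn every replication and shared between
    that replication's training and test sets.  Pool membership and pooled
    technical noise are re-randomized per replication and pool size.
    """
    seed = config.master_seed
    scenario = config.scenario
    gammas = draw_gammas(scenario, _rng(seed, rep_index, _ROLE_GAMMA))
    train_ind = simulate_individuals(scenario, gammas, _rng(seed, rep_index, _ROLE_TRAIN))
    test_set = simulate_test_set(
        scenario, gammas, config.n_test, _rng(seed, rep_index, _ROLE_TEST)
    )

    rates: dict[tuple[str, int, int], float] = {}
    chosen: dict[tuple[str, int, int], dict] = {}
    trainings: dict[int, OmicsDataset] = {}
    for p in config.pool_sizes:
        if p == 1:
            trainings[p] = train_ind  # pooling at size 1 is a pass-through
        else:
            pool_rng = _rng(seed, rep_index, _ROLE_POOL, p)
            plan = make_pooling_plan(train_ind, p, pool_rng)
            trainings[p] = pool_dataset(
                train_ind, plan, scenario.tech_variance, pool_rng
            )
    rankings = {p: rank_by_ttest(ds) for p, ds in trainings.items()}

    for spec, p, k in config.iter_cells():
        features = select_top(rankings[p], k)
        cell_key = (spec.name, p, k)
        clf_index = CLASSIFIER_INDEX[spec.name]
        t0 = time.perf_counter()
        rate, params = _evaluate_cell(
            spec,
            trainings[p],
            test_set,
            features,
            config.cv_folds,
            _rng(seed, rep_index, _ROLE_TUNE, p, k, clf_index),
            _rng(seed, rep_index, _ROLE_FIT, p, k, clf_index),
        )
        logger.debug(
            "rep %d cell %s: rate=%.4f params=%s (%.2fs)",
            rep_index, cell_key, rate, params, time.perf_counter() - t0,
        )
        rates[cell_key] = rate
        chosen[cell_key] = params
    return ReplicateResult(
        rep_index=rep_index, rates=rates, chosen_params=chosen, master_seed=seed
    )


CLASSIFIER_INDEX = {name: i for i, name in enumerate(clf.CLASSIFIER_NAMES)}


def replicates_frame(results: Sequence[ReplicateResult]) -> pd.DataFrame:
    """Long-format table: one row per (replication, cell)."""
    rows = []
    for res in results:
        for (name, p, k), rate in res.rates.items():
            rows.append(
                {
                    "rep": res.rep_index,
                    "classifier": name,
                    "pool_size": p,
                    "top_k": k,
                    "rate": rate,
                    "chosen_params": json.dumps(res.chosen_params[(name, p, k)]),
                }
            )
    return pd.DataFrame(rows)


def _pairwise_wilcoxon(
    frame: pd.DataFrame, by: list[str], across: str
) -> pd.DataFrame:
    rows = []
    for keys, sub in frame.groupby(by, sort=True):
        levels = sorted(sub[across].unique())
        for i, a in enumerate(levels):
            for b in levels[i + 1 :]:
                pval = ranksums(
                    sub.loc[sub[across] == a, "rate"],
                    sub.loc[sub[across] == b, "rate"],
                ).pvalue
                row = dict(zip(by, keys if isinstance(keys, tuple) else (keys,)))
                row.update({f"{across}_a": a, f"{across}_b": b, "p_value": float(pval)})
                rows.append(row)
    return pd.DataFrame(rows)


def summarize(results: Sequence[ReplicateResult] | pd.DataFrame) -> ExperimentSummary:
    """Aggregate replicate rates into means, 95% CIs and Wilcoxon tables.

    The CI is the normal approximation mean ± 1.96·SE across replications.
    Wilcoxon comparisons are two-sided rank-sum tests between pool sizes
    (within classifier and top-k) and between top-k settings (within
    classifier and pool size); no multiplicity correction is applied.
    """
    frame = results if isinstance(results, pd.DataFrame) else replicates_frame(results)
    if frame.empty:
        raise ValueError("no replicate results to summarize")
    n_reps = frame["rep"].nunique()
    if n_reps < 2:
        raise ValueError("need at least 2 replicates for CIs and rank tests")

    def _stats(rates: pd.Series) -> pd.Series:
        mean = rates.mean()
        se = rates.std(ddof=1) / np.sqrt(len(rates))
        return pd.Series(
            {
                "mean_rate": mean,
                "ci_low": mean - 1.96 * se,
                "ci_high": mean + 1.96 * se,
                "n_reps": len(rates),
            }
        )

    cell_stats = (
        frame.groupby(["classifier", "pool_size", "top_k"], sort=True)["rate"]
        .apply(_stats)
        .unstack()
        .reset_index()
    )
    return ExperimentSummary(
        cell_stats=cell_stats,
        pool_size_wilcoxon=_pairwise_wilcoxon(
            frame, ["classifier", "top_k"], "pool_size"
        ),
        top_k_wilcoxon=_pairwise_wilcoxon(
            frame, ["classifier", "pool_size"], "top_k"
        ),
        n_reps=n_reps,
    )


def run_experiment(
    config: ExperimentConfig,
    out_dir=None,
    progress: bool = False,
) -> tuple[ExperimentSummary, pd.DataFrame]:
    """Run all replications and aggregate; optionally write result files.

    Writes ``replicates.csv``, ``summary.csv``, ``wilcoxon.csv`` and a run
    manifest when ``out_dir`` is given.  Returns the summary and the
    long-format replicate table.
    """
    results = []
    for rep in range(config.n_reps):
        t0 = time.perf_counter()
        results.append(run_replication(config, rep))
        msg = "replication %d/%d done in %.1fs"
        if progress:
            logger.info(msg, rep + 1, config.n_reps, time.perf_counter() - t0)
        else:
            logger.debug(msg, rep + 1, config.n_reps, time.perf_counter() - t0)
    frame = replicates_frame(results)
    summary = summarize(frame)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        frame.to_csv(out / "replicates.csv", index=False)
        summary.write(out)
        from .cli_config import emit_manifest  # local import: avoids a cycle

        emit_manifest(config, out)
    return summary, frame
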