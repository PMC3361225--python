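"""Filter feature selection: rank features by a two-sample Student t-test.

The ranking is computed on training data only (pooled or individual) and the
top-k prefix is then applied unchanged to the individual-sample test set.
Selecting all features reproduces the no-selection condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simdata import CASE, CONTROL, OmicsDataset

__all__ = ["FeatureRanking", "rank_by_ttest", "select_top"]


@dataclass(frozen=True)
class FeatureRanking:
    """Features ordered best-first by absolute t statistic.

    ``statistics`` holds the per-feature |t| indexed by feature (not by
    rank); ``source_pool_size`` records the pool size of the training data
    the ranking was derived from.
    """

    ordered_indices: np.ndarray
    statistics: np.ndarray
    source_pool_size: int

    @property
    def n_features(self) -> int:
        return self.statistics.size


def rank_by_ttest(train: OmicsDataset) -> FeatureRanking:
    """Rank all features by the pooled-variance (Student) two-sample t-test
    comparing cases against controls.

    Zero-pooled-variance features get |t| = +inf when the class means differ
    and 0 when they agree; ties are broken by lower feature index, so the
    ranking is deterministic.
    """
    x_control = train.values[train.labels == CONTROL]
    x_case = train.values[train.labels == CASE]
    n1, n2 = x_control.shape[0], x_case.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("t-test ranking needs at least 2 samples per class")
    diff = x_case.mean(axis=0) - x_control.mean(axis=0)
    sp2 = (
        (n1 - 1) * x_control.var(axis=0, ddof=1)
        + (n2 - 1) * x_case.var(axis=0, ddof=1)
    ) / (n1 + n2 - 2)
    denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        abs_t = np.abs(diff) / denom
    degenerate = denom == 0
    abs_t[degenerate & (diff != 0)] = np.inf
    abs_t[degenerate & (diff == 0)] = 0.0
    # primary key: descending |t|; secondary: ascending feature index
    order = np.lexsort((np.arange(abs_t.size), -abs_t))
    return FeatureRanking(
        ordered_indices=order,
        statistics=abs_t,
        source_pool_size=train.pool_size,
    )


def select_top(ranking: FeatureRanking, k: int) -> np.ndarray:
    """First ``k`` feature indices of the ranking (k = n_features means no
    feature selection)."""
    if not 1 <= k <= ranking.n_features:
        raise ValueError(
            f"k must lie in [1, {ranking.n_features}]; got {k}"
        )
    return ranking.ordered_indices[:k]
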