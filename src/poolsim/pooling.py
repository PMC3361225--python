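"""Virtual pooling of individual samples via the exp-average-log transform.

A pool of size ``p`` averages the (natural-scale) abundances of ``p``
individuals of the same class; on the log scale stored in our datasets this
is ``z' = log((1/p) * sum(exp(z_i)))`` per feature, followed by one fresh
technical-noise draw for the pooled measurement.  Pooling reduces the
biological variance of a straight average to ``sigma2 / p`` but also shrinks
the training set from ``n`` to ``m = n / p`` instances, which is the design
trade-off this package exists to quantify.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .simdata import CASE, CONTROL, OmicsDataset

__all__ = ["PoolingPlan", "make_pooling_plan", "pool_dataset", "pooled_bio_variance"]


@dataclass(frozen=True)
class PoolingPlan:
    """A class-pure partition of training-sample indices into pools.

    ``groups`` is an ``(m, p)`` integer array of row indices; each row is one
    pool drawn entirely from a single class.
    """

    pool_size: int
    groups: np.ndarray
    group_labels: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", np.asarray(self.groups, dtype=int))
        object.__setattr__(self, "group_labels", np.asarray(self.group_labels, dtype=int))
        if self.groups.ndim != 2 or self.groups.shape[1] != self.pool_size:
            raise ValueError("groups must be an (m, pool_size) index array")
        if self.group_labels.shape != (self.groups.shape[0],):
            raise ValueError("one label per group is required")
        flat = self.groups.ravel()
        if len(np.unique(flat)) != flat.size:
            raise ValueError("every sample must appear in exactly one group")

    @property
    def n_groups(self) -> int:
        return self.groups.shape[0]


def make_pooling_plan(
    dataset: OmicsDataset, p: int, rng: np.random.Generator
) -> PoolingPlan:
    """Randomly partition each class into pools of exactly ``p`` samples.

    Requires the per-class sample count to be divisible by ``p`` (exhaustive
    designs ``n = p * m`` only).  For ``p = 1`` the partition is the identity
    (each sample its own group, original order), which makes the unpooled
    path an exact special case.
    """
    if p < 1:
        raise ValueError("pool size must be a positive integer")
    groups, labels = [], []
    for cls in (CONTROL, CASE):
        idx = dataset.class_indices(cls)
        if idx.size % p != 0:
            raise ValueError(
                f"indivisible design: {idx.size} samples of class {cls} "
                f"cannot be split into pools of {p}"
            )
        if p > 1:
            idx = rng.permutation(idx)
        groups.append(idx.reshape(-1, p))
        labels.append(np.full(idx.size // p, cls))
    return PoolingPlan(
        pool_size=p,
        groups=np.concatenate(groups, axis=0),
        group_labels=np.concatenate(labels),
    )


def pool_dataset(
    dataset: OmicsDataset,
    plan: PoolingPlan,
    tech_variance: float,
    rng: np.random.Generator,
) -> OmicsDataset:
    """Pool biological values group-wise and add one fresh technical error
    per pooled measurement.

    The pooled biological value per feature is the log of the arithmetic
    mean of ``exp(z)`` over the group (computed as ``logsumexp(z) - log(p)``,
    which is exact for singleton groups).  Marker bookkeeping and the
    scenario reference carry over; the output's ``pool_size`` is ``p``.
    """
    if dataset.pool_size != 1:
        raise ValueError("can only pool individual-sample datasets (pool_size 1)")
    if plan.groups.max(initial=-1) >= dataset.n_samples:
        raise ValueError("pooling plan refers to samples outside the dataset")
    if not all(
        (dataset.labels[g] == lab).all()
        for g, lab in zip(plan.groups, plan.group_labels)
    ):
        raise ValueError("corrupt plan: mixed-class pooling group")
    p = plan.pool_size
    z_groups = dataset.bio_values[plan.groups]  # (m, p, a)
    z_pooled = logsumexp(z_groups, axis=1) - np.log(p)
    eps = rng.normal(0.0, np.sqrt(tech_variance), size=z_pooled.shape)
    return OmicsDataset(
        values=z_pooled + eps,
        bio_values=z_pooled,
        labels=plan.group_labels,
        marker_indices=dataset.marker_indices,
        gamma_values=dataset.gamma_values,
        pool_size=p,
        scenario=dataset.scenario,
    )


def pooled_bio_variance(sigma2: float, p: int) -> float:
    """Biological variance of a straight average of ``p`` individuals."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    if p < 1:
        raise ValueError("pool size must be a positive integer")
    return sigma2 / p
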