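"""The six benchmark classifiers under a common train/predict contract.

Support vector machines (linear and radial kernel), random forest and
L2-penalized logistic regression are backed by scikit-learn; k-nearest
neighbors and the nearest-shrunken-centroid classifier (PAM) are implemented
here — k-NN to expose the nearest-single-neighbor tie rule and an efficient
cross-validation sweep over its ``k = 1..k_max`` grid, PAM because its
shrinkage and feature-elimination behaviour is part of the study itself.

Hyperparameter grids default to the study's tuning grids; all are
overridable through :class:`ClassifierSpec`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from .simdata import CASE, CONTROL, OmicsDataset

__all__ = [
    "CLASSIFIER_NAMES",
    "ClassifierSpec",
    "TunedModel",
    "default_spec",
    "default_specs",
    "grid_points",
    "train",
    "predict",
    "KNearestNeighbors",
    "NearestShrunkenCentroid",
    "nsc_shrink_centroids",
]

CLASSIFIER_NAMES = ("svm_linear", "svm_radial", "random_forest", "knn", "plr", "pam")

_SOFT_MARGINS = (0.1, 1.0, 5.0, 10.0, 50.0, 100.0, 500.0)


@dataclass(frozen=True)
class ClassifierSpec:
    """Name, tuning grid and fixed settings of one classifier.

    ``grid`` maps hyperparameter names to candidate values in their natural
    (tie-break) order.  A ``None`` grid entry is resolved at tuning time from
    the data dimensions (used for the k-NN neighbor count, whose grid runs
    from 1 to the number of selected features, capped at the training-set
    size).  ``fixed`` holds non-tuned settings such as the forest size.
    """

    name: str
    grid: Mapping[str, Sequence | None]
    fixed: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in CLASSIFIER_NAMES:
            raise ValueError(
                f"unknown classifier {self.name!r}; choose from {CLASSIFIER_NAMES}"
            )


_DEFAULT_SPECS = {
    "svm_linear": ClassifierSpec("svm_linear", grid={"c": _SOFT_MARGINS}),
    "svm_radial": ClassifierSpec(
        "svm_radial",
        grid={"c": _SOFT_MARGINS, "gamma": (0.25, 0.5, 1.0, 2.0, 4.0)},
    ),
    "random_forest": ClassifierSpec(
        "random_forest",
        grid={"mtry": (4, 8, 16, 32, 64)},
        fixed={"n_trees": 1000},
    ),
    "knn": ClassifierSpec("knn", grid={"k": None}),
    "plr": ClassifierSpec(
        "plr",
        grid={"lambda": (0.0625, 0.125, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0)},
        fixed={"tol": 1e-8},
    ),
    "pam": ClassifierSpec("pam", grid={"delta": (0.1, 0.25, 0.5, 1.0, 2.0, 5.0)}),
}


def default_spec(name: str) -> ClassifierSpec:
    """The study's default grid for one classifier."""
    try:
        return _DEFAULT_SPECS[name]
    except KeyError:
        raise ValueError(
            f"unknown classifier {name!r}; choose from {CLASSIFIER_NAMES}"
        ) from None


def default_specs(names: Sequence[str] = CLASSIFIER_NAMES) -> list[ClassifierSpec]:
    return [default_spec(n) for n in names]


def grid_points(
    spec: ClassifierSpec, n_features: int, n_train: int
) -> list[dict]:
    """Expand a spec's grid into an ordered list of parameter dicts.

    Data-dependent entries are resolved here: the k-NN grid becomes
    ``1..min(n_features, n_train)`` and random-forest candidate-feature
    counts are capped at ``n_features`` (duplicates dropped, order kept).
    The enumeration order — product of per-parameter candidate lists, first
    parameter slowest — defines the deterministic tuning tie-break.
    """
    keys, candidate_lists = [], []
    for key, values in spec.grid.items():
        if values is None:  # resolved from data (k-NN neighbor count)
            values = range(1, min(n_features, n_train) + 1)
        elif spec.name == "random_forest" and key == "mtry":
            capped = [min(int(v), n_features) for v in values]
            values = list(dict.fromkeys(capped))
        keys.append(key)
        candidate_lists.append(list(values))
    return [dict(zip(keys, combo)) for combo in itertools.product(*candidate_lists)]


class KNearestNeighbors:
    """Euclidean k-nearest-neighbor voting with a deterministic tie rule:
    a split vote is resolved by the class of the single nearest neighbor."""

    def __init__(self, k: int):
        if k < 1:
            raise ValueError("k must be a positive integer")
        self.k = k

    def fit(self, X: np.ndarray, y: np.ndarray) -> "KNearestNeighbors":
        self._X = np.asarray(X, dtype=float)
        self._y = np.asarray(y, dtype=int)
        if self.k > len(self._y):
            raise ValueError("k cannot exceed the number of training samples")
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        order = np.argsort(cdist(np.asarray(X, float), self._X), axis=1, kind="stable")
        return _vote(self._y[order], self.k)


def _vote(neighbor_labels: np.ndarray, k: int) -> np.ndarray:
    """Majority vote over the first k columns of a (queries, n_train) label
    matrix; ties fall back to column 0 (the nearest neighbor)."""
    case_votes = (neighbor_labels[:, :k] == CASE).sum(axis=1)
    pred = np.where(2 * case_votes > k, CASE, CONTROL)
    tie = 2 * case_votes == k
    pred[tie] = neighbor_labels[tie, 0]
    return pred


def knn_error_curve(
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
    test_y: np.ndarray,
    k_values: Sequence[int],
) -> np.ndarray:
    """Misclassification counts on (test_X, test_y) for every k at once.

    Sorting the neighbor labels once and sweeping k over the cumulative vote
    makes grid tuning over ``k = 1..k_max`` linear instead of quadratic.
    """
    order = np.argsort(cdist(test_X, train_X), axis=1, kind="stable")
    labels = np.asarray(train_y, dtype=int)[order]
    case_cum = np.cumsum(labels == CASE, axis=1)
    errors = np.empty(len(k_values))
    test_y = np.asarray(test_y, dtype=int)
    for i, k in enumerate(k_values):
        votes = case_cum[:, k - 1]
        pred = np.where(2 * votes > k, CASE, CONTROL)
        tie = 2 * votes == k
        pred[tie] = labels[tie, 0]
        errors[i] = np.sum(pred != test_y)
    return errors


class NearestShrunkenCentroid:
    """Nearest-shrunken-centroid (PAM) classification.

    Class centroids are standardized by the pooled within-class standard
    deviation (plus an offset ``s0``, the median of those deviations), moved
    toward the overall centroid by soft-thresholding the standardized
    difference at ``delta``, and de-standardized again.  A sample is
    assigned to the class with the smallest ``(s + s0)``-standardized
    squared distance to the shrunken centroid; class priors are uniform
    (the generated data are balanced) and exact distance ties go to the
    control class.  Features whose differences shrink to zero in all
    classes no longer influence the distance, i.e. they are eliminated.
    """

    def __init__(self, delta: float):
        if delta < 0:
            raise ValueError("delta must be >= 0")
        self.delta = float(delta)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "NearestShrunkenCentroid":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("training data must contain both classes")
        n, a = X.shape
        k_classes = len(self.classes_)
        centroids = np.vstack([X[y == c].mean(axis=0) for c in self.classes_])
        overall = X.mean(axis=0)
        within_ss = np.zeros(a)
        for c, cent in zip(self.classes_, centroids):
            within_ss += ((X[y == c] - cent) ** 2).sum(axis=0)
        s = np.sqrt(within_ss / (n - k_classes))
        s0 = np.median(s)
        n_k = np.array([(y == c).sum() for c in self.classes_])
        m_k = np.sqrt(1.0 / n_k - 1.0 / n)
        scale = m_k[:, None] * (s + s0)[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.where(scale > 0, (centroids - overall) / scale, 0.0)
        d_shrunk = np.sign(d) * np.maximum(np.abs(d) - self.delta, 0.0)
        self.s_, self.s0_ = s, s0
        self.overall_centroid_ = overall
        self.raw_differences_ = d
        self.shrunken_differences_ = d_shrunk
        self.shrunken_centroids_ = overall + scale * d_shrunk
        self.surviving_features_ = np.flatnonzero(
            (d_shrunk != 0).any(axis=0)
        )
        return self

    @property
    def n_surviving_features(self) -> int:
        return self.surviving_features_.size

    def discriminant_scores(self, X: np.ndarray) -> np.ndarray:
        """Standardized squared distances to each shrunken centroid,
        shape (n_samples, n_classes); smaller is closer."""
        X = np.asarray(X, dtype=float)
        denom = self.s_ + self.s0_
        safe = np.where(denom > 0, denom, np.inf)
        scores = np.empty((X.shape[0], len(self.classes_)))
        for j, cent in enumerate(self.shrunken_centroids_):
            scores[:, j] = (((X - cent) / safe) ** 2).sum(axis=1)
        return scores

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self.discriminant_scores(X)
        # argmin takes the first minimum: classes_ is sorted ascending, so
        # exact ties resolve to the control (negative) class
        return self.classes_[np.argmin(scores, axis=1)]


def nsc_shrink_centroids(
    train_data: OmicsDataset, features: Sequence[int], delta: float
) -> NearestShrunkenCentroid:
    """Fit the shrunken-centroid state on a feature subset of a dataset."""
    features = np.asarray(features, dtype=int)
    return NearestShrunkenCentroid(delta).fit(
        train_data.values[:, features], train_data.labels
    )


@dataclass
class TunedModel:
    """A fitted classifier together with its provenance: the spec it came
    from, the selected hyperparameters and the features it was trained on."""

    spec: ClassifierSpec
    chosen_params: dict
    fitted_state: object
    selected_features: np.ndarray


def _fit_raw(
    spec: ClassifierSpec,
    params: Mapping,
    X: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator | None = None,
):
    name = spec.name
    if name == "svm_linear":
        return SVC(kernel="linear", C=params["c"]).fit(X, y)
    if name == "svm_radial":
        return SVC(kernel="rbf", C=params["c"], gamma=params["gamma"]).fit(X, y)
    if name == "random_forest":
        seed = int(rng.integers(2**31 - 1)) if rng is not None else 0
        return RandomForestClassifier(
            n_estimators=int(spec.fixed.get("n_trees", 1000)),
            max_features=min(int(params["mtry"]), X.shape[1]),
            random_state=seed,
            n_jobs=1,
        ).fit(X, y)
    if name == "knn":
        return KNearestNeighbors(int(params["k"])).fit(X, y)
    if name == "plr":
        return LogisticRegression(  # default penalty is the L2 norm
            C=1.0 / params["lambda"],
            solver="lbfgs",
            tol=float(spec.fixed.get("tol", 1e-8)),
            max_iter=5000,
        ).fit(X, y)
    if name == "pam":
        return NearestShrunkenCentroid(params["delta"]).fit(X, y)
    raise ValueError(f"unknown classifier {name!r}")


def train(
    spec: ClassifierSpec,
    params: Mapping,
    train_data: OmicsDataset,
    features: Sequence[int],
    rng: np.random.Generator | None = None,
) -> TunedModel:
    """Fit one classifier on the given feature subset of the training data.

    ``params`` must be a point of the spec's (resolved) grid; ``rng`` seeds
    stochastic learners (the random forest) and is ignored by the rest.
    """
    features = np.asarray(features, dtype=int)
    if features.size == 0:
        raise ValueError("feature list must be nonempty")
    if len(np.unique(train_data.labels)) < 2:
        raise ValueError("training data must contain both classes")
    state = _fit_raw(
        spec, params, train_data.values[:, features], train_data.labels, rng
    )
    return TunedModel(
        spec=spec,
        chosen_params=dict(params),
        fitted_state=state,
        selected_features=features,
    )


def predict(model: TunedModel, test_data: OmicsDataset) -> np.ndarray:
    """Predict class labels for every sample of an individual-sample test set."""
    if test_data.n_features <= model.selected_features.max():
        raise ValueError("test data lacks features the model was trained on")
    X = test_data.values[:, model.selected_features]
    return np.asarray(model.fitted_state.predict(X), dtype=int)
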