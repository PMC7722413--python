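"""Six classifiers behind one train/predict surface, plus the repeated split.

The classifier battery is ANN (one hidden layer of 50 logistic units),
QDA (unregularized up to a numerical guard), SVM with the RBF kernel
only, logistic regression, Fisher's linear discriminant (closed form
W = S_W^{-1} (m1 - m2) with a midpoint threshold), and KNN with K = 4
(ties broken by the single nearest neighbor).  Evaluation uses a 70/30
stratified split repeated five times; when instances carry subject
identifiers the split is group-aware so all of one subject's instances
land on the same side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .exceptions import ParameterError

__all__ = [
    "CLASSIFIERS",
    "Dataset",
    "ClassifierSpec",
    "SplitPlan",
    "split_train_test",
    "flda_direction",
    "train_predict",
]

CLASSIFIERS = ("ANN", "QDA", "SVM", "LR", "FLDA", "KNN")


@dataclass
class Dataset:
    """Feature instances with binary labels (0 = normal, 1 = schizophrenia)."""

    instances: np.ndarray          # n x p
    labels: np.ndarray             # n, values {0, 1}
    group_id: np.ndarray           # n, subject identifier per instance

    def __post_init__(self) -> None:
        self.instances = np.asarray(self.instances, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.group_id = np.asarray(self.group_id)
        n = self.instances.shape[0]
        if self.instances.ndim != 2 or n < 1:
            raise ParameterError("instances must be an n x p matrix")
        if self.labels.shape != (n,) or self.group_id.shape != (n,):
            raise ParameterError("labels and group_id must have one entry per instance")
        if not np.isfinite(self.instances).all():
            raise ParameterError("instances contain non-finite values")
        if set(np.unique(self.labels)) - {0, 1}:
            raise ParameterError("labels must be 0 or 1")

    def require_both_classes(self) -> "Dataset":
        """Full-dataset invariant: n >= 4 with both labels present."""
        if self.n < 4 or len(np.unique(self.labels)) < 2:
            raise ParameterError("need n >= 4 instances covering both classes")
        return self

    def subset(self, rows: np.ndarray) -> "Dataset":
        return Dataset(self.instances[rows], self.labels[rows], self.group_id[rows])

    @property
    def n(self) -> int:
        return self.instances.shape[0]


@dataclass(frozen=True)
class ClassifierSpec:
    """Named classifier with its fixed hyperparameters.

    ANN: ``hidden_units`` (default 50), ``epoch_cap`` standing in for the
    zero-training-MSE target; SVM: ``C`` and ``gamma`` (default the
    1/(p * var) heuristic); KNN: ``k`` (default 4).
    """

    name: str
    hidden_units: int = 50
    epoch_cap: int = 2000
    C: float = 1.0
    gamma: str | float = "scale"
    k: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in CLASSIFIERS:
            raise ParameterError(f"unknown classifier {self.name!r}; choose from {CLASSIFIERS}")
        if self.hidden_units < 1:
            raise ParameterError("hidden_units must be >= 1")
        if self.k < 1:
            raise ParameterError("k must be >= 1")
        if self.C <= 0:
            raise ParameterError("C must be > 0")


@dataclass(frozen=True)
class SplitPlan:
    train_fraction: float = 0.70
    repetitions: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ParameterError("train_fraction must lie in (0, 1)")
        if self.repetitions < 1:
            raise ParameterError("repetitions must be >= 1")


def split_train_test(dataset: Dataset, plan: SplitPlan,
                     repetition_index: int) -> tuple[Dataset, Dataset]:
    """Group-aware stratified split, deterministic per (seed, repetition).

    Within each class the distinct subjects are shuffled and the first
    ``train_fraction`` (rounded) go to the training side, the rest to the
    test side, so no subject straddles the boundary.  When each instance
    is its own group this reduces to a plain stratified instance split.
    """
    dataset.require_both_classes()
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=int(plan.seed), spawn_key=(int(repetition_index),)))
    train_mask = np.zeros(dataset.n, dtype=bool)
    for label in (0, 1):
        in_class = dataset.labels == label
        groups = np.unique(dataset.group_id[in_class])
        if groups.size < 2:
            raise ParameterError(
                f"class {label} has {groups.size} subject(s); cannot place the class on both sides"
            )
        perm = rng.permutation(groups)
        n_train = int(round(plan.train_fraction * groups.size))
        n_train = min(max(n_train, 1), groups.size - 1)
        chosen = set(perm[:n_train].tolist())
        train_mask |= in_class & np.isin(dataset.group_id, list(chosen))
    return dataset.subset(train_mask), dataset.subset(~train_mask)


def flda_direction(train: Dataset, ridge: float = 1e-8) -> tuple[np.ndarray, float]:
    """Fisher discriminant direction W = S_W^{-1} (m1 - m0) and midpoint threshold.

    S_W is the pooled within-class scatter; when it is singular a ridge
    eps * trace/p * I is added.  Identical class means give the zero
    vector and a chance-level rule.
    """
    x0 = train.instances[train.labels == 0]
    x1 = train.instances[train.labels == 1]
    m0 = x0.mean(axis=0)
    m1 = x1.mean(axis=0)
    sw = (x0 - m0).T @ (x0 - m0) + (x1 - m1).T @ (x1 - m1)
    p = sw.shape[0]
    diff = m1 - m0
    if not np.any(diff):
        return np.zeros(p), 0.0
    try:
        w = np.linalg.solve(sw, diff)
        if not np.isfinite(w).all():
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        guard = ridge * max(np.trace(sw) / p, 1.0)
        w = np.linalg.solve(sw + guard * np.eye(p), diff)
    threshold = 0.5 * (float(m0 @ w) + float(m1 @ w))
    return w, threshold


class _FLDA:
    """Closed-form Fisher discriminant as a minimal estimator."""

    def fit(self, x: np.ndarray, y: np.ndarray) -> "_FLDA":
        self.w_, self.threshold_ = flda_direction(Dataset(x, y, np.arange(len(y))))
        return self

    def decision_function(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x) @ self.w_ - self.threshold_

    def predict(self, x: np.ndarray) -> np.ndarray:
        return (self.decision_function(x) > 0).astype(int)


def _build(spec: ClassifierSpec):
    if spec.name == "ANN":
        return MLPClassifier(
            hidden_layer_sizes=(spec.hidden_units,),
            activation="logistic",
            solver="lbfgs",
            max_iter=spec.epoch_cap,
            tol=1e-6,
            random_state=spec.seed,
        )
    if spec.name == "QDA":
        # reg_param is a numerical-stability guard only
        return QuadraticDiscriminantAnalysis(reg_param=1e-6)
    if spec.name == "SVM":
        return SVC(kernel="rbf", C=spec.C, gamma=spec.gamma)
    if spec.name == "LR":
        return LogisticRegression(max_iter=1000)
    if spec.name == "FLDA":
        return _FLDA()
    if spec.name == "KNN":
        return KNeighborsClassifier(n_neighbors=spec.k)
    raise ParameterError(f"unknown classifier {spec.name!r}")  # pragma: no cover


def train_predict(spec: ClassifierSpec, train: Dataset,
                  test: Dataset) -> tuple[np.ndarray, np.ndarray]:
    """Fit the named classifier on ``train`` and score ``test``.

    Returns (predicted labels, real-valued scores).  Scores are the
    decision function where available, otherwise the class-1 probability
    or vote fraction; KNN ties at K = 4 are broken by the single nearest
    neighbor.
    """
    if len(np.unique(train.labels)) < 2:
        raise ParameterError("training set must contain both classes")
    model = _build(spec)
    model.fit(train.instances, train.labels)
    x = test.instances
    if spec.name == "KNN":
        return _knn_predict(model, train, x, spec.k)
    if hasattr(model, "decision_function"):
        scores = np.asarray(model.decision_function(x), dtype=float)
    else:
        scores = np.asarray(model.predict_proba(x)[:, 1], dtype=float)
    pred = np.asarray(model.predict(x), dtype=int)
    return pred, scores


def _knn_predict(model: KNeighborsClassifier, train: Dataset,
                 x: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    dist, idx = model.kneighbors(x, n_neighbors=min(k, train.n))
    votes = train.labels[idx]
    frac1 = votes.mean(axis=1)
    pred = (frac1 > 0.5).astype(int)
    ties = frac1 == 0.5
    if ties.any():
        # nearest single neighbor decides an even vote
        pred[ties] = train.labels[idx[ties, 0]]
    return pred, frac1
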