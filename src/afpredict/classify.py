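"""Classification, cross-validation, metrics and the backward-in-time protocol.

The positive class is "pre-AF" (a segment ending at — or a stated offset
before — an AF onset); the negative class is "control".  The five reported
statistics are

    SEN = TP/(TP+FN)   SPE = TN/(TN+FP)   ACC = (TP+TN)/total
    PPV = TP/(TP+FP)   NPV = TN/(TN+FN)

in percent.  Cross-validation pools fold predictions into a single confusion
matrix before computing metrics.  The backward evaluation slides the 5-min
test window away from the onset in 50%-overlap steps (offsets 0, 150, 300,
450, 600 s — i.e. up to the window covering 15 to 10 minutes before onset)
to measure how early the prediction still works.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .features import FeatureVector
from .preprocess import extract_segment
from .signals import RRSeries
from .synth import LABEL_PREAF

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "TrainedModel",
    "metrics",
    "train",
    "predict",
    "cross_validate",
    "EvalRecord",
    "backward_evaluate",
    "BACKWARD_OFFSETS_S",
    "CLASSIFIER_KINDS",
]

#: 5-min windows stepped backward at 50% overlap up to 15 min before onset
BACKWARD_OFFSETS_S = (0.0, 150.0, 300.0, 450.0, 600.0)


@dataclass
class ConfusionMatrix:
    tp: int = 0
    fn: int = 0
    fp: int = 0
    tn: int = 0

    def __post_init__(self) -> None:
        for v in (self.tp, self.fn, self.fp, self.tn):
            if v < 0 or int(v) != v:
                raise ValueError("confusion counts must be non-negative integers")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @classmethod
    def from_labels(cls, y_true, y_pred) -> "ConfusionMatrix":
        cm = cls()
        for t, p in zip(y_true, y_pred, strict=True):
            if t == LABEL_PREAF:
                if p == LABEL_PREAF:
                    cm.tp += 1
                else:
                    cm.fn += 1
            else:
                if p == LABEL_PREAF:
                    cm.fp += 1
                else:
                    cm.tn += 1
        return cm


@dataclass
class MetricsReport:
    sen: float
    spe: float
    acc: float
    ppv: float
    npv: float

    def as_dict(self) -> dict[str, float]:
        return {
            "SEN": self.sen, "SPE": self.spe, "ACC": self.acc,
            "PPV": self.ppv, "NPV": self.npv,
        }

    def __str__(self) -> str:
        return "  ".join(
            f"{k} {v:.2f}%" if np.isfinite(v) else f"{k} --"
            for k, v in self.as_dict().items()
        )


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """The five confusion-matrix statistics, in percent (2-dp reporting).

    A statistic whose denominator is zero is reported as a NaN sentinel.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")

    def pct(num: int, den: int) -> float:
        return round(100.0 * num / den, 2) if den > 0 else float("nan")

    return MetricsReport(
        sen=pct(cm.tp, cm.tp + cm.fn),
        spe=pct(cm.tn, cm.tn + cm.fp),
        acc=pct(cm.tp + cm.tn, cm.total),
        ppv=pct(cm.tp, cm.tp + cm.fp),
        npv=pct(cm.tn, cm.tn + cm.fn),
    )


# --- discriminant-analysis variants not shipped by scikit-learn -------------


class _GaussianDA(BaseEstimator, ClassifierMixin):
    """Gaussian discriminant analysis with diagonal or Mahalanobis variants.

    ``mode="diaglinear"`` pools a diagonal covariance across classes,
    ``"diagquadratic"`` fits a diagonal covariance per class, and
    ``"mahalanobis"`` assigns to the nearest class mean in the
    pooled-full-covariance Mahalanobis metric.
    """

    def __init__(self, mode: str = "diaglinear"):
        self.mode = mode

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self.means_ = np.array([X[y == c].mean(axis=0) for c in self.classes_])
        self.priors_ = np.array([(y == c).mean() for c in self.classes_])
        eps = 1e-9
        if self.mode == "diaglinear":
            pooled = np.zeros(X.shape[1])
            for c, mu in zip(self.classes_, self.means_):
                d = X[y == c] - mu
                pooled += (d**2).sum(axis=0)
            self.var_ = pooled / len(X) + eps
        elif self.mode == "diagquadratic":
            self.var_ = np.array(
                [X[y == c].var(axis=0) + eps for c in self.classes_]
            )
        elif self.mode == "mahalanobis":
            resid = np.vstack(
                [X[y == c] - mu for c, mu in zip(self.classes_, self.means_)]
            )
            cov = resid.T @ resid / len(X) + eps * np.eye(X.shape[1])
            self.cov_inv_ = np.linalg.inv(cov)
        else:
            raise ValueError(f"unknown DA mode {self.mode!r}")
        return self

    def _scores(self, X):
        X = np.asarray(X, dtype=float)
        scores = np.empty((len(X), len(self.classes_)))
        for k, mu in enumerate(self.means_):
            d = X - mu
            if self.mode == "diaglinear":
                ll = -0.5 * np.sum(d**2 / self.var_, axis=1)
            elif self.mode == "diagquadratic":
                var = self.var_[k]
                ll = -0.5 * np.sum(d**2 / var + np.log(var), axis=1)
            else:  # mahalanobis: pure distance, no priors
                return_dist = np.einsum("ij,jk,ik->i", d, self.cov_inv_, d)
                scores[:, k] = -return_dist
                continue
            scores[:, k] = ll + np.log(self.priors_[k])
        return scores

    def predict(self, X):
        return self.classes_[np.argmax(self._scores(X), axis=1)]


def _make_estimator(kind: str, hyperparams: dict, n_features: int, seed: int):
    hp = dict(hyperparams or {})
    if kind == "svm_rbf":
        if "C" in hp and "gamma" in hp:
            return SVC(kernel="rbf", **hp), False
        base = SVC(kernel="rbf")
        grid = {
            "C": [0.1, 1.0, 10.0, 100.0],
            "gamma": [0.01, 0.1, 1.0 / n_features, 1.0],
        }
        return GridSearchCV(base, grid, cv=5, scoring="accuracy"), True
    if kind == "svm_linear":
        return SVC(kernel="linear", C=hp.get("C", 1.0)), False
    if kind == "rf":
        return (
            RandomForestClassifier(
                n_estimators=int(hp.get("n_trees", 50)),
                max_features="sqrt",
                random_state=seed,
            ),
            False,
        )
    if kind == "knn":
        return (
            KNeighborsClassifier(
                n_neighbors=int(hp.get("k", 5)),
                metric=hp.get("metric", "euclidean"),
            ),
            False,
        )
    if kind == "da_linear":
        return LinearDiscriminantAnalysis(), False
    if kind == "da_quadratic":
        return QuadraticDiscriminantAnalysis(), False
    if kind in ("da_diaglinear", "da_diagquadratic", "da_mahalanobis"):
        return _GaussianDA(mode=kind.removeprefix("da_")), False
    raise ValueError(f"unknown classifier kind {kind!r}")


CLASSIFIER_KINDS = (
    "svm_rbf", "svm_linear", "rf", "knn",
    "da_linear", "da_quadratic", "da_diaglinear", "da_diagquadratic",
    "da_mahalanobis",
)


@dataclass
class TrainedModel:
    kind: str
    hyperparams: dict
    feature_names: tuple[str, ...]
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    estimator: object
    seed: int = 0

    def scale(self, X: np.ndarray) -> np.ndarray:
        return (X - self.scaler_mean) / self.scaler_sd


def _design_matrix(
    vectors: list[FeatureVector], names: tuple[str, ...] | None = None
) -> tuple[np.ndarray, tuple[str, ...]]:
    if not vectors:
        raise ValueError("no feature vectors supplied")
    names = names or vectors[0].names
    for v in vectors:
        if set(names) - set(v.names):
            raise ValueError(
                f"feature schema mismatch for segment {v.segment_id!r}: "
                f"missing {sorted(set(names) - set(v.names))}"
            )
    X = np.vstack([v.as_array(names) for v in vectors])
    if not np.all(np.isfinite(X)):
        bad = [vectors[i].segment_id for i in np.where(~np.isfinite(X).all(axis=1))[0]]
        raise ValueError(f"non-finite feature values in segments {bad}")
    return X, names


def train(
    vectors: list[FeatureVector],
    kind: str = "svm_rbf",
    hyperparams: dict | None = None,
    seed: int = 0,
) -> TrainedModel:
    """Fit a classifier with training-set z-score scaling.

    The per-feature mean/sd are estimated from the training data only and
    stored with the model; the RBF SVM tunes C and γ by an inner 5-fold grid
    search when they are not supplied.  Deterministic given ``seed``.
    """
    X, names = _design_matrix(vectors)
    y = np.array([v.label for v in vectors])
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training data contain a single class")
    if counts.min() < 2:
        raise ValueError("need at least 2 examples per class")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Xs = (X - mean) / sd
    est, is_grid = _make_estimator(kind, hyperparams or {}, X.shape[1], seed)
    est.fit(Xs, y)
    hp = dict(hyperparams or {})
    if is_grid:
        hp.update(est.best_params_)
        est = est.best_estimator_
    return TrainedModel(
        kind=kind,
        hyperparams=hp,
        feature_names=names,
        scaler_mean=mean,
        scaler_sd=sd,
        estimator=est,
        seed=seed,
    )


def predict(model: TrainedModel, vectors: list[FeatureVector]) -> list[str]:
    """Apply the stored scaler and classifier; never refits."""
    if not vectors:
        return []
    X, _ = _design_matrix(vectors, model.feature_names)
    return list(model.estimator.predict(model.scale(X)))


def cross_validate(
    vectors: list[FeatureVector],
    kind: str = "rf",
    k: int = 5,
    hyperparams: dict | None = None,
    seed: int = 0,
) -> tuple[MetricsReport, ConfusionMatrix]:
    """Stratified k-fold CV with per-fold scaling, pooled into one matrix."""
    X, names = _design_matrix(vectors)
    y = np.array([v.label for v in vectors])
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("cross-validation needs both classes")
    if k > counts.min():
        raise ValueError(f"k={k} exceeds smallest class size {counts.min()}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    cm = ConfusionMatrix()
    for train_idx, test_idx in skf.split(X, y):
        fold_train = [vectors[i] for i in train_idx]
        model = train(fold_train, kind=kind, hyperparams=hyperparams, seed=seed)
        preds = predict(model, [vectors[i] for i in test_idx])
        part = ConfusionMatrix.from_labels(y[test_idx], preds)
        cm.tp += part.tp
        cm.fn += part.fn
        cm.fp += part.fp
        cm.tn += part.tn
    return metrics(cm), cm


@dataclass
class EvalRecord:
    """A long RR record with the reference point the backward windows end at.

    For pre-AF records ``onset_s`` is the adjudicated AF onset; for controls
    it is an arbitrary fixed reference point used at every offset.
    """

    rr: RRSeries
    onset_s: float
    label: str
    record_id: str = ""


@dataclass
class BackwardResult:
    offset_s: float
    report: MetricsReport
    cm: ConfusionMatrix
    n_excluded: int = 0
    excluded_ids: list[str] = field(default_factory=list)


def backward_evaluate(
    records: list[EvalRecord],
    model: TrainedModel,
    offsets_s: tuple[float, ...] = BACKWARD_OFFSETS_S,
    window_len_s: float = 300.0,
    subset: str = "selected14",
    **extract_kwargs,
) -> list[BackwardResult]:
    """Per-offset prediction metrics for windows sliding away from onset.

    For each offset ``o`` the window [onset − o − 300 s, onset − o] is
    extracted, featurised and predicted; records too short for an offset are
    excluded from that offset with a reported count.
    """
    from .features import assemble_features  # local import avoids cycle

    results = []
    for off in offsets_s:
        y_true, vecs, excluded = [], [], []
        for rec in records:
            try:
                seg = extract_segment(rec.rr, rec.onset_s, off, window_len_s)
                vec = assemble_features(
                    seg, subset=subset, segment_id=rec.record_id,
                    label=rec.label, **extract_kwargs,
                )
            except ValueError:
                excluded.append(rec.record_id)
                continue
            y_true.append(rec.label)
            vecs.append(vec)
        if not vecs:
            raise ValueError(f"no records usable at offset {off} s")
        preds = predict(model, vecs)
        cm = ConfusionMatrix.from_labels(y_true, preds)
        results.append(
            BackwardResult(
                offset_s=off,
                report=metrics(cm),
                cm=cm,
                n_excluded=len(excluded),
                excluded_ids=excluded,
            )
        )
    return results
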