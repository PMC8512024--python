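"""The three recognition techniques: Gaussian naive Bayes, K-nearest
neighbors, and one-against-all RBF-kernel SVM.

Naive Bayes is implemented directly: per-class empirical priors, per-class
per-feature Gaussian densities with population variances floored at 1e-9,
prediction by maximal log-posterior with ties broken toward the lowest
class id.  KNN and the binary SVM quadratic-programming core delegate to
scikit-learn; this module owns the hamming-metric binarization (features
thresholded at their training-set medians), the one-against-all wrapping
with decision-value aggregation, the "medium Gaussian" kernel-scale
convention (scale = sqrt(n_features), gamma = 1/scale^2), and the feature
standardization fitted on training data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .features import FeatureMatrix

VAR_FLOOR = 1e-9


@dataclass
class Standardizer:
    """Per-feature z-score scaler; constant features pass through unscaled."""

    mean_: np.ndarray
    scale_: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        return cls(mu, np.where(sd > 0, sd, 1.0))

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean_) / self.scale_


@dataclass
class Prediction:
    """Predicted label plus per-class scores (argmax-consistent)."""

    labels: np.ndarray
    classes: np.ndarray
    scores: np.ndarray          # (n, n_classes)


class TrainedModel:
    """Base: stores classes, feature names and any fitted scalers."""

    kind: str = ""

    def __init__(self, classes: np.ndarray, feature_names: list[str] | None):
        self.classes = np.asarray(classes)
        self.feature_names = feature_names

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_full(X).labels

    def predict_full(self, X: np.ndarray) -> Prediction:  # pragma: no cover
        raise NotImplementedError


# ---------------------------------------------------------------------------
# Gaussian naive Bayes
# ---------------------------------------------------------------------------

class NaiveBayesModel(TrainedModel):
    kind = "nb"

    def __init__(self, classes, feature_names, priors, means, variances):
        super().__init__(classes, feature_names)
        self.priors = priors
        self.means = means
        self.variances = variances

    def predict_full(self, X: np.ndarray) -> Prediction:
        X = np.asarray(X, dtype=float)
        # log joint: log prior + sum_f log N(x_f | mu_cf, var_cf)
        lp = np.log(self.priors)[None, :]
        diff = X[:, None, :] - self.means[None, :, :]          # (n, C, p)
        logdens = -0.5 * (
            np.log(2.0 * np.pi * self.variances)[None, :, :]
            + diff * diff / self.variances[None, :, :]
        )
        scores = lp + logdens.sum(axis=2)
        idx = np.argmax(scores, axis=1)                        # ties -> lowest id
        return Prediction(self.classes[idx], self.classes, scores)


def train_nb(fm: FeatureMatrix) -> NaiveBayesModel:
    """Fit per-class Gaussians (population variance + 1e-9 floor) and
    empirical priors; requires >= 2 rows per class when multiclass."""
    classes, y = np.unique(fm.labels, return_inverse=True)
    counts = np.bincount(y)
    if len(classes) >= 2 and counts.min() < 2:
        raise ValueError("each class needs at least 2 training rows")
    X = fm.values
    C, p = len(classes), X.shape[1]
    means = np.empty((C, p))
    variances = np.empty((C, p))
    for c in range(C):
        Xc = X[y == c]
        means[c] = Xc.mean(axis=0)
        variances[c] = np.maximum(Xc.var(axis=0), VAR_FLOOR)
    priors = counts / counts.sum()
    return NaiveBayesModel(classes, fm.feature_names, priors, means, variances)


# ---------------------------------------------------------------------------
# K-nearest neighbors
# ---------------------------------------------------------------------------

class KnnModel(TrainedModel):
    kind = "knn"

    def __init__(self, classes, feature_names, estimator, k, metric,
                 scaler=None, edges=None):
        super().__init__(classes, feature_names)
        self.estimator = estimator
        self.k = k
        self.metric = metric
        self.scaler = scaler
        self.edges = edges   # per-feature quantile cut points (hamming)

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.metric == "hamming":
            return np.stack(
                [np.digitize(X[:, j], self.edges[:, j]) for j in range(X.shape[1])],
                axis=1,
            ).astype(float)
        return self.scaler.transform(X)

    def predict_full(self, X: np.ndarray) -> Prediction:
        Xp = self._prepare(X)
        labels = self.estimator.predict(Xp)
        proba = self.estimator.predict_proba(Xp)
        # align sklearn's class order with ours (identical by construction,
        # both sorted) and re-apply the lowest-class-id tie rule
        idx = np.argmax(proba, axis=1)
        return Prediction(self.classes[idx], self.classes, proba)


def train_knn(
    fm: FeatureMatrix, k: int = 3, metric: str = "hamming", hamming_levels: int = 8
) -> KnnModel:
    """K-nearest-neighbor majority vote.

    The hamming metric applies to real-valued features via per-feature
    quantile discretization (``hamming_levels`` codes, edges fit on the
    training set); the distance is then the fraction of differing codes.
    ``hamming_levels=2`` recovers a median binarization.  ``euclidean``
    standardizes features instead.  Vote ties resolve to the lowest
    class id.
    """
    if not 1 <= k <= fm.n_rows:
        raise ValueError("K must satisfy 1 <= K <= number of training rows")
    if metric not in ("hamming", "euclidean"):
        raise ValueError(f"unsupported metric {metric!r}")
    classes = np.unique(fm.labels)
    X = fm.values
    scaler = edges = None
    if metric == "hamming":
        if hamming_levels < 2:
            raise ValueError("hamming_levels must be >= 2")
        qs = np.linspace(0.0, 1.0, hamming_levels + 1)[1:-1]
        edges = np.quantile(X, qs, axis=0)
    else:
        scaler = Standardizer.fit(X)
    est = KNeighborsClassifier(n_neighbors=k, metric=metric, algorithm="brute")
    model = KnnModel(classes, fm.feature_names, est, k, metric, scaler, edges)
    est.fit(model._prepare(X), fm.labels)
    return model


# ---------------------------------------------------------------------------
# One-against-all RBF SVM
# ---------------------------------------------------------------------------

class SvmModel(TrainedModel):
    kind = "svm"

    def __init__(self, classes, feature_names, machines, scaler, C, kernel_scale):
        super().__init__(classes, feature_names)
        self.machines = machines       # one binary SVC per class, class order
        self.scaler = scaler
        self.C = C
        self.kernel_scale = kernel_scale

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        Xs = self.scaler.transform(np.asarray(X, dtype=float))
        return np.column_stack([m.decision_function(Xs) for m in self.machines])

    def predict_full(self, X: np.ndarray) -> Prediction:
        scores = self.decision_values(X)
        idx = np.argmax(scores, axis=1)
        return Prediction(self.classes[idx], self.classes, scores)


def train_svm(
    fm: FeatureMatrix, C: float = 1.0, kernel_scale: float | None = None
) -> SvmModel:
    """One-against-all soft-margin RBF SVM.

    One binary machine per class (class vs rest); prediction takes the
    class with the maximal decision value.  The default kernel scale is
    sqrt(n_features) — the convention behind "medium Gaussian" presets —
    applied as gamma = 1/kernel_scale^2 on standardized features.
    """
    X = np.asarray(fm.values, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    classes = np.unique(fm.labels)
    if len(classes) < 2:
        raise ValueError("SVM needs at least 2 classes")
    if kernel_scale is None:
        kernel_scale = float(np.sqrt(X.shape[1]))
    scaler = Standardizer.fit(X)
    Xs = scaler.transform(X)
    gamma = 1.0 / (kernel_scale**2)
    machines = []
    for c in classes:
        yc = (fm.labels == c).astype(int)
        m = SVC(kernel="rbf", C=C, gamma=gamma)
        m.fit(Xs, yc)
        # sklearn orients the decision function by class order {0, 1}:
        # positive means "this class" since 1 = member
        machines.append(m)
    return SvmModel(classes, fm.feature_names, machines, scaler, C, kernel_scale)


# ---------------------------------------------------------------------------
# Roster
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassifierSpec:
    """A classifier id plus its hyperparameters, e.g. knn3 / svm / nb."""

    kind: str                       # nb | knn | svm
    k: int = 3
    metric: str = "hamming"
    hamming_levels: int = 8
    C: float = 1.0
    kernel_scale: float | None = None

    @property
    def name(self) -> str:
        if self.kind == "knn":
            return f"knn{self.k}"
        return self.kind


def default_roster() -> list[ClassifierSpec]:
    """The six study settings: KNN at K in {3,5,7,11}, SVM and naive Bayes."""
    return [
        ClassifierSpec("nb"),
        ClassifierSpec("knn", k=3),
        ClassifierSpec("knn", k=5),
        ClassifierSpec("knn", k=7),
        ClassifierSpec("knn", k=11),
        ClassifierSpec("svm"),
    ]


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

FORMAT_VERSION = 1


def save_model(model: TrainedModel, path) -> None:
    """Serialize a trained model.

    NB and KNN are stored as versioned JSON; the SVM additionally embeds
    its solver state (pickled scikit-learn machines, base64) since the
    support-vector expansion has no portable JSON form.
    """
    import base64
    import json
    import pickle

    doc = {
        "format_version": FORMAT_VERSION,
        "kind": model.kind,
        "classes": model.classes.tolist(),
        "feature_names": model.feature_names,
    }
    if isinstance(model, NaiveBayesModel):
        doc.update(
            priors=model.priors.tolist(),
            means=model.means.tolist(),
            variances=model.variances.tolist(),
        )
    elif isinstance(model, KnnModel):
        doc.update(
            k=model.k,
            metric=model.metric,
            train_x=model.estimator._fit_X.tolist(),
            train_y=model.estimator.classes_[model.estimator._y].tolist(),
        )
        if model.metric == "hamming":
            doc["edges"] = model.edges.tolist()
        else:
            doc["scaler"] = {
                "mean": model.scaler.mean_.tolist(),
                "scale": model.scaler.scale_.tolist(),
            }
    elif isinstance(model, SvmModel):
        doc.update(
            C=model.C,
            kernel_scale=model.kernel_scale,
            scaler={
                "mean": model.scaler.mean_.tolist(),
                "scale": model.scaler.scale_.tolist(),
            },
            machines_pickle=base64.b64encode(
                pickle.dumps(model.machines)
            ).decode("ascii"),
        )
    else:
        raise TypeError(f"cannot serialize {type(model).__name__}")
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path) -> TrainedModel:
    import base64
    import json
    import pickle

    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format_version") != FORMAT_VERSION:
        raise ValueError(f"unsupported model format: {doc.get('format_version')}")
    classes = np.array(doc["classes"])
    names = doc["feature_names"]
    if doc["kind"] == "nb":
        return NaiveBayesModel(
            classes, names,
            np.array(doc["priors"]), np.array(doc["means"]),
            np.array(doc["variances"]),
        )
    if doc["kind"] == "knn":
        est = KNeighborsClassifier(
            n_neighbors=doc["k"], metric=doc["metric"], algorithm="brute"
        )
        est.fit(np.array(doc["train_x"]), np.array(doc["train_y"]))
        scaler = edges = None
        if doc["metric"] == "hamming":
            edges = np.array(doc["edges"])
        else:
            scaler = Standardizer(
                np.array(doc["scaler"]["mean"]), np.array(doc["scaler"]["scale"])
            )
        return KnnModel(classes, names, est, doc["k"], doc["metric"], scaler, edges)
    if doc["kind"] == "svm":
        machines = pickle.loads(base64.b64decode(doc["machines_pickle"]))
        scaler = Standardizer(
            np.array(doc["scaler"]["mean"]), np.array(doc["scaler"]["scale"])
        )
        return SvmModel(classes, names, machines, scaler, doc["C"],
                        doc["kernel_scale"])
    raise ValueError(f"unknown model kind {doc['kind']!r}")


def train(fm: FeatureMatrix, spec: ClassifierSpec) -> TrainedModel:
    if spec.kind == "nb":
        return train_nb(fm)
    if spec.kind == "knn":
        return train_knn(
            fm, k=spec.k, metric=spec.metric, hamming_levels=spec.hamming_levels
        )
    if spec.kind == "svm":
        return train_svm(fm, C=spec.C, kernel_scale=spec.kernel_scale)
    raise ValueError(f"unknown classifier kind {spec.kind!r}")
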