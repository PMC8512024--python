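"""Splitting, cross-validation, confusion matrices and accuracy reporting.

Overall accuracy is trace/total of the multiclass confusion matrix;
per-activity accuracy is the class recall (diagonal over row sum).  All
reported percentages round half-up to two decimals.  Cross-validation is
stratified; any training-fold-dependent fitting (feature standardization,
hamming binarization thresholds, CFS-PSO subset selection) happens inside
the training folds only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import classify
from .features import FeatureMatrix
from .selection import PsoParams, build_correlation_table, pso_search
from .synthetic import ACTIVITIES


def round2(x: float) -> float:
    """Half-up rounding to 2 decimals (report convention)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), ROUND_HALF_UP))


@dataclass
class ConfusionMatrix:
    """Square count matrix; rows = true class, columns = predicted class."""

    counts: np.ndarray
    class_order: tuple[str, ...] = ACTIVITIES

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        c = len(self.class_order)
        if self.counts.shape != (c, c):
            raise ValueError("counts must be square in the class order")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_sum(self, activity: str) -> int:
        return int(self.counts[self.class_order.index(activity)].sum())

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            self.counts, index=list(self.class_order), columns=list(self.class_order)
        ).to_csv(path)


def confusion_matrix(
    true: np.ndarray, predicted: np.ndarray, class_order=ACTIVITIES
) -> ConfusionMatrix:
    """counts[i, j] = #(true == class_i and predicted == class_j)."""
    true = np.asarray(true)
    predicted = np.asarray(predicted)
    if len(true) != len(predicted) or len(true) == 0:
        raise ValueError("label arrays must be equal-length and non-empty")
    index = {c: i for i, c in enumerate(class_order)}
    bad = (set(true) | set(predicted)) - set(class_order)
    if bad:
        raise ValueError(f"labels outside the class order: {sorted(bad)}")
    counts = np.zeros((len(class_order), len(class_order)), dtype=int)
    ti = np.array([index[t] for t in true])
    pi = np.array([index[p] for p in predicted])
    np.add.at(counts, (ti, pi), 1)
    return ConfusionMatrix(counts, tuple(class_order))


def per_activity_accuracy(cm: ConfusionMatrix, activity: str) -> float:
    """Class recall in percent: 100 * diagonal / row sum, rounded half-up."""
    i = cm.class_order.index(activity)
    rs = cm.counts[i].sum()
    if rs == 0:
        raise ValueError(f"no true instances of {activity}")
    return round2(100.0 * cm.counts[i, i] / rs)


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """100 * trace / total, rounded half-up to 2 decimals."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return round2(100.0 * np.trace(cm.counts) / cm.total)


def per_class_tp_tn_fp_fn(cm: ConfusionMatrix) -> dict[str, dict[str, int]]:
    """Binary one-vs-rest counts per class, for transparency."""
    out = {}
    tot = cm.total
    for i, c in enumerate(cm.class_order):
        tp = int(cm.counts[i, i])
        fn = int(cm.counts[i].sum() - tp)
        fp = int(cm.counts[:, i].sum() - tp)
        out[c] = {"TP": tp, "FN": fn, "FP": fp, "TN": tot - tp - fn - fp}
    return out


@dataclass
class EvalReport:
    """One classifier's evaluation: confusion matrix plus accuracies."""

    classifier: str
    split: str
    seed: int
    cm: ConfusionMatrix
    overall: float = field(init=False)
    per_activity: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        self.overall = overall_accuracy(self.cm)
        self.per_activity = {}
        for c in self.cm.class_order:
            if self.cm.row_sum(c) > 0:
                self.per_activity[c] = per_activity_accuracy(self.cm, c)

    def to_dict(self) -> dict:
        return {
            "classifier": self.classifier,
            "split": self.split,
            "seed": self.seed,
            "overall_accuracy": self.overall,
            "per_activity_accuracy": self.per_activity,
            "per_class_counts": per_class_tp_tn_fp_fn(self.cm),
            "confusion_matrix": self.cm.counts.tolist(),
            "class_order": list(self.cm.class_order),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_text(self) -> str:
        """Aligned-text confusion matrix and accuracy table."""
        co = self.cm.class_order
        w = max(6, max(len(str(v)) for v in self.cm.counts.ravel()))
        lines = [f"classifier: {self.classifier}  split: {self.split}"]
        lines.append("true\\pred " + " ".join(f"{c:>{w}}" for c in co))
        for i, c in enumerate(co):
            lines.append(
                f"{c:>9} " + " ".join(f"{v:>{w}}" for v in self.cm.counts[i])
            )
        lines.append(
            "per-activity accuracy (%): "
            + "  ".join(f"{c}={v:.2f}" for c, v in self.per_activity.items())
        )
        lines.append(f"overall accuracy (%): {self.overall:.2f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Splits and cross-validation
# ---------------------------------------------------------------------------

def stratified_split(
    fm: FeatureMatrix, train_fraction: float = 0.75, seed: int = 0
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Seeded stratified holdout split preserving class proportions (+/-1)."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    _, counts = np.unique(fm.labels, return_counts=True)
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 instances to stratify")
    idx = np.arange(fm.n_rows)
    tr, te = train_test_split(
        idx, train_size=train_fraction, random_state=seed, stratify=fm.labels
    )
    return fm.subset_rows(np.sort(tr)), fm.subset_rows(np.sort(te))


@dataclass(frozen=True)
class SelectionSettings:
    """How each training fold chooses features: a fixed preset list, a
    CFS+PSO search, or the full bank (None)."""

    mode: str = "none"                # none | preset | pso
    preset: tuple[str, ...] = ()
    bins: int = 10
    measure: str = "su"
    pso: PsoParams = PsoParams()


def _fold_features(train_fm: FeatureMatrix, settings: SelectionSettings,
                   fold_seed: int) -> list[str]:
    if settings.mode == "none":
        return list(train_fm.feature_names)
    if settings.mode == "preset":
        return list(settings.preset)
    if settings.mode == "pso":
        table = build_correlation_table(train_fm, settings.bins, settings.measure)
        params = PsoParams(
            swarm_size=settings.pso.swarm_size,
            iterations=settings.pso.iterations,
            inertia=settings.pso.inertia,
            cognitive=settings.pso.cognitive,
            social=settings.pso.social,
            v_max=settings.pso.v_max,
            seed=fold_seed,
        )
        subset = pso_search(table, params)
        return [n for n, b in zip(train_fm.feature_names, subset.mask) if b]
    raise ValueError(f"unknown selection mode {settings.mode!r}")


def holdout_eval(
    fm: FeatureMatrix,
    spec: classify.ClassifierSpec,
    train_fraction: float = 0.75,
    seed: int = 0,
    selection: SelectionSettings | None = None,
) -> EvalReport:
    """Single stratified holdout evaluation (default 75/25, the study split)."""
    selection = selection or SelectionSettings()
    train, test = stratified_split(fm, train_fraction, seed)
    names = _fold_features(train, selection, seed)
    model = classify.train(train.select(names), spec)
    pred = model.predict(test.select(names).values)
    cm = confusion_matrix(test.labels, pred)
    return EvalReport(spec.name, f"holdout {train_fraction:.0%}", seed, cm)


def kfold_cv(
    fm: FeatureMatrix,
    k: int,
    spec: classify.ClassifierSpec,
    seed: int = 0,
    selection: SelectionSettings | None = None,
) -> EvalReport:
    """Stratified k-fold CV with a pooled confusion matrix.

    Every row is predicted exactly once; feature selection and any
    feature scaling are fit inside each training fold.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    _, counts = np.unique(fm.labels, return_counts=True)
    if counts.min() < k:
        raise ValueError("every class needs at least k instances")
    selection = selection or SelectionSettings()
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    true_all, pred_all = [], []
    for fold, (tr, te) in enumerate(skf.split(fm.values, fm.labels)):
        train = fm.subset_rows(tr)
        names = _fold_features(train, selection, (seed + fold) % (2**31))
        model = classify.train(train.select(names), spec)
        pred = model.predict(fm.subset_rows(te).select(names).values)
        true_all.append(fm.labels[te])
        pred_all.append(pred)
    cm = confusion_matrix(np.concatenate(true_all), np.concatenate(pred_all))
    return EvalReport(spec.name, f"{k}-fold CV", seed, cm)
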