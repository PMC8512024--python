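"""Correlation-based feature-subset selection (CFS) searched by binary PSO.

CFS scores a candidate subset of k features by Hall's merit

    merit = k * rbar_cf / sqrt(k + k*(k-1) * rbar_ff)

where rbar_cf is the mean feature-class correlation over the subset and
rbar_ff the mean pairwise feature-feature correlation: class-informative
but mutually redundant subsets are penalized.  Correlation is measured by
symmetrical uncertainty SU(A, B) = 2*I(A;B) / (H(A)+H(B)) on equal-width
discretized features (10 bins by default); a Pearson-based variant is
available behind a flag.

The search over subsets is a binary particle swarm: real-valued
velocities, sigmoid transfer to bit-flip probabilities, global-best
bookkeeping with the merit as fitness.  An exhaustive enumerator over all
non-empty subsets (feasible up to 20 features) serves as the exact
reference optimum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .features import FeatureMatrix


# ---------------------------------------------------------------------------
# Symmetrical uncertainty
# ---------------------------------------------------------------------------

def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-np.sum(p * np.log(p)))


def symmetrical_uncertainty(a: np.ndarray, b: np.ndarray) -> float:
    """SU = 2*I(A;B)/(H(A)+H(B)) in [0, 1]; 0 if either variable is constant."""
    a = np.asarray(a)
    b = np.asarray(b)
    if len(a) != len(b):
        raise ValueError("samples must have equal length")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    joint = np.zeros((ai.max() + 1, bi.max() + 1))
    np.add.at(joint, (ai, bi), 1.0)
    ha = _entropy(joint.sum(axis=1))
    hb = _entropy(joint.sum(axis=0))
    if ha == 0 or hb == 0:
        return 0.0
    hab = _entropy(joint.ravel())
    mi = ha + hb - hab
    su = 2.0 * mi / (ha + hb)
    return float(min(max(su, 0.0), 1.0))


def _su_from_codes(a: np.ndarray, b: np.ndarray, ka: int, kb: int,
                   ha: float, hb: float) -> float:
    """SU for pre-binned integer codes with precomputed marginal entropies."""
    if ha == 0 or hb == 0:
        return 0.0
    joint = np.bincount(a * kb + b, minlength=ka * kb)
    mi = ha + hb - _entropy(joint)
    return float(min(max(2.0 * mi / (ha + hb), 0.0), 1.0))


def discretize(x: np.ndarray, bins: int = 10) -> np.ndarray:
    """Equal-width binning over the observed range; constant -> one bin."""
    x = np.asarray(x, dtype=float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros(len(x), dtype=int)
    edges = np.linspace(lo, hi, bins + 1)
    return np.clip(np.digitize(x, edges[1:-1]), 0, bins - 1)


@dataclass
class CorrelationTable:
    """Feature-class and pairwise feature-feature correlations (unit scale)."""

    feature_class_corr: np.ndarray        # (p,)
    feature_feature_corr: np.ndarray      # (p, p), symmetric, unit diagonal
    feature_names: list[str] | None = None

    def __post_init__(self) -> None:
        ff = self.feature_feature_corr
        if ff.shape[0] != ff.shape[1] or ff.shape[0] != len(self.feature_class_corr):
            raise ValueError("correlation table dimensions disagree")
        if not np.allclose(ff, ff.T):
            raise ValueError("feature-feature correlations must be symmetric")

    @property
    def n_features(self) -> int:
        return len(self.feature_class_corr)


def build_correlation_table(
    fm: FeatureMatrix, bins: int = 10, measure: str = "su"
) -> CorrelationTable:
    """Discretize features and fill SU (or |Pearson|) correlations.

    Constant features carry no information: their correlations are set
    to 0 (off-diagonal).
    """
    if fm.n_rows == 0:
        raise ValueError("empty feature matrix")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    p = len(fm.feature_names)
    y = fm.labels
    if measure == "su":
        codes = [discretize(fm.values[:, j], bins) for j in range(p)]
        _, ycodes = np.unique(y, return_inverse=True)
        ncls = int(ycodes.max()) + 1
        ents = [_entropy(np.bincount(c, minlength=bins)) for c in codes]
        hy = _entropy(np.bincount(ycodes, minlength=ncls))
        rcf = np.array(
            [_su_from_codes(c, ycodes, bins, ncls, ents[j], hy)
             for j, c in enumerate(codes)]
        )
        rff = np.eye(p)
        for i in range(p):
            for j in range(i + 1, p):
                rff[i, j] = rff[j, i] = _su_from_codes(
                    codes[i], codes[j], bins, bins, ents[i], ents[j]
                )
    elif measure == "pearson":
        _, yi = np.unique(y, return_inverse=True)
        X = fm.values
        sd = X.std(axis=0)
        ok = sd > 0
        Z = np.where(ok, (X - X.mean(axis=0)) / np.where(ok, sd, 1.0), 0.0)
        yz = (yi - yi.mean()) / (yi.std() if yi.std() > 0 else 1.0)
        rcf = np.abs(Z.T @ yz / len(yi))
        rff = np.abs(Z.T @ Z / len(yi))
        np.fill_diagonal(rff, 1.0)
    else:
        raise ValueError(f"unknown measure {measure!r}")
    const = fm.values.std(axis=0) == 0
    rcf[const] = 0.0
    rff[const, :] = 0.0
    rff[:, const] = 0.0
    np.fill_diagonal(rff, 1.0)
    return CorrelationTable(rcf, (rff + rff.T) / 2.0, list(fm.feature_names))


# ---------------------------------------------------------------------------
# CFS merit
# ---------------------------------------------------------------------------

def merit(mask: np.ndarray, table: CorrelationTable) -> float:
    """Hall's CFS merit of the masked subset; k = 1 reduces to r_cf."""
    mask = np.asarray(mask, dtype=bool)
    k = int(mask.sum())
    if k == 0:
        raise ValueError("empty subset has no merit")
    rcf = float(table.feature_class_corr[mask].mean())
    if k == 1:
        return rcf
    sub = table.feature_feature_corr[np.ix_(mask, mask)]
    rff = float((sub.sum() - np.trace(sub)) / (k * (k - 1)))
    return k * rcf / np.sqrt(k + k * (k - 1) * rff)


@dataclass
class FeatureSubset:
    """A selected subset: boolean mask, its merit, and the selected names."""

    mask: np.ndarray
    merit: float
    names: list[str] | None = None
    trace: list[float] = field(default_factory=list)   # best merit per iteration

    @property
    def size(self) -> int:
        return int(np.asarray(self.mask, dtype=bool).sum())

    def to_json(self, params: "PsoParams | None" = None) -> str:
        doc = {
            "mask": [bool(b) for b in self.mask],
            "names": self.names,
            "merit": self.merit,
            "trace": self.trace,
        }
        if params is not None:
            doc["params"] = {
                "swarm_size": params.swarm_size,
                "iterations": params.iterations,
                "inertia": params.inertia,
                "cognitive": params.cognitive,
                "social": params.social,
                "v_max": params.v_max,
                "seed": params.seed,
            }
        return json.dumps(doc, indent=2)


def brute_force_best_subset(table: CorrelationTable) -> FeatureSubset:
    """Exact argmax of the merit over all non-empty subsets (p <= 20).

    Ties break toward smaller subsets, then lexicographic mask order
    (mask read as a tuple of bools, feature 0 first).
    """
    p = table.n_features
    if p > 20:
        raise ValueError("exhaustive search guarded at 20 features")
    best: tuple[float, int, tuple[bool, ...]] | None = None
    best_mask = None
    for code in range(1, 2**p):
        mask = np.array([(code >> j) & 1 for j in range(p)], dtype=bool)
        m = merit(mask, table)
        key = (-m, int(mask.sum()), tuple(~mask))  # ~mask: True-first lexicographic
        if best is None or key < best:
            best = key
            best_mask = mask
    names = (
        [n for n, b in zip(table.feature_names, best_mask) if b]
        if table.feature_names
        else None
    )
    return FeatureSubset(best_mask, -best[0], names)


# ---------------------------------------------------------------------------
# Binary particle swarm search
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PsoParams:
    """Swarm settings: constriction-style defaults, sigmoid transfer."""

    swarm_size: int = 20
    iterations: int = 100
    inertia: float = 0.72
    cognitive: float = 1.49
    social: float = 1.49
    v_max: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.swarm_size < 2 or self.iterations < 1:
            raise ValueError("swarm_size >= 2 and iterations >= 1 required")
        if min(self.inertia, self.cognitive, self.social) <= 0:
            raise ValueError("inertia/cognitive/social must be positive")


def _sigmoid(v: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-v))


def pso_search(table: CorrelationTable, params: PsoParams | None = None) -> FeatureSubset:
    """Binary PSO over feature masks with CFS merit as fitness.

    Velocities update as v <- w*v + c1*r1*(pbest - x) + c2*r2*(gbest - x),
    clamped to +/-v_max; each bit is then set with probability sigmoid(v).
    The best single feature is seeded into the initial swarm, so the
    returned merit is never below the best single-feature merit.  Fixed
    seed gives a fixed result.
    """
    params = PsoParams() if params is None else params
    p = table.n_features
    if p == 0:
        raise ValueError("no features to select from")
    rng = np.random.default_rng(params.seed)

    x = rng.random((params.swarm_size, p)) < 0.5
    x[0] = False
    x[0, int(np.argmax(table.feature_class_corr))] = True   # seed: best singleton
    empty = ~x.any(axis=1)
    x[empty, rng.integers(0, p, size=int(empty.sum()))] = True
    v = rng.uniform(-1.0, 1.0, size=(params.swarm_size, p))

    def fitness(rows: np.ndarray) -> np.ndarray:
        return np.array(
            [merit(row, table) if row.any() else -np.inf for row in rows]
        )

    pbest = x.copy()
    pbest_fit = fitness(x)
    g = int(np.argmax(pbest_fit))
    gbest = pbest[g].copy()
    gbest_fit = float(pbest_fit[g])
    trace = [gbest_fit]

    for _ in range(params.iterations):
        r1 = rng.random((params.swarm_size, p))
        r2 = rng.random((params.swarm_size, p))
        v = (
            params.inertia * v
            + params.cognitive * r1 * (pbest.astype(float) - x.astype(float))
            + params.social * r2 * (gbest.astype(float) - x.astype(float))
        )
        np.clip(v, -params.v_max, params.v_max, out=v)
        x = rng.random((params.swarm_size, p)) < _sigmoid(v)
        fit = fitness(x)
        improved = fit > pbest_fit
        pbest[improved] = x[improved]
        pbest_fit[improved] = fit[improved]
        g = int(np.argmax(pbest_fit))
        if pbest_fit[g] > gbest_fit:
            gbest_fit = float(pbest_fit[g])
            gbest = pbest[g].copy()
        trace.append(gbest_fit)

    names = (
        [n for n, b in zip(table.feature_names, gbest) if b]
        if table.feature_names
        else None
    )
    return FeatureSubset(gbest, gbest_fit, names, trace)
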