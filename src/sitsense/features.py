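"""Morphological and entropy feature bank for windowed IMU signals.

Nine window statistics — mean absolute value (MAV), harmonic mean (HM),
variance (Var), standard deviation (SD), skewness, root mean square
(RMS), simple squared integral (SSI), wavelet entropy (WE) and log
energy entropy (LEE) — computed on each of the nine raw channels, plus
one mean-magnitude feature per sensor ("Total-acceleration" etc.), give
the default 84-feature bank.

Conventions (documented here because several textbook variants exist):

* Variance and SD use the population divisor N.
* Skewness is the standardized third moment (1/N) * sum(((x-mu)/sigma)^3);
  a constant window (sigma = 0) yields 0.  ``skewness_as_printed`` keeps a
  legacy variant that divides the third central moment by sigma instead of
  sigma^3.
* WE is the Shannon entropy (natural log) of the window's relative energy
  distribution p_i = x_i^2 / sum_j x_j^2 — signal "disorder" in [0, ln N].
  No wavelet decomposition is applied by default; ``wavelet_entropy_multilevel``
  offers a dyadic-band variant.
* LEE is sum_i log2(x_i^2 + eps) with eps = 1e-12 guarding zeros.
* HM is computed on absolute values (raw channels are signed and
  zero-crossing) with the same eps guard.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import MAGNITUDE_CHANNELS, RAW_CHANNELS, Window, stack_windows

EPS = 1e-12

#: Statistic order within each channel block of the registry.
STAT_NAMES = ("MAV", "HM", "Var", "SD", "skewness", "RMS", "SSI", "WE", "LEE")


class NonFiniteFeatureError(ValueError):
    """A statistic produced NaN/Inf for some window."""


# ---------------------------------------------------------------------------
# Scalar statistics (1-D convenience wrappers over the vectorized kernels)
# ---------------------------------------------------------------------------

def magnitude(x: float, y: float, z: float) -> float:
    """Euclidean magnitude sqrt(x^2 + y^2 + z^2)."""
    return float(np.sqrt(x * x + y * y + z * z))


def _as2d(x) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.size == 0:
        raise ValueError("empty window")
    return np.atleast_2d(a)


def _maybe_scalar(v: np.ndarray, x) -> float | np.ndarray:
    return float(v[0]) if np.asarray(x).ndim == 1 else v


def mav(x):
    """Mean absolute value."""
    a = _as2d(x)
    return _maybe_scalar(np.mean(np.abs(a), axis=1), x)


def variance(x):
    """Population variance (divisor N)."""
    a = _as2d(x)
    return _maybe_scalar(np.var(a, axis=1), x)


def std_dev(x):
    """Population standard deviation."""
    a = _as2d(x)
    return _maybe_scalar(np.std(a, axis=1), x)


def skewness(x, as_printed: bool = False):
    """Standardized third moment; 0 for constant windows.

    ``as_printed=True`` divides the third central moment by sigma rather
    than sigma^3 (a dimensionally odd legacy form, kept for comparison).
    """
    a = _as2d(x)
    mu = np.mean(a, axis=1, keepdims=True)
    sd = np.std(a, axis=1)
    m3 = np.mean((a - mu) ** 3, axis=1)
    denom = sd if as_printed else sd**3
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(sd > 0, m3 / np.where(denom > 0, denom, 1.0), 0.0)
    return _maybe_scalar(out, x)


def rms(x):
    """Root mean square."""
    a = _as2d(x)
    return _maybe_scalar(np.sqrt(np.mean(a * a, axis=1)), x)


def ssi(x):
    """Simple squared integral (signal energy): sum of squares."""
    a = _as2d(x)
    return _maybe_scalar(np.sum(a * a, axis=1), x)


def wavelet_entropy(x):
    """Shannon entropy (nats) of the relative energy distribution."""
    a = _as2d(x)
    e = a * a
    tot = np.sum(e, axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(tot > 0, e / np.where(tot > 0, tot, 1.0), 0.0)
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    return _maybe_scalar(-np.sum(plogp, axis=1), x)


def wavelet_entropy_multilevel(x, levels: int = 3):
    """Variant: entropy over relative energies of dyadic wavelet bands.

    Off by default in the registry; provided for exploration.
    """
    import pywt  # local import: optional analysis path

    a = np.asarray(x, dtype=float)
    coeffs = pywt.wavedec(a, "db1", level=levels, axis=-1)
    energies = np.stack([np.sum(c * c, axis=-1) for c in coeffs], axis=-1)
    tot = np.sum(energies, axis=-1, keepdims=True)
    p = np.where(tot > 0, energies / np.where(tot > 0, tot, 1.0), 0.0)
    plogp = np.where(p > 0, p * np.log(p), 0.0)
    out = -np.sum(plogp, axis=-1)
    return float(out) if a.ndim == 1 else out


def log_energy_entropy(x):
    """Sum over samples of log2(x_i^2 + eps)."""
    a = _as2d(x)
    return _maybe_scalar(np.sum(np.log2(a * a + EPS), axis=1), x)


def harmonic_mean(x):
    """Harmonic mean of |x| with an eps guard: N / sum(1/(|x_i| + eps))."""
    a = _as2d(x)
    return _maybe_scalar(a.shape[1] / np.sum(1.0 / (np.abs(a) + EPS), axis=1), x)


_STAT_FUNCS = {
    "MAV": mav,
    "HM": harmonic_mean,
    "Var": variance,
    "SD": std_dev,
    "skewness": skewness,
    "RMS": rms,
    "SSI": ssi,
    "WE": wavelet_entropy,
    "LEE": log_energy_entropy,
}


# ---------------------------------------------------------------------------
# Registry and matrix extraction
# ---------------------------------------------------------------------------

def default_registry() -> list[str]:
    """The 84-feature bank: 9 statistics x 9 raw channels + 3 magnitudes."""
    names = [f"{ch}-{stat}" for ch in RAW_CHANNELS for stat in STAT_NAMES]
    names.extend(MAGNITUDE_CHANNELS)
    return names


def compute_feature(name: str, channels: dict[str, np.ndarray],
                    skewness_as_printed: bool = False) -> np.ndarray:
    """Evaluate one registry feature on stacked (n_windows, N) channels."""
    if name in MAGNITUDE_CHANNELS:
        return np.mean(channels[name], axis=1)
    channel, stat = name.rsplit("-", 1)
    if stat not in _STAT_FUNCS:
        raise KeyError(f"unknown statistic in feature name: {name}")
    if stat == "skewness":
        return skewness(channels[channel], as_printed=skewness_as_printed)
    return _STAT_FUNCS[stat](channels[channel])


@dataclass
class FeatureMatrix:
    """Rows = windows, named feature columns, one label per row."""

    values: np.ndarray          # (n_windows, n_features)
    feature_names: list[str]
    labels: np.ndarray          # (n_windows,)
    subjects: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.labels), len(self.feature_names)):
            raise ValueError("values shape must match labels x feature_names")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    def select(self, names: list[str]) -> "FeatureMatrix":
        idx = [self.feature_names.index(n) for n in names]
        return FeatureMatrix(
            self.values[:, idx], list(names), self.labels, self.subjects
        )

    def subset_rows(self, rows: np.ndarray) -> "FeatureMatrix":
        subj = None if self.subjects is None else self.subjects[rows]
        return FeatureMatrix(
            self.values[rows], list(self.feature_names), self.labels[rows], subj
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "label", self.labels)
        df.insert(0, "window_id", np.arange(self.n_rows))
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        names = [c for c in df.columns if c not in ("window_id", "label")]
        return cls(df[names].to_numpy(float), names, df["label"].to_numpy(str))


def extract_features(
    windows: list[Window],
    registry: list[str] | None = None,
    skewness_as_printed: bool = False,
) -> FeatureMatrix:
    """Compute the registry on every window; aborts on any non-finite value,
    naming the offending feature and window."""
    registry = default_registry() if registry is None else list(registry)
    channels, labels = stack_windows(windows)
    cols = []
    for name in registry:
        col = compute_feature(name, channels, skewness_as_printed)
        if not np.all(np.isfinite(col)):
            bad = int(np.flatnonzero(~np.isfinite(col))[0])
            raise NonFiniteFeatureError(
                f"feature {name!r} is non-finite at window {bad}"
            )
        cols.append(col)
    subjects = np.array([w.subject_id for w in windows])
    return FeatureMatrix(np.column_stack(cols), registry, labels, subjects)
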