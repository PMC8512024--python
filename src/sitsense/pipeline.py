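"""End-to-end orchestration: simulate -> preprocess -> extract -> select ->
train -> evaluate, as a configured, seeded, logged run.

A run writes its artifacts (raw sensor CSVs, feature matrix CSV, selection
report JSON, evaluation reports JSON/text/CSV) plus a manifest echoing the
configuration, stage timings and library versions into an output directory.
Re-running with the same configuration reproduces every non-timing artifact
byte-identically.

All randomness flows from one root seed: stage s of subject/fold i uses a
child seed derived deterministically from (root_seed, stage, i).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import classify, evaluate, features, preprocess, reference, selection, synthetic

logger = logging.getLogger("sitsense")

SENSOR_ALIASES = {"acc": "accelerometer", "gyr": "gyroscope", "mag": "magnetometer"}


def child_seed(root: int, stage: str, index: int = 0) -> int:
    """Deterministic per-stage seed below 2^31."""
    h = hashlib.sha256(f"{root}:{stage}:{index}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """Declarative settings for one full run."""

    seed: int = 0
    out_dir: str = "runs/default"
    sensors: tuple[str, ...] = ("accelerometer", "gyroscope", "magnetometer")
    # simulation
    sample_rate_hz: float = 50.0
    subject_count: int = 6
    durations_s: dict = field(
        default_factory=lambda: dict(synthetic.STUDY_DURATIONS_S)
    )
    # windowing / preprocessing
    omega_t: float = 1.0
    stride: int = 25
    cutoff_hz: float = 5.0
    # selection: "pso", "preset" (the published 27 features) or "none"
    selection_mode: str = "preset"
    su_bins: int = 10
    measure: str = "su"
    pso: selection.PsoParams = selection.PsoParams()
    # classifiers
    knn_ks: tuple[int, ...] = (3, 5, 7, 11)
    knn_metric: str = "hamming"
    svm_c: float = 1.0
    svm_kernel_scale: float | None = None
    # evaluation: "kfold" or "holdout"
    eval_mode: str = "kfold"
    k_folds: int = 10
    train_fraction: float = 0.75

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if "pso" in doc:
            doc["pso"] = selection.PsoParams(**doc["pso"])
        for key in ("sensors", "knn_ks"):
            if key in doc:
                doc[key] = tuple(doc[key])
        if "sensors" in doc:
            doc["sensors"] = tuple(SENSOR_ALIASES.get(s, s) for s in doc["sensors"])
        return cls(**doc)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pso"] = asdict(self.pso)
        return d

    def roster(self) -> list[classify.ClassifierSpec]:
        specs = [classify.ClassifierSpec("nb")]
        specs += [
            classify.ClassifierSpec("knn", k=k, metric=self.knn_metric)
            for k in self.knn_ks
        ]
        specs.append(
            classify.ClassifierSpec(
                "svm", C=self.svm_c, kernel_scale=self.svm_kernel_scale
            )
        )
        return specs


def ablate_sensors(
    fm: features.FeatureMatrix, sensors: tuple[str, ...]
) -> features.FeatureMatrix:
    """Keep only features from the chosen sensors (magnitude features
    follow their sensor: Total-acceleration belongs to the accelerometer)."""
    sensors = tuple(SENSOR_ALIASES.get(s, s) for s in sensors)
    if not sensors:
        raise ValueError("at least one sensor required")
    bad = set(sensors) - set(synthetic.SENSORS)
    if bad:
        raise ValueError(f"unknown sensors: {sorted(bad)}")
    total_of = {
        "accelerometer": "Total-acceleration",
        "gyroscope": "Total-gyroscope",
        "magnetometer": "Total-magnetometer",
    }
    keep = [
        n
        for n in fm.feature_names
        if any(n.startswith(f"{ax}-{s}") for s in sensors for ax in synthetic.AXES)
        or n in {total_of[s] for s in sensors}
    ]
    if not keep:
        raise ValueError("sensor ablation left no features")
    return fm.select(keep)


def build_feature_matrix(config: PipelineConfig) -> features.FeatureMatrix:
    """Simulate the configured dataset and extract the full feature bank."""
    sim = synthetic.SimulationConfig(
        sample_rate_hz=config.sample_rate_hz,
        durations_s=dict(config.durations_s),
        subject_count=config.subject_count,
        seed=child_seed(config.seed, "simulate"),
    )
    recs = synthetic.generate_dataset(sim)
    spec = preprocess.WindowSpec(config.omega_t, config.sample_rate_hz, config.stride)
    windows: list[preprocess.Window] = []
    for rec in recs:
        windows.extend(preprocess.make_windows(rec, spec, config.cutoff_hz))
    return features.extract_features(windows)


def _selection_settings(config: PipelineConfig) -> evaluate.SelectionSettings:
    if config.selection_mode == "preset":
        return evaluate.SelectionSettings(
            mode="preset", preset=tuple(reference.SELECTED_FEATURES_27)
        )
    if config.selection_mode == "pso":
        return evaluate.SelectionSettings(
            mode="pso", bins=config.su_bins, measure=config.measure, pso=config.pso
        )
    return evaluate.SelectionSettings(mode="none")


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage, writing artifacts and a manifest; returns the
    run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    def stage(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s started", name)

            def __exit__(self, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self.t0, 3)
                if exc_type is not None:
                    logger.error("stage %s failed: %s", name, exc)

        return _T()

    try:
        with stage("simulate"):
            sim = synthetic.SimulationConfig(
                sample_rate_hz=config.sample_rate_hz,
                durations_s=dict(config.durations_s),
                subject_count=config.subject_count,
                seed=child_seed(config.seed, "simulate"),
            )
            recs = synthetic.generate_dataset(sim)
            for rec in recs:
                synthetic.write_csv(rec, out / f"raw_subject{rec.subject_id}.csv")
    except Exception as e:
        raise RuntimeError(f"stage simulate failed ({out})") from e

    try:
        with stage("extract"):
            spec = preprocess.WindowSpec(
                config.omega_t, config.sample_rate_hz, config.stride
            )
            windows: list[preprocess.Window] = []
            for rec in recs:
                windows.extend(preprocess.make_windows(rec, spec, config.cutoff_hz))
            fm = features.extract_features(windows)
            fm = ablate_sensors(fm, config.sensors)
            fm.to_csv(out / "features.csv")
    except Exception as e:
        raise RuntimeError(f"stage extract failed ({out / 'features.csv'})") from e

    try:
        with stage("select"):
            settings = _selection_settings(config)
            if settings.mode == "pso":
                table = selection.build_correlation_table(
                    fm, config.su_bins, config.measure
                )
                params = selection.PsoParams(
                    **{
                        **asdict(config.pso),
                        "seed": child_seed(config.seed, "select"),
                    }
                )
                subset = selection.pso_search(table, params)
                (out / "selection.json").write_text(subset.to_json(params))
            else:
                names = (
                    list(settings.preset)
                    if settings.mode == "preset"
                    else list(fm.feature_names)
                )
                names = [n for n in names if n in fm.feature_names]
                (out / "selection.json").write_text(
                    json.dumps({"mode": settings.mode, "names": names}, indent=2)
                )
    except Exception as e:
        raise RuntimeError(f"stage select failed ({out / 'selection.json'})") from e

    reports = []
    try:
        with stage("evaluate"):
            settings = _selection_settings(config)
            if settings.mode == "preset":
                # keep only preset features present after sensor ablation
                settings = evaluate.SelectionSettings(
                    mode="preset",
                    preset=tuple(
                        n for n in settings.preset if n in fm.feature_names
                    ),
                )
            for spec_ in config.roster():
                seed = child_seed(config.seed, "evaluate")
                if config.eval_mode == "kfold":
                    rep = evaluate.kfold_cv(
                        fm, config.k_folds, spec_, seed, settings
                    )
                else:
                    rep = evaluate.holdout_eval(
                        fm, spec_, config.train_fraction, seed, settings
                    )
                reports.append(rep)
                (out / f"report_{spec_.name}.json").write_text(rep.to_json())
                (out / f"report_{spec_.name}.txt").write_text(rep.to_text() + "\n")
                rep.cm.to_csv(out / f"confusion_{spec_.name}.csv")
    except Exception as e:
        raise RuntimeError(f"stage evaluate failed ({out})") from e

    manifest = {
        "config": config.to_dict(),
        "seeds": {
            "root": config.seed,
            "simulate": child_seed(config.seed, "simulate"),
            "select": child_seed(config.seed, "select"),
            "evaluate": child_seed(config.seed, "evaluate"),
        },
        "decisions": {
            "window_s": config.omega_t,
            "window_samples": spec.n_samples,
            "stride": config.stride,
            "denoise": f"zero-phase 4th-order Butterworth low-pass {config.cutoff_hz} Hz",
            "normalization": "per-channel per-recording max-abs to [-1, 1]",
            "correlation_measure": config.measure,
            "selection_mode": config.selection_mode,
            "knn_metric": config.knn_metric,
            "svm": {"C": config.svm_c, "kernel_scale": config.svm_kernel_scale},
        },
        "versions": _versions(),
        "n_windows": fm.n_rows,
        "n_features": len(fm.feature_names),
        "overall_accuracy": {r.classifier: r.overall for r in reports},
        "stage_timings_s": timings,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out


def _versions() -> dict[str, str]:
    import sklearn
    import scipy
    import pandas

    return {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "scikit-learn": sklearn.__version__,
    }
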