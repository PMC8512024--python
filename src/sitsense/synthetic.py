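"""Synthetic seated-posture IMU recordings.

Generates labelled 9-channel (accelerometer, gyroscope, magnetometer)
streams for five static sitting postures sensed at the upper rear trunk
(T2 mounting point).  Each posture is a fixed trunk orientation; the
device senses the gravity vector and the local geomagnetic field rotated
into the device frame, perturbed by sensor tremor noise and a slow
orientation wander.

Frame convention (documented once, used everywhere): the device frame has
x = subject's right, y = up along the spine, z = out of the subject's
back.  In the neutral ("straight") posture the device y axis is vertical,
so the accelerometer reads (0, g, 0).  Posture orientation is intrinsic
pitch-then-roll: pitch is a rotation about the device x axis (+ = forward
trunk flexion), roll a rotation about the device z axis (+ = lean to the
subject's right).  Sensed vectors are the world vectors expressed in the
rotated device frame.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter

logger = logging.getLogger("sitsense")

# ---------------------------------------------------------------------------
# Activity label set
# ---------------------------------------------------------------------------

#: Fixed activity order used by every downstream stage (confusion matrices,
#: reports, schedules).
ACTIVITIES = ("A1", "A2", "A3", "A4", "A5")

ACTIVITY_NAMES = {
    "A1": "Left movement",
    "A2": "Right movement",
    "A3": "Front movement",
    "A4": "Back movement",
    "A5": "Straight movement",
}

SENSORS = ("accelerometer", "gyroscope", "magnetometer")
AXES = ("X", "Y", "Z")

#: Per-activity collection durations in seconds for the whole 6-subject
#: study dataset (left, right, front, back, straight).
STUDY_DURATIONS_S = {"A1": 712.0, "A2": 756.0, "A3": 665.0, "A4": 590.0, "A5": 549.0}


class UnknownActivityError(KeyError):
    """Raised when an activity id is not one of A1..A5."""


# ---------------------------------------------------------------------------
# Posture and simulation configuration
# ---------------------------------------------------------------------------

#: Default trunk lean angles (degrees).  Left/right are mirrored rolls,
#: front/back are opposite-sign pitches, straight is the zero reference.
DEFAULT_ANGLES = {
    "A1": (0.0, -20.0),   # left lean: negative roll
    "A2": (0.0, +20.0),   # right lean
    "A3": (+20.0, 0.0),   # forward flexion
    "A4": (-15.0, 0.0),   # backward lean
    "A5": (0.0, 0.0),     # straight
}


@dataclass(frozen=True)
class PostureModel:
    """Static trunk orientation plus noise levels for one activity."""

    activity_id: str
    pitch: float                     # degrees, + = forward lean
    roll: float                      # degrees, + = right lean
    tremor_sd_accel: float = 0.05    # m/s^2
    tremor_sd_gyro: float = 0.01     # rad/s
    mag_noise_sd: float = 0.5        # microtesla

    def __post_init__(self) -> None:
        if self.activity_id not in ACTIVITIES:
            raise UnknownActivityError(self.activity_id)
        if min(self.tremor_sd_accel, self.tremor_sd_gyro, self.mag_noise_sd) <= 0:
            raise ValueError("noise SDs must be positive")


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings; the defaults are the study conditions."""

    sample_rate_hz: float = 50.0
    durations_s: dict[str, float] = field(
        default_factory=lambda: dict(STUDY_DURATIONS_S)
    )
    subject_count: int = 6
    seed: int = 0
    gravity: float = 9.81                          # m/s^2
    earth_field: tuple[float, float, float] = (20.0, -44.0, 5.0)  # uT, device frame at neutral
    # Slow orientation wander: AR(1) on (pitch, roll, yaw) jitter angles.
    drift_amplitude_deg: float = 1.0               # stationary SD of the wander
    drift_tau_s: float = 10.0                      # AR(1) time constant
    subject_angle_sd_deg: float = 2.0              # per-subject posture offset SD
    # Fixed device-to-trunk mounting offset (intrinsic yaw-pitch-roll, deg).
    # A strapped phone never sits perfectly axis-aligned; a generic tilt
    # keeps every channel sensitive to posture changes instead of leaving
    # whole axes identically uninformative.
    mount_ypr_deg: tuple[float, float, float] = (10.0, 7.0, 4.0)

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.subject_count < 1:
            raise ValueError("subject_count must be >= 1")
        for act, dur in self.durations_s.items():
            if act not in ACTIVITIES:
                raise UnknownActivityError(act)
            if dur < 1.0:
                raise ValueError(f"duration for {act} must be >= 1 s")


def posture_orientation(activity: str) -> tuple[float, float]:
    """Default (pitch, roll) in degrees for an activity id."""
    if activity not in DEFAULT_ANGLES:
        raise UnknownActivityError(activity)
    return DEFAULT_ANGLES[activity]


def default_postures(
    tremor_sd_accel: float = 0.05,
    tremor_sd_gyro: float = 0.01,
    mag_noise_sd: float = 0.5,
) -> list[PostureModel]:
    """One PostureModel per activity with the default lean angles."""
    return [
        PostureModel(
            a,
            pitch=DEFAULT_ANGLES[a][0],
            roll=DEFAULT_ANGLES[a][1],
            tremor_sd_accel=tremor_sd_accel,
            tremor_sd_gyro=tremor_sd_gyro,
            mag_noise_sd=mag_noise_sd,
        )
        for a in ACTIVITIES
    ]


@dataclass
class ImuRecording:
    """Timestamped 9-channel sensor stream with per-sample activity labels."""

    time_s: np.ndarray
    accel_xyz: np.ndarray   # (n, 3) m/s^2
    gyro_xyz: np.ndarray    # (n, 3) rad/s
    mag_xyz: np.ndarray     # (n, 3) uT
    label: np.ndarray       # (n,) activity ids
    subject_id: int
    sample_rate_hz: float

    def __post_init__(self) -> None:
        n = len(self.time_s)
        for arr, cols in ((self.accel_xyz, 3), (self.gyro_xyz, 3), (self.mag_xyz, 3)):
            if arr.shape != (n, cols):
                raise ValueError("channel arrays must share the sample count")
        if len(self.label) != n:
            raise ValueError("label array must share the sample count")
        bad = set(np.unique(self.label)) - set(ACTIVITIES)
        if bad:
            raise UnknownActivityError(sorted(bad)[0])

    def __len__(self) -> int:
        return len(self.time_s)

    def channels(self) -> dict[str, np.ndarray]:
        """Named raw channels, e.g. 'X-accelerometer'."""
        out: dict[str, np.ndarray] = {}
        for sensor, arr in zip(SENSORS, (self.accel_xyz, self.gyro_xyz, self.mag_xyz)):
            for j, axis in enumerate(AXES):
                out[f"{axis}-{sensor}"] = arr[:, j]
        return out


# ---------------------------------------------------------------------------
# Rotation helpers
# ---------------------------------------------------------------------------

def rotate_to_device(vec: np.ndarray, pitch_deg, roll_deg) -> np.ndarray:
    """Express a neutral-frame vector in the pitched-then-rolled device frame.

    Accepts scalar or array angles (broadcast); returns shape (..., 3).
    Closed form for the neutral-frame vector v under intrinsic pitch
    (about x) then roll (about z):  v_dev = Rz(-roll) @ Rx(-pitch) @ v.
    """
    p = np.deg2rad(np.asarray(pitch_deg, dtype=float))
    r = np.deg2rad(np.asarray(roll_deg, dtype=float))
    cp, sp = np.cos(p), np.sin(p)
    cr, sr = np.cos(r), np.sin(r)
    vx, vy, vz = vec
    # Rx(-pitch): y' = cp*y + sp*z ; z' = -sp*y + cp*z
    y1 = cp * vy + sp * vz
    z1 = -sp * vy + cp * vz
    # Rz(-roll): x'' = cr*x + sr*y' ; y'' = -sr*x + cr*y'
    x2 = cr * vx + sr * y1
    y2 = -sr * vx + cr * y1
    return np.stack(np.broadcast_arrays(x2, y2, z1), axis=-1)


def mount_matrix(ypr_deg: tuple[float, float, float]) -> np.ndarray:
    """Device-to-trunk rotation for the fixed mounting offset, intrinsic
    yaw (about y) then pitch (about x) then roll (about z)."""
    yw, p, r = np.deg2rad(ypr_deg)
    cy, sy = np.cos(yw), np.sin(yw)
    cp, sp = np.cos(p), np.sin(p)
    cr, sr = np.cos(r), np.sin(r)
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rx = np.array([[1, 0, 0], [0, cp, -sp], [0, sp, cp]])
    Rz = np.array([[cr, -sr, 0], [sr, cr, 0], [0, 0, 1]])
    return Ry @ Rx @ Rz


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _ar1(rng: np.random.Generator, n: int, sd: float, tau_s: float, fs: float) -> np.ndarray:
    """Stationary AR(1) path with SD `sd` and time constant `tau_s`."""
    if sd <= 0 or n == 0:
        return np.zeros(n)
    rho = float(np.exp(-1.0 / (tau_s * fs)))
    innov_sd = sd * np.sqrt(1.0 - rho * rho)
    drive = np.empty(n)
    drive[0] = rng.normal(0.0, sd)          # stationary start
    drive[1:] = rng.normal(0.0, innov_sd, size=n - 1)
    return lfilter([1.0], [1.0, -rho], drive)


def generate_recording(
    config: SimulationConfig,
    postures: list[PostureModel] | None = None,
    subject_id: int = 0,
) -> ImuRecording:
    """Simulate one subject's full activity schedule.

    Per activity, emits ``round(duration * rate)`` samples: the accelerometer
    senses gravity rotated into the device frame by the posture's (pitch,
    roll) plus orientation wander, with additive tremor noise; the gyroscope
    is the time-derivative of the wander angles plus noise; the magnetometer
    is the rotated geomagnetic field plus noise.  Identical
    (config, postures, subject_id) give bitwise-identical output.
    """
    postures = default_postures() if postures is None else postures
    by_id = {p.activity_id: p for p in postures}
    missing = [a for a in config.durations_s if a not in by_id]
    if missing:
        raise UnknownActivityError(f"no PostureModel for {missing[0]}")

    fs = config.sample_rate_hz
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, subject_id]))
    # Per-subject heterogeneity: a fixed angle offset for this subject.
    pitch_off, roll_off = rng.normal(0.0, config.subject_angle_sd_deg, size=2)

    segs_accel, segs_gyro, segs_mag, segs_label = [], [], [], []
    gravity_vec = np.array([0.0, config.gravity, 0.0])
    field_vec = np.asarray(config.earth_field, dtype=float)
    # trunk-frame vector v -> device components: v_dev = M^T v == v @ M
    mount = mount_matrix(config.mount_ypr_deg)

    for activity in ACTIVITIES:
        if activity not in config.durations_s:
            continue
        p = by_id[activity]
        n = int(round(config.durations_s[activity] * fs))
        if n < 2:
            warnings.warn(f"segment {activity} has fewer than 2 samples")

        wander_pitch = _ar1(rng, n, config.drift_amplitude_deg, config.drift_tau_s, fs)
        wander_roll = _ar1(rng, n, config.drift_amplitude_deg, config.drift_tau_s, fs)
        wander_yaw = _ar1(rng, n, config.drift_amplitude_deg, config.drift_tau_s, fs)

        pitch = p.pitch + pitch_off + wander_pitch
        roll = p.roll + roll_off + wander_roll

        accel = rotate_to_device(gravity_vec, pitch, roll) @ mount
        accel += rng.normal(0.0, p.tremor_sd_accel, size=accel.shape)

        # Gyro: angular rate of the wander process (deg/s -> rad/s), one
        # wander angle per trunk axis mapped into the device frame, plus tremor.
        angles = np.stack([wander_pitch, wander_yaw, wander_roll], axis=-1)
        rate = np.gradient(np.deg2rad(angles), 1.0 / fs, axis=0) @ mount
        gyro = rate + rng.normal(0.0, p.tremor_sd_gyro, size=rate.shape)

        mag = rotate_to_device(field_vec, pitch, roll) @ mount
        mag += rng.normal(0.0, p.mag_noise_sd, size=mag.shape)

        segs_accel.append(accel)
        segs_gyro.append(gyro)
        segs_mag.append(mag)
        segs_label.append(np.full(n, activity))

    accel = np.concatenate(segs_accel)
    gyro = np.concatenate(segs_gyro)
    mag = np.concatenate(segs_mag)
    label = np.concatenate(segs_label)
    time_s = np.arange(len(label)) / fs
    return ImuRecording(time_s, accel, gyro, mag, label, subject_id, fs)


def generate_dataset(config: SimulationConfig) -> list[ImuRecording]:
    """One recording per subject, splitting the configured (dataset-total)
    durations evenly across subjects so the dataset matches the study scale."""
    per_subject = {
        a: d / config.subject_count for a, d in config.durations_s.items()
    }
    sub_cfg = replace(config, durations_s=per_subject, subject_count=1)
    return [
        generate_recording(sub_cfg, subject_id=s) for s in range(config.subject_count)
    ]


# ---------------------------------------------------------------------------
# Sensor-logger CSV dialect
# ---------------------------------------------------------------------------

CSV_HEADER = "time_s,ax,ay,az,gx,gy,gz,mx,my,mz,label,subject"


def write_csv(recording: ImuRecording, path) -> None:
    """Write a recording in the sensor-logger CSV dialect (one row/sample)."""
    df = pd.DataFrame(
        np.hstack(
            [
                recording.time_s[:, None],
                recording.accel_xyz,
                recording.gyro_xyz,
                recording.mag_xyz,
            ]
        ),
        columns=CSV_HEADER.split(",")[:10],
    )
    df["label"] = recording.label
    df["subject"] = recording.subject_id
    df.to_csv(path, index=False, float_format="%.9g")


def read_csv(path) -> ImuRecording:
    """Read a sensor-logger CSV back into an ImuRecording."""
    df = pd.read_csv(path)
    expected = CSV_HEADER.split(",")
    if list(df.columns) != expected:
        raise ValueError(f"unexpected CSV header: {list(df.columns)}")
    t = df["time_s"].to_numpy()
    if len(t) > 1:
        dt = np.diff(t)
        fs = 1.0 / np.median(dt)
        if np.any(dt <= 0):
            raise ValueError("time_s must be strictly increasing")
    else:
        fs = 50.0
    subjects = df["subject"].unique()
    if len(subjects) != 1:
        raise ValueError("one recording per file: multiple subject ids found")
    return ImuRecording(
        time_s=t,
        accel_xyz=df[["ax", "ay", "az"]].to_numpy(),
        gyro_xyz=df[["gx", "gy", "gz"]].to_numpy(),
        mag_xyz=df[["mx", "my", "mz"]].to_numpy(),
        label=df["label"].to_numpy(dtype=object).astype(str),
        subject_id=int(subjects[0]),
        sample_rate_hz=float(round(fs, 6)),
    )


def to_csv_string(recording: ImuRecording) -> str:
    buf = io.StringIO()
    write_csv(recording, buf)
    return buf.getvalue()
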