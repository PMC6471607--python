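"""Domain types and file I/O for chair-rise-test sessions.

A session couples a hip-worn IMU stream (100 Hz accelerometer + gyroscope,
axes vertical / mediolateral / anterior-posterior) with an optional
force-plate stream (200 Hz ground reaction force) and an optional
ground-truth activity label track.  All files are plain CSV with optional
``#``-prefixed metadata lines, so fixtures stay diff-able.

Conventions
-----------
* Time is in seconds, float, session-relative (origin 0).
* Label segments are half-open intervals ``[start, end)``.
* Axis order is always (V, ML, AP).
* The vertical accelerometer channel is gravity-inclusive: at rest on an
  upright sensor ``acc_v`` reads about +9.81 m/s^2.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    AlignmentError,
    FormatError,
    ValidationError,
)

#: Activity label vocabulary.  SIT/STAND are static postures, SIT_STAND and
#: STAND_SIT the two chair-rise transitions, DYNAMIC any sustained movement
#: (walking surrogate), OTHER everything else.
LABELS = ("SIT", "STAND", "SIT_STAND", "STAND_SIT", "DYNAMIC", "OTHER")

SIT, STAND, SIT_STAND, STAND_SIT, DYNAMIC, OTHER = LABELS

#: Labels that are rising/descending transitions.
TRANSITION_LABELS = (SIT_STAND, STAND_SIT)
#: Labels that are static postures.
STATIC_LABELS = (SIT, STAND)

GRAVITY = 9.81  # m/s^2

_IMU_COLUMNS = ("t", "acc_v", "acc_ml", "acc_ap", "gyr_v", "gyr_ml", "gyr_ap")
_FORCE_COLUMNS = ("t", "f_v", "f_ml", "f_ap")

_TIME_SPACING_TOL = 1e-6  # s, allowed deviation of sample spacing from 1/fs


def _check_time_axis(t: np.ndarray, sample_rate: float) -> None:
    if t.ndim != 1 or len(t) < 2:
        raise ValidationError("time axis must be 1-D with length >= 2")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValidationError("time axis must be strictly increasing")
    expected = 1.0 / sample_rate
    if np.any(np.abs(dt - expected) > _TIME_SPACING_TOL):
        raise ValidationError(
            f"sample spacing deviates from 1/{sample_rate} Hz by more than "
            f"{_TIME_SPACING_TOL} s"
        )


@dataclass(frozen=True)
class ImuRecording:
    """Uniformly sampled tri-axial acceleration / angular-velocity streams.

    Acceleration in m/s^2 (gravity-inclusive), angular velocity in deg/s,
    axes in the fixed order vertical (V), mediolateral (ML),
    anterior-posterior (AP).
    """

    t: np.ndarray
    acc_v: np.ndarray
    acc_ml: np.ndarray
    acc_ap: np.ndarray
    gyr_v: np.ndarray
    gyr_ml: np.ndarray
    gyr_ap: np.ndarray
    sample_rate: float = 100.0
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValidationError("sample_rate must be positive")
        arrays = [self.t] + [getattr(self, c) for c in self.channel_names()]
        for name, a in zip(("t",) + self.channel_names(), arrays):
            object.__setattr__(self, name, np.asarray(a, dtype=float))
        n = len(self.t)
        for c in self.channel_names():
            if len(getattr(self, c)) != n:
                raise ValidationError(f"channel {c!r} length differs from t")
        _check_time_axis(self.t, self.sample_rate)

    @staticmethod
    def channel_names() -> tuple[str, ...]:
        return _IMU_COLUMNS[1:]

    @property
    def acc(self) -> np.ndarray:
        """Acceleration as an (n, 3) array in (V, ML, AP) order."""
        return np.column_stack([self.acc_v, self.acc_ml, self.acc_ap])

    @property
    def gyr(self) -> np.ndarray:
        """Angular velocity as an (n, 3) array in (V, ML, AP) order."""
        return np.column_stack([self.gyr_v, self.gyr_ml, self.gyr_ap])

    def __len__(self) -> int:
        return len(self.t)

    def crop(self, t0: float, t1: float) -> "ImuRecording":
        """Return the sub-recording with ``t0 <= t <= t1``."""
        m = (self.t >= t0 - 1e-9) & (self.t <= t1 + 1e-9)
        if m.sum() < 2:
            raise AlignmentError("crop interval keeps fewer than 2 samples")
        kw = {c: getattr(self, c)[m] for c in self.channel_names()}
        return ImuRecording(t=self.t[m], sample_rate=self.sample_rate,
                            subject_id=self.subject_id, **kw)


@dataclass(frozen=True)
class ForcePlateRecording:
    """Tri-axial ground-reaction-force streams in newtons.

    ``body_weight`` is the subject's full weight on the plate while standing;
    ``resting_weight`` the partial weight transmitted through the feet while
    seated.  Both are optional and can be estimated from labelled intervals.
    """

    t: np.ndarray
    f_v: np.ndarray
    f_ml: np.ndarray
    f_ap: np.ndarray
    sample_rate: float = 200.0
    subject_id: str = ""
    body_weight: float | None = None
    resting_weight: float | None = None

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValidationError("sample_rate must be positive")
        for name in _FORCE_COLUMNS:
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.t)
        for c in self.channel_names():
            if len(getattr(self, c)) != n:
                raise ValidationError(f"channel {c!r} length differs from t")
        _check_time_axis(self.t, self.sample_rate)
        if np.any(self.f_v < -1.0):
            raise ValidationError("vertical force below -1 N tolerance")
        if self.body_weight is not None and self.resting_weight is not None:
            if not (self.body_weight > self.resting_weight >= 0):
                raise ValidationError(
                    "need body_weight > resting_weight >= 0 when both set"
                )

    @staticmethod
    def channel_names() -> tuple[str, ...]:
        return _FORCE_COLUMNS[1:]

    def __len__(self) -> int:
        return len(self.t)

    def crop(self, t0: float, t1: float) -> "ForcePlateRecording":
        m = (self.t >= t0 - 1e-9) & (self.t <= t1 + 1e-9)
        if m.sum() < 2:
            raise AlignmentError("crop interval keeps fewer than 2 samples")
        kw = {c: getattr(self, c)[m] for c in self.channel_names()}
        return ForcePlateRecording(
            t=self.t[m], sample_rate=self.sample_rate,
            subject_id=self.subject_id, body_weight=self.body_weight,
            resting_weight=self.resting_weight, **kw)

    def shift_time(self, dt: float) -> "ForcePlateRecording":
        return replace(self, t=self.t + dt)


class Segment(NamedTuple):
    """One labelled activity interval, half-open ``[start, end)``."""

    start: float
    end: float
    label: str

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class LabelTrack:
    """Time-ordered, non-overlapping activity segments.

    Adjacent segments with the same label are merged on construction so that
    tracks are always maximally merged.
    """

    segments: tuple[Segment, ...]

    def __init__(self, segments: Iterable[Sequence]) -> None:
        segs = [Segment(float(s[0]), float(s[1]), str(s[2])) for s in segments]
        for s in segs:
            if s.label not in LABELS:
                raise ValidationError(
                    f"unknown label {s.label!r}; vocabulary is {LABELS}"
                )
            if not s.start < s.end:
                raise ValidationError(f"segment start must precede end: {s}")
        segs.sort(key=lambda s: s.start)
        merged: list[Segment] = []
        for s in segs:
            if merged and s.start < merged[-1].end - 1e-9:
                raise ValidationError(
                    f"overlapping segments: {merged[-1]} and {s}"
                )
            if (merged and merged[-1].label == s.label
                    and abs(s.start - merged[-1].end) <= 1e-9):
                merged[-1] = Segment(merged[-1].start, s.end, s.label)
            else:
                merged.append(s)
        object.__setattr__(self, "segments", tuple(merged))

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    @property
    def start(self) -> float:
        return self.segments[0].start

    @property
    def end(self) -> float:
        return self.segments[-1].end

    def shift(self, dt: float) -> "LabelTrack":
        return LabelTrack((s.start + dt, s.end + dt, s.label) for s in self.segments)

    def label_at(self, t: float, default: str = OTHER) -> str:
        """Label of the segment containing ``t`` (half-open intervals)."""
        for s in self.segments:
            if s.start <= t < s.end:
                return s.label
        return default


@dataclass
class SessionBundle:
    """One measurement session: IMU stream plus optional references.

    ``truth`` is the ground-truth activity track (available for synthetic and
    hand-annotated sessions); ``stopwatch_5crt`` is a reference total test
    duration in seconds.  ``meta`` carries generator-provided ground truth
    (drawn parameters, programmed phase times) for synthetic sessions.
    """

    imu: ImuRecording
    force: ForcePlateRecording | None = None
    truth: LabelTrack | None = None
    stopwatch_5crt: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.force is not None:
            if min(self.imu.t[-1], self.force.t[-1]) <= max(self.imu.t[0], self.force.t[0]):
                raise ValidationError("IMU and force time axes do not overlap")


# ---------------------------------------------------------------------------
# CSV readers / writers
# ---------------------------------------------------------------------------

def _read_metadata(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
    return meta


def _read_csv(path, required: Sequence[str], kind: str) -> tuple[pd.DataFrame, dict]:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{kind} file not found: {path}")
    meta = _read_metadata(path)
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise FormatError(f"empty {kind} file: {path}") from None
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{kind} file {path} is missing column {col!r}")
    if len(df) == 0:
        raise FormatError(f"{kind} file {path} has no data rows")
    return df, meta


def _infer_sample_rate(t: np.ndarray) -> float:
    dt = np.median(np.diff(t))
    if dt <= 0:
        raise ValidationError("time column is not increasing")
    return 1.0 / dt


def read_imu_csv(path) -> ImuRecording:
    """Read an IMU recording from CSV.

    The header must name the seven columns
    ``t,acc_v,acc_ml,acc_ap,gyr_v,gyr_ml,gyr_ap``; extra columns (e.g.
    magnetometer channels) are accepted and ignored.  The sample rate is
    inferred from the median sample spacing and, when a
    ``# sample_rate_hz:`` metadata line is present, checked against it.
    """
    df, meta = _read_csv(path, _IMU_COLUMNS, "IMU")
    t = df["t"].to_numpy(dtype=float)
    fs = _infer_sample_rate(t)
    if "sample_rate_hz" in meta:
        declared = float(meta["sample_rate_hz"])
        if abs(declared - fs) > 0.01 * declared:
            raise ValidationError(
                f"declared sample rate {declared} Hz does not match "
                f"inferred {fs:.3f} Hz"
            )
        fs = declared
    kw = {c: df[c].to_numpy(dtype=float) for c in _IMU_COLUMNS[1:]}
    return ImuRecording(t=t, sample_rate=float(round(fs, 6)),
                        subject_id=meta.get("subject_id", ""), **kw)


def write_imu_csv(rec: ImuRecording, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if rec.subject_id:
            fh.write(f"# subject_id: {rec.subject_id}\n")
        fh.write(f"# sample_rate_hz: {rec.sample_rate:g}\n")
        df = pd.DataFrame({c: getattr(rec, c) for c in _IMU_COLUMNS})
        df.to_csv(fh, index=False)


def read_force_csv(path) -> ForcePlateRecording:
    """Read a force-plate recording from CSV (columns ``t,f_v,f_ml,f_ap``).

    Optional ``#``-metadata lines carry ``body_weight_N``,
    ``resting_weight_N``, ``subject_id`` and ``sample_rate_hz``.
    """
    df, meta = _read_csv(path, _FORCE_COLUMNS, "force")
    t = df["t"].to_numpy(dtype=float)
    fs = _infer_sample_rate(t)
    if "sample_rate_hz" in meta:
        fs = float(meta["sample_rate_hz"])
    bw = float(meta["body_weight_N"]) if "body_weight_N" in meta else None
    rw = float(meta["resting_weight_N"]) if "resting_weight_N" in meta else None
    kw = {c: df[c].to_numpy(dtype=float) for c in _FORCE_COLUMNS[1:]}
    return ForcePlateRecording(
        t=t, sample_rate=float(round(fs, 6)), subject_id=meta.get("subject_id", ""),
        body_weight=bw, resting_weight=rw, **kw)


def write_force_csv(rec: ForcePlateRecording, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if rec.subject_id:
            fh.write(f"# subject_id: {rec.subject_id}\n")
        fh.write(f"# sample_rate_hz: {rec.sample_rate:g}\n")
        if rec.body_weight is not None:
            fh.write(f"# body_weight_N: {rec.body_weight!r}\n")
        if rec.resting_weight is not None:
            fh.write(f"# resting_weight_N: {rec.resting_weight!r}\n")
        df = pd.DataFrame({c: getattr(rec, c) for c in _FORCE_COLUMNS})
        df.to_csv(fh, index=False)


def read_labels(path) -> LabelTrack:
    """Read a label track from CSV with columns ``start,end,label``."""
    df, _ = _read_csv(path, ("start", "end", "label"), "label")
    return LabelTrack(df[["start", "end", "label"]].itertuples(index=False, name=None))


def _labels_text(track: LabelTrack) -> str:
    # repr() keeps full float precision so read(write(x)) == x exactly
    rows = [f"{s.start!r},{s.end!r},{s.label}" for s in track.segments]
    return "start,end,label\n" + "\n".join(rows) + "\n"


def write_labels(track: LabelTrack, path) -> None:
    Path(path).write_text(_labels_text(track))


def labels_roundtrip(track: LabelTrack) -> LabelTrack:
    """write_labels followed by read_labels, through an in-memory buffer."""
    df = pd.read_csv(_stdio.StringIO(_labels_text(track)),
                 float_precision="round_trip")
    return LabelTrack(df.itertuples(index=False, name=None))


# ---------------------------------------------------------------------------
# Stream alignment
# ---------------------------------------------------------------------------

def estimate_lag(imu: ImuRecording, force: ForcePlateRecording,
                 max_lag_s: float = 2.0) -> float:
    """Estimate the delay of the force stream relative to the IMU stream.

    The vertical force is resampled onto the IMU grid; the first differences
    of both vertical channels are cross-correlated (differencing removes the
    sitting/standing baseline steps of f_v so that the shared rise/descent
    pulses dominate).  Returns the lag in seconds: positive means force
    events occur *later* than the matching IMU events.
    """
    from scipy.signal import correlate, correlation_lags

    t0 = max(imu.t[0], force.t[0])
    t1 = min(imu.t[-1], force.t[-1])
    if t1 <= t0:
        raise AlignmentError("streams share no common time interval")
    fv = np.interp(imu.t, force.t, force.f_v)
    a = np.diff(imu.acc_v)
    b = np.diff(fv)
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    c = correlate(b, a, mode="full") / denom
    lags = correlation_lags(len(b), len(a), mode="full")
    max_lag = int(round(max_lag_s * imu.sample_rate))
    keep = np.abs(lags) <= max_lag
    lag_samples = lags[keep][np.argmax(c[keep])]
    return float(lag_samples) / imu.sample_rate


def align_streams(bundle: SessionBundle, lag_threshold_s: float = 0.05,
                  max_lag_s: float = 2.0) -> SessionBundle:
    """Crop IMU and force streams to their common time interval.

    When the estimated force-vs-IMU lag exceeds ``lag_threshold_s`` the force
    time axis is shifted to compensate before cropping.  Idempotent: applying
    twice equals applying once.
    """
    if bundle.force is None:
        raise AlignmentError("bundle has no force stream to align")
    imu, force = bundle.imu, bundle.force
    lag = estimate_lag(imu, force, max_lag_s=max_lag_s)
    if abs(lag) > lag_threshold_s:
        force = force.shift_time(-lag)
    t0 = max(imu.t[0], force.t[0])
    t1 = min(imu.t[-1], force.t[-1])
    if t1 <= t0:
        raise AlignmentError("streams share no common time interval")
    return SessionBundle(
        imu=imu.crop(t0, t1), force=force.crop(t0, t1), truth=bundle.truth,
        stopwatch_5crt=bundle.stopwatch_5crt, meta=bundle.meta)
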