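"""Window-level feature extraction for activity classification.

The eight features (RMS, mean, signal energy, lag-1 autocorrelation,
pairwise Pearson correlation, signal magnitude area, sample SD, pitch) are
computed per window over configurable channel scopes: accelerometer axes,
gyroscope axes, or both.  Everything is vectorized over windows so that a
whole session is one matrix operation per feature.

Conventions frozen here (the classical definitions):

* ``rms = sqrt(mean(x^2))``, ``signal_energy = sum(x^2)/n``
* ``autocorr`` = lag-1 Pearson autocorrelation (lag configurable)
* ``corr`` = Pearson correlation per unordered axis pair within a sensor;
  a zero-variance axis yields 0 by convention (static windows are common)
* ``sma = (sum|x_v| + sum|x_ml| + sum|x_ap|)/n`` per sensor
* ``sd`` = sample standard deviation (ddof=1)
* ``pitch`` = window mean of ``atan2(acc_ap, hypot(acc_v, acc_ml))`` in
  degrees; positive pitch is a forward (AP) lean of the sensor, i.e. trunk
  flexion.  Pitch only ever uses the accelerometer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .exceptions import InputError, ParameterError
from .preprocessing import WindowSlice

log = logging.getLogger(__name__)

ACC_AXES = ("acc_v", "acc_ml", "acc_ap")
GYR_AXES = ("gyr_v", "gyr_ml", "gyr_ap")

FEATURE_NAMES = ("rms", "mean", "signal_energy", "autocorr", "corr", "sma",
                 "sd", "pitch")

_SCOPES = {"acc": (ACC_AXES,), "gyro": (GYR_AXES,), "both": (ACC_AXES, GYR_AXES)}


@dataclass(frozen=True)
class FeatureSpec:
    """One feature over one channel scope ('acc', 'gyro' or 'both')."""

    name: str
    scope: str = "acc"

    def __post_init__(self) -> None:
        if self.name not in FEATURE_NAMES:
            raise ParameterError(f"unknown feature {self.name!r}")
        if self.scope not in _SCOPES:
            raise ParameterError(f"unknown scope {self.scope!r}")


def _pearson_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation; zero-variance rows give 0."""
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    num = np.sum(xc * yc, axis=1)
    den = np.sqrt(np.sum(xc * xc, axis=1) * np.sum(yc * yc, axis=1))
    out = np.zeros(len(x))
    ok = den > 0
    if not np.all(ok):
        log.debug("zero-variance axis in correlation; emitting 0 by convention")
    out[ok] = num[ok] / den[ok]
    return np.clip(out, -1.0, 1.0)


def _columns_for(spec: FeatureSpec, channels: dict, autocorr_lag: int
                 ) -> list[tuple[str, np.ndarray]]:
    cols: list[tuple[str, np.ndarray]] = []
    sensor_name = {id(ACC_AXES): "acc", id(GYR_AXES): "gyr"}
    for axes in _SCOPES[spec.scope]:
        sensor = sensor_name[id(axes)]
        if spec.name == "sma":
            total = sum(np.sum(np.abs(channels[a]), axis=1) for a in axes)
            n = channels[axes[0]].shape[1]
            cols.append((f"sma_{sensor}", total / n))
        elif spec.name == "corr":
            for i in range(3):
                for j in range(i + 1, 3):
                    cols.append((f"corr_{axes[i]}_{axes[j]}",
                                 _pearson_rows(channels[axes[i]], channels[axes[j]])))
        elif spec.name == "pitch":
            if sensor != "acc":
                continue
            v, ml, ap = (channels[a] for a in ACC_AXES)
            pitch = np.degrees(np.arctan2(ap, np.hypot(v, ml)))
            cols.append(("pitch", pitch.mean(axis=1)))
        else:
            for a in axes:
                x = channels[a]
                if spec.name == "rms":
                    val = np.sqrt(np.mean(x * x, axis=1))
                elif spec.name == "mean":
                    val = x.mean(axis=1)
                elif spec.name == "signal_energy":
                    val = np.sum(x * x, axis=1) / x.shape[1]
                elif spec.name == "sd":
                    val = x.std(axis=1, ddof=1)
                elif spec.name == "autocorr":
                    if x.shape[1] <= autocorr_lag:
                        raise InputError("window shorter than autocorrelation lag + 1")
                    val = _pearson_rows(x[:, :-autocorr_lag], x[:, autocorr_lag:])
                else:  # pragma: no cover - guarded by FeatureSpec
                    raise ParameterError(spec.name)
                cols.append((f"{spec.name}_{a}", val))
    return cols


def feature_matrix(channels: dict, feature_set: list[FeatureSpec],
                   autocorr_lag: int = 1) -> tuple[np.ndarray, list[str]]:
    """Compute all features for stacked windows.

    ``channels`` maps the six channel names to ``(n_windows, window_n)``
    arrays (see :func:`chairrise.preprocessing.windowed_channels`).  Returns
    the ``(n_windows, n_features)`` matrix and the feature column names.
    """
    if autocorr_lag < 1:
        raise ParameterError("autocorr_lag must be >= 1")
    names: list[str] = []
    columns: list[np.ndarray] = []
    for spec in feature_set:
        for name, col in _columns_for(spec, channels, autocorr_lag):
            names.append(name)
            columns.append(col)
    X = np.column_stack(columns)
    if not np.all(np.isfinite(X)):
        raise InputError("non-finite feature value encountered")
    return X, names


def extract_features(window: WindowSlice, feature_set: list[FeatureSpec],
                     autocorr_lag: int = 1) -> dict[str, float]:
    """Feature vector for a single window, as an ordered name->value dict.

    Deterministic and pure: repeated calls on the same slice are
    bit-identical.
    """
    if len(window) < 2:
        raise InputError("window must contain at least 2 samples")
    channels = {k: v[None, :] for k, v in window.channels.items()}
    X, names = feature_matrix(channels, feature_set, autocorr_lag=autocorr_lag)
    return dict(zip(names, X[0]))
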