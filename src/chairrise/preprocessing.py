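"""Noise filtering, gravity handling and sliding-window segmentation.

The classifier stages each window the raw streams with their own window
length and step (see :mod:`chairrise.classify`); this module provides the
shared primitives.  Filtering is zero-phase (forward-backward 4th-order
Butterworth) so transition timestamps are not biased by group delay.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt

from .exceptions import InputError, ParameterError
from .io import GRAVITY, ImuRecording


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry.

    Sample counts use round-half-up of ``seconds * sample_rate`` so that e.g.
    a 1.135 s window at 100 Hz is 114 samples.  The step is at least one
    sample.
    """

    window_s: float
    step_s: float
    sample_rate: float

    def __post_init__(self) -> None:
        if self.window_s <= 0:
            raise ParameterError("window_s must be positive")
        if not (0 < self.step_s <= self.window_s):
            raise ParameterError("need 0 < step_s <= window_s")
        if self.sample_rate <= 0:
            raise ParameterError("sample_rate must be positive")
        if self.window_n < 2:
            raise ParameterError("window shorter than 2 samples")

    @property
    def window_n(self) -> int:
        return _round_half_up(self.window_s * self.sample_rate)

    @property
    def step_n(self) -> int:
        return max(1, _round_half_up(self.step_s * self.sample_rate))

    def count(self, n_samples: int) -> int:
        """Number of full windows over ``n_samples`` samples."""
        if n_samples < self.window_n:
            return 0
        return (n_samples - self.window_n) // self.step_n + 1


@dataclass(frozen=True)
class WindowSlice:
    """One window over all six IMU channels (views, not copies)."""

    index: int
    t_start: float
    t_end: float
    channels: dict = field(hash=False)

    @property
    def t_center(self) -> float:
        return 0.5 * (self.t_start + self.t_end)

    def __len__(self) -> int:
        return len(next(iter(self.channels.values())))


def lowpass(signal: np.ndarray, fc: float, sample_rate: float,
            order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass filter.

    Forward-backward filtering doubles the effective order and squares the
    magnitude response but introduces no group delay, so event times in the
    filtered stream are preserved.
    """
    if not 0 < fc < sample_rate / 2:
        raise ParameterError(
            f"cut-off {fc} Hz must lie in (0, Nyquist={sample_rate / 2} Hz)")
    signal = np.asarray(signal, dtype=float)
    b, a = butter(order, fc, fs=sample_rate)
    padlen = min(3 * max(len(a), len(b)), len(signal) - 1)
    return filtfilt(b, a, signal, padlen=padlen)


def windowed_channels(rec: ImuRecording, spec: WindowSpec,
                      filtered: dict | None = None) -> tuple[dict, np.ndarray, np.ndarray]:
    """Window all six channels at once.

    Returns ``(channels, t_starts, t_ends)`` where ``channels`` maps channel
    name to an ``(n_windows, window_n)`` strided view.  ``filtered`` may
    supply pre-filtered channel arrays to window instead of the raw ones.
    """
    n = len(rec)
    wn, sn = spec.window_n, spec.step_n
    count = spec.count(n)
    if count < 1:
        raise InputError(
            f"recording of {n} samples is shorter than one window ({wn} samples)")
    out = {}
    for name in rec.channel_names():
        x = rec.__getattribute__(name) if filtered is None else filtered[name]
        x = np.ascontiguousarray(x, dtype=float)
        view = np.lib.stride_tricks.sliding_window_view(x, wn)[::sn][:count]
        out[name] = view
    starts = rec.t[np.arange(count) * sn]
    ends = rec.t[np.arange(count) * sn + wn - 1] + 1.0 / rec.sample_rate
    return out, starts, ends


def sliding_windows(rec: ImuRecording, spec: WindowSpec) -> list[WindowSlice]:
    """Materialize :class:`WindowSlice` objects over a recording.

    Trailing samples not covered by a full window are dropped; the window
    count is ``floor((N - window_n) / step_n) + 1``.
    """
    channels, starts, ends = windowed_channels(rec, spec)
    names = rec.channel_names()
    return [
        WindowSlice(index=i, t_start=float(starts[i]), t_end=float(ends[i]),
                    channels={c: channels[c][i] for c in names})
        for i in range(len(starts))
    ]


def remove_gravity(rec: ImuRecording, quiescent_sd: float = 0.15,
                   window_s: float = 1.0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return gravity-free (V, ML, AP) acceleration channels.

    The gravity vector is taken as the per-channel median over quiescent
    windows (1 s windows whose pooled acceleration SD, the square root of the
    summed per-axis variances, is below ``quiescent_sd`` m/s^2).  If the
    recording contains no quiescent window at all, 9.81 m/s^2 is subtracted
    from the vertical axis only.
    """
    acc = rec.acc
    n = len(rec)
    wn = max(2, _round_half_up(window_s * rec.sample_rate))
    step = max(1, wn // 2)
    quiet_mask = np.zeros(n, dtype=bool)
    any_quiet = False
    for i0 in range(0, max(1, n - wn + 1), step):
        seg = acc[i0:i0 + wn]
        if len(seg) < 2:
            continue
        pooled = float(np.sqrt(np.sum(np.var(seg, axis=0, ddof=1))))
        if pooled < quiescent_sd:
            quiet_mask[i0:i0 + wn] = True
            any_quiet = True
    if any_quiet:
        g = np.median(acc[quiet_mask], axis=0)
    else:
        g = np.array([GRAVITY, 0.0, 0.0])
    out = acc - g
    return out[:, 0], out[:, 1], out[:, 2]
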