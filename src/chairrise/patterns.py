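"""Movement-pattern similarity and method-agreement statistics.

Two families of analytics:

* *Agreement* between two measurement methods of the same durations —
  ordinary least squares of y on x, Pearson correlation with a two-sided
  p-value, and Bland-Altman limits of agreement (mean difference
  +/- 1.96 * SD of the differences).
* *Similarity* of movement patterns — a normalized cross-correlation that is
  invariant to amplitude scale and offset and is maximized over a bounded
  lag range, optionally after linear time-normalization of the cycles, plus
  descriptive statistics of coefficient sets and the classical rule of
  thumb for interpreting a correlation's size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import InputError, ParameterError
from .io import ImuRecording
from .preprocessing import remove_gravity


# ---------------------------------------------------------------------------
# normalized cross-correlation and time normalization
# ---------------------------------------------------------------------------

def _pearson(a: np.ndarray, b: np.ndarray) -> float | None:
    a = a - a.mean()
    b = b - b.mean()
    den = np.linalg.norm(a) * np.linalg.norm(b)
    if den == 0:
        return None
    return float(np.dot(a, b) / den)


def normalized_xcorr(a, b, max_lag_fraction: float = 0.5) -> float:
    """Maximum normalized cross-correlation of two signals.

    At each lag the overlapping parts of the two series are mean-centered
    and unit-normalized (i.e. their Pearson correlation is taken), and the
    maximum over lags ``|l| <= max_lag_fraction * min(len(a), len(b))`` is
    returned.  The result lies in [-1, 1]; identical signals give exactly
    1.0 and a pure time shift within the lag bound is fully recovered.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InputError("both series need at least 2 samples")
    if not 0.0 <= max_lag_fraction <= 1.0:
        raise ParameterError("max_lag_fraction must lie in [0, 1]")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise InputError("similarity of a constant series is undefined")
    max_lag = int(max_lag_fraction * min(len(a), len(b)))
    best = -np.inf
    for lag in range(-max_lag, max_lag + 1):
        if lag >= 0:
            aa, bb = a[lag:], b[:len(a) - lag]
        else:
            aa, bb = a[:len(a) + lag], b[-lag:]
        n = min(len(aa), len(bb))
        if n < 2:
            continue
        r = _pearson(aa[:n], bb[:n])
        if r is not None and r > best:
            best = r
    if not np.isfinite(best):
        raise InputError("no lag with a defined correlation")
    return float(min(1.0, max(-1.0, best)))


def time_normalize(series, n_points: int) -> np.ndarray:
    """Linearly resample a series onto ``n_points`` equally spaced abscissae.

    The span is preserved, so endpoints are reproduced exactly; this removes
    duration differences before comparing movement *forms*.
    """
    series = np.asarray(series, dtype=float)
    if len(series) < 2:
        raise InputError("series needs at least 2 samples")
    if n_points < 2:
        raise ParameterError("n_points must be >= 2")
    x_old = np.linspace(0.0, 1.0, len(series))
    x_new = np.linspace(0.0, 1.0, n_points)
    return np.interp(x_new, x_old, series)


def accel_magnitude(imu: ImuRecording) -> np.ndarray:
    """Gravity-free acceleration magnitude, sample by sample.

    Gravity is removed per channel (see
    :func:`chairrise.preprocessing.remove_gravity`), then the Euclidean norm
    over (V, ML, AP) is taken; the result is non-negative.
    """
    v, ml, ap = remove_gravity(imu)
    return np.sqrt(v * v + ml * ml + ap * ap)


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric matrix of pairwise maximum normalized cross-correlations."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __getitem__(self, pair) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    def off_diagonal(self) -> np.ndarray:
        n = len(self.labels)
        iu = np.triu_indices(n, k=1)
        return self.values[iu]


def similarity_matrix(cycles: dict[str, np.ndarray],
                      max_lag_fraction: float = 0.5,
                      normalize_time: bool = True,
                      n_points: int = 200) -> SimilarityMatrix:
    """Pairwise similarity of cycle waveforms (vertical force by default).

    With ``normalize_time`` each waveform is first resampled to ``n_points``
    so only the *form* of the movement is compared; this is the right mode
    for comparing cycles across subjects with different speeds.
    """
    labels = tuple(cycles)
    series = [np.asarray(cycles[k], dtype=float) for k in labels]
    if normalize_time:
        series = [time_normalize(s, n_points) for s in series]
    n = len(labels)
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = normalized_xcorr(
                series[i], series[j], max_lag_fraction=max_lag_fraction)
    return SimilarityMatrix(labels=labels, values=out)


# ---------------------------------------------------------------------------
# agreement between two measurement methods
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AgreementResult:
    """Linear regression + Bland-Altman agreement of paired measurements.

    ``slope`` and ``intercept`` come from ordinary least squares of y on x;
    the Bland-Altman statistics describe the differences ``y - x`` with
    limits of agreement ``mean_diff +/- 1.96 * sd_diff`` (sample SD).
    """

    slope: float
    intercept: float
    pearson_r: float
    p_value: float
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int
    slope_se: float
    intercept_se: float

    def significant(self, alpha: float = 0.05) -> bool:
        """Whether the linear relation is significant at ``alpha``."""
        return self.p_value < alpha

    def summary(self) -> str:
        lines = [
            "Method agreement",
            "================",
            f"n pairs:            {self.n}",
            f"OLS fit:            y = {self.slope:.3f} * x + {self.intercept:.3f}",
            f"  slope SE:         {self.slope_se:.3f}",
            f"  intercept SE:     {self.intercept_se:.3f}",
            f"Pearson r:          {self.pearson_r:.3f} "
            f"({interpret_correlation(self.pearson_r)})",
            f"p-value (2-sided):  {self.p_value:.3g}",
            f"Bland-Altman bias:  {self.mean_diff:.3f}",
            f"  SD of differences:{self.sd_diff:.3f}",
            f"  limits of agreement: [{self.loa_low:.3f}, {self.loa_high:.3f}]",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "n": self.n, "slope": self.slope, "intercept": self.intercept,
            "slope_se": self.slope_se, "intercept_se": self.intercept_se,
            "pearson_r": self.pearson_r, "p_value": self.p_value,
            "bland_altman": {
                "mean_diff": self.mean_diff, "sd_diff": self.sd_diff,
                "loa_low": self.loa_low, "loa_high": self.loa_high,
            },
        }

    def plot_bland_altman(self, x, y, ax=None):
        """Bland-Altman plot of the paired measurements (lazy matplotlib)."""
        import matplotlib.pyplot as plt

        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if ax is None:
            _, ax = plt.subplots()
        mean = (x + y) / 2.0
        diff = y - x
        ax.scatter(mean, diff, s=18)
        for level, style in ((self.mean_diff, "-"),
                             (self.loa_low, "--"), (self.loa_high, "--")):
            ax.axhline(level, linestyle=style, color="k", linewidth=1)
        ax.set_xlabel("mean of methods [s]")
        ax.set_ylabel("difference y - x [s]")
        return ax


def agreement(x, y) -> AgreementResult:
    """Agreement analytics for paired duration measurements.

    Requires at least 3 pairs and non-zero variance in ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise InputError("paired samples must have equal length")
    if len(x) < 3:
        raise InputError("need at least 3 pairs")
    if np.ptp(x) == 0:
        raise InputError("zero variance in x; regression undefined")
    fit = stats.linregress(x, y)
    diff = y - x
    mean_diff = float(diff.mean())
    sd_diff = float(diff.std(ddof=1))
    # intercept SE from the same OLS fit
    n = len(x)
    resid = y - (fit.slope * x + fit.intercept)
    s2 = float(np.sum(resid ** 2) / (n - 2)) if n > 2 else 0.0
    sxx = float(np.sum((x - x.mean()) ** 2))
    intercept_se = float(np.sqrt(s2 * (1.0 / n + x.mean() ** 2 / sxx)))
    return AgreementResult(
        slope=float(fit.slope), intercept=float(fit.intercept),
        pearson_r=float(fit.rvalue), p_value=float(fit.pvalue),
        mean_diff=mean_diff, sd_diff=sd_diff,
        loa_low=mean_diff - 1.96 * sd_diff,
        loa_high=mean_diff + 1.96 * sd_diff,
        n=n, slope_se=float(fit.stderr), intercept_se=intercept_se)


# ---------------------------------------------------------------------------
# descriptive statistics of coefficient sets
# ---------------------------------------------------------------------------

#: rule-of-thumb bands for the size of a correlation coefficient
CORRELATION_BANDS = (
    (0.9, "very high"),
    (0.7, "high"),
    (0.5, "moderate"),
    (0.3, "low"),
    (0.0, "negligible"),
)


def interpret_correlation(r: float) -> str:
    """Rule-of-thumb label for the magnitude of a correlation coefficient."""
    if abs(r) > 1.0:
        raise InputError("|r| must not exceed 1")
    mag = abs(r)
    for lower, label in CORRELATION_BANDS:
        if mag >= lower:
            return label
    return "negligible"


def variability_stats(coeffs) -> dict[str, float]:
    """min / max / mean / median / SD / range of a coefficient set."""
    c = np.asarray(list(coeffs), dtype=float)
    if len(c) < 1:
        raise InputError("need at least one coefficient")
    return {
        "min": float(c.min()),
        "max": float(c.max()),
        "mean": float(c.mean()),
        "median": float(np.median(c)),
        "sd": float(c.std(ddof=1)) if len(c) > 1 else 0.0,
        "range": float(c.max() - c.min()),
    }
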