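"""Minute-level feature extraction.

Two fixed inventories are produced from each labeled minute:

* the **posture set** — 10 time-domain statistics of the accelerometer y axis
  (along the thigh, pointing up while standing), including the mean angle to
  the vertical and its variance;
* the **MET set** — 144 features: 12 per EMG channel (six time-domain, six
  frequency-domain) and 16 per accelerometer axis (the same 12 plus mean,
  median, 5th and 95th percentile).  Absolute-amplitude statistics are
  deliberately excluded for EMG because raw surface-EMG amplitude varies
  strongly between people; only relative/dynamical features are kept.

Feature names follow ``<stream>.<channel>.<feature>`` and the column order is
deterministic, so extraction is bit-reproducible for identical input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .io import ACCEL_AXES, EMG_CHANNELS, LabeledMinute

TIME_FEATURE_NAMES = (
    "sd",
    "autocorr_1s",
    "n_peaks",
    "peak_sum_rel_median",
    "n_median_crossings",
    "median_crossing_interval",
)

FREQ_FEATURE_NAMES = (
    "mean_freq",
    "harmonic_freq",
    "harmonic_power",
    "mean_power",
    "power_above_0p5hz",
    "power_above_5hz",
)

AMPLITUDE_FEATURE_NAMES = ("mean", "median", "p5", "p95")

POSTURE_FEATURE_NAMES = tuple(
    f"accel.y.{name}"
    for name in (
        "mean",
        "median",
        "p5",
        "p95",
        "var",
        "iqr",
        "kurtosis",
        "skewness",
        "angle_mean",
        "angle_var",
    )
)

MET_FEATURE_NAMES = tuple(
    [
        f"emg.{ch}.{name}"
        for ch in EMG_CHANNELS
        for name in TIME_FEATURE_NAMES + FREQ_FEATURE_NAMES
    ]
    + [
        f"accel.{axis}.{name}"
        for axis in ACCEL_AXES
        for name in TIME_FEATURE_NAMES + FREQ_FEATURE_NAMES + AMPLITUDE_FEATURE_NAMES
    ]
)


@dataclass
class FeatureConfig:
    """Tunable conventions for ill-specified feature primitives.

    peak_prominence_k
        A local maximum counts as a *prominent* peak when its topographic
        prominence is >= k x the signal median (no prominence constraint when
        the median is non-positive, as for zero-mean accelerometer axes).
    peak_min_distance_s
        Minimum separation between counted peaks, in seconds.
    detrend
        Remove the mean before spectral estimation and power computation.
    """

    peak_prominence_k: float = 1.0
    peak_min_distance_s: float = 1.0 / 6.0
    detrend: bool = True


def angle_to_vertical(y) -> np.ndarray | float:
    """Thigh angle to the vertical axis in degrees, from the y-axis reading.

    Under the sign convention that quiet standing reads -1 g, a quasi-static
    reading y maps to arccos(-y) degrees: -1 g -> 0 deg (vertical thigh),
    0 g -> 90 deg (horizontal), and the sitting rule's -0.774 g -> 39 deg.
    Readings are clamped to [-1, 1] before the arccosine.
    """
    y = np.clip(y, -1.0, 1.0)
    return np.degrees(np.arccos(-y))


def _guarded_moment(x: np.ndarray, fn) -> float:
    if np.var(x) == 0:
        return 0.0
    return float(fn(x))


def posture_features(accel_y_minute: np.ndarray, sample_rate: float = 30.0) -> dict[str, float]:
    """The 10 posture features of one minute of accelerometer y-axis data.

    Mean, median, 5th/95th percentile, variance, interquartile range,
    kurtosis, skewness, and the mean angle to the vertical axis with its
    variance.  Kurtosis is Fisher excess kurtosis; both shape statistics are
    defined as 0 for zero-variance signals.
    """
    y = np.asarray(accel_y_minute, dtype=float).ravel()
    expected = round(60 * sample_rate)
    if y.size != expected:
        raise ValueError(f"need one full minute ({expected} samples), got {y.size}")
    angles = angle_to_vertical(y)
    values = (
        float(np.mean(y)),
        float(np.median(y)),
        float(np.percentile(y, 5)),
        float(np.percentile(y, 95)),
        float(np.var(y)),
        float(np.percentile(y, 75) - np.percentile(y, 25)),
        _guarded_moment(y, stats.kurtosis),
        _guarded_moment(y, stats.skew),
        float(np.mean(angles)),
        float(np.var(angles)),
    )
    return dict(zip(POSTURE_FEATURE_NAMES, values))


def time_features(x: np.ndarray, sample_rate: float,
                  config: FeatureConfig | None = None) -> dict[str, float]:
    """Six time-domain features of one minute of signal.

    Standard deviation; one-second-lag autocorrelation (Pearson, 0 for
    zero-variance overlap); number of prominent peaks; sum of prominent peak
    heights relative to the median (0 when the median is 0); number of median
    crossings (strict sign changes of signal - median between consecutive
    samples; touches do not count); and the median time between adjacent
    crossings (0 when there are fewer than two crossings).
    """
    config = config or FeatureConfig()
    x = np.asarray(x, dtype=float).ravel()
    expected = round(60 * sample_rate)
    if x.size != expected:
        raise ValueError(f"need one full minute ({expected} samples), got {x.size}")

    constant = x.min() == x.max()
    sd = 0.0 if constant else float(np.std(x))

    lag = int(round(sample_rate))
    a, b = x[:-lag], x[lag:]
    if a.size < 2 or a.min() == a.max() or b.min() == b.max():
        autocorr = 0.0  # zero-variance overlap: correlation undefined
    else:
        autocorr = float(np.corrcoef(a, b)[0, 1])

    med = float(np.median(x))
    prominence = config.peak_prominence_k * med
    distance = max(1, int(round(sample_rate * config.peak_min_distance_s)))
    peaks, _ = sps.find_peaks(
        x, prominence=prominence if prominence > 0 else None, distance=distance
    )
    n_peaks = float(peaks.size)
    peak_sum_rel = float(np.sum(x[peaks]) / med) if med != 0 else 0.0

    s = x - med
    crossing_idx = np.flatnonzero(s[:-1] * s[1:] < 0)
    n_crossings = float(crossing_idx.size)
    if crossing_idx.size >= 2:
        crossing_times = (crossing_idx + 0.5) / sample_rate
        interval = float(np.median(np.diff(crossing_times)))
    else:
        interval = 0.0

    return dict(
        zip(
            TIME_FEATURE_NAMES,
            (sd, autocorr, n_peaks, peak_sum_rel, n_crossings, interval),
        )
    )


def freq_features(x: np.ndarray, sample_rate: float,
                  config: FeatureConfig | None = None) -> dict[str, float]:
    """Six frequency-domain features from a one-shot minute periodogram.

    Power-weighted mean frequency, frequency and power of the first harmonic
    (largest non-DC periodogram peak), average signal power (mean squared
    sample after detrending), and band power above 0.5 Hz and above 5 Hz.
    All six are 0 for a zero (or constant, when detrending) signal.
    """
    config = config or FeatureConfig()
    x = np.asarray(x, dtype=float).ravel()
    expected = round(60 * sample_rate)
    if x.size != expected:
        raise ValueError(f"need one full minute ({expected} samples), got {x.size}")
    if config.detrend:
        x = x - np.mean(x)

    f, p = sps.periodogram(x, fs=sample_rate, scaling="spectrum", detrend=False)
    f, p = f[1:], p[1:]  # drop DC
    total = float(np.sum(p))
    if total > 0:
        mean_freq = float(np.sum(f * p) / total)
        k = int(np.argmax(p))
        harmonic_freq = float(f[k])
        harmonic_power = float(p[k])
    else:
        mean_freq = harmonic_freq = harmonic_power = 0.0
    mean_power = float(np.mean(x**2))
    power_05 = float(np.sum(p[f > 0.5]))
    power_5 = float(np.sum(p[f > 5.0]))
    return dict(
        zip(
            FREQ_FEATURE_NAMES,
            (mean_freq, harmonic_freq, harmonic_power, mean_power, power_05, power_5),
        )
    )


def _amplitude_features(x: np.ndarray) -> dict[str, float]:
    return dict(
        zip(
            AMPLITUDE_FEATURE_NAMES,
            (
                float(np.mean(x)),
                float(np.median(x)),
                float(np.percentile(x, 5)),
                float(np.percentile(x, 95)),
            ),
        )
    )


def met_features(minute: LabeledMinute,
                 config: FeatureConfig | None = None) -> dict[str, float]:
    """The 144-entry MET feature vector of one labeled minute.

    12 features per EMG channel (six time- plus six frequency-domain) and 16
    per accelerometer axis (the 12 plus mean, median, 5th and 95th
    percentile).  Channels flagged as partially missing still produce
    (numeric) features; an all-zero channel yields 12 zeros rather than being
    dropped.
    """
    config = config or FeatureConfig()
    if minute.emg.shape[0] != len(EMG_CHANNELS):
        raise ValueError("minute must carry all 8 EMG channels")
    if minute.accel.shape[0] != len(ACCEL_AXES):
        raise ValueError("minute must carry all 3 accelerometer axes")
    out: dict[str, float] = {}
    for i, ch in enumerate(EMG_CHANNELS):
        x = minute.emg[i]
        for name, v in {
            **time_features(x, minute.emg_rate, config),
            **freq_features(x, minute.emg_rate, config),
        }.items():
            out[f"emg.{ch}.{name}"] = v
    for j, axis in enumerate(ACCEL_AXES):
        x = minute.accel[j]
        for name, v in {
            **time_features(x, minute.accel_rate, config),
            **freq_features(x, minute.accel_rate, config),
            **_amplitude_features(x),
        }.items():
            out[f"accel.{axis}.{name}"] = v
    assert tuple(out) == MET_FEATURE_NAMES
    return out


# ---------------------------------------------------------------------------
# Matrix builders / sklearn-style transformers


def _label_frame(minutes) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant_id": [m.participant_id for m in minutes],
            "task": [m.task for m in minutes],
            "posture": [m.posture for m in minutes],
            "met": [m.met for m in minutes],
            "met_category": [m.met_category for m in minutes],
        }
    )


def feature_matrix(minutes, kind: str = "met",
                   config: FeatureConfig | None = None,
                   with_labels: bool = True) -> pd.DataFrame:
    """Extract a (minutes x features) DataFrame; labels appended if asked."""
    if kind == "met":
        rows = [met_features(m, config) for m in minutes]
    elif kind == "posture":
        rows = [posture_features(m.accel_y, m.accel_rate) for m in minutes]
    else:
        raise ValueError(f"kind must be 'met' or 'posture', got {kind!r}")
    df = pd.DataFrame(rows)
    if with_labels:
        df = pd.concat([df, _label_frame(minutes)], axis=1)
    return df


def export_feature_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


class _MinuteFeatureExtractor(TransformerMixin, BaseEstimator):
    """Stateless transformer: list of LabeledMinute -> feature DataFrame."""

    _kind = "met"

    def __init__(self, config: FeatureConfig | None = None):
        self.config = config

    def fit(self, X, y=None):
        self.n_features_in_ = 1  # minutes are the single structured input
        return self

    def transform(self, X) -> pd.DataFrame:
        return feature_matrix(X, kind=self._kind, config=self.config, with_labels=False)

    def get_feature_names_out(self, input_features=None):
        names = MET_FEATURE_NAMES if self._kind == "met" else POSTURE_FEATURE_NAMES
        return np.asarray(names, dtype=object)


class METFeatureExtractor(_MinuteFeatureExtractor):
    """Extracts the 144-feature MET set from labeled minutes."""

    _kind = "met"


class PostureFeatureExtractor(_MinuteFeatureExtractor):
    """Extracts the 10-feature posture set (accelerometer y axis only)."""

    _kind = "posture"
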