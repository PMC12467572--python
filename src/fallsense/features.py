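"""Two-stage feature extraction: 40x6 window -> 168 named descriptors.

Stage 1 expands each window into 24 per-time-step channels: for each
sensor (accelerometer, gyroscope) the L2 magnitude (SMV), the L1 magnitude
(SMA series), and six cross-axis statistics (min, mean, max, range, std,
var over the three axis values at each instant); accelerometer-only
gravity-referenced roll and pitch angles; plus the six raw channels.
Stage 2 condenses every stage-1 channel into seven descriptive statistics
(min, mean, max, var, std, skew, kurt) over the 40-sample window:
24 channels x 7 statistics = 168 features.

All moments are population moments (divide by n, both across the 3 axes
and across the 40 samples); skewness is Fisher-Pearson m3 / m2^1.5 and
kurtosis is excess kurtosis m4 / m2^2 - 3, both defined as 0 when the
variance is below 1e-12.  The feature-name registry (``FEATURE_NAMES``)
is frozen: selection results are always reported by name.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import Counter

import numpy as np
import pandas as pd

from .errors import ValidationError
from .preprocessing import LabeledWindow, Window

#: Variance floor below which skewness/kurtosis are defined as zero.
MOMENT_EPS = 1e-12

_AXIS_STATS = ("axmin", "axmean", "axmax", "axrange", "axstd", "axvar")

ACCEL_CHANNELS = (
    "smv_accel", "sma_accel",
    *(f"{s}_accel" for s in _AXIS_STATS),
    "roll", "pitch",
)
GYRO_CHANNELS = ("smv_gyro", "sma_gyro", *(f"{s}_gyro" for s in _AXIS_STATS))
RAW_CHANNELS = ("ax", "ay", "az", "gx", "gy", "gz")

#: The 24 stage-1 channel names: 10 accelerometer + 8 gyroscope + 6 raw.
STAGE1_CHANNELS = ACCEL_CHANNELS + GYRO_CHANNELS + RAW_CHANNELS

STATS = ("min", "mean", "max", "var", "std", "skew", "kurt")

#: Canonical registry of the 168 feature names, in frozen order.
FEATURE_NAMES = tuple(f"{ch}__{st}" for ch in STAGE1_CHANNELS for st in STATS)


def _stage1_array(X: np.ndarray) -> np.ndarray:
    """(N, 40, 6) raw windows -> (N, 40, 24) stage-1 channel stack."""
    X = np.asarray(X, dtype=float)
    acc, gyr = X[..., 0:3], X[..., 3:6]

    def sensor_block(v: np.ndarray) -> list[np.ndarray]:
        smv = np.linalg.norm(v, axis=-1)
        sma = np.abs(v).sum(axis=-1)
        mn = v.min(axis=-1)
        mean = v.mean(axis=-1)
        mx = v.max(axis=-1)
        var = v.var(axis=-1)  # population, n = 3
        std = np.sqrt(var)
        return [smv, sma, mn, mean, mx, mx - mn, std, var]

    ax, ay, az = acc[..., 0], acc[..., 1], acc[..., 2]
    # atan2(0, 0) = 0 by numpy convention, keeping free-fall windows finite
    roll = np.degrees(np.arctan2(ay, az))
    pitch = np.degrees(np.arctan2(-ax, np.hypot(ay, az)))

    channels = sensor_block(acc) + [roll, pitch] + sensor_block(gyr) \
        + [X[..., i] for i in range(6)]
    return np.stack(channels, axis=-1)


def _stage2_array(series: np.ndarray) -> np.ndarray:
    """(..., 40, C) stage-1 series -> (..., C, 7) windowed statistics."""
    s = np.asarray(series, dtype=float)
    mn = s.min(axis=-2)
    mean = s.mean(axis=-2)
    mx = s.max(axis=-2)
    centered = s - mean[..., None, :]
    m2 = np.mean(centered ** 2, axis=-2)
    m3 = np.mean(centered ** 3, axis=-2)
    m4 = np.mean(centered ** 4, axis=-2)
    std = np.sqrt(m2)
    safe = m2 >= MOMENT_EPS
    with np.errstate(divide="ignore", invalid="ignore"):
        skew = np.where(safe, m3 / np.where(safe, m2, 1.0) ** 1.5, 0.0)
        kurt = np.where(safe, m4 / np.where(safe, m2, 1.0) ** 2 - 3.0, 0.0)
    return np.stack([mn, mean, mx, m2, std, skew, kurt], axis=-1)


def stage1_series(window: Window) -> pd.DataFrame:
    """Stage-1 expansion of one window: 40 rows x 24 named channels."""
    arr = _stage1_array(window.samples[None])[0]
    return pd.DataFrame(arr, columns=list(STAGE1_CHANNELS))


def stage2_stats(series: np.ndarray) -> tuple[float, ...]:
    """(min, mean, max, var, std, skew, kurt) of one real-valued series."""
    s = np.asarray(series, dtype=float)
    if s.ndim != 1:
        raise ValidationError("stage2_stats expects a 1-D series")
    return tuple(float(v) for v in _stage2_array(s[:, None])[0])


def extract_features(window: Window) -> pd.Series:
    """The canonical 168-dimensional feature vector of one window."""
    return extract_feature_frame([window]).iloc[0]


def extract_feature_frame(windows: list[Window]) -> pd.DataFrame:
    """Vectorized extraction: one row per window, columns = registry order."""
    if not windows:
        raise ValidationError("no windows to extract features from")
    X = np.stack([w.samples for w in windows])
    stats = _stage2_array(_stage1_array(X))  # (N, 24, 7)
    flat = stats.reshape(len(windows), -1)
    if not np.isfinite(flat).all():
        raise ValidationError("non-finite feature value; check input windows")
    return pd.DataFrame(flat, columns=list(FEATURE_NAMES))


@dataclass
class FeatureMatrix:
    """Feature rows with labels and optional per-row sample weights.

    ``registry`` is the frozen column order; ``n_c`` the per-class counts.
    Any column registry is allowed (diagnostic datasets use their own
    names); windows extracted by this module always carry the canonical
    168-name registry.
    """

    X: pd.DataFrame
    y: np.ndarray
    weights: np.ndarray | None = None
    end_times: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=object)
        if len(self.X) != len(self.y):
            raise ValidationError(
                f"{len(self.X)} feature rows but {len(self.y)} labels")
        if len(self.X) == 0:
            raise ValidationError("empty feature matrix")
        if self.weights is not None and len(self.weights) != len(self.y):
            raise ValidationError("weights length must match rows")

    @property
    def registry(self) -> tuple[str, ...]:
        return tuple(self.X.columns)

    @property
    def N(self) -> int:
        return len(self.X)

    @property
    def classes(self) -> tuple[str, ...]:
        from .io import CLASSES
        present = set(self.y)
        ordered = [c for c in CLASSES if c in present]
        ordered += sorted(present - set(CLASSES))
        return tuple(ordered)

    @property
    def K(self) -> int:
        return len(self.classes)

    @property
    def n_c(self) -> dict[str, int]:
        return dict(Counter(self.y))

    def subset(self, feature_names: list[str] | tuple[str, ...]) -> "FeatureMatrix":
        missing = [f for f in feature_names if f not in self.X.columns]
        if missing:
            raise ValidationError(f"unknown feature names: {missing[:5]}")
        return FeatureMatrix(X=self.X[list(feature_names)].copy(), y=self.y,
                             weights=self.weights, end_times=self.end_times)

    def rows(self, idx: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            X=self.X.iloc[idx].reset_index(drop=True),
            y=self.y[idx],
            weights=None if self.weights is None else self.weights[idx],
            end_times=None if self.end_times is None else self.end_times[idx])


def build_matrix(labeled_windows: list[LabeledWindow]) -> FeatureMatrix:
    """Extract features for labeled windows, in input order."""
    if not labeled_windows:
        raise ValidationError("no labeled windows")
    frame = extract_feature_frame([lw.window for lw in labeled_windows])
    return FeatureMatrix(
        X=frame,
        y=np.array([lw.label for lw in labeled_windows], dtype=object),
        end_times=np.array([lw.window.end_time for lw in labeled_windows]))
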