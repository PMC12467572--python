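"""Window segmentation, median denoising, labeling, augmentation, splitting.

Each recording's active segment is cut into fixed 40-sample (1 s) windows.
Windows are denoised with a per-window moving median filter, then labeled:
for fall recordings a window carries the fall class iff its *last* sample
falls inside the half-open critical phase [loss_of_balance, impact); windows
ending before balance loss are non-fall, windows reaching the impact or
later are discarded (post-impact data is never used for pre-impact
detection).  Keying the label to the window's last sample lets critical
phases shorter than the window (same-level falls, ~0.3-0.5 s) still
produce fall-labeled windows.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import interpolate, ndimage

from .errors import AnnotationError, ParameterError, StratificationError, ValidationError
from .io import CLASSES, EventAnnotation, ImuRecording, TIME_GRID_TOL

WINDOW_LENGTH = 40


@dataclass(frozen=True)
class Window:
    """A fixed 40-sample slice of one recording."""

    source_id: str
    start_index: int
    samples: np.ndarray  # (40, 6): ax, ay, az, gx, gy, gz
    end_time: float

    def __post_init__(self) -> None:
        if self.samples.shape != (WINDOW_LENGTH, 6):
            raise ValidationError(
                f"window must be {WINDOW_LENGTH}x6, got {self.samples.shape}")

    @property
    def length(self) -> int:
        return WINDOW_LENGTH


@dataclass(frozen=True)
class LabeledWindow:
    window: Window
    label: str
    origin: str = "real"  # or "augmented"

    def __post_init__(self) -> None:
        if self.label not in CLASSES:
            raise ValidationError(f"unknown label {self.label!r}")


def median_filter(samples: np.ndarray, kernel: int) -> np.ndarray:
    """Moving median over time, independently per channel, reflection edges.

    Accepts a 1-D series or a (time, channels) array.
    """
    samples = np.asarray(samples, dtype=float)
    if kernel % 2 == 0 or kernel < 1:
        raise ParameterError(f"kernel must be a positive odd integer, got {kernel}")
    n = samples.shape[0]
    if kernel > n:
        raise ParameterError(f"kernel {kernel} exceeds series length {n}")
    if kernel == 1:
        return samples.copy()
    size = (kernel,) if samples.ndim == 1 else (kernel, 1)
    return ndimage.median_filter(samples, size=size, mode="reflect")


def compute_smv(accel: np.ndarray) -> np.ndarray:
    """Per-sample L2 norm of tri-axial acceleration (the SMV, in g)."""
    accel = np.asarray(accel, dtype=float)
    return np.linalg.norm(np.atleast_2d(accel), axis=-1)


def segment_windows(rec: ImuRecording, stride: int = WINDOW_LENGTH,
                    kernel: int | None = 5) -> list[Window]:
    """Cut the active segment into 40-sample windows at the given stride.

    Windows start at ``active_start + k * stride`` samples and must lie
    fully inside the active segment; a partial tail is dropped.  When
    ``kernel`` is given each window is median-filtered independently.
    """
    if stride < 1:
        raise ParameterError(f"stride must be >= 1, got {stride}")
    t = rec.t
    ann = rec.annotation
    inside = np.nonzero((t >= ann.active_start - TIME_GRID_TOL)
                        & (t <= ann.active_end + TIME_GRID_TOL))[0]
    if len(inside) < WINDOW_LENGTH:
        return []
    first, last = int(inside[0]), int(inside[-1])
    sig = rec.signal
    out = []
    for start in range(first, last - WINDOW_LENGTH + 2, stride):
        block = sig[start:start + WINDOW_LENGTH]
        if kernel is not None:
            block = median_filter(block, kernel)
        out.append(Window(
            source_id=rec.recording_id,
            start_index=start,
            samples=block,
            end_time=float(t[start + WINDOW_LENGTH - 1]),
        ))
    return out


def label_windows(windows: list[Window],
                  annotation: EventAnnotation) -> list[LabeledWindow]:
    """Label windows against the recording's annotation.

    Non-fall recordings: every window is NON_FALL.  Fall recordings: a
    window is the fall class iff its last sample time lies in
    [loss_of_balance_t, impact_t); earlier windows are NON_FALL; windows
    ending at or after the impact are discarded.
    """
    if annotation is None:
        raise AnnotationError("annotation required for labeling")
    out: list[LabeledWindow] = []
    if not annotation.is_fall:
        return [LabeledWindow(w, "NON_FALL") for w in windows]
    lob, impact = annotation.loss_of_balance_t, annotation.impact_t
    if lob is None or impact is None:
        raise AnnotationError(
            f"{annotation.klass} annotation lacks loss_of_balance_t/impact_t")
    eps = TIME_GRID_TOL
    for w in windows:
        if w.end_time < lob - eps:
            out.append(LabeledWindow(w, "NON_FALL"))
        elif w.end_time < impact - eps:
            out.append(LabeledWindow(w, annotation.klass))
        # else: post-impact, discarded
    return out


def preprocess_recording(rec: ImuRecording, stride: int = WINDOW_LENGTH,
                         kernel: int = 5) -> list[LabeledWindow]:
    """Segment + denoise + label one recording."""
    return label_windows(segment_windows(rec, stride=stride, kernel=kernel),
                         rec.annotation)


# ---------------------------------------------------------------------------
# Augmentation

#: Per-level jitter noise: sigma = JITTER_ACCEL_G * level on accelerometer
#: channels, JITTER_GYRO_DPS * level on gyroscope channels.
JITTER_ACCEL_G = 0.01
JITTER_GYRO_DPS = 1.0
#: Per-level scaling half-range: factor ~ U(1 - 0.05 L, 1 + 0.05 L).
SCALE_HALF_RANGE = 0.05
#: Per-level time-warp knot displacement, as a fraction of the window.
WARP_SIGMA = 0.05
_WARP_KNOTS = np.array([0.2, 0.4, 0.6, 0.8])


def _jitter(x: np.ndarray, level: int, rng: np.random.Generator) -> np.ndarray:
    out = x.copy()
    out[:, :3] += rng.normal(0.0, JITTER_ACCEL_G * level, size=(len(x), 3))
    out[:, 3:] += rng.normal(0.0, JITTER_GYRO_DPS * level, size=(len(x), 3))
    return out


def _scale(x: np.ndarray, level: int, rng: np.random.Generator) -> np.ndarray:
    factor = rng.uniform(1.0 - SCALE_HALF_RANGE * level,
                         1.0 + SCALE_HALF_RANGE * level)
    return x * factor


def _time_warp(x: np.ndarray, level: int, rng: np.random.Generator) -> np.ndarray:
    """Smooth monotone re-timing then cubic resampling back to 40 samples."""
    n = len(x)
    displaced = _WARP_KNOTS + rng.normal(0.0, WARP_SIGMA * level, size=4)
    displaced = np.sort(np.clip(displaced, 0.02, 0.98))
    # enforce strict monotonicity of the knot sequence
    for i in range(1, 4):
        displaced[i] = max(displaced[i], displaced[i - 1] + 1e-3)
    warp = interpolate.PchipInterpolator(
        np.concatenate([[0.0], _WARP_KNOTS, [1.0]]),
        np.concatenate([[0.0], displaced, [1.0]]))
    u = np.arange(n) / (n - 1)
    src = np.clip(warp(u) * (n - 1), 0.0, n - 1)
    spline = interpolate.CubicSpline(np.arange(n), x, axis=0)
    return spline(src)


_TRANSFORMS = (_jitter, _scale, _time_warp)


def augment(train: list[LabeledWindow], level: int = 2,
            seed: int = 0) -> list[LabeledWindow]:
    """Return originals plus three transformed copies per input window.

    One copy each of jittering, scaling, and temporal warping at the given
    intensity level (1..4); copies keep the label and are marked
    ``origin="augmented"``.  Deterministic under the seed.
    """
    if level not in (1, 2, 3, 4):
        raise ParameterError(f"augmentation level must be in 1..4, got {level}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), level, 0xA06]))
    out = list(train)
    for lw in train:
        for transform in _TRANSFORMS:
            samples = transform(lw.window.samples, level, rng)
            out.append(LabeledWindow(
                window=replace(lw.window, samples=samples),
                label=lw.label,
                origin="augmented"))
    return out


# ---------------------------------------------------------------------------
# Stratified splitting


def stratified_split(windows: list[LabeledWindow], test_fraction: float = 0.2,
                     seed: int = 0) -> tuple[list[LabeledWindow], list[LabeledWindow]]:
    """Split into train/test preserving class proportions.

    Per-class test counts follow largest-remainder rounding so the total
    equals ``round(N * test_fraction)``.  Augmented windows always go to
    the training side; the original windows are partitioned exhaustively.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ParameterError(f"test_fraction must be in (0, 1), got {test_fraction}")
    originals = [w for w in windows if w.origin == "real"]
    augmented = [w for w in windows if w.origin != "real"]
    labels = sorted({w.label for w in originals}, key=CLASSES.index)
    by_class = {c: [w for w in originals if w.label == c] for c in labels}
    for c, ws in by_class.items():
        if len(ws) < 2:
            raise StratificationError(f"class {c} has {len(ws)} window(s); need >= 2")
    n = len(originals)
    target_total = int(round(n * test_fraction))
    quotas = {c: len(ws) * test_fraction for c, ws in by_class.items()}
    take = {c: int(np.floor(q)) for c, q in quotas.items()}
    leftovers = sorted(labels, key=lambda c: (-(quotas[c] - take[c]), labels.index(c)))
    for c in leftovers[: target_total - sum(take.values())]:
        take[c] += 1
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x59117]))
    train: list[LabeledWindow] = []
    test: list[LabeledWindow] = []
    for c in labels:
        ws = by_class[c]
        order = rng.permutation(len(ws))
        test.extend(ws[i] for i in order[: take[c]])
        train.extend(ws[i] for i in order[take[c]:])
    train.extend(augmented)
    return train, test
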