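"""Annotated IMU recording I/O.

A recording is one CSV file per trial: ``#``-prefixed ``key=value`` header
lines carrying the event annotation, then a header row ``t,ax,ay,az,gx,gy,gz``
and one sample per row.  Acceleration is in g (specific force, ±16 g full
scale), angular rate in deg/s (±2000 deg/s), time in seconds on an exact
1/40 s grid.  Numeric fields are written with 17 significant digits so a
write/read round trip is bit-identical.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AnnotationError, FormatError, IntegrityError, ValidationError

#: Canonical class labels, in fixed order.
CLASSES = ("NON_FALL", "SLF", "FFH")
FALL_CLASSES = ("SLF", "FFH")

SAMPLE_COLUMNS = ("t", "ax", "ay", "az", "gx", "gy", "gz")
ACCEL_COLUMNS = ("ax", "ay", "az")
GYRO_COLUMNS = ("gx", "gy", "gz")

SAMPLE_RATE_HZ = 40
ACCEL_FULL_SCALE_G = 16.0
GYRO_FULL_SCALE_DPS = 2000.0
#: Tolerance when checking that timestamps sit on the 1/40 s grid (seconds).
TIME_GRID_TOL = 1e-6


@dataclass(frozen=True)
class EventAnnotation:
    """Event annotation for one trial.

    ``loss_of_balance_t``/``impact_t`` delimit the critical phase (from the
    moment of balance loss to ground impact) and are present iff the class
    is a fall class.
    """

    klass: str
    subtype: str
    active_start: float
    active_end: float
    loss_of_balance_t: float | None = None
    impact_t: float | None = None

    @property
    def is_fall(self) -> bool:
        return self.klass in FALL_CLASSES

    @property
    def critical_duration(self) -> float | None:
        if self.loss_of_balance_t is None or self.impact_t is None:
            return None
        return self.impact_t - self.loss_of_balance_t


@dataclass(frozen=True)
class Violation:
    """One invariant violation: which invariant, where, and a message."""

    invariant: str
    index: int | None
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        where = f" at index {self.index}" if self.index is not None else ""
        return f"[{self.invariant}]{where}: {self.message}"


@dataclass
class ImuRecording:
    """One annotated 40 Hz recording: samples table plus event annotation."""

    recording_id: str
    subject_id: str
    samples: pd.DataFrame = field(repr=False)
    annotation: EventAnnotation
    sample_rate_hz: int = SAMPLE_RATE_HZ

    def __post_init__(self) -> None:
        self.samples = self.samples.reset_index(drop=True)

    @property
    def t(self) -> np.ndarray:
        return self.samples["t"].to_numpy()

    @property
    def signal(self) -> np.ndarray:
        """(n, 6) array of ax, ay, az, gx, gy, gz."""
        return self.samples[list(ACCEL_COLUMNS + GYRO_COLUMNS)].to_numpy()

    def __len__(self) -> int:
        return len(self.samples)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ImuRecording):
            return NotImplemented
        return (
            self.recording_id == other.recording_id
            and self.subject_id == other.subject_id
            and self.sample_rate_hz == other.sample_rate_hz
            and self.annotation == other.annotation
            and self.samples.shape == other.samples.shape
            and bool(
                (self.samples[list(SAMPLE_COLUMNS)].to_numpy()
                 == other.samples[list(SAMPLE_COLUMNS)].to_numpy()).all()
            )
        )


# ---------------------------------------------------------------------------
# Validation


def validate_recording(rec: ImuRecording) -> list[Violation]:
    """Check all recording invariants; return violations, never raise.

    Sample-level violations come first, ordered by sample index;
    annotation-level violations follow.  A pure function: identical input
    yields an identical list.
    """
    out: list[Violation] = []
    n = len(rec)
    if n == 0:
        return [Violation("non_empty", None, "recording has no samples")]

    t = rec.t
    dt = 1.0 / rec.sample_rate_hz

    sample_viols: list[Violation] = []
    off_grid = np.abs(t / dt - np.round(t / dt)) > TIME_GRID_TOL * rec.sample_rate_hz
    for i in np.nonzero(off_grid)[0]:
        sample_viols.append(
            Violation("time_grid", int(i),
                      f"t={t[i]!r} is not a multiple of 1/{rec.sample_rate_hz} s")
        )
    gaps = np.abs(np.diff(t) - dt) > TIME_GRID_TOL
    for i in np.nonzero(gaps)[0]:
        sample_viols.append(
            Violation("time_step", int(i + 1),
                      f"t jumps from {t[i]!r} to {t[i + 1]!r} (expected step {dt} s)")
        )

    sig = rec.samples[list(SAMPLE_COLUMNS)].to_numpy()
    bad = ~np.isfinite(sig)
    for i in np.unique(np.nonzero(bad)[0]):
        cols = [SAMPLE_COLUMNS[j] for j in np.nonzero(bad[i])[0]]
        sample_viols.append(
            Violation("finite", int(i), f"non-finite value in column(s) {cols}")
        )

    acc = rec.samples[list(ACCEL_COLUMNS)].to_numpy()
    gyr = rec.samples[list(GYRO_COLUMNS)].to_numpy()
    with np.errstate(invalid="ignore"):
        acc_over = np.abs(acc) > ACCEL_FULL_SCALE_G
        gyr_over = np.abs(gyr) > GYRO_FULL_SCALE_DPS
    for i in np.unique(np.nonzero(acc_over)[0]):
        cols = [ACCEL_COLUMNS[j] for j in np.nonzero(acc_over[i])[0]]
        sample_viols.append(
            Violation("accel_full_scale", int(i),
                      f"|{'/'.join(cols)}| exceeds {ACCEL_FULL_SCALE_G} g")
        )
    for i in np.unique(np.nonzero(gyr_over)[0]):
        cols = [GYRO_COLUMNS[j] for j in np.nonzero(gyr_over[i])[0]]
        sample_viols.append(
            Violation("gyro_full_scale", int(i),
                      f"|{'/'.join(cols)}| exceeds {GYRO_FULL_SCALE_DPS} deg/s")
        )

    sample_viols.sort(key=lambda v: (v.index, v.invariant))
    out.extend(sample_viols)
    out.extend(_validate_annotation(rec.annotation))

    ann = rec.annotation
    if not out or all(v.invariant != "time_step" for v in out):
        in_seg = np.count_nonzero(
            (t >= ann.active_start - TIME_GRID_TOL) & (t <= ann.active_end + TIME_GRID_TOL)
        )
        if in_seg < rec.sample_rate_hz:
            out.append(
                Violation("active_segment_length", None,
                          f"only {in_seg} samples inside the active segment "
                          f"(need >= {rec.sample_rate_hz})")
            )
    return out


def _validate_annotation(ann: EventAnnotation) -> list[Violation]:
    out: list[Violation] = []
    if ann.klass not in CLASSES:
        out.append(Violation("annotation_class", None,
                             f"unknown class {ann.klass!r}; expected one of {CLASSES}"))
        return out
    if ann.klass == "NON_FALL":
        if ann.loss_of_balance_t is not None or ann.impact_t is not None:
            out.append(Violation(
                "annotation_consistency", None,
                "NON_FALL recordings must not carry loss_of_balance_t/impact_t"))
    else:
        if ann.loss_of_balance_t is None or ann.impact_t is None:
            out.append(Violation(
                "annotation_consistency", None,
                f"{ann.klass} recordings require loss_of_balance_t and impact_t"))
        else:
            if not (ann.active_start <= ann.loss_of_balance_t
                    < ann.impact_t <= ann.active_end):
                out.append(Violation(
                    "annotation_ordering", None,
                    "require active_start <= loss_of_balance_t < impact_t <= active_end "
                    f"(got {ann.active_start}, {ann.loss_of_balance_t}, "
                    f"{ann.impact_t}, {ann.active_end})"))
    if not ann.active_end > ann.active_start:
        out.append(Violation("annotation_segment", None,
                             "active_end must exceed active_start"))
    return out


# ---------------------------------------------------------------------------
# Read / write

_META_STR = ("recording_id", "subject_id", "klass", "subtype")
_META_FLOAT = ("active_start", "active_end", "loss_of_balance_t", "impact_t")


def write_recording(rec: ImuRecording, path: str | Path) -> None:
    """Write a recording to ``path``; refuse invalid input.

    Raises :class:`ValidationError` on empty or non-finite samples and on
    any other invariant violation, so files on disk are always valid.
    """
    viols = validate_recording(rec)
    if viols:
        raise ValidationError(
            "refusing to write invalid recording: " + "; ".join(map(str, viols[:5])))
    ann = rec.annotation
    lines = [
        f"# recording_id={rec.recording_id}",
        f"# subject_id={rec.subject_id}",
        f"# sample_rate_hz={rec.sample_rate_hz}",
        f"# klass={ann.klass}",
        f"# subtype={ann.subtype}",
        f"# active_start={ann.active_start:.17g}",
        f"# active_end={ann.active_end:.17g}",
    ]
    if ann.loss_of_balance_t is not None:
        lines.append(f"# loss_of_balance_t={ann.loss_of_balance_t:.17g}")
    if ann.impact_t is not None:
        lines.append(f"# impact_t={ann.impact_t:.17g}")
    buf = _stdio.StringIO()
    rec.samples[list(SAMPLE_COLUMNS)].to_csv(buf, index=False, float_format="%.17g")
    Path(path).write_text("\n".join(lines) + "\n" + buf.getvalue())


def read_recording(path: str | Path) -> ImuRecording:
    """Read and validate one annotated recording file."""
    path = Path(path)
    meta: dict[str, str] = {}
    body: list[str] = []
    for line in path.read_text().splitlines():
        if line.startswith("#"):
            key, _, value = line.lstrip("# ").partition("=")
            meta[key.strip()] = value.strip()
        elif line.strip():
            body.append(line)
    if not body:
        raise FormatError(f"{path}: no sample table found")
    for key in _META_STR[2:] + ("active_start", "active_end"):
        if key not in meta:
            raise FormatError(f"{path}: missing annotation key {key!r}")
    try:
        table = pd.read_csv(_stdio.StringIO("\n".join(body)),
                            float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - defensive
        raise FormatError(f"{path}: cannot parse sample table ({exc})") from exc
    for col in SAMPLE_COLUMNS:
        if col not in table.columns:
            raise FormatError(f"{path}: missing sample column {col!r}")

    def _f(key: str) -> float | None:
        return float(meta[key]) if key in meta else None

    ann = EventAnnotation(
        klass=meta["klass"],
        subtype=meta["subtype"],
        active_start=float(meta["active_start"]),
        active_end=float(meta["active_end"]),
        loss_of_balance_t=_f("loss_of_balance_t"),
        impact_t=_f("impact_t"),
    )
    rec = ImuRecording(
        recording_id=meta.get("recording_id", path.stem),
        subject_id=meta.get("subject_id", "unknown"),
        samples=table[list(SAMPLE_COLUMNS)],
        annotation=ann,
        sample_rate_hz=int(meta.get("sample_rate_hz", SAMPLE_RATE_HZ)),
    )
    viols = validate_recording(rec)
    if viols:
        first = viols[0]
        msg = f"{path}: {'; '.join(str(v) for v in viols[:5])}"
        if first.invariant in ("time_grid", "time_step"):
            raise IntegrityError(msg)
        if first.invariant.startswith("annotation"):
            raise AnnotationError(msg)
        raise ValidationError(msg)
    return rec
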