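"""Synthetic annotated IMU recordings for the three event classes.

The study dataset behind this pipeline (waist-mounted IMU, 40 Hz, non-fall
construction activities vs. same-level-fall and fall-from-height critical
phases) is not publicly deposited, so this module generates recordings with
the same morphological structure at the SMV/orientation level:

* ``NON_FALL`` — specific force fluctuating about 1 g during the active
  segment; high-vibration tool subtypes add a 12-18 Hz component; jump
  subtypes contain a brief sub-0.5 g flight dip followed by a >2 g landing
  spike.
* ``SLF`` — gait or stance, then a critical phase of 0.25-0.6 s in which
  the trunk tilts past 30 deg while the SMV decays below 0.8 g, then a
  >3 g impact and a quiet post-fall phase.
* ``FFH`` — stance, then a near-ballistic free-fall critical phase whose
  duration is sqrt(2 h / g) for the drop height h (SMV < 0.2 g throughout),
  then a >3 g impact.

Only morphological fidelity is attempted, not biomechanical realism: the
generated windows exercise every downstream stage and are separable by
construction, which real construction-site data is not.

Seed discipline: one master seed; each recording derives its own
``SeedSequence`` from ``(master, class hash, subtype hash, index)`` so that
changing the dataset composition never reshuffles earlier recordings.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .io import CLASSES, EventAnnotation, ImuRecording, SAMPLE_COLUMNS, SAMPLE_RATE_HZ

#: Standard gravity used for the free-fall closed form, m/s^2.
GRAVITY_M_S2 = 9.81

#: Study drop heights in meters.
FFH_HEIGHTS_M = (0.5, 0.7, 0.85, 2.0)

#: Study class composition (non-fall : SLF : FFH sample counts).
STUDY_CLASS_COUNTS = {"NON_FALL": 5991, "SLF": 1630, "FFH": 729}


def free_fall_duration(height_m: float) -> float:
    """Free-fall time sqrt(2 h / g) in seconds for a drop from ``height_m``."""
    if not height_m > 0:
        raise ValueError(f"height must be positive, got {height_m}")
    return float(np.sqrt(2.0 * height_m / GRAVITY_M_S2))


# ---------------------------------------------------------------------------
# Subtype tables.  Amplitudes are in g, rates in deg/s, durations in seconds.
# These are package choices (the study reports no quantitative signal model);
# see docs/methods.md for the rationale behind each number.

NON_FALL_SUBTYPES: dict[str, dict] = {
    # construction activities
    "painting":            {"kind": "work", "freq": 1.2, "amp": 0.08},
    "bricklaying":         {"kind": "work", "freq": 0.8, "amp": 0.12},
    "front lifting":       {"kind": "bend", "tilt": 25.0},
    "back lifting":        {"kind": "bend", "tilt": 20.0},
    "wood planing":        {"kind": "work", "freq": 1.5, "amp": 0.15},
    "elevator ascending":  {"kind": "elevator", "sign": +1},
    "elevator descending": {"kind": "elevator", "sign": -1},
    "hammering":           {"kind": "impulsive", "freq": 2.0, "amp": 0.8},
    "screw driving":       {"kind": "vibration", "freq": 13.5, "amp": 0.2},
    "drilling":            {"kind": "vibration", "freq": 15.0, "amp": 0.35},
    "vertical jumping":    {"kind": "jump", "flight_s": 0.20},
    "jumping from 0.7 m":  {"kind": "jump", "flight_s": 0.25},
    "jumping from 0.85 m": {"kind": "jump", "flight_s": 0.30},
    # daily activities needed as quiet/locomotion baselines
    "standing":            {"kind": "static", "sigma": 0.015},
    "walking":             {"kind": "gait", "freq": 2.0, "amp": 0.12},
}

SLF_SUBTYPES: dict[str, dict] = {
    "forward trip":               {"duration_s": 0.40, "axis": "pitch", "sign": +1},
    "backward slip":              {"duration_s": 0.35, "axis": "pitch", "sign": -1},
    "forward fall":               {"duration_s": 0.40, "axis": "pitch", "sign": +1},
    "backward fall":              {"duration_s": 0.40, "axis": "pitch", "sign": -1},
    "leftward fall":              {"duration_s": 0.45, "axis": "roll", "sign": -1},
    "rightward fall":             {"duration_s": 0.45, "axis": "roll", "sign": +1},
    "fall while standing":        {"duration_s": 0.50, "axis": "pitch", "sign": +1},
    "sitting on empty chair":     {"duration_s": 0.30, "axis": "pitch", "sign": -1},
    "forward fall while walking": {"duration_s": 0.40, "axis": "pitch", "sign": +1},
    "backward fall while walking": {"duration_s": 0.35, "axis": "pitch", "sign": -1},
}

FFH_SUBTYPES: dict[str, dict] = {
    f"{direction} {h} m": {"height_m": h, "axis": "pitch",
                             "sign": +1 if direction == "forward" else -1}
    for h in FFH_HEIGHTS_M for direction in ("forward", "backward")
}

SUBTYPES: dict[str, dict[str, dict]] = {
    "NON_FALL": NON_FALL_SUBTYPES,
    "SLF": SLF_SUBTYPES,
    "FFH": FFH_SUBTYPES,
}

#: Channel noise (additive, Gaussian, per sample).
ACCEL_NOISE_G = 0.03
GYRO_NOISE_DPS = 2.0


@dataclass(frozen=True)
class GeneratorSpec:
    """Counts per (class, subtype) plus the master seed."""

    counts: dict[tuple[str, str], int]
    seed: int = 0
    sample_rate_hz: int = SAMPLE_RATE_HZ

    def __post_init__(self) -> None:
        for (klass, subtype), n in self.counts.items():
            if n < 0:
                raise ConfigurationError(f"negative count for {(klass, subtype)}")
            _subtype_params(klass, subtype)  # raises on unknown subtype

    @property
    def class_counts(self) -> dict[str, int]:
        out = {k: 0 for k in CLASSES}
        for (klass, _), n in self.counts.items():
            out[klass] += n
        return out

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @classmethod
    def balanced(cls, n_non_fall: int, n_slf: int, n_ffh: int,
                 seed: int = 0) -> "GeneratorSpec":
        """Spread per-class totals across all subtypes by largest remainder."""
        counts: dict[tuple[str, str], int] = {}
        for klass, total in (("NON_FALL", n_non_fall), ("SLF", n_slf), ("FFH", n_ffh)):
            names = list(SUBTYPES[klass])
            quota = total / len(names)
            base = [int(np.floor(quota))] * len(names)
            rem = total - sum(base)
            for i in range(rem):
                base[i] += 1
            for name, n in zip(names, base):
                counts[(klass, name)] = n
        return cls(counts=counts, seed=seed)

    @classmethod
    def study_scaled(cls, factor: float, seed: int = 0) -> "GeneratorSpec":
        """Class totals at the study's 5991:1630:729 ratio times ``factor``."""
        return cls.balanced(
            *(int(round(STUDY_CLASS_COUNTS[k] * factor)) for k in CLASSES), seed=seed)


def _subtype_params(klass: str, subtype: str) -> dict:
    if klass not in SUBTYPES:
        raise ConfigurationError(f"unknown class {klass!r}")
    try:
        params = SUBTYPES[klass][subtype]
    except KeyError:
        raise ConfigurationError(
            f"unknown {klass} subtype {subtype!r}; known: {sorted(SUBTYPES[klass])}"
        ) from None
    if klass == "FFH" and not (0.5 <= params["height_m"] <= 2.0):
        raise ConfigurationError("FFH drop height must lie in [0.5, 2.0] m")
    if klass == "SLF" and not (0.25 <= params["duration_s"] <= 0.6):
        raise ConfigurationError("SLF critical duration must lie in [0.25, 0.6] s")
    return params


# ---------------------------------------------------------------------------
# Signal construction


def _tilt_accel(theta_deg: np.ndarray, axis: str, sign: int) -> np.ndarray:
    """Gravity vector in the sensor frame after tilting by theta about one axis.

    At rest gravity reads (0, 0, 1) g.  A roll tilt moves it into the y/z
    plane, a pitch tilt into the x/z plane (sign convention matching the
    roll = atan2(ay, az), pitch = atan2(-ax, sqrt(ay^2+az^2)) estimators).
    """
    th = np.radians(theta_deg)
    n = len(th)
    out = np.zeros((n, 3))
    if axis == "roll":
        out[:, 1] = sign * np.sin(th)
        out[:, 2] = np.cos(th)
    else:  # pitch
        out[:, 0] = -sign * np.sin(th)
        out[:, 2] = np.cos(th)
    return out


def _gait(n: int, rng: np.random.Generator, freq: float = 2.0,
          amp: float = 0.12) -> tuple[np.ndarray, np.ndarray]:
    """Walking-like baseline: vertical bounce at step frequency, mild sway."""
    t = np.arange(n) / SAMPLE_RATE_HZ
    phase = rng.uniform(0, 2 * np.pi)
    acc = np.zeros((n, 3))
    acc[:, 2] = 1.0 + amp * np.sin(2 * np.pi * freq * t + phase)
    acc[:, 0] = 0.4 * amp * np.sin(2 * np.pi * freq * t + phase + 1.1)
    acc[:, 1] = 0.3 * amp * np.sin(np.pi * freq * t + phase)
    gyr = np.zeros((n, 3))
    gyr[:, 0] = 25.0 * np.sin(np.pi * freq * t + phase)
    gyr[:, 2] = 15.0 * np.sin(np.pi * freq * t + phase + 0.7)
    return acc, gyr


def _stance(n: int) -> tuple[np.ndarray, np.ndarray]:
    acc = np.zeros((n, 3))
    acc[:, 2] = 1.0
    return acc, np.zeros((n, 3))


def _non_fall_segment(subtype: str, params: dict,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, float]:
    """Return (accel, gyro, noise sigma) for one non-fall active segment."""
    kind = params["kind"]
    n = int(round(rng.uniform(4.0, 6.0) * SAMPLE_RATE_HZ))
    t = np.arange(n) / SAMPLE_RATE_HZ
    sigma = params.get("sigma", ACCEL_NOISE_G)
    if kind == "static":
        acc, gyr = _stance(n)
    elif kind == "gait":
        acc, gyr = _gait(n, rng, params["freq"], params["amp"])
    elif kind == "work":
        acc, gyr = _stance(n)
        phase = rng.uniform(0, 2 * np.pi)
        acc[:, 0] += params["amp"] * np.sin(2 * np.pi * params["freq"] * t + phase)
        acc[:, 2] += 0.5 * params["amp"] * np.sin(2 * np.pi * params["freq"] * t)
        gyr[:, 1] = 20.0 * np.sin(2 * np.pi * params["freq"] * t + phase)
    elif kind == "bend":
        acc, gyr = _stance(n)
        tilt = params["tilt"] * np.sin(np.pi * t / t[-1]) ** 2
        acc[:n] = _tilt_accel(tilt, "pitch", +1)
        gyr[:, 1] = np.gradient(tilt, 1.0 / SAMPLE_RATE_HZ)
    elif kind == "elevator":
        acc, gyr = _stance(n)
        ramp = 0.08 * params["sign"]
        k = n // 5
        acc[:k, 2] += ramp
        acc[-k:, 2] -= ramp
    elif kind == "impulsive":
        acc, gyr = _stance(n)
        period = int(SAMPLE_RATE_HZ / params["freq"])
        for start in range(period // 2, n - 2, period):
            acc[start:start + 2, 2] += params["amp"] * np.array([1.0, 0.45])
        gyr[:, 1] = 15.0 * np.sin(2 * np.pi * params["freq"] * t)
    elif kind == "vibration":
        acc, gyr = _stance(n)
        f = params["freq"] + rng.uniform(-1.5, 1.5)  # keeps f inside 12-18 Hz
        phase = rng.uniform(0, 2 * np.pi)
        for ax_i, gain in ((0, 1.0), (1, 0.6), (2, 0.8)):
            acc[:, ax_i] += gain * params["amp"] * np.sin(
                2 * np.pi * f * t + phase + ax_i)
        gyr[:, 0] = 10.0 * np.sin(2 * np.pi * f * t + phase)
    elif kind == "jump":
        acc, gyr = _stance(n)
        flight = max(2, int(round(params["flight_s"] * SAMPLE_RATE_HZ)))
        start = rng.integers(n // 3, n // 2)
        crouch = 6
        acc[start - crouch:start, 2] = 0.75          # takeoff crouch
        acc[start:start + 3, 2] = 1.8                # push-off
        # flight: partially ballistic (limbs moving, so not free-fall clean)
        acc[start + 3:start + 3 + flight, 2] = 0.35
        land = start + 3 + flight
        acc[land:land + 2, 2] = rng.uniform(2.3, 3.0)  # landing spike > 2 g
        gyr[:, 1] = 20.0 * np.sin(2 * np.pi * 1.0 * t)
    else:  # pragma: no cover - table is closed
        raise ConfigurationError(f"unknown non-fall kind {kind!r}")
    return acc, gyr, sigma


def generate_recording(klass: str, subtype: str, seed: int | np.random.SeedSequence,
                       recording_id: str | None = None,
                       subject_id: str | None = None) -> ImuRecording:
    """Generate one annotated recording of the given class and subtype."""
    params = _subtype_params(klass, subtype)
    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    else:
        ss = np.random.SeedSequence([int(seed), _h(klass), _h(subtype)])
    rng = np.random.default_rng(ss)
    # Subject-level gain on the dynamic (non-gravity) part of the signal:
    # models movement-intensity variability without breaking the 1 g rest level.
    gain = rng.uniform(0.9, 1.1)

    lob_i: int | None = None
    impact_i: int | None = None
    if klass == "NON_FALL":
        acc, gyr, sigma = _non_fall_segment(subtype, params, rng)
    else:
        sigma = ACCEL_NOISE_G
        if klass == "SLF":
            n_pre = int(rng.integers(60, 101))
            pre_acc, pre_gyr = _gait(n_pre, rng)
            n_crit = int(round(params["duration_s"] * SAMPLE_RATE_HZ))
            theta_max = rng.uniform(50.0, 70.0)
            # linear tilt ramp: sustained angular rate from the first critical
            # sample, well above any non-fall activity
            theta = theta_max * (np.arange(n_crit) + 1) / n_crit
            crit_acc = _tilt_accel(theta, params["axis"], params["sign"])
            decay = 0.85 - 0.35 * (np.arange(n_crit) + 1) / n_crit
            crit_acc *= decay[:, None]
            crit_gyr = np.zeros((n_crit, 3))
            rate = theta_max / params["duration_s"]
        else:  # FFH
            n_pre = int(rng.integers(40, 81))
            pre_acc, pre_gyr = _stance(n_pre)
            n_crit = int(round(free_fall_duration(params["height_m"]) * SAMPLE_RATE_HZ))
            # near-ballistic: specific force ~ 0 during free fall
            crit_acc = np.zeros((n_crit, 3))
            crit_gyr = np.zeros((n_crit, 3))
            theta_max = rng.uniform(40.0, 70.0)
            rate = rng.uniform(80.0, 200.0)
        gyr_axis = 0 if params["axis"] == "roll" else 1
        crit_gyr[:, gyr_axis] = params["sign"] * rate
        # impact spike then quiet lying posture
        n_imp, n_post = 3, SAMPLE_RATE_HZ
        imp_acc = np.zeros((n_imp, 3))
        imp_acc[:, 2] = rng.uniform(3.5, 5.0) * np.array([1.0, 0.6, 0.3])
        imp_gyr = np.zeros((n_imp, 3))
        imp_gyr[:, gyr_axis] = params["sign"] * rate * np.array([1.0, 0.4, 0.1])
        post_acc = np.tile(_tilt_accel(np.array([theta_max]), params["axis"],
                                       params["sign"]), (n_post, 1))
        post_gyr = np.zeros((n_post, 3))
        acc = np.vstack([pre_acc, crit_acc, imp_acc, post_acc])
        gyr = np.vstack([pre_gyr, crit_gyr, imp_gyr, post_gyr])
        lob_i = n_pre
        impact_i = n_pre + n_crit

    n = len(acc)
    gravity = np.zeros((n, 3))
    gravity[:, 2] = 1.0
    acc = gravity + gain * (acc - gravity)
    gyr = gain * gyr
    if klass == "FFH":
        # ballistic flight: specific force is zero regardless of subject gain
        acc[lob_i:impact_i] = 0.0
    acc = acc + rng.normal(0.0, sigma, size=acc.shape)
    gyr = gyr + rng.normal(0.0, GYRO_NOISE_DPS, size=gyr.shape)
    np.clip(acc, -16.0, 16.0, out=acc)
    np.clip(gyr, -2000.0, 2000.0, out=gyr)

    t = np.arange(n) / SAMPLE_RATE_HZ
    ann = EventAnnotation(
        klass=klass,
        subtype=subtype,
        active_start=0.0,
        active_end=float(t[-1]),
        loss_of_balance_t=None if lob_i is None else float(t[lob_i]),
        impact_t=None if impact_i is None else float(t[impact_i]),
    )
    samples = pd.DataFrame(
        np.column_stack([t, acc, gyr]), columns=list(SAMPLE_COLUMNS))
    return ImuRecording(
        recording_id=recording_id or f"{klass}:{subtype}:{ss.entropy}",
        subject_id=subject_id or f"synthetic-{_h(subtype) % 48:02d}",
        samples=samples,
        annotation=ann,
    )


def _h(s: str) -> int:
    """Stable 32-bit hash for seed derivation (composition-independent)."""
    return zlib.crc32(s.encode())


def generate_dataset(spec: GeneratorSpec) -> list[ImuRecording]:
    """Generate exactly the requested counts, deterministically under the seed.

    Each recording's sub-seed depends only on (master seed, class, subtype,
    index within subtype), so adding subtypes or counts never changes
    previously generated recordings.
    """
    out: list[ImuRecording] = []
    for klass in CLASSES:
        for subtype in SUBTYPES[klass]:
            n = spec.counts.get((klass, subtype), 0)
            for i in range(n):
                ss = np.random.SeedSequence(
                    [int(spec.seed), _h(klass), _h(subtype), i])
                out.append(generate_recording(
                    klass, subtype, ss,
                    recording_id=f"{klass}|{subtype}|{i:04d}",
                    subject_id=f"synthetic-{(i + _h(subtype)) % 48:02d}"))
    return out


# ---------------------------------------------------------------------------
# Planted-signal feature data (for selection / training diagnostics)


def planted_feature_matrix(n: int = 600, n_noise: int = 20, seed: int = 0,
                           class_proportions: tuple[float, float, float] = (0.6, 0.25, 0.15)):
    """Feature matrix in which a single planted feature determines the class.

    The ``planted_signal`` column equals the class index plus small noise
    (strong separation); the remaining ``noise_XX`` columns are independent
    standard normals.  Used to validate feature selection and training on a
    problem whose answer is known by construction.
    """
    from .features import FeatureMatrix  # local import to avoid a cycle

    if n < 10:
        raise ValidationError("need at least 10 rows")
    rng = np.random.default_rng(np.random.SeedSequence([seed, _h("planted")]))
    counts = [int(round(p * n)) for p in class_proportions]
    counts[0] = n - sum(counts[1:])
    y = np.repeat(list(CLASSES), counts)
    rng.shuffle(y)
    class_idx = np.array([CLASSES.index(c) for c in y], dtype=float)
    signal = class_idx + rng.normal(0.0, 0.05, size=n)
    X = pd.DataFrame({"planted_signal": signal})
    for j in range(n_noise):
        X[f"noise_{j:02d}"] = rng.normal(size=n)
    # a constant column exercises the permutation-invariance guarantee
    X["constant"] = 1.0
    return FeatureMatrix(X=X, y=np.asarray(y, dtype=object))
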