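"""End-to-end orchestration: simulate -> preprocess -> extract -> select ->
train -> evaluate, with per-stage artifacts, a checksum manifest, and a
deterministic report.

Every otherwise-undocumented default lives in :class:`PipelineConfig` so the full
set of package choices is inspectable at run time.  ``report.json`` is
bit-identical across reruns with the same config and seed; wall-clock
quantities (latency, stage timings) go to ``manifest.json`` instead.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .evaluation import cross_validate, lead_time_summary, measure_latency
from .features import FEATURE_NAMES, build_matrix, extract_feature_frame
from .io import CLASSES, write_recording
from .model import FallDetectionModel
from .preprocessing import preprocess_recording
from .synthetic import GeneratorSpec, generate_dataset

log = logging.getLogger("fallsense")


@dataclass
class PipelineConfig:
    """All tunables of one end-to-end run, with documented defaults."""

    # generator: recording counts per class (study ratio scaled by 1/10)
    n_non_fall: int = 600
    n_slf: int = 160
    n_ffh: int = 72
    # preprocessing
    stride: int = 40
    median_kernel: int = 5
    augment_level: int | None = 2
    test_fraction: float = 0.2
    # selection
    selection_mode: str = "ensemble"
    alpha: float = 0.05
    pfi_repeats: int = 10
    # training
    backend: str = "xgb"
    n_trials: int = 25
    params: dict | str | None = None  # None + n_trials>0 => search
    # evaluation
    k_folds: int = 5
    vote: int = 1
    measure_latency: bool = True
    # reproducibility
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ConfigurationError(
                f"test_fraction must be in (0, 1), got {self.test_fraction}")
        if self.median_kernel % 2 == 0 or self.median_kernel < 1:
            raise ConfigurationError("median_kernel must be a positive odd integer")
        if self.augment_level is not None and self.augment_level not in (1, 2, 3, 4):
            raise ConfigurationError("augment_level must be None or 1..4")
        if self.stride < 1:
            raise ConfigurationError("stride must be >= 1")
        if min(self.n_non_fall, self.n_slf, self.n_ffh) < self.k_folds:
            raise ConfigurationError("every class needs >= k_folds recordings")
        if self.backend not in ("xgb", "lgbm", "cat"):
            raise ConfigurationError(f"unknown backend {self.backend!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True))


def run_pipeline(config: PipelineConfig, out_dir: str | Path,
                 write_recordings: bool = False) -> dict:
    """Execute every stage; persist artifacts + manifest; return the report.

    Stages: simulate (synthetic recordings), preprocess (windows),
    extract (feature table), cross-validated select/train/evaluate, and a
    lead-time replay of a final model on held-out fall recordings.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "checksums": {}}
    t_start = time.perf_counter()

    def stage_done(name: str, **info) -> None:
        manifest["stages"][name] = {
            "elapsed_s": round(time.perf_counter() - t_start, 3), **info}
        log.info("stage %s done: %s", name, info)

    # -- simulate -----------------------------------------------------------
    spec = GeneratorSpec.balanced(config.n_non_fall, config.n_slf, config.n_ffh,
                                  seed=config.seed)
    recordings = generate_dataset(spec)
    if write_recordings:
        rec_dir = out / "recordings"
        rec_dir.mkdir(exist_ok=True)
        for rec in recordings:
            safe = rec.recording_id.replace("|", "_").replace(" ", "-")
            write_recording(rec, rec_dir / f"{safe}.csv")
    stage_done("simulate", n_recordings=len(recordings),
               class_counts=spec.class_counts)

    # -- hold out recordings for the lead-time replay ----------------------
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xD0]))
    by_class: dict[str, list[int]] = {c: [] for c in CLASSES}
    for i, rec in enumerate(recordings):
        by_class[rec.annotation.klass].append(i)
    replay_idx: list[int] = []
    train_idx: list[int] = []
    for c, idxs in by_class.items():
        idxs = list(rng.permutation(idxs))
        n_hold = max(2, int(round(config.test_fraction * len(idxs))))
        replay_idx.extend(idxs[:n_hold])
        train_idx.extend(idxs[n_hold:])
    replay_recs = [recordings[i] for i in sorted(replay_idx)]
    train_recs = [recordings[i] for i in sorted(train_idx)]

    # -- preprocess ---------------------------------------------------------
    windows = []
    for rec in train_recs:
        windows.extend(preprocess_recording(rec, stride=config.stride,
                                            kernel=config.median_kernel))
    win_counts = {c: sum(1 for w in windows if w.label == c) for c in CLASSES}
    stage_done("preprocess", n_windows=len(windows), window_counts=win_counts)

    # -- extract ------------------------------------------------------------
    matrix = build_matrix(windows)
    features_path = out / "features.csv"
    table = matrix.X.copy()
    table["label"] = matrix.y
    table.to_csv(features_path, index=False, float_format="%.17g")
    manifest["checksums"]["features.csv"] = _sha256(features_path)
    stage_done("extract", n_features=len(matrix.registry), n_rows=matrix.N)

    # -- one-shot ensemble feature selection (diagnostic stage) ------------
    # Selection runs once on an inner split, mirroring the study protocol
    # (select first, then train/evaluate).  On cleanly separable synthetic
    # data both selectors are expected to degenerate (see docs/methods.md),
    # so the evaluated and deployed models keep the full registry; the
    # selection stage reports what SHAP-Select/PFI find under these
    # conditions.
    results = FallDetectionModel.from_windows(windows).fit(
        backend=config.backend, params=config.params or "published-optimum",
        selection=config.selection_mode, alpha=config.alpha,
        pfi_repeats=config.pfi_repeats, seed=config.seed)
    sel = results.selection
    selection_info = {
        "mode": config.selection_mode,
        "n_shap": len(sel.shap_selected) if sel else None,
        "n_pfi": len(sel.pfi_selected) if sel else None,
        "n_union": len(sel.ensemble) if sel else None,
        "n_selected": len(results.features_used),
        "selected": list(results.features_used),
    }
    _json_dump(selection_info, out / "selection.json")
    stage_done("select", n_union=selection_info["n_union"])

    # -- cross-validated evaluation (weighted, tuned booster) --------------
    report_cv = cross_validate(
        windows, k=config.k_folds, backend=config.backend,
        params=config.params, n_trials=config.n_trials,
        selection_mode="none", augment_level=config.augment_level,
        seed=config.seed)
    stage_done("cross_validate",
               macro_f1_mean=report_cv.aggregate["macro_f1"]["mean"])

    # -- final model on all training windows -------------------------------
    final = FallDetectionModel.from_windows(windows).fit(
        backend=config.backend, params=report_cv.params,
        selection="none", seed=config.seed)
    model_path = out / "model.bin"
    final.trained.save(model_path)
    manifest["checksums"]["model.bin"] = _sha256(model_path)
    stage_done("train", n_features=len(final.features_used))

    # -- lead-time replay ---------------------------------------------------
    leads = lead_time_summary(final.trained, replay_recs,
                              kernel=config.median_kernel, vote=config.vote)
    stage_done("lead_time",
               slf_ms=leads["SLF"]["mean_lead_ms"],
               ffh_ms=leads["FFH"]["mean_lead_ms"])

    # -- latency (manifest only: wall-clock, not reproducible) --------------
    if config.measure_latency and matrix.N >= 100:
        manifest["latency"] = measure_latency(final.trained, matrix.X)

    report = {
        "config": {k: v for k, v in asdict(config).items()},
        "n_recordings": len(recordings),
        "window_counts": win_counts,
        "feature_dim": len(FEATURE_NAMES),
        "cross_validation": report_cv.to_dict(),
        "selection": selection_info,
        "lead_time": leads,
    }
    report_path = out / "report.json"
    _json_dump(report, report_path)
    manifest["checksums"]["report.json"] = _sha256(report_path)
    _json_dump(manifest, out / "manifest.json")
    return report
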