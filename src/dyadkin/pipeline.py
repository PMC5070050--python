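"""End-to-end pipeline: calibrate -> align -> extract -> validate.

A *session directory* holds two raw skeleton files plus optional
calibration fixtures::

    session/
      mother.csv            (or .xml)
      infant.csv            (or .xml)
      calibration.csv       optional: x_src,y_src,z_src,x_dst,y_dst,z_dst
      sync_mother.csv       optional: '# rate=<Hz>' comment + 'value' column
      sync_infant.csv

Without calibration fixtures the streams are assumed pre-aligned
(identity transform, zero offset).  Every run writes a manifest (config
snapshot, input digests, seed, stage timings, outputs) so a run can be
reproduced bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import (
    RigidTransform,
    TemporalAlignment,
    align_dyad,
    estimate_rigid_transform,
    estimate_temporal_offset,
)
from .errors import ParseError, ValidationError
from .features import ExtractionConfig, extract_feature_vector
from .io import (
    CANONICAL_FEATURES,
    read_feature_table,
    read_skeleton_stream,
    write_feature_table,
)
from .stats import (
    CIB_COMPOSITES,
    classify_dyads,
    correlate_features_with_cib,
)


@dataclass
class PipelineConfig:
    """Single structured configuration for the whole pipeline."""

    rate: float = 30.0
    max_gap: float = 0.33
    max_lag: float = 2.0  # s, search range for the clock offset
    subsample_offset: bool = True
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    holm_family: str = "per_composite"
    cv_folds: int = 10
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["extraction"]["task_point"] = list(d["extraction"]["task_point"])
        if d["extraction"]["joints"] is not None:
            d["extraction"]["joints"] = list(d["extraction"]["joints"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        ex = dict(d.pop("extraction", {}))
        if "task_point" in ex:
            ex["task_point"] = tuple(ex["task_point"])
        if ex.get("joints") is not None:
            ex["joints"] = tuple(ex["joints"])
        return cls(extraction=ExtractionConfig(**ex), **d)


def load_config(path: str | Path | None) -> PipelineConfig:
    if path is None:
        return PipelineConfig()
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _find_stream_file(session_dir: Path, partner: str) -> Path:
    for suffix in (".csv", ".xml"):
        p = session_dir / f"{partner}{suffix}"
        if p.exists():
            return p
    raise ValidationError(
        f"session dir {session_dir} lacks {partner}.csv or {partner}.xml "
        f"(expected files: mother.csv|xml, infant.csv|xml, and optionally "
        "calibration.csv, sync_mother.csv, sync_infant.csv)"
    )


def read_sync_signal(path: Path) -> tuple[np.ndarray, float]:
    """Single-column sync CSV with a '# rate=<Hz>' comment line."""
    rate = None
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#") and "rate=" in line:
                rate = float(line.split("rate=")[1].strip())
            if not line.startswith("#"):
                break
    if rate is None:
        raise ParseError(f"{path}: missing '# rate=<Hz>' comment line")
    df = pd.read_csv(path, comment="#")
    col = df.columns[0]
    return df[col].to_numpy(dtype=float), rate


def write_sync_signal(path: Path, signal: np.ndarray, rate: float) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# rate={rate:g}\n")
        fh.write("value\n")
        np.savetxt(fh, np.asarray(signal), fmt="%.9g")


def read_calibration_points(path: Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, comment="#")
    cols = ["x_src", "y_src", "z_src", "x_dst", "y_dst", "z_dst"]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing calibration columns {missing}")
    return (
        df[cols[:3]].to_numpy(dtype=float),
        df[cols[3:]].to_numpy(dtype=float),
    )


def write_calibration_points(
    path: Path, src: np.ndarray, dst: np.ndarray
) -> None:
    df = pd.DataFrame(
        np.hstack([src, dst]),
        columns=["x_src", "y_src", "z_src", "x_dst", "y_dst", "z_dst"],
    )
    df.to_csv(path, index=False, float_format="%.12g")


def run_extract(
    session_dir: str | Path,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    session_id: str | None = None,
    group=None,
):
    """Calibrate, align and extract one session's 17-feature vector.

    Returns ``(MotionFeatureSet, manifest_dict)``; when ``out_dir`` is
    given, also writes ``features.csv``, ``session.json`` and
    ``manifest.json`` there.
    """
    session_dir = Path(session_dir)
    config = config or PipelineConfig()
    session_id = session_id or session_dir.name
    manifest: dict = {
        "version": __version__,
        "session_id": session_id,
        "config": config.to_dict(),
        "seed": config.seed,
        "inputs": {},
        "stages": {},
        "outputs": [],
    }

    t0 = time.perf_counter()
    mother_path = _find_stream_file(session_dir, "mother")
    infant_path = _find_stream_file(session_dir, "infant")
    mother = read_skeleton_stream(mother_path, partner="mother")
    infant = read_skeleton_stream(infant_path, partner="infant")
    manifest["inputs"][mother_path.name] = _sha256(mother_path)
    manifest["inputs"][infant_path.name] = _sha256(infant_path)
    manifest["stages"]["read"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    calib_path = session_dir / "calibration.csv"
    if calib_path.exists():
        src, dst = read_calibration_points(calib_path)
        xf = estimate_rigid_transform(src, dst)
        manifest["inputs"][calib_path.name] = _sha256(calib_path)
    else:
        xf = RigidTransform.identity()
    sync_m = session_dir / "sync_mother.csv"
    sync_i = session_dir / "sync_infant.csv"
    if sync_m.exists() and sync_i.exists():
        sig_a, rate_a = read_sync_signal(sync_m)
        sig_b, rate_b = read_sync_signal(sync_i)
        if abs(rate_a - rate_b) > 1e-9:
            raise ValidationError(
                f"sync signals sampled at different rates "
                f"({rate_a} vs {rate_b} Hz)"
            )
        ta = estimate_temporal_offset(
            sig_a,
            sig_b,
            rate_a,
            max_lag=config.max_lag,
            refine=config.subsample_offset,
        )
        manifest["inputs"][sync_m.name] = _sha256(sync_m)
        manifest["inputs"][sync_i.name] = _sha256(sync_i)
    else:
        ta = TemporalAlignment(offset=0.0, confidence=1.0)
    manifest["stages"]["calibrate"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    dyad = align_dyad(
        mother, infant, xf, ta, rate=config.rate, max_gap=config.max_gap
    )
    manifest["stages"]["align"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    fs = extract_feature_vector(
        dyad, config.extraction, session_id=session_id, group=group
    )
    manifest["stages"]["extract"] = time.perf_counter() - t0
    manifest["calibration"] = {
        "rotation": xf.rotation.tolist(),
        "translation": xf.translation.tolist(),
        "offset": ta.offset,
        "offset_confidence": ta.confidence,
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        feat_path = out_dir / "features.csv"
        write_feature_table([fs], feat_path)
        summary = {
            "session_id": session_id,
            "n_frames": dyad.n_frames,
            "duration_s": dyad.duration,
            "rate_hz": dyad.rate,
            "features": fs.values,
        }
        (out_dir / "session.json").write_text(
            json.dumps(summary, indent=2), encoding="utf-8"
        )
        manifest["outputs"] = [str(feat_path), str(out_dir / "session.json")]
        (out_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=2), encoding="utf-8"
        )
    return fs, manifest


def run_validate(
    features_path: str | Path,
    cib_path: str | Path,
    out_dir: str | Path | None = None,
    config: PipelineConfig | None = None,
):
    """Correlation report + group classification from saved tables.

    Group labels come from the feature table's ``group`` column.
    Returns ``(CorrelationReport, ClassificationResult)``.
    """
    config = config or PipelineConfig()
    features = read_feature_table(features_path)
    cib = pd.read_csv(cib_path)
    report = correlate_features_with_cib(
        features, cib, family=config.holm_family
    )
    if "group" not in features.columns:
        raise ValidationError("feature table lacks a 'group' column")
    result = classify_dyads(
        features,
        features["group"].to_numpy(),
        k=config.cv_folds,
        seed=config.seed,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        report.to_long().to_csv(
            out_dir / "correlations.csv", index=False, float_format="%.12g"
        )
        (out_dir / "classification.json").write_text(
            json.dumps(result.to_dict(), indent=2), encoding="utf-8"
        )
    return report, result
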