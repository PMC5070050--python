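"""Skeleton-stream containers, file formats and resampling.

A *skeleton stream* is one partner's time-stamped 3D joint trajectories
(metres, in a named sensor frame) plus a face-forward head-orientation unit
vector per frame.  Two co-registered, co-sampled streams form a
:class:`DyadRecording`, the unit of analysis for all dyadic features.

Two interchangeable on-disk dialects are supported:

* **CSV (reference dialect)** — long format with mandatory header
  ``t,joint,x,y,z,ox,oy,oz,valid``; orientation columns are filled on
  ``head`` rows and empty elsewhere.  Optional leading comment lines
  ``# partner=mother`` and ``# frame_id=kinect_a`` carry stream metadata.
* **XML** — ``<stream partner frame_id><frame t><joint name x y z valid/>
  <orientation ox oy oz/></frame>...</stream>``.

Trackers drop frames routinely, so missing data are first-class: every
joint carries a per-frame validity mask, readers never silently drop
invalid frames, and :func:`resample_stream` only interpolates across gaps
shorter than ``max_gap``.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from lxml import etree

from .errors import ParseError, ValidationError

PARTNERS = ("mother", "infant")

#: Canonical order of the 17-element session feature vector.
CANONICAL_FEATURES = (
    "mother_qom_mean",
    "mother_qom_sd",
    "infant_qom_mean",
    "infant_qom_sd",
    "mother_activity_ratio",
    "infant_activity_ratio",
    "heads_distance_mean",
    "heads_distance_sd",
    "mother_heads_contribution",
    "infant_heads_contribution",
    "face_to_face_ratio",
    "mother_task_ratio",
    "infant_task_ratio",
    "sync_parent_to_infant",
    "sync_infant_to_parent",
    "overlap_ratio",
    "pause_ratio",
)

_CSV_COLUMNS = ("t", "joint", "x", "y", "z", "ox", "oy", "oz", "valid")
_FLOAT_FMT = "%.12g"


@dataclass
class JointTrack:
    """One joint's 3D trajectory with a per-frame validity mask."""

    name: str
    positions: np.ndarray  # (T, 3) metres
    valid: np.ndarray  # (T,) bool

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValidationError(
                f"joint '{self.name}': positions must be (T, 3), "
                f"got {self.positions.shape}"
            )
        if self.valid.shape != (self.positions.shape[0],):
            raise ValidationError(
                f"joint '{self.name}': valid mask length "
                f"{self.valid.shape} does not match T={len(self.positions)}"
            )
        if not np.all(np.isfinite(self.positions[self.valid])):
            raise ValidationError(
                f"joint '{self.name}': non-finite position on a valid frame"
            )

    def __len__(self) -> int:
        return self.positions.shape[0]


@dataclass
class SkeletonStream:
    """One partner's tracked skeleton over a session.

    Parameters
    ----------
    partner
        ``"mother"`` or ``"infant"``.
    timestamps
        Strictly increasing session time in seconds, shape ``(T,)``.
    joints
        Mapping joint name -> :class:`JointTrack`; must include ``"head"``.
    head_orientation
        ``(T, 3)`` face-forward unit vectors; validated (unit norm within
        1e-6) only on frames where the head joint is valid.
    frame_id
        Coordinate frame label, e.g. a sensor name, or ``"common"`` once
        co-registered.
    """

    partner: str
    timestamps: np.ndarray
    joints: dict[str, JointTrack]
    head_orientation: np.ndarray
    frame_id: str = "common"

    def __post_init__(self) -> None:
        if self.partner not in PARTNERS:
            raise ValidationError(
                f"partner must be one of {PARTNERS}, got {self.partner!r}"
            )
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.timestamps.ndim != 1 or len(self.timestamps) < 1:
            raise ValidationError("timestamps must be a non-empty 1-D array")
        if np.any(np.diff(self.timestamps) <= 0):
            bad = int(np.argmax(np.diff(self.timestamps) <= 0))
            raise ValidationError(
                "timestamps must be strictly increasing "
                f"(violated between samples {bad} and {bad + 1})"
            )
        if "head" not in self.joints:
            raise ValidationError("stream must contain a 'head' joint")
        T = len(self.timestamps)
        for name, track in self.joints.items():
            if len(track) != T:
                raise ValidationError(
                    f"joint '{name}' has {len(track)} frames, expected {T}"
                )
        self.head_orientation = np.asarray(self.head_orientation, dtype=float)
        if self.head_orientation.shape != (T, 3):
            raise ValidationError(
                f"head_orientation must be ({T}, 3), "
                f"got {self.head_orientation.shape}"
            )
        hv = self.joints["head"].valid
        norms = np.linalg.norm(self.head_orientation[hv], axis=1)
        if norms.size and np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValidationError(
                "head_orientation must have unit norm on valid frames "
                f"(worst deviation {np.max(np.abs(norms - 1.0)):.2e})"
            )

    # -- derived quantities -------------------------------------------------

    @property
    def n_frames(self) -> int:
        return len(self.timestamps)

    @property
    def rate(self) -> float:
        """Sampling rate in Hz inferred from the median frame interval."""
        if self.n_frames < 2:
            raise ValidationError("rate undefined for a single-frame stream")
        return 1.0 / float(np.median(np.diff(self.timestamps)))

    @property
    def duration(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])

    @property
    def head(self) -> JointTrack:
        return self.joints["head"]

    def copy(self) -> "SkeletonStream":
        return SkeletonStream(
            partner=self.partner,
            timestamps=self.timestamps.copy(),
            joints={
                n: JointTrack(n, t.positions.copy(), t.valid.copy())
                for n, t in self.joints.items()
            },
            head_orientation=self.head_orientation.copy(),
            frame_id=self.frame_id,
        )


@dataclass
class DyadRecording:
    """Two co-registered, co-sampled streams (mother and infant)."""

    mother: SkeletonStream
    infant: SkeletonStream
    rate: float

    def __post_init__(self) -> None:
        if self.mother.partner != "mother" or self.infant.partner != "infant":
            raise ValidationError("streams must be labelled mother and infant")
        for s in (self.mother, self.infant):
            if s.frame_id != "common":
                raise ValidationError(
                    f"{s.partner} stream is in frame '{s.frame_id}'; both "
                    "streams must be in the 'common' frame (run calibration)"
                )
        if self.mother.n_frames != self.infant.n_frames or not np.allclose(
            self.mother.timestamps, self.infant.timestamps, atol=1e-9
        ):
            raise ValidationError("streams must share identical timestamps")
        if self.rate <= 0:
            raise ValidationError("rate must be positive")

    @property
    def timestamps(self) -> np.ndarray:
        return self.mother.timestamps

    @property
    def n_frames(self) -> int:
        return self.mother.n_frames

    @property
    def duration(self) -> float:
        return (self.n_frames - 1) / self.rate


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _infer_dialect(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in ("csv", "xml"):
            raise ValidationError(f"unknown dialect {dialect!r}")
        return dialect
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("csv", "xml"):
        return suffix
    raise ValidationError(
        f"cannot infer dialect from suffix {path.suffix!r}; pass dialect="
    )


def read_skeleton_stream(
    path: str | Path,
    dialect: str | None = None,
    partner: str | None = None,
    frame_id: str | None = None,
) -> SkeletonStream:
    """Read a skeleton stream from disk.

    ``partner``/``frame_id`` override metadata found in the file; metadata
    is mandatory in files written by :func:`write_skeleton_stream`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    d = _infer_dialect(path, dialect)
    if d == "csv":
        return _read_csv(path, partner, frame_id)
    return _read_xml(path, partner, frame_id)


def write_skeleton_stream(
    stream: SkeletonStream, path: str | Path, dialect: str | None = None
) -> None:
    path = Path(path)
    d = _infer_dialect(path, dialect)
    if d == "csv":
        _write_csv(stream, path)
    else:
        _write_xml(stream, path)


def _read_csv(
    path: Path, partner: str | None, frame_id: str | None
) -> SkeletonStream:
    meta: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    partner = partner or meta.get("partner")
    if partner is None:
        raise ParseError(
            f"{path}: no '# partner=' metadata line and no partner argument"
        )
    frame_id = frame_id or meta.get("frame_id", "common")

    joints: dict[str, JointTrack] = {}
    timestamps: np.ndarray | None = None
    orientation: np.ndarray | None = None
    for name, grp in df.groupby("joint", sort=False):
        t = grp["t"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            bad = int(np.argmax(np.diff(t) <= 0))
            raise ValidationError(
                f"{path}: joint '{name}' timestamps not strictly increasing "
                f"(rows {grp.index[bad]}..{grp.index[bad + 1]})"
            )
        if timestamps is None:
            timestamps = t
        elif len(t) != len(timestamps) or not np.allclose(t, timestamps):
            raise ValidationError(
                f"{path}: joint '{name}' uses a different time base than "
                "the first joint; all joints must share timestamps"
            )
        valid = _parse_valid(grp["valid"], path)
        pos = grp[["x", "y", "z"]].to_numpy(dtype=float)
        pos[~valid & ~np.isfinite(pos).all(axis=1)] = 0.0
        joints[str(name)] = JointTrack(str(name), pos, valid)
        if name == "head":
            orientation = grp[["ox", "oy", "oz"]].to_numpy(dtype=float)
    if timestamps is None:
        raise ParseError(f"{path}: file contains no data rows")
    if "head" not in joints:
        raise ValidationError(f"{path}: no 'head' joint present")
    if orientation is None or not np.isfinite(
        orientation[joints["head"].valid]
    ).all():
        raise ParseError(
            f"{path}: head rows must carry finite ox,oy,oz orientation "
            "on valid frames"
        )
    return SkeletonStream(
        partner=partner,
        timestamps=timestamps,
        joints=joints,
        head_orientation=np.nan_to_num(orientation, nan=0.0),
        frame_id=frame_id,
    )


def _parse_valid(col: pd.Series, path: Path) -> np.ndarray:
    vals = col.astype(str).str.strip().str.lower()
    ok = vals.isin(["0", "1", "true", "false"])
    if not ok.all():
        bad = vals[~ok].iloc[0]
        raise ParseError(f"{path}: unparseable 'valid' entry {bad!r}")
    return vals.isin(["1", "true"]).to_numpy()


def _write_csv(stream: SkeletonStream, path: Path) -> None:
    buf = _stdio.StringIO()
    buf.write(f"# partner={stream.partner}\n")
    buf.write(f"# frame_id={stream.frame_id}\n")
    buf.write(",".join(_CSV_COLUMNS) + "\n")
    fmt = _FLOAT_FMT
    for name, track in stream.joints.items():
        is_head = name == "head"
        for i, t in enumerate(stream.timestamps):
            x, y, z = track.positions[i]
            if is_head:
                ox, oy, oz = stream.head_orientation[i]
                ori = f"{fmt % ox},{fmt % oy},{fmt % oz}"
            else:
                ori = ",,"
            buf.write(
                f"{fmt % t},{name},{fmt % x},{fmt % y},{fmt % z},"
                f"{ori},{int(track.valid[i])}\n"
            )
    path.write_text(buf.getvalue(), encoding="utf-8")


def _write_xml(stream: SkeletonStream, path: Path) -> None:
    fmt = _FLOAT_FMT
    root = etree.Element(
        "stream", partner=stream.partner, frame_id=stream.frame_id
    )
    for i, t in enumerate(stream.timestamps):
        frame = etree.SubElement(root, "frame", t=fmt % t)
        for name, track in stream.joints.items():
            x, y, z = track.positions[i]
            etree.SubElement(
                frame,
                "joint",
                name=name,
                x=fmt % x,
                y=fmt % y,
                z=fmt % z,
                valid=str(int(track.valid[i])),
            )
        ox, oy, oz = stream.head_orientation[i]
        etree.SubElement(
            frame, "orientation", ox=fmt % ox, oy=fmt % oy, oz=fmt % oz
        )
    etree.ElementTree(root).write(
        str(path), pretty_print=True, xml_declaration=True, encoding="utf-8"
    )


def _read_xml(
    path: Path, partner: str | None, frame_id: str | None
) -> SkeletonStream:
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    root = tree.getroot()
    if root.tag != "stream":
        raise ParseError(f"{path}: root element is <{root.tag}>, not <stream>")
    partner = partner or root.get("partner")
    if partner is None:
        raise ParseError(f"{path}: <stream> lacks a partner attribute")
    frame_id = frame_id or root.get("frame_id", "common")

    timestamps: list[float] = []
    per_joint: dict[str, list[tuple[np.ndarray, bool]]] = {}
    orientation: list[np.ndarray] = []
    for frame in root.iterfind("frame"):
        try:
            timestamps.append(float(frame.get("t")))
        except (TypeError, ValueError):
            raise ParseError(
                f"{path}: <frame> at line {frame.sourceline} has a "
                "missing or non-numeric t attribute"
            ) from None
        seen = set()
        for j in frame.iterfind("joint"):
            name = j.get("name")
            if name is None:
                raise ParseError(
                    f"{path}: <joint> at line {j.sourceline} lacks name"
                )
            try:
                pos = np.array(
                    [float(j.get(k)) for k in ("x", "y", "z")], dtype=float
                )
                valid = bool(int(j.get("valid", "1")))
            except (TypeError, ValueError):
                raise ParseError(
                    f"{path}: <joint name={name!r}> at line {j.sourceline} "
                    "has non-numeric coordinates"
                ) from None
            per_joint.setdefault(name, []).append((pos, valid))
            seen.add(name)
        if per_joint and seen != set(per_joint):
            raise ParseError(
                f"{path}: frame at line {frame.sourceline} is missing "
                f"joints {sorted(set(per_joint) - seen)}"
            )
        o = frame.find("orientation")
        if o is None:
            orientation.append(np.zeros(3))
        else:
            orientation.append(
                np.array(
                    [float(o.get(k, "0")) for k in ("ox", "oy", "oz")],
                    dtype=float,
                )
            )
    ts = np.asarray(timestamps, dtype=float)
    if ts.size == 0:
        raise ParseError(f"{path}: stream contains no <frame> elements")
    if np.any(np.diff(ts) <= 0):
        bad = int(np.argmax(np.diff(ts) <= 0))
        raise ValidationError(
            f"{path}: frame timestamps not strictly increasing "
            f"(frames {bad}..{bad + 1})"
        )
    joints = {
        name: JointTrack(
            name,
            np.array([p for p, _ in rows]),
            np.array([v for _, v in rows]),
        )
        for name, rows in per_joint.items()
    }
    if "head" not in joints:
        raise ValidationError(f"{path}: no 'head' joint present")
    return SkeletonStream(
        partner=partner,
        timestamps=ts,
        joints=joints,
        head_orientation=np.array(orientation),
        frame_id=frame_id,
    )


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------


def uniform_timestamps(t0: float, t1: float, rate: float) -> np.ndarray:
    """Grid ``t0 + k/rate`` covering ``[t0, t1]`` (last point <= t1 + eps)."""
    n = int(np.floor((t1 - t0) * rate + 1e-9)) + 1
    return t0 + np.arange(n) / rate


def _interp_positions(
    t_src: np.ndarray,
    track: JointTrack,
    t_new: np.ndarray,
    max_gap: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Linear interpolation of one track onto ``t_new``.

    A new frame is valid when it coincides with a valid source sample, or
    lies inside an interval between consecutive valid samples no longer
    than ``max_gap``.
    """
    tv = t_src[track.valid]
    if tv.size == 0:
        raise ValidationError(f"joint '{track.name}' has no valid frames")
    if tv.size < 2:
        raise ValidationError(
            f"joint '{track.name}' has fewer than 2 valid frames; "
            "cannot interpolate"
        )
    pv = track.positions[track.valid]
    out = np.column_stack(
        [np.interp(t_new, tv, pv[:, k]) for k in range(3)]
    )
    idx = np.searchsorted(tv, t_new, side="right")
    lo = np.clip(idx - 1, 0, tv.size - 1)
    hi = np.clip(idx, 0, tv.size - 1)
    inside = (t_new >= tv[0] - 1e-9) & (t_new <= tv[-1] + 1e-9)
    at_knot = np.minimum(
        np.abs(t_new - tv[lo]), np.abs(t_new - tv[hi])
    ) < 1e-9
    gap_ok = (tv[hi] - tv[lo]) <= max_gap + 1e-12
    return out, inside & (at_knot | gap_ok)


def resample_to(
    stream: SkeletonStream, t_new: np.ndarray, max_gap: float = 0.33
) -> SkeletonStream:
    """Resample a stream onto an explicit timestamp grid."""
    joints: dict[str, JointTrack] = {}
    for name, track in stream.joints.items():
        pos, valid = _interp_positions(
            stream.timestamps, track, t_new, max_gap
        )
        joints[name] = JointTrack(name, pos, valid)
    head_track = JointTrack(
        "head", stream.head_orientation, stream.joints["head"].valid
    )
    ori, _ = _interp_positions(stream.timestamps, head_track, t_new, max_gap)
    norms = np.linalg.norm(ori, axis=1)
    degenerate = norms < 1e-8
    if np.any(degenerate):
        # opposite vectors can cancel under linear interpolation;
        # fall back to the nearest source orientation
        tv = stream.timestamps[stream.joints["head"].valid]
        ov = stream.head_orientation[stream.joints["head"].valid]
        nearest = np.clip(
            np.searchsorted(tv, t_new[degenerate]), 0, tv.size - 1
        )
        ori[degenerate] = ov[nearest]
        norms = np.linalg.norm(ori, axis=1)
    ori = ori / np.where(norms > 0, norms, 1.0)[:, None]
    return SkeletonStream(
        partner=stream.partner,
        timestamps=t_new,
        joints=joints,
        head_orientation=ori,
        frame_id=stream.frame_id,
    )


def resample_stream(
    stream: SkeletonStream, rate: float, max_gap: float = 0.33
) -> SkeletonStream:
    """Resample to a uniform grid ``t0 + k/rate`` spanning the stream.

    Positions are linearly interpolated inside gaps no longer than
    ``max_gap`` seconds; frames inside longer gaps remain invalid.
    Orientation vectors are re-normalised after interpolation.
    """
    if rate <= 0:
        raise ValidationError("rate must be positive")
    t_new = uniform_timestamps(
        float(stream.timestamps[0]), float(stream.timestamps[-1]), rate
    )
    return resample_to(stream, t_new, max_gap=max_gap)


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------


def write_feature_table(features: Sequence, path: str | Path) -> None:
    """Write session feature vectors as CSV.

    Accepts any objects exposing ``values`` (mapping with the 17 canonical
    feature names, in order), ``session_id`` and ``group`` —
    i.e. :class:`dyadkin.features.MotionFeatureSet`.
    An empty list produces a header-only file.
    """
    rows = []
    for i, fs in enumerate(features):
        names = tuple(fs.values.keys())
        if names != CANONICAL_FEATURES:
            extra = sorted(set(names) - set(CANONICAL_FEATURES))
            miss = sorted(set(CANONICAL_FEATURES) - set(names))
            raise ValidationError(
                f"feature set {i} ({getattr(fs, 'session_id', '?')}) does "
                f"not match the canonical feature list: unexpected={extra}, "
                f"missing={miss}, or wrong order"
            )
        row = {"session_id": fs.session_id, "group": fs.group}
        row.update(fs.values)
        rows.append(row)
    df = pd.DataFrame(
        rows, columns=["session_id", "group", *CANONICAL_FEATURES]
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature table CSV back into a DataFrame."""
    df = pd.read_csv(path)
    missing = [
        c for c in ("session_id", *CANONICAL_FEATURES) if c not in df.columns
    ]
    if missing:
        raise ParseError(f"{path}: missing feature-table columns {missing}")
    return df
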