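"""Individual and dyadic motion features of a mother-infant play session.

Given a co-registered, co-sampled :class:`~dyadkin.io.DyadRecording`, this
module computes:

* per partner: **quantity of movement** (QoM, summed joint speed in m/s)
  and the binary moving/still state it induces (**motion activity**);
* dyadic: the inter-head distance and each partner's **contribution** to
  its change, the fraction of time spent **face to face** or **oriented to
  the task**, and three event/state couplings of the two activity streams —
  **synchrony ratio** (movement onsets of one partner answered by the
  other within a response window), **overlap ratio** (both moving) and
  **pause ratio** (both still).

The canonical 17-element session vector (``dyadkin.io.CANONICAL_FEATURES``)
assembles: 4 QoM mean/sd + 2 activity ratios + 2 heads-distance mean/sd +
2 contributions + 1 face-to-face + 2 task ratios + 2 directional synchrony
ratios + overlap + pause.

Missing-data policy: per-frame validity masks are propagated everywhere;
dyadic ratios use jointly valid frames as denominator, and movement onsets
are detected on the validity-compressed state sequence so tracking
dropouts never masquerade as behavioural stillness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .io import CANONICAL_FEATURES, DyadRecording, SkeletonStream

DEFAULT_JOINTS = ("head", "hand_left", "hand_right")


@dataclass
class ActivitySeries:
    """Quantity-of-movement signal and derived binary moving state."""

    timestamps: np.ndarray
    qom: np.ndarray  # (T,) m/s, meaningful where valid
    valid: np.ndarray  # (T,) bool
    moving: np.ndarray  # (T,) bool, subset of valid
    threshold: float  # m/s
    min_duration: float  # s

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.qom = np.asarray(self.qom, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        self.moving = np.asarray(self.moving, dtype=bool)
        T = len(self.timestamps)
        for name, arr in (
            ("qom", self.qom),
            ("valid", self.valid),
            ("moving", self.moving),
        ):
            if arr.shape != (T,):
                raise ValidationError(f"{name} must have shape ({T},)")
        if np.any(self.moving & ~self.valid):
            raise ValidationError("moving frames must be valid frames")
        if np.any(self.qom[self.valid] < 0):
            raise ValidationError("qom must be non-negative on valid frames")

    @property
    def rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.timestamps)))

    def __len__(self) -> int:
        return len(self.timestamps)


@dataclass
class MotionFeatureSet:
    """The canonical 17-element feature vector for one session."""

    values: dict[str, float]
    session_id: str = ""
    group: object = None

    def __post_init__(self) -> None:
        names = tuple(self.values.keys())
        if names != CANONICAL_FEATURES:
            raise ValidationError(
                "feature names/order must match the canonical list; got "
                f"{names}"
            )
        self.values = {k: float(v) for k, v in self.values.items()}

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.values.keys())

    def to_array(self) -> np.ndarray:
        return np.array([self.values[k] for k in CANONICAL_FEATURES])


@dataclass
class ExtractionConfig:
    """Tunable parameters of feature extraction.

    Defaults are scaled to tabletop play: the activity threshold is 0.05
    m/s on the summed head+hands speed, state runs shorter than 0.25 s are
    smoothed away, a movement response counts within 3 s, and gaze counts
    as "at partner"/"at task" within a 30 degree cone.
    """

    activity_threshold: float = 0.05  # m/s on summed joint speed
    min_duration: float = 0.25  # s, shortest believable state run
    synchrony_window: float = 3.0  # s, response window
    face_angle_deg: float = 30.0
    task_angle_deg: float = 30.0
    task_point: tuple[float, float, float] = (0.0, 0.0, 0.1)
    joints: tuple[str, ...] | None = None  # None -> head+hands if present


# ---------------------------------------------------------------------------
# individual features
# ---------------------------------------------------------------------------


def quantity_of_movement(
    stream: SkeletonStream, joints: tuple[str, ...] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame summed joint speed (m/s).

    ``qom[i] = sum_j ||p_j[i] - p_j[i-1]|| / (t[i] - t[i-1])`` over the
    requested joints.  Frame ``i`` is valid only when every requested
    joint is valid at both ``i-1`` and ``i``; frame 0 is always invalid.

    Returns ``(qom, valid)`` arrays of length T.
    """
    if joints is None:
        joints = _select_joints(stream, None)
    missing = [j for j in joints if j not in stream.joints]
    if missing:
        raise ValidationError(
            f"requested joint(s) {missing} absent from "
            f"{stream.partner} stream (has {sorted(stream.joints)})"
        )
    T = stream.n_frames
    qom = np.zeros(T)
    valid = np.ones(T, dtype=bool)
    valid[0] = False
    dt = np.diff(stream.timestamps)
    for name in joints:
        track = stream.joints[name]
        if track.valid.sum() < 2:
            raise ValidationError(
                f"joint '{name}' has fewer than 2 valid frames"
            )
        step = np.linalg.norm(np.diff(track.positions, axis=0), axis=1)
        qom[1:] += step / dt
        valid[1:] &= track.valid[1:] & track.valid[:-1]
    qom[~valid] = 0.0
    return qom, valid


def _select_joints(
    stream: SkeletonStream, requested: tuple[str, ...] | None
) -> tuple[str, ...]:
    if requested is not None:
        return tuple(requested)
    present = tuple(j for j in DEFAULT_JOINTS if j in stream.joints)
    return present if len(present) > 1 else tuple(sorted(stream.joints))


def _runs(mask: np.ndarray):
    """Yield (start, stop, value) for maximal constant runs of a 1-D bool."""
    if len(mask) == 0:
        return
    edges = np.flatnonzero(np.diff(mask)) + 1
    bounds = np.concatenate(([0], edges, [len(mask)]))
    for s, e in zip(bounds[:-1], bounds[1:]):
        yield int(s), int(e), bool(mask[s])


def _fill_short_gaps(moving: np.ndarray, k_min: int) -> np.ndarray:
    """Closing: interior still runs shorter than k_min become moving."""
    out = moving.copy()
    for s, e, val in _runs(moving):
        if not val and s > 0 and e < len(moving) and (e - s) < k_min:
            out[s:e] = True
    return out


def _drop_short_runs(moving: np.ndarray, k_min: int) -> np.ndarray:
    """Opening: moving runs shorter than k_min become still."""
    out = moving.copy()
    for s, e, val in _runs(moving):
        if val and (e - s) < k_min:
            out[s:e] = False
    return out


def detect_activity(
    qom: np.ndarray,
    valid: np.ndarray,
    timestamps: np.ndarray,
    threshold: float = 0.05,
    min_duration: float = 0.25,
) -> ActivitySeries:
    """Threshold the QoM signal into a smoothed binary moving state.

    Raw state is ``qom > threshold`` on valid frames.  Temporal smoothing
    is a morphological closing (interior still gaps shorter than
    ``min_duration`` are filled) followed by an opening (moving runs
    shorter than ``min_duration`` are removed), so every surviving moving
    run lasts at least ``min_duration``.  The morphology operates on the
    validity-compressed sequence: invalid frames are non-observations,
    not stillness, so a tracking dropout inside a bout neither splits the
    bout nor lets a short flanked fragment be opened away.  Invalid
    frames are always reported as not moving.
    """
    if threshold <= 0:
        raise ValidationError("threshold must be positive")
    qom = np.asarray(qom, dtype=float)
    valid = np.asarray(valid, dtype=bool)
    timestamps = np.asarray(timestamps, dtype=float)
    if timestamps.size < 2:
        # a single-frame series has no time base: return it unsmoothed
        k_min = 0
    else:
        rate = 1.0 / float(np.median(np.diff(timestamps)))
        k_min = int(math.ceil(min_duration * rate - 1e-9))
    moving = valid & (qom > threshold)
    if k_min > 1:
        vi = np.flatnonzero(valid)
        sub = moving[vi]
        sub = _fill_short_gaps(sub, k_min)
        sub = _drop_short_runs(sub, k_min)
        moving = np.zeros_like(moving)
        moving[vi] = sub
    return ActivitySeries(
        timestamps=timestamps,
        qom=qom,
        valid=valid,
        moving=moving,
        threshold=threshold,
        min_duration=min_duration,
    )


def activity_ratio(act: ActivitySeries) -> float:
    """Fraction of valid frames spent in the moving state."""
    n_valid = int(act.valid.sum())
    if n_valid == 0:
        raise ValidationError("activity ratio undefined: no valid frames")
    return float(act.moving.sum() / n_valid)


# ---------------------------------------------------------------------------
# dyadic features
# ---------------------------------------------------------------------------


def heads_distance(dyad: DyadRecording) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame inter-head distance (m) with joint validity mask."""
    hm = dyad.mother.head
    hi = dyad.infant.head
    valid = hm.valid & hi.valid
    if not valid.any():
        raise ValidationError("no frame with both heads tracked")
    d = np.linalg.norm(hm.positions - hi.positions, axis=1)
    d[~valid] = 0.0
    return d, valid


def heads_distance_contributions(
    dyad: DyadRecording,
) -> tuple[float, float]:
    """Each partner's share of inter-head distance change.

    Per consecutive jointly valid frame pair, head displacements are
    projected on the previous frame's inter-head axis ``u`` (unit vector
    infant-head -> mother-head): ``c_m = dh_m . u`` and ``c_i = -dh_i . u``
    (moving along +u opens the distance for the mother, closes it for the
    infant, hence the sign).  To first order ``c_m + c_i`` equals the
    distance change.  Shares aggregate approach and withdrawal
    symmetrically via absolute values; a fully static pair of heads gets
    (0.5, 0.5) by convention.
    """
    hm = dyad.mother.head
    hi = dyad.infant.head
    valid_pair = hm.valid[1:] & hm.valid[:-1] & hi.valid[1:] & hi.valid[:-1]
    if valid_pair.sum() < 1:
        raise ValidationError(
            "need at least 2 consecutive jointly valid head frames"
        )
    sep = hm.positions[:-1] - hi.positions[:-1]
    norm = np.linalg.norm(sep, axis=1)
    usable = valid_pair & (norm > 1e-12)
    u = sep[usable] / norm[usable, None]
    dm = np.diff(hm.positions, axis=0)[usable]
    di = np.diff(hi.positions, axis=0)[usable]
    c_m = np.einsum("ij,ij->i", dm, u)
    c_i = -np.einsum("ij,ij->i", di, u)
    total = np.abs(c_m).sum() + np.abs(c_i).sum()
    if total < 1e-15:
        return 0.5, 0.5
    share_m = float(np.abs(c_m).sum() / total)
    return share_m, 1.0 - share_m


def _angles_to_target(
    orientation: np.ndarray, origin: np.ndarray, target: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Angle (rad) between gaze vectors and origin->target directions.

    Returns (angles, defined) where frames with coincident origin/target
    are flagged undefined.
    """
    to_target = target - origin
    norm = np.linalg.norm(to_target, axis=1)
    onorm = np.linalg.norm(orientation, axis=1)
    defined = (norm > 1e-12) & (onorm > 1e-12)
    cosang = np.zeros(len(norm))
    cosang[defined] = np.einsum(
        "ij,ij->i", orientation[defined], to_target[defined]
    ) / (onorm[defined] * norm[defined])
    return np.arccos(np.clip(cosang, -1.0, 1.0)), defined


def face_to_face_ratio(
    dyad: DyadRecording, angle_threshold: float = 30.0
) -> float:
    """Fraction of jointly valid frames where each partner's head
    orientation points within ``angle_threshold`` degrees of the other's
    head."""
    hm = dyad.mother.head
    hi = dyad.infant.head
    valid = hm.valid & hi.valid
    if not valid.any():
        raise ValidationError("no jointly valid frame for face-to-face")
    ang_m, def_m = _angles_to_target(
        dyad.mother.head_orientation, hm.positions, hi.positions
    )
    ang_i, def_i = _angles_to_target(
        dyad.infant.head_orientation, hi.positions, hm.positions
    )
    usable = valid & def_m & def_i
    if not usable.any():
        raise ValidationError("head positions coincide on all valid frames")
    thr = np.deg2rad(angle_threshold)
    both = (ang_m[usable] <= thr + 1e-12) & (ang_i[usable] <= thr + 1e-12)
    return float(both.mean())


def task_orientation_ratio(
    stream: SkeletonStream,
    task_point: np.ndarray,
    angle_threshold: float = 30.0,
) -> float:
    """Fraction of valid frames with head orientation within
    ``angle_threshold`` degrees of the head -> task-point direction.

    Frames where the head coincides with the task point are skipped as
    undefined."""
    head = stream.head
    if not head.valid.any():
        raise ValidationError("no valid head frame")
    target = np.broadcast_to(
        np.asarray(task_point, dtype=float), head.positions.shape
    )
    ang, defined = _angles_to_target(
        stream.head_orientation, head.positions, target
    )
    usable = head.valid & defined
    if not usable.any():
        raise ValidationError("task point coincides with head on all frames")
    thr = np.deg2rad(angle_threshold)
    return float((ang[usable] <= thr + 1e-12).mean())


def movement_onsets(act: ActivitySeries) -> np.ndarray:
    """Times of still -> moving transitions.

    Edges are detected on the validity-compressed sequence so that a
    tracking dropout inside a movement bout does not create a spurious
    onset when tracking resumes.
    """
    vi = np.flatnonzero(act.valid)
    if vi.size < 2:
        return np.empty(0)
    m = act.moving[vi]
    rising = vi[1:][m[1:] & ~m[:-1]]
    return act.timestamps[rising]


def _check_shared_timebase(a: ActivitySeries, b: ActivitySeries) -> None:
    if len(a) != len(b):
        raise ValidationError(
            f"activity series lengths differ ({len(a)} vs {len(b)})"
        )
    if not np.allclose(a.timestamps, b.timestamps, atol=1e-9):
        raise ValidationError("activity series must share timestamps")


def synchrony_ratio(
    leader: ActivitySeries, responder: ActivitySeries, window: float = 3.0
) -> float:
    """Fraction of leader movement onsets answered by a responder onset
    within ``(0, window]`` seconds.

    Directional: ``synchrony_ratio(infant, mother)`` is the parent's
    response rate to infant movement initiations.  Returns NaN (an
    undefined marker, not an error) when the leader never onsets, and 0.0
    when the responder never onsets.
    """
    _check_shared_timebase(leader, responder)
    if window <= 0:
        raise ValidationError("window must be positive")
    t_lead = movement_onsets(leader)
    if t_lead.size == 0:
        return float("nan")
    t_resp = movement_onsets(responder)
    if t_resp.size == 0:
        return 0.0
    answered = 0
    for t0 in t_lead:
        j = np.searchsorted(t_resp, t0, side="right")
        if j < t_resp.size and t_resp[j] - t0 <= window + 1e-9:
            answered += 1
    return answered / t_lead.size


def overlap_ratio(a: ActivitySeries, b: ActivitySeries) -> float:
    """Fraction of jointly valid frames where both partners move."""
    _check_shared_timebase(a, b)
    joint = a.valid & b.valid
    if not joint.any():
        raise ValidationError("no jointly valid frame")
    return float((a.moving & b.moving)[joint].mean())


def pause_ratio(a: ActivitySeries, b: ActivitySeries) -> float:
    """Fraction of jointly valid frames where neither partner moves."""
    _check_shared_timebase(a, b)
    joint = a.valid & b.valid
    if not joint.any():
        raise ValidationError("no jointly valid frame")
    return float((~a.moving & ~b.moving)[joint].mean())


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------


def partner_activity(
    dyad: DyadRecording,
    config: ExtractionConfig,
) -> tuple[ActivitySeries, ActivitySeries]:
    """Activity series for (mother, infant) under a config."""
    out = []
    for stream in (dyad.mother, dyad.infant):
        joints = _select_joints(stream, config.joints)
        qom, valid = quantity_of_movement(stream, joints)
        out.append(
            detect_activity(
                qom,
                valid,
                dyad.timestamps,
                threshold=config.activity_threshold,
                min_duration=config.min_duration,
            )
        )
    return out[0], out[1]


def _masked_mean_sd(x: np.ndarray, mask: np.ndarray) -> tuple[float, float]:
    v = x[mask]
    mean = float(v.mean())
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    return mean, sd


def extract_feature_vector(
    dyad: DyadRecording,
    config: ExtractionConfig | None = None,
    session_id: str = "",
    group: object = None,
) -> MotionFeatureSet:
    """Compute the canonical 17-feature vector for one session.

    Deterministic given inputs; any sub-operation failure is re-raised
    with the feature name attached.
    """
    config = config or ExtractionConfig()
    values: dict[str, float] = {}

    def _run(name: str, fn):
        try:
            return fn()
        except ValidationError as exc:
            raise ValidationError(f"feature '{name}': {exc}") from exc

    act_m, act_i = _run(
        "activity", lambda: partner_activity(dyad, config)
    )
    values["mother_qom_mean"], values["mother_qom_sd"] = _masked_mean_sd(
        act_m.qom, act_m.valid
    )
    values["infant_qom_mean"], values["infant_qom_sd"] = _masked_mean_sd(
        act_i.qom, act_i.valid
    )
    values["mother_activity_ratio"] = _run(
        "mother_activity_ratio", lambda: activity_ratio(act_m)
    )
    values["infant_activity_ratio"] = _run(
        "infant_activity_ratio", lambda: activity_ratio(act_i)
    )
    d, dv = _run("heads_distance", lambda: heads_distance(dyad))
    values["heads_distance_mean"], values["heads_distance_sd"] = (
        _masked_mean_sd(d, dv)
    )
    share_m, share_i = _run(
        "heads_contribution", lambda: heads_distance_contributions(dyad)
    )
    values["mother_heads_contribution"] = share_m
    values["infant_heads_contribution"] = share_i
    values["face_to_face_ratio"] = _run(
        "face_to_face_ratio",
        lambda: face_to_face_ratio(dyad, config.face_angle_deg),
    )
    task = np.asarray(config.task_point, dtype=float)
    values["mother_task_ratio"] = _run(
        "mother_task_ratio",
        lambda: task_orientation_ratio(
            dyad.mother, task, config.task_angle_deg
        ),
    )
    values["infant_task_ratio"] = _run(
        "infant_task_ratio",
        lambda: task_orientation_ratio(
            dyad.infant, task, config.task_angle_deg
        ),
    )
    values["sync_parent_to_infant"] = _run(
        "sync_parent_to_infant",
        lambda: synchrony_ratio(act_i, act_m, config.synchrony_window),
    )
    values["sync_infant_to_parent"] = _run(
        "sync_infant_to_parent",
        lambda: synchrony_ratio(act_m, act_i, config.synchrony_window),
    )
    values["overlap_ratio"] = _run(
        "overlap_ratio", lambda: overlap_ratio(act_m, act_i)
    )
    values["pause_ratio"] = _run(
        "pause_ratio", lambda: pause_ratio(act_m, act_i)
    )
    ordered = {k: values[k] for k in CANONICAL_FEATURES}
    return MotionFeatureSet(ordered, session_id=session_id, group=group)
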