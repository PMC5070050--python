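"""Spatial and temporal co-registration of the two sensors.

Each sensor observes the scene in its own coordinate frame and on its own
clock.  Before any dyadic feature can be computed the infant sensor's data
must be mapped into the mother sensor's ("common") frame and onto its
clock:

* **space** — a rigid transform (rotation + translation, no scale) fitted
  by SVD-based least squares (Kabsch/Umeyama) to corresponding 3D points,
  e.g. chessboard corners seen by both sensors;
* **time** — a constant offset estimated from the normalised
  cross-correlation of two 1-D synchronisation envelopes (a hand clap
  recorded by both microphones), refined to sub-sample precision by
  parabolic interpolation around the correlation peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import DegenerateGeometryError, ValidationError
from .io import DyadRecording, SkeletonStream, resample_to, uniform_timestamps


@dataclass
class RigidTransform:
    """Proper rigid transform ``p -> R p + t`` (metres)."""

    rotation: np.ndarray  # (3, 3), orthonormal, det +1
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValidationError("rotation must be 3x3 and translation 3")
        if not np.allclose(
            self.rotation.T @ self.rotation, np.eye(3), atol=1e-9
        ):
            raise ValidationError("rotation matrix is not orthonormal")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-9:
            raise ValidationError(
                "rotation determinant is not +1 (reflections are excluded)"
            )

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an ``(..., 3)`` array of points."""
        return np.asarray(points, dtype=float) @ self.rotation.T + (
            self.translation
        )

    def rotate(self, vectors: np.ndarray) -> np.ndarray:
        """Rotate free vectors (no translation), e.g. orientations."""
        return np.asarray(vectors, dtype=float) @ self.rotation.T

    def inverse(self) -> "RigidTransform":
        return RigidTransform(
            self.rotation.T, -self.rotation.T @ self.translation
        )

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` then self."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


@dataclass
class TemporalAlignment:
    """Constant clock offset: signal B lags signal A by ``offset`` seconds."""

    offset: float
    confidence: float  # peak normalised correlation in [-1, 1]

    def __post_init__(self) -> None:
        if abs(self.confidence) > 1.0 + 1e-9:
            raise ValidationError("|confidence| must be <= 1")


def estimate_rigid_transform(
    src: np.ndarray, dst: np.ndarray
) -> RigidTransform:
    """Least-squares rigid transform mapping ``src`` onto ``dst``.

    Minimises ``sum_i || R src_i + t - dst_i ||^2`` over proper rotations
    (Kabsch/Umeyama without scale); reflections are excluded by the usual
    sign correction of the smallest singular vector.

    Raises
    ------
    DegenerateGeometryError
        Fewer than 3 correspondences, or (near-)collinear points.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 3:
        raise ValidationError(
            f"src and dst must both be (N, 3); got {src.shape}, {dst.shape}"
        )
    n = src.shape[0]
    if n < 3:
        raise DegenerateGeometryError(
            f"need at least 3 correspondences, got {n}"
        )
    if not (np.isfinite(src).all() and np.isfinite(dst).all()):
        raise ValidationError("correspondences must be finite")
    src_mean = src.mean(axis=0)
    dst_mean = dst.mean(axis=0)
    src_c = src - src_mean
    dst_c = dst - dst_mean
    sv = np.linalg.svd(src_c, compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1e-300):
        raise DegenerateGeometryError(
            "source points are collinear (or coincident); the rotation "
            "about their axis is unconstrained"
        )
    H = src_c.T @ dst_c
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = dst_mean - R @ src_mean
    return RigidTransform(R, t)


def apply_transform(
    stream: SkeletonStream, xf: RigidTransform
) -> SkeletonStream:
    """Map a stream into the common frame: positions ``p -> R p + t``,
    orientations ``o -> R o``; validity is unchanged."""
    out = stream.copy()
    for track in out.joints.values():
        track.positions = xf.apply(track.positions)
    out.head_orientation = xf.rotate(out.head_orientation)
    out.frame_id = "common"
    return out


def estimate_temporal_offset(
    sig_a: np.ndarray,
    sig_b: np.ndarray,
    rate: float,
    max_lag: float,
    refine: bool = True,
) -> TemporalAlignment:
    """Clock offset between two synchronisation envelopes.

    Returns the lag (in seconds, positive when B lags A, i.e.
    ``b(t) ~ a(t - offset)``) maximising the normalised cross-correlation
    over ``[-max_lag, +max_lag]``.  With ``refine=True`` the discrete peak
    is sharpened by fitting a parabola through its two neighbours.
    """
    a = np.asarray(sig_a, dtype=float)
    b = np.asarray(sig_b, dtype=float)
    if a.ndim != 1 or b.ndim != 1:
        raise ValidationError("sync signals must be 1-D")
    if rate <= 0 or max_lag <= 0:
        raise ValidationError("rate and max_lag must be positive")
    min_len = int(np.ceil(2 * max_lag * rate))
    if len(a) < min_len or len(b) < min_len:
        raise ValidationError(
            f"signals shorter than 2*max_lag ({min_len} samples)"
        )
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValidationError("sync signals must be finite")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValidationError(
            "flat synchronisation signal (no clap energy to align on)"
        )
    az = (a - a.mean()) / (a.std() * np.sqrt(len(a)))
    bz = (b - b.mean()) / (b.std() * np.sqrt(len(b)))
    c = signal.correlate(az, bz, mode="full")
    lags = signal.correlation_lags(len(az), len(bz), mode="full")
    max_lag_samples = int(np.floor(max_lag * rate))
    window = np.abs(lags) <= max_lag_samples
    c_w = c[window]
    lags_w = lags[window]
    k = int(np.argmax(c_w))
    peak_lag = float(lags_w[k])
    peak_val = float(c_w[k])
    if refine and 0 < k < len(c_w) - 1:
        y0, y1, y2 = c_w[k - 1], c_w[k], c_w[k + 1]
        denom = y0 - 2 * y1 + y2
        # a parabola is only meaningful through a genuinely curved peak;
        # an isolated impulse (flanks at the noise floor) stays discrete
        if min(y0, y2) > 0 and abs(denom) > 1e-15:
            delta = 0.5 * (y0 - y2) / denom
            if abs(delta) <= 1.0:
                peak_lag += delta
    # correlate(a, b) peaks at lag = -d when b[n] = a[n - d]
    offset = -peak_lag / rate
    return TemporalAlignment(
        offset=offset, confidence=float(np.clip(peak_val, -1.0, 1.0))
    )


def align_dyad(
    mother: SkeletonStream,
    infant: SkeletonStream,
    xf: RigidTransform | None = None,
    ta: TemporalAlignment | None = None,
    rate: float = 30.0,
    max_gap: float = 0.33,
) -> DyadRecording:
    """Build a co-registered, co-sampled recording from two raw streams.

    The infant stream is mapped into the mother sensor's frame by ``xf``,
    its timestamps are shifted onto the mother clock by ``-ta.offset``,
    and both streams are resampled to a shared uniform grid over their
    temporal overlap (which must be at least 1 s).
    """
    if xf is None:
        xf = RigidTransform.identity()
    offset = 0.0 if ta is None else float(ta.offset)
    infant_c = apply_transform(infant, xf)
    infant_c.timestamps = infant_c.timestamps - offset
    mother_c = mother.copy()
    mother_c.frame_id = "common"
    t0 = max(mother_c.timestamps[0], infant_c.timestamps[0])
    t1 = min(mother_c.timestamps[-1], infant_c.timestamps[-1])
    if t1 - t0 < 1.0:
        raise ValidationError(
            f"temporal overlap after offset removal is {t1 - t0:.3f} s; "
            "need at least 1 s"
        )
    t_new = uniform_timestamps(float(t0), float(t1), rate)
    m = resample_to(mother_c, t_new, max_gap=max_gap)
    i = resample_to(infant_c, t_new, max_gap=max_gap)
    return DyadRecording(mother=m, infant=i, rate=rate)
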