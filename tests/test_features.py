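"""Individual and dyadic motion features."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from dyadkin import (
    CANONICAL_FEATURES,
    ActivitySeries,
    DyadRecording,
    DyadSimConfig,
    ExtractionConfig,
    RigidTransform,
    ValidationError,
    activity_ratio,
    apply_transform,
    detect_activity,
    extract_feature_vector,
    face_to_face_ratio,
    heads_distance,
    heads_distance_contributions,
    overlap_ratio,
    pause_ratio,
    quantity_of_movement,
    simulate_dyad,
    synchrony_ratio,
    task_orientation_ratio,
)

from conftest import make_stream


def _activity(moving, rate=1.0, valid=None):
    moving = np.asarray(moving, dtype=bool)
    valid = (
        np.ones_like(moving) if valid is None else np.asarray(valid, bool)
    )
    return ActivitySeries(
        timestamps=np.arange(moving.size) / rate,
        qom=moving.astype(float),
        valid=valid,
        moving=moving & valid,
        threshold=0.5,
        min_duration=0.0,
    )


def _facing_dyad(pos_m, pos_i, ori_m=None, ori_i=None, T=None):
    pos_m = np.atleast_2d(pos_m)
    pos_i = np.atleast_2d(pos_i)
    if T is not None:
        pos_m = np.tile(pos_m, (T, 1))
        pos_i = np.tile(pos_i, (T, 1))
    T = len(pos_m)

    def _ori(ori, default):
        if ori is None:
            ori = default
        ori = np.atleast_2d(np.asarray(ori, dtype=float))
        if len(ori) == 1:
            ori = np.tile(ori, (T, 1))
        return ori / np.linalg.norm(ori, axis=1, keepdims=True)

    to_i = pos_i - pos_m
    to_i = to_i / np.linalg.norm(to_i, axis=1, keepdims=True)
    mother = make_stream(
        {"head": pos_m}, partner="mother", orientation=_ori(ori_m, to_i)
    )
    infant = make_stream(
        {"head": pos_i}, partner="infant", orientation=_ori(ori_i, -to_i)
    )
    return DyadRecording(mother=mother, infant=infant, rate=30.0)


class TestQuantityOfMovement:
    def test_uniform_motion_one_joint(self):
        T = 10
        pos = np.zeros((T, 3))
        pos[:, 0] = np.arange(T) * 0.1  # 0.1 m per frame at 10 Hz
        s = make_stream({"head": pos}, timestamps=np.arange(T) / 10.0)
        qom, valid = quantity_of_movement(s, ("head",))
        assert not valid[0]
        np.testing.assert_allclose(qom[1:], 1.0, atol=1e-12)

    def test_stationary_skeleton_is_zero(self):
        s = make_stream({"head": np.zeros((8, 3))})
        qom, valid = quantity_of_movement(s, ("head",))
        np.testing.assert_allclose(qom[valid], 0.0)

    def test_two_joints_sum_speeds(self):
        T = 6
        h = np.zeros((T, 3))
        h[:, 0] = np.arange(T) * 0.05
        g = np.zeros((T, 3))
        g[:, 1] = np.arange(T) * 0.10
        s = make_stream(
            {"head": h, "hand_left": g}, timestamps=np.arange(T) / 10.0
        )
        qom, valid = quantity_of_movement(s, ("head", "hand_left"))
        np.testing.assert_allclose(qom[valid], 1.5, atol=1e-12)

    def test_absent_joint_named_in_error(self):
        s = make_stream({"head": np.zeros((5, 3))})
        with pytest.raises(ValidationError, match="hand_right"):
            quantity_of_movement(s, ("head", "hand_right"))

    def test_frames_next_to_invalid_are_invalid(self):
        s = make_stream({"head": np.zeros((6, 3))})
        s.joints["head"].valid[3] = False
        _, valid = quantity_of_movement(s, ("head",))
        assert not valid[3] and not valid[4]
        assert valid[2] and valid[5]


class TestDetectActivity:
    def test_direct_count_without_smoothing(self):
        qom = np.array([0, 0, 1, 1, 0, 1, 0, 0, 0, 0], dtype=float)
        act = detect_activity(
            qom,
            np.ones(10, bool),
            np.arange(10) / 30.0,
            threshold=0.1,
            min_duration=0.0,
        )
        assert activity_ratio(act) == pytest.approx(0.3)

    def test_single_frame_spike_removed(self):
        qom = np.zeros(30)
        qom[10] = 1.0
        act = detect_activity(
            qom,
            np.ones(30, bool),
            np.arange(30) / 30.0,
            threshold=0.1,
            min_duration=0.2,
        )
        assert not act.moving.any()

    def test_short_gap_closed(self):
        qom = np.ones(30)
        qom[14:16] = 0.0  # 2-frame dip << 0.2 s at 30 Hz
        act = detect_activity(
            qom,
            np.ones(30, bool),
            np.arange(30) / 30.0,
            threshold=0.1,
            min_duration=0.2,
        )
        assert act.moving.all()

    def test_moving_never_on_invalid_frames(self):
        qom = np.ones(30)
        valid = np.ones(30, bool)
        valid[5:8] = False
        act = detect_activity(
            qom, valid, np.arange(30) / 30.0, threshold=0.1, min_duration=0.2
        )
        assert not act.moving[5:8].any()
        assert act.moving[valid].all()


class TestActivityRatio:
    @pytest.mark.parametrize(
        "moving,expected",
        [
            ([1, 1, 1, 1], 1.0),
            ([0, 0, 0, 0], 0.0),
            ([1, 1, 0, 0, 1], 0.6),
        ],
    )
    def test_hand_counts(self, moving, expected):
        assert activity_ratio(_activity(moving)) == pytest.approx(expected)

    def test_no_valid_frames_rejected(self):
        act = _activity([0, 0], valid=[0, 0])
        with pytest.raises(ValidationError):
            activity_ratio(act)


class TestHeadsDistance:
    def test_unit_separation(self):
        dyad = _facing_dyad([0, 0, 0], [1, 0, 0], T=5)
        d, valid = heads_distance(dyad)
        np.testing.assert_allclose(d[valid], 1.0)

    def test_translation_invariant(self, rng):
        pm = rng.normal(size=(6, 3))
        pi = rng.normal(size=(6, 3)) + 1.0
        shift = np.array([3.0, -2.0, 5.0])
        d1, _ = heads_distance(_facing_dyad(pm, pi))
        d2, _ = heads_distance(_facing_dyad(pm + shift, pi + shift))
        np.testing.assert_allclose(d1, d2, atol=1e-12)

    def test_matches_bruteforce_norm(self, rng):
        pm = rng.normal(size=(20, 3))
        pi = rng.normal(size=(20, 3)) + 2.0
        d, valid = heads_distance(_facing_dyad(pm, pi))
        expected = np.array(
            [np.sqrt(((a - b) ** 2).sum()) for a, b in zip(pm, pi)]
        )
        np.testing.assert_allclose(d[valid], expected[valid], atol=1e-12)


class TestHeadsContributions:
    def test_single_mover_takes_full_share(self):
        T = 10
        pm = np.zeros((T, 3))
        pm[:, 0] = -1.0 - np.arange(T) * 0.01  # along the inter-head axis
        pi = np.tile([1.0, 0, 0], (T, 1))
        shares = heads_distance_contributions(_facing_dyad(pm, pi))
        assert shares == pytest.approx((1.0, 0.0), abs=1e-12)

    def test_mirror_symmetric_motion_splits_evenly(self):
        T = 10
        step = np.zeros((T, 3))
        step[:, 0] = np.arange(T) * 0.01
        pm = np.tile([-1.0, 0, 0], (T, 1)) - step
        pi = np.tile([1.0, 0, 0], (T, 1)) + step
        shares = heads_distance_contributions(_facing_dyad(pm, pi))
        assert shares == pytest.approx((0.5, 0.5), abs=1e-12)

    def test_static_heads_use_half_half_convention(self):
        dyad = _facing_dyad([0, 0, 0], [1, 0, 0], T=5)
        assert heads_distance_contributions(dyad) == (0.5, 0.5)

    def test_contributions_match_distance_change_to_first_order(self, rng):
        T = 50
        scale = 1e-4
        pm = np.tile([-1.0, 0, 0], (T, 1)) + np.cumsum(
            rng.normal(0, scale, (T, 3)), axis=0
        )
        pi = np.tile([1.0, 0, 0], (T, 1)) + np.cumsum(
            rng.normal(0, scale, (T, 3)), axis=0
        )
        dyad = _facing_dyad(pm, pi)
        d, _ = heads_distance(dyad)
        sep = pm[:-1] - pi[:-1]
        u = sep / np.linalg.norm(sep, axis=1, keepdims=True)
        c_m = np.einsum("ij,ij->i", np.diff(pm, axis=0), u)
        c_i = -np.einsum("ij,ij->i", np.diff(pi, axis=0), u)
        np.testing.assert_allclose(
            c_m + c_i, np.diff(d), atol=50 * scale**2 * T
        )


class TestOrientationRatios:
    def test_mutual_gaze_counts_fully(self):
        dyad = _facing_dyad([0, 0, 0], [1, 0, 0], T=5)
        assert face_to_face_ratio(dyad, 30.0) == 1.0

    def test_mother_turned_away_zeroes_ratio(self):
        dyad = _facing_dyad(
            [0, 0, 0], [1, 0, 0], ori_m=[-1.0, 0, 0], T=5
        )
        assert face_to_face_ratio(dyad, 30.0) == 0.0

    def test_threshold_is_inclusive_of_20_degrees(self):
        ori_m = [np.cos(np.radians(20)), np.sin(np.radians(20)), 0.0]
        dyad = _facing_dyad([0, 0, 0], [1, 0, 0], ori_m=ori_m, T=5)
        assert face_to_face_ratio(dyad, 30.0) == 1.0

    def test_task_ratio_at_task_and_away(self):
        task = np.array([0.0, 0.0, 0.0])
        s_at = make_stream(
            {"head": np.tile([1.0, 0, 0], (4, 1))},
            orientation=np.tile([-1.0, 0, 0], (4, 1)),
        )
        s_away = make_stream(
            {"head": np.tile([1.0, 0, 0], (4, 1))},
            orientation=np.tile([1.0, 0, 0], (4, 1)),
        )
        assert task_orientation_ratio(s_at, task, 30.0) == 1.0
        assert task_orientation_ratio(s_away, task, 30.0) == 0.0

    def test_task_ratio_mixture(self):
        ori = np.tile([-1.0, 0, 0], (10, 1))
        ori[5:] = [1.0, 0, 0]
        s = make_stream(
            {"head": np.tile([1.0, 0, 0], (10, 1))}, orientation=ori
        )
        assert task_orientation_ratio(s, np.zeros(3), 30.0) == 0.5


class TestEventCoupling:
    def test_half_of_onsets_answered(self):
        # infant onsets at 1.0 and 5.0 s; mother onsets at 1.5 and 9.0 s
        T, rate = 120, 10.0
        infant = np.zeros(T, bool)
        infant[10:30] = True
        infant[50:70] = True
        mother = np.zeros(T, bool)
        mother[15:35] = True
        mother[90:110] = True
        ratio = synchrony_ratio(
            _activity(infant, rate), _activity(mother, rate), window=2.0
        )
        assert ratio == pytest.approx(0.5)

    def test_responder_without_onsets_scores_zero(self):
        leader = np.zeros(50, bool)
        leader[10:20] = True
        ratio = synchrony_ratio(
            _activity(leader, 10.0), _activity(np.zeros(50, bool), 10.0)
        )
        assert ratio == 0.0

    def test_leader_without_onsets_is_undefined(self):
        ratio = synchrony_ratio(
            _activity(np.zeros(50, bool), 10.0),
            _activity(np.ones(50, bool), 10.0),
        )
        assert np.isnan(ratio)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValidationError, match="length"):
            synchrony_ratio(_activity([0, 1]), _activity([0, 1, 0]))

    def test_overlap_and_pause_hand_counts(self):
        a = _activity([1, 1, 0, 0, 1])
        b = _activity([1, 0, 0, 1, 1])
        assert overlap_ratio(a, b) == pytest.approx(0.4)
        assert pause_ratio(a, b) == pytest.approx(0.2)

    def test_disjoint_activity_has_zero_overlap(self):
        a = _activity([1, 1, 0, 0])
        b = _activity([0, 0, 1, 1])
        assert overlap_ratio(a, b) == 0.0

    def test_overlap_with_self_equals_activity_ratio(self, rng):
        m = rng.random(200) < 0.4
        a = _activity(m)
        assert overlap_ratio(a, a) == pytest.approx(activity_ratio(a))

    @given(st.integers(0, 2**32 - 1))
    def test_state_fractions_partition_unity(self, seed):
        r = np.random.default_rng(seed)
        a = _activity(r.random(100) < 0.5)
        b = _activity(r.random(100) < 0.3)
        both = overlap_ratio(a, b)
        neither = pause_ratio(a, b)
        one = np.mean(a.moving ^ b.moving)
        assert both + neither + one == pytest.approx(1.0, abs=1e-12)


class TestExtractFeatureVector:
    def test_static_dyad_degenerate_features(self):
        dyad = _facing_dyad([0, 0, 0], [1, 0, 0], T=200)
        fs = extract_feature_vector(
            dyad, ExtractionConfig(joints=("head",))
        )
        assert fs["mother_qom_mean"] == 0.0
        assert fs["mother_qom_sd"] == 0.0
        assert fs["mother_activity_ratio"] == 0.0
        assert fs["infant_activity_ratio"] == 0.0
        assert fs["overlap_ratio"] == 0.0
        assert fs["pause_ratio"] == 1.0
        assert fs["mother_heads_contribution"] == 0.5
        assert np.isnan(fs["sync_parent_to_infant"])

    def test_vector_has_canonical_names_in_order(self, short_dyad):
        rec, _ = short_dyad
        fs = extract_feature_vector(rec)
        assert fs.names == CANONICAL_FEATURES
        assert fs.to_array().shape == (17,)

    def test_ratio_features_bounded(self, short_dyad):
        rec, _ = short_dyad
        fs = extract_feature_vector(rec)
        for name in CANONICAL_FEATURES:
            if name.endswith("_ratio") or "contribution" in name or (
                name.startswith("sync")
            ):
                v = fs[name]
                assert np.isnan(v) or 0.0 <= v <= 1.0

    def test_invariant_under_rigid_transform_and_time_shift(self, short_dyad):
        rec, _ = short_dyad
        cfg = ExtractionConfig()
        base = extract_feature_vector(rec, cfg)

        R = Rotation.from_euler("xyz", [10, -30, 45], degrees=True)
        xf = RigidTransform(R.as_matrix(), np.array([2.0, -1.0, 0.5]))
        mother = apply_transform(rec.mother, xf)
        infant = apply_transform(rec.infant, xf)
        mother.timestamps = mother.timestamps + 100.0
        infant.timestamps = infant.timestamps + 100.0
        moved = DyadRecording(mother=mother, infant=infant, rate=rec.rate)
        cfg_moved = dataclasses.replace(
            cfg, task_point=tuple(xf.apply(np.array(cfg.task_point)))
        )
        got = extract_feature_vector(moved, cfg_moved)
        for name in CANONICAL_FEATURES:
            b, g = base[name], got[name]
            if np.isnan(b):
                assert np.isnan(g)
            else:
                assert g == pytest.approx(b, abs=1e-9), name
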