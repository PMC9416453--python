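"""REBA rule engine: angles, band scores, table lookups, risk levels,
smoothing and distributions."""

import numpy as np
import pytest

from ergoreba.reba import (Coupling, JointAngles, RebaAdjustments,
                           RebaPartialScores, RebaScoreVector, RiskLevel,
                           compute_joint_angles, partial_scores,
                           risk_distribution, risk_level, score_sequence,
                           smooth_scores, total_score)
from ergoreba.skeleton import JointId, SkeletonFrame, SkeletonSequence


def neutral_angles(**overrides):
    base = dict(
        trunk_flexion=0.0, trunk_side_bend=0.0, trunk_twist=0.0,
        neck_flexion=10.0, neck_side_bend_or_twist=False,
        legs_knee_flexion_left=5.0, legs_knee_flexion_right=5.0,
        legs_bilateral_support=True,
        upper_arm_flexion_left=5.0, upper_arm_flexion_right=5.0,
        upper_arm_abducted_left=False, upper_arm_abducted_right=False,
        shoulder_raised_left=False, shoulder_raised_right=False,
        lower_arm_flexion_left=80.0, lower_arm_flexion_right=80.0,
    )
    base.update(overrides)
    return JointAngles(**base)


ALL_PARTIALS = [
    RebaPartialScores(n, t, l, ua, la)
    for n in range(1, 4) for t in range(1, 6) for l in range(1, 5)
    for ua in range(1, 7) for la in range(1, 3)
]

ALL_ADJUSTMENTS = [
    RebaAdjustments(load_kg=load, coupling=c, activity_static=s,
                    activity_repeated=r, activity_rapid_change=q)
    for load in (0.0, 7.0, 15.0) for c in Coupling
    for s in (False, True) for r in (False, True) for q in (False, True)
]


class TestAnglesFromGeometry:
    def test_upright_frame_is_neutral(self, upright_frame):
        a = compute_joint_angles(upright_frame)
        assert a.trunk_flexion == pytest.approx(0.0, abs=1e-6)
        assert a.trunk_side_bend == pytest.approx(0.0, abs=1e-6)
        assert a.trunk_twist == pytest.approx(0.0, abs=1e-6)
        assert a.legs_bilateral_support
        assert a.legs_knee_flexion_max == pytest.approx(0.0, abs=1e-6)
        assert a.lower_arm_flexion_left == pytest.approx(80.0, abs=1e-6)
        assert a.lower_arm_flexion_right == pytest.approx(80.0, abs=1e-6)

    def test_trunk_tilted_45_degrees_sagittal(self, upright_frame):
        # rotate every joint above the hips 45 deg about the hip (z) axis
        pos = upright_frame.positions.copy()
        mid_hip = pos[8:10].mean(axis=0)
        c, s = np.cos(np.radians(45)), np.sin(np.radians(45))
        rot = np.array([[c, s, 0.0], [-s, c, 0.0], [0.0, 0.0, 1.0]])
        pos[:8] = (pos[:8] - mid_hip) @ rot.T + mid_hip
        a = compute_joint_angles(SkeletonFrame(pos))
        assert a.trunk_flexion == pytest.approx(45.0, abs=1e-6)
        assert a.trunk_side_bend == pytest.approx(0.0, abs=1e-6)

    def test_angles_match_independent_rederivation(self, mixed_sequence):
        for frame in mixed_sequence.frames[::60]:
            a = compute_joint_angles(frame)
            p = frame.as_mapping()
            # knee: interior angle via arccos on raw coordinates
            thigh = p[JointId.RIGHT_KNEE] - p[JointId.RIGHT_HIP]
            shank = p[JointId.RIGHT_ANKLE] - p[JointId.RIGHT_KNEE]
            expected = np.degrees(np.arccos(np.clip(
                thigh @ shank / np.linalg.norm(thigh)
                / np.linalg.norm(shank), -1, 1)))
            assert a.legs_knee_flexion_right == pytest.approx(expected,
                                                              abs=1e-6)
            # elbow: 180 - interior angle
            ua = p[JointId.LEFT_SHOULDER] - p[JointId.LEFT_ELBOW]
            fa = p[JointId.LEFT_WRIST] - p[JointId.LEFT_ELBOW]
            interior = np.degrees(np.arccos(np.clip(
                ua @ fa / np.linalg.norm(ua) / np.linalg.norm(fa), -1, 1)))
            assert a.lower_arm_flexion_left == pytest.approx(
                180.0 - interior, abs=1e-6)

    def test_zero_length_segment_names_it(self, upright_frame):
        pos = upright_frame.positions.copy()
        pos[4] = pos[2]  # elbow onto shoulder
        from ergoreba.reba import AngleUndefinedError
        with pytest.raises(AngleUndefinedError, match="upper arm"):
            compute_joint_angles(SkeletonFrame(pos))


class TestPartialScores:
    def test_all_neutral_gives_all_ones(self):
        p = partial_scores(neutral_angles())
        assert (p.neck, p.trunk, p.legs, p.upper_arms, p.lower_arms) == \
            (1, 1, 1, 1, 1)

    @pytest.mark.parametrize("flexion,expected", [
        (0.0, 1), (15.0, 2), (-15.0, 2), (45.0, 3), (-30.0, 3), (70.0, 4)])
    def test_trunk_bands(self, flexion, expected):
        assert partial_scores(
            neutral_angles(trunk_flexion=flexion)).trunk == expected

    def test_trunk_twist_modifier(self):
        p = partial_scores(neutral_angles(trunk_flexion=70.0,
                                          trunk_twist=25.0))
        assert p.trunk == 5

    @pytest.mark.parametrize("flexion,expected", [
        (80.0, 1), (10.0, 2), (120.0, 2), (60.0, 1), (100.0, 1)])
    def test_lower_arm_bands(self, flexion, expected):
        p = partial_scores(neutral_angles(lower_arm_flexion_left=flexion,
                                          lower_arm_flexion_right=flexion))
        assert p.lower_arms == expected

    @pytest.mark.parametrize("flexion,abducted,raised,expected", [
        (0.0, False, False, 1), (-30.0, False, False, 2),
        (30.0, False, False, 2), (60.0, False, False, 3),
        (120.0, False, False, 4), (120.0, True, True, 6)])
    def test_upper_arm_bands(self, flexion, abducted, raised, expected):
        p = partial_scores(neutral_angles(
            upper_arm_flexion_right=flexion,
            upper_arm_abducted_right=abducted,
            shoulder_raised_right=raised))
        assert p.upper_arms == expected

    def test_worst_arm_wins(self):
        p = partial_scores(neutral_angles(upper_arm_flexion_left=120.0))
        assert p.upper_arms == 4

    @pytest.mark.parametrize("neck,side,expected", [
        (10.0, False, 1), (30.0, False, 2), (-5.0, False, 2),
        (10.0, True, 2), (30.0, True, 3)])
    def test_neck_bands(self, neck, side, expected):
        p = partial_scores(neutral_angles(neck_flexion=neck,
                                          neck_side_bend_or_twist=side))
        assert p.neck == expected

    @pytest.mark.parametrize("knee,bilateral,expected", [
        (10.0, True, 1), (45.0, True, 2), (70.0, True, 3),
        (10.0, False, 2), (70.0, False, 4)])
    def test_legs_bands(self, knee, bilateral, expected):
        p = partial_scores(neutral_angles(
            legs_knee_flexion_left=knee, legs_knee_flexion_right=0.0,
            legs_bilateral_support=bilateral))
        assert p.legs == expected


class TestTotalScore:
    def test_all_minimal_is_one(self):
        p = RebaPartialScores(1, 1, 1, 1, 1)
        assert total_score(p, RebaAdjustments()) == 1

    def test_exhaustive_range_is_1_to_15(self):
        totals = {total_score(p, a)
                  for p in ALL_PARTIALS for a in ALL_ADJUSTMENTS}
        assert min(totals) == 1
        assert max(totals) == 15
        assert totals == set(range(1, 16))

    def test_monotone_in_every_partial_and_adjustment(self):
        default = RebaAdjustments()
        fields = ["neck", "trunk", "legs", "upper_arms", "lower_arms"]
        limits = dict(zip(fields, [3, 5, 4, 6, 2]))
        for p in ALL_PARTIALS:
            base = total_score(p, default)
            for f in fields:
                v = getattr(p, f)
                if v < limits[f]:
                    bumped = RebaPartialScores(
                        **{k: (getattr(p, k) + 1 if k == f
                               else getattr(p, k)) for k in fields})
                    assert total_score(bumped, default) >= base
        p = RebaPartialScores(2, 3, 2, 3, 2)
        seq = [total_score(p, RebaAdjustments(load_kg=kg))
               for kg in (0, 7, 15)]
        assert seq == sorted(seq)
        seq = [total_score(p, RebaAdjustments(coupling=c)) for c in Coupling]
        assert seq == sorted(seq)

    def test_load_and_activity_raise_score(self):
        p = RebaPartialScores(3, 5, 4, 6, 2)
        assert total_score(p, RebaAdjustments(
            load_kg=15, coupling=Coupling.UNACCEPTABLE,
            activity_static=True, activity_repeated=True,
            activity_rapid_change=True)) == 15


class TestRiskLevels:
    @pytest.mark.parametrize("total,expected", [
        (1.0, RiskLevel.NEGLIGIBLE), (1.5, RiskLevel.NEGLIGIBLE),
        (2.0, RiskLevel.LOW), (3.999, RiskLevel.LOW),
        (4.0, RiskLevel.MEDIUM), (7.999, RiskLevel.MEDIUM),
        (8.0, RiskLevel.HIGH), (10.999, RiskLevel.HIGH),
        (11.0, RiskLevel.VERY_HIGH), (15.0, RiskLevel.VERY_HIGH)])
    def test_threshold_binning(self, total, expected):
        assert risk_level(total) is expected

    def test_bins_partition_fine_grid(self):
        for t in np.linspace(0.01, 15.0, 2000):
            assert risk_level(float(t)) is not None  # exactly one bin

    def test_distribution_sums_to_100(self, rng):
        scores = [RebaScoreVector(1, 1, 1, 1, 1, t)
                  for t in rng.uniform(1, 15, size=500)]
        dist = risk_distribution(scores)
        assert sum(dist.values()) == pytest.approx(100.0, abs=1e-9)

    def test_distribution_direct_binning(self):
        scores = [RebaScoreVector(1, 1, 1, 1, 1, t)
                  for t in (1, 3, 5, 9, 12)]
        dist = risk_distribution(scores)
        assert all(v == pytest.approx(20.0) for v in dist.values())

    def test_empty_list_errors(self):
        with pytest.raises(ValueError):
            risk_distribution([])


class TestScoreSequence:
    def test_constant_posture_constant_scores(self, upright_frame):
        seq = SkeletonSequence(
            [SkeletonFrame(upright_frame.positions, i) for i in range(10)])
        scores = score_sequence(seq)
        assert len(scores) == 10
        assert all(s == scores[0] for s in scores)
        assert scores[0].total == 1.0

    def test_matches_per_frame_composition(self, mixed_sequence):
        from ergoreba.reba import score_frame
        scores = score_sequence(mixed_sequence)
        assert len(scores) == len(mixed_sequence)
        for i in (0, 57, 119):
            assert scores[i] == score_frame(mixed_sequence.frames[i])


class TestSmoothing:
    @staticmethod
    def sliding_lsq(y, window, polyorder):
        """Independent oracle: centered sliding least-squares poly fit."""
        half = window // 2
        out = np.empty_like(y, dtype=float)
        n = len(y)
        for i in range(n):
            lo, hi = i - half, i + half + 1
            if lo < 0 or hi > n:
                continue  # interior only; edges handled separately
            t = np.arange(lo, hi) - i
            coef = np.polyfit(t, y[lo:hi], polyorder)
            out[i] = np.polyval(coef, 0.0)
        return out, half

    def test_constant_sequence_unchanged(self):
        scores = [RebaScoreVector(1, 2, 3, 4, 1, 7) for _ in range(40)]
        out = smooth_scores(scores, 13, 3)
        for s in out:
            np.testing.assert_allclose(s.as_array(), scores[0].as_array(),
                                       atol=1e-9)

    def test_linear_ramp_reproduced(self):
        scores = [RebaScoreVector(*(i * 0.1 + np.arange(6)))
                  for i in range(40)]
        out = smooth_scores(scores, 13, 3)
        for got, want in zip(out, scores):
            np.testing.assert_allclose(got.as_array(), want.as_array(),
                                       atol=1e-9)

    def test_matches_direct_least_squares(self, rng):
        arr = rng.normal(size=(60, 6))
        scores = [RebaScoreVector.from_array(r) for r in arr]
        out = np.stack([s.as_array() for s in smooth_scores(scores, 13, 3)])
        for c in range(6):
            expected, half = self.sliding_lsq(arr[:, c], 13, 3)
            np.testing.assert_allclose(out[half:-half, c],
                                       expected[half:-half], atol=1e-9)

    def test_even_window_normalized_up(self):
        scores = [RebaScoreVector(1, 1, 1, 1, 1, 1) for _ in range(40)]
        out = smooth_scores(scores, 12, 3)  # acts as window 13
        assert len(out) == 40

    def test_short_sequence_warns_and_passes_through(self):
        scores = [RebaScoreVector(1, 1, 1, 1, 1, 5) for _ in range(5)]
        with pytest.warns(UserWarning, match="shorter"):
            out = smooth_scores(scores, 13, 3)
        assert out == scores
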