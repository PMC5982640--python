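"""Kinematic features: angles, personal coordinate system, buffered speeds,
quaternion rotations and the feature-extraction pipeline."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.transform import Rotation

from rehabmotion.features import (
    ConfigError, DegeneratePoseError, DomainError, FeatureSeries, FeatureSpec,
    abduction_preset, angle_at_joint, angle_from_sides, assessment_preset,
    buffered_speed, build_pcs, cross_product, default_buffer_len,
    extract_features, quaternion_to_rotations, to_personal_coords, vector_angle,
)
from rehabmotion.synth import SyntheticMotionSpec, simulate_abduction

finite = st.floats(-5, 5, allow_nan=False)


class TestAngles:
    @pytest.mark.parametrize("sides,expected", [
        ((1, 1, 1), 60.0),
        ((5, 3, 4), 90.0),
        ((np.sqrt(2), 1, 1), 90.0),
    ])
    def test_cosine_law_worked_examples(self, sides, expected):
        assert angle_from_sides(*sides) == pytest.approx(expected, abs=1e-9)

    def test_triangle_inequality_enforced(self):
        with pytest.raises(DomainError):
            angle_from_sides(10, 1, 1)
        # flat triangle allowed at the boundary
        assert angle_from_sides(2, 1, 1) == pytest.approx(180.0)

    @pytest.mark.parametrize("pts,expected", [
        (((1, 0, 0), (0, 0, 0), (0, 1, 0)), 90.0),
        (((2, 0, 0), (1, 0, 0), (0, 0, 0)), 180.0),
    ])
    def test_angle_at_joint_examples(self, pts, expected):
        assert angle_at_joint(*pts) == pytest.approx(expected, abs=1e-9)

    def test_coincident_points_rejected(self):
        with pytest.raises(DomainError):
            angle_at_joint((0, 0, 0), (0, 0, 0), (1, 0, 0))

    def test_cosine_law_agrees_with_vector_formulation(self, rng):
        """Dual-formula oracle: the cosine-law angle equals the direct
        arccos of the normalized dot product on 1000 random triples."""
        for _ in range(1000):
            p = rng.normal(size=(3, 3))
            u, v = p[0] - p[1], p[2] - p[1]
            if min(np.linalg.norm(u), np.linalg.norm(v)) < 1e-6:
                continue
            direct = np.degrees(np.arccos(np.clip(
                u @ v / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1)))
            assert angle_at_joint(p[0], p[1], p[2]) == pytest.approx(direct, abs=1e-9)


class TestCrossProduct:
    @pytest.mark.parametrize("u,v,expected", [
        ((1, 0, 0), (0, 1, 0), (0, 0, 1)),
        ((1, 2, 3), (4, 5, 6), (-3, 6, -3)),
    ])
    def test_component_formula(self, u, v, expected):
        np.testing.assert_allclose(cross_product(u, v), expected)

    @given(st.tuples(finite, finite, finite))
    def test_parallel_vectors_vanish(self, u):
        np.testing.assert_allclose(cross_product(u, u), np.zeros(3), atol=1e-12)

    @given(st.tuples(finite, finite, finite), st.tuples(finite, finite, finite))
    def test_matches_numpy(self, u, v):
        np.testing.assert_allclose(cross_product(u, v), np.cross(u, v), atol=1e-9)


class TestPersonalCoordinateSystem:
    def test_axis_aligned_configuration(self):
        pcs = build_pcs((-0.1, 1.0, 2.0), (0.1, 1.0, 2.0), (0, 1, 0, 0))
        np.testing.assert_allclose(pcs.origin, [0, 0, 2], atol=1e-12)
        np.testing.assert_allclose(pcs.axis_ud, [0, 1, 0], atol=1e-12)
        np.testing.assert_allclose(np.abs(pcs.axis_lr), [1, 0, 0], atol=1e-12)

    def test_equivariance_under_rotation_about_vertical(self):
        """Rotating hips and floor by 37 deg about the vertical rotates
        every PCS axis by exactly 37 deg."""
        rot = Rotation.from_euler("y", 37, degrees=True)
        hl, hr = np.array([-0.1, 1.0, 2.0]), np.array([0.12, 1.05, 2.1])
        base = build_pcs(hl, hr, (0, 1, 0, 0))
        rotated = build_pcs(rot.apply(hl), rot.apply(hr), (0, 1, 0, 0))
        for axis in ("axis_lr", "axis_ud", "axis_fb"):
            np.testing.assert_allclose(getattr(rotated, axis),
                                       rot.apply(getattr(base, axis)), atol=1e-9)

    def test_coincident_hips_degenerate(self):
        with pytest.raises(DegeneratePoseError):
            build_pcs((0, 1, 2), (0, 1, 2), (0, 1, 0, 0))
        with pytest.raises(DegeneratePoseError):
            build_pcs((0, 0.5, 2), (0, 1.5, 2), (0, 1, 0, 0))  # vertically stacked

    def test_rotation_invariance_of_pcs_sequence(self, clean_trial):
        """A subject rotated 90 deg about the vertical yields identical
        PCS-expressed joint positions."""
        seq, _ = clean_trial
        rot = Rotation.from_euler("y", 90, degrees=True)
        rotated = seq.copy()
        for f in rotated.frames:
            for j in f.joints:
                f.joints[j] = rot.apply(f.joints[j])
        a, b = to_personal_coords(seq), to_personal_coords(rotated)
        for fa, fb in zip(a.frames[::40], b.frames[::40]):
            for j in fa.joints:
                np.testing.assert_allclose(fa.joints[j], fb.joints[j], atol=1e-6)

    def test_translation_invariance(self, clean_trial):
        seq, _ = clean_trial
        shifted = seq.copy()
        for f in shifted.frames:
            for j in f.joints:
                f.joints[j] = f.joints[j] + np.array([1.0, 0.0, 0.5])
        a, b = to_personal_coords(seq), to_personal_coords(shifted)
        for fa, fb in zip(a.frames[::60], b.frames[::60]):
            for j in fa.joints:
                np.testing.assert_allclose(fa.joints[j], fb.joints[j], atol=1e-9)

    def test_hips_straddle_origin_symmetrically(self, clean_trial):
        seq, _ = clean_trial
        local = to_personal_coords(seq)
        f = local.frames[0]
        assert f.joints["hip_left"][0] == pytest.approx(-f.joints["hip_right"][0],
                                                        abs=1e-9)


class TestBufferedSpeed:
    def test_constant_position_is_zero(self):
        out = buffered_speed(np.zeros((100, 3)), 15, 60.0)
        assert np.all(np.isnan(out[:14]))
        np.testing.assert_allclose(out[14:], 0.0)

    def test_uniform_motion_recovers_speed(self):
        # 0.01 m per frame at 60 Hz -> 0.6 m/s
        pos = np.outer(np.arange(100) * 0.01, [1, 0, 0])
        out = buffered_speed(pos, 15, 60.0)
        np.testing.assert_allclose(out[14:], 0.6, atol=1e-12)

    def test_magnitude_mode_matches_bruteforce_window_mean(self, rng):
        """Naive re-computation oracle: averaging the per-frame speed
        magnitudes over each buffer window."""
        pos = np.cumsum(rng.normal(size=(200, 3)) * 0.01, axis=0)
        bl, fps = 15, 60.0
        out = buffered_speed(pos, bl, fps, average="magnitude")
        speeds = np.linalg.norm(np.diff(pos, axis=0), axis=1) * fps
        for i in range(bl - 1, 200):
            window = speeds[i - bl + 1:i]
            assert out[i] == pytest.approx(window.mean(), abs=1e-12)

    def test_velocity_mode_is_magnitude_of_mean_velocity(self, rng):
        pos = np.cumsum(rng.normal(size=(120, 2)) * 0.01, axis=0)
        bl, fps = 15, 60.0
        out = buffered_speed(pos, bl, fps)
        vel = np.diff(pos, axis=0) * fps
        for i in range(bl - 1, 120):
            expected = np.linalg.norm(vel[i - bl + 1:i].mean(axis=0))
            assert out[i] == pytest.approx(expected, abs=1e-12)

    def test_masked_prefix_length_exact(self):
        out = buffered_speed(np.random.default_rng(0).normal(size=50), 10, 60.0)
        assert np.isnan(out[:9]).all() and not np.isnan(out[9:]).any()

    def test_short_series_rejected(self):
        with pytest.raises(DomainError):
            buffered_speed(np.zeros(10), 15, 60.0)

    def test_buffer_spans_quarter_second(self):
        assert default_buffer_len(60.0) == 15
        assert default_buffer_len(120.0) == 30


class TestQuaternionRotations:
    def test_identity(self):
        angles, lock = quaternion_to_rotations((1, 0, 0, 0))
        np.testing.assert_allclose(angles, (0, 0, 0), atol=1e-9)
        assert not lock

    def test_single_axis_rotation(self):
        q = (np.sqrt(0.5), np.sqrt(0.5), 0, 0)  # 90 deg about parent x
        angles, lock = quaternion_to_rotations(q)
        np.testing.assert_allclose(angles, (90, 0, 0), atol=1e-6)
        assert not lock

    def test_compose_then_decompose_round_trip(self, rng):
        for _ in range(50):
            euler = rng.uniform(-80, 80, size=3)  # away from gimbal lock
            q = Rotation.from_euler("XYZ", euler, degrees=True).as_quat(scalar_first=True)
            angles, lock = quaternion_to_rotations(q)
            assert not lock
            np.testing.assert_allclose(angles, euler, atol=1e-6)

    def test_gimbal_lock_flagged(self):
        q = Rotation.from_euler("XYZ", [30, 90, 0], degrees=True).as_quat(scalar_first=True)
        _, lock = quaternion_to_rotations(q)
        assert lock

    def test_non_unit_quaternion_rejected(self):
        with pytest.raises(DomainError):
            quaternion_to_rotations((2, 0, 0, 0))


class TestExtractFeatures:
    def test_static_pose_speeds_vanish(self):
        spec = SyntheticMotionSpec(noise_sd=0.0, peak_abduction=30.0, seed=0)
        seq, _ = simulate_abduction(spec)
        # truncate to the initial rest only
        seq.frames = seq.frames[:50]
        fs = extract_features(seq, abduction_preset())
        v = fs.values[fs.valid_from:]
        np.testing.assert_allclose(v[:, 0], 0.0, atol=1e-9)   # hip center speed
        np.testing.assert_allclose(v[:, 1], 0.0, atol=1e-9)   # shoulder speed
        np.testing.assert_allclose(v[:, 2], 0.0, atol=1e-9)   # angular speed
        assert np.ptp(v[:, 3]) < 1e-9                          # constant angle

    def test_peak_angle_matches_generator(self, clean_trial):
        seq, _ = clean_trial
        fs = extract_features(seq, abduction_preset())
        assert np.nanmax(fs.column("hip_right_frontal_angle")) == pytest.approx(
            40.0, abs=0.5)

    def test_preset_arity(self, clean_trial):
        fs = extract_features(clean_trial[0], abduction_preset())
        assert len(fs.feature_names) == 4

    def test_extraction_deterministic(self, noisy_trial):
        seq, _ = noisy_trial
        a = extract_features(seq, assessment_preset())
        b = extract_features(seq, assessment_preset())
        assert np.array_equal(a.values, b.values, equal_nan=True)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ConfigError):
            FeatureSpec("x", "wavelet", {})

    def test_rotation_kind_recovers_leg_rotation(self, clean_trial):
        """The hip_right orientation quaternion encodes the frontal leg
        rotation; the 'rotation' feature recovers its peak angle."""
        seq, _ = clean_trial
        specs = [FeatureSpec("hip_roll", "rotation",
                             {"joint": "hip_right", "component": "roll"})]
        fs = extract_features(seq, specs)
        assert np.max(np.abs(fs.column("hip_roll"))) == pytest.approx(40.0, abs=0.5)

    def test_pcs_position_kind(self, clean_trial):
        seq, _ = clean_trial
        specs = [FeatureSpec("head_height", "pcs_position",
                             {"joint": "head", "axis": "ud"})]
        fs = extract_features(seq, specs)
        assert np.all(fs.column("head_height") > 1.5)  # head stays above hips

    def test_feature_spec_config_round_trip(self, tmp_path):
        from rehabmotion.features import load_feature_specs, save_feature_specs
        specs = assessment_preset()
        path = save_feature_specs(specs, tmp_path / "specs.json")
        assert load_feature_specs(path) == specs

    def test_feature_series_csv_round_trip(self, clean_trial, tmp_path):
        fs = extract_features(clean_trial[0], abduction_preset())
        path = fs.to_csv(tmp_path / "features.csv")
        back = FeatureSeries.from_csv(path, frame_rate=fs.frame_rate)
        assert back.feature_names == fs.feature_names
        assert back.valid_from == fs.valid_from
        np.testing.assert_allclose(back.values, fs.values, atol=1e-12)
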