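"""Forward kinematics, representation conversions, Jacobian and marker-based
joint-angle extraction for the two-link, 4-DOF arm model."""

import numpy as np
import pytest

from armik.arm_model import (
    AbsoluteAngles,
    AnatomicalAngles,
    MarkerFrame,
    SegmentLengths,
    absolute_to_anatomical,
    anatomical_to_absolute,
    estimate_joint_centre,
    extract_joint_angles,
    forward_kinematics,
    numeric_jacobian,
)
from conftest import random_anatomical


def _rotz(a):
    return np.array([[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]])


def _rot_axis(axis, a):
    """Rodrigues rotation matrix about a unit axis."""
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * K @ K


def oracle_forward(a: AnatomicalAngles, lengths: SegmentLengths):
    """Independent sequential-rotation-matrix composition of the same convention.

    Start from the arm hanging down (both segments along -z, flexion plane
    towards -z's projection): rotate elevation about the in-plane horizontal
    axis, then azimuth about z; humeral rotation about the upper-arm axis;
    flexion opens the elbow in the rotated flexion plane.
    """
    down = np.array([0.0, 0.0, -1.0])
    # upper arm direction: elevation theta from vertical towards +x, then yaw eta
    u = _rotz(a.eta) @ _rot_axis(np.array([0.0, 1.0, 0.0]), -a.theta) @ down
    elbow = lengths.upper_arm * u
    # flexion-plane reference: projection of down onto plane normal to u
    m0 = down - np.dot(down, u) * u
    m0 /= np.linalg.norm(m0)
    m = _rot_axis(u, a.zeta) @ m0
    v = np.cos(np.pi - a.phi) * u + np.sin(np.pi - a.phi) * m
    return elbow, elbow + lengths.forearm * v


class TestForwardKinematics:
    def test_hanging_arm_fully_extended(self):
        l = SegmentLengths(0.3, 0.3)
        elbow, wrist = forward_kinematics(AnatomicalAngles(0, 0, 0, np.pi), l)
        np.testing.assert_allclose(elbow, [0, 0, -0.3], atol=1e-12)
        np.testing.assert_allclose(wrist, [0, 0, -0.6], atol=1e-12)

    def test_horizontal_fully_extended(self, lengths):
        elbow, wrist = forward_kinematics(AnatomicalAngles(np.pi / 2, 0, 0, np.pi), lengths)
        np.testing.assert_allclose(elbow, [0.3, 0, 0], atol=1e-12)
        np.testing.assert_allclose(wrist, [0.55, 0, 0], atol=1e-12)

    def test_matches_rotation_matrix_oracle(self, lengths, rng):
        for _ in range(50):
            a = random_anatomical(rng)
            elbow, wrist = forward_kinematics(a, lengths)
            oe, ow = oracle_forward(a, lengths)
            np.testing.assert_allclose(elbow, oe, atol=1e-12)
            np.testing.assert_allclose(wrist, ow, atol=1e-12)

    def test_segment_lengths_conserved(self, lengths, rng):
        for _ in range(20):
            a = random_anatomical(rng)
            elbow, wrist = forward_kinematics(a, lengths)
            assert np.isclose(np.linalg.norm(elbow), lengths.upper_arm)
            assert np.isclose(np.linalg.norm(wrist - elbow), lengths.forearm)

    def test_angle_range_validation(self):
        with pytest.raises(ValueError):
            AnatomicalAngles(theta=-0.1, eta=0, zeta=0, phi=np.pi)
        with pytest.raises(ValueError):
            AnatomicalAngles(theta=0.5, eta=0, zeta=0, phi=0.0)
        with pytest.raises(ValueError):
            AbsoluteAngles(theta=0.5, eta=0, beta=3.5, alpha=0)
        with pytest.raises(ValueError):
            SegmentLengths(0.0, 0.3)


class TestRepresentationConversion:
    def test_full_extension_gives_equal_angles(self):
        b = anatomical_to_absolute(AnatomicalAngles(0.7, 0.3, 1.2, np.pi))
        assert np.isclose(b.beta, 0.7) and np.isclose(b.alpha, 0.3)

    def test_forearm_spherical_oracle(self, lengths):
        a = AnatomicalAngles(np.pi / 2, 0, 0, np.pi / 2)
        b = anatomical_to_absolute(a)
        _, wrist = forward_kinematics(a, lengths)
        elbow, _ = forward_kinematics(a, lengths)
        v = (wrist - elbow) / np.linalg.norm(wrist - elbow)
        assert np.isclose(b.beta, np.arccos(-v[2]), atol=1e-12)

    def test_round_trip_identity(self, rng):
        for _ in range(1000):
            a = random_anatomical(rng)
            a2 = absolute_to_anatomical(anatomical_to_absolute(a))
            np.testing.assert_allclose(a.as_array(), a2.as_array(), atol=1e-10)

    def test_representation_equivalence_in_forward_kinematics(self, lengths, rng):
        for _ in range(200):
            a = random_anatomical(rng)
            b = anatomical_to_absolute(a)
            _, wa = forward_kinematics(a, lengths)
            _, wb = forward_kinematics(b, lengths)
            np.testing.assert_allclose(wa, wb, atol=1e-12)

    def test_collinear_gives_phi_pi_zeta_zero(self):
        a = absolute_to_anatomical(AbsoluteAngles(theta=0.8, eta=0.2, beta=0.8, alpha=0.2))
        assert np.isclose(a.phi, np.pi) and a.zeta == 0.0

    def test_phi_matches_dot_product_oracle(self, rng):
        for _ in range(100):
            b = AbsoluteAngles(
                theta=rng.uniform(0.1, np.pi - 0.1),
                eta=rng.uniform(-np.pi, np.pi),
                beta=rng.uniform(0.1, np.pi - 0.1),
                alpha=rng.uniform(-np.pi, np.pi),
            )
            l = SegmentLengths(1.0, 1.0)
            elbow, wrist = forward_kinematics(b, l)
            u = elbow
            v = wrist - elbow
            cos_phi = np.dot(-u, v)
            try:
                a = absolute_to_anatomical(b)
            except ValueError:
                assert cos_phi > 1 - 1e-8  # antiparallel segments
                continue
            np.testing.assert_allclose(a.phi, np.arccos(np.clip(cos_phi, -1, 1)), atol=1e-10)

    def test_antiparallel_errors(self):
        with pytest.raises(ValueError):
            # forearm folded exactly back onto the upper arm
            absolute_to_anatomical(AbsoluteAngles(theta=0.8, eta=0.2, beta=np.pi - 0.8, alpha=0.2 + np.pi))


class TestJacobian:
    def test_phi_column_tangential_at_full_extension(self, lengths):
        a = AnatomicalAngles(np.pi / 2, 0.3, 0.4, np.pi - 1e-7)
        J = numeric_jacobian(a, lengths)
        elbow, wrist = forward_kinematics(a, lengths)
        forearm_axis = (wrist - elbow) / np.linalg.norm(wrist - elbow)
        # at the extension extremum the phi column has no radial component
        assert abs(np.dot(J[:, 3], forearm_axis)) < 1e-4

    def test_step_halving_agreement(self, lengths, rng):
        a = random_anatomical(rng)
        J1 = numeric_jacobian(a, lengths, step=1e-5)
        J2 = numeric_jacobian(a, lengths, step=5e-6)
        # richer-step oracle: central differences converge O(h^2)
        np.testing.assert_allclose(J1, J2, rtol=1e-6, atol=1e-8)

    def test_velocity_consistency_along_trajectory(self, lengths):
        # x_dot = J q_dot against finite differences of the wrist path
        t = np.linspace(0, 1, 11)
        q = lambda tt: np.array(
            [1.0 + 0.3 * np.sin(tt), 0.2 * tt, 0.5 * np.cos(tt), 2.0 + 0.4 * np.sin(2 * tt)]
        )
        qd = lambda tt: np.array([0.3 * np.cos(tt), 0.2, -0.5 * np.sin(tt), 0.8 * np.cos(2 * tt)])
        errs = []
        for delta in (1e-3, 1e-4):
            e = 0.0
            for tt in t:
                J = numeric_jacobian(AnatomicalAngles(*q(tt)), lengths)
                _, wp = forward_kinematics(AnatomicalAngles(*q(tt + delta)), lengths)
                _, wm = forward_kinematics(AnatomicalAngles(*q(tt - delta)), lengths)
                e = max(e, np.max(np.abs(J @ qd(tt) - (wp - wm) / (2 * delta))))
            errs.append(e)
        assert errs[1] < errs[0]  # error decreases as delta shrinks
        assert errs[1] < 1e-6


def _sphere_markers(centre, radii, n_frames, rng, noise=0.0):
    frames = []
    for _ in range(n_frames):
        pos = {}
        for k, r in enumerate(radii):
            d = rng.standard_normal(3)
            d /= np.linalg.norm(d)
            pos[f"m{k}"] = centre + r * d + noise * rng.standard_normal(3)
        frames.append(MarkerFrame(positions=pos))
    return frames


class TestJointCentre:
    def test_noiseless_exact_recovery(self, rng):
        centre = np.array([0.1, -0.2, 0.05])
        frames = _sphere_markers(centre, [0.08, 0.12, 0.1], 100, rng)
        est = estimate_joint_centre(frames, ["m0", "m1", "m2"])
        np.testing.assert_allclose(est, centre, atol=1e-9)

    def test_noisy_recovery_within_3mm(self):
        # Monte-Carlo over seeds at 1 mm isotropic noise, 500 frames
        errs = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            centre = np.array([0.05, 0.02, -0.1])
            frames = _sphere_markers(centre, [0.08, 0.12, 0.1], 500, r, noise=1e-3)
            est = estimate_joint_centre(frames, ["m0", "m1", "m2"])
            errs.append(np.linalg.norm(est - centre))
        assert max(errs) < 3e-3

    def test_no_rotation_is_conditioning_error(self, rng):
        pos = {"m0": np.array([0.1, 0.0, 0.0]), "m1": np.array([0.0, 0.1, 0.0])}
        frames = [MarkerFrame(positions=pos) for _ in range(60)]
        with pytest.raises(np.linalg.LinAlgError):
            estimate_joint_centre(frames, ["m0", "m1"])


class TestExtractJointAngles:
    def _frames_from_trajectory(self, configs, lengths, transform=None):
        frames = []
        for a in configs:
            elbow, wrist = forward_kinematics(a, lengths)
            pos = {"shoulder": np.zeros(3), "elbow": elbow, "wrist": wrist}
            if transform is not None:
                R, t = transform
                pos = {k: R @ v + t for k, v in pos.items()}
            frames.append(MarkerFrame(positions=pos))
        return frames

    def test_closed_generative_loop(self, lengths, rng):
        configs = random_anatomical(rng, n=50)
        frames = self._frames_from_trajectory(configs, lengths)
        anat, absl, est_len = extract_joint_angles(frames)
        truth = np.array([a.as_array() for a in configs])
        assert np.rad2deg(np.max(np.abs(anat - truth))) < 0.5
        assert np.isclose(est_len.upper_arm, lengths.upper_arm, atol=1e-9)

    def test_constant_configuration_gives_constant_angles(self, lengths, rng):
        a = random_anatomical(rng)
        frames = self._frames_from_trajectory([a] * 10, lengths)
        anat, absl, _ = extract_joint_angles(frames)
        assert np.ptp(anat, axis=0).max() < 1e-12

    def test_invariance_to_rigid_translation(self, lengths, rng):
        # a pure translation of all markers must not change the angles;
        # (a rotation would, since the absolute frame is gravity-fixed)
        configs = random_anatomical(rng, n=20)
        frames = self._frames_from_trajectory(configs, lengths)
        shifted = self._frames_from_trajectory(
            configs, lengths, transform=(np.eye(3), np.array([0.5, -0.2, 1.0]))
        )
        a1, b1, _ = extract_joint_angles(frames)
        a2, b2, _ = extract_joint_angles(shifted)
        np.testing.assert_allclose(a1, a2, atol=1e-12)
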