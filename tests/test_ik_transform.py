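"""Shared-basis inverse kinematics: static maps, symbol-matrix inversion,
full anechoic task-to-joint transform and velocity-level maps."""

import numpy as np
import pytest

from armik.arm_model import AnatomicalAngles, SegmentLengths, forward_kinematics
from armik.ik_transform import (
    SharedBasisIK,
    SingularFrequencyError,
    build_symbol_matrix,
    invert_mixture,
    task_to_joint_full,
    task_to_joint_static,
    velocity_map,
)
from armik.synthetic_data import generate_sources, mix_channels
from conftest import random_anatomical


@pytest.fixture
def mixing(rng):
    a = rng.uniform(0.4, 1.0, (3, 3)) * rng.choice([-1, 1], (3, 3))
    while abs(np.linalg.det(a)) < 0.05:
        a = rng.uniform(0.4, 1.0, (3, 3)) * rng.choice([-1, 1], (3, 3))
    tau = rng.uniform(0, 200, (3, 3))
    return a, tau


class TestStaticMap:
    def test_algebraic_identity(self, rng):
        S = generate_sources(3, 200, seed=1)
        B = rng.uniform(0.5, 1.5, (3, 3))
        A = rng.uniform(0.2, 0.8, (4, 3))
        x = B @ S
        q = task_to_joint_static(x, A, B)
        np.testing.assert_allclose(q, A @ S, atol=1e-12)

    def test_identity_map_when_A_equals_B(self, rng):
        S = generate_sources(3, 200, seed=2)
        B = rng.uniform(0.5, 1.5, (3, 3))
        x = B @ S
        np.testing.assert_allclose(task_to_joint_static(x, B, B), x, atol=1e-12)

    def test_matches_per_sample_solve_oracle(self, rng):
        S = generate_sources(3, 200, seed=3)
        B = rng.normal(size=(3, 3))
        A = rng.normal(size=(4, 3))
        x = B @ S
        q = task_to_joint_static(x, A, B)
        for i in (0, 57, 199):  # brute-force per-sample linear solve
            s_i = np.linalg.solve(B, x[:, i])
            np.testing.assert_allclose(q[:, i], A @ s_i, atol=1e-12)

    def test_singular_B_rejected(self):
        B = np.ones((3, 3))
        with pytest.raises(np.linalg.LinAlgError):
            task_to_joint_static(np.zeros((3, 200)), np.eye(3), B)


class TestSymbolMatrix:
    def test_zero_delays_constant_matrix(self, mixing):
        a, _ = mixing
        sm = build_symbol_matrix(a, np.zeros((3, 3)), K=8, P=200)
        for k in range(8):
            np.testing.assert_allclose(sm.entries[k], a, atol=1e-14)

    def test_half_period_delay_fundamental_sign(self):
        a = np.eye(3)
        tau = np.zeros((3, 3))
        tau[0, 0] = 100.0  # P/2
        sm = build_symbol_matrix(a, tau, K=2, P=200)
        assert np.isclose(sm.entries[0][0, 0], -1.0)  # e^{-i pi}
        assert np.isclose(sm.entries[1][0, 0], 1.0)   # e^{-2 i pi}

    def test_entries_match_complex_exponential_oracle(self, mixing):
        a, tau = mixing
        sm = build_symbol_matrix(a, tau, K=10, P=200)
        for k in (1, 4, 10):
            xi = k / 200
            oracle = a * np.exp(-2j * np.pi * tau * xi)
            np.testing.assert_allclose(sm.entries[k - 1], oracle, atol=1e-14)


class TestInvertMixture:
    def test_closed_generative_loop(self, mixing):
        a, tau = mixing
        S = generate_sources(3, 200, seed=5)
        x = mix_channels(S, a, tau)
        sm = build_symbol_matrix(a, tau, K=10, P=200)
        s_rec = invert_mixture(x, sm)
        for i in range(3):
            assert np.corrcoef(s_rec[i], S[i])[0, 1] > 0.999

    def test_identity_weights_zero_delays_pass_through(self):
        S = generate_sources(3, 200, seed=6)
        sm = build_symbol_matrix(np.eye(3), np.zeros((3, 3)), K=10, P=200)
        s_rec = invert_mixture(S, sm)
        np.testing.assert_allclose(s_rec, S, atol=1e-10)

    def test_rank_one_weights_raise_singular(self):
        a = np.outer([1.0, 2.0, 3.0], [1.0, 0.5, 0.2])
        sm = build_symbol_matrix(a, np.zeros((3, 3)), K=5, P=200)
        with pytest.raises(SingularFrequencyError):
            invert_mixture(np.zeros((3, 200)), sm)

    def test_recovered_sources_are_real(self, mixing):
        a, tau = mixing
        S = generate_sources(3, 200, seed=7)
        x = mix_channels(S, a, tau)
        sm = build_symbol_matrix(a, tau, K=10, P=200)
        assert np.isrealobj(invert_mixture(x, sm))

    def test_singularity_detection_matches_determinant_oracle(self, rng):
        for _ in range(20):
            a = rng.normal(size=(3, 3))
            sm = build_symbol_matrix(a, rng.uniform(0, 200, (3, 3)), K=6, P=200)
            dets = [abs(np.linalg.det(e)) for e in sm.entries]
            x = np.zeros((3, 200))
            if min(dets) < 1e-10 * np.linalg.norm(a) ** 3:
                with pytest.raises(SingularFrequencyError):
                    invert_mixture(x, sm)
            else:
                invert_mixture(x, sm)  # must not raise


class TestTaskToJointFull:
    def test_round_trip_to_joint_cycles(self, mixing, rng):
        a, tau = mixing
        S = generate_sources(3, 200, seed=8)
        beta = rng.uniform(0.3, 0.8, (4, 3)) * rng.choice([-1, 1], (4, 3))
        taub = rng.uniform(0, 200, (4, 3))
        x = mix_channels(S, a, tau)
        q_true = mix_channels(S, beta, taub)
        sm = build_symbol_matrix(a, tau, K=10, P=200)
        q = task_to_joint_full(x, sm, beta, taub)
        assert np.sqrt(np.mean((q - q_true) ** 2)) < 1e-8

    def test_zero_joint_weights_give_means(self, mixing):
        a, tau = mixing
        S = generate_sources(3, 200, seed=9)
        x = mix_channels(S, a, tau)
        sm = build_symbol_matrix(a, tau, K=10, P=200)
        q = task_to_joint_full(x, sm, np.zeros((4, 3)), np.zeros((4, 3)),
                               joint_means=np.array([1.0, 2.0, 3.0, 4.0]))
        for i, v in enumerate([1.0, 2.0, 3.0, 4.0]):
            np.testing.assert_allclose(q[i], v, atol=1e-12)

    def test_zero_delay_reduction_equals_static(self, rng):
        S = generate_sources(3, 200, seed=10)
        a = rng.normal(size=(3, 3)) + 2 * np.eye(3)
        beta = rng.uniform(0.3, 0.8, (4, 3))
        x = mix_channels(S, a, np.zeros((3, 3)))
        sm = build_symbol_matrix(a, np.zeros((3, 3)), K=10, P=200)
        q_full = task_to_joint_full(x, sm, beta, np.zeros((4, 3)))
        q_static = task_to_joint_static(x, beta, a)
        np.testing.assert_allclose(q_full, q_static, atol=1e-10)


class TestVelocityMap:
    def test_zero_source_velocity_maps_to_zero(self, lengths, rng):
        config = random_anatomical(rng)
        A = rng.normal(size=(4, 3))
        B = rng.normal(size=(3, 3)) + 2 * np.eye(3)
        x_dot, q_dot, _ = velocity_map(config, A, B, np.zeros(3), lengths)
        np.testing.assert_allclose(x_dot, 0, atol=1e-12)
        np.testing.assert_allclose(q_dot, 0, atol=1e-12)

    def test_task_velocity_matches_finite_differences(self, lengths):
        # a source-generated joint trajectory: q(t) = q0 + A s(t)
        t_grid = np.linspace(0, 2 * np.pi, 9)
        A = np.array([[0.3, 0.1, 0.0], [0.0, 0.2, 0.1], [0.1, 0.0, 0.2], [0.2, 0.1, 0.1]])
        B = np.eye(3) * 0.5 + 0.1
        q0 = np.array([1.2, 0.3, 0.5, 2.0])
        s = lambda tt: np.array([np.sin(tt), np.cos(2 * tt), np.sin(3 * tt)])
        sd = lambda tt: np.array([np.cos(tt), -2 * np.sin(2 * tt), 3 * np.cos(3 * tt)])
        for tt in t_grid[:4]:
            q = q0 + A @ s(tt)
            config = AnatomicalAngles(*q)
            x_dot, _, _ = velocity_map(config, A, B, sd(tt), lengths)
            delta = 1e-6
            _, wp = forward_kinematics(AnatomicalAngles(*(q0 + A @ s(tt + delta))), lengths)
            _, wm = forward_kinematics(AnatomicalAngles(*(q0 + A @ s(tt - delta))), lengths)
            np.testing.assert_allclose(x_dot, (wp - wm) / (2 * delta), atol=1e-5)


class TestSharedBasisIK:
    def test_fit_predict_on_exact_shared_mixture(self, rng):
        from armik.synthetic_data import default_ground_truth, synthesize_trial
        from armik.evaluation import accuracy

        gt = default_ground_truth(n_cycles=6, noise_sd=0.0, seed=11, delay_jitter_sd=0.0)
        gt.weight_jitter_sd = 0.0
        trial = synthesize_trial(gt, exact_shared=True)
        ik = SharedBasisIK(random_state=0).fit(trial["task"], trial["joints_abs"])
        q_hat = ik.predict(trial["task"])
        q_ref = trial["joints_abs"]
        acc = accuracy(q_hat.reshape(-1, 200), q_ref.reshape(-1, 200))
        assert acc > 0.95

    def test_requires_three_task_channels(self):
        with pytest.raises(ValueError):
            SharedBasisIK().fit(np.zeros((2, 4, 200)), np.zeros((2, 4, 200)))
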