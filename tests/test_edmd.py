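"""Tests of the EDMD operator fits, recovery map, and switched predictor."""

import numpy as np
import pytest

from koopgait.edmd import (
    DegenerateFitError,
    EmptySnapshotError,
    KoopmanModel,
    SnapshotSet,
    assemble_snapshots,
    fit_koopman,
    fit_operator,
    fit_recovery,
    predict,
    prediction_rmse,
    reduce_model,
)
from koopgait.lifting import lift_series, make_dictionary
from koopgait.experiments import evaluate_prediction, make_reference, split_dataset


def random_stable_system(rng, n, m, rho=0.85):
    A = rng.normal(size=(n, n))
    A *= rho / np.max(np.abs(np.linalg.eigvals(A)))
    B = rng.normal(size=(n, m))
    return A, B


def linear_snapshots(rng, n=4, m=1, n_steps=400, dict_const=True):
    """Snapshot pairs from a known linear system, lifted by the state dictionary."""
    A, B = random_stable_system(rng, n, m)
    x = np.zeros(n)
    states = [x]
    inputs = []
    for _ in range(n_steps):
        u = rng.normal(size=m)
        inputs.append(u)
        x = A @ x + B @ u
        states.append(x)
    states = np.array(states)
    inputs = np.array(inputs)
    d = make_dictionary("state", 1, state_dim=n, include_constant=dict_const)
    psi = lift_series(states, d)
    D_k = np.vstack([psi[:, :-1], inputs.T])
    D_k1 = np.vstack([psi[:, 1:], np.vstack([inputs[1:], inputs[-1:]]).T])
    snaps = SnapshotSet(D_k, D_k1, "stance", states[:-1].T, input_dim=m)
    return A, B, snaps, d


class TestFitOperator:
    def test_exact_recovery_on_representable_linear_system(self, rng):
        # the module's primary oracle: the state dictionary makes a linear
        # system exactly representable, so EDMD must return (A, B)
        A, B, snaps, _ = linear_snapshots(rng, n=3)
        K_xx, K_xu, diag = fit_operator(snaps)
        assert np.max(np.abs(K_xx[:3, :3] - A)) < 1e-10
        assert np.max(np.abs(K_xu[:3] - B)) < 1e-10
        assert diag["residual_per_pair"] < 1e-10

    def test_matches_normal_equation_oracle(self, rng):
        # K = F G^-1 assembled explicitly from the snapshot sums
        D_k = rng.normal(size=(6, 80))
        D_k1 = rng.normal(size=(6, 80))
        snaps = SnapshotSet(D_k, D_k1, "swing", rng.normal(size=(4, 80)), input_dim=1)
        K_xx, K_xu, _ = fit_operator(snaps)
        M = 80
        F = D_k1 @ D_k.T / M
        G = D_k @ D_k.T / M
        K_oracle = F @ np.linalg.pinv(G)
        np.testing.assert_allclose(
            np.hstack([K_xx, K_xu]), K_oracle[:5], atol=1e-10
        )

    def test_scalar_single_pair(self):
        snaps = SnapshotSet(
            np.array([[2.0]]), np.array([[3.0]]), "stance", np.array([[2.0]]), input_dim=0
        )
        K_xx, K_xu, _ = fit_operator(snaps)
        assert K_xx[0, 0] == pytest.approx(1.5)
        assert K_xu.shape == (1, 0)

    def test_all_zero_snapshots_degenerate(self):
        snaps = SnapshotSet(
            np.zeros((3, 10)), np.zeros((3, 10)), "stance", np.zeros((2, 10)), input_dim=1
        )
        with pytest.raises(DegenerateFitError):
            fit_operator(snaps)

    def test_perturbing_solution_never_lowers_residual(self, rng):
        A, B, snaps, _ = linear_snapshots(rng, n=3, n_steps=150)
        K_xx, K_xu, _ = fit_operator(snaps)
        P = snaps.lifted_dim
        K_full = np.linalg.lstsq(snaps.D_k.T, snaps.D_k1.T, rcond=None)[0].T
        base = np.linalg.norm(snaps.D_k1 - K_full @ snaps.D_k, "fro")
        for _ in range(20):
            i, j = rng.integers(0, K_full.shape[0]), rng.integers(0, K_full.shape[1])
            for delta in (1e-3, -1e-3):
                K_pert = K_full.copy()
                K_pert[i, j] += delta
                assert np.linalg.norm(snaps.D_k1 - K_pert @ snaps.D_k, "fro") >= base - 1e-12


class TestFitRecovery:
    def test_state_dictionary_gives_identity_block(self, rng):
        _, _, snaps, _ = linear_snapshots(rng, n=3)
        C, diag = fit_recovery(snaps)
        np.testing.assert_allclose(C, np.hstack([np.eye(3), np.zeros((3, 1))]), atol=1e-10)
        assert diag["recovery_residual_per_sample"] < 1e-10

    def test_matches_pseudoinverse_oracle(self, rng):
        Psi = rng.normal(size=(6, 100))
        Z = rng.normal(size=(3, 100))
        snaps = SnapshotSet(
            np.vstack([Psi, np.zeros((1, 100))]),
            np.vstack([Psi, np.zeros((1, 100))]),
            "stance",
            Z,
            input_dim=1,
        )
        C, _ = fit_recovery(snaps)
        np.testing.assert_allclose(C, Z @ np.linalg.pinv(Psi), atol=1e-10)

    def test_square_full_rank_reproduces_states_exactly(self, rng):
        # square invertible lift: C must invert it and reproduce the states
        Z = rng.normal(size=(3, 50))
        T = rng.normal(size=(3, 3)) + 3.0 * np.eye(3)
        Psi = T @ Z
        snaps = SnapshotSet(
            np.vstack([Psi, np.zeros((1, 50))]),
            np.vstack([Psi, np.zeros((1, 50))]),
            "stance",
            Z,
            input_dim=1,
        )
        C, _ = fit_recovery(snaps)
        np.testing.assert_allclose(C @ Psi, Z, atol=1e-8)

    def test_rank_deficient_warns_and_regularizes(self, rng):
        Psi = np.vstack([rng.normal(size=(2, 50))] * 2)  # duplicated rows
        snaps = SnapshotSet(
            np.vstack([Psi, np.zeros((1, 50))]),
            np.vstack([Psi, np.zeros((1, 50))]),
            "stance",
            rng.normal(size=(2, 50)),
            input_dim=1,
        )
        with pytest.warns(RuntimeWarning):
            C, _ = fit_recovery(snaps)
        assert np.all(np.isfinite(C))


class TestReduceModel:
    def test_linear_system_round_trip(self, rng):
        A, B, snaps, _ = linear_snapshots(rng, n=3)
        K_xx, K_xu, _ = fit_operator(snaps)
        C, _ = fit_recovery(snaps)
        A_t, B_t = reduce_model(K_xx, K_xu, C)
        np.testing.assert_allclose(A_t, A, atol=1e-8)
        np.testing.assert_allclose(B_t, B, atol=1e-8)

    def test_zero_input_block_gives_zero_B(self, rng):
        C = np.hstack([np.eye(2), np.zeros((2, 1))])
        A_t, B_t = reduce_model(rng.normal(size=(3, 3)), np.zeros((3, 1)), C)
        np.testing.assert_allclose(B_t, 0.0)

    def test_path_equivalence_on_training_data(self, dataset30, sine_ref):
        # one-step prediction through (A, B) agrees with lift -> K -> recover
        # within the recorded fit residuals
        train, _ = split_dataset(dataset30)
        d = make_dictionary("custom", 1)
        model = fit_koopman(train[:6], sine_ref, d)
        snaps = assemble_snapshots(train[:6], sine_ref, d, "stance")
        P = snaps.lifted_dim
        psi = snaps.D_k[:P]
        u = snaps.D_k[P]
        z = snaps.states
        via_lift = model.C @ (model.K_xx["stance"] @ psi + model.K_xu["stance"] * u)
        via_reduced = model.A_tilde["stance"] @ z + model.B_tilde["stance"] * u
        rms = np.sqrt(np.mean((via_lift - via_reduced) ** 2))
        enc = model.diagnostics["recovery"]["encoder_residual"]
        assert rms < 0.5 * enc + 1e-6


class TestAssemble:
    def test_single_phase_three_samples(self, sine_ref):
        from koopgait.plant import Trajectory

        t = np.arange(3) * 0.005
        traj = Trajectory(
            t, np.full(3, 0.1), np.zeros(3), np.zeros(3), np.zeros(3),
            np.zeros(3), np.ones(3, int),
        )
        snaps = assemble_snapshots(traj, sine_ref, make_dictionary("state", 1), "swing")
        assert snaps.n_pairs == 2

    def test_column_count_matches_brute_force(self, dataset30, sine_ref):
        traj = dataset30[0]
        d = make_dictionary("custom", 1)
        for phase, sig in (("stance", 0), ("swing", 1)):
            snaps = assemble_snapshots(traj, sine_ref, d, phase)
            brute = sum(
                1
                for k in range(len(traj) - 1)
                if traj.sigma[k] == sig and traj.sigma[k + 1] == sig
            )
            assert snaps.n_pairs == brute

    def test_no_qualifying_pairs_raises(self, sine_ref, params):
        from koopgait.plant import simulate

        traj = simulate((0.0, 0.0), np.zeros(3), np.zeros(3), params, 200.0)
        # samples 0..2 at 200 Hz are all stance; no swing pairs exist
        with pytest.raises(EmptySnapshotError):
            assemble_snapshots(traj, sine_ref, make_dictionary("state", 1), "swing")

    def test_phase_pools_across_trajectories(self, dataset30, sine_ref):
        d = make_dictionary("custom", 1)
        trajs = dataset30[:4]
        pooled = assemble_snapshots(trajs, sine_ref, d, "swing")
        singles = sum(
            assemble_snapshots(t, sine_ref, d, "swing").n_pairs for t in trajs
        )
        assert pooled.n_pairs == singles


class TestPredict:
    @staticmethod
    def _toy_model(A_st, B_st, A_sw, B_sw):
        n = A_st.shape[0]
        d = make_dictionary("state", 1, state_dim=n, include_constant=False)
        C = np.eye(n)
        return KoopmanModel(
            dictionary=d,
            K_xx={"stance": A_st, "swing": A_sw},
            K_xu={"stance": B_st, "swing": B_sw},
            C=C,
            A_tilde={"stance": A_st, "swing": A_sw},
            B_tilde={"stance": B_st, "swing": B_sw},
        )

    def test_identity_dynamics_constant_prediction(self):
        m = self._toy_model(np.eye(4), np.zeros((4, 1)), np.eye(4), np.zeros((4, 1)))
        z0 = np.array([0.1, -0.2, 0.3, 0.0])
        for mode in ("lifted", "reduced"):
            out = predict(m, z0, np.ones(5), np.ones(5), np.zeros(5, int), mode=mode)
            np.testing.assert_allclose(out, np.tile(z0, (6, 1)))

    def test_one_step_equals_hand_computation(self, rng):
        A, B = random_stable_system(rng, 4, 1)
        m = self._toy_model(A, B, 0.5 * A, 2.0 * B)
        z0 = rng.normal(size=4)
        out = predict(m, z0, [3.0], [0.0], [0], mode="reduced")
        np.testing.assert_allclose(out[1], A @ z0 + B[:, 0] * 3.0)
        out_sw = predict(m, z0, [0.0], [4.0], [1], mode="reduced")
        np.testing.assert_allclose(out_sw[1], 0.5 * A @ z0 + 2.0 * B[:, 0] * 4.0)

    def test_switched_rollout_respects_sigma(self, rng):
        A, B = random_stable_system(rng, 4, 1)
        m = self._toy_model(A, B, 0.5 * A, 2.0 * B)
        z0 = rng.normal(size=4)
        sigma = np.array([0, 1, 0])
        u = np.array([1.0, 2.0, 0.5])
        out = predict(m, z0, u, u, sigma, mode="reduced")
        z = z0
        for k, s in enumerate(sigma):
            Ak = A if s == 0 else 0.5 * A
            Bk = B if s == 0 else 2.0 * B
            z = Ak @ z + Bk[:, 0] * u[k]
            np.testing.assert_allclose(out[k + 1], z)

    def test_bad_sigma_rejected(self, rng):
        m = self._toy_model(np.eye(2), np.zeros((2, 1)), np.eye(2), np.zeros((2, 1)))
        with pytest.raises(ValueError):
            predict(m, np.zeros(2), [0.0], [0.0], [2])

    def test_held_out_cycle_rmse_meets_threshold(self, custom_model, dataset30, sine_ref):
        # the 13-observable custom model predicts a held-out gait cycle
        # within the 0.5 deg accuracy threshold
        _, test = split_dataset(dataset30)
        rmses = [evaluate_prediction(custom_model, t, sine_ref) for t in test]
        assert np.mean(rmses) <= 0.5


class TestPredictionRMSE:
    def test_identical_sequences_zero(self, rng):
        z = rng.normal(size=(20, 4))
        assert prediction_rmse(z, z) == 0.0

    def test_constant_offset_closed_form(self):
        a = np.zeros(10)
        assert prediction_rmse(a + 0.7, a) == pytest.approx(0.7)

    def test_random_pair_matches_two_line_recomputation(self, rng):
        p = rng.normal(size=(15, 4))
        a = rng.normal(size=(15, 4))
        diff_deg = ((p[:, 0] + p[:, 2]) - (a[:, 0] + a[:, 2])) * 180.0 / np.pi
        assert prediction_rmse(p, a) == pytest.approx(np.sqrt(np.mean(diff_deg**2)))
        assert prediction_rmse(p, a, "state") == pytest.approx(
            np.sqrt(np.mean(np.sum((p - a) ** 2, axis=1)))
        )

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            prediction_rmse(rng.normal(size=(5, 4)), rng.normal(size=(6, 4)))


class TestModelStructure:
    def test_phase_operators_differ_on_asymmetric_dynamics(self, custom_model):
        dA = np.linalg.norm(
            custom_model.A_tilde["stance"] - custom_model.A_tilde["swing"]
        )
        assert dA > 1e-3

    def test_dictionary_ordering_custom_beats_state(self, dataset30, sine_ref):
        # held-out multi-step RMSE: the nonlinear custom library outperforms
        # the raw state dictionary on the simulated plant
        train, test = split_dataset(dataset30)
        out = {}
        for name in ("state", "custom"):
            m = fit_koopman(train, sine_ref, make_dictionary(name, 1))
            out[name] = np.mean([evaluate_prediction(m, t, sine_ref) for t in test])
        assert out["custom"] < out["state"]
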