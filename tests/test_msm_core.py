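"""MSM estimation, spectra, CK testing, PCCA+ lumping, MFPTs, bootstrap."""

import numpy as np
import pytest

import networkx as nx
from scipy.optimize import minimize

from thrombin_msm import msm_core as mc
from thrombin_msm.synthetic_dynamics import DiscreteTrajectory, sample_markov_chain


def random_reversible_T(n, seed):
    rng = np.random.default_rng(seed)
    S = rng.random((n, n)) + 0.1
    S = S + S.T
    return S / S.sum(axis=1, keepdims=True)


def optimizer_reversible_mle(counts):
    """Independent constrained-likelihood oracle: parametrize the symmetric
    flux matrix x_ij = exp(theta_ij) and maximize sum c_ij ln(x_ij / x_i)."""
    n = len(counts)
    iu = np.triu_indices(n)

    def unpack(theta):
        x = np.zeros((n, n))
        x[iu] = np.exp(theta)
        x = x + np.triu(x, 1).T
        return x

    def negloglik(theta):
        x = unpack(theta)
        T = x / x.sum(axis=1, keepdims=True)
        return -np.sum(counts * np.log(T + 1e-300))

    theta0 = np.log((counts + counts.T + 1.0)[iu])
    res = minimize(negloglik, theta0, method="BFGS",
                   options={"gtol": 1e-12, "maxiter": 10_000})
    x = unpack(res.x)
    return x / x.sum(axis=1, keepdims=True)


class TestCounting:
    def test_single_transition(self):
        C = mc.count_transitions([[0, 1]], lag=1)
        assert np.array_equal(C.counts, [[0, 1], [0, 0]])

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        traj = rng.integers(0, 5, size=1000)
        C = mc.count_transitions([traj], lag=3)
        oracle = np.zeros((5, 5), dtype=int)
        for t in range(len(traj) - 3):
            oracle[traj[t], traj[t + 3]] += 1
        assert np.array_equal(C.counts, oracle)

    def test_total_count_arithmetic(self):
        trajs = [np.zeros(100, dtype=int), np.ones(100, dtype=int)]
        C = mc.count_transitions(trajs, lag=10)
        assert C.total == 180

    def test_all_too_short_rejected(self):
        with pytest.raises(ValueError):
            mc.count_transitions([[0, 1, 0]], lag=5)


class TestConnectivity:
    def test_fully_connected_keeps_all(self):
        C = np.ones((3, 3), dtype=int)
        assert np.array_equal(mc.largest_connected_set(C), [0, 1, 2])

    def test_two_blocks_keeps_larger(self):
        C = np.zeros((6, 6), dtype=int)
        C[:4, :4] = 1
        C[4:, 4:] = 1
        assert np.array_equal(mc.largest_connected_set(C), [0, 1, 2, 3])

    def test_matches_networkx_oracle(self):
        rng = np.random.default_rng(1)
        for trial in range(5):
            C = (rng.random((30, 30)) < 0.08).astype(int)
            got = set(mc.largest_connected_set(C).tolist())
            G = nx.from_numpy_array(C, create_using=nx.DiGraph)
            expected = max(nx.strongly_connected_components(G), key=len)
            if len(got) == len(expected):  # unique-maximum guard
                assert got == expected or len(expected) == 1


class TestReversibleMLE:
    def test_symmetric_counts_closed_form(self):
        C = np.array([[10, 4, 2], [4, 8, 3], [2, 3, 12]])
        cm = mc.CountMatrix(C, 1, int(C.sum()), np.arange(3))
        m = mc.estimate_reversible(cm)
        expected_T = C / C.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(m.transition_matrix, expected_T, atol=1e-9)
        np.testing.assert_allclose(
            m.stationary_distribution, C.sum(axis=1) / C.sum(), atol=1e-9
        )

    def test_matches_generic_optimizer_oracle(self):
        rng = np.random.default_rng(2)
        C = rng.integers(1, 60, size=(3, 3))
        cm = mc.CountMatrix(C, 1, int(C.sum()), np.arange(3))
        ours = mc.estimate_reversible(cm).transition_matrix
        oracle = optimizer_reversible_mle(C.astype(float))
        np.testing.assert_allclose(ours, oracle, atol=1e-6)

    def test_detailed_balance_and_stochasticity(self):
        rng = np.random.default_rng(3)
        for seed in range(5):
            T_true = random_reversible_T(4, seed)
            d = sample_markov_chain(T_true, 20_000, seed=seed)
            m = mc.estimate_msm([d], lag=1)
            T, pi = m.transition_matrix, m.stationary_distribution
            assert np.abs(T.sum(axis=1) - 1.0).max() < 1e-10
            assert np.abs(pi @ T - pi).max() < 1e-8
            flux = pi[:, None] * T
            assert np.abs(flux - flux.T).max() < 1e-8

    def test_parameter_recovery_within_3se(self):
        T_true = random_reversible_T(3, seed=7)
        d = sample_markov_chain(T_true, 100_000, seed=8)
        m = mc.estimate_msm([d], lag=1)
        counts = mc.count_transitions([d], lag=1).counts
        rows = counts.sum(axis=1)
        for i in range(3):
            for j in range(3):
                se = np.sqrt(T_true[i, j] * (1 - T_true[i, j]) / rows[i])
                assert abs(m.transition_matrix[i, j] - T_true[i, j]) < 3 * se + 1e-12


class TestImpliedTimescales:
    def test_two_state_closed_form(self):
        lam2 = np.exp(-1.0)
        p = (1 + lam2) / 2
        T = np.array([[p, 1 - p], [1 - p, p]])
        d = sample_markov_chain(T, 400_000, seed=9)
        table = mc.implied_timescales([d], lags=[1])
        assert table["t2"].iloc[0] == pytest.approx(1.0, rel=0.05)

    def test_flat_curve_on_markovian_data(self):
        T = np.array([[0.98, 0.02], [0.02, 0.98]])
        t2_true = -1.0 / np.log(0.96)
        d = [sample_markov_chain(T, 100_000, seed=s) for s in (10, 11, 12)]
        table = mc.implied_timescales(d, lags=[1, 2, 5, 10])
        assert np.all(np.abs(table["t2"] / t2_true - 1.0) < 0.15)

    def test_non_positive_eigenvalue_flagged_undefined(self):
        model = mc.MSMModel(
            transition_matrix=np.eye(3),
            stationary_distribution=np.full(3, 1 / 3),
            eigenvalues=np.array([1.0, 1.0, -0.4]),
            right_eigenvectors=np.eye(3),
            left_eigenvectors=np.eye(3),
            lag=1, lag_time=1.0, active_set=np.arange(3),
        )
        ts = model.timescales()
        assert np.all(np.isnan(ts))


class TestCK:
    def _model_and_data(self, T, n_traj=6, n_steps=20_000, lag=1):
        dtrajs = [sample_markov_chain(T, n_steps, seed=s) for s in range(n_traj)]
        model = mc.estimate_msm(dtrajs, lag)
        return model, dtrajs

    def test_k1_predicted_equals_estimated(self):
        T = random_reversible_T(3, 20)
        model, dtrajs = self._model_and_data(T)
        pcca = mc.pcca_plus(model, 2)
        table = mc.ck_test(model, dtrajs, pcca, K=1)
        np.testing.assert_allclose(table["predicted"], table["estimated"], atol=1e-12)

    def test_self_consistency_on_markovian_data(self):
        T = np.array(
            [[0.95, 0.04, 0.01], [0.04, 0.93, 0.03], [0.01, 0.03, 0.96]]
        )
        model, dtrajs = self._model_and_data(T, n_traj=8, n_steps=30_000)
        pcca = mc.pcca_plus(model, 2)
        table = mc.ck_test(model, dtrajs, pcca, K=5, n_boot=25, seed=1)
        dev = np.abs(table["predicted"] - table["estimated"])
        assert np.all(dev <= 3 * table["estimated_std"] + 1e-3)

    def test_hidden_state_violation_detected(self):
        # 3-state chain observed through a 2-state lumping that hides a slow
        # internal mode: CK must show a significant predicted/estimated gap
        T3 = np.array([[0.995, 0.005, 0.0], [0.005, 0.795, 0.2], [0.0, 0.2, 0.8]])
        rng_obs = {0: 0, 1: 0, 2: 1}
        dtrajs = []
        for s in range(8):
            d = sample_markov_chain(T3, 30_000, seed=100 + s)
            dtrajs.append(DiscreteTrajectory(np.vectorize(rng_obs.get)(d.states)))
        model = mc.estimate_msm(dtrajs, 1)
        pcca = mc.pcca_plus(model, 2)
        table = mc.ck_test(model, dtrajs, pcca, K=5, n_boot=25, seed=2)
        late = table[table["k"] == 5]
        gap = np.abs(late["predicted"] - late["estimated"])
        assert np.any(gap > 3 * late["estimated_std"])


class TestPCCA:
    def test_block_diagonal_crisp_memberships(self):
        T = np.zeros((4, 4))
        T[:2, :2] = [[0.7, 0.3], [0.3, 0.7]]
        T[2:, 2:] = [[0.6, 0.4], [0.4, 0.6]]
        # connect infinitesimally to keep a single model but preserve blocks
        res = mc.pcca_plus(T, 2)
        assert len(set(res.crisp[:2])) == 1
        assert len(set(res.crisp[2:])) == 1
        assert res.crisp[0] != res.crisp[2]
        assert np.all((res.memberships > 0.999) | (res.memberships < 0.001))
        pi = mc._stationary(T)
        block_sums = [pi[res.crisp == a].sum() for a in range(2)]
        np.testing.assert_allclose(res.coarse_stationary, block_sums, atol=1e-8)

    def test_nearly_lumpable_coarse_probabilities(self):
        eps = 1e-3
        T = np.array(
            [
                [0.7 - eps, 0.3, eps, 0.0],
                [0.3, 0.7 - eps, 0.0, eps],
                [eps, 0.0, 0.6, 0.4 - eps],
                [0.0, eps, 0.4 - eps, 0.6],
            ]
        )
        res = mc.pcca_plus(T, 2)
        block = [res.coarse_stationary[res.crisp[0]], res.coarse_stationary[res.crisp[2]]]
        np.testing.assert_allclose(block, [0.5, 0.5], atol=1e-2)

    def test_membership_rows_sum_to_one_random_models(self):
        for seed in range(20):
            T = random_reversible_T(6, seed)
            res = mc.pcca_plus(T, 2)
            np.testing.assert_allclose(res.memberships.sum(axis=1), 1.0, atol=1e-8)
            assert np.all(res.memberships >= 0) and np.all(res.memberships <= 1)
            assert res.coarse_stationary.sum() == pytest.approx(1.0, abs=1e-10)

    def test_degenerate_spectrum_rejected_naming_gap(self):
        ring = 0.8 * np.eye(3) + 0.1 * (np.roll(np.eye(3), 1, 0) + np.roll(np.eye(3), -1, 0))
        with pytest.raises(ValueError, match="gap"):
            mc.pcca_plus(ring, 2)


class TestMFPT:
    def _model(self, T, lag_time=1.0):
        pi = mc._stationary(T)
        vals, right, left = mc._spectrum(T, pi)
        return mc.MSMModel(T, pi, vals, right, left, 1, lag_time, np.arange(len(T)))

    def test_two_state_geometric_law(self):
        m = self._model(np.array([[0.5, 0.5], [0.5, 0.5]]))
        assert mc.mfpt(m, [0], [1]) == pytest.approx(2.0, abs=1e-12)

    def test_absorbing_neighbor_equals_lag(self):
        T = np.array([[0.0, 1.0], [0.5, 0.5]])
        m = self._model(T, lag_time=3.0)
        assert mc.mfpt(m, [0], [1]) == pytest.approx(3.0, abs=1e-12)

    def test_matches_monte_carlo_first_passages(self):
        T = np.array(
            [
                [0.8, 0.2, 0.0, 0.0],
                [0.2, 0.6, 0.2, 0.0],
                [0.0, 0.2, 0.6, 0.2],
                [0.0, 0.0, 0.2, 0.8],
            ]
        )
        m = self._model(T)
        expected = mc.mfpt(m, [0], [3])
        rng = np.random.default_rng(30)
        cum = np.cumsum(T, axis=1)
        times = np.empty(20_000)
        for k in range(len(times)):
            s, t = 0, 0
            while s != 3:
                s = int(np.searchsorted(cum[s], rng.random(), side="right"))
                t += 1
            times[k] = t
        se = times.std(ddof=1) / np.sqrt(len(times))
        assert abs(times.mean() - expected) < 3 * se

    def test_two_state_ratio_identity(self):
        """mfpt(A->B)/mfpt(B->A) = pi_A/pi_B exactly on any 2-state chain."""
        for seed in range(5):
            T = random_reversible_T(2, seed + 40)
            m = self._model(T)
            ratio = mc.mfpt(m, [0], [1]) / mc.mfpt(m, [1], [0])
            pi = m.stationary_distribution
            assert ratio == pytest.approx(pi[0] / pi[1], abs=1e-10)

    def test_overlapping_sets_rejected(self):
        m = self._model(np.array([[0.5, 0.5], [0.5, 0.5]]))
        with pytest.raises(ValueError):
            mc.mfpt(m, [0], [0, 1])

    def test_unreachable_target_rejected(self):
        m = self._model(np.eye(2) * 0.999 + 0.001 * np.eye(2)[::-1])
        T = np.eye(3)
        pi = np.full(3, 1 / 3)
        m = mc.MSMModel(T, pi, np.ones(3), np.eye(3), np.eye(3), 1, 1.0, np.arange(3))
        with pytest.raises(ValueError):
            mc.mfpt(m, [0], [2])


class TestBootstrap:
    def test_identical_trajectories_zero_width(self):
        T = np.array([[0.9, 0.1], [0.1, 0.9]])
        d = sample_markov_chain(T, 5000, seed=50)
        ens = mc.bootstrap_ensemble([d, d, d], lag=1, n_resamples=10, seed=0)
        width = ens.coarse_interval[1] - ens.coarse_interval[0]
        assert np.allclose(width, 0.0, atol=1e-12)

    def test_single_resample_degenerate_interval(self):
        T = np.array([[0.9, 0.1], [0.1, 0.9]])
        dtrajs = [sample_markov_chain(T, 5000, seed=s) for s in (51, 52)]
        ens = mc.bootstrap_ensemble(dtrajs, lag=1, n_resamples=1, seed=1)
        assert np.allclose(ens.coarse_interval[0], ens.coarse_interval[1])

    def test_interval_contains_point_estimate(self):
        T = random_reversible_T(4, 60)
        dtrajs = [sample_markov_chain(T, 5000, seed=s) for s in range(8)]
        ens = mc.bootstrap_ensemble(dtrajs, lag=1, n_resamples=50, seed=2)
        assert np.all(ens.coarse_interval[0] <= ens.point_coarse + 1e-9)
        assert np.all(ens.point_coarse <= ens.coarse_interval[1] + 1e-9)

    def test_nominal_coverage_of_true_coarse_probability(self):
        """95% percentile intervals cover the truth in >= 90% of repetitions."""
        T = np.zeros((4, 4))
        T[:2, :2] = [[0.88, 0.1], [0.1, 0.88]]
        T[2:, 2:] = [[0.86, 0.1], [0.1, 0.86]]
        T[0, 2] = T[1, 3] = T[2, 0] = T[3, 1] = 0.02
        T += np.diag(1.0 - T.sum(axis=1))
        pi = mc._stationary(T)
        ref = mc.pcca_plus(T, 2)
        true_block = np.array([pi[:2].sum(), pi[2:].sum()])
        hits = 0
        reps = 60
        for rep in range(reps):
            dtrajs = [
                sample_markov_chain(T, 4000, seed=1000 * rep + s, start_state=s % 4)
                for s in range(16)
            ]
            try:
                ens = mc.bootstrap_ensemble(dtrajs, lag=1, n_resamples=150, seed=rep)
            except (RuntimeError, ValueError):
                continue
            lo, hi = ens.coarse_interval
            covered = all(
                lo[a] - 1e-9 <= true_block[a] <= hi[a] + 1e-9 for a in range(2)
            )
            hits += covered
        assert hits >= 0.9 * reps
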