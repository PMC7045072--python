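"""MSM estimation, validation and kinetics against independent oracles."""

import numpy as np
import pandas as pd
import pytest
import scipy.linalg
import scipy.optimize

from unfoldmsm.msm import (ConnectivityError, CountMatrix,
                           DegenerateClusteringError, InsufficientDataError,
                           InvalidRequestError, InvalidSetsError,
                           ReferenceLostError, TransitionModel,
                           bayesian_samples, chapman_kolmogorov_test,
                           count_transitions, estimate_transition_matrix,
                           folded_population, implied_timescales,
                           kmeans_discretize, mfpt, pcca_plus, reactive_flux,
                           reversible_mle, sample_stationary_distributions,
                           stationary_distribution_matrix, tica_fit,
                           tica_transform, transition_timescale)


def _simulate_chain(T, n_steps, seed, start=0):
    rng = np.random.default_rng(seed)
    cum = np.cumsum(T, axis=1)
    out = np.empty(n_steps, dtype=np.int64)
    s = start
    for t in range(n_steps):
        out[t] = s
        s = int(np.searchsorted(cum[s], rng.random()))
    return out


def _model_from_T(T, lag=1, dt=1.0):
    pi = stationary_distribution_matrix(T)
    return TransitionModel(T=T, pi=pi, lag=lag, estimator="reversible_mle",
                           active_set=np.arange(T.shape[0]), dt_per_frame=dt)


# ---------------------------------------------------------------------------
# tICA
# ---------------------------------------------------------------------------

class TestTICA:
    def test_lag_zero_gives_unit_eigenvalues(self, rng):
        x = rng.normal(size=(500, 3))
        model = tica_fit(x, lag=0)
        # epsilon regularization of C0 shifts eigenvalues by ~epsilon_scale
        np.testing.assert_allclose(model.eigenvalues, 1.0, atol=1e-5)

    def test_recovers_slow_ar1_component(self, rng):
        n = 100000
        rhos = (0.9, 0.5)
        x = np.empty((n, 2))
        for k, rho in enumerate(rhos):
            v = np.empty(n)
            v[0] = 0.0
            noise = rng.normal(size=n)
            for t in range(1, n):
                v[t] = rho * v[t - 1] + noise[t]
            x[:, k] = v
        model = tica_fit(x, lag=1)
        assert model.eigenvalues[0] == pytest.approx(0.9, abs=0.02)
        comp = model.components[:, 0] / np.linalg.norm(model.components[:, 0])
        assert abs(comp[0]) > 0.99

    def test_matches_dense_generalized_eigensolver(self, rng):
        """Whitened-basis solution vs scipy.linalg.eigh(Ct, C0) directly."""
        x = rng.normal(size=(2000, 4)).cumsum(axis=0) * 0.01 \
            + rng.normal(size=(2000, 4))
        model = tica_fit(x, lag=5)
        w, v = scipy.linalg.eigh(model.Ct,
                                 model.C0 + model.epsilon * np.eye(4))
        np.testing.assert_allclose(model.eigenvalues, w[::-1], atol=1e-8)

    def test_components_c0_orthonormal(self, rng):
        x = rng.normal(size=(3000, 3)) @ np.diag([3.0, 1.0, 0.2])
        model = tica_fit(x, lag=2)
        C0r = model.C0 + model.epsilon * np.eye(3)
        gram = model.components.T @ C0r @ model.components
        np.testing.assert_allclose(gram, np.eye(3), atol=1e-8)

    def test_transform_is_linear(self, rng):
        x = rng.normal(size=(500, 2))
        model = tica_fit(x, lag=1)
        y = tica_transform(model, x)
        y2 = tica_transform(model, x[:10])
        np.testing.assert_allclose(y[:10], y2, atol=1e-12)

    def test_too_short_trajectories_rejected(self, rng):
        with pytest.raises(InsufficientDataError):
            tica_fit(rng.normal(size=(4, 2)), lag=10)


# ---------------------------------------------------------------------------
# discretization and counting
# ---------------------------------------------------------------------------

class TestDiscretization:
    def test_k_equals_distinct_points_zero_inertia(self):
        pts = np.array([[0.0], [1.0], [2.0], [3.0]])
        disc = kmeans_discretize(pts, k=4, seed=0)
        assert len(np.unique(disc.dtrajs[0])) == 4

    def test_two_blobs_recovered(self, rng):
        pts = np.concatenate([rng.normal(0, 0.1, (50, 1)),
                              rng.normal(10, 0.1, (50, 1))])
        disc = kmeans_discretize(pts, k=2, seed=0)
        labels = disc.dtrajs[0]
        assert len(set(labels[:50])) == 1
        assert labels[0] != labels[-1]

    def test_deterministic_given_seed(self, rng):
        pts = rng.normal(size=(200, 2))
        d1 = kmeans_discretize(pts, k=5, seed=3)
        d2 = kmeans_discretize(pts, k=5, seed=3)
        np.testing.assert_array_equal(d1.centers, d2.centers)
        np.testing.assert_array_equal(d1.dtrajs[0], d2.dtrajs[0])

    def test_k_exceeding_distinct_points_rejected(self):
        pts = np.zeros((10, 1))
        with pytest.raises(DegenerateClusteringError):
            kmeans_discretize(pts, k=2, seed=0)


class TestCounting:
    def test_hand_counts_self_loop(self):
        cm = count_transitions([np.array([0, 0, 0, 0])], lag=1)
        assert cm.active_counts.tolist() == [[3]]

    def test_hand_counts_alternating(self):
        cm = count_transitions([np.array([0, 1, 0, 1, 0])], lag=1)
        assert cm.active_counts.tolist() == [[0, 2], [2, 0]]

    def test_disconnected_components_trimmed(self):
        d1 = np.array([0, 1, 0, 1, 0, 1])
        d2 = np.array([2, 3, 2])
        cm = count_transitions([d1, d2], lag=1)
        assert cm.trimmed
        assert set(cm.active_set.tolist()) == {0, 1}

    def test_all_short_trajectories_rejected(self):
        with pytest.raises(InsufficientDataError):
            count_transitions([np.array([0, 1])], lag=5)


# ---------------------------------------------------------------------------
# transition-matrix estimation
# ---------------------------------------------------------------------------

class TestEstimation:
    def test_symmetric_counts_both_estimators_coincide(self):
        C = np.array([[90, 10], [10, 90]])
        cm = CountMatrix(1, C, np.arange(2), False)
        for est in ("nonreversible", "reversible_mle"):
            m = estimate_transition_matrix(cm, est)
            np.testing.assert_allclose(m.T, [[0.9, 0.1], [0.1, 0.9]],
                                       atol=1e-9)
            np.testing.assert_allclose(m.pi, [0.5, 0.5], atol=1e-9)

    def test_pure_exchange_counts(self):
        cm = CountMatrix(1, np.array([[0, 5], [5, 0]]), np.arange(2), False)
        m = estimate_transition_matrix(cm)
        np.testing.assert_allclose(m.T, [[0, 1], [1, 0]], atol=1e-12)

    def test_reversible_mle_matches_brute_force_optimization(self):
        """Fixed-point MLE vs direct likelihood maximization over the
        reversible parameterization (x_ij symmetric, on the simplex)."""
        C = np.array([[8.0, 2.0], [3.0, 7.0]])

        def negloglik(params):
            x01 = params[0]
            x0, x1 = params[1], 1.0 - params[1]
            T = np.array([[ (x0 - x01) / x0, x01 / x0],
                          [x01 / x1, (x1 - x01) / x1]])
            if np.any(T <= 0):
                return 1e9
            return -np.sum(C * np.log(T))

        best = None
        for x01 in np.linspace(1e-4, 0.4, 400):
            for x0 in np.linspace(0.05, 0.95, 400):
                if x01 < x0 and x01 < 1 - x0:
                    val = negloglik([x01, x0])
                    if best is None or val < best[0]:
                        best = (val, x01, x0)
        res = scipy.optimize.minimize(negloglik, [best[1], best[2]],
                                      method="Nelder-Mead",
                                      options={"xatol": 1e-12, "fatol": 1e-14})
        x01, x0 = res.x
        T_oracle = np.array([[(x0 - x01) / x0, x01 / x0],
                             [x01 / (1 - x0), (1 - x0 - x01) / (1 - x0)]])
        cm = CountMatrix(1, C.astype(int), np.arange(2), False)
        m = estimate_transition_matrix(cm, "reversible_mle")
        np.testing.assert_allclose(m.T, T_oracle, atol=1e-6)

    def test_detailed_balance_and_row_stochasticity(self, rng):
        C = rng.integers(1, 50, size=(4, 4))
        cm = CountMatrix(1, C, np.arange(4), False)
        m = estimate_transition_matrix(cm, "reversible_mle")
        np.testing.assert_allclose(m.T.sum(axis=1), 1.0, atol=1e-10)
        flux = m.pi[:, None] * m.T
        np.testing.assert_allclose(flux, flux.T, atol=1e-8)
        np.testing.assert_allclose(m.pi @ m.T, m.pi, atol=1e-8)


class TestStationaryDistribution:
    def test_doubly_stochastic_is_uniform(self):
        T = np.array([[0.6, 0.2, 0.2], [0.2, 0.6, 0.2], [0.2, 0.2, 0.6]])
        np.testing.assert_allclose(stationary_distribution_matrix(T),
                                   1.0 / 3.0, atol=1e-10)

    def test_hand_solved_two_state(self):
        T = np.array([[0.5, 0.5], [0.25, 0.75]])
        pi = stationary_distribution_matrix(T)
        np.testing.assert_allclose(pi, [1.0 / 3.0, 2.0 / 3.0], atol=1e-12)
        # power-iteration oracle
        p = np.array([1.0, 0.0])
        for _ in range(200):
            p = p @ T
        np.testing.assert_allclose(pi, p, atol=1e-10)

    def test_reducible_matrix_rejected(self):
        T = np.eye(2)
        with pytest.raises(ConnectivityError):
            stationary_distribution_matrix(T)


# ---------------------------------------------------------------------------
# validation machinery
# ---------------------------------------------------------------------------

class TestImpliedTimescales:
    T = np.array([[0.9, 0.1], [0.1, 0.9]])

    def test_recovers_eigenvalue_arithmetic(self):
        dtraj = _simulate_chain(self.T, 1_000_000, seed=4)
        its = implied_timescales([dtraj], lags=[1], n_timescales=1)
        expected = -1.0 / np.log(0.8)
        assert its.loc[0, "t2"] == pytest.approx(expected, rel=0.05)

    def test_flat_across_lags_for_markovian_data(self):
        dtraj = _simulate_chain(self.T, 500_000, seed=5)
        its = implied_timescales([dtraj], lags=[1, 2, 4], n_timescales=1)
        vals = its["t2"].to_numpy()
        assert np.all(np.isfinite(vals))
        assert np.max(np.abs(vals / vals[0] - 1.0)) < 0.15

    def test_insufficient_lag_flagged_not_dropped(self):
        dtraj = np.array([0, 1, 0, 1, 0, 1])
        its = implied_timescales([dtraj], lags=[1, 50])
        assert len(its) == 2
        assert bool(its.loc[its["lag"] == 50, "flagged"].iloc[0])

    def test_unit_eigenvalue_reported_as_infinite(self):
        T = np.array([[1.0 - 5e-14, 5e-14], [5e-14, 1.0 - 5e-14]])
        model = TransitionModel(T=T, pi=np.array([0.5, 0.5]), lag=1,
                                estimator="reversible_mle",
                                active_set=np.arange(2))
        assert np.isinf(model.timescales(1)[0])


class TestBayesianSampling:
    def test_fewer_than_two_samples_rejected(self):
        cm = CountMatrix(1, np.array([[5, 5], [5, 5]]), np.arange(2), False)
        with pytest.raises(InvalidRequestError):
            bayesian_samples(cm, 1)

    def test_posterior_concentrates_with_huge_counts(self):
        C = (np.array([[0.9, 0.1], [0.1, 0.9]]) * 1e7).astype(int)
        cm = CountMatrix(1, C, np.arange(2), False)
        pis = sample_stationary_distributions(bayesian_samples(cm, 50, seed=0))
        assert pis[:, 0].std() < 1e-3

    def test_symmetric_counts_centered_at_half(self):
        cm = CountMatrix(1, np.array([[400, 100], [100, 400]]),
                         np.arange(2), False)
        pis = sample_stationary_distributions(bayesian_samples(cm, 400, seed=1))
        assert pis[:, 0].mean() == pytest.approx(0.5, abs=0.02)

    def test_interval_coverage_on_simulated_chains(self):
        """95% posterior intervals for pi_1 cover the truth >= 90/100 times."""
        T = np.array([[0.85, 0.1, 0.05],
                      [0.1, 0.8, 0.1],
                      [0.05, 0.1, 0.85]])
        pi_true = stationary_distribution_matrix(T)[0]
        hits = 0
        for rep in range(100):
            dtraj = _simulate_chain(T, 3000, seed=1000 + rep)
            cm = count_transitions([dtraj], lag=1)
            if cm.active_set.size < 3:
                continue
            pis = sample_stationary_distributions(
                bayesian_samples(cm, 200, seed=rep))
            lo, hi = np.quantile(pis[:, 0], [0.025, 0.975])
            hits += lo <= pi_true <= hi
        assert hits >= 90


class TestChapmanKolmogorov:
    def _fit(self, dtrajs, lag=1):
        cm = count_transitions(dtrajs, lag)
        model = estimate_transition_matrix(cm)
        macro = pcca_plus(model, 2)
        return model, macro

    def test_passes_on_markovian_data(self):
        T = np.array([[0.95, 0.05, 0.0],
                      [0.05, 0.9, 0.05],
                      [0.0, 0.05, 0.95]])
        dtrajs = [_simulate_chain(T, 200_000, seed=s) for s in range(3)]
        model, macro = self._fit(dtrajs)
        ck = chapman_kolmogorov_test(dtrajs, model, macro, factors=(2, 4),
                                     n_samples=100, seed=0)
        assert ck["within_band"].mean() >= 0.95

    def test_identity_factor_consistent(self):
        T = np.array([[0.9, 0.1], [0.1, 0.9]])
        dtrajs = [_simulate_chain(T, 50_000, seed=2)]
        model, macro = self._fit(dtrajs)
        ck = chapman_kolmogorov_test(dtrajs, model, macro, factors=(1,),
                                     n_samples=50, seed=0)
        np.testing.assert_allclose(ck["predicted"], ck["estimated"], atol=5e-3)

    def test_fails_on_hidden_state_counterexample(self):
        """Lumping two kinetically distinct states must break CK."""
        # 3-state chain: states 1 and 2 lumped into observed state 1;
        # state 2 is a slow trap, so the lumped process is non-Markovian
        T = np.array([[0.90, 0.10, 0.00],
                      [0.20, 0.60, 0.20],
                      [0.00, 0.02, 0.98]])
        hidden = _simulate_chain(T, 400_000, seed=9)
        observed = np.where(hidden == 0, 0, 1)
        model, macro = self._fit([observed])
        ck = chapman_kolmogorov_test([observed], model, macro,
                                     factors=(4, 8), n_samples=100, seed=0)
        assert ck["within_band"].mean() < 0.95


# ---------------------------------------------------------------------------
# coarse-graining and kinetics
# ---------------------------------------------------------------------------

class TestPCCA:
    def test_block_structure_recovered(self):
        eps = 1e-3
        T = np.array([[0.9 - eps, 0.1, eps, 0.0],
                      [0.1, 0.9 - eps, 0.0, eps],
                      [eps, 0.0, 0.9 - eps, 0.1],
                      [0.0, eps, 0.1, 0.9 - eps]])
        macro = pcca_plus(_model_from_T(T), 2)
        a = macro.crisp_assignment
        assert a[0] == a[1] and a[2] == a[3] and a[0] != a[2]
        np.testing.assert_allclose(macro.populations.sum(), 1.0, atol=1e-10)

    def test_full_resolution_memberships_are_crisp(self):
        T = np.array([[0.8, 0.15, 0.05],
                      [0.15, 0.7, 0.15],
                      [0.05, 0.15, 0.8]])
        macro = pcca_plus(_model_from_T(T), 3)
        assert set(macro.crisp_assignment) == {0, 1, 2}
        np.testing.assert_allclose(macro.memberships.sum(axis=1), 1.0,
                                   atol=1e-8)

    def test_membership_rows_sum_to_one_random_reversible(self, rng):
        C = rng.integers(1, 30, size=(6, 6))
        cm = CountMatrix(1, C, np.arange(6), False)
        model = estimate_transition_matrix(cm, "reversible_mle")
        macro = pcca_plus(model, 3)
        np.testing.assert_allclose(macro.memberships.sum(axis=1), 1.0,
                                   atol=1e-8)
        assert np.all(macro.memberships >= -1e-8)


class TestMFPT:
    def test_two_state_closed_form(self):
        T = np.array([[0.9, 0.1], [0.1, 0.9]])
        assert mfpt(_model_from_T(T), [0], [1]) == pytest.approx(10.0)

    def test_matches_first_passage_simulation(self):
        T = np.array([[0.90, 0.08, 0.02],
                      [0.15, 0.80, 0.05],
                      [0.05, 0.10, 0.85]])
        model = _model_from_T(T)
        expected = mfpt(model, [0], [2])
        rng = np.random.default_rng(11)
        cum = np.cumsum(T, axis=1)
        total, n_events = 0, 20000
        for _ in range(n_events):
            s, steps = 0, 0
            while s != 2:
                s = int(np.searchsorted(cum[s], rng.random()))
                steps += 1
            total += steps
        assert expected == pytest.approx(total / n_events, rel=0.05)

    def test_absorbing_target_leaves_mfpt_unchanged(self):
        T = np.array([[0.9, 0.08, 0.02],
                      [0.1, 0.85, 0.05],
                      [0.05, 0.05, 0.9]])
        m1 = mfpt(_model_from_T(T), [0], [2])
        T_abs = T.copy()
        T_abs[2] = [0.0, 0.0, 1.0]
        model_abs = TransitionModel(T=T_abs,
                                    pi=stationary_distribution_matrix(T),
                                    lag=1, estimator="nonreversible",
                                    active_set=np.arange(3))
        assert m1 == pytest.approx(mfpt(model_abs, [0], [2]))

    def test_self_mfpt_is_zero_and_overlap_rejected(self):
        T = np.array([[0.9, 0.1], [0.1, 0.9]])
        model = _model_from_T(T)
        assert mfpt(model, [0], [0]) == 0.0
        with pytest.raises(InvalidSetsError):
            mfpt(model, [0, 1], [1])


class TestReactiveFlux:
    def test_symmetric_chain_committor(self):
        T = np.array([[0.5, 0.5, 0.0],
                      [0.25, 0.5, 0.25],
                      [0.0, 0.5, 0.5]])
        rf = reactive_flux(_model_from_T(T), [0], [2])
        np.testing.assert_allclose(rf.q_forward, [0.0, 0.5, 1.0], atol=1e-12)

    def test_committor_duality_for_reversible_dynamics(self, rng):
        C = rng.integers(1, 20, size=(5, 5))
        cm = CountMatrix(1, C, np.arange(5), False)
        model = estimate_transition_matrix(cm, "reversible_mle")
        rf = reactive_flux(model, [0], [4])
        np.testing.assert_allclose(rf.q_forward + rf.q_backward, 1.0,
                                   atol=1e-10)

    def test_flux_conservation_across_cut(self, rng):
        C = rng.integers(1, 20, size=(5, 5))
        cm = CountMatrix(1, C, np.arange(5), False)
        model = estimate_transition_matrix(cm, "reversible_mle")
        rf = reactive_flux(model, [0], [4])
        out_of_source = rf.net_flux[0].sum() - rf.net_flux[:, 0].sum()
        into_sink = rf.net_flux[:, 4].sum() - rf.net_flux[4].sum()
        assert out_of_source == pytest.approx(into_sink, abs=1e-10)
        assert rf.total_flux == pytest.approx(out_of_source, abs=1e-10)
        assert sum(w for _, w in rf.pathways) <= rf.total_flux + 1e-10

    def test_overlapping_source_sink_rejected(self):
        T = np.array([[0.9, 0.1], [0.1, 0.9]])
        with pytest.raises(InvalidSetsError):
            reactive_flux(_model_from_T(T), [0], [0, 1])


class TestFoldedPopulation:
    def test_reference_macro_population_returned(self):
        eps = 1e-3
        T = np.array([[0.95 - eps, 0.05, eps, 0.0],
                      [0.05, 0.95 - eps, 0.0, eps],
                      [eps, 0.0, 0.9 - eps, 0.1],
                      [0.0, eps, 0.1, 0.9 - eps]])
        model = _model_from_T(T)
        macro = pcca_plus(model, 2)
        p, sd = folded_population(macro, reference_microstate=0, model=model)
        expected = model.pi[macro.crisp_assignment ==
                            macro.crisp_assignment[0]].sum()
        assert p == pytest.approx(expected)

    def test_trimmed_reference_rejected(self):
        T = np.array([[0.9, 0.1], [0.1, 0.9]])
        model = _model_from_T(T)
        model.active_set = np.array([3, 4])   # original labels after trimming
        macro = pcca_plus(model, 2)
        with pytest.raises(ReferenceLostError):
            folded_population(macro, reference_microstate=0, model=model)


class TestSeedingBiasRemoval:
    def test_msm_recovers_boltzmann_from_biased_pool(self):
        """Raw frame fractions of a deliberately 50/50-seeded pool
        misrepresent an asymmetric equilibrium; the reversible MSM does not.

        Small version of the seeding-bias-removal argument: equal numbers
        of chains started in each of two lumped basins of a known chain.
        """
        # reversible 4-state chain (from a symmetric count template): two
        # basins {0,1} and {2,3} exchanging slowly vs the trajectory length
        C = np.array([[8000, 900, 10, 0],
                      [900, 8000, 10, 0],
                      [10, 10, 2600, 300],
                      [0, 0, 300, 2600]], dtype=float)
        T = C / C.sum(axis=1, keepdims=True)
        pi = stationary_distribution_matrix(T)
        p_basin = pi[:2].sum()
        dtrajs = []
        for rep in range(600):
            start = 0 if rep % 2 == 0 else 3
            dtrajs.append(_simulate_chain(T, 700, seed=300 + rep,
                                          start=start))
        raw = np.mean([np.mean(d < 2) for d in dtrajs])
        cm = count_transitions(dtrajs, lag=1)
        model = estimate_transition_matrix(cm, "reversible_mle")
        est = model.pi[np.isin(model.active_set, [0, 1])].sum()
        assert abs(raw - p_basin) > 0.05          # the pool really is biased
        assert est == pytest.approx(p_basin, abs=0.03)
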