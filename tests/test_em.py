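"""EM fitting: E/M steps, initialisation, restarts, BIC selection, assignment."""

import numpy as np
import pytest
from scipy.stats import special_ortho_group

from navmix import (
    MixtureModel,
    Responsibilities,
    VMFParams,
    assign,
    e_step,
    fit_fixed_k,
    initialize,
    log_likelihood,
    m_step,
    select_k,
    spherical_kmeans,
)
from navmix.em import NOISE_KAPPA, _bic, _mean_direction

from conftest import make_directional, sample_vmf3, unit_rows


def uniform_circle(n, rng):
    t = rng.uniform(0, 2 * np.pi, n)
    return make_directional(np.column_stack([np.cos(t), np.sin(t)]))


class TestEStep:
    def test_symmetric_components_get_equal_responsibility(self):
        # mu1 and mu2 mirror images about the observation direction
        data = make_directional(np.array([[1.0, 0.0]]))
        model = MixtureModel(
            components=[
                VMFParams(mu=unit_rows([[1.0, 0.5]])[0], kappa=3.0),
                VMFParams(mu=unit_rows([[1.0, -0.5]])[0], kappa=3.0),
            ],
            noise_mu=np.array([1.0, 0.0]),
            pi=np.array([0.45, 0.45, 0.1]),
        )
        g = e_step(data, model).gamma[0]
        assert g[0] == pytest.approx(g[1], abs=1e-12)

    def test_concentration_limit(self):
        data = make_directional(np.array([[0.0, 1.0]]))
        model = MixtureModel(
            components=[VMFParams(mu=np.array([0.0, 1.0]), kappa=400.0)],
            noise_mu=np.array([0.0, 1.0]),
            pi=np.array([0.5, 0.5]),
        )
        # density ratio to the near-uniform noise grows like sqrt(kappa),
        # so the responsibility approaches 1 but only polynomially fast
        assert e_step(data, model).gamma[0, 0] > 0.97

    def test_uniform_component_splits_evenly_with_noise(self):
        # K=1 with kappa=0 against the near-uniform noise: equal pis give
        # responsibilities ~(0.5, 0.5)
        data = make_directional(np.array([[0.6, 0.8]]))
        model = MixtureModel(
            components=[VMFParams(mu=np.array([1.0, 0.0]), kappa=0.0)],
            noise_mu=np.array([0.0, 1.0]),
            pi=np.array([0.5, 0.5]),
        )
        g = e_step(data, model).gamma[0]
        assert g[0] == pytest.approx(0.5, abs=1e-4)

    def test_rows_sum_to_one(self, rng):
        data = uniform_circle(50, rng)
        model = MixtureModel(
            components=[VMFParams(mu=np.array([1.0, 0.0]), kappa=2.0),
                        VMFParams(mu=np.array([0.0, 1.0]), kappa=5.0)],
            noise_mu=_mean_direction(data.x),
            pi=np.array([0.3, 0.3, 0.4]),
        )
        g = e_step(data, model).gamma
        assert np.max(np.abs(g.sum(axis=1) - 1.0)) < 1e-12


class TestMStep:
    def test_mean_direction_of_two_points(self):
        data = make_directional(np.array([[1.0, 0.0], [0.0, 1.0]]))
        resp = Responsibilities(np.array([[0.9, 0.1], [0.9, 0.1]]))
        model = m_step(data, resp)
        assert np.allclose(model.components[0].mu, [1 / np.sqrt(2), 1 / np.sqrt(2)])

    def test_identical_points_hit_kappa_cap(self):
        data = make_directional(np.tile([0.6, 0.8], (5, 1)))
        resp = Responsibilities(np.tile([0.95, 0.05], (5, 1)))
        model = m_step(data, resp)
        assert model.components[0].kappa == 500.0
        assert np.allclose(model.components[0].mu, [0.6, 0.8])

    def test_uniform_sample_gives_small_kappa(self, rng):
        data = uniform_circle(1000, rng)
        resp = Responsibilities(np.tile([0.95, 0.05], (1000, 1)))
        model = m_step(data, resp)
        assert model.components[0].kappa < 0.3

    def test_noise_parameters_not_updated(self, two_cluster_data):
        noise_mu = np.array([0.0, 1.0])
        resp = Responsibilities(np.tile([0.9, 0.1], (two_cluster_data.n, 1)))
        model = m_step(two_cluster_data, resp, noise_mu=noise_mu)
        assert np.allclose(model.noise_mu, noise_mu)
        assert model.noise_kappa == NOISE_KAPPA

    def test_mixing_proportions_are_responsibility_means(self, two_cluster_data):
        gamma = np.tile([0.7, 0.2, 0.1], (two_cluster_data.n, 1))
        model = m_step(two_cluster_data, Responsibilities(gamma))
        assert np.allclose(model.pi, [0.7, 0.2, 0.1])


class TestInitialize:
    def test_rows_sum_to_one_and_structure(self, two_cluster_data, rng):
        resp = initialize(two_cluster_data, K=2, noise_prop0=0.05, rng=rng)
        g = resp.gamma
        assert g.shape == (40, 3)
        assert np.allclose(g.sum(axis=1), 1.0)
        assert np.allclose(g[:, 2], 0.05)
        assert set(np.unique(g[:, :2])) == {0.0, 0.95}

    def test_identical_observations_single_centroid(self, rng):
        data = make_directional(np.tile([0.0, 1.0], (8, 1)))
        labels = spherical_kmeans(data.x, 1, rng)
        assert np.all(labels == 0)

    def test_antipodal_groups_always_separated(self, two_cluster_data):
        for seed in range(10):
            labels = spherical_kmeans(two_cluster_data.x, 2, np.random.default_rng(seed))
            assert len(set(labels[:20])) == 1
            assert len(set(labels[20:])) == 1
            assert labels[0] != labels[-1]

    def test_k_larger_than_n_rejected(self, two_cluster_data):
        with pytest.raises(ValueError):
            initialize(two_cluster_data, K=41)

    def test_reproducible_given_seed(self, two_cluster_data):
        a = initialize(two_cluster_data, 2, rng=123).gamma
        b = initialize(two_cluster_data, 2, rng=123).gamma
        assert np.array_equal(a, b)


class TestFitFixedK:
    def test_recovers_single_tight_component(self, rng):
        mu = unit_rows([[1.0, 1.0, 1.0]])[0]
        x = sample_vmf3(mu, 50.0, 500, rng)
        data = make_directional(x)
        fit = fit_fixed_k(data, K=1, seed=0)
        angle = np.degrees(np.arccos(np.clip(fit.model.components[0].mu @ mu, -1, 1)))
        assert angle < 2.0
        assert fit.model.pi[-1] < 0.05

    def test_outliers_collect_in_noise_cluster(self, rng):
        tight = sample_vmf3(np.array([0.0, 0.0, 1.0]), 100.0, 80, rng)
        outliers = unit_rows(rng.standard_normal((20, 3)))
        # keep outliers away from the cluster so the check is unambiguous
        outliers = outliers[outliers[:, 2] < 0.5][:15]
        data = make_directional(np.vstack([tight, outliers]))
        fit = fit_fixed_k(data, K=1, seed=1)
        noise_resp = fit.resp.gamma[80:, -1]
        assert np.mean(noise_resp > 0.5) >= 0.8

    def test_best_restart_selected(self, two_cluster_data):
        fit = fit_fixed_k(two_cluster_data, K=2, n_restarts=5, seed=3)
        for r in range(5):
            single = fit_fixed_k(two_cluster_data, K=2, n_restarts=1, seed=None)
            # any individual restart cannot beat the maximum over restarts
            # (compare likelihoods on the same data)
            assert fit.loglik >= single.loglik - 1e-6

    def test_monotone_loglik_on_random_problems(self):
        # with the exact concentration update EM ascends strictly; the
        # closed-form approximation may dip by at most its own error
        for seed in range(50):
            rng = np.random.default_rng(seed)
            x = unit_rows(rng.standard_normal((60, 3)))
            data = make_directional(x)
            K = int(rng.integers(1, 4))
            exact = fit_fixed_k(data, K=K, n_restarts=1, kappa_method="exact", seed=seed)
            assert np.all(np.diff(exact.loglik_trace) > -1e-8)
            approx = fit_fixed_k(data, K=K, n_restarts=1, seed=seed)
            assert np.all(np.diff(approx.loglik_trace) > -0.05)

    def test_rotation_equivariance(self, rng):
        x = np.vstack([
            sample_vmf3(np.array([0.0, 0.0, 1.0]), 30.0, 60, rng),
            sample_vmf3(np.array([1.0, 0.0, 0.0]), 30.0, 60, rng),
        ])
        data = make_directional(x)
        R = special_ortho_group.rvs(3, random_state=rng)
        data_rot = make_directional(data.x @ R.T)
        fit = fit_fixed_k(data, K=2, seed=5)
        fit_rot = fit_fixed_k(data_rot, K=2, seed=5)
        assert fit_rot.loglik == pytest.approx(fit.loglik, abs=1e-8)
        assert np.allclose(np.sort(fit_rot.model.pi), np.sort(fit.model.pi), atol=1e-8)
        kap = sorted(c.kappa for c in fit.model.components)
        kap_rot = sorted(c.kappa for c in fit_rot.model.components)
        assert np.allclose(kap, kap_rot, rtol=1e-8)
        # mean directions rotate with the data (match components by kappa order)
        mus = {round(c.kappa, 6): c.mu for c in fit.model.components}
        for c in fit_rot.model.components:
            assert np.max(np.abs(c.mu - R @ mus[round(c.kappa, 6)])) < 1e-6

    def test_label_permutation_leaves_likelihood_unchanged(self, two_cluster_data):
        fit = fit_fixed_k(two_cluster_data, K=2, seed=7)
        m = fit.model
        permuted = MixtureModel(
            components=[m.components[1], m.components[0]],
            noise_mu=m.noise_mu,
            pi=np.array([m.pi[1], m.pi[0], m.pi[2]]),
        )
        assert log_likelihood(two_cluster_data, permuted) == pytest.approx(
            log_likelihood(two_cluster_data, m), abs=1e-10
        )

    def test_parameter_recovery_two_components(self, rng):
        mus = unit_rows([[1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        x = np.vstack([sample_vmf3(mus[0], 50.0, 250, rng), sample_vmf3(mus[1], 50.0, 250, rng)])
        data = make_directional(x)
        fit = fit_fixed_k(data, K=2, seed=11)
        fitted = sorted(fit.model.components, key=lambda c: -c.mu[0])
        for c, mu in zip(fitted, mus):
            angle = np.degrees(np.arccos(np.clip(c.mu @ mu, -1, 1)))
            assert angle < 2.0
            assert abs(c.kappa - 50.0) / 50.0 < 0.15


class TestSelectK:
    def test_bic_formula(self):
        # parameter count (m+2)K + m: m=9, K=4 -> 53
        n, ll = 100, -123.4
        assert _bic(ll, 4, 9, n) == pytest.approx(-2 * ll + 53 * np.log(n), abs=1e-12)

    def test_selects_two_for_two_clear_clusters(self, two_cluster_data):
        fit = select_k(two_cluster_data, seed=2)
        assert fit.model.K == 2

    def test_argmin_over_evaluated_k(self, rng):
        # one tight cluster: K=1 must win over K=2 despite both being fit
        x = sample_vmf3(np.array([0.0, 0.0, 1.0]), 80.0, 200, rng)
        data = make_directional(x)
        fit = select_k(data, seed=4)
        assert fit.model.K == 1


class TestAssign:
    def make_result(self, gamma):
        gamma = np.atleast_2d(gamma)
        K = gamma.shape[1] - 1
        comps = [VMFParams(mu=np.array([1.0, 0.0]), kappa=1.0) for _ in range(K)]
        model = MixtureModel(components=comps, noise_mu=np.array([1.0, 0.0]),
                             pi=np.full(K + 1, 1.0 / (K + 1)))
        from navmix import FitResult

        return FitResult(model=model, resp=Responsibilities(gamma),
                         loglik_trace=[-1.0], bic=0.0, n_iter=1, converged=True,
                         n_restarts_used=1, seed=0)

    def test_hard_argmax(self):
        a = assign(self.make_result([[0.7, 0.2, 0.1]]))
        assert a.hard_labels == ["1"]

    def test_hard_tie_breaks_to_lowest_index(self):
        a = assign(self.make_result([[0.4, 0.4, 0.2]]))
        assert a.hard_labels == ["1"]

    def test_noise_label(self):
        a = assign(self.make_result([[0.1, 0.2, 0.7]]))
        assert a.hard_labels == ["noise"]

    def test_threshold_unassigned(self):
        a = assign(self.make_result([[0.4, 0.35, 0.25]]), mode="threshold", threshold=0.5)
        assert a.hard_labels == ["unassigned"]

    def test_soft_sets(self):
        a = assign(self.make_result([[0.45, 0.35, 0.20]]), mode="soft", threshold=0.3)
        assert a.soft_labels == [["1", "2"]]

    def test_invalid_mode_and_threshold(self):
        with pytest.raises(ValueError):
            assign(self.make_result([[0.5, 0.5]]), mode="weird")
        with pytest.raises(ValueError):
            assign(self.make_result([[0.5, 0.5]]), mode="soft", threshold=0.0)
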