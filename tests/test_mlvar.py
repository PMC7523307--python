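"""Unit-level checks of the model module: draw containers, composition,
diagnostics, and the conjugate/FFBS kernels against brute-force oracles."""

import numpy as np
import pytest

from bridgevar import _sampler
from bridgevar.mlvar import (PosteriorDraws, edge_density, edge_summaries,
                             group_phi_draws, psr_diagnostic, split_rhat)
from bridgevar.simulate import stationary_cov

CODES = ["REL", "CHE", "IRR", "LIS", "DOW", "NER", "WOR"]


def make_draws(gamma, groups=("comorbid", "depression_only")):
    gamma = np.asarray(gamma, dtype=float)
    c, d, k, q = gamma.shape
    return PosteriorDraws(gamma=gamma, tau2=np.ones((c, d, q)),
                          sigma=np.tile(np.eye(7), (c, d, 1, 1)),
                          groups=list(groups[:k]), item_codes=CODES)


class TestComposition:
    def test_reference_group_is_gamma0(self):
        rng = np.random.default_rng(0)
        gamma = rng.normal(size=(2, 30, 2, 56))
        draws = make_draws(gamma)
        assert np.array_equal(draws.phi_group("comorbid"),
                              gamma[:, :, 0, :49].reshape(2, 30, 7, 7))

    def test_zero_offset_group_equals_reference_drawwise(self):
        rng = np.random.default_rng(1)
        gamma = rng.normal(size=(2, 30, 2, 56))
        gamma[:, :, 1, :] = 0.0
        draws = make_draws(gamma)
        assert np.array_equal(draws.phi_group("comorbid"),
                              draws.phi_group("depression_only"))

    def test_offset_arithmetic(self):
        gamma = np.zeros((2, 10, 2, 56))
        gamma[:, :, 0, 0] = 0.2    # phi[REL<-REL] reference mean
        gamma[:, :, 1, 0] = -0.1   # depression-only offset
        draws = make_draws(gamma)
        assert np.allclose(draws.phi_group("depression_only")[:, :, 0, 0], 0.1)
        # composition identity holds at every draw
        recon = draws.gamma[:, :, 0, :] + draws.gamma[:, :, 1, :]
        assert np.array_equal(draws._group_gamma("depression_only"), recon)

    def test_unknown_group_rejected(self):
        draws = make_draws(np.zeros((2, 10, 2, 56)))
        with pytest.raises(KeyError):
            draws.phi_group("nope")
        with pytest.raises(KeyError):
            group_phi_draws(draws, "nope")


class TestPsr:
    def test_identical_chains_near_one(self):
        x = np.tile(np.random.default_rng(0).normal(size=400), (2, 1))
        assert split_rhat(x) == pytest.approx(1.0, abs=0.02)

    def test_shifted_chains_flagged(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(2, 400))
        x[1] += 2.0
        assert split_rhat(x) > 1.5

    def test_matches_arviz_split_rhat(self):
        arviz = pytest.importorskip("arviz")
        rng = np.random.default_rng(2)
        for shift in (0.0, 0.2, 0.7):
            x = rng.normal(size=(2, 400))
            x[1] += shift
            assert split_rhat(x) == pytest.approx(
                float(arviz.rhat(x, method="split")), abs=1e-10)

    def test_single_chain_rejected(self):
        draws = make_draws(np.zeros((1, 10, 2, 56)))
        with pytest.raises(ValueError):
            psr_diagnostic(draws)

    def test_diagnostic_table_covers_all_fixed_effects(self):
        rng = np.random.default_rng(3)
        draws = make_draws(rng.normal(size=(2, 40, 2, 56)))
        table = psr_diagnostic(draws)
        assert len(table) == 2 * 56 + 7
        assert table["ok"].all()


class TestEdgeSummaries:
    def test_constant_positive_entry_is_significant(self):
        gamma = np.zeros((2, 20, 1, 56))
        gamma[:, :, 0, 1] = 0.3           # phi[REL<-CHE]
        edges = edge_summaries(make_draws(gamma, groups=("comorbid",)))
        assert len(edges) == 49
        row = edges[(edges["to"] == "REL") & (edges["from"] == "CHE")].iloc[0]
        assert (row["lo"], row["hi"]) == (0.3, 0.3) and row["significant"]
        assert int(edges["significant"].sum()) == 1

    def test_symmetric_draws_not_significant(self):
        gamma = np.zeros((2, 20, 1, 56))
        gamma[:, :, 0, 5] = np.linspace(-1, 1, 20)
        edges = edge_summaries(make_draws(gamma, groups=("comorbid",)))
        assert not edges["significant"].any()
        dens = edge_density(edges)
        assert dens.iloc[0]["n_edges"] == 49 and dens.iloc[0]["n_significant"] == 0


class TestConjugateKernels:
    """Brute-force oracles for the compiled full-conditional draws."""

    def _data(self, T=40, p=3, seed=0):
        rng = np.random.default_rng(seed)
        phi = 0.3 * np.eye(p) + rng.normal(0, 0.05, (p, p))
        sigma = np.eye(p) + 0.2
        z = np.zeros((T, p))
        for t in range(1, T):
            z[t] = phi @ z[t - 1] + rng.multivariate_normal(np.zeros(p), sigma)
        return z, sigma

    def test_phi_conditional_mean_matches_kron_solve(self):
        z, sigma = self._data()
        p = z.shape[1]
        sigma_inv = np.linalg.inv(sigma)
        tau_inv = np.full(p * p, 1.0 / 0.01)
        prior = np.full((p, p), 0.05)
        # noise = 0 returns the conditional mean
        got = _sampler._draw_phi(z, sigma_inv, tau_inv, prior, np.zeros(p * p))
        X, Z = z[:-1], z[1:]
        prec = np.kron(sigma_inv, X.T @ X) + np.diag(tau_inv)
        h = (sigma_inv @ (Z.T @ X)).ravel() + prior.ravel() * tau_inv
        expected = np.linalg.solve(prec, h).reshape(p, p)
        assert np.allclose(got, expected, atol=1e-10)

    def test_phi_conditional_covariance_matches(self):
        z, sigma = self._data(T=30, seed=1)
        p = z.shape[1]
        sigma_inv = np.linalg.inv(sigma)
        tau_inv = np.full(p * p, 1.0 / 0.04)
        prior = np.zeros((p, p))
        rng = np.random.default_rng(2)
        draws = np.array([
            _sampler._draw_phi(z, sigma_inv, tau_inv, prior,
                               rng.standard_normal(p * p)).ravel()
            for _ in range(4000)])
        X = z[:-1]
        prec = np.kron(sigma_inv, X.T @ X) + np.diag(tau_inv)
        cov_expected = np.linalg.inv(prec)
        emp = np.cov(draws, rowvar=False)
        dg = np.diag(cov_expected)
        se = np.sqrt((np.outer(dg, dg) + cov_expected**2) / len(draws))
        assert np.abs(emp - cov_expected).max() < (5 * se).max()
        assert np.abs((np.diag(emp) - dg) / dg).max() < 0.1

    def test_mu_conditional_mean_matches_direct_formula(self):
        z, sigma = self._data(T=60, seed=3)
        p = z.shape[1]
        y = z + 4.0
        phi = 0.25 * np.eye(p)
        sigma_inv = np.linalg.inv(sigma)
        tau_inv = np.full(p, 1.0 / 0.25)
        prior = np.full(p, 4.0)
        got = _sampler._draw_mu(y, y.shape[0], phi, sigma_inv, tau_inv,
                                prior, np.zeros(p))
        A = np.eye(p) - phi
        csum = (y[1:] - y[:-1] @ phi.T).sum(axis=0)
        prec = (y.shape[0] - 1) * A.T @ sigma_inv @ A + np.diag(tau_inv)
        h = A.T @ sigma_inv @ csum + prior * tau_inv
        assert np.allclose(got, np.linalg.solve(prec, h), atol=1e-10)

    def test_stationary_cov_kernel_matches_lyapunov_solver(self):
        rng = np.random.default_rng(4)
        phi = 0.4 * np.eye(7) + rng.normal(0, 0.05, (7, 7))
        sigma = np.eye(7) + 0.3
        got = _sampler._stationary_cov(phi, sigma)
        assert np.allclose(got, stationary_cov(phi, sigma), atol=1e-8)


class TestFfbs:
    def test_imputation_distribution_matches_gaussian_conditional(self):
        """A fully missing middle slot: FFBS draws must match the exact
        conditional N(z1 | z0, z2) computed from the joint covariance."""
        p = 2
        rng = np.random.default_rng(0)
        phi = np.array([[0.5, 0.1], [0.0, 0.4]])
        sigma = np.array([[1.0, 0.3], [0.3, 0.8]])
        v0 = stationary_cov(phi, sigma)
        mu = np.array([3.0, 4.0])
        y_obs = np.array([[3.5, 4.2], [np.nan, np.nan], [2.8, 3.9]])
        obs = np.isfinite(y_obs)

        # exact conditional from the joint of (z0, z1, z2)
        v1 = phi @ v0 @ phi.T + sigma
        v2 = phi @ v1 @ phi.T + sigma
        c01 = v0 @ phi.T                 # cov(z0, z1)
        c12 = v1 @ phi.T                 # cov(z1, z2)
        c02 = v0 @ (phi @ phi).T         # cov(z0, z2)
        Z = np.block([[v0, c01, c02],
                      [c01.T, v1, c12],
                      [c02.T, c12.T, v2]])
        idx_m, idx_o = [2, 3], [0, 1, 4, 5]
        Smm = Z[np.ix_(idx_m, idx_m)]
        Smo = Z[np.ix_(idx_m, idx_o)]
        Soo = Z[np.ix_(idx_o, idx_o)]
        zobs = (y_obs - mu)[obs]
        cond_mean = Smo @ np.linalg.solve(Soo, zobs)
        cond_cov = Smm - Smo @ np.linalg.solve(Soo, Smo.T)

        samples = []
        for _ in range(6000):
            y = np.where(obs, y_obs, 0.0)
            _sampler._ffbs_person(y, obs, 3, phi, mu, sigma, v0,
                                  rng.standard_normal((3, p)))
            samples.append(y[1] - mu[:p])
        samples = np.asarray(samples)
        se = np.sqrt(np.diag(cond_cov) / len(samples))
        assert np.all(np.abs(samples.mean(axis=0) - cond_mean) < 4 * se)
        assert np.allclose(np.cov(samples, rowvar=False), cond_cov, atol=0.05)

    def test_observed_cells_never_modified(self):
        rng = np.random.default_rng(1)
        p = 7
        phi, sigma = 0.2 * np.eye(p), np.eye(p)
        v0 = stationary_cov(phi, sigma)
        y = rng.normal(4.0, 1.0, size=(20, p))
        obs = rng.random((20, p)) > 0.3
        y_in = np.where(obs, y, 0.0)
        y_work = y_in.copy()
        _sampler._ffbs_person(y_work, obs, 20, phi, np.full(p, 4.0), sigma, v0,
                              rng.standard_normal((20, p)))
        assert np.array_equal(y_work[obs], y_in[obs])
        assert np.all(np.isfinite(y_work))
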