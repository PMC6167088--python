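"""No-spikes model: identifiability machinery and chain behavior."""

import numpy as np
import pytest

from scdisp.data import ExpressionDataset
from scdisp.sampler_nospikes import (
    compute_mu0,
    conditional_prior_mu,
    constraint_set,
    pick_reference,
    reference_value,
    run_chain_nospikes,
)
from scdisp.simulate import default_truth, simulate_nospikes, simulate_spikes

import oracles as orc


class TestMu0:
    def test_geometric_mean_of_empirical_means(self):
        # equal library sizes: size factors 1; means 1 and 4 -> mu0 = 2
        counts = np.array([[1, 1], [4, 4]])
        assert compute_mu0(counts) == pytest.approx(2.0)

    def test_zero_total_gene_excluded(self):
        counts = np.array([[1, 1], [4, 4], [0, 0]])
        assert compute_mu0(counts) == pytest.approx(2.0)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(4.0, size=(30, 20))
        base = compute_mu0(counts)
        assert compute_mu0(3 * counts) == pytest.approx(3 * base, rel=1e-9)

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            compute_mu0(np.zeros((3, 2), dtype=int))


class TestConstraintSet:
    def test_boundary_inclusive_at_one(self):
        counts = np.array(
            [
                [1, 1, 1, 1],      # mean 1.0: included
                [1, 1, 1, 0],      # mean 0.75: excluded
                [9, 9, 9, 9],
            ]
        )
        np.testing.assert_array_equal(constraint_set(counts), [True, False, True])

    def test_all_high_all_included(self):
        counts = np.full((4, 3), 7)
        assert constraint_set(counts).all()

    def test_empty_set_errors(self):
        with pytest.raises(ValueError, match="constraint set"):
            constraint_set(np.zeros((2, 5), dtype=int))


class TestReferenceValue:
    def test_two_gene_example(self):
        # q_c = 2, mu0 = 2, other = 1: log mu_r = 2 log 2 - 0 -> mu_r = 4
        assert reference_value(np.array([1.0]), 2.0, 2) == pytest.approx(4.0)

    def test_symmetric_case(self):
        assert reference_value(np.full(4, 3.0), 3.0, 5) == pytest.approx(3.0)

    def test_overflow_guarded(self):
        with pytest.raises(OverflowError):
            reference_value(np.full(100, 1e-30), 1e6, 101)


class TestConditionalPrior:
    def test_variance_is_half_a_mu2(self):
        mu = np.exp(np.random.default_rng(0).normal(0, 1, 6))
        constrained = np.ones(6, bool)
        _, var = conditional_prior_mu(2, mu, 1.5, 0.8, constrained, reference=0)
        assert var == pytest.approx(0.4)

    def test_symmetric_case_mean_zero(self):
        mu = np.ones(3)
        constrained = np.ones(3, bool)
        mean, _ = conditional_prior_mu(1, mu, 1.0, 0.5, constrained, reference=0)
        assert mean == pytest.approx(0.0)

    def test_reference_gene_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            conditional_prior_mu(0, np.ones(3), 1.0, 0.5, np.ones(3, bool), 0)

    def test_matches_degenerate_mvn_linear_algebra(self):
        """Pseudo-inverse conditional of N(log mu0 1, a(I - 11'/q)) at q = 10."""
        rng = np.random.default_rng(3)
        q, a_mu2, mu0 = 10, 0.7, 2.0
        r, i = 0, 4
        y = rng.normal(np.log(mu0), 0.3, q)
        # marginal of the q-1 non-reference coords is full rank
        cov = a_mu2 * (np.eye(q - 1) - np.ones((q - 1, q - 1)) / q)
        keep = [k for k in range(q) if k != r]
        pos = keep.index(i)
        rest = [k for k in range(q - 1) if k != pos]
        c_ii = cov[pos, pos]
        c_ir = cov[np.ix_([pos], rest)]
        c_rr = cov[np.ix_(rest, rest)]
        sol = np.linalg.solve(c_rr, c_ir.T)
        cond_var = c_ii - (c_ir @ sol).item()
        cond_mean = np.log(mu0) + (
            sol.T @ (y[np.array(keep)[rest]] - np.log(mu0))
        ).item()
        mean, var = conditional_prior_mu(
            i, np.exp(y), mu0, a_mu2, np.ones(q, bool), reference=r
        )
        assert var == pytest.approx(cond_var, abs=1e-10)
        assert mean == pytest.approx(cond_mean, abs=1e-10)

    def test_reference_conditional_variance_is_zero(self):
        """Given all other coords, the reference has a point-mass conditional."""
        q, a_mu2 = 10, 0.7
        cov = a_mu2 * (np.eye(q) - np.ones((q, q)) / q)
        r = 3
        rest = [k for k in range(q) if k != r]
        c_rr = cov[np.ix_(rest, rest)]
        c_r = cov[np.ix_([r], rest)]
        cond_var = cov[r, r] - (c_r @ np.linalg.solve(c_rr, c_r.T)).item()
        assert abs(cond_var) < 1e-10


class TestPickReference:
    def test_always_inside_constraint_set(self):
        rng = np.random.default_rng(1)
        mask = np.array([False, True, False, True, True, False])
        draws = {pick_reference(rng, mask) for _ in range(200)}
        assert draws <= {1, 3, 4}

    def test_uniform_frequencies(self):
        rng = np.random.default_rng(2)
        mask = np.array([True, True, True, True, False])
        n = 10000
        counts = np.bincount(
            [pick_reference(rng, mask) for _ in range(n)], minlength=5
        )
        se = np.sqrt(0.25 * 0.75 / n)
        np.testing.assert_allclose(counts[:4] / n, 0.25, atol=3 * se)
        assert counts[4] == 0

    def test_singleton_set(self):
        rng = np.random.default_rng(3)
        mask = np.array([False, False, True])
        assert pick_reference(rng, mask) == 2


class TestPriorConstruction:
    def test_projected_lognormals_match_correlated_covariance(self):
        """Sampling independent log-Normals then projecting onto the
        constraint reproduces the a_mu2 (I - 11'/q) covariance."""
        rng = np.random.default_rng(4)
        q, a_mu2, mu0 = 8, 0.6, 1.7
        n = 60000
        y = rng.normal(0.0, np.sqrt(a_mu2), size=(n, q))
        y = y - y.mean(axis=1, keepdims=True) + np.log(mu0)
        target = a_mu2 * (np.eye(q) - np.ones((q, q)) / q)
        emp = np.cov(y.T)
        assert np.linalg.norm(emp - target) / np.linalg.norm(target) < 0.02
        np.testing.assert_allclose(y.mean(axis=0), np.log(mu0), atol=0.02)


class TestChain:
    @pytest.fixture(scope="class")
    def fitted(self):
        truth = default_truth(n_genes=80, n_cells=48, seed=41)
        truth.theta = np.array([0.4, 0.4])
        ds = simulate_nospikes(truth, [24, 24], seed=42)
        chain = run_chain_nospikes(ds, n_iter=900, burn_in=400, thin=1, seed=43)
        return truth, ds, chain

    def test_constraint_exact_in_every_stored_draw(self, fitted):
        _, _, chain = fitted
        mask = chain.extra["constrained"].astype(bool)
        mu0 = float(chain.extra["mu0"])
        logsum = np.log(chain.draws["mu"][:, mask]).mean(axis=1)
        np.testing.assert_allclose(logsum, np.log(mu0), atol=1e-10)

    def test_reference_always_constrained(self, fitted):
        _, _, chain = fitted
        mask = chain.extra["constrained"].astype(bool)
        refs = chain.draws["reference"][:, 0]
        assert mask[refs].all()

    def test_theta_per_batch_and_positive(self, fitted):
        _, _, chain = fitted
        assert chain.draws["theta"].shape[1] == 2
        assert (chain.draws["theta"] > 0).all()

    def test_two_seeds_agree_on_posterior_medians(self, fitted):
        """Stochastic reference: no single gene distorted in either run."""
        truth, ds, chain = fitted
        other = run_chain_nospikes(ds, n_iter=900, burn_in=400, thin=1, seed=77)
        m1 = np.log(np.median(chain.draws["mu"], axis=0))
        m2 = np.log(np.median(other.draws["mu"], axis=0))
        assert np.corrcoef(m1, m2)[0, 1] > 0.99
        assert np.max(np.abs(m1 - m2)) < 0.5

    def test_single_batch_warns_but_runs(self):
        truth = default_truth(n_genes=30, n_cells=16, seed=44)
        ds = simulate_nospikes(truth, [16], seed=45)
        with pytest.warns(RuntimeWarning, match="single batch"):
            chain = run_chain_nospikes(ds, n_iter=60, burn_in=30, thin=1, seed=46)
        assert chain.draws["theta"].shape[1] == 1


class TestAgreementWithSpikesModel:
    def test_mu_delta_agree_across_integration_strategies(self):
        """Fit the same cells with and without using their spike-ins."""
        truth = default_truth(n_genes=150, n_cells=60, seed=51)
        ds = simulate_spikes(truth, seed=52)
        # the no-spikes fit needs batch structure: split cells into 2 batches
        ds.batch = np.array(["b1"] * 30 + ["b2"] * 30)
        kw = dict(n_iter=2400, burn_in=1200, thin=3)
        from scdisp.sampler_spikes import run_chain

        with_spk = run_chain(ds, seed=53, **kw)
        without = run_chain_nospikes(ds, seed=54, **kw)
        mu_a = np.log(np.median(with_spk.draws["mu"], axis=0))
        mu_b = np.log(np.median(without.draws["mu"], axis=0))
        d_a = np.log(np.median(with_spk.draws["delta"], axis=0))
        d_b = np.log(np.median(without.draws["delta"], axis=0))
        assert np.corrcoef(mu_a, mu_b)[0, 1] > 0.9
        assert np.corrcoef(d_a, d_b)[0, 1] > 0.9
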