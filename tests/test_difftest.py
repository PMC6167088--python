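"""Differential tests: tail probabilities, EFDR calibration, classification."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from scdisp.chain import PosteriorChain
from scdisp.data import ExpressionDataset
from scdisp.difftest import (
    calibrate_efdr,
    classify_four_way,
    decompose_log2fc,
    denoised_counts,
    eligibility_filter,
    offset_correct,
)
from scdisp.difftest import test_mean as de_mean
from scdisp.difftest import test_overdispersion as de_disp
from scdisp.difftest import test_residual as de_resid


def _chain(draws, gene_ids=None, variant="spikes-regression", n_iter=None):
    n_stored = next(iter(draws.values())).shape[0]
    q = draws["mu"].shape[1] if "mu" in draws else draws["epsilon"].shape[1]
    return PosteriorChain(
        draws={k: np.asarray(v, float) for k, v in draws.items()},
        n_iter=n_stored,
        burn_in=0,
        thin=1,
        seed=0,
        model_variant=variant,
        gene_ids=np.array(
            [f"g{i}" for i in range(q)] if gene_ids is None else gene_ids,
            dtype=object,
        ),
    )


def _const_chain(mu, delta, eps, n_stored=10):
    q = len(mu)
    return _chain(
        {
            "mu": np.tile(mu, (n_stored, 1)),
            "delta": np.tile(delta, (n_stored, 1)),
            "epsilon": np.tile(eps, (n_stored, 1)),
        }
    )


class TestCalibrateEfdr:
    def test_hand_computed_example(self):
        # probs (1, 1, .6): above alpha ~ 0.9 only the two certain genes
        # remain, EFDR = 0 with 2 calls
        alpha, efdr = calibrate_efdr(np.array([1.0, 1.0, 0.6]), 0.10)
        assert alpha is not None and alpha > 0.6
        assert efdr == 0.0

    def test_uninformative_probs_give_no_calls(self):
        with pytest.warns(RuntimeWarning, match="no probability cutoff"):
            alpha, efdr = calibrate_efdr(np.full(20, 0.5), 0.10)
        assert alpha is None and efdr is None

    def test_many_confident_genes(self):
        alpha, efdr = calibrate_efdr(np.full(100, 0.99), 0.10)
        assert efdr == pytest.approx(0.01)
        called = (np.full(100, 0.99) > alpha).sum()
        assert called == 100

    def test_achieved_at_or_below_target_whenever_calls_made(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            probs = rng.beta(0.5, 0.5, 200)
            alpha, efdr = calibrate_efdr(probs, 0.10)
            if alpha is not None:
                assert efdr <= 0.10
                assert (probs > alpha).sum() >= 1

    def test_empty_vector_errors(self):
        with pytest.raises(ValueError):
            calibrate_efdr(np.array([]), 0.1)


class TestOffsetCorrect:
    def test_identical_chains_offset_one(self):
        a = _const_chain([2.0, 4.0], [1.0, 1.0], [0.0, 0.0])
        b = _const_chain([2.0, 4.0], [1.0, 1.0], [0.0, 0.0])
        adjA, adjB, offset = offset_correct(a, b)
        assert offset == pytest.approx(1.0)
        np.testing.assert_allclose(adjB.draws["mu"], b.draws["mu"])

    def test_doubled_mu_corrected_exactly(self):
        a = _const_chain([2.0, 4.0], [1.0, 3.0], [0.1, -0.1])
        b = _const_chain([4.0, 8.0], [1.0, 3.0], [0.1, -0.1])
        adjA, adjB, offset = offset_correct(a, b)
        assert offset == pytest.approx(0.5)
        np.testing.assert_allclose(adjB.draws["mu"], adjA.draws["mu"])
        # delta fold change untouched draw-wise
        np.testing.assert_allclose(
            adjB.draws["delta"], b.draws["delta"]
        )

    def test_mismatched_genes_error(self):
        a = _const_chain([2.0, 4.0], [1.0, 1.0], [0.0, 0.0])
        b = dataclasses.replace(a, gene_ids=np.array(["x", "y"], dtype=object))
        with pytest.raises(ValueError, match="mismatched gene sets"):
            offset_correct(a, b)

    def test_unequal_lengths_error(self):
        a = _const_chain([2.0], [1.0], [0.0], n_stored=10)
        b = _const_chain([2.0], [1.0], [0.0], n_stored=8)
        with pytest.raises(ValueError, match="paired by index"):
            offset_correct(a, b)


class TestTailProbabilities:
    def test_counting_oracle_exact_fractions(self):
        """Hand-built 10-draw chains: probabilities are exact draw fractions."""
        rng = np.random.default_rng(1)
        base = np.full((10, 1), 1.0)
        # gene exceeds |log2 fc| > 0.58 in exactly 7 of 10 paired draws
        muA = np.hstack([np.where(np.arange(10) < 7, 2.0, 1.0)[:, None]])
        a = _chain({"mu": muA, "delta": base, "epsilon": base * 0})
        b = _chain({"mu": base, "delta": base, "epsilon": base * 0})
        res = de_mean(a, b, tau0=0.58, efdr_target=0.1)
        assert res.table["tail_prob"].iloc[0] == pytest.approx(0.7)

    def test_identical_chains_no_calls(self):
        mu = np.tile([2.0, 5.0, 9.0], (10, 1))
        a = _chain({"mu": mu, "delta": mu, "epsilon": mu * 0})
        b = _chain({"mu": mu.copy(), "delta": mu.copy(), "epsilon": mu * 0})
        with pytest.warns(RuntimeWarning):
            res = de_mean(a, b, tau0=0.58)
        assert (res.table["tail_prob"] == 0).all()
        assert res.n_calls == 0

    def test_zero_threshold_sign_rule(self):
        rng = np.random.default_rng(2)
        diff = rng.normal(0, 1, (400, 1))  # symmetric null
        eps_a = diff
        eps_b = np.zeros_like(diff)
        mu = np.ones_like(diff)
        a = _chain({"mu": mu, "delta": mu, "epsilon": eps_a})
        b = _chain({"mu": mu, "delta": mu, "epsilon": eps_b})
        with pytest.warns(RuntimeWarning):
            res = de_resid(a, b, psi0=0.0)
        assert res.table["tail_prob"].iloc[0] < 0.2
        assert res.n_calls == 0

    def test_residual_thresholds_bracket_known_difference(self):
        # |eps_A - eps_B| = 0.5 in every draw
        mu = np.ones((10, 1))
        a = _chain({"mu": mu, "delta": mu, "epsilon": np.full((10, 1), 0.5)})
        b = _chain({"mu": mu, "delta": mu, "epsilon": np.zeros((10, 1))})
        r1 = de_resid(a, b, psi0=0.41)
        assert r1.table["tail_prob"].iloc[0] == 1.0
        with pytest.warns(RuntimeWarning):
            r2 = de_resid(a, b, psi0=0.6)
        assert r2.table["tail_prob"].iloc[0] == 0.0

    def test_residual_requires_regression_chains(self):
        mu = np.ones((5, 1))
        a = _chain({"mu": mu, "delta": mu}, variant="spikes-nonregression")
        b = _chain({"mu": mu, "delta": mu}, variant="spikes-nonregression")
        with pytest.raises(ValueError, match="regression"):
            de_resid(a, b)

    def test_large_overdispersion_shift_detected(self):
        rng = np.random.default_rng(3)
        delta = np.exp(rng.normal(0, 0.05, (50, 3)))
        a = _chain({"mu": np.ones((50, 3)), "delta": delta, "epsilon": delta * 0})
        b = _chain(
            {"mu": np.ones((50, 3)), "delta": delta * 2.0**5, "epsilon": delta * 0}
        )
        res = de_disp(a, b, omega0=0.58)
        np.testing.assert_allclose(res.table["tail_prob"], 1.0)

    def test_overdispersion_restriction_to_non_de(self):
        mu = np.ones((10, 2))
        muA = mu.copy()
        muA[:, 0] = 8.0  # gene 0 strongly DE in mean
        delta = np.tile([1.0, 1.0], (10, 1))
        a = _chain({"mu": muA, "delta": delta * 4, "epsilon": delta * 0})
        b = _chain({"mu": mu, "delta": delta, "epsilon": delta * 0})
        m = de_mean(a, b, tau0=0.58)
        res = de_disp(
            a, b, omega0=0.58, mean_result=m, restrict_to_non_de=True
        )
        assert res.table["call"].iloc[0] == "excluded"
        assert res.table["call"].iloc[1] == "more_disp"


class TestEligibility:
    def _ds(self, counts):
        counts = np.asarray(counts)
        return ExpressionDataset(
            counts=counts,
            gene_ids=np.array([f"g{i}" for i in range(counts.shape[0])], dtype=object),
            is_spike=np.zeros(counts.shape[0], bool),
            batch=np.array(["b"] * counts.shape[1]),
        )

    def test_boundary_and_exclusions(self):
        dsA = self._ds([[1, 0, 0], [3, 2, 0], [0, 0, 0]])
        dsB = self._ds([[5, 5, 5], [1, 1, 0], [0, 0, 0]])
        elig = eligibility_filter(dsA, dsB)
        # gene0: 1 cell in A -> excluded; gene1: 2 and 2 -> eligible;
        # gene2: all-zero -> excluded
        assert elig.tolist() == [False, True, False]


class TestDecomposeAndClassify:
    def test_identity_holds_per_draw(self):
        rng = np.random.default_rng(4)
        n, q = 30, 8
        mk = lambda: {
            "mu": np.exp(rng.normal(1, 0.5, (n, q))),
            "delta": np.exp(rng.normal(0, 0.5, (n, q))),
            "epsilon": rng.normal(0, 0.5, (n, q)),
        }
        a, b = _chain(mk()), _chain(mk())
        log2e = np.log2(np.e)
        # per-draw identity: log2(dA/dB) = log2(e)[(fA-fB) + (epsA-epsB)]
        fA = np.log(a.draws["delta"]) - a.draws["epsilon"]
        fB = np.log(b.draws["delta"]) - b.draws["epsilon"]
        lhs = np.log2(a.draws["delta"] / b.draws["delta"])
        rhs = log2e * (fA - fB) + log2e * (a.draws["epsilon"] - b.draws["epsilon"])
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)
        table = decompose_log2fc(a, b)
        # medians of the two components recombine consistently with the
        # brute-force recomputation above
        np.testing.assert_allclose(
            table["mean_contribution"], np.median(log2e * (fA - fB), axis=0), atol=1e-12
        )

    def test_four_way_labels_partition(self):
        def res(kind, calls):
            from scdisp.difftest import TestResult

            return TestResult(
                table=pd.DataFrame(
                    {"id": [f"g{i}" for i in range(len(calls))], "call": calls}
                ),
                threshold=0.5,
                alpha=0.9,
                efdr_achieved=0.0,
                efdr_target=0.1,
                kind=kind,
            )

        m = res("mean", ["up", "down", "up", "none", "down", "excluded"])
        r = res("residual", ["more_var", "less_var", "none", "more_var", "more_var", "excluded"])
        out = classify_four_way(m, r)
        assert out["category"].tolist() == [
            "up+higherVar",
            "down+lowerVar",
            "mean-only",
            "variability-only",
            "down+higherVar",
            "excluded",
        ]
        assert len(out) == 6


class TestDenoisedCounts:
    def _ds_chain(self, factors):
        counts = np.array([[4, 8, 2], [10, 6, 2]])
        ds = ExpressionDataset(
            counts=counts,
            gene_ids=np.array(["a", "b"], dtype=object),
            is_spike=np.zeros(2, bool),
            batch=np.array(["b"] * 3),
        )
        n_stored = 5
        chain = _chain(
            {
                "mu": np.ones((n_stored, 2)),
                "delta": np.ones((n_stored, 2)),
                "epsilon": np.zeros((n_stored, 2)),
                "phi": np.tile(factors, (n_stored, 1)),
                "nu": np.ones((n_stored, 3)),
            }
        )
        return ds, chain

    def test_unit_factors_identity(self):
        ds, chain = self._ds_chain(np.ones(3))
        np.testing.assert_allclose(denoised_counts(ds, chain), ds.counts)

    def test_doubling_a_cell_factor_halves_its_column(self):
        ds, chain = self._ds_chain(np.array([2.0, 1.0, 1.0]))
        out = denoised_counts(ds, chain)
        np.testing.assert_allclose(out[:, 0], ds.counts[:, 0] / 2.0)
        np.testing.assert_allclose(out[:, 1:], ds.counts[:, 1:])
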