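"""Sampler for the horizontal-integration (no-spikes) model.

Without spike-in controls the scale of mean expression mu_i and of the
cell-level normalisation parameters s_jk cannot be separated. The model is
identified by fixing the geometric mean of mu over a constraint set of
well-expressed genes to an empirical constant mu0, implemented through a
correlated prior on log(mu): a point mass determines one *reference* gene
given all others, and the reference is redrawn uniformly at every iteration
so that no single gene's posterior is distorted. Technical noise is
identified through replication: batch-specific parameters theta_k absorb
spurious between-batch variability, which requires >= 2 batches.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy.special import gammaln
from scipy.stats import geninvgauss

from ._mcmc import ADAPT_EVERY, AdaptiveProposal, draw_beta_sigma2, metropolis_mask
from .chain import PosteriorChain
from .data import ExpressionDataset
from .params import HyperParams
from .regression import (
    RegressionConfig,
    build_design_matrix,
    refresh_locations,
    set_locations,
)
from .sampler_spikes import _mom_delta

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Identifiability helpers
# ---------------------------------------------------------------------------

def size_factors(counts: np.ndarray) -> np.ndarray:
    """Library-size factors: cell totals scaled to geometric mean 1."""
    totals = counts.sum(axis=0).astype(float)
    if (totals <= 0).any():
        raise ValueError("every cell must have a positive total count")
    return totals / np.exp(np.mean(np.log(totals)))


def compute_mu0(
    ds_or_counts, gene_mask: np.ndarray | None = None
) -> float:
    """Empirical anchor mu0: geometric mean of normalized per-gene means.

    Genes with zero total counts are always excluded (their empirical mean
    is 0 and the geometric mean would be ill-defined). ``gene_mask``
    restricts the computation further, e.g. to the constraint set.
    """
    counts = (
        ds_or_counts.counts
        if isinstance(ds_or_counts, ExpressionDataset)
        else np.asarray(ds_or_counts)
    )
    sf = size_factors(counts)
    means = (counts / sf[None, :]).mean(axis=1)
    keep = counts.sum(axis=1) > 0
    if gene_mask is not None:
        keep &= np.asarray(gene_mask, dtype=bool)
    if not keep.any():
        raise ValueError("no genes with positive counts to anchor mu0")
    return float(np.exp(np.mean(np.log(means[keep]))))


def constraint_set(ds_or_counts) -> np.ndarray:
    """Genes participating in the geometric-mean constraint.

    A gene is included iff its average count across all cells is >= 1
    (boundary inclusive); lowly expressed genes get an unconstrained
    independent log-Normal prior instead.
    """
    counts = (
        ds_or_counts.counts
        if isinstance(ds_or_counts, ExpressionDataset)
        else np.asarray(ds_or_counts)
    )
    mask = counts.mean(axis=1) >= 1.0
    if not mask.any():
        raise ValueError("constraint set is empty: no gene averages >= 1 count")
    return mask


def reference_value(mu_others: np.ndarray, mu0: float, q_c: int) -> float:
    """Deterministic reference-gene mean from the point-mass conditional.

    log(mu_r) = q_c log(mu0) - sum over the other constraint-set genes.
    """
    mu_others = np.asarray(mu_others, dtype=float)
    log_mu_r = q_c * np.log(mu0) - np.log(mu_others).sum()
    if abs(log_mu_r) > 700:
        raise OverflowError("reference-gene log mean overflows")
    return float(np.exp(log_mu_r))


def conditional_prior_mu(
    i: int,
    mu: np.ndarray,
    mu0: float,
    a_mu2: float,
    constrained: np.ndarray,
    reference: int,
) -> tuple[float, float]:
    """Conditional prior of log(mu_i) given all others except the reference.

    Returns (mean, variance): mean is half of (q_c log mu0 minus the sum of
    the other non-reference constrained log means); the variance is a_mu2/2
    regardless of the values.
    """
    if i == reference:
        raise ValueError("the reference gene has a point-mass conditional")
    if not constrained[i]:
        raise ValueError("gene is not in the constraint set")
    q_c = int(constrained.sum())
    idx = np.flatnonzero(constrained)
    others = idx[(idx != i) & (idx != reference)]
    mean = 0.5 * (q_c * np.log(mu0) - np.log(mu[others]).sum())
    return float(mean), a_mu2 / 2.0


def pick_reference(rng: np.random.Generator, constrained: np.ndarray) -> int:
    """Uniform draw of the reference gene from the constraint set."""
    idx = np.flatnonzero(constrained)
    if idx.size == 0:
        raise ValueError("constraint set is empty")
    return int(idx[rng.integers(idx.size)])


# ---------------------------------------------------------------------------
# Sampler
# ---------------------------------------------------------------------------

class NoSpikesSampler:
    """Chain state and block updates for the no-spikes model.

    Only biological genes enter the fit (spike-in rows, if present in the
    dataset, are dropped). The geometric mean of constrained mu is restored
    exactly (recomputing the reference value) after every mu sweep, so the
    identifiability restriction holds to machine precision in every stored
    draw.
    """

    def __init__(
        self,
        ds: ExpressionDataset,
        hyper: HyperParams | None = None,
        cfg: RegressionConfig | None = None,
        regression: bool = True,
        seed: int = 0,
    ) -> None:
        self.hp = hyper or HyperParams()
        self.regression = regression
        self.rng = np.random.default_rng(seed)
        self.seed = seed

        self.gene_ids = ds.gene_ids[~ds.is_spike]
        self.x = ds.bio_counts.astype(float)
        self.q, self.n = self.x.shape
        batches, self.batch_of_cell = np.unique(ds.batch, return_inverse=True)
        self.batches = batches
        self.K = len(batches)
        if self.K < 2:
            warnings.warn(
                "single batch: technical and biological variability cannot "
                "be separated without replication",
                RuntimeWarning,
            )
        self.nk = np.bincount(self.batch_of_cell, minlength=self.K).astype(float)

        self.xsum_gene = self.x.sum(axis=1)
        self.colsum = self.x.sum(axis=0)

        self.constrained = constraint_set(self.x)
        self.mu0 = compute_mu0(self.x, gene_mask=self.constrained)
        self.q_c = int(self.constrained.sum())

        sf = size_factors(self.x)
        mu = np.maximum((self.x / sf[None, :]).mean(axis=1), 1e-3)
        logmu = np.log(mu)
        # project the constrained genes onto the identifiability manifold
        shift = np.log(self.mu0) - logmu[self.constrained].mean()
        logmu[self.constrained] += shift
        self.mu = np.exp(logmu)
        self.delta = _mom_delta(self.x)
        self.lam = np.ones(self.q)
        self.s = np.ones(self.n)
        self.nu = np.ones(self.n)
        self.theta = np.full(self.K, 0.5)
        self.cfg = cfg or RegressionConfig(eta=self.hp.eta)
        if self.regression and not self.cfg.initialized():
            set_locations(self.cfg, np.log(self.mu))
        self.beta = np.zeros(self.cfg.n_coef)
        self.sigma2 = 1.0
        self.reference = pick_reference(self.rng, self.constrained)

        self._T = self._t_matrix(self.mu, self.delta)
        self._lg = gammaln(self.x + (1.0 / self.delta)[:, None]).sum(axis=1)

        s0 = np.log(0.4)
        self.prop_mu = AdaptiveProposal(np.full(self.q, s0))
        self.prop_delta = AdaptiveProposal(np.full(self.q, s0))
        self.prop_nu = AdaptiveProposal(np.full(self.n, s0))
        self.prop_theta = AdaptiveProposal(np.full(self.K, np.log(0.2)))

    @property
    def theta_cell(self) -> np.ndarray:
        return self.theta[self.batch_of_cell]

    def _t_matrix(self, mu: np.ndarray, delta: np.ndarray) -> np.ndarray:
        inv_d = (1.0 / delta)[:, None]
        return (self.x + inv_d) * np.log(mu[:, None] * self.nu[None, :] + inv_d)

    def _t_row(self, i: int, mu_i: float) -> np.ndarray:
        inv_d = 1.0 / self.delta[i]
        return (self.x[i] + inv_d) * np.log(mu_i * self.nu + inv_d)

    def refresh_caches(self) -> None:
        """Recompute cached likelihood terms after a manual state change."""
        self._T = self._t_matrix(self.mu, self.delta)
        self._lg = gammaln(self.x + (1.0 / self.delta)[:, None]).sum(axis=1)

    def trend(self, logmu: np.ndarray) -> np.ndarray:
        return build_design_matrix(np.atleast_1d(logmu), self.cfg) @ self.beta

    def _coupling(self, logmu, logdelta, lam) -> np.ndarray:
        if not self.regression:
            return np.zeros_like(np.atleast_1d(logmu))
        dev = np.atleast_1d(logdelta) - self.trend(logmu)
        return -np.atleast_1d(lam) * dev * dev / (2.0 * self.sigma2)

    # -- mu updates -----------------------------------------------------
    def _log_alpha_mu_pair(self, i: int, y_new: float) -> float:
        """Acceptance log-ratio for a constrained gene i (reference moves too)."""
        r = self.reference
        y_i, y_r = np.log(self.mu[i]), np.log(self.mu[r])
        y_r_new = y_r + (y_i - y_new)  # preserves the constrained log-sum
        mu_i_new, mu_r_new = np.exp(y_new), np.exp(y_r_new)

        lik_cur = (
            self.xsum_gene[i] * y_i
            - self._T[i].sum()
            + self.xsum_gene[r] * y_r
            - self._T[r].sum()
        )
        row_i = self._t_row(i, mu_i_new)
        row_r = self._t_row(r, mu_r_new)
        lik_new = (
            self.xsum_gene[i] * y_new
            - row_i.sum()
            + self.xsum_gene[r] * y_r_new
            - row_r.sum()
        )
        m_i = 0.5 * (y_i + y_r)  # Proposition-3 mean under the exact constraint
        prior = ((y_i - m_i) ** 2 - (y_new - m_i) ** 2) / self.hp.a_mu2

        coup = 0.0
        if self.regression:
            ld = np.log(self.delta[[i, r]])
            lam = self.lam[[i, r]]
            coup = float(
                self._coupling(np.array([y_new, y_r_new]), ld, lam).sum()
                - self._coupling(np.array([y_i, y_r]), ld, lam).sum()
            )
        self._pending = (row_i, row_r, mu_i_new, mu_r_new)
        return float(lik_new - lik_cur) + prior + coup

    def _log_alpha_mu_unconstrained(
        self, y_new: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Acceptance log-ratios for the unconstrained genes (vectorized)."""
        un = ~self.constrained
        y = np.log(self.mu[un])
        mu_new = np.exp(y_new)
        inv_d = (1.0 / self.delta[un])[:, None]
        T_new = (self.x[un] + inv_d) * np.log(
            mu_new[:, None] * self.nu[None, :] + inv_d
        )
        ld = np.log(self.delta[un])

        def kernel(y_, Tsum):
            base = self.xsum_gene[un] * y_ - Tsum - y_ * y_ / (2 * self.hp.a_mu2)
            if self.regression:
                base = base + self._coupling(y_, ld, self.lam[un])
            return base

        log_alpha = kernel(y_new, T_new.sum(axis=1)) - kernel(
            y, self._T[un].sum(axis=1)
        )
        return log_alpha, T_new

    def _apply_mu_pair(self, i: int) -> None:
        row_i, row_r, mu_i_new, mu_r_new = self._pending
        self.mu[i] = mu_i_new
        self.mu[self.reference] = mu_r_new
        self._T[i] = row_i
        self._T[self.reference] = row_r

    def update_mu(self) -> None:
        """One mu sweep: constrained genes sequentially, unconstrained jointly."""
        r = self.reference
        acc_flags = np.zeros(self.q, dtype=bool)
        for i in np.flatnonzero(self.constrained):
            if i == r:
                continue
            y_new = np.log(self.mu[i]) + float(self.prop_mu.scale[i]) * (
                self.rng.standard_normal()
            )
            la = self._log_alpha_mu_pair(i, y_new)
            if np.log(self.rng.random()) < la:
                self._apply_mu_pair(i)
                acc_flags[i] = True

        un = ~self.constrained
        if un.any():
            y_new = np.log(self.mu[un]) + self.prop_mu.scale[un] * (
                self.rng.standard_normal(un.sum())
            )
            log_alpha, T_new = self._log_alpha_mu_unconstrained(y_new)
            mu_new = np.exp(y_new)
            acc = metropolis_mask(self.rng, log_alpha)
            mu_un = self.mu[un]
            mu_un[acc] = mu_new[acc]
            self.mu[un] = mu_un
            Tu = self._T[un]
            Tu[acc] = T_new[acc]
            self._T[un] = Tu
            acc_flags[np.flatnonzero(un)[acc]] = True

        # restore the constraint exactly (guards against float drift)
        idx = np.flatnonzero(self.constrained)
        others = idx[idx != r]
        self.mu[r] = reference_value(self.mu[others], self.mu0, self.q_c)
        self._T[r] = self._t_row(r, self.mu[r])
        self.prop_mu.record_indicator(acc_flags)

    # -- remaining blocks ------------------------------------------------
    def update_delta(self, proposal: np.ndarray | None = None):
        u = np.log(self.delta)
        if proposal is None:
            u_new = u + self.prop_delta.scale * self.rng.standard_normal(self.q)
        else:
            u_new = np.log(np.asarray(proposal, dtype=float))
        d_new = np.exp(u_new)
        inv_new = 1.0 / d_new
        T_new = self._t_matrix(self.mu, d_new)
        lg_new = gammaln(self.x + inv_new[:, None]).sum(axis=1)
        y = np.log(self.mu)

        def kernel(u_, d_, Tsum, lg_):
            inv = 1.0 / d_
            base = lg_ - self.n * gammaln(inv) - self.n * inv * u_ - Tsum
            if self.regression:
                return base + self._coupling(y, u_, self.lam)
            return base - u_ * u_ / (2.0 * self.hp.a_delta2)

        log_alpha = kernel(u_new, d_new, T_new.sum(axis=1), lg_new) - kernel(
            u, self.delta, self._T.sum(axis=1), self._lg
        )
        acc = metropolis_mask(self.rng, log_alpha)
        self.delta = np.where(acc, d_new, self.delta)
        self._T[acc] = T_new[acc]
        self._lg = np.where(acc, lg_new, self._lg)
        self.prop_delta.record_indicator(acc)
        return acc, log_alpha

    def update_lambda(self) -> None:
        dev = np.log(self.delta) - self.trend(np.log(self.mu))
        shape = (self.hp.eta + 1.0) / 2.0
        rate = (self.hp.eta + dev * dev / self.sigma2) / 2.0
        self.lam = self.rng.gamma(shape, 1.0 / rate)

    def update_beta_sigma2(self) -> None:
        X = build_design_matrix(np.log(self.mu), self.cfg)
        self.beta, self.sigma2 = draw_beta_sigma2(
            X, np.log(self.delta), self.lam, self.beta, self.hp, self.rng
        )

    def update_s(self) -> None:
        th = self.theta_cell
        p = self.hp.a_s - 1.0 / th
        psi = 2.0 * self.hp.b_s
        chi = 2.0 * self.nu / th
        b = np.sqrt(chi * psi)
        z = geninvgauss.rvs(p, np.maximum(b, 1e-10), random_state=self.rng)
        self.s = np.sqrt(np.maximum(chi, 1e-300) / psi) * z

    def update_nu(self, proposal: np.ndarray | None = None):
        v = np.log(self.nu)
        if proposal is None:
            v_new = v + self.prop_nu.scale * self.rng.standard_normal(self.n)
        else:
            v_new = np.log(np.asarray(proposal, dtype=float))
        nu_new = np.exp(v_new)
        inv_d = (1.0 / self.delta)[:, None]
        T_new = (self.x + inv_d) * np.log(
            self.mu[:, None] * nu_new[None, :] + inv_d
        )
        th = self.theta_cell
        coef = self.colsum + 1.0 / th

        def kernel(v_, nu_, Tcol):
            return coef * v_ - Tcol - nu_ / (self.s * th)

        log_alpha = kernel(v_new, nu_new, T_new.sum(axis=0)) - kernel(
            v, self.nu, self._T.sum(axis=0)
        )
        acc = metropolis_mask(self.rng, log_alpha)
        self.nu = np.where(acc, nu_new, self.nu)
        self._T[:, acc] = T_new[:, acc]
        self.prop_nu.record_indicator(acc)
        return acc, log_alpha

    def update_theta(self, proposal: np.ndarray | None = None):
        acc_flags = np.zeros(self.K, dtype=bool)
        log_alphas = np.empty(self.K)
        for k in range(self.K):
            cells = self.batch_of_cell == k
            s_k, nu_k = self.s[cells], self.nu[cells]
            t = np.log(self.theta[k])
            if proposal is None:
                t_new = t + float(self.prop_theta.scale[k]) * (
                    self.rng.standard_normal()
                )
            else:
                t_new = float(np.log(proposal[k]))

            def kernel(t_):
                th = np.exp(t_)
                inv = 1.0 / th
                return (
                    self.hp.a_theta * t_
                    - self.hp.b_theta * th
                    + np.sum(
                        -inv * np.log(s_k * th)
                        - gammaln(inv)
                        + (inv - 1.0) * np.log(nu_k)
                        - nu_k / (s_k * th)
                    )
                )

            log_alphas[k] = kernel(t_new) - kernel(t)
            if np.log(self.rng.random()) < log_alphas[k]:
                self.theta[k] = float(np.exp(t_new))
                acc_flags[k] = True
        self.prop_theta.record_indicator(acc_flags)
        return acc_flags, log_alphas

    def sweep(self) -> None:
        self.reference = pick_reference(self.rng, self.constrained)
        self.update_mu()
        self.update_delta()
        if self.regression:
            self.update_lambda()
            self.update_beta_sigma2()
        self.update_s()
        self.update_nu()
        self.update_theta()

    def _adapt_all(self) -> None:
        for p in (self.prop_mu, self.prop_delta, self.prop_nu, self.prop_theta):
            p.adapt()


def run_chain_nospikes(
    ds: ExpressionDataset,
    hyper: HyperParams | None = None,
    cfg: RegressionConfig | None = None,
    n_iter: int = 20000,
    burn_in: int = 10000,
    thin: int = 10,
    seed: int = 0,
    regression: bool = True,
) -> PosteriorChain:
    """Run the no-spikes chain and return thinned post-burn-in draws."""
    if n_iter <= burn_in:
        raise ValueError("n_iter must exceed burn_in")
    if thin < 1 or (n_iter - burn_in) % thin != 0:
        raise ValueError("(n_iter - burn_in) must be a positive multiple of thin")

    smp = NoSpikesSampler(ds, hyper, cfg, regression=regression, seed=seed)
    n_stored = (n_iter - burn_in) // thin
    store = {
        "mu": np.empty((n_stored, smp.q)),
        "delta": np.empty((n_stored, smp.q)),
        "epsilon": np.empty((n_stored, smp.q)),
        "lam": np.empty((n_stored, smp.q)),
        "s": np.empty((n_stored, smp.n)),
        "nu": np.empty((n_stored, smp.n)),
        "theta": np.empty((n_stored, smp.K)),
        "beta": np.empty((n_stored, smp.cfg.n_coef)),
        "sigma2": np.empty((n_stored, 1)),
        "reference": np.empty((n_stored, 1), dtype=np.int64),
    }

    k = 0
    for it in range(n_iter):
        if smp.regression:
            refresh_locations(smp.cfg, np.log(smp.mu), it, burn_in)
        smp.sweep()
        if it < burn_in and (it + 1) % ADAPT_EVERY == 0:
            smp._adapt_all()
        if it >= burn_in and (it - burn_in) % thin == 0:
            store["mu"][k] = smp.mu
            store["delta"][k] = smp.delta
            store["lam"][k] = smp.lam
            store["s"][k] = smp.s
            store["nu"][k] = smp.nu
            store["theta"][k] = smp.theta
            store["beta"][k] = smp.beta
            store["sigma2"][k, 0] = smp.sigma2
            store["reference"][k, 0] = smp.reference
            store["epsilon"][k] = (
                np.log(smp.delta) - smp.trend(np.log(smp.mu))
                if regression
                else np.nan
            )
            k += 1
        if (it + 1) % 1000 == 0:
            logger.info(
                "iter=%d accept_mu=%.2f accept_delta=%.2f",
                it + 1,
                smp.prop_mu.mean_rate(),
                smp.prop_delta.mean_rate(),
            )

    variant = "nospikes-regression" if regression else "nospikes-nonregression"
    if not regression:
        for name in ("epsilon", "lam", "beta", "sigma2"):
            del store[name]
    return PosteriorChain(
        draws=store,
        n_iter=n_iter,
        burn_in=burn_in,
        thin=thin,
        seed=seed,
        model_variant=variant,
        gene_ids=smp.gene_ids,
        extra={
            "mu0": np.array(smp.mu0),
            "constrained": smp.constrained.astype(np.int8),
            **(
                {
                    "grbf_locations": smp.cfg.locations.copy(),
                    "grbf_scales": smp.cfg.scales.copy(),
                }
                if regression
                else {}
            ),
        },
    )
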