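"""Adaptive Metropolis-within-Gibbs sampler for the spike-in (vertical) model.

Biological counts are Negative Binomial with size 1/delta_i and mean
phi_j nu_j mu_i; spike-in counts are Poisson with mean nu_j mu_i at known
input mu_i; nu_j ~ Gamma(1/theta, 1/(s_j theta)) carries technical noise.
Under the regression variant, (mu_i, delta_i) are coupled through the GRBF
trend prior log(delta_i) ~ t_eta(f(mu_i), sigma2), represented by the
Normal scale-mixture augmentation lambda_i ~ Gamma(eta/2, eta/2).

One sweep updates, in order: mu, delta, lambda, (beta, sigma2), phi, s, nu,
theta. mu, delta and nu are element-wise Gaussian random walks on the log
scale (their full conditionals are independent across genes/cells given the
rest); phi is a joint Dirichlet-perturbation move on the simplex
{sum phi_j = n}; s_j is drawn exactly from its generalized-inverse-Gaussian
full conditional; lambda, beta and sigma2 are conjugate Gibbs draws.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.special import gammaln
from scipy.stats import geninvgauss

from ._mcmc import ADAPT_EVERY, AdaptiveProposal, draw_beta_sigma2, metropolis_mask
from .chain import PosteriorChain
from .data import ExpressionDataset
from .params import CellState, GeneState, HyperParams
from .regression import (
    RegressionConfig,
    RegressionState,
    build_design_matrix,
    refresh_locations,
    set_locations,
)

logger = logging.getLogger(__name__)

__all__ = ["SpikesSampler", "run_chain", "marginal_loglik"]

# re-export: the integrated likelihood lives with the other model densities
from .likelihood import marginal_loglik  # noqa: E402,F401


def _mom_delta(x: np.ndarray) -> np.ndarray:
    """Method-of-moments over-dispersion: (var - mean)/mean^2, floored."""
    m = x.mean(axis=1)
    v = x.var(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (v - m) / np.maximum(m, 1e-12) ** 2
    return np.clip(np.nan_to_num(d, nan=1e-3), 1e-3, None)


class SpikesSampler:
    """Holds the data, hyper-parameters and current state of one chain."""

    def __init__(
        self,
        ds: ExpressionDataset,
        hyper: HyperParams | None = None,
        cfg: RegressionConfig | None = None,
        regression: bool = True,
        seed: int = 0,
    ) -> None:
        ds.require_spikes()
        self.ds = ds
        self.hp = hyper or HyperParams()
        self.regression = regression
        self.rng = np.random.default_rng(seed)
        self.seed = seed

        self.x = ds.bio_counts.astype(float)          # q0 x n
        self.q0, self.n = self.x.shape
        self.xsum_gene = self.x.sum(axis=1)
        self.colsum_bio = self.x.sum(axis=0)
        self.spike_colsum = ds.spike_counts.sum(axis=0).astype(float)
        self.mu_spike = np.asarray(ds.spike_input, dtype=float)
        self.sum_mu_spike = float(self.mu_spike.sum())

        # initial state from empirical moments
        totals = np.maximum(self.colsum_bio, 1.0)
        self.phi = totals / totals.mean()             # sums to n
        self.s = np.ones(self.n)
        self.nu = np.ones(self.n)
        self.theta = 0.5
        self.mu = np.maximum((self.x / self.phi[None, :]).mean(axis=1), 1e-3)
        self.delta = _mom_delta(self.x)
        self.lam = np.ones(self.q0)
        self.cfg = cfg or RegressionConfig(eta=self.hp.eta)
        if self.regression and not self.cfg.initialized():
            set_locations(self.cfg, np.log(self.mu))
        self.beta = np.zeros(self.cfg.n_coef)
        self.sigma2 = 1.0

        # cached per-entry term (x + 1/delta) * log(phi nu mu + 1/delta)
        self._T = self._t_matrix(self.mu, self.delta)
        self._lg = self._lgamma_vec(self.delta)

        s0 = np.log(0.4)
        self.prop_mu = AdaptiveProposal(np.full(self.q0, s0))
        self.prop_delta = AdaptiveProposal(np.full(self.q0, s0))
        self.prop_nu = AdaptiveProposal(np.full(self.n, s0))
        self.prop_theta = AdaptiveProposal(np.array([np.log(0.2)]))
        self.prop_phi = AdaptiveProposal(np.array([0.0]))  # scales kappa
        self._phi_kappa0 = 50.0 * self.n

    # -- cached likelihood pieces --------------------------------------
    def _t_matrix(self, mu: np.ndarray, delta: np.ndarray) -> np.ndarray:
        inv_d = (1.0 / delta)[:, None]
        cf = (self.phi * self.nu)[None, :]
        return (self.x + inv_d) * np.log(mu[:, None] * cf + inv_d)

    def _lgamma_vec(self, delta: np.ndarray) -> np.ndarray:
        return gammaln(self.x + (1.0 / delta)[:, None]).sum(axis=1)

    def refresh_caches(self) -> None:
        """Recompute cached likelihood terms after a manual state change."""
        self._T = self._t_matrix(self.mu, self.delta)
        self._lg = self._lgamma_vec(self.delta)

    def trend(self, logmu: np.ndarray) -> np.ndarray:
        return build_design_matrix(logmu, self.cfg) @ self.beta

    def _coupling(self, logmu: np.ndarray, logdelta: np.ndarray) -> np.ndarray:
        """Regression-prior term tying log(delta) to the trend at mu."""
        if not self.regression:
            return np.zeros_like(logmu)
        dev = logdelta - self.trend(logmu)
        return -self.lam * dev * dev / (2.0 * self.sigma2)

    # -- block updates --------------------------------------------------
    def update_mu(self, proposal: np.ndarray | None = None):
        """Element-wise MH on log(mu_i) for biological genes."""
        y = np.log(self.mu)
        if proposal is None:
            y_new = y + self.prop_mu.scale * self.rng.standard_normal(self.q0)
        else:
            y_new = np.log(np.asarray(proposal, dtype=float))
        mu_new = np.exp(y_new)
        T_new = self._t_matrix(mu_new, self.delta)
        logdelta = np.log(self.delta)

        cur = (
            self.xsum_gene * y
            - self._T.sum(axis=1)
            - y * y / (2.0 * self.hp.a_mu2)
            + self._coupling(y, logdelta)
        )
        new = (
            self.xsum_gene * y_new
            - T_new.sum(axis=1)
            - y_new * y_new / (2.0 * self.hp.a_mu2)
            + self._coupling(y_new, logdelta)
        )
        log_alpha = new - cur
        acc = metropolis_mask(self.rng, log_alpha)
        self.mu = np.where(acc, mu_new, self.mu)
        self._T[acc] = T_new[acc]
        self.prop_mu.record_indicator(acc)
        return acc, log_alpha

    def update_delta(self, proposal: np.ndarray | None = None):
        """Element-wise MH on log(delta_i)."""
        u = np.log(self.delta)
        if proposal is None:
            u_new = u + self.prop_delta.scale * self.rng.standard_normal(self.q0)
        else:
            u_new = np.log(np.asarray(proposal, dtype=float))
        d_new = np.exp(u_new)
        T_new = self._t_matrix(self.mu, d_new)
        lg_new = self._lgamma_vec(d_new)
        y = np.log(self.mu)

        def kernel(u_, d_, T_, lg_):
            inv = 1.0 / d_
            base = lg_ - self.n * gammaln(inv) - self.n * inv * u_ - T_.sum(axis=1)
            if self.regression:
                return base + self._coupling(y, u_)
            return base - u_ * u_ / (2.0 * self.hp.a_delta2)

        log_alpha = kernel(u_new, d_new, T_new, lg_new) - kernel(
            u, self.delta, self._T, self._lg
        )
        acc = metropolis_mask(self.rng, log_alpha)
        self.delta = np.where(acc, d_new, self.delta)
        self._T[acc] = T_new[acc]
        self._lg = np.where(acc, lg_new, self._lg)
        self.prop_delta.record_indicator(acc)
        return acc, log_alpha

    def update_lambda(self) -> np.ndarray:
        """Conjugate Gibbs draw of the Student-t augmentation variables."""
        if self.sigma2 <= 0:
            raise RuntimeError("sigma2 must be positive before lambda update")
        dev = np.log(self.delta) - self.trend(np.log(self.mu))
        shape = (self.hp.eta + 1.0) / 2.0
        rate = (self.hp.eta + dev * dev / self.sigma2) / 2.0
        self.lam = self.rng.gamma(shape, 1.0 / rate)
        return self.lam

    def update_beta_sigma2(self):
        """Conjugate draws of the regression block (sigma2 | beta, then beta)."""
        X = build_design_matrix(np.log(self.mu), self.cfg)
        self.beta, self.sigma2 = draw_beta_sigma2(
            X, np.log(self.delta), self.lam, self.beta, self.hp, self.rng
        )
        return self.beta, self.sigma2

    def update_phi(self, proposal: np.ndarray | None = None):
        """Joint Dirichlet-perturbation MH on the mRNA-content simplex."""
        kappa = self._phi_kappa0 / float(self.prop_phi.scale[0])
        alpha = kappa * self.phi / self.n
        if proposal is None:
            d = self.rng.dirichlet(alpha)
            if (d <= 0).any():
                self.prop_phi.record_indicator([False])
                return False, -np.inf
            phi_new = self.n * d
        else:
            phi_new = np.asarray(proposal, dtype=float)
        alpha_rev = kappa * phi_new / self.n

        T_new = self._t_with_factors(phi_new * self.nu)
        gain = (
            (self.colsum_bio + self.hp.a_phi - 1.0)
            @ (np.log(phi_new) - np.log(self.phi))
            - T_new.sum()
            + self._T.sum()
        )
        log_q_fwd = self._dirichlet_logpdf(phi_new / self.n, alpha)
        log_q_rev = self._dirichlet_logpdf(self.phi / self.n, alpha_rev)
        log_alpha = gain + log_q_rev - log_q_fwd
        acc = bool(np.log(self.rng.random()) < log_alpha)
        if acc:
            self.phi = phi_new
            self._T = T_new
        self.prop_phi.record_indicator([acc])
        return acc, log_alpha

    @staticmethod
    def _dirichlet_logpdf(x: np.ndarray, alpha: np.ndarray) -> float:
        return float(
            gammaln(alpha.sum()) - gammaln(alpha).sum() + ((alpha - 1) * np.log(x)).sum()
        )

    def _t_with_factors(self, cell_factors: np.ndarray) -> np.ndarray:
        inv_d = (1.0 / self.delta)[:, None]
        return (self.x + inv_d) * np.log(
            self.mu[:, None] * cell_factors[None, :] + inv_d
        )

    def update_s(self) -> np.ndarray:
        """Exact GIG draw: pi(s_j|.) ~ s^{a_s - 1/theta - 1} e^{-nu/(s theta) - b_s s}."""
        p = self.hp.a_s - 1.0 / self.theta
        psi = 2.0 * self.hp.b_s
        chi = 2.0 * self.nu / self.theta
        b = np.sqrt(chi * psi)
        if np.any(b < 1e-10):  # degenerate GIG: fall back to the Gamma limit
            self.s = np.where(
                b < 1e-10,
                self.rng.gamma(max(p, 1e-3), 2.0 / psi, size=self.n),
                self.s,
            )
            ok = b >= 1e-10
            if ok.any():
                z = geninvgauss.rvs(p, b[ok], random_state=self.rng)
                self.s[ok] = np.sqrt(chi[ok] / psi) * z
            return self.s
        z = geninvgauss.rvs(p, b, random_state=self.rng)
        self.s = np.sqrt(chi / psi) * z
        return self.s

    def update_nu(self, proposal: np.ndarray | None = None):
        """Element-wise MH on log(nu_j)."""
        v = np.log(self.nu)
        if proposal is None:
            v_new = v + self.prop_nu.scale * self.rng.standard_normal(self.n)
        else:
            v_new = np.log(np.asarray(proposal, dtype=float))
        nu_new = np.exp(v_new)
        T_new = self._t_with_factors(self.phi * nu_new)

        coef = self.colsum_bio + self.spike_colsum + 1.0 / self.theta

        def kernel(v_, nu_, Tcol):
            return (
                coef * v_
                - Tcol
                - nu_ * (self.sum_mu_spike + 1.0 / (self.s * self.theta))
            )

        log_alpha = kernel(v_new, nu_new, T_new.sum(axis=0)) - kernel(
            v, self.nu, self._T.sum(axis=0)
        )
        acc = metropolis_mask(self.rng, log_alpha)
        self.nu = np.where(acc, nu_new, self.nu)
        self._T[:, acc] = T_new[:, acc]
        self.prop_nu.record_indicator(acc)
        return acc, log_alpha

    def update_theta(self, proposal: float | None = None):
        """MH on log(theta)."""
        t = np.log(self.theta)
        if proposal is None:
            t_new = t + float(self.prop_theta.scale[0]) * self.rng.standard_normal()
        else:
            t_new = float(np.log(proposal))

        def kernel(t_):
            th = np.exp(t_)
            inv = 1.0 / th
            return (
                self.hp.a_theta * t_
                - self.hp.b_theta * th
                + np.sum(
                    -inv * np.log(self.s * th)
                    - gammaln(inv)
                    + (inv - 1.0) * np.log(self.nu)
                    - self.nu / (self.s * th)
                )
            )

        log_alpha = float(kernel(t_new) - kernel(t))
        acc = bool(np.log(self.rng.random()) < log_alpha)
        if acc:
            self.theta = float(np.exp(t_new))
        self.prop_theta.record_indicator([acc])
        return acc, log_alpha

    # -- chain driver ----------------------------------------------------
    def sweep(self) -> None:
        self.update_mu()
        self.update_delta()
        if self.regression:
            self.update_lambda()
            self.update_beta_sigma2()
        self.update_phi()
        self.update_s()
        self.update_nu()
        self.update_theta()

    def _adapt_all(self) -> None:
        for p in (self.prop_mu, self.prop_delta, self.prop_nu,
                  self.prop_theta, self.prop_phi):
            p.adapt()

    def gene_state(self) -> GeneState:
        eps = (
            np.log(self.delta) - self.trend(np.log(self.mu))
            if self.regression
            else np.full(self.q0, np.nan)
        )
        return GeneState(self.mu, self.delta, eps, self.lam, self.mu_spike)

    def cell_state(self) -> CellState:
        return CellState(self.s, self.nu, np.atleast_1d(self.theta), self.phi)

    def reg_state(self) -> RegressionState:
        return RegressionState(self.beta, self.sigma2)


def run_chain(
    ds: ExpressionDataset,
    hyper: HyperParams | None = None,
    cfg: RegressionConfig | None = None,
    n_iter: int = 20000,
    burn_in: int = 10000,
    thin: int = 10,
    seed: int = 0,
    regression: bool = True,
) -> PosteriorChain:
    """Run the spikes-model chain and return thinned post-burn-in draws."""
    if n_iter <= burn_in:
        raise ValueError("n_iter must exceed burn_in")
    if thin < 1 or (n_iter - burn_in) % thin != 0:
        raise ValueError("(n_iter - burn_in) must be a positive multiple of thin")

    smp = SpikesSampler(ds, hyper, cfg, regression=regression, seed=seed)
    n_stored = (n_iter - burn_in) // thin
    q0, n = smp.q0, smp.n
    store = {
        "mu": np.empty((n_stored, q0)),
        "delta": np.empty((n_stored, q0)),
        "epsilon": np.empty((n_stored, q0)),
        "lam": np.empty((n_stored, q0)),
        "phi": np.empty((n_stored, n)),
        "s": np.empty((n_stored, n)),
        "nu": np.empty((n_stored, n)),
        "theta": np.empty((n_stored, 1)),
        "beta": np.empty((n_stored, smp.cfg.n_coef)),
        "sigma2": np.empty((n_stored, 1)),
    }

    k = 0
    for it in range(n_iter):
        if smp.regression:
            old_range = smp.cfg.range
            refresh_locations(smp.cfg, np.log(smp.mu), it, burn_in)
            if smp.cfg.range != old_range:
                # kernel locations moved: cached T unaffected (it only
                # depends on counts and states), only f(mu) changes
                pass
        smp.sweep()
        if it < burn_in and (it + 1) % ADAPT_EVERY == 0:
            smp._adapt_all()
        if it >= burn_in and (it - burn_in) % thin == 0:
            if (smp.mu <= 0).any() or (smp.delta <= 0).any() or smp.theta <= 0:
                raise RuntimeError(
                    f"positivity invariant violated at iteration {it}: "
                    f"state dump mu={smp.mu}, delta={smp.delta}, theta={smp.theta}"
                )
            store["mu"][k] = smp.mu
            store["delta"][k] = smp.delta
            store["lam"][k] = smp.lam
            store["phi"][k] = smp.phi
            store["s"][k] = smp.s
            store["nu"][k] = smp.nu
            store["theta"][k, 0] = smp.theta
            store["beta"][k] = smp.beta
            store["sigma2"][k, 0] = smp.sigma2
            store["epsilon"][k] = (
                np.log(smp.delta) - smp.trend(np.log(smp.mu))
                if regression
                else np.nan
            )
            k += 1
        if (it + 1) % 1000 == 0:
            logger.info(
                "iter=%d accept_mu=%.2f accept_delta=%.2f accept_nu=%.2f",
                it + 1,
                smp.prop_mu.mean_rate(),
                smp.prop_delta.mean_rate(),
                smp.prop_nu.mean_rate(),
            )

    variant = "spikes-regression" if regression else "spikes-nonregression"
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
        gene_ids=ds.gene_ids[~ds.is_spike],
        extra=(
            {
                "grbf_locations": smp.cfg.locations.copy(),
                "grbf_scales": smp.cfg.scales.copy(),
            }
            if regression
            else {}
        ),
    )
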