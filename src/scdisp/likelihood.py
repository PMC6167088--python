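"""Model log-densities: marginal likelihoods and full joint posteriors.

The gene-level Gamma random effect rho_ij is integrated out analytically, so
biological counts follow a Negative Binomial with size 1/delta_i and mean
phi_j nu_j mu_i (spikes model) or nu_jk mu_i (no-spikes model), while
spike-in counts are Poisson with mean nu_j mu_i.

The ``log_joint_*`` functions evaluate the complete unnormalized posterior
density term by term, with every parameter-dependent normalizing factor
included. They are deliberately written as direct transliterations of the
model (naive loops over simple scalar terms are acceptable here): the
samplers use their own block-wise targets, and these functions serve as the
independent reference when validating Metropolis acceptance ratios.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

from .data import ExpressionDataset
from .params import CellState, GeneState, HyperParams
from .regression import RegressionConfig, RegressionState, predict_trend


def nb_logpmf(x: np.ndarray, size: np.ndarray, mean: np.ndarray) -> np.ndarray:
    """Negative Binomial log pmf with size r and mean m (p = r/(m+r))."""
    x = np.asarray(x, dtype=float)
    r, m = np.broadcast_arrays(size, mean)
    return (
        gammaln(x + r)
        - gammaln(r)
        - gammaln(x + 1.0)
        + r * (np.log(r) - np.log(m + r))
        + x * (np.log(m) - np.log(m + r))
    )


def poisson_logpmf(x: np.ndarray, mean: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x * np.log(mean) - mean - gammaln(x + 1.0)


def gamma_logpdf(x: np.ndarray, shape, rate) -> np.ndarray:
    """Gamma log density in the shape/rate parametrization."""
    x = np.asarray(x, dtype=float)
    shape = np.asarray(shape, dtype=float)
    rate = np.asarray(rate, dtype=float)
    return shape * np.log(rate) - gammaln(shape) + (shape - 1.0) * np.log(x) - rate * x


def marginal_loglik(
    ds: ExpressionDataset, gs: GeneState, cs: CellState
) -> float:
    """Log-likelihood of the spikes model with rho integrated out.

    Negative Binomial terms for biological genes, Poisson terms for
    spike-ins, and the Gamma density of the technical random effects nu.
    Raises on a non-finite result, naming the offending gene or cell.
    """
    bio = ds.bio_counts
    factors = cs.phi * cs.nu  # per cell
    mean_bio = gs.mu[:, None] * factors[None, :]
    size = (1.0 / gs.delta)[:, None]
    ll_bio = nb_logpmf(bio, size, mean_bio)

    total = 0.0
    if not np.all(np.isfinite(ll_bio)):
        i, j = np.argwhere(~np.isfinite(ll_bio))[0]
        raise FloatingPointError(
            f"non-finite NB log-likelihood at biological gene {i}, cell {j}"
        )
    total += float(ll_bio.sum())

    if ds.is_spike.any():
        mean_spk = gs.mu_spike[:, None] * cs.nu[None, :]
        ll_spk = poisson_logpmf(ds.spike_counts, mean_spk)
        if not np.all(np.isfinite(ll_spk)):
            i, j = np.argwhere(~np.isfinite(ll_spk))[0]
            raise FloatingPointError(
                f"non-finite Poisson log-likelihood at spike-in {i}, cell {j}"
            )
        total += float(ll_spk.sum())

    theta = float(np.atleast_1d(cs.theta)[0])
    ll_nu = gamma_logpdf(cs.nu, 1.0 / theta, 1.0 / (cs.s * theta))
    if not np.all(np.isfinite(ll_nu)):
        j = int(np.argwhere(~np.isfinite(ll_nu))[0])
        raise FloatingPointError(f"non-finite nu log-density at cell {j}")
    total += float(ll_nu.sum())
    return total


def loglik_nospikes(
    counts: np.ndarray,
    mu: np.ndarray,
    delta: np.ndarray,
    nu: np.ndarray,
    s: np.ndarray,
    theta_cell: np.ndarray,
) -> float:
    """Log-likelihood of the no-spikes model (all genes biological).

    ``theta_cell`` carries each cell's batch-specific theta_k.
    """
    mean = mu[:, None] * nu[None, :]
    size = (1.0 / delta)[:, None]
    ll = nb_logpmf(counts, size, mean)
    ll_nu = gamma_logpdf(nu, 1.0 / theta_cell, 1.0 / (s * theta_cell))
    return float(ll.sum() + ll_nu.sum())


# ---------------------------------------------------------------------------
# Full joint posteriors (natural-scale densities; reference for MH ratios)
# ---------------------------------------------------------------------------

def _lognormal_logpdf(x: np.ndarray, mean_log, var_log) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    lx = np.log(x)
    return -lx - 0.5 * np.log(2 * np.pi * var_log) - (lx - mean_log) ** 2 / (
        2.0 * var_log
    )


def log_joint_spikes(
    ds: ExpressionDataset,
    gs: GeneState,
    cs: CellState,
    hp: HyperParams,
    reg: RegressionState | None = None,
    cfg: RegressionConfig | None = None,
    regression: bool = True,
) -> float:
    """Unnormalized log joint posterior of the spikes model.

    Density with respect to the natural scale of every parameter
    (mu, delta, lambda, beta, sigma2, phi, s, nu, theta). With
    ``regression=False`` the independent log-Normal priors on mu and delta
    replace the joint regression prior (no lambda/beta/sigma2 terms).
    """
    total = marginal_loglik(ds, gs, cs)

    # mu prior: log-Normal(0, a_mu2)
    total += float(_lognormal_logpdf(gs.mu, 0.0, hp.a_mu2).sum())

    if regression:
        f = predict_trend(np.log(gs.mu), reg, cfg)
        # delta | mu, beta, sigma2, lambda ~ log-Normal(f(mu), sigma2/lambda)
        total += float(
            _lognormal_logpdf(gs.delta, f, reg.sigma2 / gs.lam).sum()
        )
        # lambda ~ Gamma(eta/2, eta/2)
        total += float(gamma_logpdf(gs.lam, hp.eta / 2.0, hp.eta / 2.0).sum())
        # beta | sigma2 ~ N(m_beta, sigma2 V_beta)
        p = len(reg.beta)
        m_beta = np.zeros(p) if hp.m_beta is None else hp.m_beta
        dev = reg.beta - m_beta
        total += float(
            -0.5 * p * np.log(2 * np.pi * reg.sigma2 * hp.v_beta_diag)
            - dev @ dev / (2.0 * reg.sigma2 * hp.v_beta_diag)
        )
        # sigma2 ~ Inv-Gamma(a, b)
        total += float(
            -(hp.a_sigma2 + 1.0) * np.log(reg.sigma2) - hp.b_sigma2 / reg.sigma2
        )
    else:
        total += float(_lognormal_logpdf(gs.delta, 0.0, hp.a_delta2).sum())

    # phi/n ~ Dirichlet(a_phi) kernel
    total += float((hp.a_phi - 1.0) * np.log(cs.phi).sum())
    # s ~ Gamma(a_s, b_s)
    total += float(gamma_logpdf(cs.s, hp.a_s, hp.b_s).sum())
    # theta ~ Gamma(a_theta, b_theta)
    theta = float(np.atleast_1d(cs.theta)[0])
    total += float(gamma_logpdf(theta, hp.a_theta, hp.b_theta))
    return total


def log_joint_nospikes(
    counts: np.ndarray,
    mu: np.ndarray,
    delta: np.ndarray,
    lam: np.ndarray,
    cs: CellState,
    batch_of_cell: np.ndarray,
    hp: HyperParams,
    mu0: float,
    constrained: np.ndarray,
    reference: int,
    reg: RegressionState | None = None,
    cfg: RegressionConfig | None = None,
    regression: bool = True,
) -> float:
    """Unnormalized log joint posterior of the no-spikes model.

    The density is over the free coordinates: mu_i for every gene except the
    reference (whose value is a deterministic function of the others through
    the geometric-mean constraint), delta, lambda, beta, sigma2, s, nu and
    the batch-specific theta_k. The correlated prior for constraint-set
    genes is the (q_c - 1)-dimensional Normal obtained after conditioning on
    the reference (its precision is (I + 1 1')/a_mu2).
    """
    theta_cell = np.atleast_1d(cs.theta)[batch_of_cell]
    total = loglik_nospikes(counts, mu, delta, cs.nu, cs.s, theta_cell)

    # prior over log mu on the constrained manifold, excluding the reference
    free = constrained.copy()
    free[reference] = False
    y = np.log(mu[free]) - np.log(mu0)
    qc = int(constrained.sum())
    # N_{qc-1}(0, a_mu2 (I - 11'/qc)) with inverse covariance (I + 11')/a_mu2
    total += float(
        -(y @ y + y.sum() ** 2) / (2.0 * hp.a_mu2) - np.log(mu[free]).sum()
    )
    del qc
    # unconstrained genes: independent log-Normal(0, a_mu2)
    if (~constrained).any():
        total += float(
            _lognormal_logpdf(mu[~constrained], 0.0, hp.a_mu2).sum()
        )

    if regression:
        f = predict_trend(np.log(mu), reg, cfg)
        total += float(_lognormal_logpdf(delta, f, reg.sigma2 / lam).sum())
        total += float(gamma_logpdf(lam, hp.eta / 2.0, hp.eta / 2.0).sum())
        p = len(reg.beta)
        m_beta = np.zeros(p) if hp.m_beta is None else hp.m_beta
        dev = reg.beta - m_beta
        total += float(
            -0.5 * p * np.log(2 * np.pi * reg.sigma2 * hp.v_beta_diag)
            - dev @ dev / (2.0 * reg.sigma2 * hp.v_beta_diag)
        )
        total += float(
            -(hp.a_sigma2 + 1.0) * np.log(reg.sigma2) - hp.b_sigma2 / reg.sigma2
        )
    else:
        total += float(_lognormal_logpdf(delta, 0.0, hp.a_delta2).sum())

    total += float(gamma_logpdf(cs.s, hp.a_s, hp.b_s).sum())
    total += float(
        gamma_logpdf(np.atleast_1d(cs.theta), hp.a_theta, hp.b_theta).sum()
    )
    return total
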