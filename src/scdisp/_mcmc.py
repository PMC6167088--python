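"""Shared Metropolis-within-Gibbs machinery: adaptive proposal scales."""

from __future__ import annotations

import dataclasses

import numpy as np

#: standard optimal acceptance rate for univariate random-walk Metropolis
TARGET_RATE = 0.44
#: proposal scales are revised every this many iterations during burn-in
ADAPT_EVERY = 50


@dataclasses.dataclass
class AdaptiveProposal:
    """Per-block Gaussian random-walk scales, adapted during burn-in.

    Scales move on the log scale toward the target acceptance rate in
    diminishing steps bounded by batch^(-1/2), which preserves ergodicity
    (adaptation vanishes asymptotically and stops entirely after burn-in).
    """

    log_scale: np.ndarray
    target_rate: float = TARGET_RATE
    _accept_sum: np.ndarray = None
    _n: int = 0
    _batch: int = 0

    def __post_init__(self) -> None:
        self.log_scale = np.atleast_1d(np.asarray(self.log_scale, dtype=float))
        self._accept_sum = np.zeros_like(self.log_scale)

    @property
    def scale(self) -> np.ndarray:
        return np.exp(self.log_scale)

    def record(self, accept_prob: np.ndarray) -> None:
        self._accept_sum = self._accept_sum + np.minimum(
            1.0, np.exp(np.minimum(accept_prob, 0.0))
        )
        self._n += 1

    def record_indicator(self, accepted) -> None:
        self._accept_sum = self._accept_sum + np.asarray(accepted, dtype=float)
        self._n += 1

    def adapt(self) -> None:
        """Nudge scales toward the target rate; call every ADAPT_EVERY iters."""
        if self._n == 0:
            return
        self._batch += 1
        rate = self._accept_sum / self._n
        step = min(0.25, 1.0 / np.sqrt(self._batch))
        self.log_scale = self.log_scale + step * np.sign(rate - self.target_rate)
        self._accept_sum = np.zeros_like(self.log_scale)
        self._n = 0

    def mean_rate(self) -> float:
        return float(np.mean(self._accept_sum) / max(self._n, 1))


def metropolis_mask(rng: np.random.Generator, log_alpha: np.ndarray) -> np.ndarray:
    """Vector of accept decisions for element-wise MH steps."""
    log_alpha = np.asarray(log_alpha, dtype=float)
    log_u = np.log(rng.random(log_alpha.shape))
    return log_u < log_alpha


def draw_beta_sigma2(
    X: np.ndarray,
    Y: np.ndarray,
    lam: np.ndarray,
    beta_cur: np.ndarray,
    hp,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float]:
    """Conjugate Gibbs draw of the regression block.

    Model: Y_i | beta, sigma2, lam_i ~ N(x_i' beta, sigma2 / lam_i),
    beta | sigma2 ~ N(m_beta, sigma2 * v * I), sigma2 ~ Inv-Gamma(a, b).
    Draws sigma2 from its full conditional given the current beta (shape
    a + (q + p)/2 since the beta prior scales with sigma2), then beta given
    the new sigma2.
    """
    from scipy import linalg

    q, p = X.shape
    m_beta = np.zeros(p) if hp.m_beta is None else hp.m_beta
    vinv = 1.0 / hp.v_beta_diag

    A = X.T @ (lam[:, None] * X) + vinv * np.eye(p)
    rhs = X.T @ (lam * Y) + vinv * m_beta
    cho = linalg.cho_factor(A, lower=True)
    m_star = linalg.cho_solve(cho, rhs)

    resid = Y - X @ beta_cur
    dev = beta_cur - m_beta
    b_star = hp.b_sigma2 + 0.5 * (lam @ (resid * resid) + vinv * (dev @ dev))
    a_star = hp.a_sigma2 + 0.5 * (q + p)
    sigma2 = float(b_star / rng.gamma(a_star))

    z = rng.standard_normal(p)
    L = linalg.cholesky(A, lower=True)
    beta = m_star + np.sqrt(sigma2) * linalg.solve_triangular(L.T, z, lower=False)
    return beta, sigma2
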