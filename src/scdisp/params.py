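"""Parameter containers: gene-level and cell-level states, fixed hyper-parameters."""

from __future__ import annotations

import dataclasses
import math

import numpy as np

#: default minimum-tolerance thresholds for the differential tests:
#: a 1.5-fold change on the log2 scale for mean and over-dispersion, and its
#: natural-log equivalent for residual over-dispersion (epsilon lives on the
#: natural-log scale).
TAU0_DEFAULT = math.log2(1.5)          # ~0.58
OMEGA0_DEFAULT = math.log2(1.5)        # ~0.58
PSI0_DEFAULT = math.log2(1.5) / math.log2(math.e)  # = ln(1.5) ~ 0.41


@dataclasses.dataclass
class HyperParams:
    """Fixed hyper-parameters of the hierarchical model.

    ``a_mu2`` is the prior variance of log mean expression; ``a_delta2`` the
    prior variance of log over-dispersion under the independent (non
    regression) prior. ``a_s``/``b_s`` are the Gamma shape/rate for the cell
    scale s_j, ``a_phi`` the Dirichlet concentration for mRNA content,
    ``a_theta``/``b_theta`` the Gamma shape/rate for the technical noise
    parameter theta. The regression block uses a conjugate
    Normal-inverse-Gamma prior: beta | sigma2 ~ N(m_beta, sigma2 * V_beta),
    sigma2 ~ Inv-Gamma(a_sigma2, b_sigma2), with Student-t residual degrees
    of freedom ``eta``.
    """

    a_mu2: float = 0.5
    a_delta2: float = 0.5
    a_s: float = 1.0
    b_s: float = 1.0
    a_phi: float = 1.0
    a_theta: float = 1.0
    b_theta: float = 1.0
    m_beta: np.ndarray | None = None     # defaults to zeros(L+2)
    v_beta_diag: float = 1.0             # V_beta = v_beta_diag * I
    a_sigma2: float = 2.0
    b_sigma2: float = 2.0
    eta: float = 5.0
    tau0: float = TAU0_DEFAULT
    omega0: float = OMEGA0_DEFAULT
    psi0: float = PSI0_DEFAULT
    efdr_target: float = 0.10

    def __post_init__(self) -> None:
        for name in ("a_mu2", "a_delta2", "a_s", "b_s", "a_phi", "a_theta",
                     "b_theta", "v_beta_diag", "a_sigma2", "b_sigma2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.eta < 1:
            raise ValueError("eta must be >= 1")
        if not 0 < self.efdr_target < 1:
            raise ValueError("efdr_target must lie in (0, 1)")
        if min(self.tau0, self.omega0, self.psi0) < 0:
            raise ValueError("tolerance thresholds must be >= 0")


@dataclasses.dataclass
class GeneState:
    """Current gene-level parameter values.

    mu/delta/epsilon/lam are over biological genes (length q0); mu_spike
    holds the fixed, known means of spike-in genes.
    """

    mu: np.ndarray
    delta: np.ndarray
    epsilon: np.ndarray
    lam: np.ndarray
    mu_spike: np.ndarray | None = None

    def validate(self) -> None:
        if (self.mu <= 0).any() or (self.delta <= 0).any() or (self.lam <= 0).any():
            raise ValueError("mu, delta and lambda must be strictly positive")
        if self.mu_spike is not None and (self.mu_spike <= 0).any():
            raise ValueError("spike-in means must be strictly positive")


@dataclasses.dataclass
class CellState:
    """Current cell-level parameter values.

    phi (mRNA content, spikes model only) satisfies sum(phi) == n_cells;
    theta is a scalar in the spikes model and a per-batch vector in the
    no-spikes model.
    """

    s: np.ndarray
    nu: np.ndarray
    theta: np.ndarray
    phi: np.ndarray | None = None

    def validate(self, n_cells: int | None = None) -> None:
        if (self.s <= 0).any() or (self.nu <= 0).any():
            raise ValueError("s and nu must be strictly positive")
        if (np.atleast_1d(self.theta) <= 0).any():
            raise ValueError("theta must be strictly positive")
        if self.phi is not None:
            if (self.phi <= 0).any():
                raise ValueError("phi must be strictly positive")
            n = n_cells if n_cells is not None else len(self.phi)
            if abs(self.phi.sum() - n) > 1e-8 * n:
                raise ValueError("phi must sum to the number of cells")
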