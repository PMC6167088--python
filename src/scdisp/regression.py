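"""GRBF design matrix and the mean/over-dispersion trend f(mu).

The trend is a linear model in an intercept, log(mu), and L Gaussian radial
basis functions with equally spaced locations spanning the current range of
log(mu) across biological genes:

    f(mu_i) = alpha0 + alpha1 * log(mu_i) + sum_l beta_l * g_l(log(mu_i)),
    g_l(x)  = exp{ -((x - m_l) / h_l)^2 / 2 },    h_l = c * (m_2 - m_1).

Because mu is unknown a priori, the kernel range is refreshed every 50
iterations during burn-in and frozen afterwards.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

REFRESH_EVERY = 50


@dataclasses.dataclass
class RegressionConfig:
    """GRBF basis configuration (locations, scales, Student-t dof)."""

    L: int = 10
    c: float = 1.2
    eta: float = 5.0
    locations: np.ndarray | None = None
    scales: np.ndarray | None = None
    range: tuple[float, float] | None = None
    frozen: bool = False

    def __post_init__(self) -> None:
        if self.L < 2:
            raise ValueError("need at least 2 GRBF kernels (L >= 2)")
        if self.c <= 0:
            raise ValueError("kernel width constant c must be positive")

    @property
    def n_coef(self) -> int:
        return self.L + 2

    def initialized(self) -> bool:
        return self.locations is not None

    def to_dict(self) -> dict:
        d = {"L": self.L, "c": self.c, "eta": self.eta, "frozen": self.frozen}
        if self.locations is not None:
            d["locations"] = list(map(float, self.locations))
            d["scales"] = list(map(float, self.scales))
            d["range"] = [float(self.range[0]), float(self.range[1])]
        return d


@dataclasses.dataclass
class RegressionState:
    """Current regression coefficients (alpha0, alpha1, beta_1..L) and sigma2."""

    beta: np.ndarray
    sigma2: float

    def validate(self) -> None:
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be strictly positive")
        if not np.all(np.isfinite(self.beta)):
            raise ValueError("regression coefficients must be finite")


def kernel_locations(logmu: np.ndarray, L: int) -> np.ndarray:
    """Equally spaced kernel locations spanning [min, max] of log(mu)."""
    logmu = np.asarray(logmu, dtype=float)
    if logmu.size == 0 or not np.all(np.isfinite(logmu)):
        raise ValueError("logmu must be non-empty with finite entries")
    a, b = float(logmu.min()), float(logmu.max())
    if a == b:
        raise ValueError("degenerate range: all log(mu) values equal")
    return a + np.arange(L) * (b - a) / (L - 1)


def grbf_value(x: float, m: float, h: float) -> float:
    """Gaussian radial basis kernel exp{-((x-m)/h)^2 / 2}."""
    if h <= 0:
        raise ValueError("kernel scale h must be positive")
    return float(np.exp(-0.5 * ((x - m) / h) ** 2))


def set_locations(cfg: RegressionConfig, logmu: np.ndarray) -> RegressionConfig:
    """Populate locations/scales of ``cfg`` from the current log(mu) range."""
    locs = kernel_locations(logmu, cfg.L)
    dm = locs[1] - locs[0]
    cfg.locations = locs
    cfg.scales = np.full(cfg.L, cfg.c * dm)
    cfg.range = (float(locs[0]), float(locs[-1]))
    return cfg


def build_design_matrix(logmu: np.ndarray, cfg: RegressionConfig) -> np.ndarray:
    """q0 x (L+2) design matrix: [1, log(mu), g_1(log mu), ..., g_L(log mu)]."""
    logmu = np.asarray(logmu, dtype=float)
    if not np.all(np.isfinite(logmu)):
        bad = int(np.flatnonzero(~np.isfinite(logmu))[0])
        raise ValueError(f"non-finite log(mu) for gene index {bad}")
    if not cfg.initialized():
        raise ValueError("RegressionConfig locations not initialized")
    z = (logmu[:, None] - cfg.locations[None, :]) / cfg.scales[None, :]
    kernels = np.exp(-0.5 * z * z)
    return np.column_stack([np.ones_like(logmu), logmu, kernels])


def predict_trend(
    logmu: np.ndarray, state: RegressionState, cfg: RegressionConfig
) -> np.ndarray:
    """Evaluate f(mu) = X beta at the given log(mu) values."""
    X = build_design_matrix(np.atleast_1d(logmu), cfg)
    if X.shape[1] != len(state.beta):
        raise ValueError(
            f"beta length {len(state.beta)} != {X.shape[1]} design columns"
        )
    return X @ state.beta


def refresh_locations(
    cfg: RegressionConfig,
    logmu_current: np.ndarray,
    iteration: int,
    burn_in: int,
) -> RegressionConfig:
    """Refresh the kernel range every 50 iterations during burn-in.

    After burn-in the configuration is frozen permanently. A degenerate
    range (all log(mu) equal) keeps the previous locations with a warning
    instead of aborting the chain.
    """
    if iteration >= burn_in:
        cfg.frozen = True
        return cfg
    if cfg.frozen or iteration % REFRESH_EVERY != 0:
        return cfg
    logmu_current = np.asarray(logmu_current, dtype=float)
    if float(logmu_current.min()) == float(logmu_current.max()):
        if cfg.initialized():
            warnings.warn(
                "degenerate log(mu) range during refresh; keeping previous "
                "kernel locations",
                RuntimeWarning,
            )
            return cfg
        raise ValueError("degenerate range: all log(mu) values equal")
    return set_locations(cfg, logmu_current)
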