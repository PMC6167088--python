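"""Probabilistic two-group differential tests calibrated by EFDR.

Two fitted chains (equal stored length, shared gene set) are combined by
stored-draw index. For each gene a tail posterior probability is computed:
the fraction of paired draws in which the absolute difference (log2 fold
change in mu or delta, or the difference in residual over-dispersion
epsilon) exceeds a minimum tolerance threshold. With a zero threshold the
tail probability degenerates to 1, so the rule switches to the maximum of
the two one-sided posterior probabilities, 2*max(pi, 1-pi) - 1.

The probability cutoff alpha_R is calibrated so that the expected false
discovery rate, EFDR(alpha) = sum (1 - pi_i) 1{pi_i > alpha} / sum 1{pi_i >
alpha}, stays at or below the target (default 10%).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .chain import PosteriorChain
from .data import ExpressionDataset
from .params import OMEGA0_DEFAULT, PSI0_DEFAULT, TAU0_DEFAULT

#: cutoff grid: directional calls require probability > 1/2
ALPHA_GRID = np.arange(0.50, 1.0, 0.0025)

EXCLUDED = "excluded"


@dataclasses.dataclass
class TestResult:
    """Per-gene tail probabilities, calibrated cutoff and calls."""

    table: pd.DataFrame
    threshold: float
    alpha: float | None
    efdr_achieved: float | None
    efdr_target: float
    kind: str
    offset: float | None = None

    @property
    def calls(self) -> np.ndarray:
        return self.table["call"].to_numpy()

    @property
    def n_calls(self) -> int:
        return int((self.table["call"] != "none").sum() - self.n_excluded)

    @property
    def n_excluded(self) -> int:
        return int((self.table["call"] == EXCLUDED).sum())

    def to_tsv(self, path) -> None:
        meta = (
            f"# kind={self.kind} threshold={self.threshold:.6g} "
            f"alpha={self.alpha} efdr_achieved={self.efdr_achieved} "
            f"efdr_target={self.efdr_target}\n"
        )
        with open(path, "w") as fh:
            fh.write(meta)
            self.table.to_csv(fh, sep="\t", index=False)


def _check_pair(chainA: PosteriorChain, chainB: PosteriorChain) -> None:
    if list(chainA.gene_ids) != list(chainB.gene_ids):
        missing = set(chainA.gene_ids) ^ set(chainB.gene_ids)
        raise ValueError(f"chains have mismatched gene sets: {sorted(missing)[:10]}")
    if chainA.n_stored != chainB.n_stored:
        raise ValueError(
            f"chains store different draw counts "
            f"({chainA.n_stored} vs {chainB.n_stored}); draws are paired by index"
        )
    if chainA.n_stored == 0:
        raise ValueError("chains contain zero stored draws")


def offset_correct(
    chainA: PosteriorChain, chainB: PosteriorChain
) -> tuple[PosteriorChain, PosteriorChain, float]:
    """Remove the global scale offset between two populations.

    The identifiability constraints of the two fits anchor mean expression
    on population-specific scales. Per stored draw, group-B mu values are
    multiplied by Omega_d = sum_i mu_iA,d / sum_i mu_iB,d and the cell-level
    factors of group B are divided by the same amount, leaving the
    likelihood (and delta, epsilon) untouched. Returns adjusted copies of
    the chains and the median offset.
    """
    _check_pair(chainA, chainB)
    omega = chainA.draws["mu"].sum(axis=1) / chainB.draws["mu"].sum(axis=1)
    drawsB = {k: v.copy() for k, v in chainB.draws.items()}
    drawsB["mu"] = drawsB["mu"] * omega[:, None]
    for name in ("nu", "phi", "s"):
        if name in drawsB:
            drawsB[name] = drawsB[name] / omega[:, None]
            break  # compensate once, on the innermost scale factor
    adjB = dataclasses.replace(chainB, draws=drawsB)
    adjA = dataclasses.replace(chainA, draws={k: v.copy() for k, v in chainA.draws.items()})
    return adjA, adjB, float(np.median(omega))


def calibrate_efdr(
    tail_probs: np.ndarray, target: float
) -> tuple[float | None, float | None]:
    """Pick the probability cutoff controlling EFDR at the target.

    Scans the grid and returns the cutoff whose EFDR is closest to the
    target from below (ties resolved toward the larger cutoff), together
    with the achieved EFDR. Returns (None, None) with a warning when no
    cutoff on the grid yields any call with EFDR <= target.
    """
    probs = np.asarray(tail_probs, dtype=float)
    if probs.size == 0:
        raise ValueError("no tail probabilities to calibrate")
    best_alpha, best_efdr = None, None
    for alpha in ALPHA_GRID:
        called = probs > alpha
        n = int(called.sum())
        if n == 0:
            continue
        efdr = float((1.0 - probs[called]).sum() / n)
        if efdr <= target and (best_efdr is None or efdr >= best_efdr):
            # ">=" resolves ties toward the larger alpha (grid is ascending)
            best_alpha, best_efdr = float(alpha), efdr
    if best_alpha is None:
        warnings.warn(
            "no probability cutoff achieves the EFDR target with at least "
            "one call; returning no calls",
            RuntimeWarning,
        )
    return best_alpha, best_efdr


def eligibility_filter(dsA: ExpressionDataset, dsB: ExpressionDataset) -> np.ndarray:
    """Genes detected (count > 0) in >= 2 cells in BOTH groups."""
    bioA, bioB = dsA.bio_counts, dsB.bio_counts
    if bioA.shape[0] != bioB.shape[0]:
        raise ValueError("groups must share the gene set")
    return ((bioA > 0).sum(axis=1) >= 2) & ((bioB > 0).sum(axis=1) >= 2)


def _tail_probability(diff_draws: np.ndarray, threshold: float) -> np.ndarray:
    """Fraction of draws exceeding the tolerance; sign rule at threshold 0."""
    if threshold > 0:
        return (np.abs(diff_draws) > threshold).mean(axis=0)
    pi = (diff_draws > 0).mean(axis=0)
    return 2.0 * np.maximum(pi, 1.0 - pi) - 1.0


def _run_test(
    diff_draws: np.ndarray,
    point_log2fc: np.ndarray,
    gene_ids: np.ndarray,
    threshold: float,
    efdr_target: float,
    eligible: np.ndarray | None,
    kind: str,
    direction_labels: tuple[str, str],
    extra_cols: dict | None = None,
) -> TestResult:
    q = diff_draws.shape[1]
    eligible = np.ones(q, dtype=bool) if eligible is None else np.asarray(eligible)
    probs = _tail_probability(diff_draws, threshold)

    alpha, efdr = calibrate_efdr(probs[eligible], efdr_target)
    call = np.full(q, "none", dtype=object)
    if alpha is not None:
        sig = eligible & (probs > alpha)
        up = point_log2fc > 0
        call[sig & up] = direction_labels[0]
        call[sig & ~up] = direction_labels[1]
    call[~eligible] = EXCLUDED

    table = pd.DataFrame(
        {
            "id": gene_ids,
            "estimate": point_log2fc,
            "tail_prob": probs,
            "eligible": eligible,
            "call": call,
        }
    )
    if extra_cols:
        for k, v in extra_cols.items():
            table[k] = v
    return TestResult(
        table=table,
        threshold=threshold,
        alpha=alpha,
        efdr_achieved=efdr,
        efdr_target=efdr_target,
        kind=kind,
    )


def test_mean(
    chainA: PosteriorChain,
    chainB: PosteriorChain,
    tau0: float = TAU0_DEFAULT,
    efdr_target: float = 0.10,
    eligible: np.ndarray | None = None,
) -> TestResult:
    """Differential mean expression: |log2(mu_A / mu_B)| > tau0."""
    _check_pair(chainA, chainB)
    lfc = np.log2(chainA.draws["mu"]) - np.log2(chainB.draws["mu"])
    return _run_test(
        lfc,
        np.median(lfc, axis=0),
        chainA.gene_ids,
        tau0,
        efdr_target,
        eligible,
        kind="mean",
        direction_labels=("up", "down"),
    )


def test_overdispersion(
    chainA: PosteriorChain,
    chainB: PosteriorChain,
    omega0: float = OMEGA0_DEFAULT,
    efdr_target: float = 0.10,
    mean_result: TestResult | None = None,
    restrict_to_non_de: bool = False,
    eligible: np.ndarray | None = None,
) -> TestResult:
    """Differential over-dispersion: |log2(delta_A / delta_B)| > omega0.

    Because delta is confounded with mean expression, the classical
    workflow restricts this test to genes without a mean-expression call;
    pass ``mean_result`` (and optionally ``restrict_to_non_de=True``) to
    annotate or enforce that restriction.
    """
    _check_pair(chainA, chainB)
    lfc = np.log2(chainA.draws["delta"]) - np.log2(chainB.draws["delta"])
    q = lfc.shape[1]
    eligible = np.ones(q, dtype=bool) if eligible is None else np.asarray(eligible).copy()
    extra = None
    if mean_result is not None:
        mean_call = mean_result.table["call"].to_numpy()
        extra = {"mean_call": mean_call}
        if restrict_to_non_de:
            eligible &= mean_call == "none"
    return _run_test(
        lfc,
        np.median(lfc, axis=0),
        chainA.gene_ids,
        omega0,
        efdr_target,
        eligible,
        kind="overdispersion",
        direction_labels=("more_disp", "less_disp"),
        extra_cols=extra,
    )


def test_residual(
    chainA: PosteriorChain,
    chainB: PosteriorChain,
    psi0: float = PSI0_DEFAULT,
    efdr_target: float = 0.10,
    eligible: np.ndarray | None = None,
) -> TestResult:
    """Differential residual over-dispersion: |epsilon_A - epsilon_B| > psi0.

    Requires regression-variant chains (epsilon is defined as the departure
    of log over-dispersion from the mean-expression trend).
    """
    _check_pair(chainA, chainB)
    if "epsilon" not in chainA.draws or "epsilon" not in chainB.draws:
        raise ValueError(
            "residual over-dispersion test requires regression-variant chains"
        )
    diff = chainA.draws["epsilon"] - chainB.draws["epsilon"]
    return _run_test(
        diff,
        np.median(diff, axis=0),
        chainA.gene_ids,
        psi0,
        efdr_target,
        eligible,
        kind="residual",
        direction_labels=("more_var", "less_var"),
    )


def decompose_log2fc(
    chainA: PosteriorChain, chainB: PosteriorChain
) -> pd.DataFrame:
    """Split log2(delta_A/delta_B) into trend and residual contributions.

    Per draw: log2(delta_A/delta_B) = log2(e) * [f_A(mu_A) - f_B(mu_B)]
    + log2(e) * [eps_A - eps_B]; the identity holds exactly because
    eps = log(delta) - f(mu) by construction. Returns posterior medians of
    both components.
    """
    _check_pair(chainA, chainB)
    log2e = np.log2(np.e)
    trendA = np.log(chainA.draws["delta"]) - chainA.draws["epsilon"]
    trendB = np.log(chainB.draws["delta"]) - chainB.draws["epsilon"]
    mean_part = log2e * (trendA - trendB)
    resid_part = log2e * (chainA.draws["epsilon"] - chainB.draws["epsilon"])
    return pd.DataFrame(
        {
            "id": chainA.gene_ids,
            "mean_contribution": np.median(mean_part, axis=0),
            "residual_change": np.median(resid_part, axis=0),
            "log2fc_delta": np.median(
                np.log2(chainA.draws["delta"] / chainB.draws["delta"]), axis=0
            ),
        }
    )


FOUR_WAY = {
    ("down", "more_var"): "down+higherVar",
    ("down", "less_var"): "down+lowerVar",
    ("up", "more_var"): "up+higherVar",
    ("up", "less_var"): "up+lowerVar",
}


def classify_four_way(
    mean_result: TestResult, residual_result: TestResult
) -> pd.DataFrame:
    """Joint labels from the mean and residual over-dispersion tests.

    Genes significant in both tests are assigned one of the four combined
    categories; genes significant in a single test are labelled
    'mean-only' or 'variability-only'; the rest 'none' (or 'excluded').
    """
    ids_m = list(mean_result.table["id"])
    ids_r = list(residual_result.table["id"])
    if ids_m != ids_r:
        raise ValueError("test results cover different gene sets")
    mcall = mean_result.table["call"].to_numpy()
    rcall = residual_result.table["call"].to_numpy()
    labels = []
    for m, r in zip(mcall, rcall):
        if m == EXCLUDED and r == EXCLUDED:
            labels.append(EXCLUDED)
        elif (m, r) in FOUR_WAY:
            labels.append(FOUR_WAY[(m, r)])
        elif m in ("up", "down"):
            labels.append("mean-only")
        elif r in ("more_var", "less_var"):
            labels.append("variability-only")
        else:
            labels.append("none")
    return pd.DataFrame({"id": ids_m, "category": labels})


def denoised_counts(ds: ExpressionDataset, chain: PosteriorChain) -> np.ndarray:
    """Counts rescaled by posterior-median cell-specific factors.

    Divides biological gene counts by phi_j * nu_j (spikes model) or nu_jk
    (no-spikes model), making expression values comparable across cells.
    """
    if chain.model_variant.startswith("spikes"):
        factors = np.median(chain.draws["phi"] * chain.draws["nu"], axis=0)
    else:
        factors = np.median(chain.draws["nu"], axis=0)
    if len(factors) != ds.n_cells:
        raise ValueError("chain and dataset have different cell counts")
    return ds.bio_counts / factors[None, :]
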