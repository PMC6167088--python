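"""Posterior chain container, HDF5 serialization, and per-gene summaries."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

VARIANTS = (
    "spikes-regression",
    "spikes-nonregression",
    "nospikes-regression",
    "nospikes-nonregression",
)


@dataclasses.dataclass
class PosteriorChain:
    """Thinned post-burn-in posterior draws with run metadata.

    ``draws`` maps parameter names (mu, delta, epsilon, phi, s, nu, theta,
    beta, sigma2, lam, ...) to arrays whose leading axis indexes stored
    iterations. ``extra`` carries variant-specific audit data (e.g. mu0,
    the constraint mask and the per-iteration reference gene in the
    no-spikes model).
    """

    draws: dict
    n_iter: int
    burn_in: int
    thin: int
    seed: int
    model_variant: str
    gene_ids: np.ndarray
    extra: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model_variant not in VARIANTS:
            raise ValueError(f"unknown model variant {self.model_variant!r}")
        expect = (self.n_iter - self.burn_in) // self.thin
        for name, arr in self.draws.items():
            if arr.shape[0] != expect:
                raise ValueError(
                    f"draws[{name!r}] stores {arr.shape[0]} iterations, "
                    f"expected {expect}"
                )

    @property
    def n_stored(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin

    @property
    def regression(self) -> bool:
        return self.model_variant.endswith("-regression")

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with h5py.File(path, "w") as f:
            g = f.create_group("draws")
            for name, arr in self.draws.items():
                g.create_dataset(name, data=arr)
            f.attrs["n_iter"] = self.n_iter
            f.attrs["burn_in"] = self.burn_in
            f.attrs["thin"] = self.thin
            f.attrs["seed"] = self.seed
            f.attrs["model_variant"] = self.model_variant
            f.create_dataset(
                "gene_ids", data=np.asarray(self.gene_ids, dtype="S")
            )
            e = f.create_group("extra")
            for name, val in self.extra.items():
                e.create_dataset(name, data=val)

    @classmethod
    def load(cls, path: str | Path) -> "PosteriorChain":
        with h5py.File(path, "r") as f:
            draws = {k: f["draws"][k][...] for k in f["draws"]}
            extra = {k: f["extra"][k][...] for k in f.get("extra", {})}
            gene_ids = np.array(
                [s.decode() for s in f["gene_ids"][...]], dtype=object
            )
            return cls(
                draws=draws,
                n_iter=int(f.attrs["n_iter"]),
                burn_in=int(f.attrs["burn_in"]),
                thin=int(f.attrs["thin"]),
                seed=int(f.attrs["seed"]),
                model_variant=str(f.attrs["model_variant"]),
                gene_ids=gene_ids,
                extra=extra,
            )


def hpd_interval(x: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Narrowest interval containing ``prob`` of the draws."""
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    k = max(1, int(np.ceil(prob * n)))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k:] - x[: n - k]
    j = int(np.argmin(widths))
    return float(x[j]), float(x[j + k])


def chain_summary(chain: PosteriorChain, prob: float = 0.95) -> pd.DataFrame:
    """Posterior medians and HPD intervals of the gene-level parameters."""
    rows = {"id": chain.gene_ids}
    for name in ("mu", "delta", "epsilon"):
        if name not in chain.draws:
            continue
        arr = chain.draws[name]
        rows[f"{name}_median"] = np.median(arr, axis=0)
        lo, hi = zip(*(hpd_interval(arr[:, i], prob) for i in range(arr.shape[1])))
        rows[f"{name}_lo"] = np.array(lo)
        rows[f"{name}_hi"] = np.array(hi)
    return pd.DataFrame(rows)
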