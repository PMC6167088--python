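"""Count-matrix container, I/O and the gene-eligibility filters.

Counts are stored genes x cells. Biological genes are internally ordered
before spike-in genes (the samplers rely on this); the original input order
is preserved through ``gene_ids`` so that every table written back out can be
re-indexed by identifier.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse


class ValidationError(ValueError):
    """A dataset violates one of the model's structural requirements."""


@dataclasses.dataclass
class ExpressionDataset:
    """Gene x cell expression counts with gene roles and batch labels.

    Parameters
    ----------
    counts
        Non-negative integer matrix, shape ``(n_genes, n_cells)``.
    gene_ids
        Gene identifiers, length ``n_genes``.
    is_spike
        Boolean flag per gene; True marks a technical spike-in.
    batch
        Batch label per cell. A single shared label is valid for the
        spike-in model; the no-spikes model requires >= 2 distinct labels.
    spike_input
        Known input quantity (molecule number, arbitrary units) per spike-in
        gene, aligned with ``gene_ids[is_spike]``. Required in spikes mode.
    cell_ids
        Optional cell identifiers; generated if omitted.
    """

    counts: np.ndarray
    gene_ids: np.ndarray
    is_spike: np.ndarray
    batch: np.ndarray
    spike_input: np.ndarray | None = None
    cell_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = _as_int_matrix(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.is_spike = np.asarray(self.is_spike, dtype=bool)
        self.batch = np.asarray(self.batch)
        if self.cell_ids is None:
            self.cell_ids = np.array(
                [f"cell{j}" for j in range(self.counts.shape[1])], dtype=object
            )
        else:
            self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.spike_input is not None:
            self.spike_input = np.asarray(self.spike_input, dtype=float)
        self.validate()
        # biological genes first: the samplers index genes [0, q0) as biological
        if self.is_spike[: self.n_biological].any():
            order = np.argsort(self.is_spike, kind="stable")
            self.counts = self.counts[order]
            self.gene_ids = self.gene_ids[order]
            self.is_spike = self.is_spike[order]

    # -- shape helpers -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def n_biological(self) -> int:
        return int((~self.is_spike).sum())

    @property
    def n_batches(self) -> int:
        return len(np.unique(self.batch))

    @property
    def bio_counts(self) -> np.ndarray:
        return self.counts[~self.is_spike]

    @property
    def spike_counts(self) -> np.ndarray:
        return self.counts[self.is_spike]

    def validate(self) -> None:
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-d genes x cells matrix")
        q, n = self.counts.shape
        if len(self.gene_ids) != q:
            raise ValidationError(
                f"gene_ids length {len(self.gene_ids)} != {q} rows of counts"
            )
        if len(self.is_spike) != q:
            raise ValidationError("is_spike length must match gene count")
        if len(self.batch) != n:
            raise ValidationError(
                f"batch length {len(self.batch)} != {n} columns of counts"
            )
        if len(self.cell_ids) != n:
            raise ValidationError("cell_ids length must match cell count")
        if (self.counts < 0).any():
            raise ValidationError("counts contain negative entries")
        if self.spike_input is not None and len(self.spike_input) != int(
            self.is_spike.sum()
        ):
            raise ValidationError(
                "spike_input must have one entry per spike-in gene"
            )
        if self.spike_input is not None and (self.spike_input <= 0).any():
            raise ValidationError("spike_input quantities must be positive")

    def require_spikes(self) -> None:
        """Check the requirements of the spike-in (vertical) model."""
        if not self.is_spike.any():
            raise ValidationError("spikes model requires >= 1 spike-in gene")
        if self.spike_input is None:
            raise ValidationError(
                "spikes model requires spike_input quantities for spike-ins"
            )

    def require_batches(self) -> None:
        """Check the requirements of the no-spikes (horizontal) model."""
        if self.n_batches < 2:
            raise ValidationError(
                "no-spikes model requires >= 2 distinct batch labels "
                "(technical noise is identified through replication)"
            )

    def subset_genes(self, keep: np.ndarray) -> "ExpressionDataset":
        keep = np.asarray(keep, dtype=bool)
        spike_input = None
        if self.spike_input is not None:
            spike_input = self.spike_input[keep[self.is_spike]]
        return ExpressionDataset(
            counts=self.counts[keep],
            gene_ids=self.gene_ids[keep],
            is_spike=self.is_spike[keep],
            batch=self.batch.copy(),
            spike_input=spike_input,
            cell_ids=self.cell_ids.copy(),
        )


def _as_int_matrix(x) -> np.ndarray:
    """Coerce to an integer matrix, failing loudly on fractional entries."""
    if sparse.issparse(x):
        x = x.toarray()
    arr = np.asarray(x)
    if arr.dtype.kind in "iu":
        return arr.astype(np.int64)
    flt = arr.astype(float)
    rounded = np.rint(flt)
    if not np.all(np.isfinite(flt)) or np.any(np.abs(flt - rounded) > 0):
        bad = np.argwhere(np.abs(flt - rounded) > 0)
        where = tuple(bad[0]) if len(bad) else "?"
        raise ValidationError(
            f"counts must be integers; non-integer entry at {where}"
        )
    return rounded.astype(np.int64)


# ---------------------------------------------------------------------------
# I/O: MTX + sidecar TSVs, or a dense TSV
# ---------------------------------------------------------------------------

def _sidecar_paths(path: Path) -> tuple[Path, Path]:
    base = path.with_suffix("")
    return base.parent / (base.name + ".genes.tsv"), base.parent / (
        base.name + ".cells.tsv"
    )


def read_counts(
    path: str | Path,
    format: str = "mtx",
    genes_as_rows: bool = True,
) -> ExpressionDataset:
    """Read a counts file plus its gene/cell annotation sidecars.

    ``mtx``: MatrixMarket coordinate file ``<stem>.mtx`` with sidecars
    ``<stem>.genes.tsv`` (columns: id, is_spike, spike_input) and
    ``<stem>.cells.tsv`` (columns: id, batch).

    ``tsv``: dense table, header row = cell ids, first column = gene ids;
    the same gene sidecar supplies roles, and batch defaults to one batch
    unless a cell sidecar exists.

    ``genes_as_rows`` states the orientation of the stored matrix explicitly
    (no auto-detection).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    gpath, cpath = _sidecar_paths(path)

    if format == "mtx":
        mat = spio.mmread(path)
        counts = _as_int_matrix(mat)
        if not genes_as_rows:
            counts = counts.T
        genes = pd.read_csv(gpath, sep="\t")
        cells = pd.read_csv(cpath, sep="\t")
    elif format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        counts = _as_int_matrix(df.to_numpy())
        if not genes_as_rows:
            counts = counts.T
            gene_index = np.asarray(df.columns, dtype=object)
            cell_index = np.asarray(df.index, dtype=object)
        else:
            gene_index = np.asarray(df.index, dtype=object)
            cell_index = np.asarray(df.columns, dtype=object)
        if gpath.exists():
            genes = pd.read_csv(gpath, sep="\t")
        else:
            genes = pd.DataFrame({"id": gene_index, "is_spike": False})
        if cpath.exists():
            cells = pd.read_csv(cpath, sep="\t")
        else:
            cells = pd.DataFrame({"id": cell_index, "batch": "batch1"})
    else:
        raise ValueError(f"unknown format {format!r} (use 'mtx' or 'tsv')")

    is_spike = genes["is_spike"].to_numpy(dtype=bool)
    spike_input = None
    if "spike_input" in genes.columns and is_spike.any():
        spike_input = genes.loc[is_spike, "spike_input"].to_numpy(dtype=float)
    return ExpressionDataset(
        counts=counts,
        gene_ids=genes["id"].to_numpy(dtype=object),
        is_spike=is_spike,
        batch=cells["batch"].to_numpy(),
        spike_input=spike_input,
        cell_ids=cells["id"].to_numpy(dtype=object),
    )


def write_counts(ds: ExpressionDataset, path: str | Path, format: str = "mtx") -> None:
    """Write a dataset in one of the supported formats (with sidecars)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    gpath, cpath = _sidecar_paths(path)

    spike_input_col = np.full(ds.n_genes, np.nan)
    if ds.spike_input is not None:
        spike_input_col[ds.is_spike] = ds.spike_input
    genes = pd.DataFrame(
        {"id": ds.gene_ids, "is_spike": ds.is_spike, "spike_input": spike_input_col}
    )
    cells = pd.DataFrame({"id": ds.cell_ids, "batch": ds.batch})

    if format == "mtx":
        spio.mmwrite(path, sparse.coo_matrix(ds.counts), field="integer")
        genes.to_csv(gpath, sep="\t", index=False)
        cells.to_csv(cpath, sep="\t", index=False)
    elif format == "tsv":
        df = pd.DataFrame(ds.counts, index=ds.gene_ids, columns=ds.cell_ids)
        df.to_csv(path, sep="\t")
        genes.to_csv(gpath, sep="\t", index=False)
        cells.to_csv(cpath, sep="\t", index=False)
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Gene filtering
# ---------------------------------------------------------------------------

def filter_genes(
    ds: ExpressionDataset,
    min_mean_count: float = 1.0,
    min_cells_detected: int = 2,
) -> tuple[ExpressionDataset, pd.DataFrame]:
    """Remove lowly-expressed biological genes and undetected spike-ins.

    A biological gene is kept iff its mean count across all cells is
    >= ``min_mean_count`` AND it is detected (count > 0) in at least
    ``min_cells_detected`` cells. A spike-in gene is kept iff its total
    count is positive (undetected spike-ins carry no information about the
    technical model).

    Returns the filtered dataset and a per-gene removal report.
    """
    if min_mean_count < 0 or min_cells_detected < 0:
        raise ValueError("filter thresholds must be non-negative")
    mean_count = ds.counts.mean(axis=1)
    n_detected = (ds.counts > 0).sum(axis=1)
    total = ds.counts.sum(axis=1)

    keep = np.where(
        ds.is_spike,
        total > 0,
        (mean_count >= min_mean_count) & (n_detected >= min_cells_detected),
    )
    report = pd.DataFrame(
        {
            "id": ds.gene_ids,
            "is_spike": ds.is_spike,
            "mean_count": mean_count,
            "n_cells_detected": n_detected,
            "kept": keep,
        }
    )
    if not keep[~ds.is_spike].any():
        raise ValidationError("filtering removed every biological gene")
    return ds.subset_genes(keep), report
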