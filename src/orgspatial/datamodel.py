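"""Core in-memory containers for spatial single-cell datasets.

A :class:`SpatialDataset` holds, for one experiment, the cell centroids in
micrometres, per-cell sample and condition labels, and an aligned
cells x genes integer count matrix (stored sparsely).  All transforms in
this package return new objects; datasets are never mutated in place.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import sparse


def _as_str_array(values) -> np.ndarray:
    return np.asarray(values, dtype=object)


@dataclass
class SpatialDataset:
    """Cells with centroids, sample/condition labels and a count matrix.

    Parameters
    ----------
    cell_ids
        Unique cell identifiers, length ``n_cells``.
    x, y
        Centroid coordinates in micrometres (arbitrary origin).
    sample_id
        Section / replicate identifier per cell.
    condition
        Condition label per cell (e.g. ``control`` / ``MCT8``).
    counts
        Nonnegative integer matrix, ``n_cells x n_genes`` (sparse CSR).
    gene_ids
        Unique gene identifiers, length ``n_genes``.
    cell_type
        Optional per-cell type label, filled by
        :func:`orgspatial.annotate.assign_cell_types`.
    """

    cell_ids: np.ndarray
    x: np.ndarray
    y: np.ndarray
    sample_id: np.ndarray
    condition: np.ndarray
    counts: sparse.csr_matrix
    gene_ids: np.ndarray
    cell_type: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.cell_ids = _as_str_array(self.cell_ids)
        self.gene_ids = _as_str_array(self.gene_ids)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.sample_id = _as_str_array(self.sample_id)
        self.condition = _as_str_array(self.condition)
        if not sparse.issparse(self.counts):
            self.counts = sparse.csr_matrix(np.asarray(self.counts))
        else:
            self.counts = sparse.csr_matrix(self.counts)
        if self.cell_type is not None:
            self.cell_type = _as_str_array(self.cell_type)
        n, g = self.counts.shape
        if len(self.cell_ids) != n:
            raise ValueError(
                f"counts has {n} rows but {len(self.cell_ids)} cell IDs"
            )
        if len(self.gene_ids) != g:
            raise ValueError(
                f"counts has {g} columns but {len(self.gene_ids)} gene IDs"
            )
        for name in ("x", "y", "sample_id", "condition"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"field {name!r} has wrong length")
        if self.cell_type is not None and len(self.cell_type) != n:
            raise ValueError("cell_type has wrong length")

    # -- basic properties -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def total_counts(self) -> np.ndarray:
        """Total transcript count per cell."""
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def genes_detected(self) -> np.ndarray:
        """Number of genes with at least one transcript, per cell."""
        return np.diff(self.counts.indptr)

    def gene_index(self, genes) -> np.ndarray:
        """Column indices for ``genes``; raises KeyError for unknowns."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([lookup[g] for g in genes], dtype=int)
        except KeyError as exc:
            raise KeyError(f"gene {exc.args[0]!r} not in dataset") from None

    # -- derived views ----------------------------------------------------
    def subset_cells(self, mask) -> "SpatialDataset":
        """New dataset restricted to cells where ``mask`` is True."""
        mask = np.asarray(mask)
        if mask.dtype == bool and len(mask) != self.n_cells:
            raise ValueError("boolean mask has wrong length")
        return SpatialDataset(
            cell_ids=self.cell_ids[mask],
            x=self.x[mask],
            y=self.y[mask],
            sample_id=self.sample_id[mask],
            condition=self.condition[mask],
            counts=self.counts[mask],
            gene_ids=self.gene_ids.copy(),
            cell_type=None if self.cell_type is None else self.cell_type[mask],
        )

    def with_cell_types(self, labels) -> "SpatialDataset":
        """Copy of the dataset with per-cell type labels attached."""
        labels = _as_str_array(labels)
        if len(labels) != self.n_cells:
            raise ValueError("labels must align with cells")
        return replace(self, cell_type=labels)

    def metadata_frame(self) -> pd.DataFrame:
        """Per-cell metadata as a DataFrame indexed by cell ID."""
        data = {
            "x": self.x,
            "y": self.y,
            "sample": self.sample_id,
            "condition": self.condition,
        }
        if self.cell_type is not None:
            data["cell_type"] = self.cell_type
        return pd.DataFrame(data, index=pd.Index(self.cell_ids, name="cell_id"))

    def equals(self, other: "SpatialDataset") -> bool:
        """Field-wise equality (integer counts compared exactly)."""
        if self.counts.shape != other.counts.shape:
            return False
        same_meta = (
            np.array_equal(self.cell_ids, other.cell_ids)
            and np.array_equal(self.gene_ids, other.gene_ids)
            and np.array_equal(self.x, other.x)
            and np.array_equal(self.y, other.y)
            and np.array_equal(self.sample_id, other.sample_id)
            and np.array_equal(self.condition, other.condition)
        )
        if not same_meta:
            return False
        if (self.cell_type is None) != (other.cell_type is None):
            return False
        if self.cell_type is not None and not np.array_equal(
            self.cell_type, other.cell_type
        ):
            return False
        return (self.counts != other.counts).nnz == 0


@dataclass
class ExpressionMatrix:
    """Log-normalized expression aligned to a :class:`SpatialDataset`.

    ``values[c, g] = ln(1 + counts[c, g] * norm_scale / total(c))`` where
    the per-cell total runs over all genes in the panel.
    """

    values: np.ndarray
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    norm_scale: float = 10_000.0
    log_base: str = "e"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_ids = _as_str_array(self.cell_ids)
        self.gene_ids = _as_str_array(self.gene_ids)
        if self.values.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValueError("values shape does not match cell/gene IDs")

    def gene_index(self, genes) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([lookup[g] for g in genes], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.cell_ids, name="cell_id"),
            columns=self.gene_ids,
        )
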