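"""Cell-level quality control and log-normalization.

Two QC dialects are provided.  The spatial (imaging panel) filter is
deliberately relaxed — keep cells with more than 15 genes detected and
more than 20 transcripts — because imaging panels are shallow.  The
split-pool scRNA filter uses the usual whole-transcriptome bounds on
genes detected, total counts and mitochondrial fraction.  All boundaries
are strict/inclusive exactly as configured and are recorded in the QC
report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import sparse

from .datamodel import ExpressionMatrix, SpatialDataset

logger = logging.getLogger(__name__)


@dataclass
class QCThresholds:
    """Cell-filter thresholds.

    ``spatial_min_genes`` / ``spatial_min_counts`` are exclusive lower
    bounds (a cell must exceed them).  The scRNA ranges are inclusive and
    the mitochondrial bound is a strict upper bound.
    """

    spatial_min_genes: int = 15
    spatial_min_counts: int = 20
    sc_gene_range: tuple[int, int] = (500, 10_000)
    sc_count_range: tuple[int, int] = (1_000, 15_000)
    sc_max_mito_frac: float = 0.10
    mito_prefix: str = "MT-"

    def __post_init__(self) -> None:
        if self.sc_gene_range[0] > self.sc_gene_range[1]:
            raise ValueError("sc_gene_range is not ordered")
        if self.sc_count_range[0] > self.sc_count_range[1]:
            raise ValueError("sc_count_range is not ordered")
        if not 0.0 <= self.sc_max_mito_frac <= 1.0:
            raise ValueError("sc_max_mito_frac must lie in [0, 1]")


@dataclass
class QCReport:
    """Kept/removed cell counts per sample plus the thresholds applied."""

    kept: dict
    removed: dict
    thresholds: dict
    doublet_flags: dict | None = field(default=None)  # externally supplied

    @property
    def n_kept(self) -> int:
        return int(sum(self.kept.values()))

    @property
    def n_removed(self) -> int:
        return int(sum(self.removed.values()))

    def to_dict(self) -> dict:
        return {
            "kept": self.kept,
            "removed": self.removed,
            "thresholds": self.thresholds,
            "doublet_flags": self.doublet_flags,
        }


def _per_sample_counts(sample_id: np.ndarray, keep: np.ndarray):
    kept: dict[str, int] = {}
    removed: dict[str, int] = {}
    for s in np.unique(sample_id):
        in_s = sample_id == s
        kept[str(s)] = int(np.sum(keep & in_s))
        removed[str(s)] = int(np.sum(~keep & in_s))
    return kept, removed


def filter_cells_spatial(
    ds: SpatialDataset, thr: QCThresholds | None = None
) -> tuple[SpatialDataset, QCReport]:
    """Relaxed QC for imaging-panel data.

    Keeps cells with strictly more than ``thr.spatial_min_genes`` genes
    detected and strictly more than ``thr.spatial_min_counts`` total
    transcripts.  Returns the filtered dataset and a per-sample report.
    """
    thr = thr or QCThresholds()
    keep = (ds.genes_detected() > thr.spatial_min_genes) & (
        ds.total_counts() > thr.spatial_min_counts
    )
    if not keep.any():
        logger.warning("spatial QC removed every cell")
    kept, removed = _per_sample_counts(ds.sample_id, keep)
    report = QCReport(kept=kept, removed=removed, thresholds=asdict(thr))
    return ds.subset_cells(keep), report


def filter_cells_scrna(
    counts,
    gene_ids,
    thr: QCThresholds | None = None,
    sample_id=None,
):
    """QC for whole-transcriptome (split-pool) scRNA counts.

    Keeps cells with genes detected within ``sc_gene_range`` (inclusive),
    total counts within ``sc_count_range`` (inclusive) and mitochondrial
    fraction strictly below ``sc_max_mito_frac``.  Mitochondrial genes are
    identified by ``mito_prefix``; if none match, the mitochondrial filter
    passes everything through with a warning.

    Returns ``(keep_mask, report)``; the caller subsets its own container.
    """
    thr = thr or QCThresholds()
    mat = sparse.csr_matrix(counts)
    gene_ids = np.asarray(gene_ids, dtype=object)
    n_cells = mat.shape[0]
    if sample_id is None:
        sample_id = np.array(["all"] * n_cells, dtype=object)
    else:
        sample_id = np.asarray(sample_id, dtype=object)

    genes_det = np.diff(mat.indptr)
    totals = np.asarray(mat.sum(axis=1)).ravel()
    is_mito = np.array([str(g).startswith(thr.mito_prefix) for g in gene_ids])
    if is_mito.any():
        mito_counts = np.asarray(mat[:, is_mito].sum(axis=1)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)
        mito_ok = mito_frac < thr.sc_max_mito_frac
    else:
        logger.warning(
            "no genes match mito_prefix %r; mitochondrial filter skipped",
            thr.mito_prefix,
        )
        mito_ok = np.ones(n_cells, dtype=bool)

    lo_g, hi_g = thr.sc_gene_range
    lo_c, hi_c = thr.sc_count_range
    keep = (
        (genes_det >= lo_g)
        & (genes_det <= hi_g)
        & (totals >= lo_c)
        & (totals <= hi_c)
        & mito_ok
    )
    kept, removed = _per_sample_counts(sample_id, keep)
    report = QCReport(kept=kept, removed=removed, thresholds=asdict(thr))
    return keep, report


def lognormalize(ds: SpatialDataset, scale: float = 10_000.0) -> ExpressionMatrix:
    """Library-size normalization over all panel genes, then natural log1p.

    ``value(c, g) = ln(1 + count(c, g) * scale / total(c))`` where
    ``total(c)`` sums every gene in the panel.  Cells with zero total are
    an error: run QC first.
    """
    totals = ds.total_counts()
    if (totals == 0).any():
        bad = ds.cell_ids[totals == 0][:5].tolist()
        raise ValueError(
            f"cells with zero total counts (e.g. {bad}); run QC before normalizing"
        )
    dense = ds.counts.toarray().astype(float)
    values = np.log1p(dense * (scale / totals[:, None]))
    return ExpressionMatrix(
        values=values,
        cell_ids=ds.cell_ids.copy(),
        gene_ids=ds.gene_ids.copy(),
        norm_scale=float(scale),
    )
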