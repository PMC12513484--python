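"""Readers/writers for spatial molecular imager flatfiles.

Flatfiles are the CSV export of an imaging-based spatial platform: a
cells x genes count table plus per-cell metadata carrying centroid
coordinates (micrometres), section/sample ID and condition label.  Column
names vary between instrument software versions, so they are configurable
through :class:`FlatfileColumns`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as scipy_io
from scipy import sparse

from .datamodel import SpatialDataset

logger = logging.getLogger(__name__)


class FlatfileFormatError(ValueError):
    """A flatfile is missing a required column or violates the format."""


@dataclass
class FlatfileColumns:
    """Metadata column dialect. Defaults match a plain AtoMx-style export."""

    cell_id: str = "cell_id"
    x: str = "x"
    y: str = "y"
    sample: str = "sample"
    condition: str = "condition"
    cell_type: str = "cell_type"  # optional on read, written when present

    def required(self) -> list[str]:
        return [self.x, self.y, self.sample, self.condition]


DEFAULT_COLUMNS = FlatfileColumns()


def read_flatfiles(
    counts_path,
    metadata_path,
    columns: FlatfileColumns = DEFAULT_COLUMNS,
) -> SpatialDataset:
    """Read a counts CSV and a metadata CSV into a :class:`SpatialDataset`.

    The counts CSV must have a cell-ID index column and one column per
    gene; the metadata CSV must contain the cell-ID, x, y, sample and
    condition columns named by ``columns``.  Cells present in only one of
    the two files are dropped (a warning reports how many).

    Raises
    ------
    FlatfileFormatError
        If a required column is missing or cell IDs are duplicated.
    """
    counts = pd.read_csv(counts_path, index_col=0)
    # round_trip: centroid floats must survive write->read bit-exactly
    meta = pd.read_csv(metadata_path, float_precision="round_trip")

    if columns.cell_id not in meta.columns:
        raise FlatfileFormatError(
            f"metadata file is missing required column {columns.cell_id!r}"
        )
    for col in columns.required():
        if col not in meta.columns:
            raise FlatfileFormatError(
                f"metadata file is missing required column {col!r}"
            )
    meta = meta.set_index(columns.cell_id)
    meta.index = meta.index.astype(str)
    counts.index = counts.index.astype(str)

    if counts.index.duplicated().any():
        dups = counts.index[counts.index.duplicated()].unique().tolist()
        raise FlatfileFormatError(f"duplicate cell IDs in counts file: {dups[:5]}")
    if meta.index.duplicated().any():
        dups = meta.index[meta.index.duplicated()].unique().tolist()
        raise FlatfileFormatError(f"duplicate cell IDs in metadata file: {dups[:5]}")

    common = counts.index.intersection(meta.index)
    n_dropped = (len(counts) - len(common)) + (len(meta) - len(common))
    if n_dropped:
        logger.warning(
            "dropped %d cells present in only one of counts/metadata", n_dropped
        )
    counts = counts.loc[common]
    meta = meta.loc[common]

    values = counts.to_numpy()
    if values.size and not np.issubdtype(values.dtype, np.number):
        raise FlatfileFormatError("counts file contains non-numeric entries")

    cell_type = None
    if columns.cell_type in meta.columns:
        cell_type = meta[columns.cell_type].to_numpy()

    return SpatialDataset(
        cell_ids=common.to_numpy(),
        x=meta[columns.x].to_numpy(dtype=float),
        y=meta[columns.y].to_numpy(dtype=float),
        sample_id=meta[columns.sample].astype(str).to_numpy(),
        condition=meta[columns.condition].astype(str).to_numpy(),
        counts=sparse.csr_matrix(np.asarray(values, dtype=np.int64)),
        gene_ids=counts.columns.to_numpy(),
        cell_type=cell_type,
    )


def write_flatfiles(
    ds: SpatialDataset,
    out_dir,
    columns: FlatfileColumns = DEFAULT_COLUMNS,
) -> dict[str, Path]:
    """Write ``ds`` as counts + metadata CSVs under ``out_dir``.

    The written pair round-trips bit-exactly through
    :func:`read_flatfiles` for integer counts and string fields.
    Returns the written paths keyed by ``"counts"`` and ``"metadata"``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counts_path = out_dir / "counts.csv"
    meta_path = out_dir / "metadata.csv"

    counts_df = pd.DataFrame(
        ds.counts.toarray(),
        index=pd.Index(ds.cell_ids, name=columns.cell_id),
        columns=ds.gene_ids,
    )
    counts_df.to_csv(counts_path)

    meta = ds.metadata_frame()
    meta.index.name = columns.cell_id
    meta = meta.rename(
        columns={
            "x": columns.x,
            "y": columns.y,
            "sample": columns.sample,
            "condition": columns.condition,
            "cell_type": columns.cell_type,
        }
    )
    meta.to_csv(meta_path)
    return {"counts": counts_path, "metadata": meta_path}


def write_mtx(ds: SpatialDataset, out_dir) -> dict[str, Path]:
    """Interoperability export: MTX matrix + barcodes/features TSVs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out_dir / "matrix.mtx",
        "barcodes": out_dir / "barcodes.tsv",
        "features": out_dir / "features.tsv",
    }
    scipy_io.mmwrite(paths["matrix"], sparse.coo_matrix(ds.counts))
    pd.Series(ds.cell_ids).to_csv(paths["barcodes"], index=False, header=False, sep="\t")
    pd.Series(ds.gene_ids).to_csv(paths["features"], index=False, header=False, sep="\t")
    return paths


@dataclass
class Violation:
    rule: str
    offenders: list = field(default_factory=list)

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return f"{self.rule}: {self.offenders}"


def validate_dataset(ds: SpatialDataset) -> list[Violation]:
    """Check the dataset invariants; return a (possibly empty) report.

    Each violation names the broken rule and the offending cell/gene IDs.
    This never raises: an empty list means all invariants hold.
    """
    report: list[Violation] = []

    ids, idx, counts_per = np.unique(ds.cell_ids, return_index=True, return_counts=True)
    if (counts_per > 1).any():
        report.append(Violation("duplicate cell IDs", ids[counts_per > 1].tolist()))
    gids, gcounts = np.unique(ds.gene_ids, return_counts=True)
    if (gcounts > 1).any():
        report.append(Violation("duplicate gene IDs", gids[gcounts > 1].tolist()))

    bad_coord = ~(np.isfinite(ds.x) & np.isfinite(ds.y))
    if bad_coord.any():
        report.append(
            Violation("non-finite coordinates", ds.cell_ids[bad_coord].tolist())
        )

    coo = sparse.coo_matrix(ds.counts)
    neg = coo.data < 0
    if neg.any():
        offenders = [
            (str(ds.cell_ids[r]), str(ds.gene_ids[c]))
            for r, c in zip(coo.row[neg], coo.col[neg])
        ]
        report.append(Violation("negative counts", offenders))
    if coo.data.size and not np.allclose(coo.data, np.round(coo.data)):
        frac = ~np.isclose(coo.data, np.round(coo.data))
        offenders = [
            (str(ds.cell_ids[r]), str(ds.gene_ids[c]))
            for r, c in zip(coo.row[frac], coo.col[frac])
        ]
        report.append(Violation("non-integer counts", offenders))

    return report
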