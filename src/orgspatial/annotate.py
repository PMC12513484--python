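"""Exclusive marker-based cell-type assignment.

A cell is labelled with type T when it expresses at least one of T's
marker genes and none of the markers of any other type; every other cell
is labelled ``undefined``.  "Expressed" means a raw count of at least
``expressed_min_count`` (default 1) — imaging panels are shallow, so the
rule operates on raw counts rather than normalized values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datamodel import SpatialDataset

logger = logging.getLogger(__name__)

UNDEFINED = "undefined"

#: Marker sets identifying the three neural populations of a cortical
#: organoid section: neural precursors, intermediate progenitors and
#: projection neurons.
CORTICAL_PANEL = {
    "NPC": ["VIM", "NOTCH1", "BMP7"],
    "IPC": ["EOMES", "BMP5"],
    "neuron": ["GATA3", "DCN", "SPOCK2", "SOX4"],
}


@dataclass
class MarkerPanel:
    """Mapping from cell-type name to its (pairwise disjoint) marker set."""

    markers: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in CORTICAL_PANEL.items()}
    )
    expressed_min_count: int = 1

    def __post_init__(self) -> None:
        if self.expressed_min_count < 1:
            raise ValueError("expressed_min_count must be >= 1")
        seen: dict[str, str] = {}
        for ctype, genes in self.markers.items():
            if UNDEFINED == ctype:
                raise ValueError(f"{UNDEFINED!r} is reserved and cannot be a type name")
            for g in genes:
                if g in seen:
                    raise ValueError(
                        f"marker {g!r} appears in both {seen[g]!r} and {ctype!r}; "
                        "marker sets must be pairwise disjoint"
                    )
                seen[g] = ctype

    @property
    def types(self) -> list[str]:
        return list(self.markers)

    def restricted_to(self, gene_ids) -> "MarkerPanel":
        """Drop markers absent from ``gene_ids`` (warning per dropped gene)."""
        available = set(map(str, gene_ids))
        kept: dict[str, list[str]] = {}
        for ctype, genes in self.markers.items():
            present = [g for g in genes if g in available]
            missing = [g for g in genes if g not in available]
            if missing:
                logger.warning(
                    "markers %s for type %r absent from dataset; dropped",
                    missing,
                    ctype,
                )
            kept[ctype] = present
        return MarkerPanel(markers=kept, expressed_min_count=self.expressed_min_count)

    @classmethod
    def from_file(cls, path, expressed_min_count: int = 1) -> "MarkerPanel":
        """Load a ``{type: [genes...]}`` mapping from YAML or JSON."""
        with open(Path(path)) as fh:
            markers = yaml.safe_load(fh)
        if not isinstance(markers, dict):
            raise ValueError("panel file must map cell types to marker lists")
        return cls(
            markers={k: list(v) for k, v in markers.items()},
            expressed_min_count=expressed_min_count,
        )

    def to_file(self, path) -> None:
        with open(Path(path), "w") as fh:
            yaml.safe_dump(self.markers, fh, sort_keys=False)


def assign_cell_types(ds: SpatialDataset, panel: MarkerPanel) -> np.ndarray:
    """Assign each cell a type by the exclusive-marker rule.

    Returns an array of labels in ``panel.types() + [UNDEFINED]``, aligned
    to ``ds.cell_ids``.  Deterministic: independent of gene column order.
    """
    if not panel.markers or all(len(v) == 0 for v in panel.markers.values()):
        raise ValueError("marker panel is empty")
    panel = panel.restricted_to(ds.gene_ids)

    labels = np.full(ds.n_cells, UNDEFINED, dtype=object)
    # per-type indicator: cell expresses >=1 marker of that type
    expressed = {}
    for ctype, genes in panel.markers.items():
        if not genes:
            expressed[ctype] = np.zeros(ds.n_cells, dtype=bool)
            continue
        cols = ds.gene_index(genes)
        sub = ds.counts[:, cols]
        expressed[ctype] = (
            np.asarray((sub >= panel.expressed_min_count).sum(axis=1)).ravel() > 0
        )
    n_types_on = np.sum(np.column_stack(list(expressed.values())), axis=1)
    for ctype, mask in expressed.items():
        labels[mask & (n_types_on == 1)] = ctype
    return labels


def annotation_summary(labels, ds: SpatialDataset) -> pd.DataFrame:
    """Cell counts by (sample, condition) x cell type; totals conserved."""
    labels = np.asarray(labels, dtype=object)
    if len(labels) != ds.n_cells:
        raise ValueError("labels must align with cells")
    if ds.n_cells == 0:
        return pd.DataFrame()
    df = pd.DataFrame(
        {
            "sample": ds.sample_id,
            "condition": ds.condition,
            "cell_type": labels,
        }
    )
    table = (
        df.groupby(["sample", "condition", "cell_type"], sort=True)
        .size()
        .unstack("cell_type", fill_value=0)
    )
    table.columns.name = None
    return table
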