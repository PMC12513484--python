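"""Seeded generator of synthetic spatial single-cell datasets.

The generator emulates the statistical structure of an imaging-based
spatial transcriptomics experiment on organoid sections: two conditions
with replicate sections, a clustered spatial layout (homogeneous Poisson
background plus Thomas-process clusters) that produces both sparse and
dense neighborhoods, three marker-defined cell types plus undefined
cells, and negative-binomial counts with planted condition effects and
planted density effects.  Every dataset carries a :class:`SimTruth`
recording the planted parameters so downstream estimates can be checked
against the truth.

All randomness flows from a single integer seed through spawned
``numpy.random.Generator`` streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .annotate import CORTICAL_PANEL, UNDEFINED, MarkerPanel
from .datamodel import SpatialDataset


def _default_proportions() -> dict:
    # MCT8-deficient sections carry proportionally fewer neurons and more
    # precursors, mirroring the delayed-differentiation phenotype.
    return {
        "control": {"NPC": 0.30, "IPC": 0.20, "neuron": 0.35, UNDEFINED: 0.15},
        "MCT8": {"NPC": 0.40, "IPC": 0.25, "neuron": 0.20, UNDEFINED: 0.15},
    }


def _default_de_effects() -> dict:
    return {}


@dataclass
class SimConfig:
    """Parameters of the synthetic experiment.

    Layout: each section covers ``area`` (micrometres) and receives a
    homogeneous Poisson background of intensity ``background_intensity``
    (cells per square micrometre) plus ``n_clusters`` Thomas-process
    clusters (uniform parents; Poisson(``cluster_mean_size``) offspring
    scattered with isotropic Gaussian sd ``cluster_sd``).  The defaults
    put roughly 100 cells on a 1.5 x 1.5 mm section, with both sparse
    (n = 1 within 100 um) and dense (n >= 5) neighborhoods populated.

    Counts: gene g in cell c is negative binomial with dispersion
    ``nb_dispersion`` and mean ``nb_mean_hi`` if g is a marker of c's
    type, ``density_gene_mean`` if g is a planted density-effect gene,
    ``marker_offtype_mean`` if g is a marker of another type (marker
    probes are highly type-specific, so off-type leakage is rare), and
    ``nb_mean_lo`` otherwise.  The mean is multiplied by
    ``2**effect`` for planted condition effects (``de_effects``, applied
    in ``de_condition``) and by ``2**(slope * n(c))`` for planted
    density effects (``density_effects``).
    """

    area: tuple[float, float] = (1500.0, 1500.0)  # um
    background_intensity: float = 2.5e-5  # cells / um^2
    n_clusters: int = 3
    cluster_mean_size: float = 13.0
    cluster_sd: float = 40.0  # um
    conditions: tuple[str, ...] = ("control", "MCT8")
    sections_per_condition: int = 2
    type_proportions: dict = field(default_factory=_default_proportions)
    panel: MarkerPanel = field(default_factory=MarkerPanel)
    n_genes: int = 60
    nb_mean_hi: float = 4.0
    nb_mean_lo: float = 0.6
    marker_offtype_mean: float = 0.01
    density_gene_mean: float = 5.0
    nb_dispersion: float = 2.0
    de_effects: dict = field(default_factory=_default_de_effects)  # gene -> log2FC
    de_condition: str = "MCT8"
    density_effects: dict = field(default_factory=dict)  # gene -> log2 per unit n
    density_radius: float = 100.0  # um
    seed: int = 0

    def __post_init__(self) -> None:
        if self.area[0] <= 0 or self.area[1] <= 0:
            raise ValueError("section area must be positive")
        if self.background_intensity <= 0 or self.nb_dispersion <= 0:
            raise ValueError("intensities and dispersion must be positive")
        if min(self.nb_mean_hi, self.nb_mean_lo, self.density_gene_mean) <= 0:
            raise ValueError("negative-binomial means must be positive")
        for cond, props in self.type_proportions.items():
            total = sum(props.values())
            if not np.isclose(total, 1.0):
                raise ValueError(
                    f"type proportions for {cond!r} sum to {total}, expected 1"
                )

    def gene_ids(self) -> np.ndarray:
        """Marker genes, then planted genes, then numbered filler genes."""
        markers = [g for genes in self.panel.markers.values() for g in genes]
        planted = [
            g
            for g in list(self.de_effects) + list(self.density_effects)
            if g not in markers
        ]
        named = list(dict.fromkeys(markers + planted))
        if len(named) > self.n_genes:
            raise ValueError(
                f"{len(named)} named genes exceed n_genes={self.n_genes}"
            )
        filler = [f"G{i:03d}" for i in range(self.n_genes - len(named))]
        return np.array(named + filler, dtype=object)


@dataclass
class SimTruth:
    """The planted parameters realized in one synthetic dataset."""

    cell_type: np.ndarray
    n: np.ndarray
    condition: np.ndarray
    de_effects: dict
    de_condition: str
    density_effects: dict
    seed: int


def spawn_seeds(base_seed: int, n: int) -> list[int]:
    """n well-separated 31-bit seeds derived from one base seed.

    Replicated experiments must not use consecutive raw integers as
    seeds: the leading outputs of generators seeded 0, 1, 2, ... carry
    small but measurable cross-seed correlations that bias Monte-Carlo
    averages.  Hashing through ``SeedSequence`` removes this.
    """
    state = np.random.SeedSequence(base_seed).generate_state(n) & 0x7FFFFFFF
    return [int(s) for s in state]


def _rngs(seed: int, n_streams: int) -> list[np.random.Generator]:
    return [np.random.Generator(np.random.PCG64(s)) for s in np.random.SeedSequence(seed).spawn(n_streams)]


def simulate_layout(cfg: SimConfig) -> pd.DataFrame:
    """Draw cell centroids for every section of the experiment.

    Each section receives a homogeneous Poisson background plus
    Thomas-process clusters whose parents fall uniformly in the section.
    Fully reproducible from ``cfg.seed``.  Returns a frame with columns
    ``x, y, sample, condition``.
    """
    rng = _rngs(cfg.seed, 2)[0]
    w, h = cfg.area
    frames = []
    for cond in cfg.conditions:
        for k in range(cfg.sections_per_condition):
            sample = f"{cond}_s{k + 1}"
            n_bg = rng.poisson(cfg.background_intensity * w * h)
            xs = [rng.uniform(0, w, n_bg)]
            ys = [rng.uniform(0, h, n_bg)]
            for _ in range(cfg.n_clusters):
                px, py = rng.uniform(0, w), rng.uniform(0, h)
                n_off = rng.poisson(cfg.cluster_mean_size)
                xs.append(px + rng.normal(0, cfg.cluster_sd, n_off))
                ys.append(py + rng.normal(0, cfg.cluster_sd, n_off))
            x = np.concatenate(xs)
            y = np.concatenate(ys)
            frames.append(
                pd.DataFrame({"x": x, "y": y, "sample": sample, "condition": cond})
            )
    return pd.concat(frames, ignore_index=True)


def _neighbor_counts(layout: pd.DataFrame, radius: float) -> np.ndarray:
    from .spatial import neighborhood_metric  # avoid import cycle at module load

    ds = SpatialDataset(
        cell_ids=np.array([f"c{i}" for i in range(len(layout))], dtype=object),
        x=layout["x"].to_numpy(),
        y=layout["y"].to_numpy(),
        sample_id=layout["sample"].to_numpy(),
        condition=layout["condition"].to_numpy(),
        counts=sparse.csr_matrix((len(layout), 0), dtype=np.int64),
        gene_ids=np.array([], dtype=object),
    )
    return neighborhood_metric(ds, r=radius).n


def simulate_counts(
    layout: pd.DataFrame, cfg: SimConfig
) -> tuple[SpatialDataset, SimTruth]:
    """Draw cell types and negative-binomial counts on a given layout.

    Types are drawn per condition from ``cfg.type_proportions``;
    per-cell, per-gene means follow the rules documented on
    :class:`SimConfig`, and counts are negative binomial with dispersion
    ``cfg.nb_dispersion`` (variance ``mu + mu^2 / dispersion``).
    """
    rng = _rngs(cfg.seed, 2)[1]
    gene_ids = cfg.gene_ids()
    gene_pos = {g: j for j, g in enumerate(gene_ids)}
    missing = [
        g
        for genes in cfg.panel.markers.values()
        for g in genes
        if g not in gene_pos
    ]
    if missing:
        raise ValueError(f"panel genes missing from gene universe: {missing}")

    n_cells = len(layout)
    conditions = layout["condition"].to_numpy()
    cell_type = np.empty(n_cells, dtype=object)
    for cond in cfg.conditions:
        mask = conditions == cond
        props = cfg.type_proportions[cond]
        names = list(props)
        cell_type[mask] = rng.choice(
            names, size=int(mask.sum()), p=[props[t] for t in names]
        )

    n = _neighbor_counts(layout, cfg.density_radius)

    mu = np.full((n_cells, cfg.n_genes), cfg.nb_mean_lo)
    all_marker_cols = []
    for ctype, genes in cfg.panel.markers.items():
        cols = [gene_pos[g] for g in genes]
        all_marker_cols.extend(cols)
        mu[:, cols] = cfg.marker_offtype_mean
        mu[np.ix_(cell_type == ctype, cols)] = cfg.nb_mean_hi
    for g, slope in cfg.density_effects.items():
        j = gene_pos[g]
        if j not in all_marker_cols:
            mu[:, j] = cfg.density_gene_mean
        mu[:, j] = mu[:, j] * 2.0 ** (slope * n)
    for g, lfc in cfg.de_effects.items():
        j = gene_pos[g]
        mu[conditions == cfg.de_condition, j] *= 2.0**lfc

    r = cfg.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu))

    ds = SpatialDataset(
        cell_ids=np.array([f"cell_{i:05d}" for i in range(n_cells)], dtype=object),
        x=layout["x"].to_numpy(),
        y=layout["y"].to_numpy(),
        sample_id=layout["sample"].to_numpy(),
        condition=conditions,
        counts=sparse.csr_matrix(counts.astype(np.int64)),
        gene_ids=gene_ids,
    )
    truth = SimTruth(
        cell_type=cell_type,
        n=n,
        condition=conditions.copy(),
        de_effects=dict(cfg.de_effects),
        de_condition=cfg.de_condition,
        density_effects=dict(cfg.density_effects),
        seed=cfg.seed,
    )
    return ds, truth


def simulate_dataset(cfg: SimConfig) -> tuple[SpatialDataset, SimTruth]:
    """Convenience wrapper: layout plus counts in one call."""
    return simulate_counts(simulate_layout(cfg), cfg)


def null_config(
    seed: int, n_genes: int = 200, background_intensity: float = 3.6e-5
) -> SimConfig:
    """A no-effect experiment for calibration checks: no condition effects,
    no density effects, and identical type proportions in both conditions
    (a composition shift would itself make marker genes differential).
    The default background intensity puts ~500 cells on the four sections."""
    props = {"NPC": 0.30, "IPC": 0.20, "neuron": 0.35, UNDEFINED: 0.15}
    return SimConfig(
        n_genes=n_genes,
        background_intensity=background_intensity,
        type_proportions={"control": dict(props), "MCT8": dict(props)},
        seed=seed,
    )


FIXTURE_SEED = 20240917
FIXTURE_DE_EFFECTS = {"DEG_A": 1.5, "DEG_B": 1.5, "DEG_C": -1.5, "DEG_D": 1.5}
FIXTURE_DENSITY_EFFECTS = {"DENS_A": 0.08, "DENS_B": 0.08}


def fixture_config(seed: int = FIXTURE_SEED) -> SimConfig:
    """The reference synthetic experiment used across the test suite:
    ~400 cells on four sections, 60 genes, three types plus undefined,
    four planted condition-effect genes (|log2FC| = 1.5) and two planted
    density-effect genes (0.08 log2 per neighbor)."""
    return SimConfig(
        de_effects=dict(FIXTURE_DE_EFFECTS),
        density_effects=dict(FIXTURE_DENSITY_EFFECTS),
        seed=seed,
    )


def fixture_small(seed: int = FIXTURE_SEED) -> tuple[SpatialDataset, SimTruth]:
    """Generate the reference fixture (deterministic for a given seed)."""
    return simulate_dataset(fixture_config(seed))
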