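"""End-to-end orchestration: QC -> normalize -> annotate -> spatial
statistics -> differential expression -> composition, driven by a single
config, with a JSON run manifest for reproducibility.

Given the same config and seed the pipeline reproduces every output
table byte-for-byte; the manifest records a SHA-256 digest of each table
so reruns can be compared at a glance.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._version import __version__ as _pkg_version
from .annotate import MarkerPanel, UNDEFINED, annotation_summary, assign_cell_types
from .datamodel import SpatialDataset
from .de import DE_PRESETS, composition_chisq, pairwise_proportions, select_degs, wilcoxon_de
from .io import read_flatfiles
from .qc import QCThresholds, filter_cells_spatial, lognormalize
from .simulate import SimConfig, simulate_dataset
from .spatial import (
    compare_distances_between_conditions,
    density_expression_linear,
    density_expression_logistic,
    neighborhood_metric,
    pairwise_type_distances,
)

logger = logging.getLogger(__name__)

TABLE_NAMES = [
    "annotation_summary",
    "distance_ks",
    "neighborhood_profile",
    "density_linear",
    "density_logistic",
    "de_results",
    "composition",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class RunConfig:
    """Pipeline configuration.

    Exactly one of ``counts_path``/``metadata_path`` or ``simulate`` must
    be provided.  Defaults follow the organoid study design: 100 um
    neighborhood radius, sparse at n = 1, dense at n >= 5, and the
    imaging-panel DE preset (adjusted p < 0.05, no fold-change floor).
    """

    counts_path: str | None = None
    metadata_path: str | None = None
    simulate: SimConfig | None = None
    thresholds: QCThresholds = field(default_factory=QCThresholds)
    panel: MarkerPanel = field(default_factory=MarkerPanel)
    radius: float = 100.0
    sparse_n: int = 1
    dense_n: int = 5
    de_preset: str = "spatial_nofc"
    out_dir: str = "results"
    seed: int = 0

    def __post_init__(self) -> None:
        has_paths = self.counts_path is not None or self.metadata_path is not None
        if has_paths and self.simulate is not None:
            raise ValueError("config must give input paths OR a simulate block, not both")
        if not has_paths and self.simulate is None:
            raise ValueError("config must give input paths or a simulate block")
        if has_paths and (self.counts_path is None or self.metadata_path is None):
            raise ValueError("both counts_path and metadata_path are required")
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if self.de_preset not in DE_PRESETS:
            raise ValueError(f"unknown DE preset {self.de_preset!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(Path(path)) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        inp = raw.get("input", {})
        kwargs["counts_path"] = inp.get("counts")
        kwargs["metadata_path"] = inp.get("metadata")
        if "simulate" in raw:
            sim = dict(raw["simulate"])
            if "panel" in sim:
                sim["panel"] = MarkerPanel(markers=sim["panel"])
            kwargs["simulate"] = SimConfig(**sim)
        if "thresholds" in raw:
            kwargs["thresholds"] = QCThresholds(**raw["thresholds"])
        if "panel" in raw:
            panel = raw["panel"]
            kwargs["panel"] = (
                MarkerPanel.from_file(panel)
                if isinstance(panel, str)
                else MarkerPanel(markers=panel)
            )
        for key in ("radius", "sparse_n", "dense_n", "de_preset", "out_dir", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)

    def describe(self) -> dict:
        d = {
            "counts_path": self.counts_path,
            "metadata_path": self.metadata_path,
            "simulate": None,
            "thresholds": asdict(self.thresholds),
            "panel": {k: list(v) for k, v in self.panel.markers.items()},
            "radius": self.radius,
            "sparse_n": self.sparse_n,
            "dense_n": self.dense_n,
            "de_preset": self.de_preset,
            "seed": self.seed,
        }
        if self.simulate is not None:
            sim = asdict(self.simulate)
            sim["panel"] = {k: list(v) for k, v in self.simulate.panel.markers.items()}
            sim["conditions"] = list(self.simulate.conditions)
            sim["area"] = list(self.simulate.area)
            d["simulate"] = sim
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name: str):
    def decorator(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return decorator


@_stage("load")
def _load(cfg: RunConfig) -> SpatialDataset:
    if cfg.simulate is not None:
        sim = cfg.simulate
        if sim.seed != cfg.seed:
            sim = SimConfig(**{**asdict_simconfig(sim), "seed": cfg.seed})
        ds, _ = simulate_dataset(sim)
        return ds
    return read_flatfiles(cfg.counts_path, cfg.metadata_path)


def asdict_simconfig(sim: SimConfig) -> dict:
    d = asdict(sim)
    d["panel"] = MarkerPanel(
        markers={k: list(v) for k, v in sim.panel.markers.items()},
        expressed_min_count=sim.panel.expressed_min_count,
    )
    return d


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage and write the result tables plus ``manifest.json``.

    Writes, under ``cfg.out_dir``: ``qc_report.json``, seven CSV tables
    (annotation summary, distance/KS comparisons, neighborhood profile,
    linear and logistic density associations, DE results, composition
    tests) and a manifest with the config, package version, seed and a
    SHA-256 digest per table.  Returns ``{"tables": {...}, "manifest": path}``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    ds = _load(cfg)

    @_stage("qc")
    def do_qc():
        filtered, report = filter_cells_spatial(ds, cfg.thresholds)
        path = out / "qc_report.json"
        path.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))
        return filtered, path

    ds_f, paths["qc_report"] = do_qc()

    @_stage("normalize")
    def do_norm():
        return lognormalize(ds_f)

    expr = do_norm()

    @_stage("annotate")
    def do_annotate():
        labels = assign_cell_types(ds_f, cfg.panel)
        table = annotation_summary(labels, ds_f)
        path = out / "annotation_summary.csv"
        table.to_csv(path)
        return labels, path

    labels, paths["annotation_summary"] = do_annotate()
    ds_t = ds_f.with_cell_types(labels)

    @_stage("distances")
    def do_distances():
        rows = []
        for a, b in itertools.combinations(cfg.panel.types, 2):
            d = pairwise_type_distances(ds_t, a, b)
            if d.empty or d["condition"].nunique() < 2:
                logger.warning("pair (%s, %s): not enough data for KS", a, b)
                continue
            cmp_res = compare_distances_between_conditions(d, (a, b))
            rows.append(
                {
                    "type_a": a,
                    "type_b": b,
                    "condition_1": cmp_res.conditions[0],
                    "condition_2": cmp_res.conditions[1],
                    "n_1": cmp_res.n1,
                    "n_2": cmp_res.n2,
                    "ks_D": cmp_res.statistic,
                    "p": cmp_res.pvalue,
                }
            )
        path = out / "distance_ks.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        return path

    paths["distance_ks"] = do_distances()

    @_stage("neighborhood")
    def do_neighborhood():
        profile = neighborhood_metric(
            ds_t, r=cfg.radius, sparse_n=cfg.sparse_n, dense_n=cfg.dense_n
        )
        path = out / "neighborhood_profile.csv"
        frame = profile.to_frame()
        frame["cell_type"] = labels
        frame.to_csv(path, index=False)
        return profile, path

    profile, paths["neighborhood_profile"] = do_neighborhood()

    @_stage("density_association")
    def do_density():
        lin = density_expression_linear(expr, profile, labels)
        logi = density_expression_logistic(expr, profile, labels)
        p_lin = out / "density_linear.csv"
        p_log = out / "density_logistic.csv"
        lin.to_csv(p_lin, index=False)
        logi.to_csv(p_log, index=False)
        return p_lin, p_log

    paths["density_linear"], paths["density_logistic"] = do_density()

    @_stage("differential_expression")
    def do_de():
        conds = sorted(np.unique(ds_t.condition))
        if len(conds) != 2:
            raise ValueError(f"DE needs exactly 2 conditions, found {conds}")
        padj_max, lfc_min = DE_PRESETS[cfg.de_preset]
        frames = []
        for group in list(cfg.panel.types) + [UNDEFINED]:
            in_g = labels == group
            a = expr.values[in_g & (ds_t.condition == conds[0])]
            b = expr.values[in_g & (ds_t.condition == conds[1])]
            if len(a) < 3 or len(b) < 3:
                logger.warning("group %r too small for DE; skipped", group)
                continue
            res = wilcoxon_de(a, b, gene_ids=expr.gene_ids)
            res.insert(0, "group", group)
            sig, _ = select_degs(res, padj_max=padj_max, lfc_min=lfc_min)
            res["significant"] = res.index.isin(sig.index)
            frames.append(res)
        table = (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame(
                columns=["group", "gene", "avg_log2FC", "p", "padj", "significant"]
            )
        )
        path = out / "de_results.csv"
        table.to_csv(path, index=False)
        return path, conds

    paths["de_results"], conds = do_de()

    @_stage("composition")
    def do_composition():
        table = pd.crosstab(pd.Series(labels, name="cell_type"), ds_t.condition)
        pairwise = pairwise_proportions(table)
        chi2, df, p = composition_chisq(table)
        path = out / "composition.csv"
        pairwise.to_csv(path, index=False)
        return path, {"chi2": chi2, "df": df, "p": p}

    paths["composition"], overall = do_composition()

    manifest = {
        "package": "orgspatial",
        "version": _pkg_version,
        "seed": cfg.seed,
        "config": cfg.describe(),
        "conditions": conds,
        "composition_overall": overall,
        "tables": {name: _sha256(p) for name, p in sorted(paths.items())},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return {"tables": paths, "manifest": manifest_path}
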