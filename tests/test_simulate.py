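import numpy as np
import pandas as pd
import pytest

import orgspatial as osp
from orgspatial.annotate import UNDEFINED
from orgspatial.simulate import (
    SimConfig,
    fixture_small,
    null_config,
    simulate_counts,
    simulate_layout,
)


def test_layout_deterministic_from_seed():
    cfg = SimConfig(seed=123)
    a, b = simulate_layout(cfg), simulate_layout(cfg)
    pd.testing.assert_frame_equal(a, b)
    c = simulate_layout(SimConfig(seed=124))
    assert len(a) != len(c) or not np.allclose(a[["x", "y"]], c[["x", "y"]])


def test_background_poisson_mean():
    # no clusters, lambda * area = 50 per section: Monte-Carlo mean check
    from orgspatial.simulate import spawn_seeds

    sizes = []
    for seed in spawn_seeds(55, 500):
        cfg = SimConfig(
            seed=seed,
            n_clusters=0,
            area=(1000.0, 1000.0),
            background_intensity=5e-5,
            sections_per_condition=1,
        )
        layout = simulate_layout(cfg)
        sizes.append((layout["sample"] == "control_s1").sum())
    sem = np.sqrt(50 / 500)
    assert abs(np.mean(sizes) - 50) < 3 * sem


def test_cluster_sd_zero_collapses_offspring():
    cfg = SimConfig(
        seed=5,
        background_intensity=1e-9,
        n_clusters=2,
        cluster_mean_size=10,
        cluster_sd=0.0,
        sections_per_condition=1,
        conditions=("control",),
    )
    layout = simulate_layout(cfg)
    for s, grp in layout.groupby("sample"):
        # offspring coincide with their parents: <= n_clusters unique points
        assert len(grp[["x", "y"]].drop_duplicates()) <= cfg.n_clusters + 1


def test_zero_area_rejected():
    with pytest.raises(ValueError):
        SimConfig(area=(0.0, 100.0))


def test_counts_marginal_mean_and_dispersion():
    cfg = SimConfig(
        seed=9,
        type_proportions={"control": {"NPC": 1.0}},
        conditions=("control",),
        sections_per_condition=1,
    )
    layout = pd.DataFrame(
        {
            "x": np.random.default_rng(0).uniform(0, 50_000, 2000),
            "y": np.random.default_rng(1).uniform(0, 50_000, 2000),
            "sample": "control_s1",
            "condition": "control",
        }
    )
    ds, truth = simulate_counts(layout, cfg)
    vim = ds.counts[:, list(ds.gene_ids).index("VIM")].toarray().ravel()
    assert abs(vim.mean() - cfg.nb_mean_hi) / cfg.nb_mean_hi < 0.05
    # NB variance: mu + mu^2 / dispersion
    expect_var = cfg.nb_mean_hi + cfg.nb_mean_hi**2 / cfg.nb_dispersion
    assert abs(vim.var() - expect_var) / expect_var < 0.25


def test_truth_consistent_with_dataset(fixture_data):
    ds, truth = fixture_data
    assert len(truth.cell_type) == ds.n_cells
    prof = osp.neighborhood_metric(ds, r=100)
    np.testing.assert_array_equal(prof.n, truth.n)
    assert set(truth.de_effects) <= set(ds.gene_ids)


def test_fixture_stable_across_calls(fixture_data):
    ds, _ = fixture_data
    ds2, _ = fixture_small()
    assert ds.equals(ds2)
    assert int(ds.counts.sum()) == 19223  # frozen checksum of the fixture


def test_fixture_density_classes_populated(fixture_data):
    ds, _ = fixture_data
    cls = osp.neighborhood_metric(ds).density_class
    sparse_frac = np.mean(cls == "sparse")
    dense_frac = np.mean(cls == "dense")
    assert 0.10 <= sparse_frac <= 0.30
    assert 0.25 <= dense_frac <= 0.55


def test_fixture_de_recovery_with_at_most_one_false_positive(fixture_data):
    ds, truth = fixture_data
    dsf, _ = osp.filter_cells_spatial(ds)
    expr = osp.lognormalize(dsf)
    labels = osp.assign_cell_types(dsf, osp.MarkerPanel())
    union = set()
    for group in ["NPC", "IPC", "neuron", UNDEFINED]:
        m = labels == group
        a = expr.values[m & (dsf.condition == "MCT8")]
        b = expr.values[m & (dsf.condition == "control")]
        if len(a) < 3 or len(b) < 3:
            continue
        res = osp.wilcoxon_de(a, b, gene_ids=expr.gene_ids)
        sig, _ = osp.select_degs(res, preset="spatial_nofc")
        union |= set(sig.gene)
    planted = set(truth.de_effects)
    assert planted <= union
    assert len(union - planted) <= 1


def test_null_config_has_no_planted_structure():
    cfg = null_config(seed=0)
    assert not cfg.de_effects and not cfg.density_effects
    assert cfg.type_proportions["control"] == cfg.type_proportions["MCT8"]


def test_gene_universe_too_small_for_panel_rejected():
    cfg = SimConfig(seed=1, n_genes=5)  # 9 marker genes cannot fit
    with pytest.raises(ValueError, match="n_genes"):
        cfg.gene_ids()
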