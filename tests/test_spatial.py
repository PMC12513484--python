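import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import sparse

from orgspatial import (
    ExpressionMatrix,
    SpatialDataset,
    classify_density,
    density_expression_linear,
    density_expression_logistic,
    ks_two_sample,
    neighborhood_metric,
    pairwise_type_distances,
)
from orgspatial.spatial import DENSE, INTERMEDIATE, SPARSE, NeighborhoodProfile


def make_ds(x, y, sample=None, types=None):
    n = len(x)
    return SpatialDataset(
        cell_ids=[f"c{i}" for i in range(n)],
        x=x,
        y=y,
        sample_id=sample or ["s1"] * n,
        condition=["control"] * n,
        counts=sparse.csr_matrix((n, 0), dtype=np.int64),
        gene_ids=[],
        cell_type=types,
    )


# --- distances ---------------------------------------------------------


def test_pairwise_distance_345_triangle():
    ds = make_ds([0.0, 3.0], [0.0, 4.0], types=["NPC", "neuron"])
    d = pairwise_type_distances(ds, "NPC", "neuron")
    assert len(d) == 1
    assert d.distance.iloc[0] == pytest.approx(5.0)


def test_pairwise_distance_cardinality_and_aggregation():
    # sample s1: 2 NPC x 3 neuron = 6; sample s2: 1 x 4 = 4; same condition
    x = np.arange(10.0)
    types = ["NPC", "NPC", "neuron", "neuron", "neuron", "NPC"] + ["neuron"] * 4
    sample = ["s1"] * 5 + ["s2"] * 5
    ds = make_ds(x, np.zeros(10), sample=sample, types=types)
    d = pairwise_type_distances(ds, "NPC", "neuron")
    assert (d["sample"] == "s1").sum() == 6
    assert (d["sample"] == "s2").sum() == 4
    assert len(d) == 10  # condition-level aggregate conserves all distances


def test_same_type_requires_flag():
    ds = make_ds([0.0, 1.0], [0.0, 0.0], types=["NPC", "NPC"])
    with pytest.raises(ValueError):
        pairwise_type_distances(ds, "NPC", "NPC")
    d = pairwise_type_distances(ds, "NPC", "NPC", allow_same=True)
    assert len(d) == 1  # self-pairs and duplicates excluded


# --- KS ----------------------------------------------------------------


def test_ks_identity_and_disjoint_and_half():
    assert ks_two_sample([1, 2, 3], [1, 2, 3])[0] == 0.0
    assert ks_two_sample([1, 2, 3], [4, 5, 6])[0] == 1.0
    d, _ = ks_two_sample([1, 2], [1, 3])
    assert d == pytest.approx(0.5)


def test_ks_empty_sample_rejected():
    with pytest.raises(ValueError):
        ks_two_sample([], [1.0])


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    st.lists(st.floats(0.1, 100), min_size=3, max_size=30),
    st.lists(st.floats(0.1, 100), min_size=3, max_size=30),
)
def test_ks_invariant_under_common_monotone_transform(a, b):
    d1, _ = ks_two_sample(a, b)
    d2, _ = ks_two_sample(np.log(a), np.log(b))
    assert d1 == pytest.approx(d2)


# --- neighborhood metric ----------------------------------------------


def test_neighborhood_metric_line_of_three():
    ds = make_ds([0.0, 50.0, 120.0], [0.0, 0.0, 0.0])
    prof = neighborhood_metric(ds, r=100)
    np.testing.assert_array_equal(prof.n, [1, 2, 1])


def test_neighborhood_single_cell_and_handshake(fixture_data):
    ds = make_ds([5.0], [5.0])
    assert neighborhood_metric(ds).n[0] == 0

    full, _ = fixture_data
    prof = neighborhood_metric(full)
    assert prof.n.sum() % 2 == 0  # every within-radius pair counted twice


def test_neighborhood_does_not_cross_samples():
    ds = make_ds([0.0, 1.0], [0.0, 0.0], sample=["s1", "s2"])
    np.testing.assert_array_equal(neighborhood_metric(ds).n, [0, 0])


def test_kdtree_matches_bruteforce(fixture_data):
    ds, _ = fixture_data
    a = neighborhood_metric(ds, method="kdtree")
    b = neighborhood_metric(ds, method="brute")
    np.testing.assert_array_equal(a.n, b.n)


def test_rigid_motion_leaves_n_and_classes_unchanged(fixture_data):
    ds, _ = fixture_data
    before = neighborhood_metric(ds)
    theta = 0.7
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    xy = rot @ np.vstack([ds.x, ds.y]) + np.array([[123.0], [-456.0]])
    moved = make_ds(xy[0], xy[1], sample=list(ds.sample_id))
    after = neighborhood_metric(moved)
    np.testing.assert_array_equal(before.n, after.n)
    np.testing.assert_array_equal(before.density_class, after.density_class)


@pytest.mark.parametrize(
    "n,expected",
    [(1, SPARSE), (5, DENSE), (7, DENSE), (0, INTERMEDIATE), (3, INTERMEDIATE)],
)
def test_classify_density(n, expected):
    assert classify_density([n])[0] == expected


def test_radius_must_be_positive(toy_dataset):
    with pytest.raises(ValueError):
        neighborhood_metric(toy_dataset, r=0)


# --- density-expression association -----------------------------------


def _expr(values, genes=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    genes = genes or [f"g{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        values=values,
        cell_ids=[f"c{i}" for i in range(values.shape[0])],
        gene_ids=genes,
    )


def _profile(n):
    n = np.asarray(n)
    return NeighborhoodProfile(cell_ids=[f"c{i}" for i in range(len(n))], n=n)


def test_linear_recovers_deterministic_slope():
    n = np.arange(10)
    expr = _expr((2.0 * n + 1.0)[:, None])
    res = density_expression_linear(expr, _profile(n), ["NPC"] * 10)
    assert res.slope[0] == pytest.approx(2.0)
    assert res.p[0] < 1e-12


def test_linear_constant_gene_and_zero_variance_n():
    n = np.arange(6)
    expr = _expr(np.full((6, 1), 3.0))
    res = density_expression_linear(expr, _profile(n), ["NPC"] * 6)
    assert res.slope[0] == 0.0 and res.p[0] == 1.0

    expr2 = _expr(np.random.default_rng(0).normal(size=(6, 2)))
    res2 = density_expression_linear(expr2, _profile(np.full(6, 4)), ["NPC"] * 6)
    assert (res2.p == 1.0).all()


def test_linear_matches_statsmodels_oracle():
    import statsmodels.api as sm

    rng = np.random.default_rng(11)
    n = rng.integers(0, 20, 40)
    y = rng.normal(size=(40, 3)) + 0.1 * n[:, None]
    res = density_expression_linear(_expr(y), _profile(n), ["g"] * 40)
    for j in range(3):
        fit = sm.OLS(y[:, j], sm.add_constant(n.astype(float))).fit()
        assert res.slope[j] == pytest.approx(fit.params[1])
        assert res.p[j] == pytest.approx(fit.pvalues[1])


def test_linear_null_type_one_error_rate():
    rng = np.random.default_rng(42)
    n = rng.integers(0, 20, 500)
    y = rng.normal(size=(500, 400))  # independent of n
    res = density_expression_linear(_expr(y), _profile(n), ["NPC"] * 500)
    frac = np.mean(res.p < 0.05)
    se = np.sqrt(0.05 * 0.95 / 400)
    assert abs(frac - 0.05) < 3 * se + 1e-9


def test_linear_slope_recovery_within_two_se():
    # planted Gaussian-noise slope: mean estimate over 200 seeds within 2 SE
    from orgspatial.simulate import spawn_seeds

    beta, sigma, m = 0.3, 1.0, 60
    estimates = []
    for seed in spawn_seeds(1234, 200):
        rng = np.random.default_rng(seed)
        n = rng.integers(0, 15, m)
        y = beta * n + rng.normal(0, sigma, m)
        res = density_expression_linear(_expr(y[:, None]), _profile(n), ["g"] * m)
        estimates.append(res.slope[0])
    sem = np.std(estimates) / np.sqrt(len(estimates))
    assert abs(np.mean(estimates) - beta) < 2 * sem


def test_logistic_null_and_planted_effect():
    rng = np.random.default_rng(5)
    m = 400
    x = rng.normal(1.0, 1.0, m)
    # planted log-odds effect of 1.0 per unit expression
    p_dense = 1.0 / (1.0 + np.exp(-(x - 1.0)))
    dense = rng.random(m) < p_dense
    n = np.where(dense, 6, 1)
    res = density_expression_logistic(_expr(x[:, None]), _profile(n), ["g"] * m)
    assert res.coef[0] == pytest.approx(1.0, abs=0.25)

    # identical expression in both classes: coefficient ~ 0, p ~ 1
    x0 = np.full(m, 2.5)
    res0 = density_expression_logistic(_expr(x0[:, None]), _profile(n), ["g"] * m)
    assert res0.coef[0] == 0.0 and res0.p[0] == 1.0


def test_logistic_flags_complete_separation():
    n = np.array([1, 1, 1, 6, 6, 6])
    x = np.array([0.0, 0.1, 0.2, 5.0, 5.1, 5.2])  # expressed only in dense
    res = density_expression_logistic(_expr(x[:, None]), _profile(n), ["g"] * 6)
    assert bool(res.separated[0])
    assert np.isnan(res.p[0])


def test_logistic_skips_underpopulated_groups():
    n = np.array([1, 6, 6, 6])
    x = np.random.default_rng(0).normal(size=(4, 1))
    res = density_expression_logistic(_expr(x), _profile(n), ["g"] * 4)
    assert res.empty
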