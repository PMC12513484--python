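import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from orgspatial import (
    bh_adjust,
    composition_chisq,
    pairwise_proportions,
    select_degs,
    wilcoxon_de,
)


# --- Wilcoxon ----------------------------------------------------------


def test_wilcoxon_identical_groups():
    a = np.tile([1.0, 2.0, 3.0], (1, 1)).T
    res = wilcoxon_de(a, a.copy())
    assert res.avg_log2FC[0] == 0.0
    assert res.p[0] == 1.0


def test_wilcoxon_exact_p_for_fully_separated_triples():
    # 20 equally likely rank assignments; the observed extreme split has
    # probability 2/20 = 0.1 two-sided
    res = wilcoxon_de(np.array([[1.0], [2.0], [3.0]]), np.array([[4.0], [5.0], [6.0]]))
    assert res.p[0] == pytest.approx(0.1)
    assert res.avg_log2FC[0] < 0


def test_wilcoxon_antisymmetric_under_group_swap():
    rng = np.random.default_rng(2)
    a, b = rng.lognormal(size=(20, 5)), rng.lognormal(1.0, size=(15, 5))
    ab = wilcoxon_de(a, b)
    ba = wilcoxon_de(b, a)
    np.testing.assert_allclose(ab.avg_log2FC, -ba.avg_log2FC)
    np.testing.assert_allclose(ab.p, ba.p)


def test_wilcoxon_all_tied_gene_p_is_one():
    a = np.full((5, 1), 2.0)
    b = np.full((6, 1), 2.0)
    assert wilcoxon_de(a, b).p[0] == 1.0


def test_wilcoxon_requires_three_cells():
    with pytest.raises(ValueError):
        wilcoxon_de(np.zeros((2, 1)), np.zeros((5, 1)))


def test_wilcoxon_normal_approx_close_to_exact():
    rng = np.random.default_rng(0)
    diffs = []
    for _ in range(100):
        a, b = rng.normal(size=(8, 1)), rng.normal(size=(8, 1))
        pa = wilcoxon_de(a, b, method="asymptotic").p[0]
        pe = wilcoxon_de(a, b, method="exact").p[0]
        diffs.append(abs(pa - pe))
    assert max(diffs) < 0.02


# --- BH ---------------------------------------------------------------


@pytest.mark.parametrize(
    "pvals,expected",
    [
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([0.005, 0.04, 0.04], [0.015, 0.04, 0.04]),
        ([0.5], [0.5]),
    ],
)
def test_bh_hand_computed(pvals, expected):
    np.testing.assert_allclose(bh_adjust(pvals), expected)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.2])


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
def test_bh_properties(pvals):
    adj = bh_adjust(pvals)
    assert np.all(adj >= np.asarray(pvals) - 1e-12)
    assert np.all(adj <= 1.0)
    # permutation equivariance
    rng = np.random.default_rng(0)
    perm = rng.permutation(len(pvals))
    adj_perm = bh_adjust(np.asarray(pvals)[perm])
    np.testing.assert_allclose(adj_perm, adj[perm])


# --- selection --------------------------------------------------------


def _de_table():
    return pd.DataFrame(
        {
            "gene": ["a", "b", "c", "d"],
            "avg_log2FC": [0.30, -0.30, 0.10, 0.50],
            "p": [0.001, 0.001, 0.001, 0.5],
            "padj": [0.04, 0.04, 0.04, 0.9],
        }
    )


def test_select_degs_thresholds_and_direction():
    out, counts = select_degs(_de_table(), padj_max=0.05, lfc_min=0.26)
    assert set(out.gene) == {"a", "b"}  # c fails lfc, d fails padj
    assert counts == {"up": 1, "down": 1, "total": 2}


def test_select_degs_spatial_preset_keeps_small_fold_changes():
    out, counts = select_degs(_de_table(), preset="spatial_nofc")
    assert set(out.gene) == {"a", "b", "c"}
    assert counts["total"] == 3


def test_select_degs_empty_when_nothing_passes():
    table = _de_table().assign(padj=1.0)
    out, counts = select_degs(table)
    assert out.empty and counts["total"] == 0


# --- composition ------------------------------------------------------


def test_chisq_homogeneous_table():
    chi2, df, p = composition_chisq([[50, 50], [50, 50]])
    assert chi2 == 0.0 and p == pytest.approx(1.0)


def test_chisq_hand_computed():
    chi2, df, p = composition_chisq([[10, 20], [20, 10]])
    assert chi2 == pytest.approx(20 / 3)
    assert df == 1
    assert p == pytest.approx(0.0098, abs=2e-4)


def test_chisq_scales_linearly_with_counts():
    t = np.array([[10, 20], [20, 10]])
    chi2_1, _, _ = composition_chisq(t)
    chi2_10, _, _ = composition_chisq(t * 10)
    assert chi2_10 == pytest.approx(10 * chi2_1)


def test_chisq_drops_zero_margins():
    chi2, df, p = composition_chisq([[10, 20], [0, 0], [20, 10]])
    assert df == 1  # zero row dropped


def test_pairwise_proportions_homogeneous_and_planted():
    table = pd.DataFrame({"control": [50, 50, 50], "MCT8": [50, 50, 50]},
                         index=["c0", "c1", "c2"])
    res = pairwise_proportions(table)
    assert np.allclose(res.p, 1.0)

    rng = np.random.default_rng(8)
    counts = pd.DataFrame(
        {"control": rng.poisson(100, 5), "MCT8": rng.poisson(100, 5)},
        index=[f"c{i}" for i in range(5)],
    )
    counts.loc["c2", "MCT8"] *= 2  # planted doubling
    res = pairwise_proportions(counts)
    assert res.loc[res.padj.idxmin(), "cluster"] == "c2"


def test_pairwise_proportions_single_row_rejected():
    with pytest.raises(ValueError):
        pairwise_proportions(pd.DataFrame({"a": [5], "b": [5]}, index=["only"]))
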