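"""Cross-type distance distributions and neighborhood-density statistics.

The neighborhood metric ``n`` of a cell is the number of other cells, of
any type, within a fixed radius (default 100 micrometres) in the same
tissue section.  Cells with ``n == 1`` sit in sparse areas, cells with
``n >= 5`` in dense areas; everything else (including isolated cells with
``n == 0``) is intermediate.  Density-expression association is tested
two ways: ordinary least squares of expression on ``n`` within each
cell-type group, and logistic regression of the sparse/dense class on
expression.  P-values are Benjamini-Hochberg adjusted across genes within
each group.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .datamodel import ExpressionMatrix, SpatialDataset
from .de import bh_adjust

logger = logging.getLogger(__name__)

SPARSE, DENSE, INTERMEDIATE = "sparse", "dense", "intermediate"


@dataclass
class NeighborhoodProfile:
    """Per-cell neighbor counts within radius ``r`` plus density classes."""

    cell_ids: np.ndarray
    n: np.ndarray
    r: float = 100.0
    sparse_n: int = 1
    dense_n: int = 5

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=int)
        if (self.n < 0).any():
            raise ValueError("neighbor counts must be nonnegative")

    @property
    def density_class(self) -> np.ndarray:
        return classify_density(self.n, self.sparse_n, self.dense_n)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cell_id": self.cell_ids, "n": self.n, "density_class": self.density_class}
        )


@dataclass
class DistanceComparison:
    """KS comparison of a cross-type distance distribution between conditions."""

    type_pair: tuple[str, str]
    conditions: tuple[str, str]
    n1: int
    n2: int
    statistic: float
    pvalue: float


def pairwise_type_distances(
    ds: SpatialDataset,
    type_a: str,
    type_b: str,
    allow_same: bool = False,
) -> pd.DataFrame:
    """All Euclidean distances between cells of two types, per sample.

    Distances are computed within each sample (section) between every
    cell of ``type_a`` and every cell of ``type_b``; aggregation by
    condition is then a concatenation of the per-sample distances.
    Returns a tidy frame with columns ``sample, condition, distance``.
    """
    if ds.cell_type is None:
        raise ValueError("cell types not assigned; run assign_cell_types first")
    if type_a == type_b and not allow_same:
        raise ValueError(
            "same-type distances require allow_same=True (self-pairs excluded)"
        )
    frames = []
    for s in np.unique(ds.sample_id):
        in_s = ds.sample_id == s
        a_mask = in_s & (ds.cell_type == type_a)
        b_mask = in_s & (ds.cell_type == type_b)
        if not a_mask.any() or not b_mask.any():
            logger.info("sample %s lacks %s or %s cells; no distances", s, type_a, type_b)
            continue
        pa = np.column_stack([ds.x[a_mask], ds.y[a_mask]])
        pb = np.column_stack([ds.x[b_mask], ds.y[b_mask]])
        d = cdist(pa, pb)
        if type_a == type_b:
            iu = np.triu_indices_from(d, k=1)
            dist = d[iu]
        else:
            dist = d.ravel()
        cond = ds.condition[a_mask][0]
        frames.append(
            pd.DataFrame({"sample": s, "condition": cond, "distance": dist})
        )
    if not frames:
        return pd.DataFrame(columns=["sample", "condition", "distance"])
    return pd.concat(frames, ignore_index=True)


def ks_two_sample(
    d1, d2, exact_max_product: int = 10_000
) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test.

    ``D = sup |ECDF1 - ECDF2|`` with a two-sided p-value; the exact
    small-sample distribution is used when ``n1 * n2 <= exact_max_product``,
    the asymptotic Kolmogorov distribution otherwise.
    """
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    if d1.size == 0 or d2.size == 0:
        raise ValueError("KS test requires two nonempty samples")
    method = "exact" if d1.size * d2.size <= exact_max_product else "asymp"
    res = stats.ks_2samp(d1, d2, method=method)
    return float(res.statistic), float(res.pvalue)


def compare_distances_between_conditions(
    distances: pd.DataFrame, type_pair: tuple[str, str]
) -> DistanceComparison:
    """Aggregate per-sample distances by condition and KS-compare them."""
    conds = sorted(distances["condition"].unique())
    if len(conds) != 2:
        raise ValueError(f"expected exactly 2 conditions, found {conds}")
    d1 = distances.loc[distances["condition"] == conds[0], "distance"].to_numpy()
    d2 = distances.loc[distances["condition"] == conds[1], "distance"].to_numpy()
    stat, p = ks_two_sample(d1, d2)
    return DistanceComparison(
        type_pair=tuple(type_pair),
        conditions=(conds[0], conds[1]),
        n1=len(d1),
        n2=len(d2),
        statistic=stat,
        pvalue=p,
    )


def neighborhood_metric(
    ds: SpatialDataset,
    r: float = 100.0,
    method: str = "kdtree",
    sparse_n: int = 1,
    dense_n: int = 5,
) -> NeighborhoodProfile:
    """Count, for each cell, the other cells within radius ``r``.

    Neighbors are counted within the cell's own sample only, over cells of
    every type (including undefined); the boundary is inclusive
    (``dist <= r``) and the cell itself is excluded.  ``method`` selects
    spatial indexing (``"kdtree"``) or the O(N^2) all-pairs computation
    (``"brute"``); both give identical counts.
    """
    if r <= 0:
        raise ValueError("radius must be > 0")
    n = np.zeros(ds.n_cells, dtype=int)
    for s in np.unique(ds.sample_id):
        idx = np.flatnonzero(ds.sample_id == s)
        pts = np.column_stack([ds.x[idx], ds.y[idx]])
        if method == "kdtree":
            tree = cKDTree(pts)
            counts = tree.query_ball_point(pts, r, return_length=True) - 1
        elif method == "brute":
            d = cdist(pts, pts)
            counts = (d <= r).sum(axis=1) - 1
        else:
            raise ValueError(f"unknown method {method!r}")
        n[idx] = counts
    return NeighborhoodProfile(
        cell_ids=ds.cell_ids.copy(), n=n, r=float(r), sparse_n=sparse_n, dense_n=dense_n
    )


def classify_density(n, sparse_n: int = 1, dense_n: int = 5) -> np.ndarray:
    """Map neighbor counts to density classes.

    ``n == sparse_n`` -> sparse, ``n >= dense_n`` -> dense, anything else
    (including ``n == 0``) -> intermediate.
    """
    n = np.asarray(n)
    out = np.full(n.shape, INTERMEDIATE, dtype=object)
    out[n == sparse_n] = SPARSE
    out[n >= dense_n] = DENSE
    return out


def _ols_by_gene(y: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column OLS of y on x: returns (slopes, two-sided t-test p)."""
    m = len(x)
    xc = x - x.mean()
    sxx = float(np.sum(xc**2))
    n_genes = y.shape[1]
    if sxx == 0.0:
        return np.zeros(n_genes), np.ones(n_genes)
    yc = y - y.mean(axis=0)
    slopes = yc.T @ xc / sxx
    resid = yc - np.outer(xc, slopes)
    df = m - 2
    rss = np.sum(resid**2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(rss / df / sxx)
        t = slopes / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    # zero residual variance: perfect fit (p -> 0) unless the slope is 0 too
    exact = se == 0
    p[exact] = np.where(slopes[exact] != 0, 0.0, 1.0)
    # numerically constant genes
    const = np.ptp(y, axis=0) == 0
    slopes[const] = 0.0
    p[const] = 1.0
    return slopes, p


def density_expression_linear(
    expr: ExpressionMatrix,
    profile: NeighborhoodProfile,
    group: np.ndarray,
    min_cells: int = 3,
) -> pd.DataFrame:
    """OLS of expression on the neighborhood metric, per cell-type group.

    Within each group the expression of every gene is regressed on ``n``;
    the slope is tested two-sided (t-test) and p-values are BH-adjusted
    across genes within the group.  Groups smaller than ``min_cells`` are
    skipped; a group with zero variance in ``n`` reports all p = 1.

    Returns a tidy frame: ``group, gene, slope, p, padj``.
    """
    group = np.asarray(group, dtype=object)
    if len(group) != expr.values.shape[0] or len(profile.n) != len(group):
        raise ValueError("expr, profile and group must align on cells")
    rows = []
    for g in pd.unique(group):
        mask = group == g
        m = int(mask.sum())
        if m < min_cells:
            logger.warning("group %r has %d < %d cells; skipped", g, m, min_cells)
            continue
        x = profile.n[mask].astype(float)
        if np.ptp(x) == 0:
            logger.warning("group %r has zero variance in n; all p set to 1", g)
            slopes = np.zeros(expr.values.shape[1])
            p = np.ones(expr.values.shape[1])
        else:
            slopes, p = _ols_by_gene(expr.values[mask], x)
        rows.append(
            pd.DataFrame(
                {
                    "group": g,
                    "gene": expr.gene_ids,
                    "slope": slopes,
                    "p": p,
                    "padj": bh_adjust(p),
                }
            )
        )
    if not rows:
        return pd.DataFrame(columns=["group", "gene", "slope", "p", "padj"])
    return pd.concat(rows, ignore_index=True)


def _logit_one_gene(y: np.ndarray, x: np.ndarray) -> tuple[float, float, bool]:
    """Logistic fit of binary y on x; returns (coef, wald p, separated)."""
    if np.ptp(x) == 0:
        return 0.0, 1.0, False
    # complete separation: the two classes occupy disjoint x ranges
    if x[y == 1].min() > x[y == 0].max() or x[y == 1].max() < x[y == 0].min():
        return np.nan, np.nan, True
    X = sm.add_constant(x)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
    except (PerfectSeparationError, np.linalg.LinAlgError):
        return np.nan, np.nan, True
    coef = float(fit.params[1])
    p = float(fit.pvalues[1])
    if not np.isfinite(p):
        return np.nan, np.nan, True
    return coef, p, False


def density_expression_logistic(
    expr: ExpressionMatrix,
    profile: NeighborhoodProfile,
    group: np.ndarray,
    min_cells_per_class: int = 2,
) -> pd.DataFrame:
    """Logistic regression of density class on expression, per group.

    Intermediate cells are excluded; the response is dense = 1 vs
    sparse = 0 and the predictor is the gene's normalized expression.
    The Wald test on the expression coefficient gives the p-value; BH is
    applied across genes within the group.  Genes with complete
    separation are flagged (``separated = True``) and carry NaN p-values,
    which BH ignores.

    Returns ``group, gene, coef, p, padj, separated``.
    """
    group = np.asarray(group, dtype=object)
    classes = profile.density_class
    rows = []
    for g in pd.unique(group):
        mask = group == g
        sparse_mask = mask & (classes == SPARSE)
        dense_mask = mask & (classes == DENSE)
        n_sp, n_de = int(sparse_mask.sum()), int(dense_mask.sum())
        if n_sp < min_cells_per_class or n_de < min_cells_per_class:
            logger.warning(
                "group %r has %d sparse / %d dense cells; skipped", g, n_sp, n_de
            )
            continue
        sel = sparse_mask | dense_mask
        y = (classes[sel] == DENSE).astype(float)
        coefs, ps, seps = [], [], []
        for j in range(expr.values.shape[1]):
            coef, p, sep = _logit_one_gene(y, expr.values[sel, j])
            coefs.append(coef)
            ps.append(p)
            seps.append(sep)
        ps = np.asarray(ps, dtype=float)
        padj = np.full_like(ps, np.nan)
        ok = np.isfinite(ps)
        if ok.any():
            padj[ok] = bh_adjust(ps[ok])
        rows.append(
            pd.DataFrame(
                {
                    "group": g,
                    "gene": expr.gene_ids,
                    "coef": coefs,
                    "p": ps,
                    "padj": padj,
                    "separated": seps,
                }
            )
        )
    if not rows:
        return pd.DataFrame(columns=["group", "gene", "coef", "p", "padj", "separated"])
    return pd.concat(rows, ignore_index=True)
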