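"""Rank-based differential expression and composition tests.

Between-condition differential expression within a cell group uses the
two-sided Wilcoxon rank-sum test on log-normalized expression, with the
Seurat-style average log2 fold change
``log2((mean(expm1(A)) + 1) / (mean(expm1(B)) + 1))`` and
Benjamini-Hochberg adjustment across genes.  Two selection presets are
provided: ``findmarkers_026`` (adjusted p < 0.05, |log2FC| >= 0.26, the
split-pool convention) and ``spatial_nofc`` (adjusted p < 0.05, no fold
change threshold, the imaging-panel convention).  Cluster composition
between conditions is compared with Pearson's chi-squared test, overall
and per-cluster (cluster vs rest).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: Named DE selection presets: (padj_max, lfc_min).
DE_PRESETS = {
    "findmarkers_026": (0.05, 0.26),
    "spatial_nofc": (0.05, 0.0),
    "seurat_fc15": (0.01, np.log2(1.5)),
}


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def wilcoxon_de(
    expr_a: np.ndarray,
    expr_b: np.ndarray,
    gene_ids=None,
    method: str = "auto",
    exact_max_product: int = 200,
) -> pd.DataFrame:
    """Per-gene two-sided Wilcoxon rank-sum test between two cell groups.

    ``expr_a`` / ``expr_b`` are cells x genes arrays of log-normalized
    expression for the two groups.  The normal approximation with tie
    correction is used by default; when ``method="auto"`` the exact null
    distribution replaces it for genes without ties whenever
    ``nA * nB <= exact_max_product``.  ``method`` may be forced to
    ``"exact"`` or ``"asymptotic"``.

    Returns a frame with ``gene, avg_log2FC, p, padj, pct_a, pct_b,
    n_a, n_b``; log2FC is positive when the gene is higher in group A.
    """
    expr_a = np.atleast_2d(np.asarray(expr_a, dtype=float))
    expr_b = np.atleast_2d(np.asarray(expr_b, dtype=float))
    n_a, n_genes = expr_a.shape
    n_b = expr_b.shape[0]
    if expr_b.shape[1] != n_genes:
        raise ValueError("groups have different gene counts")
    if n_a < 3 or n_b < 3:
        raise ValueError("each group needs at least 3 cells")
    if gene_ids is None:
        gene_ids = np.array([f"g{i}" for i in range(n_genes)], dtype=object)

    with np.errstate(invalid="ignore"):
        res = stats.mannwhitneyu(
            expr_a, expr_b, axis=0, alternative="two-sided", method="asymptotic"
        )
    p = np.asarray(res.pvalue, dtype=float)

    combined = np.vstack([expr_a, expr_b])
    all_tied = np.ptp(combined, axis=0) == 0
    p[all_tied] = 1.0

    if method in ("auto", "exact") and n_a * n_b <= exact_max_product:
        for j in range(n_genes):
            if all_tied[j]:
                continue
            col = combined[:, j]
            has_ties = len(np.unique(col)) < len(col)
            if has_ties and method == "auto":
                continue  # exact null is not tie-corrected; keep asymptotic
            p[j] = stats.mannwhitneyu(
                expr_a[:, j], expr_b[:, j], alternative="two-sided", method="exact"
            ).pvalue
    elif method == "exact":
        raise ValueError(
            f"exact test limited to nA*nB <= {exact_max_product} (got {n_a * n_b})"
        )

    p = np.clip(p, 0.0, 1.0)
    mean_a = np.expm1(expr_a).mean(axis=0)
    mean_b = np.expm1(expr_b).mean(axis=0)
    log2fc = np.log2((mean_a + 1.0) / (mean_b + 1.0))
    return pd.DataFrame(
        {
            "gene": gene_ids,
            "avg_log2FC": log2fc,
            "p": p,
            "padj": bh_adjust(p),
            "pct_a": (expr_a > 0).mean(axis=0),
            "pct_b": (expr_b > 0).mean(axis=0),
            "n_a": n_a,
            "n_b": n_b,
        }
    )


def select_degs(
    results: pd.DataFrame,
    padj_max: float = 0.05,
    lfc_min: float = 0.0,
    preset: str | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Filter a DE table to significant genes.

    Keeps genes with ``padj < padj_max`` and ``|avg_log2FC| >= lfc_min``;
    ``preset`` (a key of :data:`DE_PRESETS`) overrides both thresholds.
    Returns the filtered table and ``{"up": ..., "down": ..., "total": ...}``.
    """
    if preset is not None:
        padj_max, lfc_min = DE_PRESETS[preset]
    keep = (results["padj"] < padj_max) & (results["avg_log2FC"].abs() >= lfc_min)
    out = results.loc[keep].copy()
    counts = {
        "up": int((out["avg_log2FC"] > 0).sum()),
        "down": int((out["avg_log2FC"] < 0).sum()),
        "total": int(len(out)),
    }
    return out, counts


def _clean_table(table: pd.DataFrame) -> pd.DataFrame:
    """Drop all-zero rows/columns (with a warning)."""
    arr = table.to_numpy()
    if (arr < 0).any():
        raise ValueError("composition table must be nonnegative")
    row_ok = arr.sum(axis=1) > 0
    col_ok = arr.sum(axis=0) > 0
    if not row_ok.all() or not col_ok.all():
        logger.warning(
            "dropped %d zero rows and %d zero columns from composition table",
            int((~row_ok).sum()),
            int((~col_ok).sum()),
        )
    return table.loc[row_ok, col_ok]


def composition_chisq(table: pd.DataFrame) -> tuple[float, int, float]:
    """Pearson chi-squared test of homogeneity on a clusters x conditions table.

    No continuity correction; expected counts come from the margins;
    ``df = (r - 1)(c - 1)``.  Zero-margin rows/columns are dropped first.
    """
    table = _clean_table(pd.DataFrame(table))
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("composition test needs at least a 2x2 table")
    chi2, p, df, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    return float(chi2), int(df), float(p)


def pairwise_proportions(table: pd.DataFrame) -> pd.DataFrame:
    """Per-cluster 2x2 chi-squared tests (cluster vs all others), BH-adjusted.

    For each row of the clusters x conditions table, the counts of that
    cluster are compared against the summed counts of every other cluster
    across conditions.  Returns ``cluster, chi2, df, p, padj``.
    """
    table = _clean_table(pd.DataFrame(table))
    if table.shape[0] < 2:
        raise ValueError("pairwise proportions need at least 2 clusters")
    if table.shape[1] < 2:
        raise ValueError("pairwise proportions need at least 2 conditions")
    totals = table.to_numpy().sum(axis=0)
    rows = []
    for cluster, row in table.iterrows():
        contingency = np.vstack([row.to_numpy(), totals - row.to_numpy()])
        chi2, p, df, _ = stats.chi2_contingency(contingency, correction=False)
        rows.append({"cluster": cluster, "chi2": float(chi2), "df": int(df), "p": float(p)})
    out = pd.DataFrame(rows)
    out["padj"] = bh_adjust(out["p"].to_numpy())
    return out
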