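"""Marker genes of antigen-high cells: rank-sum + AUC with the standard
filter set.

Every gene is tested between the antigen-high ("in") and antigen-low
("out") classes with a Wilcoxon rank-sum test on log-normalized
expression.  The AUC is the U statistic scaled to [0, 1] (midranks give
ties half weight).  A gene passes when the BH-adjusted p-value is below
0.05, the log fold-change (difference of mean log-normalized expression)
exceeds 0.25, the AUC exceeds 0.5, and at least 50% of the antigen-high
cells express it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .qc import NormalizedMatrix
from . import stats as _st

__all__ = ["rank_auc_test", "find_markers"]


def rank_auc_test(expr_in, expr_out) -> tuple[float, float, float]:
    """(U statistic, AUC, two-sided p) for one gene.

    Exact p by enumeration when n_in + n_out <= 12 with tie-free data,
    otherwise a normal approximation with tie and continuity correction.
    """
    expr_in = np.asarray(expr_in, dtype=float)
    expr_out = np.asarray(expr_out, dtype=float)
    if expr_in.size == 0 or expr_out.size == 0:
        raise ValueError("both groups must be nonempty")
    res = _st.wilcoxon_ranksum(expr_in, expr_out)
    return res.u, res.u / (expr_in.size * expr_out.size), res.p


def _ranksum_matrix(expr: np.ndarray, in_mask: np.ndarray):
    """Vectorised rank-sum over genes (rows) for one in/out split.

    Uses midranks per gene; returns (U, auc, p_approx) arrays.  The
    normal approximation with tie and continuity correction is used for
    every gene (callers fall back to the scalar exact path for small
    totals).
    """
    m, n = expr.shape
    n1 = int(in_mask.sum())
    n2 = n - n1
    ranks = sps.rankdata(expr, axis=1)
    r1 = ranks[:, in_mask].sum(axis=1)
    u = r1 - n1 * (n1 + 1) / 2.0
    # per-gene tie correction
    srt = np.sort(expr, axis=1)
    tie_term = np.zeros(m)
    for g in range(m):
        _, counts = np.unique(srt[g], return_counts=True)
        tie_term[g] = ((counts**3 - counts).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    sd = np.sqrt(np.maximum(var, 0.0))
    mean = n1 * n2 / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (np.abs(u - mean) - 0.5) / sd
    p = np.where(sd > 0, np.minimum(1.0, 2.0 * sps.norm.sf(np.maximum(z, 0.0))), 1.0)
    return u, u / (n1 * n2), p


def find_markers(
    norm: NormalizedMatrix,
    labels,
    bundle=None,
    alpha: float = 0.05,
    min_lfc: float = 0.25,
    min_auc: float = 0.5,
    min_pct_in: float = 50.0,
) -> pd.DataFrame:
    """Test every gene between antigen-high and antigen-low cells.

    ``labels`` holds "high"/"low" per cell (cells with other/NA labels
    are excluded).  ``pct_in``/``pct_out`` count cells with a raw count
    > 0; they come from ``bundle.gene_counts`` when a bundle is given,
    otherwise nonzero log-normalized expression is used (identical
    pattern).  Genes with zero expression in both classes are reported
    with ``tested=False`` and excluded from the BH family.

    Returns the full marker table (one row per gene) with a ``pass``
    flag; filtering to passing rows is the caller's choice.
    """
    labels = pd.Series(np.asarray(labels, dtype=object),
                       index=norm.cell_ids)
    use = labels.isin(["high", "low"]).to_numpy()
    lab = labels.to_numpy()[use]
    in_mask = lab == "high"
    n_in, n_out = int(in_mask.sum()), int((~in_mask).sum())
    if n_in < 2 or n_out < 2:
        raise ValueError("need >= 2 cells in each of the high and low classes")

    expr = np.asarray(norm.log_expr.todense())[:, use]
    if bundle is not None:
        raw = np.asarray(bundle.gene_counts.todense())[:, use]
    else:
        raw = expr
    expressed = raw > 0
    pct_in = 100.0 * expressed[:, in_mask].mean(axis=1)
    pct_out = 100.0 * expressed[:, ~in_mask].mean(axis=1)
    mean_in = expr[:, in_mask].mean(axis=1)
    mean_out = expr[:, ~in_mask].mean(axis=1)
    lfc = mean_in - mean_out

    tested = expressed.any(axis=1)
    m = expr.shape[0]
    u = np.full(m, np.nan)
    auc = np.full(m, np.nan)
    p = np.full(m, np.nan)
    if tested.any():
        if n_in + n_out <= 12:
            for g in np.where(tested)[0]:
                u[g], auc[g], p[g] = rank_auc_test(expr[g, in_mask],
                                                   expr[g, ~in_mask])
        else:
            u_t, auc_t, p_t = _ranksum_matrix(expr[tested], in_mask)
            u[tested], auc[tested], p[tested] = u_t, auc_t, p_t
    padj = np.full(m, np.nan)
    if tested.any():
        padj[tested] = _st.adjust_pvalues(p[tested], method="bh")

    table = pd.DataFrame({
        "gene_id": norm.gene_ids,
        "avgExpr": mean_in,       # mean log-normalized expression, high class
        "logFC": lfc,
        "statistic": u,
        "auc": auc,
        "pval": p,
        "padj": padj,
        "pct_in": pct_in,
        "pct_out": pct_out,
        "tested": tested,
    })
    table["pass"] = (
        table["tested"]
        & (table["padj"] < alpha)
        & (table["logFC"] > min_lfc)
        & (table["auc"] > min_auc)
        & (table["pct_in"] >= min_pct_in)
    )
    return table
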