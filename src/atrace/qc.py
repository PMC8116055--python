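"""Cell QC, log-normalization, variable-gene selection, scaling and PCA.

QC keeps cells with a detected-gene count strictly between the bounds
and a mitochondrial read percentage strictly below the cap (>250, <5000
genes and <15% mitochondrial reads by default).  Normalization is
ln(1 + count * 1e4 / cell total).  Variable genes are ranked by
standardized variance against a binned mean-variance trend of the raw
counts; scaled values are clipped at +/-10 before PCA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA

from .datamodel import CountsBundle, subset_bundle

__all__ = ["QCParams", "NormalizedMatrix", "qc_filter", "lognormalize",
           "select_hvg", "run_pca"]


@dataclass
class QCParams:
    min_genes: int = 250          # exclusive lower bound on detected genes
    max_genes: int = 5000         # exclusive upper bound
    max_mito_pct: float = 15.0    # exclusive upper bound, percent
    mito_gene_prefix: str = "mt-"
    scale_factor: float = 10000.0
    n_hvg: int = 2000
    n_pcs: int = 40

    def __post_init__(self):
        if not 0 <= self.min_genes < self.max_genes:
            raise ValueError("need 0 <= min_genes < max_genes")
        if not 0 < self.max_mito_pct <= 100:
            raise ValueError("max_mito_pct must be in (0, 100]")
        if self.n_pcs > self.n_hvg:
            raise ValueError("n_pcs cannot exceed n_hvg")


@dataclass
class NormalizedMatrix:
    """Log-normalized expression plus the derived QC/PCA artefacts."""

    log_expr: sp.csr_matrix            # genes x cells, ln(1 + cp10k)
    gene_ids: list
    cell_ids: list
    detected_genes: np.ndarray
    mito_pct: np.ndarray
    hvg_ids: list = field(default_factory=list)
    scaled_expr: np.ndarray | None = None   # HVG x cells, clipped z-scores
    pca_scores: np.ndarray | None = None    # cells x n_pcs
    pca_loadings: np.ndarray | None = None  # HVG x n_pcs
    explained_variance_ratio: np.ndarray | None = None


def _per_cell_stats(bundle: CountsBundle, mito_prefix: str):
    counts = bundle.gene_counts.tocsc()
    detected = np.asarray((counts > 0).sum(axis=0)).ravel()
    totals = np.asarray(counts.sum(axis=0)).ravel().astype(float)
    mito_mask = np.array([g.startswith(mito_prefix) for g in bundle.gene_ids])
    mito = np.asarray(counts[mito_mask].sum(axis=0)).ravel().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_pct = np.where(totals > 0, 100.0 * mito / totals, 0.0)
    return detected, totals, mito_pct


def qc_filter(bundle: CountsBundle, params: QCParams | None = None
              ) -> tuple[CountsBundle, pd.DataFrame]:
    """Apply the strict-inequality QC thresholds cell by cell.

    Returns the filtered bundle and a per-cell report with pass/fail
    reasons.  An empty surviving set is a warning, not an error.
    """
    params = params or QCParams()
    detected, _, mito_pct = _per_cell_stats(bundle, params.mito_gene_prefix)
    ok_lo = detected > params.min_genes
    ok_hi = detected < params.max_genes
    ok_mito = mito_pct < params.max_mito_pct
    keep = ok_lo & ok_hi & ok_mito
    reasons = []
    for lo, hi, mi in zip(ok_lo, ok_hi, ok_mito):
        r = []
        if not lo:
            r.append("too_few_genes")
        if not hi:
            r.append("too_many_genes")
        if not mi:
            r.append("high_mito")
        reasons.append(";".join(r) if r else "")
    report = pd.DataFrame({
        "cell_id": bundle.cell_ids,
        "detected_genes": detected,
        "mito_pct": mito_pct,
        "pass": keep,
        "fail_reason": reasons,
    })
    if not keep.any():
        warnings.warn("no cells survive QC; returning an empty bundle")
    return subset_bundle(bundle, keep), report


def lognormalize(bundle: CountsBundle, params: QCParams | None = None
                 ) -> NormalizedMatrix:
    """ln(1 + count * scale_factor / cell total), per cell.

    Zero-total cells yield all-zero columns with a warning.
    """
    params = params or QCParams()
    if bundle.n_cells < 1:
        raise ValueError("need at least one cell")
    counts = bundle.gene_counts.tocsc().astype(float)
    totals = np.asarray(counts.sum(axis=0)).ravel()
    if (totals == 0).any():
        warnings.warn(f"{int((totals == 0).sum())} cells have zero total counts")
    inv = np.where(totals > 0, params.scale_factor / np.maximum(totals, 1.0), 0.0)
    norm = counts @ sp.diags(inv)
    norm.data = np.log1p(norm.data)
    detected, _, mito_pct = _per_cell_stats(bundle, params.mito_gene_prefix)
    return NormalizedMatrix(
        log_expr=norm.tocsr(),
        gene_ids=list(bundle.gene_ids),
        cell_ids=list(bundle.cell_ids),
        detected_genes=detected,
        mito_pct=mito_pct,
    )


def select_hvg(bundle: CountsBundle, n_hvg: int = 2000, n_bins: int = 20
               ) -> list:
    """Rank genes by standardized variance against a binned trend.

    Per-gene mean and variance of the raw counts are computed; genes are
    binned by log-mean and each gene's variance is divided by the median
    variance in its bin.  Ties break lexicographically by gene id so the
    selection is deterministic.  Asking for more genes than exist returns
    all genes with a warning.
    """
    counts = bundle.gene_counts.astype(float)
    n = bundle.n_cells
    if n == 0:
        raise ValueError("cannot select variable genes with zero cells")
    mean = np.asarray(counts.mean(axis=1)).ravel()
    sq = np.asarray(counts.multiply(counts).mean(axis=1)).ravel()
    var = np.maximum(sq - mean**2, 0.0) * (n / max(n - 1, 1))
    if n_hvg >= len(mean):
        if n_hvg > len(mean):
            warnings.warn("fewer genes than requested; returning all genes")
        order = sorted(range(len(mean)), key=lambda i: bundle.gene_ids[i])
        return [bundle.gene_ids[i] for i in order]

    logmean = np.log10(mean + 1e-12)
    edges = np.quantile(logmean, np.linspace(0, 1, n_bins + 1))
    binidx = np.clip(np.searchsorted(edges, logmean, side="right") - 1, 0, n_bins - 1)
    expected = np.ones_like(var)
    for b in range(n_bins):
        sel = binidx == b
        if sel.any():
            med = np.median(var[sel])
            expected[sel] = med if med > 0 else 1.0
    std_var = var / expected
    order = sorted(range(len(std_var)),
                   key=lambda i: (-std_var[i], bundle.gene_ids[i]))
    return [bundle.gene_ids[i] for i in order[:n_hvg]]


def run_pca(norm: NormalizedMatrix, hvg_ids: list, n_pcs: int = 40,
            clip: float = 10.0, seed: int = 0) -> NormalizedMatrix:
    """Scale the HVG block to unit variance, clip, and project onto PCs.

    Per-gene centering/scaling happens before clipping at ``+/-clip``.
    Component signs are fixed by making the largest-magnitude loading of
    each component positive, so scores are fully deterministic.
    """
    n_cells = len(norm.cell_ids)
    if n_pcs > min(len(hvg_ids), max(n_cells - 1, 1)):
        raise ValueError(
            f"n_pcs={n_pcs} exceeds min(n_hvg={len(hvg_ids)}, n_cells-1={n_cells - 1})"
        )
    gene_index = {g: i for i, g in enumerate(norm.gene_ids)}
    rows = [gene_index[g] for g in hvg_ids]
    x = np.asarray(norm.log_expr[rows].todense(), dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    sd_safe = np.where(sd > 0, sd, 1.0)
    scaled = np.clip((x - mu) / sd_safe, -clip, clip)

    pca = PCA(n_components=n_pcs, svd_solver="full", random_state=seed)
    scores = pca.fit_transform(scaled.T)        # cells x n_pcs
    loadings = pca.components_.T                # HVG x n_pcs
    # deterministic sign: largest |loading| entry positive per component
    for k in range(n_pcs):
        j = np.argmax(np.abs(loadings[:, k]))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1
    norm.hvg_ids = list(hvg_ids)
    norm.scaled_expr = scaled
    norm.pca_scores = scores
    norm.pca_loadings = loadings
    norm.explained_variance_ratio = pca.explained_variance_ratio_
    return norm
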