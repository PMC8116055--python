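"""Graph-based clustering in PC space and correlation-based annotation.

Cells are clustered on a shared-nearest-neighbor (SNN) graph: k nearest
neighbours (Euclidean, the cell itself included), Jaccard overlap of
neighbour sets as edge weights, weights below 1/15 pruned, then
modularity optimisation (Leiden, RB-configuration quality, which refines
the classic Louvain scheme) at a given resolution and seed.

Annotation mirrors reference-correlation cell typing: each cluster's
mean log-expression profile is correlated (Spearman by default) against
every reference type over the shared genes, and the cluster takes the
best-correlated type; a small top1-top2 margin flags the call ambiguous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import igraph
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import rankdata
from sklearn.neighbors import NearestNeighbors

from .datamodel import ReferenceProfiles
from .qc import NormalizedMatrix

__all__ = ["ClusterAssignment", "TypeAnnotation", "cluster_cells",
           "annotate_clusters"]

SNN_PRUNE = 1.0 / 15.0


@dataclass
class ClusterAssignment:
    labels: np.ndarray        # per-cell integer label, contiguous from 0
    k_neighbors: int
    resolution: float
    seed: int
    modularity: float

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0


@dataclass
class TypeAnnotation:
    table: pd.DataFrame       # cluster, assigned_type, r per type, margin, ambiguous

    def cell_types(self, labels: np.ndarray) -> np.ndarray:
        """Expand the per-cluster assignment to per-cell type labels."""
        mapping = dict(zip(self.table["cluster"], self.table["assigned_type"]))
        return np.array([mapping[c] for c in labels])


def _snn_graph(scores: np.ndarray, k: int) -> sp.csr_matrix:
    n = scores.shape[0]
    nn = NearestNeighbors(n_neighbors=min(k, n)).fit(scores)
    knn = nn.kneighbors_graph(scores, mode="connectivity")  # includes self
    shared = (knn @ knn.T).tocoo()  # |A intersect B| for neighbour sets
    union = 2 * min(k, n) - shared.data
    jac = shared.data / union
    keep = jac >= SNN_PRUNE
    snn = sp.coo_matrix((jac[keep], (shared.row[keep], shared.col[keep])),
                        shape=(n, n)).tocsr()
    snn.setdiag(0)
    snn.eliminate_zeros()
    return snn


def cluster_cells(pca_scores, k_neighbors: int = 20, resolution: float = 1.0,
                  seed: int = 0) -> ClusterAssignment:
    """SNN-graph community detection on PC scores; deterministic per seed."""
    scores = np.asarray(pca_scores, dtype=float)
    if scores.ndim != 2 or scores.shape[0] < 2:
        raise ValueError("need a cells x PCs matrix with >= 2 cells")
    n = scores.shape[0]
    if k_neighbors >= n:
        raise ValueError("k_neighbors must be smaller than the number of cells")
    if np.allclose(scores, scores[0]):
        warnings.warn("all cells identical in PC space; single cluster")
        return ClusterAssignment(np.zeros(n, dtype=int), k_neighbors,
                                 resolution, seed, 0.0)
    snn = _snn_graph(scores, k_neighbors)
    coo = sp.triu(snn, k=1).tocoo()
    g = igraph.Graph(n=n, edges=list(zip(coo.row.tolist(), coo.col.tolist())),
                     edge_attrs={"weight": coo.data.tolist()})
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        weights="weight", resolution_parameter=resolution, seed=seed,
        n_iterations=4,
    )
    labels = np.asarray(part.membership, dtype=int)
    # relabel by decreasing cluster size (stable across cell permutations
    # up to cluster identity), keeping labels contiguous from 0
    sizes = pd.Series(labels).value_counts()
    remap = {old: new for new, old in enumerate(sizes.index)}
    labels = np.array([remap[c] for c in labels])
    modularity = g.modularity(part.membership, weights="weight")
    return ClusterAssignment(labels, k_neighbors, resolution, seed,
                             float(modularity))


def annotate_clusters(
    norm: NormalizedMatrix,
    clusters: ClusterAssignment,
    ref: ReferenceProfiles,
    genes=None,
    method: str = "spearman",
    margin_min: float = 0.02,
) -> TypeAnnotation:
    """Assign each cluster the reference type its profile correlates best with.

    ``genes`` defaults to the HVGs intersected with the reference genes.
    Ties go to the earlier reference type and are flagged ambiguous, as
    is any call whose top1-top2 correlation margin falls below
    ``margin_min``.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown correlation method {method!r}")
    if genes is None:
        genes = [g for g in (norm.hvg_ids or norm.gene_ids) if g in set(ref.gene_ids)]
    genes = [g for g in genes if g in set(ref.gene_ids) and g in set(norm.gene_ids)]
    if len(genes) < 10:
        raise ValueError(
            f"only {len(genes)} genes shared with the reference; "
            "annotation would be meaningless (need >= 10)"
        )
    gidx_norm = {g: i for i, g in enumerate(norm.gene_ids)}
    gidx_ref = {g: i for i, g in enumerate(ref.gene_ids)}
    rows_norm = [gidx_norm[g] for g in genes]
    rows_ref = [gidx_ref[g] for g in genes]
    ref_mat = ref.mean_expr[rows_ref]                      # genes x types
    expr = np.asarray(norm.log_expr[rows_norm].todense())  # genes x cells

    rows = []
    for c in range(clusters.n_clusters):
        profile = expr[:, clusters.labels == c].mean(axis=1)
        rs = np.array([
            _corr(profile, ref_mat[:, t], method)
            for t in range(len(ref.type_names))
        ])
        order = np.argsort(-rs, kind="stable")  # ties -> earlier reference type
        top1, top2 = order[0], (order[1] if len(order) > 1 else order[0])
        margin = float(rs[top1] - rs[top2]) if len(order) > 1 else np.inf
        row = {"cluster": c, "assigned_type": ref.type_names[top1],
               "r_top1": float(rs[top1]), "r_top2": float(rs[top2]),
               "margin": margin, "ambiguous": bool(margin < margin_min)}
        for t, r in zip(ref.type_names, rs):
            row[f"r_{t}"] = float(r)
        rows.append(row)
    return TypeAnnotation(pd.DataFrame(rows))


def _corr(a: np.ndarray, b: np.ndarray, method: str) -> float:
    if method == "spearman":
        a, b = rankdata(a), rankdata(b)
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0  # flat profile carries no information
    return float(np.corrcoef(a, b)[0, 1])
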