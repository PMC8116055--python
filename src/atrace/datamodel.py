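"""Core data containers and plain-text I/O.

Count matrices follow the 10x convention: features in rows, cells in
columns.  A :class:`CountsBundle` keeps the gene-expression block and the
antigen-tag block of a feature-barcode capture side by side, with a shared
cell axis.  All on-disk formats are plain text: MatrixMarket coordinate
triplets for sparse counts, TSV for feature/barcode lists, reference
profiles and result tables.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "CountsBundle",
    "ReferenceProfiles",
    "FormatError",
    "read_triplet_matrix",
    "write_triplet_matrix",
    "read_reference_profiles",
    "write_reference_profiles",
    "read_result_table",
    "write_result_table",
    "subset_bundle",
]

#: feature-class labels used in the features file to split blocks; the tags
#: ride the antibody-capture route of feature-barcode chemistry.
GENE_FEATURE_CLASS = "Gene Expression"
TAG_FEATURE_CLASS = "Antibody Capture"


class FormatError(ValueError):
    """A file violates the expected on-disk format."""


def _check_unique(ids, what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise FormatError(f"duplicate {what}: {x!r}")
        seen.add(x)


@dataclass
class CountsBundle:
    """Gene and antigen-tag UMI counts over a shared set of cells.

    Attributes
    ----------
    gene_counts, tag_counts
        Sparse integer matrices, features x cells, identical column order.
    cell_meta
        Per-cell table aligned with ``cell_ids`` (sample / timepoint /
        fraction labels; may carry more columns downstream).
    """

    gene_counts: sp.csr_matrix
    tag_counts: sp.csr_matrix
    gene_ids: list[str]
    tag_ids: list[str]
    cell_ids: list[str]
    cell_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.gene_counts = sp.csr_matrix(self.gene_counts)
        self.tag_counts = sp.csr_matrix(self.tag_counts)
        self.gene_ids = list(self.gene_ids)
        self.tag_ids = list(self.tag_ids)
        self.cell_ids = list(self.cell_ids)
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=pd.Index(self.cell_ids, name="cell_id"))
        self.validate()

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def validate(self) -> None:
        _check_unique(self.gene_ids, "gene id")
        _check_unique(self.tag_ids, "tag id")
        _check_unique(self.cell_ids, "cell barcode")
        n = len(self.cell_ids)
        if self.gene_counts.shape != (len(self.gene_ids), n):
            raise FormatError(
                f"gene_counts shape {self.gene_counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {n} cells"
            )
        if self.tag_counts.shape != (len(self.tag_ids), n):
            raise FormatError(
                f"tag_counts shape {self.tag_counts.shape} does not match "
                f"{len(self.tag_ids)} tags x {n} cells"
            )
        if len(self.cell_meta) != n:
            raise FormatError("cell_meta row count does not match number of cells")
        for m in (self.gene_counts, self.tag_counts):
            if m.nnz and (m.data < 0).any():
                raise FormatError("negative counts are not allowed")

    def copy(self) -> "CountsBundle":
        return CountsBundle(
            self.gene_counts.copy(),
            self.tag_counts.copy(),
            list(self.gene_ids),
            list(self.tag_ids),
            list(self.cell_ids),
            self.cell_meta.copy(),
        )


@dataclass
class ReferenceProfiles:
    """Mean log-expression of each reference cell type (genes x types)."""

    type_names: list[str]
    gene_ids: list[str]
    mean_expr: np.ndarray

    def __post_init__(self):
        self.type_names = list(self.type_names)
        self.gene_ids = list(self.gene_ids)
        self.mean_expr = np.asarray(self.mean_expr, dtype=float)
        _check_unique(self.type_names, "reference type")
        if self.mean_expr.shape != (len(self.gene_ids), len(self.type_names)):
            raise FormatError("mean_expr shape does not match gene/type labels")
        if not np.isfinite(self.mean_expr).all():
            raise FormatError("reference profiles contain non-finite values")


# ---------------------------------------------------------------------------
# triplet matrix (MatrixMarket) + features + barcodes
# ---------------------------------------------------------------------------

def read_triplet_matrix(
    matrix_path,
    features_path,
    barcodes_path,
    gene_class: str = GENE_FEATURE_CLASS,
    tag_class: str = TAG_FEATURE_CLASS,
) -> CountsBundle:
    """Read a feature-barcode matrix and split it into gene and tag blocks.

    ``features_path`` is a TSV with one row per feature: either
    ``id<TAB>class`` or the 10x-style ``id<TAB>name<TAB>class``.  Features
    whose class equals ``tag_class`` form the tag block; everything else is
    treated as gene expression.  Cells listed in the barcodes file but
    absent from the triplets are kept as all-zero columns — removing empty
    cells is QC's job, not I/O's.
    """
    try:
        mat = scipy.io.mmread(str(matrix_path))
    except Exception as exc:  # mmread raises assorted ValueErrors
        raise FormatError(f"cannot parse matrix {matrix_path}: {exc}") from exc
    mat = sp.csr_matrix(mat)

    feats = pd.read_csv(features_path, sep="\t", header=None, dtype=str)
    if feats.shape[1] < 2:
        raise FormatError("features file needs at least id and class columns")
    feat_ids = feats.iloc[:, 0].tolist()
    feat_class = feats.iloc[:, -1].tolist()

    barcodes = [
        line.strip()
        for line in Path(barcodes_path).read_text().splitlines()
        if line.strip()
    ]
    dup = _first_duplicate(barcodes)
    if dup is not None:
        raise FormatError(f"duplicate barcodes: first duplicate is {dup!r}")

    if mat.shape[0] != len(feat_ids):
        raise FormatError(
            f"matrix header claims {mat.shape[0]} features but features "
            f"table lists {len(feat_ids)}"
        )
    if mat.shape[1] != len(barcodes):
        raise FormatError(
            f"matrix header claims {mat.shape[1]} cells but barcodes file "
            f"lists {len(barcodes)}"
        )

    is_tag = np.array([c == tag_class for c in feat_class])
    gene_rows = np.where(~is_tag)[0]
    tag_rows = np.where(is_tag)[0]
    return CountsBundle(
        gene_counts=mat[gene_rows],
        tag_counts=mat[tag_rows],
        gene_ids=[feat_ids[i] for i in gene_rows],
        tag_ids=[feat_ids[i] for i in tag_rows],
        cell_ids=barcodes,
    )


def write_triplet_matrix(bundle: CountsBundle, outdir, prefix: str = "") -> dict:
    """Write a bundle back to matrix.mtx / features.tsv / barcodes.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stacked = sp.vstack([bundle.gene_counts, bundle.tag_counts]).tocoo()
    paths = {
        "matrix": outdir / f"{prefix}matrix.mtx",
        "features": outdir / f"{prefix}features.tsv",
        "barcodes": outdir / f"{prefix}barcodes.tsv",
    }
    scipy.io.mmwrite(str(paths["matrix"]), stacked, field="integer")
    with open(paths["features"], "w") as fh:
        for g in bundle.gene_ids:
            fh.write(f"{g}\t{g}\t{GENE_FEATURE_CLASS}\n")
        for t in bundle.tag_ids:
            fh.write(f"{t}\t{t}\t{TAG_FEATURE_CLASS}\n")
    with open(paths["barcodes"], "w") as fh:
        fh.writelines(c + "\n" for c in bundle.cell_ids)
    return paths


def _first_duplicate(items):
    seen = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None


# ---------------------------------------------------------------------------
# result tables and reference profiles
# ---------------------------------------------------------------------------

def write_result_table(table: pd.DataFrame, path) -> Path:
    """Write a result table as TSV with >= 9 significant digits for floats.

    Round-trips through :func:`read_result_table` to within 1e-9.
    """
    if len(set(table.columns)) != len(table.columns):
        raise FormatError("result table has duplicate column names")
    path = Path(path)
    table.to_csv(path, sep="\t", index=False, float_format="%.12g")
    return path


def read_result_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_reference_profiles(ref: ReferenceProfiles, path) -> Path:
    path = Path(path)
    df = pd.DataFrame(ref.mean_expr, columns=ref.type_names)
    df.insert(0, "gene_id", ref.gene_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")
    return path


def read_reference_profiles(path) -> ReferenceProfiles:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise FormatError("reference profile file needs gene id + >=1 type column")
    return ReferenceProfiles(
        type_names=list(df.columns[1:]),
        gene_ids=df.iloc[:, 0].astype(str).tolist(),
        mean_expr=df.iloc[:, 1:].to_numpy(dtype=float),
    )


def subset_bundle(bundle: CountsBundle, cell_mask) -> CountsBundle:
    """Restrict a bundle to the cells selected by a boolean mask.

    Feature rows are untouched; metadata rows are subset consistently and
    cell order is preserved.
    """
    mask = np.asarray(cell_mask, dtype=bool)
    if mask.shape != (bundle.n_cells,):
        raise ValueError(
            f"mask length {mask.shape} does not match {bundle.n_cells} cells"
        )
    idx = np.where(mask)[0]
    return CountsBundle(
        gene_counts=bundle.gene_counts[:, idx],
        tag_counts=bundle.tag_counts[:, idx],
        gene_ids=bundle.gene_ids,
        tag_ids=bundle.tag_ids,
        cell_ids=[bundle.cell_ids[i] for i in idx],
        cell_meta=bundle.cell_meta.iloc[idx].copy(),
    )
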