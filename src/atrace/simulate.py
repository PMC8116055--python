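"""Synthetic data with the statistical structure of an antigen-tracking
feature-barcode capture.

The generator emulates a lymph-node capture in which myeloid and stromal
populations were enriched and recombined with lymphocytes at a 4:4:1:1
ratio: several cell types with distinct gene signatures, a conjugated
antigen tag whose per-cell counts follow a two-component log10-normal
mixture (a "high" fraction that varies by type), unconjugated control
tags that are essentially undetectable, and T/B cells carrying only the
low component so they can serve as the normalisation baseline.

Gene counts are negative binomial (mean x signature fold on the type's
signature genes); a block of mitochondrially encoded genes (``mt-``
prefix) is included so QC's mito fraction is exercised.  Tag reads, when
requested, are emitted as (cell barcode, UMI, tag barcode) tuples with a
shifted-Poisson PCR duplicate count per molecule and independent
per-base substitution errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .datamodel import CountsBundle, ReferenceProfiles

__all__ = ["SimConfig", "SyntheticTruth", "TagRead",
           "simulate_counts", "simulate_tag_reads", "make_reference",
           "DEFAULT_TAG_BARCODES"]

BASES = np.array(list("ACGT"))

#: conjugated tag first, unconjugated controls after; pairwise Hamming
#: distance >= 3 by construction so 1-mismatch correction is unambiguous
DEFAULT_TAG_BARCODES = {
    "ova-psDNA": "AACCGGTTACGT",
    "psDNA": "CCAATTGGCATG",
    "pDNA": "GGTTAACCTGCA",
}


@dataclass
class SimConfig:
    """Generator parameters; defaults define the standard study-like run."""

    n_cells_per_type: dict = field(default_factory=lambda: {
        "cDC2": 800, "LEC": 800, "Tcell": 200, "Bcell": 200,
    })
    #: relative 4:4:1:1-style enrichment weights (documentation of the
    #: composition; n_cells_per_type is authoritative for cell numbers)
    mixing_ratio: dict = field(default_factory=lambda: {
        "cDC2": 4, "LEC": 4, "Tcell": 1, "Bcell": 1,
    })
    n_genes: int = 1000
    n_signature_genes: int = 20
    type_signature_genes: Optional[dict] = None  # derived if None
    n_mito_genes: int = 10
    mito_gene_prefix: str = "mt-"
    baseline_gene_mean: float = 0.5
    mito_gene_mean: float = 2.0
    signature_fold: float = 4.0
    nb_dispersion: float = 2.0
    antigen_high_fraction: dict = field(default_factory=lambda: {
        "cDC2": 0.7, "LEC": 0.1, "Tcell": 0.0, "Bcell": 0.0,
    })
    baseline_types: tuple = ("Tcell", "Bcell")
    antigen_low_logmean: float = 0.3   # log10 counts; ~2 molecules
    antigen_high_logmean: float = 2.3  # two decades above the low mode
    antigen_logsd: float = 0.35
    control_tag_rate: float = 0.05
    tag_barcodes: dict = field(default_factory=lambda: dict(DEFAULT_TAG_BARCODES))
    conjugated_tag: str = "ova-psDNA"
    pcr_duplication_mean: float = 3.0
    seq_error_rate: float = 0.001
    cell_barcode_len: int = 16
    umi_len: int = 12
    sample_label: str = "sample1"
    seed: int = 0

    def validate(self) -> None:
        for t in self.antigen_high_fraction:
            if t not in self.n_cells_per_type:
                raise ValueError(f"antigen_high_fraction names unknown type {t!r}")
        for t, f in self.antigen_high_fraction.items():
            if not 0 <= f <= 1:
                raise ValueError(f"high fraction for {t!r} outside [0, 1]")
        for t in self.baseline_types:
            if t not in self.n_cells_per_type:
                raise ValueError(f"baseline type {t!r} not simulated")
        if any(w <= 0 for w in self.mixing_ratio.values()):
            raise ValueError("mixing ratio weights must be positive")
        if self.control_tag_rate < 0:
            raise ValueError("control_tag_rate must be >= 0")
        if self.pcr_duplication_mean < 1:
            raise ValueError("pcr_duplication_mean must be >= 1")
        if not 0 <= self.seq_error_rate <= 1:
            raise ValueError("seq_error_rate must be in [0, 1]")
        if min(self.cell_barcode_len, self.umi_len,
               *(len(b) for b in self.tag_barcodes.values())) < 4:
            raise ValueError("barcode lengths must be >= 4")
        if self.conjugated_tag not in self.tag_barcodes:
            raise ValueError("conjugated_tag missing from tag_barcodes")


@dataclass
class SyntheticTruth:
    """Ground truth for every simulated cell plus the generating config."""

    cells: pd.DataFrame   # cell_id, true_type, true_antigen_class, true_tag_umi_count
    genes: pd.DataFrame   # gene_id, is_signature_of
    config: SimConfig
    tag_counts_true: pd.DataFrame  # tags x cells true UMI counts


@dataclass(frozen=True)
class TagRead:
    cell_barcode: str
    umi: str
    tag_barcode: str


def _gene_table(config: SimConfig) -> pd.DataFrame:
    types = list(config.n_cells_per_type)
    if config.type_signature_genes is not None:
        sig_map = config.type_signature_genes
        sig_genes = [g for gs in sig_map.values() for g in gs]
        other = [f"gene{i:04d}" for i in range(config.n_genes - len(sig_genes)
                                               - config.n_mito_genes)]
        rows = [(g, t) for t, gs in sig_map.items() for g in gs]
        rows += [(g, "") for g in other]
    else:
        rows = []
        gi = 0
        for t in types:
            for _ in range(config.n_signature_genes):
                rows.append((f"gene{gi:04d}", t))
                gi += 1
        n_other = config.n_genes - gi - config.n_mito_genes
        for _ in range(max(n_other, 0)):
            rows.append((f"gene{gi:04d}", ""))
            gi += 1
    rows += [(f"{config.mito_gene_prefix}gene{i}", "") for i in range(config.n_mito_genes)]
    return pd.DataFrame(rows, columns=["gene_id", "is_signature_of"])


def _random_seqs(rng, n: int, length: int) -> list[str]:
    """Distinct random DNA sequences (resampling collisions away)."""
    seqs: list[str] = []
    seen = set()
    while len(seqs) < n:
        block = ["".join(BASES[rng.integers(0, 4, length)])
                 for _ in range(n - len(seqs))]
        for s in block:
            if s not in seen:
                seen.add(s)
                seqs.append(s)
    return seqs


def simulate_counts(config: SimConfig) -> tuple[CountsBundle, SyntheticTruth]:
    """Draw a gene x cell and tag x cell count matrix plus ground truth.

    Gene counts: NB(mean = baseline x fold on signature genes, dispersion
    theta) — var = mu + mu^2/theta.  Conjugated tag: class ~
    Bernoulli(high fraction of the type), count = round(10^z) with z
    normal on the log10 scale.  Baseline (T/B) types are forced to the
    low class.  Control tags: Poisson(control_tag_rate).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = _gene_table(config)
    types = list(config.n_cells_per_type)
    n_cells = int(sum(config.n_cells_per_type.values()))

    cell_types = np.repeat(types, [config.n_cells_per_type[t] for t in types])
    perm = rng.permutation(n_cells)  # shuffle so cell order carries no signal
    cell_types = cell_types[perm]
    cell_ids = _random_seqs(rng, n_cells, config.cell_barcode_len)

    # gene counts
    theta = config.nb_dispersion
    mito_mask = genes["gene_id"].str.startswith(config.mito_gene_prefix).to_numpy()
    mean_mat = np.full((len(genes), n_cells), config.baseline_gene_mean)
    mean_mat[mito_mask, :] = config.mito_gene_mean
    for t in types:
        sig = (genes["is_signature_of"] == t).to_numpy()
        cols = cell_types == t
        mean_mat[np.ix_(sig, cols)] *= config.signature_fold
    p_nb = theta / (theta + mean_mat)
    gene_counts = rng.negative_binomial(theta, p_nb)

    # antigen classes and tag counts
    high_frac = np.array([
        0.0 if t in config.baseline_types else config.antigen_high_fraction.get(t, 0.0)
        for t in cell_types
    ])
    is_high = rng.random(n_cells) < high_frac
    logmean = np.where(is_high, config.antigen_high_logmean, config.antigen_low_logmean)
    z = rng.normal(logmean, config.antigen_logsd)
    conj_counts = np.round(10.0 ** z).astype(np.int64)

    tag_ids = list(config.tag_barcodes)
    tag_counts = np.zeros((len(tag_ids), n_cells), dtype=np.int64)
    for i, t in enumerate(tag_ids):
        if t == config.conjugated_tag:
            tag_counts[i] = conj_counts
        else:
            tag_counts[i] = rng.poisson(config.control_tag_rate, n_cells)

    cell_meta = pd.DataFrame(
        {
            "sample": config.sample_label,
            "timepoint": "t0",
            "fraction": "mixed",
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    bundle = CountsBundle(
        gene_counts=sp.csr_matrix(gene_counts),
        tag_counts=sp.csr_matrix(tag_counts),
        gene_ids=genes["gene_id"].tolist(),
        tag_ids=tag_ids,
        cell_ids=cell_ids,
        cell_meta=cell_meta,
    )
    truth = SyntheticTruth(
        cells=pd.DataFrame({
            "cell_id": cell_ids,
            "true_type": cell_types,
            "true_antigen_class": np.where(is_high, "high", "low"),
            "true_tag_umi_count": conj_counts,
        }),
        genes=genes,
        config=config,
        tag_counts_true=pd.DataFrame(tag_counts, index=tag_ids, columns=cell_ids),
    )
    return bundle, truth


def simulate_tag_reads(truth: SyntheticTruth, config: SimConfig) -> list[TagRead]:
    """Expand true tag molecules into PCR-duplicated, error-prone reads.

    Each true UMI yields ``1 + Poisson(pcr_duplication_mean - 1)`` reads;
    every emitted base is substituted independently with probability
    ``seq_error_rate`` (uniform over the three other bases).
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    reads: list[TagRead] = []
    tag_mat = truth.tag_counts_true
    for tag_id in tag_mat.index:
        tag_bc = config.tag_barcodes[tag_id]
        counts = tag_mat.loc[tag_id]
        for cell_bc, n_umi in counts.items():
            if n_umi == 0:
                continue
            umis = ["".join(BASES[rng.integers(0, 4, config.umi_len)])
                    for _ in range(int(n_umi))]
            for umi in umis:
                n_reads = 1 + rng.poisson(config.pcr_duplication_mean - 1.0)
                for _ in range(n_reads):
                    reads.append(TagRead(
                        _mutate(cell_bc, config.seq_error_rate, rng),
                        _mutate(umi, config.seq_error_rate, rng),
                        _mutate(tag_bc, config.seq_error_rate, rng),
                    ))
    return reads


def _mutate(seq: str, rate: float, rng) -> str:
    if rate == 0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(arr.size) < rate
    if hit.any():
        for i in np.where(hit)[0]:
            choices = [b for b in "ACGT" if b != arr[i]]
            arr[i] = choices[rng.integers(0, 3)]
        return "".join(arr)
    return seq


def make_reference(config: SimConfig) -> ReferenceProfiles:
    """Expected per-type log expression implied by the generator.

    Mirrors what a bulk reference atlas provides for correlation-based
    annotation: log1p of the expected count of every gene in every type.
    With ``signature_fold == 1`` all profiles are identical and
    annotation must report ambiguity.
    """
    config.validate()
    genes = _gene_table(config)
    types = list(config.n_cells_per_type)
    mito_mask = genes["gene_id"].str.startswith(config.mito_gene_prefix).to_numpy()
    expr = np.full((len(genes), len(types)), config.baseline_gene_mean)
    expr[mito_mask, :] = config.mito_gene_mean
    for j, t in enumerate(types):
        sig = (genes["is_signature_of"] == t).to_numpy()
        expr[sig, j] *= config.signature_fold
    return ReferenceProfiles(
        type_names=types,
        gene_ids=genes["gene_id"].tolist(),
        mean_expr=np.log1p(expr),
    )
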