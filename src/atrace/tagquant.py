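"""Antigen-tag read counting: barcode matching and UMI collapsing.

Turns (cell barcode, UMI, tag barcode) read tuples into a tags x cells
UMI count matrix.  Cell barcodes are matched exactly against the cell
whitelist; tag barcodes may be corrected at up to one mismatch, which is
unambiguous because the tag whitelist is validated to have pairwise
Hamming distance >= 3.  Within each (cell, tag) group UMIs are
deduplicated exactly, or additionally merged with the directional
rule: u is absorbed into v when Hamming(u, v) = 1 and
reads(v) >= 2 * reads(u) - 1.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .simulate import TagRead

__all__ = ["TagWhitelist", "TagCountResult", "match_tag", "collapse_umis",
           "hamming", "read_tag_reads_tsv"]


def hamming(a: str, b: str) -> int:
    """Hamming distance; N (or any non-ACGT symbol) mismatches everything."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    return sum(1 for x, y in zip(a, b) if x != y or x not in "ACGT")


@dataclass
class TagWhitelist:
    """tag id -> barcode, all equal length, pairwise Hamming distance >= 3."""

    barcodes: dict

    def __post_init__(self):
        items = list(self.barcodes.items())
        if not items:
            raise ValueError("empty tag whitelist")
        length = len(items[0][1])
        for _, bc in items:
            if len(bc) != length:
                raise ValueError("tag barcodes must all have the same length")
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                d = hamming(items[i][1], items[j][1])
                if d < 3:
                    raise ValueError(
                        f"tag barcodes {items[i][0]!r} and {items[j][0]!r} are "
                        f"at Hamming distance {d} < 3; 1-mismatch correction "
                        "would be ambiguous"
                    )
        self.length = length

    @classmethod
    def from_tsv(cls, path) -> "TagWhitelist":
        df = pd.read_csv(path, sep="\t", header=None, names=["tag_id", "barcode"],
                         dtype=str)
        return cls(dict(zip(df["tag_id"], df["barcode"])))


@dataclass
class TagCountResult:
    tag_counts: sp.csr_matrix   # tags x cells
    tag_ids: list
    cell_ids: list
    n_exact: int
    n_corrected: int
    n_ambiguous: int
    n_unmatched: int
    n_duplicate_umi: int

    @property
    def n_reads(self) -> int:
        return self.n_exact + self.n_corrected + self.n_ambiguous + self.n_unmatched

    def audit_table(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "n_exact": self.n_exact, "n_corrected": self.n_corrected,
            "n_ambiguous": self.n_ambiguous, "n_unmatched": self.n_unmatched,
            "n_duplicate_umi": self.n_duplicate_umi,
        }])


def match_tag(read_barcode: str, whitelist: TagWhitelist, max_mismatch: int = 1):
    """Assign a read's tag barcode to the unique whitelist entry within
    ``max_mismatch`` substitutions; None when nothing qualifies or two
    entries tie at the minimum distance."""
    if max_mismatch not in (0, 1):
        raise ValueError("max_mismatch must be 0 or 1")
    if len(read_barcode) != whitelist.length:
        raise ValueError(
            f"read barcode length {len(read_barcode)} != whitelist length "
            f"{whitelist.length}"
        )
    best_id, best_d, n_best = None, None, 0
    for tag_id, bc in whitelist.barcodes.items():
        d = hamming(read_barcode, bc)
        if best_d is None or d < best_d:
            best_id, best_d, n_best = tag_id, d, 1
        elif d == best_d:
            n_best += 1
    if best_d is None or best_d > max_mismatch or n_best > 1:
        return None
    return best_id


def collapse_umis(
    reads,
    whitelist: TagWhitelist,
    cell_whitelist,
    umi_merge: str = "none",
    max_mismatch: int = 1,
) -> TagCountResult:
    """Count surviving UMIs per (cell, tag) after dedup and optional merge.

    Reads whose cell barcode is not in the whitelist, or whose tag
    barcode cannot be assigned, are excluded and tallied.  The output
    matrix columns follow the iteration order of ``cell_whitelist`` and
    rows the whitelist's tag order; results are invariant to read order.
    """
    if umi_merge not in ("none", "hamming1_directional"):
        raise ValueError(f"unknown umi_merge mode {umi_merge!r}")
    cell_ids = list(dict.fromkeys(cell_whitelist))
    cell_index = {c: i for i, c in enumerate(cell_ids)}
    tag_ids = list(whitelist.barcodes)
    tag_index = {t: i for i, t in enumerate(tag_ids)}

    n_exact = n_corrected = n_ambiguous = n_unmatched = 0
    umi_reads: dict = defaultdict(Counter)  # (cell, tag) -> Counter(umi -> reads)
    for r in reads:
        cell, umi, tag_bc = r.cell_barcode, r.umi, r.tag_barcode
        if cell not in cell_index:
            n_unmatched += 1
            continue
        if len(tag_bc) != whitelist.length:
            n_unmatched += 1
            continue
        exact = next((t for t, bc in whitelist.barcodes.items() if bc == tag_bc), None)
        if exact is not None:
            n_exact += 1
            tag = exact
        else:
            tag = match_tag(tag_bc, whitelist, max_mismatch)
            if tag is None:
                # distinguish a two-way tie from a plain miss
                dists = sorted(hamming(tag_bc, bc) for bc in whitelist.barcodes.values())
                if (len(dists) > 1 and dists[0] == dists[1]
                        and dists[0] <= max_mismatch):
                    n_ambiguous += 1
                else:
                    n_unmatched += 1
                continue
            n_corrected += 1
        umi_reads[(cell, tag)][umi] += 1

    n_duplicate = 0
    mat = sp.dok_matrix((len(tag_ids), len(cell_ids)), dtype=np.int64)
    for (cell, tag), counter in umi_reads.items():
        n_duplicate += sum(counter.values()) - len(counter)
        if umi_merge == "hamming1_directional":
            n_umis = _directional_merge(counter)
        else:
            n_umis = len(counter)
        mat[tag_index[tag], cell_index[cell]] = n_umis
    return TagCountResult(
        tag_counts=mat.tocsr(), tag_ids=tag_ids, cell_ids=cell_ids,
        n_exact=n_exact, n_corrected=n_corrected,
        n_ambiguous=n_ambiguous, n_unmatched=n_unmatched,
        n_duplicate_umi=n_duplicate,
    )


def _directional_merge(counter: Counter) -> int:
    """Directional UMI network collapse (UMI-tools rule).

    UMIs are visited in decreasing read count (ties by sequence, so the
    result is order-independent); a UMI is absorbed by an already
    accepted UMI at Hamming distance 1 whose read count is at least
    2x its own minus 1.
    """
    accepted: list[tuple[str, int]] = []
    for umi, cnt in sorted(counter.items(), key=lambda kv: (-kv[1], kv[0])):
        absorbed = any(
            hamming(umi, parent) == 1 and parent_cnt >= 2 * cnt - 1
            for parent, parent_cnt in accepted
        )
        if not absorbed:
            accepted.append((umi, cnt))
    return len(accepted)


def read_tag_reads_tsv(path) -> list[TagRead]:
    """Load reads from a 3-column TSV (cell barcode, UMI, tag barcode)."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["cell_barcode", "umi", "tag_barcode"], dtype=str)
    return [TagRead(*row) for row in df.itertuples(index=False)]
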