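"""Relative antigen signal against the T/B-cell baseline, and per-type
comparison statistics.

The antigen tag is captured in T and B cells only at background levels,
and those cell types appear in every capture, so the per-sample median
tag count over T/B cells serves as the normalisation baseline: relative
signal r_c = a_c / m.  For log-scale display a per-sample pseudocount of
half the smallest positive relative signal is added.

Group comparisons mirror the source-data layout of the study design:
per cell type, the number and fraction of cells, the median relative
signal, a two-sided Wilcoxon rank-sum test against the reference group
(or all pairs), the Hodges-Lehmann estimate of the median difference
with its confidence interval, and a Bonferroni-adjusted p-value over the
family of tests within the sample.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datamodel import CountsBundle
from . import stats as _st

__all__ = ["relative_signal", "compare_types"]


def relative_signal(
    bundle: CountsBundle,
    tag: str,
    baseline_types,
    annotations,
) -> pd.DataFrame:
    """Per-cell relative antigen signal, computed sample by sample.

    Parameters
    ----------
    tag
        Tag id of the conjugated antigen tag to track.
    baseline_types
        Cell types whose median raw tag count defines the denominator.
    annotations
        Per-cell type labels aligned with ``bundle.cell_ids``.

    Returns a DataFrame indexed by cell id with columns ``raw_count``,
    ``baseline_median``, ``rel_signal``, ``pseudocount``, ``display``
    (log10(rel_signal + pseudocount)), ``sample``, ``cell_type`` and
    ``baseline_degenerate``.

    If a sample's baseline median is zero the median of the positive
    baseline counts is used instead, then 1; either fallback sets the
    ``baseline_degenerate`` flag for that sample.
    """
    if tag not in bundle.tag_ids:
        raise ValueError(f"tag {tag!r} not present in bundle")
    baseline_types = set(baseline_types)
    ann = np.asarray(annotations, dtype=object)
    if ann.shape != (bundle.n_cells,):
        raise ValueError("annotations must align with the bundle's cells")
    counts = np.asarray(
        bundle.tag_counts[bundle.tag_ids.index(tag)].todense()
    ).ravel().astype(float)
    samples = (
        bundle.cell_meta["sample"].to_numpy()
        if "sample" in bundle.cell_meta.columns
        else np.repeat("sample1", bundle.n_cells)
    )
    out = pd.DataFrame({
        "raw_count": counts,
        "sample": samples,
        "cell_type": ann,
    }, index=pd.Index(bundle.cell_ids, name="cell_id"))
    out["baseline_median"] = np.nan
    out["rel_signal"] = np.nan
    out["pseudocount"] = np.nan
    out["baseline_degenerate"] = False

    for s in pd.unique(samples):
        sel = samples == s
        is_base = sel & np.isin(ann, list(baseline_types))
        if not is_base.any():
            raise ValueError(f"no baseline cells in sample {s!r}")
        base_counts = counts[is_base]
        m = float(np.median(base_counts))
        degenerate = False
        if m == 0:
            pos = base_counts[base_counts > 0]
            m = float(np.median(pos)) if pos.size else 1.0
            degenerate = True
        r = counts[sel] / m
        pos_r = r[r > 0]
        pseudo = 0.5 * float(pos_r.min()) if pos_r.size else 0.5
        out.loc[sel, "baseline_median"] = m
        out.loc[sel, "rel_signal"] = r
        out.loc[sel, "pseudocount"] = pseudo
        out.loc[sel, "baseline_degenerate"] = degenerate
    out["display"] = np.log10(out["rel_signal"] + out["pseudocount"])
    return out


def compare_types(
    signal: pd.DataFrame,
    reference_group: str = "pairwise",
    baseline_types=(),
    level: float = 0.95,
) -> pd.DataFrame:
    """Per-sample comparisons of relative signal between cell types.

    ``reference_group`` is either ``"pairwise"`` (every unordered pair
    of types, the default), ``"baseline"`` (each type against the pooled
    cells of ``baseline_types``), or a single type name.  Bonferroni
    adjustment is applied over the family of tests within each sample.
    """
    rows = []
    for s, sub in signal.groupby("sample", sort=False):
        n_total = len(sub)
        types = list(pd.unique(sub["cell_type"]))
        groups = {t: sub.loc[sub["cell_type"] == t, "rel_signal"].to_numpy()
                  for t in types}
        if reference_group == "pairwise":
            pairs = [(a, b) for i, a in enumerate(types) for b in types[i + 1:]]
        elif reference_group == "baseline":
            pooled = sub.loc[sub["cell_type"].isin(set(baseline_types)),
                             "rel_signal"].to_numpy()
            if pooled.size == 0:
                raise ValueError(f"no pooled baseline cells in sample {s!r}")
            groups["__baseline__"] = pooled
            pairs = [(t, "__baseline__") for t in types
                     if t not in set(baseline_types)]
        else:
            if reference_group not in groups:
                raise ValueError(f"reference group {reference_group!r} absent "
                                 f"from sample {s!r}")
            pairs = [(t, reference_group) for t in types if t != reference_group]

        sample_rows = []
        for a, b in pairs:
            xa, xb = groups[a], groups[b]
            row = {
                "sample": s, "group1": a, "group2": b,
                "n_cells": len(xa), "frac_cells": len(xa) / n_total,
                "median": float(np.median(xa)) if len(xa) else np.nan,
            }
            if len(xa) == 0 or len(xb) == 0:
                row.update({"statistic": np.nan, "estimate": np.nan,
                            "conf.low": np.nan, "conf.high": np.nan,
                            "p": np.nan})
            else:
                res = _st.wilcoxon_ranksum(xa, xb)
                hl = _st.hodges_lehmann(xa, xb, level=level)
                row.update({"statistic": res.u, "estimate": hl.estimate,
                            "conf.low": hl.conf_low, "conf.high": hl.conf_high,
                            "p": res.p})
            sample_rows.append(row)
        ps = np.array([r["p"] for r in sample_rows], dtype=float)
        tested = ~np.isnan(ps)
        padj = np.full_like(ps, np.nan)
        if tested.any():
            padj[tested] = _st.adjust_pvalues(ps[tested], method="bonferroni")
        for r, pa in zip(sample_rows, padj):
            r["p_adj"] = pa
        rows.extend(sample_rows)
    return pd.DataFrame(rows)
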