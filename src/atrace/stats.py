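"""Rank-based statistical kernels shared across the pipeline.

Implements the Wilcoxon/Mann-Whitney rank-sum test with an exact
small-sample null distribution, the Hodges-Lehmann shift estimate with a
rank-based confidence interval, multiple-testing procedures (Bonferroni,
Benjamini-Hochberg, and the Benjamini-Krieger-Yekutieli two-stage
step-up), the proliferation-dye "fraction diluted" statistic, and qPCR
standard-curve quantification.

The exact rank-sum distribution is computed by counting, for every value
of the Mann-Whitney U statistic, the number of equally likely rank
assignments that produce it (the coefficients of the Gaussian binomial
polynomial).  Two-sided exact p-values are defined as ``min(1, 2 * min
tail probability)``; the exact route refuses tied data and falls back to
the normal approximation with tie correction and continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RankSumResult",
    "HLInterval",
    "BkyResult",
    "wilcoxon_ranksum",
    "exact_u_pmf",
    "hodges_lehmann",
    "adjust_pvalues",
    "fraction_diluted",
    "StandardCurve",
    "quantify_standard_curve",
]


# ---------------------------------------------------------------------------
# Wilcoxon / Mann-Whitney rank sum
# ---------------------------------------------------------------------------

@dataclass
class RankSumResult:
    u: float          # Mann-Whitney U for the first sample (pairwise wins)
    p: float
    method: str       # "exact" or "approx"
    alternative: str
    tie_corrected_var: float

    @property
    def auc(self) -> float:
        """U scaled to [0, 1]: P(random x exceeds random y), ties half."""
        return self.u / self._n1n2

    _n1n2: int = 1


def exact_u_pmf(n1: int, n2: int) -> np.ndarray:
    """Null pmf of the Mann-Whitney U statistic for tie-free samples.

    ``pmf[u]`` is the probability of exactly u pairwise wins under random
    assignment of ranks; computed by dynamic programming over the number
    of assignments (partition counting), so it is exact enumeration in
    effect without materialising all C(n1+n2, n1) subsets.
    """
    n = n1 + n2
    max_sum = n * (n + 1) // 2
    # dp[j, s] = number of j-subsets of ranks {1..r} with rank sum s
    dp = np.zeros((n1 + 1, max_sum + 1))
    dp[0, 0] = 1.0
    for r in range(1, n + 1):
        for j in range(min(r, n1), 0, -1):
            dp[j, r:] += dp[j - 1, :-r]
    offset = n1 * (n1 + 1) // 2  # U = rank sum of x minus its minimum
    counts = dp[n1, offset: offset + n1 * n2 + 1]
    return counts / counts.sum()


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return sps.rankdata(pooled, method="average")


def wilcoxon_ranksum(
    x, y, alternative: str = "two_sided", mode: str = "auto"
) -> RankSumResult:
    """Two-sample rank-sum test on independent samples.

    Parameters
    ----------
    alternative
        ``two_sided``, ``greater`` (x tends larger), or ``less``.
    mode
        ``exact`` forces enumeration (refused for tied data), ``approx``
        forces the normal approximation, ``auto`` uses the exact route
        when ``n1 + n2 <= 12`` and the pooled data are tie-free.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    if alternative not in ("two_sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0  # pairwise wins of x over y, ties 0.5

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = (tie_counts > 1).any()
    n = n1 + n2
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)

    use_exact = mode == "exact" or (mode == "auto" and n <= 12 and not has_ties)
    if mode == "exact" and has_ties:
        raise ValueError("exact mode requires tie-free data; use mode='auto' or 'approx'")

    if use_exact and not has_ties:
        pmf = exact_u_pmf(n1, n2)
        ui = int(round(u))
        p_le = pmf[: ui + 1].sum()
        p_ge = pmf[ui:].sum()
        if alternative == "greater":
            p = p_ge
        elif alternative == "less":
            p = p_le
        else:
            p = min(1.0, 2.0 * min(p_le, p_ge))
        method = "exact"
    else:
        mean = n1 * n2 / 2.0
        sd = np.sqrt(var)
        if sd == 0:
            p = 1.0
        else:
            # continuity correction of 0.5 toward the mean
            if alternative == "greater":
                z = (u - mean - 0.5) / sd
                p = sps.norm.sf(z)
            elif alternative == "less":
                z = (u - mean + 0.5) / sd
                p = sps.norm.cdf(z)
            else:
                z = (abs(u - mean) - 0.5) / sd
                p = min(1.0, 2.0 * sps.norm.sf(max(z, 0.0)))
        method = "approx"
    return RankSumResult(
        u=float(u), p=float(p), method=method, alternative=alternative,
        tie_corrected_var=float(var), _n1n2=n1 * n2,
    )


# ---------------------------------------------------------------------------
# Hodges-Lehmann shift estimate and confidence interval
# ---------------------------------------------------------------------------

@dataclass
class HLInterval:
    estimate: float
    conf_low: float
    conf_high: float
    level: float
    achieved_level: float | None  # exact case only
    method: str


def hodges_lehmann(x, y, level: float = 0.95) -> HLInterval:
    """Median of pairwise differences x_i - y_j with a rank-based CI.

    The confidence interval consists of order statistics of the sorted
    pairwise differences; the selecting index comes from the exact null
    distribution of U for small samples (achieved coverage reported), or
    its normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    n1, n2 = x.size, y.size
    diffs = np.sort((x[:, None] - y[None, :]).ravel())
    m = n1 * n2
    est = float(np.median(diffs))
    alpha = 1 - level

    if m <= 2000:
        pmf = exact_u_pmf(n1, n2)
        cdf = np.cumsum(pmf)
        # largest k with P(U <= k) <= alpha/2
        k = int(np.searchsorted(cdf, alpha / 2, side="right")) - 1
        if k < 0:
            lo, hi = diffs[0], diffs[-1]
            achieved = 1.0
        else:
            # CI = [D_(k+1), D_(m-k)] in 1-based order statistics
            lo, hi = diffs[k], diffs[m - k - 1]
            achieved = float(1 - 2 * cdf[k])
        return HLInterval(est, float(lo), float(hi), level, achieved, "exact")
    z = sps.norm.ppf(1 - alpha / 2)
    k = int(np.floor(m / 2 - z * np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)))
    k = max(k, 0)
    lo = diffs[k] if k < m else diffs[0]
    hi = diffs[m - k - 1]
    return HLInterval(est, float(lo), float(hi), level, None, "approx")


# ---------------------------------------------------------------------------
# multiple-testing procedures
# ---------------------------------------------------------------------------

@dataclass
class BkyResult:
    """Two-stage step-up outcome: rejection set plus stagewise diagnostics."""

    reject: np.ndarray
    n_rejected: int
    q: float
    q_stage1: float
    q_stage2: float | None
    n_stage1: int


def adjust_pvalues(p, method: str = "bh", q: float = 0.05):
    """Multiple-testing adjustment.

    ``bonferroni`` and ``bh`` return adjusted p-value arrays;
    ``bky_two_stage`` returns a :class:`BkyResult` with the rejection
    indicator set (the procedure's natural output).
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if method == "bonferroni":
        return np.minimum(1.0, p * m)
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    if method == "bky_two_stage":
        q1 = q / (1 + q)
        r1 = int(multipletests(p, alpha=q1, method="fdr_bh")[0].sum())
        if r1 == 0 or r1 == m:
            reject = multipletests(p, alpha=q1, method="fdr_bh")[0]
            return BkyResult(reject, int(reject.sum()), q, q1, None, r1)
        q2 = q1 * m / (m - r1)
        reject = multipletests(p, alpha=q2, method="fdr_bh")[0]
        return BkyResult(reject, int(reject.sum()), q, q1, q2, r1)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# proliferation-dye fraction diluted
# ---------------------------------------------------------------------------

def fraction_diluted(event_counts) -> float:
    """Precursor-weighted fraction of cells that divided at least once.

    ``event_counts[i]`` is the number of events in dye-dilution generation
    i (generation 0 = undivided).  Each generation's events are divided by
    2^i to convert to precursor numbers:

        fraction = sum_{i>=1} N_i / 2^i  /  sum_{i>=0} N_i / 2^i
    """
    n = np.asarray(event_counts, dtype=float)
    if n.ndim != 1 or n.size == 0:
        raise ValueError("event counts must be a nonempty 1-D vector")
    if (n < 0).any():
        raise ValueError("event counts must be nonnegative")
    if n.sum() == 0:
        raise ValueError("all-zero division profile")
    w = n / 2.0 ** np.arange(n.size)
    return float(w[1:].sum() / w.sum())


# ---------------------------------------------------------------------------
# qPCR standard-curve quantification
# ---------------------------------------------------------------------------

@dataclass
class StandardCurve:
    slope: float       # Cq per log10 quantity; negative for a valid series
    intercept: float
    r_squared: float
    efficiency: float  # 10^(-1/slope) - 1; 1.0 means perfect doubling


def quantify_standard_curve(standards, unknown_cq, protein_mass=None):
    """Absolute quantification against an external dilution series.

    ``standards`` is a sequence of (log10 quantity, Cq) pairs.  Fits
    Cq = slope * log10(Q) + intercept by least squares, inverts it for the
    unknown Cq values, and optionally normalizes the quantities to lysate
    protein content.  Unknowns whose Cq falls outside the standards' range
    are flagged as extrapolated.

    Returns ``(curve, quantities, normalized, extrapolated)``.
    """
    standards = np.asarray(standards, dtype=float)
    if standards.ndim != 2 or standards.shape[1] != 2 or standards.shape[0] < 3:
        raise ValueError("need >= 3 (log10_quantity, Cq) standards")
    logq, cq = standards[:, 0], standards[:, 1]
    if logq.max() - logq.min() < 2:
        raise ValueError("standards must span >= 2 log decades")
    fit = sps.linregress(logq, cq)
    if fit.slope >= 0:
        raise ValueError("invalid dilution series: fitted slope is non-negative")
    curve = StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        efficiency=float(10 ** (-1.0 / fit.slope) - 1.0),
    )
    unknown_cq = np.asarray(unknown_cq, dtype=float)
    quantities = 10 ** ((unknown_cq - curve.intercept) / curve.slope)
    extrapolated = (unknown_cq < cq.min()) | (unknown_cq > cq.max())
    normalized = None
    if protein_mass is not None:
        protein_mass = np.asarray(protein_mass, dtype=float)
        if (protein_mass <= 0).any():
            raise ValueError("protein mass must be positive")
        normalized = quantities / protein_mass
    return curve, quantities, normalized, extrapolated
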