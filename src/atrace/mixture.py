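"""Two-component Gaussian mixture EM for antigen-high/low classification.

Per-cell antigen signal spans several orders of magnitude, so the mixture
is fit on ``log10(relative signal + pseudocount)``, where the two
components correspond to antigen-low and antigen-high populations.  EM is
initialised deterministically from the 25th/75th percentiles; components
are always relabelled so that component 2 is the one with the larger mean
("high").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = ["MixtureFit", "fit_gmm2", "classify_antigen"]


@dataclass
class MixtureFit:
    weights: np.ndarray        # (pi_low, pi_high), sums to 1
    means: np.ndarray          # (mu_low, mu_high), mu_low < mu_high
    sds: np.ndarray
    posterior_high: np.ndarray  # per-observation P(high | x)
    labels: np.ndarray          # "low" / "high" by posterior >= 0.5
    loglik_trace: list = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False
    input_scale: str = "log10(relative_signal + pseudocount)"

    @property
    def class_means(self) -> dict:
        """Mean of the observed values in each hard class."""
        out = {}
        for cls in ("low", "high"):
            sel = self.labels == cls
            out[cls] = float(self._values[sel].mean()) if sel.any() else np.nan
        return out

    _values: np.ndarray = None  # type: ignore[assignment]


def _loglik(x, w, mu, sd):
    dens = w[0] * norm.pdf(x, mu[0], sd[0]) + w[1] * norm.pdf(x, mu[1], sd[1])
    return float(np.log(np.maximum(dens, 1e-300)).sum())


def fit_gmm2(
    values,
    tol: float = 1e-8,
    max_iter: int = 1000,
    seed: int | None = None,
    min_sd: float | None = None,
    n_restarts: int = 0,
) -> MixtureFit:
    """Fit a two-component univariate Gaussian mixture by EM.

    Initialisation is deterministic (means at the 25th and 75th
    percentiles, both sds at half the overall sd, equal weights), so a
    seed only matters when ``n_restarts > 0`` adds randomly perturbed
    starts.  Component standard deviations are floored at ``min_sd``
    (default 1e-3 x overall sd) to prevent a component collapsing onto a
    single point.  The log-likelihood is checked to be non-decreasing at
    every iteration.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 10:
        raise ValueError(f"need at least 10 observations, got {x.size}")
    if not np.isfinite(x).all():
        raise ValueError("values must be finite")
    overall_sd = float(x.std())
    if overall_sd == 0:
        raise ValueError("degenerate input: all values identical")
    if min_sd is None:
        min_sd = 1e-3 * overall_sd

    starts = [(np.percentile(x, [25, 75]), np.array([overall_sd / 2] * 2),
               np.array([0.5, 0.5]))]
    if n_restarts:
        rng = np.random.default_rng(seed)
        for _ in range(n_restarts):
            mu = np.sort(rng.choice(x, 2, replace=False))
            starts.append((mu, np.array([overall_sd / 2] * 2), np.array([0.5, 0.5])))

    best = None
    for mu0, sd0, w0 in starts:
        fit = _em(x, mu0.astype(float).copy(), sd0.copy(), w0.copy(),
                  tol, max_iter, min_sd)
        if best is None or fit.loglik_trace[-1] > best.loglik_trace[-1]:
            best = fit
    return best


def _em(x, mu, sd, w, tol, max_iter, min_sd):
    trace = []
    converged = False
    resp_high = np.full_like(x, 0.5)
    if mu[0] == mu[1]:  # identical quantiles: nudge apart deterministically
        mu = mu + np.array([-0.5, 0.5]) * max(x.std(), min_sd)
    it = 0
    for it in range(1, max_iter + 1):
        # E step
        d0 = w[0] * norm.pdf(x, mu[0], sd[0])
        d1 = w[1] * norm.pdf(x, mu[1], sd[1])
        tot = np.maximum(d0 + d1, 1e-300)
        resp_high = d1 / tot
        ll = float(np.log(tot).sum())
        if trace and ll < trace[-1] - 1e-9:
            raise RuntimeError("EM log-likelihood decreased; numerical failure")
        done = len(trace) > 0 and abs(ll - trace[-1]) < tol
        trace.append(ll)
        if done:
            converged = True
            break
        # M step
        r1 = resp_high
        r0 = 1.0 - r1
        n0, n1 = max(r0.sum(), 1e-12), max(r1.sum(), 1e-12)
        mu = np.array([(r0 * x).sum() / n0, (r1 * x).sum() / n1])
        sd = np.sqrt(np.array([
            (r0 * (x - mu[0]) ** 2).sum() / n0,
            (r1 * (x - mu[1]) ** 2).sum() / n1,
        ]))
        sd = np.maximum(sd, min_sd)
        w = np.array([n0, n1]) / x.size

    if mu[0] > mu[1]:  # relabel so component 2 is the high component
        mu, sd, w = mu[::-1].copy(), sd[::-1].copy(), w[::-1].copy()
        resp_high = 1.0 - resp_high
    labels = np.where(resp_high >= 0.5, "high", "low")
    fit = MixtureFit(
        weights=w, means=mu, sds=sd, posterior_high=resp_high,
        labels=labels, loglik_trace=trace, n_iter=it, converged=converged,
    )
    fit._values = x
    return fit


def classify_antigen(
    signal: pd.DataFrame,
    grouping: str = "pooled",
    min_cells: int = 10,
    **fit_params,
) -> tuple[dict, pd.Series]:
    """Hard-classify cells as antigen-low/high per population.

    ``signal`` is the per-cell table from
    :func:`atrace.antigen.relative_signal` (needs ``display`` =
    log10(relative signal + pseudocount) and ``cell_type`` columns).
    ``grouping='pooled'`` fits a single mixture over all cells (the
    LEC-style analysis); ``grouping='per_type'`` fits each cell type
    independently (the DC-style analysis).  Groups with fewer than
    ``min_cells`` cells are skipped with a warning and left unlabelled.

    Returns ``(fits_by_group, per_cell_labels)`` where unlabelled cells
    carry NA.
    """
    if grouping not in ("pooled", "per_type"):
        raise ValueError(f"unknown grouping {grouping!r}")
    groups = (
        {"all": signal.index}
        if grouping == "pooled"
        else {t: idx for t, idx in signal.groupby("cell_type").groups.items()}
    )
    fits: dict = {}
    labels = pd.Series(pd.NA, index=signal.index, dtype="object", name="antigen_class")
    for name, idx in groups.items():
        vals = signal.loc[idx, "display"].to_numpy(dtype=float)
        if vals.size < min_cells:
            warnings.warn(f"group {name!r} has {vals.size} < {min_cells} cells; skipped")
            fits[name] = None
            continue
        fit = fit_gmm2(vals, **fit_params)
        fits[name] = fit
        labels.loc[idx] = fit.labels
    return fits, labels
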