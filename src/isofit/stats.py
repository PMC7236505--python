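"""Shared statistical machinery: BH correction and the negative-binomial
log-linear likelihood-ratio engine used by DGE/DIU/DCU/DFI/DPA.

The two-group usage test fits ``log mu = log(offset) + unit + condition +
unit:condition`` and compares against the additive reduced model with a
likelihood-ratio chi-square on ``(k - 1)(c - 1)`` degrees of freedom.
Dispersion is a pooled per-group method-of-moments estimate on
offset-normalized counts, floored at 0.01.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps

from isofit.errors import ContractError

DISPERSION_FLOOR = 0.01


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    n = p.size
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


@dataclass
class InteractionTestResult:
    unit_group_id: str
    k_units: int
    p: float | None
    statistic: float | None
    df: int | None
    status: str  # "tested" | "not_testable"
    dispersion: float | None = None


def estimate_dispersion(
    counts: np.ndarray, groups: np.ndarray, offsets: np.ndarray
) -> float:
    """Pooled method-of-moments NB dispersion.

    Counts are scaled to a common depth (offset-normalized, rescaled to the
    mean offset); per unit x group cell, ``var - mean`` over ``mean^2`` is
    pooled across cells.  The mean-squared denominator is corrected for its
    own sampling variance (``E[m^2] = mu^2 + var/n``).
    """
    offsets = np.asarray(offsets, dtype=float)
    q = counts / offsets * offsets.mean()
    num = den = 0.0
    for g in np.unique(groups):
        sub = q[:, groups == g]
        n = sub.shape[1]
        if n < 2:
            continue
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        num += float(np.sum(v - m))
        den += float(np.sum(np.maximum(m**2 - v / n, 0.0)))
    if den <= 0:
        return DISPERSION_FLOOR
    return max(num / den, DISPERSION_FLOOR)


def moderate_dispersions(
    alphas, resid_df: float, prior_df: float = 8.0
) -> np.ndarray:
    """Shrink per-gene dispersion estimates toward their across-gene mean.

    Raw method-of-moments estimates are unbiased but noisy with few
    replicates, which makes the plug-in chi-square LRT anti-conservative.
    Borrowing strength across genes (weights ``resid_df`` vs ``prior_df``)
    restores type-I error control; single-gene calls fall back to the raw
    estimate.
    """
    alphas = np.asarray(alphas, dtype=float)
    if alphas.size <= 1:
        return alphas.copy()
    prior = float(alphas.mean())
    out = (prior_df * prior + resid_df * alphas) / (prior_df + resid_df)
    return np.maximum(out, DISPERSION_FLOOR)


def _nb_lrt(y: np.ndarray, x_full: np.ndarray, x_red: np.ndarray,
            offsets: np.ndarray, alpha: float) -> tuple[float, int]:
    fam = sm.families.NegativeBinomial(alpha=alpha)
    log_off = np.log(offsets)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = sm.GLM(y, x_full, family=fam, offset=log_off).fit(maxiter=200, tol=1e-9)
        red = sm.GLM(y, x_red, family=fam, offset=log_off).fit(maxiter=200, tol=1e-9)
    stat = 2.0 * (full.llf - red.llf)
    return max(float(stat), 0.0), x_full.shape[1] - x_red.shape[1]


def fit_interaction_test(
    counts,
    groups,
    offsets,
    unit_group_id: str = "",
    dispersion: float | None = None,
) -> InteractionTestResult:
    """Likelihood-ratio test for the unit x condition interaction.

    Parameters
    ----------
    counts : (k, n) array of raw counts (units x samples).
    groups : length-n condition labels.
    offsets : length-n positive effective library sizes.
    dispersion : optional fixed NB dispersion; estimated when omitted.
    """
    counts = np.asarray(counts, dtype=float)
    groups = np.asarray(groups)
    offsets = np.asarray(offsets, dtype=float)
    if counts.ndim != 2:
        raise ContractError("counts must be a units x samples matrix")
    if (offsets <= 0).any():
        raise ContractError("offsets must be positive")
    conds = np.unique(groups)
    n_cond = len(conds)
    if n_cond < 2:
        raise ContractError("need at least 2 conditions")

    if not np.allclose(counts, np.round(counts)):
        counts = np.round(counts)
    keep = counts.sum(axis=1) > 0
    counts = counts[keep]
    k = counts.shape[0]
    if k < 2:
        return InteractionTestResult(unit_group_id, k, None, None, None, "not_testable")

    if dispersion is None:
        dispersion = estimate_dispersion(counts, groups, offsets)

    # long format: one observation per (unit, sample)
    n = counts.shape[1]
    y = counts.reshape(-1)
    unit_idx = np.repeat(np.arange(k), n)
    cond_idx = np.tile(np.searchsorted(conds, groups), k)
    off_long = np.tile(offsets, k)

    # full model: cell-means coding (one column per unit x condition cell)
    cell = unit_idx * n_cond + cond_idx
    x_full = np.eye(k * n_cond)[cell]
    # reduced model: intercept + unit + condition dummies
    x_red = np.column_stack(
        [np.ones(y.size)]
        + [(unit_idx == u).astype(float) for u in range(1, k)]
        + [(cond_idx == c).astype(float) for c in range(1, n_cond)]
    )
    try:
        stat, df = _nb_lrt(y, x_full, x_red, off_long, dispersion)
    except Exception:
        # numerical failure (e.g. empty cells); retry with a half-count shift
        try:
            stat, df = _nb_lrt(y + 0.5, x_full, x_red, off_long, dispersion)
        except Exception:
            return InteractionTestResult(
                unit_group_id, k, None, None, None, "not_testable"
            )
    p = float(sps.chi2.sf(stat, df))
    return InteractionTestResult(
        unit_group_id, k, p, stat, df, "tested", dispersion
    )


def nb_condition_test(
    counts_row,
    groups,
    offsets,
    dispersion: float | None = None,
) -> tuple[float, float]:
    """Per-gene NB LRT of a two-group condition effect; returns (stat, p)."""
    y = np.asarray(counts_row, dtype=float)
    groups = np.asarray(groups)
    offsets = np.asarray(offsets, dtype=float)
    if not np.allclose(y, np.round(y)):
        y = np.round(y)
    conds = np.unique(groups)
    if dispersion is None:
        dispersion = estimate_dispersion(y[None, :], groups, offsets)
    cond_idx = np.searchsorted(conds, groups)
    x_full = np.column_stack([np.ones(y.size)] + [
        (cond_idx == c).astype(float) for c in range(1, len(conds))
    ])
    x_red = np.ones((y.size, 1))
    try:
        stat, df = _nb_lrt(y, x_full, x_red, offsets, dispersion)
    except Exception:
        stat, df = _nb_lrt(y + 0.5, x_full, x_red, offsets, dispersion)
    return stat, float(sps.chi2.sf(stat, df))
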