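"""Shared statistics: Matthews correlation coefficient, hypergeometric
upper-tail tests and Benjamini-Hochberg correction.

Both the congruence and the enrichment modules score 2x2 confusion tables;
they share this single MCC implementation.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats as _sps
from statsmodels.stats.multitest import multipletests


def mcc(tp: int, fp: int, fn: int, tn: int) -> float:
    """Matthews correlation coefficient of a 2x2 confusion table.

    MCC = (tp*tn - fp*fn) / sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn)).
    If any factor of the denominator is zero the coefficient is defined
    as 0. All-zero tables are rejected.
    """
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("confusion counts must be non-negative")
    if tp == 0 and fp == 0 and fn == 0 and tn == 0:
        raise ValueError("MCC undefined for an all-zero confusion table")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def mcc_array(tp, fp, fn, tn) -> np.ndarray:
    """Vectorised MCC with the same zero-denominator convention."""
    tp = np.asarray(tp, dtype=float)
    fp = np.asarray(fp, dtype=float)
    fn = np.asarray(fn, dtype=float)
    tn = np.asarray(tn, dtype=float)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    out = np.zeros(np.broadcast(tp, fp, fn, tn).shape, dtype=float)
    nz = denom > 0
    num = tp * tn - fp * fn
    out[nz] = num[nz] / np.sqrt(denom[nz])
    return out


def hypergeom_sf(tp: int, universe: int, successes: int, draws: int) -> float:
    """P(X >= tp) for X ~ Hypergeometric(universe, successes, draws)."""
    return float(_sps.hypergeom.sf(tp - 1, universe, successes, draws))


def hypergeom_sf_array(tp, universe, successes, draws) -> np.ndarray:
    return _sps.hypergeom.sf(np.asarray(tp) - 1, universe, successes, draws)


def bh_qvalues(pvalues, n_tests: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    ``n_tests`` sets the size of the test family when it exceeds the number
    of materialised p-values (tests with p = 1, e.g. empty gene-set
    intersections, need not be listed explicitly: they cannot lower the
    step-up minimum but they do count in the family size).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([], dtype=float)
    if n_tests is None or n_tests <= p.size:
        return multipletests(p, method="fdr_bh")[1]
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n_tests / np.arange(1, p.size + 1)
    q_sorted = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    out = np.empty_like(q_sorted)
    out[order] = q_sorted
    return out


def one_sample_t_greater(observations, popmean: float) -> float:
    """One-tailed one-sample t-test p-value for mean(observations) > popmean.

    Degenerate zero-variance samples (where the t statistic is undefined)
    resolve by direct comparison of the common value with ``popmean``.
    """
    obs = np.asarray(observations, dtype=float)
    if obs.size < 2:
        raise ValueError("need at least two observations for the t-test")
    if np.ptp(obs) == 0.0:
        return 0.0 if obs[0] > popmean else 1.0
    res = _sps.ttest_1samp(obs, popmean, alternative="greater")
    return float(res.pvalue)
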