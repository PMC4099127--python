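"""Shared statistical primitives: paired t-test, BH step-up, correlation p-values.

The paired t-test operates on per-pair log2 tumor/normal ratios, i.e. it is a
one-sample t-test of the ratios against zero with n_pairs - 1 degrees of
freedom.  Probes with zero variance are handled explicitly: a zero mean gives
t = 0, p = 1; a nonzero mean is the p -> 0 limit and is flagged by the caller.
"""
from __future__ import annotations

import warnings

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import InsufficientPairsError

__all__ = ["paired_t_test", "bh_fdr", "correlation_p"]


def paired_t_test(diffs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided paired t-test on paired differences.

    Parameters
    ----------
    diffs : array, shape (n_features, n_pairs) or (n_pairs,)
        Per-pair differences (log2 T/N ratios).  At least two pairs.

    Returns
    -------
    t, p : arrays of shape (n_features,) (scalars collapse to 0-d arrays)
    """
    d = np.atleast_2d(np.asarray(diffs, dtype=float))
    n = d.shape[1]
    if n < 2:
        raise InsufficientPairsError(
            f"paired t-test requires >= 2 pairs, got {n}"
        )
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite paired differences")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_1samp(d, 0.0, axis=1)
    # zero-variance rows: scipy emits nan; resolve the limits explicitly
    sd = d.std(axis=1, ddof=1)
    mean = d.mean(axis=1)
    degen = sd == 0
    t = np.asarray(t, dtype=float).copy()
    p = np.asarray(p, dtype=float).copy()
    t[degen & (mean == 0)] = 0.0
    t[degen & (mean > 0)] = np.inf
    t[degen & (mean < 0)] = -np.inf
    p[degen] = np.where(mean[degen] == 0, 1.0, 0.0)
    if np.ndim(diffs) == 1:
        return t[0], p[0]
    return t, p


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def correlation_p(r, n: int):
    """Two-sided p-value for a Pearson coefficient via the t-transform.

    t = r * sqrt(n - 2) / sqrt(1 - r^2) with n - 2 degrees of freedom;
    |r| = 1 maps to p = 0.
    """
    r = np.asarray(r, dtype=float)
    if n < 3:
        raise InsufficientPairsError(
            f"correlation p-value requires n >= 3 samples, got {n}"
        )
    if np.any(np.abs(r) > 1 + 1e-12):
        raise ValueError("|r| > 1")
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = np.where(np.abs(r) == 1.0, 0.0, 2.0 * stats.t.sf(np.abs(t), n - 2))
    return p if p.ndim else float(p)
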