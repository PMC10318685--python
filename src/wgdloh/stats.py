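"""Shared statistical helpers.

Non-computable results are reported as NaN alongside a ``computable``
flag rather than raised, so that one degenerate stratum never aborts a
cohort-wide table.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaN-tolerant)."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def ranksum_p(x, y, alternative: str = "two-sided") -> float:
    """Wilcoxon rank-sum p-value (exact where SciPy supports it).

    Returns NaN when either group is empty.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if len(x) == 0 or len(y) == 0:
        return float("nan")
    return float(stats.mannwhitneyu(x, y, alternative=alternative).pvalue)


def fisher_p(table) -> float:
    """Two-sided Fisher's exact p on a 2x2 count table."""
    return float(stats.fisher_exact(np.asarray(table), alternative="two-sided")[1])


def pearson_with_p(x, y) -> tuple[float, float]:
    """Pearson r with two-sided t-distribution p; NaN on zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def log_or_difference_test(or1, se1, or2, se2) -> tuple[float, float]:
    """Two-sided z-test for a difference of two log odds ratios.

    Interpretive contrast between two independent pooled odds ratios; the
    standard errors are on the ln OR scale.
    """
    z = (np.log(or1) - np.log(or2)) / np.hypot(se1, se2)
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)
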