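"""Shared statistical helpers.

The Wilcoxon rank-sum (Mann-Whitney) p-value is used in three places:
differential reaction detection, composite-pathway target selection, and
the unit/property tests.  The exact null is used for small tie-free groups
(both n <= EXACT_MAX_N and no pooled ties); otherwise the tie-corrected
normal approximation.  The switch point is deliberate: the exact method does
not condition on ties, and determinism of the small-sample examples matters
for testing.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

# exact enumeration up to this group size (both groups); beyond it, or in the
# presence of ties, the tie-corrected normal approximation is used
EXACT_MAX_N = 6


def rank_sum_pvalue(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p-value for samples ``x`` vs ``y``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    tie_free = np.unique(pooled).size == pooled.size
    if x.size <= EXACT_MAX_N and y.size <= EXACT_MAX_N and tie_free:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)


def benjamini_hochberg(pvalues, alpha: float = 0.05):
    """BH step-up rejection mask and adjusted p-values.

    Thin wrapper over statsmodels so every caller shares one convention.
    """
    from statsmodels.stats.multitest import multipletests

    pvalues = np.asarray(pvalues, dtype=float)
    reject, adjusted, _, _ = multipletests(pvalues, alpha=alpha, method="fdr_bh")
    return reject, adjusted


def bonferroni(pvalues, alpha: float = 0.05):
    """Bonferroni rejection mask and adjusted (capped) p-values."""
    from statsmodels.stats.multitest import multipletests

    pvalues = np.asarray(pvalues, dtype=float)
    reject, adjusted, _, _ = multipletests(pvalues, alpha=alpha, method="bonferroni")
    return reject, adjusted
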