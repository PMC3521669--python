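"""Shared statistical helpers."""

from __future__ import annotations

import numpy as np
from scipy import stats

EXACT_MAX_N = 25


def ranksum(a, b, alternative: str = "two-sided"):
    """Wilcoxon rank-sum (Mann-Whitney U).

    Uses the exact null distribution when both samples are small and
    tie-free; otherwise the normal approximation with midranks and tie
    correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = ("exact" if no_ties and max(a.size, b.size) <= EXACT_MAX_N
              else "asymptotic")
    return stats.mannwhitneyu(a, b, alternative=alternative, method=method)
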