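"""Paired rank statistics.

A self-contained two-sided Wilcoxon signed-rank test: exact null
distribution (enumerated by dynamic programming over signed midranks) for
small samples, normal approximation with continuity and tie corrections for
larger ones. Zero differences are dropped before ranking (Wilcoxon's
convention).
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata


def _exact_sf_grid(ranks2: np.ndarray) -> np.ndarray:
    """Distribution of 2*W (sum of positive signed ranks) over sign flips.

    ``ranks2`` are midranks doubled so they are integers even under ties.
    Returns the probability mass function over 0..sum(ranks2).
    """
    total = int(ranks2.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in ranks2:
        r = int(r)
        shifted = np.zeros_like(pmf)
        shifted[r:] = pmf[: total + 1 - r]
        pmf = 0.5 * (pmf + shifted)
    return pmf


def wilcoxon_signed_rank(
    x: np.ndarray, y: np.ndarray, exact_max_n: int = 25
) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Returns (W, p) where W is the sum of ranks of positive differences.
    Exact (sign-flip enumeration) when the number of nonzero differences is
    <= ``exact_max_n``; otherwise normal approximation with continuity
    correction and tie-corrected variance.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 0.0, 1.0
    ranks = rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        ranks2 = np.rint(2 * ranks).astype(int)
        pmf = _exact_sf_grid(ranks2)
        w2 = int(round(2 * w_pos))
        p_low = pmf[: w2 + 1].sum()
        p_high = pmf[w2:].sum()
        p = min(1.0, 2.0 * min(p_low, p_high))
        return w_pos, float(p)
    mu = n * (n + 1) / 4.0
    # tie correction: subtract sum(t^3 - t)/48 over tied groups
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / 48.0
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if sigma2 <= 0:
        return w_pos, 1.0
    z = (w_pos - mu - 0.5 * np.sign(w_pos - mu)) / np.sqrt(sigma2)
    from scipy.stats import norm

    p = float(min(1.0, 2.0 * norm.sf(abs(z))))
    return w_pos, p
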