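"""Small shared statistical helpers (BH adjustment, Spearman p policy)."""

from __future__ import annotations

from itertools import permutations

import numpy as np
from scipy import stats

#: Sample-size regimes for the Spearman p-value: exact enumeration is
#: tractable up to n = 8 (8! = 40320 permutations); between 9 and 30 a
#: seeded Monte-Carlo permutation null is used; above that the t
#: approximation is accurate. 2000 resamples give the p-value a resolution
#: of 5e-4, ample for 0.05-level screening across panels of this size.
_SPEARMAN_EXACT_N = 8
_SPEARMAN_MC_N = 30
_SPEARMAN_MC_RESAMPLES = 2_000


def _cached_permutations(n: int, kind: str) -> np.ndarray:
    key = (n, kind)
    if key not in _PERM_CACHE:
        if kind == "exact":
            _PERM_CACHE[key] = np.array(list(permutations(range(n))), dtype=np.intp)
        else:
            rng = np.random.default_rng(0)  # fixed: the null is data-independent
            _PERM_CACHE[key] = np.argsort(
                rng.random((_SPEARMAN_MC_RESAMPLES, n)), axis=1)
    return _PERM_CACHE[key]


_PERM_CACHE: dict = {}


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    return stats.false_discovery_control(p, method="bh")


def _perm_rhos(rx: np.ndarray, ry: np.ndarray, perms: np.ndarray) -> np.ndarray:
    """Spearman rho of rx against every row-permutation of ry (vectorized)."""
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = np.sqrt((rx_c ** 2).sum() * (ry_c ** 2).sum())
    return (ry_c[perms] @ rx_c) / denom


def spearman_test(x, y) -> tuple[float, float]:
    """Spearman correlation with a sample-size-adaptive p-value.

    n <= 8: exact permutation enumeration; 9 <= n <= 30: seeded Monte-Carlo
    permutation (2000 resamples); n > 30: t approximation. Returns
    ``(scc, p_value)``; ``(nan, nan)`` if either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    rho = float(stats.spearmanr(x, y).statistic)
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    if n <= _SPEARMAN_EXACT_N:
        rhos = _perm_rhos(rx, ry, _cached_permutations(n, "exact"))
        return rho, float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    if n <= _SPEARMAN_MC_N:
        rhos = _perm_rhos(rx, ry, _cached_permutations(n, "mc"))
        count = int(np.sum(np.abs(rhos) >= abs(rho) - 1e-12))
        return rho, (count + 1) / (_SPEARMAN_MC_RESAMPLES + 1)
    res = stats.spearmanr(x, y)
    return rho, float(res.pvalue)


def ranksum_test(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney with tie correction)."""
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
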