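"""Shared statistical utilities: multiple-testing adjustments and group tests.

Single implementations of Benjamini-Hochberg, Holm-Bonferroni and the
Mann-Whitney U test used by every analysis stage of the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "bh_adjust",
    "holm_bonferroni",
    "HolmResult",
    "TestResult",
    "mann_whitney",
]


def _check_pvalues(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.size and (np.any(~np.isfinite(p)) or p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must be finite and within [0, 1]")
    return p


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Adjusted values are monotone in the p-value ranks and never smaller
    than the raw p-value.
    """
    p = _check_pvalues(p)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class HolmResult:
    adjusted: np.ndarray
    reject: np.ndarray
    alpha: float


def holm_bonferroni(p, alpha: float = 0.05) -> HolmResult:
    """Sequential Holm-Bonferroni step-down adjustment.

    p_(i) (ascending) is compared against alpha/(m-i+1); rejection stops at
    the first failure. Adjusted p-values are the running maxima of
    min(1, (m-i+1)*p_(i)).
    """
    p = _check_pvalues(p)
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if p.size == 0:
        return HolmResult(p, np.zeros(0, dtype=bool), alpha)
    reject, adjusted, *_ = multipletests(p, alpha=alpha, method="holm")
    return HolmResult(adjusted, reject, alpha)


@dataclass(frozen=True)
class TestResult:
    """Two-sample comparison result.

    ``u`` is the Mann-Whitney statistic of the first sample, counting pairs
    (a, b) with a > b (ties count 1/2), so ``u`` lies in [0, nA*nB].
    """

    u: float
    p: float
    method: str

    def __post_init__(self):
        if not 0 <= self.p <= 1 + 1e-12:
            raise ValueError("p out of range")


def _u_statistic(ranks: np.ndarray, idx_a: np.ndarray, n_a: int) -> float:
    # ranks are midranks of the pooled sample
    return float(ranks[idx_a].sum() - n_a * (n_a + 1) / 2.0)


@lru_cache(maxsize=64)
def _labelings(n: int, n_a: int) -> np.ndarray:
    return np.array(list(combinations(range(n), n_a)), dtype=np.intp)


def mann_whitney(a, b, exact_threshold: int = 12) -> TestResult:
    """Two-sided Mann-Whitney U test.

    For nA + nB <= ``exact_threshold`` the null distribution of U is built
    by full enumeration of all C(nA+nB, nA) group labelings of the pooled
    sample (valid with ties); otherwise the tie-corrected normal
    approximation with continuity correction is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    if np.unique(pooled).size < 2:
        warnings.warn("fewer than two distinct values; test is degenerate, p = 1")
        return TestResult(u=a.size * b.size / 2.0, p=1.0, method="degenerate")
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    ranks = sps.rankdata(pooled)
    u_obs = _u_statistic(ranks, np.arange(n_a), n_a)
    mu = n_a * n_b / 2.0
    if n <= exact_threshold:
        # permutation null over all labelings of the pooled values
        dev_obs = abs(u_obs - mu)
        idx = _labelings(n, n_a)
        u_all = ranks[idx].sum(axis=1) - n_a * (n_a + 1) / 2.0
        p = float(np.mean(np.abs(u_all - mu) >= dev_obs - 1e-9))
        return TestResult(u=u_obs, p=p, method="exact")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return TestResult(u=float(res.statistic), p=float(res.pvalue), method="normal")
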