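"""Statistical tests used throughout the analysis.

Small-sample paths are exact: the Wilcoxon rank-sum test enumerates the full
permutation distribution of the midrank sum when n + m <= RANKSUM_EXACT_MAX,
which stays correct under ties (the usual exact tables do not). Larger samples
use a tie-corrected normal approximation with continuity correction.
Hypergeometric tails are computed in log space so p-values far below float
underflow of the PMF remain accurate.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as sps

#: Largest pooled sample size for which the rank-sum test enumerates the exact
#: permutation distribution (C(16, 8) = 12870 assignments, sub-second).
RANKSUM_EXACT_MAX = 16

#: Largest n*m for which the two-sample KS test uses the exact distribution
#: under method="auto" (the convention R's ks.test follows).
KS_EXACT_MAX = 10_000


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    tails: str
    n_params: tuple[int, ...]
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of range: {self.p_value}")


# ---------------------------------------------------------------------------
# hypergeometric enrichment / depletion
# ---------------------------------------------------------------------------

def hypergeometric_enrichment(
    universe_n: int, set_k: int, draw_n: int, overlap_x: int, tail: str = "greater"
) -> TestResult:
    """Tail probability of the overlap between a gene set and a drawn group.

    With X ~ Hypergeom(N=universe_n, K=set_k, n=draw_n): tail="greater" gives
    the enrichment p-value P(X >= x), tail="less" the depletion p-value
    P(X <= x). Computed via log-space survival/cumulative functions.
    """
    if not (0 <= overlap_x <= min(set_k, draw_n) <= universe_n) or set_k > universe_n:
        raise ValueError(
            f"inconsistent counts: N={universe_n}, K={set_k}, n={draw_n}, x={overlap_x}"
        )
    dist = sps.hypergeom(universe_n, set_k, draw_n)
    if tail == "greater":
        logp = dist.logsf(overlap_x - 1)  # P(X >= x)
    elif tail == "less":
        logp = dist.logcdf(overlap_x)
    else:
        raise ValueError("tail must be 'greater' or 'less'")
    p = float(min(1.0, np.exp(logp)))
    return TestResult(float(overlap_x), p, "hypergeometric", tail,
                      (universe_n, set_k, draw_n))


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

def _midranks(pooled: np.ndarray) -> np.ndarray:
    return sps.rankdata(pooled, method="average")


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float], tail: str = "two_sided") -> TestResult:
    """Rank-sum test of location shift between two samples, midranks for ties.

    Exact permutation p-value when n + m <= RANKSUM_EXACT_MAX, else a normal
    approximation with tie-corrected variance and a 0.5 continuity correction.
    The statistic reported is W, the sum of x's midranks in the pooled sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    if n < 1 or m < 1:
        raise ValueError("both samples must be nonempty")
    if tail not in ("two_sided", "greater", "less"):
        raise ValueError(f"unknown tail {tail!r}")
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    w = float(ranks[:n].sum())
    mu = n * (n + m + 1) / 2.0

    if np.ptp(pooled) == 0:
        return TestResult(w, 1.0, "rank-sum (degenerate)", tail, (n, m), degenerate=True)

    if n + m <= RANKSUM_EXACT_MAX:
        sums = np.array([ranks[list(idx)].sum() for idx in combinations(range(n + m), n)])
        if tail == "two_sided":
            p = float(np.mean(np.abs(sums - mu) >= abs(w - mu) - 1e-12))
        elif tail == "greater":
            p = float(np.mean(sums >= w - 1e-12))
        else:
            p = float(np.mean(sums <= w + 1e-12))
        return TestResult(w, p, "rank-sum (exact)", tail, (n, m))

    # tie correction: subtract sum(t^3 - t) over tie groups
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = n * m / 12.0 * ((n + m + 1) - tie_term / ((n + m) * (n + m - 1)))
    if var <= 0:
        return TestResult(w, 1.0, "rank-sum (degenerate)", tail, (n, m), degenerate=True)
    if tail == "two_sided":
        z = (abs(w - mu) - 0.5) / np.sqrt(var)
        p = float(min(1.0, 2.0 * sps.norm.sf(z)))
    elif tail == "greater":
        z = (w - mu - 0.5) / np.sqrt(var)
        p = float(sps.norm.sf(z))
    else:
        z = (w - mu + 0.5) / np.sqrt(var)
        p = float(sps.norm.cdf(z))
    return TestResult(w, p, "rank-sum (normal approx)", tail, (n, m))


# ---------------------------------------------------------------------------
# two-sample Kolmogorov-Smirnov
# ---------------------------------------------------------------------------

def ks_statistic(x: Sequence[float], y: Sequence[float]) -> float:
    """D = sup |ECDF_x - ECDF_y| evaluated at the pooled sample points."""
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    pooled = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, pooled, side="right") / len(x)
    cdf_y = np.searchsorted(y, pooled, side="right") / len(y)
    return float(np.abs(cdf_x - cdf_y).max())


def ks_two_sample(x: Sequence[float], y: Sequence[float], method: str = "auto") -> TestResult:
    """Two-sided two-sample KS test.

    The D statistic is computed here from the pooled ECDFs; the p-value comes
    from the exact null distribution when n*m <= KS_EXACT_MAX under
    method="auto" (or always with method="exact"), otherwise from the
    asymptotic Kolmogorov distribution.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    if n < 1 or m < 1:
        raise ValueError("both samples must be nonempty")
    d = ks_statistic(x, y)
    if method == "auto":
        method = "exact" if n * m <= KS_EXACT_MAX else "asymptotic"
    if method == "exact":
        p = float(sps.ks_2samp(x, y, method="exact").pvalue)
        label = "ks (exact)"
    elif method == "asymptotic":
        en = np.sqrt(n * m / (n + m))
        from scipy.special import kolmogorov

        p = float(min(1.0, kolmogorov(en * d)))
        label = "ks (asymptotic)"
    else:
        raise ValueError(f"unknown method {method!r}")
    return TestResult(d, p, label, "two_sided", (n, m))


# ---------------------------------------------------------------------------
# Spearman rank correlation
# ---------------------------------------------------------------------------

def spearman(x: Sequence[float], y: Sequence[float]) -> float | None:
    """Pearson correlation of midranks; None when either vector is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("spearman needs >= 3 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    return float(sps.spearmanr(x, y).statistic)


def spearman_test(x: Sequence[float], y: Sequence[float], tail: str = "two_sided") -> TestResult:
    """Spearman correlation with its t-approximation p-value."""
    rho = spearman(x, y)
    if rho is None:
        return TestResult(0.0, 1.0, "spearman (degenerate)", tail, (len(x),), degenerate=True)
    alt = {"two_sided": "two-sided", "greater": "greater", "less": "less"}[tail]
    res = sps.spearmanr(x, y, alternative=alt)
    return TestResult(float(res.statistic), float(res.pvalue), "spearman", tail, (len(x),))


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH-adjusted q-values (helper; the analyses report raw p-values)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]
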