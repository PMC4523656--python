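"""Rank-based tests for the variability analysis.

The focality percentages (V70, V50) are compared across the phantom family
with a Kruskal-Wallis one-way analysis of variance by ranks (factor: human
model, three levels); when the omnibus test is significant at alpha = 0.05,
Mann-Whitney post hoc pairwise comparisons follow, Bonferroni-adjusted for
the three model pairs.  Statistics and asymptotic p-values come from
scipy.stats (midranks, tie corrections, chi-square and normal
approximations); for small samples an exact permutation p-value for the
Kruskal-Wallis H is computed in-package by full enumeration, and the exact
Mann-Whitney distribution is used whenever both groups are small and
tie-free.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

__all__ = [
    "TestResult",
    "kruskal_wallis",
    "mann_whitney_u",
    "bonferroni",
    "model_factor_analysis",
]

#: Largest pooled sample size for which the exact Kruskal-Wallis permutation
#: distribution is enumerated (multinomial assignments of midranks).
EXACT_KW_MAX_N = 12
#: Largest per-group size for which Mann-Whitney uses the exact distribution
#: (tie-free samples only), matching common statistical practice.
EXACT_MW_MAX_N = 8


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    adjusted_p: float | None = None


def _h_statistic(rank_groups: list[np.ndarray], tie_term: float, N: int) -> float:
    """Tie-corrected Kruskal-Wallis H from midrank groups."""
    ssq = sum(g.sum() ** 2 / len(g) for g in rank_groups)
    h = 12.0 / (N * (N + 1)) * ssq - 3.0 * (N + 1)
    return h / tie_term if tie_term > 0 else float("nan")


def _tie_term(all_ranks: np.ndarray) -> float:
    N = len(all_ranks)
    _, counts = np.unique(all_ranks, return_counts=True)
    return 1.0 - float(np.sum(counts**3 - counts)) / (N**3 - N)


def kruskal_wallis(groups, exact: str | bool = "auto") -> TestResult:
    """Kruskal-Wallis H test across >= 2 groups.

    ``groups`` is a mapping name -> values or a sequence of value sequences.
    H uses midranks with the tie correction.  ``exact`` controls the p-value:
    chi-square approximation (``False``), full permutation enumeration
    (``True``, pooled N <= EXACT_KW_MAX_N), or enumeration whenever the
    pooled sample is small enough (``"auto"``).
    """
    vals = list(groups.values()) if isinstance(groups, dict) else list(groups)
    if len(vals) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(v, dtype=float) for v in vals]
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group must be non-empty")
    N = sum(a.size for a in arrays)
    h, p_chi2 = stats.kruskal(*arrays)
    use_exact = exact is True or (exact == "auto" and N <= EXACT_KW_MAX_N)
    if not use_exact:
        return TestResult(float(h), float(p_chi2), "kruskal-wallis/chi2")
    if N > EXACT_KW_MAX_N:
        raise ValueError(f"exact enumeration supported only for pooled N <= {EXACT_KW_MAX_N}")
    # Enumerate all distinct assignments of the pooled midranks to the groups;
    # ranks are permutation-invariant, so the null distribution of H follows.
    pooled = np.concatenate(arrays)
    ranks = stats.rankdata(pooled)
    tie = _tie_term(ranks)
    sizes = [a.size for a in arrays]
    h_obs = _h_statistic(_split(ranks, sizes), tie, N)

    def perms(avail: np.ndarray, remaining_sizes):
        if len(remaining_sizes) == 1:
            yield [avail]
            return
        k = remaining_sizes[0]
        idx = np.arange(len(avail))
        for pick in combinations(idx, k):
            pick = np.array(pick)
            rest = np.delete(idx, pick)
            for tail in perms(avail[rest], remaining_sizes[1:]):
                yield [avail[pick]] + tail

    count = total = 0
    for assignment in perms(ranks, sizes):
        total += 1
        if _h_statistic(assignment, tie, N) >= h_obs - 1e-12:
            count += 1
    return TestResult(float(h_obs), count / total, "kruskal-wallis/exact-permutation")


def _split(arr: np.ndarray, sizes):
    out, i = [], 0
    for s in sizes:
        out.append(arr[i:i + s])
        i += s
    return out


def mann_whitney_u(a, b) -> TestResult:
    """Two-sided Mann-Whitney U test (midranks).

    Exact distribution when both groups have <= EXACT_MW_MAX_N observations
    and there are no ties; otherwise the normal approximation with tie
    correction and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    small = a.size <= EXACT_MW_MAX_N and b.size <= EXACT_MW_MAX_N
    method = "exact" if (no_ties and small) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult(float(res.statistic), float(res.pvalue), f"mann-whitney/{method}")


def bonferroni(pvals, m: int | None = None) -> list[float]:
    """Bonferroni-adjusted p-values: min(1, p*m); m defaults to len(pvals)."""
    pvals = list(pvals)
    if any(not 0 <= p <= 1 for p in pvals):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(pvals) if m is None else m
    return [min(1.0, p * m) for p in pvals]


def model_factor_analysis(groups: dict[str, list[float]], alpha: float = 0.05,
                          exact: str | bool = "auto") -> dict:
    """Omnibus Kruskal-Wallis plus conditional Mann-Whitney post hocs.

    The post hoc pairwise comparisons run only if the omnibus p-value is
    below ``alpha``; their p-values are Bonferroni-adjusted for the number of
    pairs.  Returns a dict with the omnibus result and (possibly empty)
    pairwise results.
    """
    omnibus = kruskal_wallis(groups, exact=exact)
    pairwise = {}
    if omnibus.p_value < alpha:
        names = list(groups)
        pairs = list(combinations(names, 2))
        raw = [mann_whitney_u(groups[x], groups[y]) for x, y in pairs]
        adj = bonferroni([r.p_value for r in raw], m=len(pairs))
        pairwise = {
            f"{x} vs {y}": TestResult(r.statistic, r.p_value, r.method, adjusted_p=ap)
            for (x, y), r, ap in zip(pairs, raw, adj)
        }
    return {"omnibus": omnibus, "pairwise": pairwise, "alpha": alpha}


def null_rejection_rate(n_groups: int = 3, n_per_group: int = 8, alpha: float = 0.05,
                        replicates: int = 5000, seed: int = 0) -> float:
    """Simulated type-I error of the omnibus test under identical continuous nulls."""
    rng = np.random.default_rng(seed)
    rejected = 0
    for _ in range(replicates):
        g = [rng.standard_normal(n_per_group) for _ in range(n_groups)]
        if stats.kruskal(*g).pvalue < alpha:
            rejected += 1
    return rejected / replicates
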