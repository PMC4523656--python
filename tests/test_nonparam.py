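"""Rank tests against hand computations and full-enumeration oracles."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from tdcsim.nonparam import (bonferroni, kruskal_wallis, mann_whitney_u,
                             model_factor_analysis)


def _enumerate_kw_p(groups):
    """Oracle: exact permutation p for H by enumerating group assignments,
    recomputing H with scipy on every relabelling."""
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    sizes = [len(g) for g in groups]
    h_obs = stats.kruskal(*groups).statistic
    idx = list(range(len(pooled)))

    def assignments(avail, remaining):
        if len(remaining) == 1:
            yield [avail]
            return
        for pick in combinations(avail, remaining[0]):
            rest = [i for i in avail if i not in pick]
            for tail in assignments(rest, remaining[1:]):
                yield [list(pick)] + tail

    count = total = 0
    for parts in assignments(idx, sizes):
        total += 1
        h = stats.kruskal(*[pooled[list(p)] for p in parts]).statistic
        if h >= h_obs - 1e-12:
            count += 1
    return count / total


def _enumerate_mw_p(a, b):
    """Oracle: exact two-sided p by enumerating which pooled values are 'a'."""
    pooled = np.concatenate([np.asarray(a, float), np.asarray(b, float)])
    n, m = len(a), len(b)
    centre = n * m / 2.0

    def ustat(xs, ys):
        return sum((x > y) + 0.5 * (x == y) for x in xs for y in ys)

    u_obs = ustat(a, b)
    hits = total = 0
    for pick in combinations(range(n + m), n):
        xs = pooled[list(pick)]
        ys = pooled[[i for i in range(n + m) if i not in pick]]
        total += 1
        if abs(ustat(xs, ys) - centre) >= abs(u_obs - centre) - 1e-12:
            hits += 1
    return hits / total


class TestKruskalWallis:
    def test_hand_computed_h(self):
        r = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]], exact=False)
        assert r.statistic == pytest.approx(7.2, rel=1e-12)

    def test_identical_groups_not_significant(self):
        r = kruskal_wallis({"a": [1, 2, 3], "b": [1, 2, 3], "c": [1, 2, 3]})
        assert r.p_value > 0.05

    @pytest.mark.parametrize("groups", [
        [[1, 2, 3], [4, 5, 6], [7, 8, 9]],
        [[1.0, 2.0], [2.0, 3.5, 1.5], [4.0, 0.5]],
        [[3, 3, 1], [2, 4], [5, 2]],
    ], ids=["separated", "mixed", "tied"])
    def test_exact_p_matches_enumeration_oracle(self, groups):
        ours = kruskal_wallis(groups, exact=True)
        assert ours.p_value == pytest.approx(_enumerate_kw_p(groups), abs=1e-12)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2], []])

    @given(st.lists(st.integers(-5, 5), min_size=2, max_size=6),
           st.lists(st.integers(-5, 5), min_size=2, max_size=6),
           st.lists(st.integers(-5, 5), min_size=2, max_size=6))
    def test_monotone_transform_invariance(self, a, b, c):
        from hypothesis import assume
        assume(len(set(a) | set(b) | set(c)) > 1)
        base = kruskal_wallis([a, b, c], exact=False).statistic
        f = lambda xs: [np.expm1(x / 2.0) for x in xs]  # strictly increasing
        transformed = kruskal_wallis([f(a), f(b), f(c)], exact=False).statistic
        assert transformed == pytest.approx(base, rel=1e-9, abs=1e-9)


class TestMannWhitney:
    def test_complete_separation(self):
        r = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert r.statistic == 0.0

    def test_identical_sets_midrank_u(self):
        r = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert r.statistic == pytest.approx(9 / 2)

    @pytest.mark.parametrize("a,b", [
        ([1, 3], [2, 4]),
        ([1, 2, 7], [3, 5, 6, 8]),
        ([0.5, 2.5, 9.0], [1.0, 4.0]),
    ])
    def test_exact_p_matches_enumeration_oracle(self, a, b):
        assert mann_whitney_u(a, b).p_value == pytest.approx(
            _enumerate_mw_p(a, b), abs=1e-12)

    @given(st.lists(st.integers(0, 30), min_size=1, max_size=7),
           st.lists(st.integers(0, 30), min_size=1, max_size=7))
    def test_u_sum_identity(self, a, b):
        u1 = mann_whitney_u(a, b).statistic
        u2 = mann_whitney_u(b, a).statistic
        assert u1 + u2 == pytest.approx(len(a) * len(b))

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1])


class TestBonferroni:
    def test_simple_multiplication(self):
        assert bonferroni([0.01], m=3) == [pytest.approx(0.03)]

    def test_capped_at_one(self):
        assert bonferroni([0.5], m=3) == [1.0]

    def test_invalid_p_raises(self):
        with pytest.raises(ValueError):
            bonferroni([1.5])

    def test_adjusted_never_below_raw(self):
        ps = [0.001, 0.02, 0.4]
        assert all(a >= p for a, p in zip(bonferroni(ps), ps))


class TestModelFactorAnalysis:
    def test_three_pairwise_comparisons_when_significant(self):
        groups = {"ella": [1, 2, 3, 4], "duke": [11, 12, 13, 14],
                  "billie": [21, 22, 23, 24]}
        out = model_factor_analysis(groups, exact=True)
        assert out["omnibus"].p_value < 0.05
        assert len(out["pairwise"]) == 3
        for r in out["pairwise"].values():
            assert r.adjusted_p == pytest.approx(min(1.0, 3 * r.p_value))

    def test_no_posthoc_when_not_significant(self):
        groups = {"a": [1, 4, 2, 5], "b": [2, 3, 5, 1], "c": [1.5, 3.5, 4.5, 2.5]}
        out = model_factor_analysis(groups)
        assert out["omnibus"].p_value >= 0.05
        assert out["pairwise"] == {}
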