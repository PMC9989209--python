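"""Mostly-zero filter, transitive correlation clustering, and F ranking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy import stats as sps

from serosig import (
    FilterConfig,
    build_clusters,
    f_statistic,
    mostly_zero_filter,
    rank_and_select,
    select_representatives,
    spearman_sq,
)
from serosig.feature_selection import rank_features, selection_size


# --- independent oracle: pairwise Spearman (scipy) + union-find closure ---

def brute_force_clusters(matrix, marker_ids, p2):
    m = len(marker_ids)
    parent = list(range(m))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(m):
        for j in range(i + 1, m):
            xi, xj = matrix[:, i], matrix[:, j]
            if np.std(xi) == 0 or np.std(xj) == 0:
                rho = 0.0
            else:
                rho = sps.spearmanr(xi, xj).statistic
            if rho * rho >= p2:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(m):
        groups.setdefault(find(i), set()).add(marker_ids[i])
    return {frozenset(g) for g in groups.values()}


def test_mostly_zero_strict_inequality():
    """10 rows at fraction 0.3 -> P1 = 3; a zero count of exactly 3 survives."""
    counts = [0, 2, 3, 6, 10]
    matrix = np.ones((10, 5))
    for j, c in enumerate(counts):
        matrix[:c, j] = 0.0
    ids = [f"m{j}" for j in range(5)]
    retained, removed = mostly_zero_filter(matrix, ids, 0.3)
    assert retained == ["m0", "m1", "m2"]
    assert removed == 2


def test_mostly_zero_trivial_cases(rng):
    matrix = rng.random((8, 4)) + 0.1  # no zeros
    retained, removed = mostly_zero_filter(matrix, list("abcd"), 0.25)
    assert retained == list("abcd") and removed == 0
    matrix[:, 1] = 0.0  # all-zero marker always falls
    _, removed = mostly_zero_filter(matrix, list("abcd"), 0.25)
    assert removed == 1


def test_spearman_sq_hand_example():
    """x=(1,2,3,4), y=(2,1,4,3): sum d^2 = 4, rho = 1 - 24/60 = 0.6."""
    rsq = spearman_sq(np.array([1, 2, 3, 4]), np.array([2, 1, 4, 3]))
    assert rsq == pytest.approx(0.36, abs=1e-12)


def test_spearman_sq_monotone_and_degenerate(rng):
    x = rng.random(20)
    assert spearman_sq(x, np.exp(3 * x)) == pytest.approx(1.0)
    assert spearman_sq(x, np.full(20, 7.0)) == 0.0


def test_chain_cluster_is_transitive(rng):
    """Edges A-B and B-C suffice for {A,B,C} even when A-C is subthreshold."""
    n = 200
    b = rng.standard_normal(n)
    # corr(a,b) = corr(b,c) ~ 0.78 (rho^2 ~ 0.6) but corr(a,c) ~ 0.6 (rho^2 ~ 0.36)
    a = b + 0.815 * rng.standard_normal(n)
    c = b + 0.815 * rng.standard_normal(n)
    d = rng.standard_normal(n)
    matrix = np.column_stack([a, b, c, d])
    ids = list("ABCD")
    assert spearman_sq(a, c) < 0.5 <= min(spearman_sq(a, b), spearman_sq(b, c))
    cs = build_clusters(matrix, ids, 0.5)
    assert {frozenset(cl) for cl in cs.clusters} == {frozenset("ABC"), frozenset("D")}
    # the middle of the chain has the highest mean correlation -> representative
    rep = next(r for r, cl in zip(cs.representatives, cs.clusters) if len(cl) == 3)
    assert rep == "B"


def test_clusters_match_brute_force_oracle(rng):
    """Randomized instances with <= 12 markers against spearman+union-find."""
    for _ in range(40):
        m = rng.integers(2, 13)
        n = int(rng.integers(10, 25))
        base = rng.standard_normal((n, max(1, m // 3)))
        matrix = np.column_stack(
            [
                base[:, rng.integers(base.shape[1])]
                + rng.uniform(0.2, 2.0) * rng.standard_normal(n)
                for _ in range(m)
            ]
        )
        ids = [f"m{j}" for j in range(m)]
        cs = build_clusters(matrix, ids, 0.5)
        assert {frozenset(cl) for cl in cs.clusters} == brute_force_clusters(
            matrix, ids, 0.5
        )


def test_independent_markers_are_singletons(rng):
    matrix = rng.standard_normal((50, 6))
    cs = build_clusters(matrix, list("abcdef"), 0.5)
    assert all(len(cl) == 1 for cl in cs.clusters)
    retained, removed = select_representatives(cs)
    assert retained == list("abcdef") and removed == 0


def test_two_member_tie_broken_lexicographically(rng):
    x = rng.standard_normal(30)
    matrix = np.column_stack([x + 1.0, 2 * x])  # rank-identical pair
    cs = build_clusters(matrix, ["b_second", "a_first"], 0.5)
    retained, removed = select_representatives(cs)
    assert removed == 1 and retained == ["a_first"]


def test_representative_removal_count_identity(rng):
    """F(P2) always equals sum(|cluster| - 1) over multi-member clusters."""
    base = rng.standard_normal((40, 3))
    matrix = np.column_stack(
        [base[:, j % 3] + 0.3 * rng.standard_normal(40) for j in range(9)]
    )
    ids = [f"m{j}" for j in range(9)]
    cs = build_clusters(matrix, ids, 0.5)
    _, removed = select_representatives(cs)
    assert removed == sum(len(cl) - 1 for cl in cs.clusters)
    assert removed + len(cs.clusters) == 9


def test_f_statistic_closed_form():
    """x=(1,2,3,5), y=(0,0,1,1): r^2 = 6.25/8.75 so F = 2 r^2/(1-r^2) = 5."""
    f = f_statistic(np.array([1.0, 2, 3, 5]), np.array([0, 0, 1, 1]))
    assert f == pytest.approx(5.0, abs=1e-12)


def test_f_statistic_degenerate_and_perfect():
    y = np.array([0, 0, 1, 1])
    assert f_statistic(np.array([1.0, 2, 2, 1]), y) == 0.0  # r = 0 by symmetry
    assert f_statistic(np.full(4, 3.0), y) == 0.0
    assert f_statistic(y.astype(float), y) == np.inf


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    a=hst.floats(min_value=0.01, max_value=100.0),
    b=hst.floats(min_value=-50.0, max_value=50.0),
    sign=hst.sampled_from([-1.0, 1.0]),
)
def test_f_statistic_affine_invariant(a, b, sign):
    rng = np.random.default_rng(12)
    x = rng.standard_normal(25)
    y = (rng.random(25) < 0.5).astype(float)
    y[:2], y[-2:] = 0, 1  # both classes present
    f0 = f_statistic(x, y)
    f1 = f_statistic(sign * a * x + b, y)
    assert f1 == pytest.approx(f0, rel=1e-9)


def test_f_statistic_matches_sklearn_reference(rng):
    from sklearn.feature_selection import f_regression

    x = rng.gamma(2.0, 10.0, size=(40, 6))
    y = (rng.random(40) < 0.5).astype(int)
    y[:2], y[-2:] = 0, 1
    ours = [f_statistic(x[:, j], y) for j in range(6)]
    ref = f_regression(x, y)[0]
    np.testing.assert_allclose(ours, ref, rtol=1e-10)


def test_rank_and_select_sizes(rng):
    assert selection_size(0.01, 1000) == 10
    assert selection_size(0.01, 100) == 1
    x = rng.standard_normal((30, 20))
    y = (np.arange(30) < 15).astype(int)
    ids = [f"m{j:02d}" for j in range(20)]
    sel = rank_and_select(x, ids, y, FilterConfig(top_fraction=0.2), 20)
    assert len(sel) == 4
    with pytest.raises(ValueError, match="survivors"):
        rank_and_select(x[:, :2], ids[:2], y, FilterConfig(top_fraction=0.2), 20)


def test_planted_marker_ranked_first(rng):
    n = 100
    y = (np.arange(n) < 50).astype(int)
    x = rng.standard_normal((n, 30))
    x[:, 17] += 3.0 * y  # large planted effect
    ids = [f"m{j:02d}" for j in range(30)]
    ranked = rank_features(x, ids, y)
    assert ranked[0].marker_id == "m17"
    # agrees with exhaustive per-marker F computation
    best = max(ids, key=lambda mid: f_statistic(x[:, ids.index(mid)], y))
    assert best == "m17"


def test_filter_config_validation():
    with pytest.raises(ValueError):
        FilterConfig(p1_zero_fraction=0.0)
    with pytest.raises(ValueError):
        FilterConfig(p2_threshold=1.5)
    with pytest.raises(ValueError):
        FilterConfig(ranking_split="validation")
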