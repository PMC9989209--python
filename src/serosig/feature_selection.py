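"""The pipeline's bespoke feature filters and univariate ranking.

Three stages, always in this order and always computed on one stated split:

1. **Mostly-zero filter (P1).**  A marker is discarded when its count of
   exact-zero (below-detection) readings in the split exceeds the threshold
   P1 = floor(p1_zero_fraction * n_rows).  "More than" is strict: a count
   equal to P1 survives.
2. **Correlation clustering (P2).**  A graph connects any two surviving
   markers whose squared Spearman correlation is >= P2 (default 0.5);
   clusters are the connected components (transitive closure), and only the
   member with the highest mean squared correlation to the rest of its
   cluster is retained.
3. **Univariate F ranking.**  Survivors are ranked by the one-predictor
   regression F statistic of marker against the 0/1 label, F = (n-2) r^2 /
   (1 - r^2), and the top fraction of the ORIGINAL marker count is selected
   (1% of 1,000 markers = 10 features).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.stats import rankdata


@dataclass
class FilterConfig:
    """Parameters of the filter/rank/select cascade.

    p1_zero_fraction : fraction of split rows defining the zero-count
        threshold P1 (a marker with more than floor(p1_zero_fraction * n)
        zeros is removed).
    p2_threshold : squared Spearman correlation defining a cluster edge.
    top_fraction : fraction of the original marker count selected after
        ranking (ceil; 0.01 of 1,000 -> 10).
    ranking_split : which split ranks features, "train" (default, leakage
        free) or "test" (flagged as information leakage in reports).
    p2_on_rho : if True, threshold raw |rho| instead of rho squared.
    """

    p1_zero_fraction: float = 0.25
    p2_threshold: float = 0.5
    top_fraction: float = 0.01
    ranking_split: str = "train"
    p2_on_rho: bool = False

    def __post_init__(self) -> None:
        for name in ("p1_zero_fraction", "p2_threshold", "top_fraction"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if self.ranking_split not in ("train", "test"):
            raise ValueError("ranking_split must be 'train' or 'test'")


@dataclass
class ClusterSet:
    """Connected components of the correlation-threshold graph."""

    clusters: list[list[str]]
    representatives: list[str]
    edges: list[tuple[str, str, float]]
    marker_ids: list[str] = field(default_factory=list)


@dataclass
class RankedFeature:
    marker_id: str
    F: float
    rank: int


def mostly_zero_filter(
    matrix: np.ndarray, marker_ids: list[str], p1_zero_fraction: float
) -> tuple[list[str], int]:
    """Remove markers whose exact-zero count strictly exceeds P1.

    Returns the retained marker ids and the removal count (the per-fold
    F(P1) statistic).
    """
    x = np.asarray(matrix, dtype=float)
    if x.shape[0] == 0:
        raise ValueError("split must be nonempty")
    p1 = math.floor(p1_zero_fraction * x.shape[0])
    zero_counts = (x == 0).sum(axis=0)
    keep = zero_counts <= p1
    retained = [mid for mid, k in zip(marker_ids, keep) if k]
    return retained, int((~keep).sum())


def spearman_sq(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Spearman rank correlation, with ties sharing average ranks.

    Zero-variance input has no measurable monotone association and returns 0.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("vectors must have equal length >= 3")
    rx = rankdata(x)
    ry = rankdata(y)
    if rx.std() == 0 or ry.std() == 0:
        return 0.0
    rho = np.corrcoef(rx, ry)[0, 1]
    return float(rho * rho)


def _rank_corr_matrix(matrix: np.ndarray) -> np.ndarray:
    """Pairwise Spearman rho over columns; zero-variance columns -> rho 0."""
    ranks = rankdata(np.asarray(matrix, float), axis=0)
    sd = ranks.std(axis=0)
    degenerate = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
    rho = np.atleast_2d(rho)
    rho[degenerate, :] = 0.0
    rho[:, degenerate] = 0.0
    np.fill_diagonal(rho, 1.0)
    return rho


def build_clusters(
    matrix: np.ndarray,
    marker_ids: list[str],
    p2_threshold: float,
    *,
    on_rho: bool = False,
) -> ClusterSet:
    """Cluster markers by transitive closure of the correlation-threshold graph.

    Nodes are the retained markers; an edge joins two markers whose squared
    Spearman correlation (or |rho| when ``on_rho``) reaches the threshold.
    Clusters are connected components, so a chain A-B, B-C places A and C in
    one cluster even if their direct correlation is below threshold.
    Representatives (the member with the highest mean statistic against the
    rest of its cluster; ties to the lexicographically smallest id) are
    computed here so that the cluster set is self-describing.
    """
    x = np.asarray(matrix, float)
    m = len(marker_ids)
    if m < 1:
        raise ValueError("need at least one marker")
    if m == 1:
        return ClusterSet([list(marker_ids)], list(marker_ids), [], list(marker_ids))
    rho = _rank_corr_matrix(x)
    stat = np.abs(rho) if on_rho else rho**2
    adjacency = stat >= p2_threshold
    np.fill_diagonal(adjacency, False)
    n_comp, comp = connected_components(csr_matrix(adjacency), directed=False)
    clusters: list[list[str]] = [[] for _ in range(n_comp)]
    index_of = {mid: j for j, mid in enumerate(marker_ids)}
    for mid, c in zip(marker_ids, comp):
        clusters[c].append(mid)
    edges = [
        (marker_ids[i], marker_ids[j], float(stat[i, j]))
        for i in range(m)
        for j in range(i + 1, m)
        if adjacency[i, j]
    ]
    representatives = []
    for members in clusters:
        if len(members) == 1:
            representatives.append(members[0])
            continue
        idx = [index_of[mid] for mid in members]
        sub = stat[np.ix_(idx, idx)]
        mean_corr = (sub.sum(axis=1) - np.diag(sub)) / (len(idx) - 1)
        # highest mean correlation wins; exact ties to the smallest marker id
        best = sorted(
            range(len(members)), key=lambda i: (-mean_corr[i], members[i])
        )[0]
        representatives.append(members[best])
    return ClusterSet(clusters, representatives, edges, list(marker_ids))


def select_representatives(clusters: ClusterSet) -> tuple[list[str], int]:
    """Keep one representative per cluster, in original marker order.

    The removal count is the per-fold F(P2) statistic and always equals
    the sum of (cluster size - 1) over multi-member clusters.
    """
    reps = set(clusters.representatives)
    retained = [mid for mid in clusters.marker_ids if mid in reps]
    return retained, len(clusters.marker_ids) - len(retained)


def f_statistic(feature: np.ndarray, labels: np.ndarray) -> float:
    """One-predictor regression F of feature against the 0/1 labels.

    F = (n - 2) r^2 / (1 - r^2) with r the Pearson correlation; this is the
    F test with (1, n-2) degrees of freedom.  Zero-variance features return
    0; a perfectly label-aligned feature (|r| = 1) returns +inf, which ranks
    above every finite value.
    """
    x = np.asarray(feature, float)
    y = np.asarray(labels, float)
    n = len(x)
    if n < 3 or len(y) != n:
        raise ValueError("need equal-length vectors with n >= 3")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if x.std() == 0:
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    r2 = min(r * r, 1.0)
    if r2 >= 1.0 - 1e-15:
        return float("inf")
    return float((n - 2) * r2 / (1.0 - r2))


def _f_vector(matrix: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Vectorized ``f_statistic`` over columns."""
    x = np.asarray(matrix, float)
    y = np.asarray(labels, float)
    n = len(y)
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc * yc[:, None]).sum(axis=0) / (sx * sy)
    r2 = np.clip(r * r, 0.0, 1.0)
    r2[sx == 0] = 0.0
    with np.errstate(divide="ignore"):
        f = (n - 2) * r2 / (1.0 - r2)
    f[r2 >= 1.0 - 1e-15] = np.inf
    return f


def rank_features(
    matrix: np.ndarray, marker_ids: list[str], labels: np.ndarray
) -> list[RankedFeature]:
    """Rank survivors by descending F; ties broken by marker id order."""
    f = _f_vector(matrix, labels)
    order = sorted(range(len(marker_ids)), key=lambda j: (-f[j], marker_ids[j]))
    return [
        RankedFeature(marker_ids[j], float(f[j]), rank + 1)
        for rank, j in enumerate(order)
    ]


def selection_size(top_fraction: float, original_marker_count: int) -> int:
    """Number of features selected: ceil(top_fraction * original count)."""
    return math.ceil(top_fraction * original_marker_count)


def rank_and_select(
    matrix: np.ndarray,
    marker_ids: list[str],
    labels: np.ndarray,
    config: FilterConfig,
    original_marker_count: int,
) -> list[str]:
    """Top-``k_sel`` survivors by univariate F, k_sel from the ORIGINAL count.

    The fraction is applied to the pre-filter marker count (1% of 1,000 gives
    10 features) rather than to the survivor count.
    """
    k_sel = selection_size(config.top_fraction, original_marker_count)
    if len(marker_ids) < k_sel:
        raise ValueError(
            f"only {len(marker_ids)} survivors but selection size is {k_sel}"
        )
    ranked = rank_features(matrix, marker_ids, labels)
    return [rf.marker_id for rf in ranked[:k_sel]]
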