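"""Per-marker case-control statistics, multiplicity control, and study design.

Covers the volcano-table columns (Student's t, Benjamini-Hochberg adjusted p,
log2 fold change of group means), the chi-square independence test used for
accuracy-by-covariate checks, the one-sample t comparing fold accuracies with
chance, and the diagnostic-study sample-size calculation for estimating a
sensitivity or specificity to a stated absolute error.

The elementary tests are computed from their defining formulas (pooled t,
Pearson chi-square, BH step-up) so that they can be cross-checked against
independent reference implementations; p-values come from scipy's t and
chi-square distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class VolcanoRow:
    """One marker's differential-abundance summary (case vs control)."""

    marker_id: str
    t: float
    p: float
    p_adj: float
    log2_fc: float
    significant: bool
    direction: str  # "up" or "down" in cases


@dataclass
class SampleSizeSpec:
    """Inputs of the sensitivity/specificity estimation sample-size formula."""

    p: float = 0.80
    confidence: float = 0.95
    error: float = 0.08

    def __post_init__(self) -> None:
        if not 0 < self.p < 1 or not 0 < self.confidence < 1:
            raise ValueError("p and confidence must lie in (0, 1)")
        if not 0 < self.error < 0.5:
            raise ValueError("absolute error must lie in (0, 0.5)")


def two_sample_t(
    x_case: np.ndarray, x_control: np.ndarray, *, welch: bool = False
) -> tuple[float, float]:
    """Two-sided Student's t-test (pooled variance; Welch by flag).

    Degenerate inputs: equal constant groups give (0, 1); zero pooled sd with
    unequal means gives a p = 0 sentinel with a warning.
    """
    a = np.asarray(x_case, float)
    b = np.asarray(x_control, float)
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 values")
    v1, v2 = a.var(ddof=1), b.var(ddof=1)
    diff = a.mean() - b.mean()
    if welch:
        se2 = v1 / n1 + v2 / n2
        if se2 == 0:
            return _degenerate_t(diff)
        t = diff / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    else:
        df = n1 + n2 - 2
        pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        if pooled == 0:
            return _degenerate_t(diff)
        t = diff / np.sqrt(pooled * (1 / n1 + 1 / n2))
    p = 2 * sps.t.sf(abs(t), df)
    return float(t), float(p)


def _degenerate_t(diff: float) -> tuple[float, float]:
    if diff == 0:
        return 0.0, 1.0
    warnings.warn("zero pooled sd with unequal means; reporting p = 0", stacklevel=3)
    return float(np.sign(diff) * np.inf), 0.0


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the original order.

    adjusted_(i) = min over j >= i of p_(j) * m / j on the ascending sort,
    capped at 1.
    """
    p = np.asarray(p_values, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    adjusted = np.empty(m)
    adjusted[order] = adjusted_sorted
    return adjusted


def log2_fc(
    x_case: np.ndarray, x_control: np.ndarray, epsilon: float | None = None
) -> float:
    """log2 of the ratio of group means, stabilized for zero-inflated data.

    FC = log2((mean_case + eps) / (mean_control + eps)), eps defaulting to
    1e-6 times the grand mean so that below-detection zeros cannot produce an
    infinite fold change.  Both means zero gives 0.
    """
    a = np.asarray(x_case, float)
    b = np.asarray(x_control, float)
    if len(a) == 0 or len(b) == 0 or np.any(a < 0) or np.any(b < 0):
        raise ValueError("groups must be nonempty with nonnegative values")
    mc, mt = a.mean(), b.mean()
    if mc == 0 and mt == 0:
        return 0.0
    if epsilon is None:
        epsilon = 1e-6 * np.concatenate([a, b]).mean()
    return float(np.log2((mc + epsilon) / (mt + epsilon)))


def _t_by_column(
    values: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized pooled two-sided t over marker columns."""
    case = values[labels == 1]
    ctrl = values[labels == 0]
    n1, n2 = case.shape[0], ctrl.shape[0]
    df = n1 + n2 - 2
    v1 = case.var(axis=0, ddof=1)
    v2 = ctrl.var(axis=0, ddof=1)
    pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    diff = case.mean(axis=0) - ctrl.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = diff / np.sqrt(pooled * (1 / n1 + 1 / n2))
    t = np.where(pooled == 0, np.where(diff == 0, 0.0, np.inf * np.sign(diff)), t)
    p = np.where(
        np.isinf(t), 0.0, np.where(np.isnan(t), 1.0, 2 * sps.t.sf(np.abs(t), df))
    )
    return t, p


def volcano_table(panel, alpha: float = 0.05) -> list[VolcanoRow]:
    """Per-marker t / BH-adjusted p / log2 FC rows over the whole panel.

    BH is applied jointly across all markers; the significance flag is
    adjusted p <= alpha.  Direction is the sign of the fold change (up =
    higher mean in cases).
    """
    labels = panel.labels
    if np.sum(labels == 1) < 2 or np.sum(labels == 0) < 2:
        raise ValueError("both arms need at least 2 subjects")
    t, p = _t_by_column(panel.values, labels)
    p_adj = bh_adjust(p)
    case = panel.values[labels == 1]
    ctrl = panel.values[labels == 0]
    grand = panel.values.mean()
    eps = 1e-6 * grand
    mc = case.mean(axis=0)
    mt = ctrl.mean(axis=0)
    with np.errstate(divide="ignore"):
        fc = np.where(
            (mc == 0) & (mt == 0), 0.0, np.log2((mc + eps) / (mt + eps))
        )
    return [
        VolcanoRow(
            marker_id=mid,
            t=float(t[j]),
            p=float(p[j]),
            p_adj=float(p_adj[j]),
            log2_fc=float(fc[j]),
            significant=bool(p_adj[j] <= alpha),
            direction="up" if fc[j] > 0 else "down",
        )
        for j, mid in enumerate(panel.marker_ids)
    ]


def volcano_summary(rows: list[VolcanoRow]) -> dict:
    """Counts of significant up/down markers (the reduction-bias diagnostic)."""
    sig = [r for r in rows if r.significant]
    return {
        "n_markers": len(rows),
        "n_significant": len(sig),
        "n_significant_up": sum(r.direction == "up" for r in sig),
        "n_significant_down": sum(r.direction == "down" for r in sig),
    }


def one_sample_t(values: np.ndarray, mu0: float) -> tuple[float, float]:
    """Two-sided one-sample t of the mean against mu0 (n-1 df)."""
    x = np.asarray(values, float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 values")
    sd = x.std(ddof=1)
    diff = x.mean() - mu0
    if sd == 0:
        if diff == 0:
            return 0.0, 1.0
        warnings.warn("zero sd with mean != mu0; reporting p = 0", stacklevel=2)
        return float(np.sign(diff) * np.inf), 0.0
    t = diff / (sd / np.sqrt(n))
    return float(t), float(2 * sps.t.sf(abs(t), n - 1))


def sample_size_sensspec(spec: SampleSizeSpec) -> tuple[int, int]:
    """Per-group n to estimate a sensitivity/specificity to absolute error e.

    n_per_group = ceil(z^2 p (1-p) / e^2), z the two-sided normal quantile at
    the stated confidence (1.959964 at 95%); the total doubles it for a
    case-control design.  For p = 0.80, 95% confidence, e = 0.08 this gives
    97 per group (194 total).
    """
    z = sps.norm.ppf(1 - (1 - spec.confidence) / 2)
    n_raw = z**2 * spec.p * (1 - spec.p) / spec.error**2
    n_per_group = int(np.ceil(n_raw))
    return n_per_group, 2 * n_per_group


def chi_square_independence(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square of independence, no continuity correction.

    Zero-margin rows/columns are dropped with a warning; df = (r-1)(c-1) on
    the remaining table.
    """
    obs = np.asarray(table, float)
    if obs.ndim != 2 or np.any(obs < 0):
        raise ValueError("need a 2-D table of nonnegative counts")
    row_ok = obs.sum(axis=1) > 0
    col_ok = obs.sum(axis=0) > 0
    if not row_ok.all() or not col_ok.all():
        warnings.warn("dropping zero-margin rows/columns", stacklevel=2)
        obs = obs[np.ix_(row_ok, col_ok)]
    r, c = obs.shape
    if r < 2 or c < 2:
        raise ValueError("need at least 2 rows and 2 columns with positive margins")
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
    statistic = float(((obs - expected) ** 2 / expected).sum())
    df = (r - 1) * (c - 1)
    return statistic, df, float(sps.chi2.sf(statistic, df))
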