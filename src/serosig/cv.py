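"""Class-preserving k-fold cross-validation of the signature pipeline.

Each fold holds out ~10% of subjects; on the remaining 90% the full cascade
runs — mostly-zero filter, correlation clustering, Z-normalization fit,
univariate F ranking, top-fraction selection, all-in logistic fit — and the
held-out subjects are Z-transformed with the training parameters and scored.
Nothing computed from a fold's test split can influence its training (unless
the leaky ``ranking_split='test'`` variant is explicitly requested, in which
case the report flags it).

The aggregate report mirrors the fold-level grid of a diagnostic CV study:
per-fold filter counts F(P1)/F(P2), metrics with mean +/- sample sd over the
k folds, a marker-recurrence table, pooled held-out predictions, and a
one-sample t-test of the fold accuracies against chance (the majority-class
proportion of the cohort, which is what always guessing the majority class
attains).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import feature_selection as fs
from . import preprocessing as pp
from .model import (
    LogisticModel,
    Metrics,
    classify,
    confusion_metrics,
    fit_logistic,
    predict_prob,
    roc_auc,
)
from .panel import MarkerPanel, SubjectMeta
from .stats import chi_square_independence, one_sample_t

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "f1", "auc")


@dataclass
class PipelineConfig:
    """Cross-validation settings: fold count, cutoff, seed, filters, normalization."""

    k: int = 10
    cutoff: float = 0.5
    seed: int = 0
    filters: fs.FilterConfig = field(default_factory=fs.FilterConfig)
    normalization: str = "fold"  # "fold" (leakage-free) or "global"
    ridge: float = 0.0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if not 0 < self.cutoff < 1:
            raise ValueError("cutoff must lie in (0, 1)")
        if self.normalization not in ("fold", "global"):
            raise ValueError("normalization must be 'fold' or 'global'")


@dataclass
class FoldPlan:
    """Fold index per subject; class-preserving and balanced to within 1."""

    fold_of: np.ndarray
    k: int
    seed: int


@dataclass
class FoldResult:
    fold_index: int
    f_p1: int  # markers removed by the mostly-zero filter
    f_p2: int  # markers removed by correlation clustering
    n_survivors: int
    selected: list[str]
    model: LogisticModel
    metrics: Metrics
    test_subjects: list[str]
    test_probs: np.ndarray
    test_labels: np.ndarray


@dataclass
class CVReport:
    folds: list[FoldResult]
    aggregate: dict  # metric -> (mean, sample sd)
    recurrence: dict  # marker id -> number of folds selecting it
    pooled_subjects: list[str]
    pooled_probs: np.ndarray
    pooled_labels: np.ndarray
    pooled_predictions: np.ndarray
    pooled_auc: float
    chance_accuracy: float
    t_vs_chance: tuple[float, float]
    config: PipelineConfig
    leakage_flag: bool = False


def make_folds(labels: np.ndarray, k: int, seed: int) -> FoldPlan:
    """Class-preserving fold assignment, balanced within each class and overall.

    Within each class, subjects are shuffled by the seeded generator and
    dealt in equal base shares; each class's remainder goes to the folds with
    the currently smallest totals, so overall fold sizes also differ by at
    most one (with 102 + 97 subjects in 10 folds: sizes 19-20, case counts
    10-11, control counts 9-10).
    """
    y = np.asarray(labels, int)
    rng = np.random.default_rng(seed)
    counts = {c: int(np.sum(y == c)) for c in np.unique(y)}
    if min(counts.values()) < k:
        raise ValueError(f"every class needs >= k={k} members, got {counts}")
    fold_of = np.empty(len(y), int)
    totals = np.zeros(k, int)
    for c in sorted(counts, key=counts.get, reverse=True):
        idx = rng.permutation(np.flatnonzero(y == c))
        base, extra = divmod(len(idx), k)
        # folds with the smallest running totals absorb this class's remainder
        fold_order = rng.permutation(k)
        by_load = fold_order[np.argsort(totals[fold_order], kind="stable")]
        share = np.full(k, base)
        share[by_load[:extra]] += 1
        pos = 0
        for f in range(k):
            fold_of[idx[pos: pos + share[f]]] = f
            pos += share[f]
        totals += share
    return FoldPlan(fold_of=fold_of, k=k, seed=seed)


def run_fold(
    panel: MarkerPanel,
    plan: FoldPlan,
    fold_index: int,
    config: PipelineConfig,
    *,
    global_params: pp.NormalizationParams | None = None,
) -> FoldResult:
    """Filter, rank, fit and evaluate one fold of the plan."""
    test_mask = plan.fold_of == fold_index
    train_rows = np.flatnonzero(~test_mask)
    test_rows = np.flatnonzero(test_mask)
    y_train = panel.labels[train_rows]
    y_test = panel.labels[test_rows]
    if len(np.unique(y_train)) < 2:
        raise ValueError(f"training split of fold {fold_index} lost a class")
    x_train = panel.values[train_rows]
    x_test = panel.values[test_rows]
    col = {mid: j for j, mid in enumerate(panel.marker_ids)}

    retained, f_p1 = fs.mostly_zero_filter(
        x_train, panel.marker_ids, config.filters.p1_zero_fraction
    )
    idx1 = [col[mid] for mid in retained]
    clusters = fs.build_clusters(
        x_train[:, idx1],
        retained,
        config.filters.p2_threshold,
        on_rho=config.filters.p2_on_rho,
    )
    survivors, f_p2 = fs.select_representatives(clusters)
    idx2 = [col[mid] for mid in survivors]

    if config.normalization == "global":
        params = pp.NormalizationParams(
            mean=global_params.mean[idx2],
            sd=global_params.sd[idx2],
            degenerate=global_params.degenerate[idx2],
        )
    else:
        params = pp.zscore_fit(x_train[:, idx2])
    z_train = pp.zscore_apply(x_train[:, idx2], params)
    z_test = pp.zscore_apply(x_test[:, idx2], params)

    # degenerate (zero-variance) survivors carry no signal; rank the rest
    rankable = [
        (j, mid)
        for j, (mid, deg) in enumerate(zip(survivors, params.degenerate))
        if not deg
    ]
    rank_matrix = z_train if config.filters.ranking_split == "train" else z_test
    rank_labels = y_train if config.filters.ranking_split == "train" else y_test
    selected = fs.rank_and_select(
        rank_matrix[:, [j for j, _ in rankable]],
        [mid for _, mid in rankable],
        rank_labels,
        config.filters,
        panel.n_markers,
    )
    sel_idx = [survivors.index(mid) for mid in selected]

    model = fit_logistic(
        z_train[:, sel_idx], y_train, selected, ridge=config.ridge
    )
    probs = predict_prob(model, z_test[:, sel_idx])
    metrics = confusion_metrics(classify(probs, config.cutoff), y_test, config.cutoff)
    if len(np.unique(y_test)) == 2:
        metrics.auc = roc_auc(probs, y_test)[0]
    return FoldResult(
        fold_index=fold_index,
        f_p1=f_p1,
        f_p2=f_p2,
        n_survivors=len(survivors),
        selected=selected,
        model=model,
        metrics=metrics,
        test_subjects=[panel.subject_ids[i] for i in test_rows],
        test_probs=probs,
        test_labels=y_test,
    )


def run_cv(panel: MarkerPanel, config: PipelineConfig) -> CVReport:
    """Full k-fold cross-validation; deterministic given the config seed."""
    plan = make_folds(panel.labels, config.k, config.seed)
    global_params = (
        pp.zscore_fit(panel.values) if config.normalization == "global" else None
    )
    folds = [
        run_fold(panel, plan, f, config, global_params=global_params)
        for f in range(config.k)
    ]

    aggregate = {}
    for name in METRIC_NAMES:
        vals = np.array(
            [getattr(fr.metrics, name) if name != "auc" else fr.metrics.auc
             for fr in folds],
            dtype=float,
        )
        aggregate[name] = (float(np.nanmean(vals)), float(np.nanstd(vals, ddof=1)))
    for name, getter in (("f_p1", "f_p1"), ("f_p2", "f_p2")):
        vals = np.array([getattr(fr, getter) for fr in folds], float)
        aggregate[name] = (float(vals.mean()), float(vals.std(ddof=1)))

    recurrence: dict[str, int] = {}
    for fr in folds:
        for mid in fr.selected:
            recurrence[mid] = recurrence.get(mid, 0) + 1

    pooled_subjects = [s for fr in folds for s in fr.test_subjects]
    pooled_probs = np.concatenate([fr.test_probs for fr in folds])
    pooled_labels = np.concatenate([fr.test_labels for fr in folds])
    pooled_predictions = classify(pooled_probs, config.cutoff)
    pooled_auc = roc_auc(pooled_probs, pooled_labels)[0]

    chance = float(max(np.mean(panel.labels), 1 - np.mean(panel.labels)))
    accuracies = [fr.metrics.accuracy for fr in folds]
    return CVReport(
        folds=folds,
        aggregate=aggregate,
        recurrence=recurrence,
        pooled_subjects=pooled_subjects,
        pooled_probs=pooled_probs,
        pooled_labels=pooled_labels,
        pooled_predictions=pooled_predictions,
        pooled_auc=pooled_auc,
        chance_accuracy=chance,
        t_vs_chance=one_sample_t(accuracies, chance),
        config=config,
        leakage_flag=config.filters.ranking_split == "test",
    )


def recurrence_table(report: CVReport, min_count: int = 2) -> list[tuple[str, int]]:
    """Markers selected in at least ``min_count`` folds, by descending count."""
    return sorted(
        ((mid, c) for mid, c in report.recurrence.items() if c >= min_count),
        key=lambda item: (-item[1], item[0]),
    )


def accuracy_independence(
    report: CVReport, meta: list[SubjectMeta], covariate: str
) -> tuple[float, int, float]:
    """Chi-square test of prediction correctness against a subject covariate.

    Builds the correctness (correct/incorrect) x covariate-level contingency
    table over the pooled held-out predictions; Pearson chi-square without
    continuity correction, df = levels - 1.
    """
    level_of = {m.subject_id: getattr(m, covariate) for m in meta}
    levels = sorted({level_of[s] for s in report.pooled_subjects})
    if len(levels) < 2:
        raise ValueError(f"covariate {covariate!r} has fewer than 2 levels")
    correct = report.pooled_predictions == report.pooled_labels
    table = np.array(
        [
            [
                int(np.sum([c and level_of[s] == lev
                            for s, c in zip(report.pooled_subjects, correct)])),
                int(np.sum([(not c) and level_of[s] == lev
                            for s, c in zip(report.pooled_subjects, correct)])),
            ]
            for lev in levels
        ]
    )
    return chi_square_independence(table)


def report_to_dict(report: CVReport, truth=None) -> dict:
    """JSON-ready summary: fold grid, equations, recurrence, pooled results."""
    out = {
        "config": {
            "k": report.config.k,
            "cutoff": report.config.cutoff,
            "seed": report.config.seed,
            "normalization": report.config.normalization,
            "p1_zero_fraction": report.config.filters.p1_zero_fraction,
            "p2_threshold": report.config.filters.p2_threshold,
            "top_fraction": report.config.filters.top_fraction,
            "ranking_split": report.config.filters.ranking_split,
        },
        "leakage_flag": report.leakage_flag,
        "folds": [
            {
                "fold": fr.fold_index,
                "F_P1": fr.f_p1,
                "F_P2": fr.f_p2,
                "survivors": fr.n_survivors,
                "selected": fr.selected,
                "equation": fr.model.equation(),
                "separated": fr.model.separated,
                "accuracy": fr.metrics.accuracy,
                "sensitivity": fr.metrics.sensitivity,
                "specificity": fr.metrics.specificity,
                "f1": fr.metrics.f1,
                "auc": fr.metrics.auc,
            }
            for fr in report.folds
        ],
        "aggregate": {k: {"mean": v[0], "sd": v[1]} for k, v in report.aggregate.items()},
        "recurrence": recurrence_table(report, min_count=1),
        "pooled_auc": report.pooled_auc,
        "chance_accuracy": report.chance_accuracy,
        "t_vs_chance": {"t": report.t_vs_chance[0], "p": report.t_vs_chance[1]},
    }
    return out


def write_report(report: CVReport, path, truth=None) -> None:
    with open(path, "w") as fh:
        json.dump(report_to_dict(report, truth), fh, indent=2)
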