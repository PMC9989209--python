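"""Fold geometry, per-fold pipeline contracts, aggregation, leakage guards."""

import numpy as np
import pytest

from serosig import (
    FilterConfig,
    MarkerPanel,
    PipelineConfig,
    SubjectMeta,
    accuracy_independence,
    generate_cohort,
    make_folds,
    recurrence_table,
    run_cv,
    run_fold,
    study_default_config,
)
from serosig.cv import report_to_dict
from serosig.synthetic import SyntheticConfig


def cohort_labels(n_case=102, n_control=97):
    return np.r_[np.ones(n_case, int), np.zeros(n_control, int)]


def fold_counts(plan, labels):
    sizes, cases, controls = [], [], []
    for f in range(plan.k):
        mask = plan.fold_of == f
        sizes.append(int(mask.sum()))
        cases.append(int((labels[mask] == 1).sum()))
        controls.append(int((labels[mask] == 0).sum()))
    return sizes, cases, controls


def test_study_fold_geometry():
    """102 + 97 subjects in 10 folds: sizes 19-20, cases 10-11, controls 9-10."""
    labels = cohort_labels()
    for seed in range(20):
        plan = make_folds(labels, 10, seed)
        sizes, cases, controls = fold_counts(plan, labels)
        assert set(sizes) <= {19, 20}
        assert set(cases) <= {10, 11}
        assert set(controls) <= {9, 10}
        assert sum(sizes) == 199


def test_minimal_fold_geometry():
    labels = cohort_labels(10, 10)
    plan = make_folds(labels, 10, 0)
    sizes, cases, controls = fold_counts(plan, labels)
    assert sizes == [2] * 10 and cases == [1] * 10 and controls == [1] * 10


def test_fold_balance_oracle_random_shapes(rng):
    """Per-class and overall counts always within 1 of each other."""
    for _ in range(20):
        k = int(rng.integers(2, 8))
        n1 = int(rng.integers(k, 60))
        n0 = int(rng.integers(k, 60))
        labels = cohort_labels(n1, n0)
        plan = make_folds(labels, k, int(rng.integers(1_000_000)))
        sizes, cases, controls = fold_counts(plan, labels)
        for counts, total in ((sizes, n1 + n0), (cases, n1), (controls, n0)):
            assert max(counts) - min(counts) <= 1
            assert sum(counts) == total


def test_make_folds_rejects_small_class():
    with pytest.raises(ValueError, match="class"):
        make_folds(cohort_labels(5, 50), 10, 0)


def small_cohort(seed=0, n_markers=120, **kw):
    cfg = study_default_config(seed=seed, n_markers=n_markers)
    return generate_cohort(cfg)


def test_marker_conservation_per_fold():
    """Original M = F(P1) + F(P2) + survivors in every fold."""
    panel, _, _ = small_cohort(seed=2)
    report = run_cv(panel, PipelineConfig(seed=2))
    for fr in report.folds:
        assert fr.f_p1 + fr.f_p2 + fr.n_survivors == panel.n_markers
        assert len(fr.selected) == 2  # ceil(0.01 * 120)
        assert set(np.unique(report.pooled_labels)) == {0, 1}


def test_cv_determinism():
    panel, _, _ = small_cohort(seed=3)
    r1 = run_cv(panel, PipelineConfig(seed=5))
    r2 = run_cv(panel, PipelineConfig(seed=5))
    assert r1.aggregate == r2.aggregate
    np.testing.assert_array_equal(r1.pooled_probs, r2.pooled_probs)
    assert [f.selected for f in r1.folds] == [f.selected for f in r2.folds]


def test_aggregate_recomputable_from_folds():
    panel, _, _ = small_cohort(seed=4)
    report = run_cv(panel, PipelineConfig(seed=4))
    accs = [fr.metrics.accuracy for fr in report.folds]
    assert report.aggregate["accuracy"][0] == pytest.approx(np.mean(accs))
    assert report.aggregate["accuracy"][1] == pytest.approx(np.std(accs, ddof=1))
    sens = [fr.metrics.sensitivity for fr in report.folds]
    assert report.aggregate["sensitivity"][0] == pytest.approx(np.mean(sens))


def test_perfectly_separating_marker_gives_fold_accuracy_1(rng):
    n = 60
    labels = cohort_labels(30, 30)
    values = rng.gamma(2.0, 10.0, size=(n, 5)) + 0.5
    values[:, 3] = 1.0 + 9.0 * labels  # perfect separator
    panel = MarkerPanel(
        [f"s{i}" for i in range(n)], labels,
        [f"m{j}" for j in range(5)], values,
    )
    config = PipelineConfig(k=5, seed=0, filters=FilterConfig(top_fraction=0.2))
    plan = make_folds(labels, 5, 0)
    fr = run_fold(panel, plan, 0, config)
    assert fr.metrics.accuracy == 1.0
    assert "m3" in fr.selected


def test_training_pipeline_ignores_test_split(rng):
    """Permuting held-out values changes nothing about the trained model."""
    panel, _, _ = small_cohort(seed=6)
    config = PipelineConfig(seed=6)
    plan = make_folds(panel.labels, 10, 6)
    fr = run_fold(panel, plan, 0, config)
    test_rows = np.flatnonzero(plan.fold_of == 0)
    scrambled = panel.values.copy()
    scrambled[test_rows] = scrambled[test_rows][:, rng.permutation(panel.n_markers)]
    panel2 = MarkerPanel(
        panel.subject_ids, panel.labels, panel.marker_ids, scrambled
    )
    fr2 = run_fold(panel2, plan, 0, config)
    assert fr2.selected == fr.selected
    np.testing.assert_array_equal(
        fr2.model.coefficients, fr.model.coefficients
    )


def test_leaky_ranking_split_is_flagged():
    panel, _, _ = small_cohort(seed=7)
    config = PipelineConfig(
        seed=7, filters=FilterConfig(ranking_split="test")
    )
    report = run_cv(panel, config)
    assert report.leakage_flag
    assert report_to_dict(report)["leakage_flag"]


def test_recurrence_table_counts():
    panel, _, truth = small_cohort(seed=8)
    report = run_cv(panel, PipelineConfig(seed=8))
    table = recurrence_table(report, min_count=2)
    tally = {}
    for fr in report.folds:
        for mid in fr.selected:
            tally[mid] = tally.get(mid, 0) + 1
    assert dict(table) == {m: c for m, c in tally.items() if c >= 2}
    assert all(c <= 10 for _, c in table)
    counts = [c for _, c in table]
    assert counts == sorted(counts, reverse=True)
    assert recurrence_table(report, min_count=11) == []


def test_accuracy_independence_contract():
    panel, meta, _ = small_cohort(seed=9)
    report = run_cv(panel, PipelineConfig(seed=9))
    stat, df, p = accuracy_independence(report, meta, "gender")
    assert df == 1 and 0 <= p <= 1
    for m in meta:
        m.source = "only_site"
    with pytest.raises(ValueError, match="levels"):
        accuracy_independence(report, meta, "source")


def test_identical_folds_have_zero_sd(rng):
    """A cohort tiled so every fold sees the same subjects gives sd 0."""
    block_vals = np.vstack([
        np.linspace(1, 5, 5)[:, None] * np.ones((5, 6)) + 10 * np.eye(5, 6)
    ])
    values = np.tile(block_vals, (4, 1))
    labels = np.tile(np.array([1, 1, 1, 0, 0]), 4)
    values[labels == 1, 0] += 50.0  # strong separator
    panel = MarkerPanel(
        [f"s{i}" for i in range(20)], labels,
        [f"m{j}" for j in range(6)], values,
    )
    # identical content in every fold; use k=4 with fold = subject block
    from serosig.cv import FoldPlan, run_fold
    plan = FoldPlan(fold_of=np.repeat(np.arange(4), 5), k=4, seed=0)
    config = PipelineConfig(k=4, seed=0, filters=FilterConfig(top_fraction=0.34))
    accs = [run_fold(panel, plan, f, config).metrics.accuracy for f in range(4)]
    assert np.std(accs, ddof=1) == 0.0


def test_global_normalization_mode_runs():
    panel, _, _ = small_cohort(seed=10)
    report = run_cv(panel, PipelineConfig(seed=10, normalization="global"))
    assert len(report.folds) == 10
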