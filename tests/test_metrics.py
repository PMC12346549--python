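"""metrics: AUROC/AUPRC oracles, operating points, correlation, subgroups."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecgaudit.metrics import (
    ConfusionCounts,
    auprc,
    auroc,
    auroc_ci,
    binarized_scores,
    compute_report,
    counts_from_rates,
    metrics_from_counts,
    operating_point_metrics,
    pearson_r,
    subgroup_performance,
    threshold_for_sensitivity,
)


def brute_force_auroc(scores, labels):
    """Pairwise-probability oracle: wins + half-ties over all pos-neg pairs."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels > 0.5]
    neg = scores[labels <= 0.5]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def brute_force_auprc(scores, labels):
    """Threshold-enumeration oracle with explicit loop integration."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int((labels > 0.5).sum())
    best = {}
    for thr in sorted(set(scores), reverse=True):
        called = scores >= thr
        tp = int((called & (labels > 0.5)).sum())
        if tp == 0:
            continue
        r, p = tp / n_pos, tp / int(called.sum())
        best[r] = max(best.get(r, 0.0), p)
    pts = [(0.0, 1.0)] + sorted(best.items())
    area = 0.0
    for (r0, p0), (r1, p1) in zip(pts, pts[1:]):
        area += (r1 - r0) * (p0 + p1) / 2.0
    return area


class TestAUROC:
    def test_worked_example(self):
        # pairs: (0.35 vs 0.1) win, (0.35 vs 0.4) loss, (0.8 vs both) wins
        assert auroc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75

    def test_perfect_separation(self):
        assert auroc([1, 2, 9, 10], [0, 0, 1, 1]) == 1.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(4, 60))
            scores = rng.normal(size=n)
            if rng.uniform() < 0.5:
                scores = np.round(scores)  # force ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            assert abs(auroc(scores, labels)
                       - brute_force_auroc(scores, labels)) < 1e-12

    def test_binarized_identity_matches_se_sp(self):
        counts = counts_from_rates(98, 583, 0.898, 0.940)
        scores, labels = binarized_scores(counts)
        se = counts.tp / counts.n_pos
        sp = counts.tn / counts.n_neg
        assert abs(auroc(scores, labels) - (se + sp) / 2) < 1e-12
        assert round(auroc(scores, labels), 3) == 0.919

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([1, 2], [1, 1])

    def test_delong_ci_brackets_value(self):
        rng = np.random.default_rng(1)
        scores = np.concatenate([rng.normal(1, 1, 40), rng.normal(0, 1, 60)])
        labels = np.array([1] * 40 + [0] * 60)
        value, (lo, hi) = auroc_ci(scores, labels, method="delong")
        assert 0 <= lo <= value <= hi <= 1
        assert hi - lo < 0.5

    def test_bootstrap_seeded(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, size=30)
        labels[:2] = [0, 1]
        a = auroc_ci(scores, labels, method="bootstrap", seed=7, n_boot=200)
        b = auroc_ci(scores, labels, method="bootstrap", seed=7, n_boot=200)
        assert a == b


class TestAUPRC:
    def test_worked_example_11_12(self):
        assert abs(auprc([0.9, 0.8, 0.7], [1, 0, 1]) - 11 / 12) < 1e-12

    def test_perfect_separation(self):
        assert auprc([1, 2, 9, 10], [0, 0, 1, 1]) == 1.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(4, 50))
            scores = rng.normal(size=n)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            assert abs(auprc(scores, labels)
                       - brute_force_auprc(scores, labels)) < 1e-12

    def test_random_scores_approach_prevalence(self):
        rng = np.random.default_rng(4)
        n, p = 10_000, 0.15
        labels = (rng.uniform(size=n) < p).astype(int)
        scores = rng.uniform(size=n)
        assert abs(auprc(scores, labels) - labels.mean()) < 0.03


class TestOperatingPoint:
    def test_table2_reconstruction(self):
        counts = counts_from_rates(98, 583, 0.898, 0.940)
        assert (counts.tp, counts.fn, counts.tn, counts.fp) == (88, 10, 548, 35)
        metrics = metrics_from_counts(counts)
        assert round(metrics["ppv"][0], 3) == 0.715
        assert round(metrics["npv"][0], 3) == 0.982
        assert counts.n_called_positive == 123

    def test_threshold_below_min(self):
        counts, m = operating_point_metrics([1, 2, 3, 4], [0, 0, 1, 1], 0.5)
        assert m["sensitivity"][0] == 1.0 and m["specificity"][0] == 0.0

    def test_threshold_above_max(self):
        counts, m = operating_point_metrics([1, 2, 3, 4], [0, 0, 1, 1], 5.0)
        assert m["sensitivity"][0] == 0.0 and m["specificity"][0] == 1.0

    def test_boundary_inclusive(self):
        counts, _ = operating_point_metrics([9.7, 9.69], [1, 0], 9.7)
        assert counts.tp == 1 and counts.fp == 0

    def test_undefined_ppv_flagged_not_fabricated(self):
        _, m = operating_point_metrics([1, 2], [0, 1], 5.0)  # nobody called pos
        assert m["ppv"] == (None, None)

    def test_wilson_ci_brackets(self):
        _, m = operating_point_metrics(
            np.r_[np.ones(80), np.zeros(20), np.zeros(90), np.ones(10)],
            np.r_[np.ones(100), np.zeros(100)], 0.5)
        for key in ("sensitivity", "specificity", "ppv", "npv"):
            value, (lo, hi) = m[key]
            assert 0 <= lo <= value <= hi <= 1

    @given(st.integers(5, 60), st.integers(5, 60), st.integers(0, 10**6))
    @settings(max_examples=30, deadline=None)
    def test_binary_auroc_identity_property(self, n_pos, n_neg, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=n_pos + n_neg)
        labels = np.r_[np.ones(n_pos), np.zeros(n_neg)]
        thr = float(np.median(scores))
        binarized = (scores >= thr).astype(float)
        counts, m = operating_point_metrics(scores, labels, thr)
        se = counts.tp / counts.n_pos
        sp = counts.tn / counts.n_neg
        assert abs(auroc(binarized, labels) - (se + sp) / 2) < 1e-12

    def test_ppv_bayes_identity(self):
        counts = counts_from_rates(98, 583, 0.898, 0.940)
        se = counts.tp / counts.n_pos
        sp = counts.tn / counts.n_neg
        p = counts.n_pos / (counts.n_pos + counts.n_neg)
        ppv = counts.tp / (counts.tp + counts.fp)
        assert abs(ppv - se * p / (se * p + (1 - sp) * (1 - p))) < 1e-12


class TestThresholdForSensitivity:
    def test_decile_example(self):
        scores = list(range(10, 101, 10)) + [1, 2, 3]
        labels = [1] * 10 + [0] * 3
        assert threshold_for_sensitivity(scores, labels, 0.9) == 20

    def test_target_one_gives_min_positive(self):
        scores = [5, 15, 25, 1]
        labels = [1, 1, 1, 0]
        assert threshold_for_sensitivity(scores, labels, 1.0) == 5

    def test_constant_positives(self):
        assert threshold_for_sensitivity([7, 7, 7, 2], [1, 1, 1, 0], 0.5) == 7

    def test_sensitivity_at_threshold_meets_target(self):
        rng = np.random.default_rng(5)
        scores = rng.uniform(size=100)
        labels = rng.integers(0, 2, size=100)
        labels[0] = 1
        thr = threshold_for_sensitivity(scores, labels, 0.9)
        pos = scores[labels > 0.5]
        assert (pos >= thr).mean() >= 0.9

    def test_bad_target_rejected(self):
        with pytest.raises(ValueError):
            threshold_for_sensitivity([1, 2], [1, 0], 1.5)


class TestPearson:
    def test_perfect_negative(self):
        x = np.arange(10.0)
        r, p = pearson_r(x, -x)
        assert abs(r + 1) < 1e-12

    def test_independent_near_zero(self):
        rng = np.random.default_rng(6)
        r, _ = pearson_r(rng.normal(size=10_000), rng.normal(size=10_000))
        assert abs(r) < 0.03

    def test_hand_computed_five_points(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 7.0])
        # closed-form sums oracle
        n = 5
        num = n * (x * y).sum() - x.sum() * y.sum()
        den = np.sqrt(n * (x**2).sum() - x.sum() ** 2) * np.sqrt(
            n * (y**2).sum() - y.sum() ** 2)
        r, _ = pearson_r(x, y)
        assert abs(r - num / den) < 1e-12

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1, 1, 1], [1, 2, 3])


class TestSubgroups:
    def _data(self):
        rng = np.random.default_rng(7)
        labels = rng.integers(0, 2, size=200)
        labels[:4] = [0, 1, 0, 1]
        scores = labels * 1.5 + rng.normal(size=200)
        return scores, labels

    def test_single_group_equals_global(self):
        scores, labels = self._data()
        df = subgroup_performance(scores, labels, ["all"] * 200, threshold=0.5)
        assert len(df) == 1
        assert df.iloc[0]["auroc"] == auroc_ci(scores, labels)[0]

    def test_disjoint_group_sizes_sum(self):
        scores, labels = self._data()
        groups = np.array(["a"] * 120 + ["b"] * 80)
        df = subgroup_performance(scores, labels, groups, threshold=0.5)
        assert df["n"].sum() == 200

    def test_single_class_group_flagged(self):
        scores = np.array([1.0, 2.0, 3.0, 4.0])
        labels = np.array([1, 1, 0, 1])
        groups = np.array(["x", "x", "y", "y"])
        df = subgroup_performance(scores, labels, groups, threshold=2.5)
        x_row = df[df["group"] == "x"].iloc[0]
        assert not x_row["evaluable"] and np.isnan(x_row["auroc"])

    def test_neutral_covariate_groups_overlap(self, small_cohort, trained_small):
        from ecgaudit.surrogate import predict_scores

        model, _ = trained_small
        records = [r for r, _ in small_cohort]
        metas = [m for _, m in small_cohort]
        labels = np.array([1 if m.label == "LVSD" else 0 for m in metas])
        scores = np.array([o.score for o in predict_scores(model, records)])
        sexes = np.array([m.sex for m in metas])
        df = subgroup_performance(scores, labels, sexes, threshold=9.7, seed=0)
        assert df["evaluable"].all()
        rows = df.set_index("group")
        # sex is performance-neutral: the two groups' 95% CIs overlap
        assert max(rows["auroc_lo"]) <= min(rows["auroc_hi"])
        assert (rows["auroc"] > 0.8).all()

    def test_empty_grouping_rejected(self):
        with pytest.raises(ValueError):
            subgroup_performance([1], [1], {}, threshold=0.5)


class TestReport:
    def test_report_fields_consistent(self):
        rng = np.random.default_rng(8)
        labels = np.r_[np.ones(40), np.zeros(160)]
        scores = labels * 30 + rng.uniform(0, 20, size=200)
        report = compute_report(scores, labels, threshold=25.0,
                                lvef=60 - scores / 3, seed=0)
        assert report.n_pos == 40 and report.n_neg == 160
        assert abs(report.auroc_binary
                   - (report.sensitivity + report.specificity) / 2) < 1e-12
        assert report.pearson_r < -0.9
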