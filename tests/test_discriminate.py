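"""Boxplot summaries, rank-sum test, k-means and the combined protocol."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import mannwhitneyu

from qpcdiff import (
    ValidationError,
    boxplot_summary,
    kmeans_cluster,
    run_discrimination,
    wilcoxon_rank_sum,
)
from qpcdiff.discriminate import _exact_two_sided_p, _phenotype_labels


class TestBoxplotSummary:
    def test_one_to_nine(self):
        s = boxplot_summary(range(1, 10))
        assert s.median == 5 and s.q25 == 3 and s.q75 == 7
        assert s.whisker_low == 1 and s.whisker_high == 9
        assert s.outliers == []

    def test_single_value(self):
        s = boxplot_summary([4.2])
        assert s.median == s.q25 == s.q75 == 4.2
        assert s.whisker_low == s.whisker_high == 4.2

    def test_extreme_point_flagged_as_outlier(self):
        s = boxplot_summary(list(range(1, 10)) + [100])
        assert 100 in s.outliers
        assert s.whisker_high < 100

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            boxplot_summary([])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=60))
    def test_invariants_on_random_input(self, values):
        s = boxplot_summary(values)
        iqr = s.q75 - s.q25
        assert s.q25 <= s.median <= s.q75
        assert s.q25 - 1.5 * iqr <= s.whisker_low <= s.whisker_high \
            <= s.q75 + 1.5 * iqr
        for o in s.outliers:
            assert o < s.whisker_low or o > s.whisker_high
        assert s.n_cells == len(values)


class TestWilcoxonRankSum:
    def test_exact_enumeration_small_case(self):
        """x={1,2} vs y={3,4}: W=3 is the minimum of C(4,2)=6 equally
        likely assignments, so the two-sided exact p is 2/6 = 1/3."""
        r = wilcoxon_rank_sum([1, 2], [3, 4])
        assert r.method == "exact"
        assert r.W == 3
        assert r.p_two_sided == pytest.approx(1 / 3)

    def test_identical_samples(self):
        r = wilcoxon_rank_sum([5, 5, 7], [5, 5, 7])
        assert r.z == 0.0
        assert r.p_two_sided == 1.0
        assert not r.rejected_at_alpha

    def test_exact_matches_enumeration_oracle(self):
        """All size pairs with pooled n <= 12: exact equals a from-scratch
        enumeration over rank assignments to machine precision."""
        import itertools
        import math

        rng = np.random.default_rng(8)
        for n_x in range(1, 7):
            for n_y in range(n_x, 13 - n_x):
                x = rng.normal(size=n_x)
                y = rng.normal(0.5, size=n_y)
                r = wilcoxon_rank_sum(x, y)
                ranks = np.concatenate([x, y]).argsort().argsort() + 1.0
                w = ranks[:n_x].sum()
                sums = [sum(c) for c in
                        itertools.combinations(ranks, n_x)]
                lo = sum(s <= w for s in sums) / len(sums)
                hi = sum(s >= w for s in sums) / len(sums)
                p_oracle = min(1.0, 2 * min(lo, hi))
                assert r.method == "exact"
                assert r.W == w
                assert r.p_two_sided == pytest.approx(p_oracle, abs=1e-12)

    def test_normal_approximation_close_in_decision_tail(self):
        """Where the exact two-sided p is at most 0.1 — the region where a
        5% decision could hinge on the approximation — the continuity-
        corrected normal p agrees with the exact p to within 0.02, for
        every achievable statistic at every pooled size up to 12.

        (Near the centre of the null distribution the discrete point mass
        makes the exact p jump by more than any smooth approximation can
        follow, so no uniform bound holds there.)"""
        import itertools

        from scipy.stats import norm

        for n_x in range(1, 12):
            for n_y in range(n_x, 12):
                n_total = n_x + n_y
                if n_total > 12:
                    continue
                ranks = np.arange(1, n_total + 1, dtype=float)
                sums = np.array([sum(c) for c in
                                 itertools.combinations(ranks, n_x)])
                mu = n_x * (n_total + 1) / 2
                var = n_x * n_y * (n_total + 1) / 12
                for w in np.unique(sums):
                    lo = np.mean(sums <= w + 1e-9)
                    hi = np.mean(sums >= w - 1e-9)
                    p_exact = min(1.0, 2 * min(lo, hi))
                    if p_exact > 0.1:
                        continue
                    z = (w - mu - 0.5 * np.sign(w - mu)) / np.sqrt(var)
                    p_norm = min(1.0, 2 * norm.sf(abs(z)))
                    assert abs(p_norm - p_exact) < 0.02

    def test_agrees_with_scipy_on_large_samples(self):
        """Cross-check against the independent scipy implementation."""
        rng = np.random.default_rng(12)
        for _ in range(10):
            x = rng.normal(size=25)
            y = rng.normal(0.3, size=30)
            r = wilcoxon_rank_sum(x, y)
            ref = mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic", use_continuity=True)
            assert r.p_two_sided == pytest.approx(ref.pvalue, abs=1e-9)

    def test_type_one_error_calibration(self):
        """Null rejection rate stays at the nominal 5% level."""
        rng = np.random.default_rng(99)
        n_sim = 600
        rejections = sum(
            wilcoxon_rank_sum(rng.normal(size=30),
                              rng.normal(size=30)).rejected_at_alpha
            for _ in range(n_sim))
        rate = rejections / n_sim
        se = np.sqrt(0.05 * 0.95 / n_sim)
        assert abs(rate - 0.05) < 3 * se

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            wilcoxon_rank_sum([], [1, 2])


class TestKMeans:
    def test_two_points_two_clusters(self):
        labels, centroids, inertia, _ = kmeans_cluster(
            np.array([[0.0, 0.0], [10.0, 3.0]]), k=2, seed=0)
        assert set(labels) == {0, 1}
        assert inertia == pytest.approx(0.0, abs=1e-12)

    def test_planted_partition_recovery(self):
        """Two tight blobs are recovered exactly across seeds."""
        for seed in range(10):
            rng = np.random.default_rng(seed)
            a = rng.normal([-5, 0], 1.0, (50, 2))
            b = rng.normal([5, 0], 1.0, (50, 2))
            pts = np.vstack([a, b])
            labels, _, _, _ = kmeans_cluster(pts, k=2, seed=seed,
                                             standardize=False)
            assert len(set(labels[:50])) == 1
            assert len(set(labels[50:])) == 1
            assert labels[0] != labels[50]

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            kmeans_cluster(np.array([[1.0, 2.0]]), k=2)

    def test_phenotype_rule(self):
        """Large-area, low-aspect-ratio cluster is astrocyte-like."""
        centroids = np.array([[1.2, -0.9], [-1.2, 0.9]])  # (z_area, z_ar)
        labels = _phenotype_labels(centroids)
        assert labels[0] == "astrocyte-like"
        assert labels[1] == "neuron-like"


def _metrics_frame(rows):
    return pd.DataFrame(rows, columns=["cell_id", "day", "modality",
                                       "area_px", "major_axis_px",
                                       "minor_axis_px", "aspect_ratio"])


class TestRunDiscrimination:
    def _null_table(self, seed=0, days=4, n=15):
        rng = np.random.default_rng(seed)
        rows = []
        for day in range(1, days + 1):
            for modality in ("QPC", "TIRM"):
                for i in range(n):
                    area = rng.normal(800, 120)
                    ar = rng.normal(2.2, 0.3)
                    rows.append([f"{day}{modality}{i}", day, modality,
                                 area, 40.0, 20.0, ar])
        return _metrics_frame(rows)

    def test_null_configuration_no_division(self):
        """Identically distributed modalities: no division, no clustering."""
        report = run_discrimination(self._null_table(seed=1), seed=0)
        assert report.division_day is None
        assert report.cluster is None

    def test_internal_consistency_of_flags(self):
        report = run_discrimination(self._null_table(seed=2), seed=0)
        recomputed = report.ranksum["p_two_sided"] < report.alpha
        assert (report.ranksum["rejected_at_alpha"] == recomputed).all()

    def test_shifted_later_days_divide_and_cluster(self):
        """From day 3 the channels sample different phenotypes; the
        division lands there and the clusters split by modality."""
        rng = np.random.default_rng(5)
        rows = []
        for day in (1, 2):
            for modality in ("QPC", "TIRM"):
                for i in range(15):
                    rows.append([f"{day}{modality}{i}", day, modality,
                                 rng.normal(800, 100), 40, 20,
                                 rng.normal(2.3, 0.3)])
        for day in (3, 4, 5):
            for i in range(15):
                rows.append([f"{day}Q{i}", day, "QPC",
                             rng.normal(600, 80), 40, 20,
                             rng.normal(2.8, 0.3)])
                rows.append([f"{day}T{i}", day, "TIRM",
                             rng.normal(2500, 300), 60, 50,
                             rng.normal(1.3, 0.1)])
        report = run_discrimination(_metrics_frame(rows), seed=0)
        assert report.division_day == 3
        by_modality = {}
        for (_, row), lab in zip(report.cluster.points.iterrows(),
                                 report.cluster.labels):
            by_modality.setdefault(row["modality"], set()).add(
                report.phenotype_labels[int(lab)])
        assert by_modality == {"QPC": {"neuron-like"},
                               "TIRM": {"astrocyte-like"}}

    def test_day_missing_modality_excluded(self, caplog):
        import logging

        table = self._null_table(seed=3, days=3)
        table = table[~((table["day"] == 2) & (table["modality"] == "TIRM"))]
        with caplog.at_level(logging.WARNING, logger="qpcdiff.discriminate"):
            report = run_discrimination(table, seed=0)
        assert 2 not in set(report.ranksum["day"])
        assert any("excluded" in r.message for r in caplog.records)
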