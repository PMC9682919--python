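"""Percentile tables, norm lookups, conditional curves, correlations."""

import random

import numpy as np
import pytest

import crtlab
from crtlab import (ValidationError, conditional_curve, correlation_report,
                    individual_percentile, percentile_table, reference_table)
from tests.conftest import make_score


class TestPercentileTable:
    def test_single_score_extremes(self):
        table = percentile_table([make_score(25, 25, 0.8)],
                                 {"n_correct": [50], "rt": [0.5]})
        assert table.lookup("n_correct", 50) == (0.0, False)
        assert table.lookup("rt", 0.5) == (1.0, False)

    def test_matches_brute_force_counting_oracle(self):
        rng = random.Random(2)
        scores = [make_score(rng.randint(10, 25), rng.randint(10, 25),
                             round(rng.uniform(0.5, 2.0), 3))
                  for _ in range(10)]
        thresholds = {"hits": [12, 18, 25], "rt": [0.7, 1.0, 1.5]}
        table = percentile_table(scores, thresholds)
        n = len(scores)
        for x in thresholds["hits"]:
            expected = sum(s.hits < x for s in scores) / n
            assert table.lookup("hits", x)[0] == expected
        for t in thresholds["rt"]:
            expected = sum(s.mean_hit_rt > t for s in scores) / n
            assert table.lookup("rt", t)[0] == expected

    def test_adding_low_score_raises_every_fraction(self):
        base = [make_score(20, 20, 0.9) for _ in range(5)]
        t = {"n_correct": [40], "hits": [20], "crs": [20]}
        before = percentile_table(base, t)
        after = percentile_table(base + [make_score(5, 5, 0.9)], t)
        for metric in t:
            assert after.lookup(metric, t[metric][0])[0] > before.lookup(
                metric, t[metric][0])[0]

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            percentile_table([])


class TestNormLookup:
    def test_reference_table_shape_and_monotonicity(self):
        table = reference_table()
        assert set(table.metrics()) == {"n_correct", "hits", "crs", "rt"}
        assert table.n == 282_140
        for metric in ("n_correct", "hits", "crs"):
            _, frac = table.columns[metric]
            assert np.all(np.diff(frac) >= 0)  # more below a higher bar
        _, rt_frac = table.columns["rt"]
        assert np.all(np.diff(rt_frac) <= 0)  # fewer slower at slower bars

    def test_tabulated_threshold_returns_tabulated_fraction(self):
        table = reference_table()
        assert table.lookup("n_correct", 45) == (0.371, False)
        assert table.lookup("hits", 24) == (0.521, False)

    def test_rt_09_gives_475_percent_slower(self):
        report = individual_percentile(make_score(25, 25, 0.9),
                                       reference_table())
        assert report["rt"].fraction == pytest.approx(0.475)

    def test_interpolated_value_lies_between_bracketing_entries(self):
        table = reference_table()
        mid = table.lookup("rt", 0.95)[0]
        lo, hi = table.lookup("rt", 1.0)[0], table.lookup("rt", 0.9)[0]
        assert lo < mid < hi

    def test_out_of_range_value_clamped_and_flagged(self):
        frac, clamped = reference_table().lookup("rt", 2.5)
        assert clamped and frac == 0.0

    def test_table_rt_column_matches_survival_formula(self):
        """The embedded RT column agrees with the closed-form survival
        percentile at every tabulated point (within rounding)."""
        thresholds, fractions = reference_table().columns["rt"]
        model = crtlab.survival_percentile(thresholds)
        # 0.5 s row is tabulated as 100.00%; the formula gives 99.97%
        assert np.max(np.abs(model - fractions)) < 5e-4


class TestConditionalCurve:
    def test_identical_scores_give_flat_curve(self):
        scores = [make_score(22, 23, 0.9)] * 8
        curve = conditional_curve(scores, by="hits", of="rt")
        assert list(curve.strata) == [22]
        assert curve.means[0] == pytest.approx(0.9)
        assert curve.counts[0] == 8

    def test_matches_group_by_mean_oracle(self):
        rng = random.Random(5)
        scores = [make_score(rng.choice([20, 22, 24]), rng.randint(15, 25),
                             round(rng.uniform(0.6, 1.4), 3))
                  for _ in range(12)]
        curve = conditional_curve(scores, by="hits", of="rt")
        for h, mean in zip(curve.strata, curve.means):
            expected = np.mean([s.mean_hit_rt for s in scores if s.hits == h])
            assert mean == pytest.approx(expected)

    def test_rt_binning_coarsens(self):
        scores = [make_score(20, 20, rt) for rt in (0.901, 0.909, 0.952)]
        curve = conditional_curve(scores, by="rt", of="hits", rt_bin_width=0.05)
        assert list(curve.strata) == [0.9, 0.95]
        assert list(curve.counts) == [2, 1]

    def test_sparse_strata_flagged_not_dropped(self):
        scores = [make_score(20, 20, 0.9)] * 6 + [make_score(15, 20, 1.2)]
        curve = conditional_curve(scores, by="hits", of="rt", min_stratum=5)
        assert list(curve.sparse) == [True, False]

    def test_unknown_variable_rejected(self):
        with pytest.raises(ValidationError):
            conditional_curve([make_score()], by="speed", of="rt")

    def test_conditional_means_stay_in_observed_range(self, calibrated_cohort):
        _, _, scores = calibrated_cohort
        curve = conditional_curve(scores[:2000], by="hits", of="rt")
        rts = [s.mean_hit_rt for s in scores[:2000] if s.mean_hit_rt is not None]
        assert curve.means.min() >= min(rts)
        assert curve.means.max() <= max(rts)


class TestCorrelationReport:
    def test_perfectly_linear_pair(self):
        scores = [make_score(h, h - 3, 0.9) for h in range(15, 25)]
        rep = correlation_report(scores, [("hits", "crs")],
                                 subset_policy=None)[0]
        assert rep.r_squared == pytest.approx(1.0)

    def test_matches_textbook_formula_oracle(self):
        rng = random.Random(8)
        scores = [make_score(rng.randint(10, 25), rng.randint(10, 25),
                             round(rng.uniform(0.6, 1.4), 3))
                  for _ in range(10)]
        rep = correlation_report(scores, [("rt", "hits")],
                                 subset_policy=None)[0]
        x = np.array([s.mean_hit_rt for s in scores])
        y = np.array([s.hits for s in scores])
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        expected = sxy ** 2 / (((x - x.mean()) ** 2).sum()
                               * ((y - y.mean()) ** 2).sum())
        assert rep.r_squared == pytest.approx(expected)

    def test_zero_variance_reported_undefined(self):
        scores = [make_score(20, 20, 0.9)] * 5
        rep = correlation_report(scores, [("hits", "crs")],
                                 subset_policy=None)[0]
        assert rep.undefined and rep.r_squared is None

    def test_requires_three_scores(self):
        with pytest.raises(ValidationError):
            correlation_report([make_score()] * 2, [("hits", "crs")])
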