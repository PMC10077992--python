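"""Tests of the correlation-driven data reduction and cleaning pipeline."""

import numpy as np
import pandas as pd
import pytest

from ddpsa import (
    AggregationPlan,
    PNSDMatrix,
    RawPNSD,
    WindSeries,
    apply_bin_aggregation,
    apply_hour_aggregation,
    impute_covariates_mean,
    plan_bin_aggregation,
    plan_hour_aggregation,
    replace_zeros,
)


def make_raw(values, start="2019-01-25", freq="h", bins=None, mask=None):
    values = np.asarray(values, dtype=float)
    P, T = values.shape
    bins = np.arange(1, P + 1) * 10.0 if bins is None else np.asarray(bins)
    return RawPNSD(times=pd.date_range(start, periods=T, freq=freq),
                   bin_labels=bins, values=values, missing_mask=mask)


class TestBinPlanning:
    def test_identical_series_form_one_group(self):
        base = np.linspace(1, 50, 500)
        raw = make_raw(np.tile(base, (4, 1)))
        plan = plan_bin_aggregation(raw, tau=0.97)
        assert plan.bin_groups == [[0, 1, 2, 3]]

    def test_independent_noise_stays_singleton(self):
        rng = np.random.default_rng(123)
        vals = rng.lognormal(0, 1, size=(4, 500))
        # verify the construction: all pairwise correlations well below tau
        C = np.corrcoef(vals)
        assert np.all(C[np.triu_indices(4, 1)] < 0.9)
        plan = plan_bin_aggregation(make_raw(vals), tau=0.97)
        assert plan.bin_groups == [[0], [1], [2], [3]]

    def test_anchor_correlation_splits_where_it_drops(self):
        rng = np.random.default_rng(5)
        b0 = rng.lognormal(2, 1, size=800)
        b1 = b0 * np.exp(rng.normal(0, 0.02, size=800))      # corr ~0.999
        b2 = rng.lognormal(2, 1, size=800)                   # independent
        assert np.corrcoef(b0, b1)[0, 1] > 0.97
        assert np.corrcoef(b0, b2)[0, 1] < 0.97
        plan = plan_bin_aggregation(make_raw(np.vstack([b0, b1, b2])), tau=0.97)
        assert plan.bin_groups == [[0, 1], [2]]

    def test_too_few_joint_observations_is_an_error(self):
        vals = np.ones((2, 4))
        mask = np.array([[False, False, True, True],
                         [True, True, False, False]])
        with pytest.raises(ValueError, match="fewer than 2"):
            plan_bin_aggregation(make_raw(vals, mask=mask), tau=0.9)

    def test_replanning_aggregated_output_is_idempotent(self):
        rng = np.random.default_rng(5)
        b0 = rng.lognormal(2, 1, size=800)
        b1 = b0 * np.exp(rng.normal(0, 0.02, size=800))
        b2 = rng.lognormal(2, 1, size=800)
        raw = make_raw(np.vstack([b0, b1, b2]))
        plan = plan_bin_aggregation(raw, tau=0.97)
        agg = apply_bin_aggregation(raw, plan)
        replan = plan_bin_aggregation(agg, tau=0.97)
        assert replan.bin_groups == [[0], [1]]


class TestBinApplication:
    def test_sums_within_groups(self):
        raw = make_raw([[1, 2], [3, 4], [5, 6]])
        plan = AggregationPlan(tau=0.9, bin_groups=[[0, 1], [2]])
        agg = apply_bin_aggregation(raw, plan)
        np.testing.assert_allclose(agg.values, [[4, 6], [5, 6]])
        assert agg.bin_ranges == [(10.0, 20.0), (30.0, 30.0)]

    def test_all_singletons_is_identity(self):
        raw = make_raw([[1, 2], [3, 4]])
        plan = AggregationPlan(tau=0.9, bin_groups=[[0], [1]])
        np.testing.assert_allclose(apply_bin_aggregation(raw, plan).values,
                                   raw.values)

    def test_single_group_gives_column_sums(self):
        raw = make_raw([[1, 2], [3, 4], [5, 6]])
        plan = AggregationPlan(tau=0.9, bin_groups=[[0, 1, 2]])
        np.testing.assert_allclose(apply_bin_aggregation(raw, plan).values,
                                   [[9, 12]])

    def test_total_particle_count_is_conserved(self):
        rng = np.random.default_rng(9)
        raw = make_raw(rng.lognormal(0, 1, size=(6, 40)))
        plan = AggregationPlan(tau=0.9, bin_groups=[[0, 1], [2, 3, 4], [5]])
        agg = apply_bin_aggregation(raw, plan)
        np.testing.assert_allclose(agg.values.sum(axis=0), raw.values.sum(axis=0))

    def test_representative_label_is_geometric_mean(self):
        raw = make_raw([[1, 2], [3, 4]], bins=[10.0, 40.0])
        plan = AggregationPlan(tau=0.9, bin_groups=[[0, 1]])
        agg = apply_bin_aggregation(raw, plan)
        assert agg.bin_labels[0] == pytest.approx(20.0)


def hourly_raw_from_day_pattern(day_values, n_days, noise=0.0, seed=0, n_bins=1):
    """Repeat a 24-hour pattern across days with multiplicative daily level."""
    rng = np.random.default_rng(seed)
    day_values = np.asarray(day_values, dtype=float)
    rows = []
    for _ in range(n_bins):
        cols = []
        for _d in range(n_days):
            level = rng.lognormal(0, 1)
            cols.append(level * day_values * np.exp(noise * rng.standard_normal(24)))
        rows.append(np.concatenate(cols))
    return make_raw(np.vstack(rows))


class TestHourPlanning:
    def test_identical_hours_merge_into_one_group(self):
        raw = hourly_raw_from_day_pattern(np.ones(24), n_days=50)
        plan = plan_hour_aggregation(raw, tau=0.97)
        assert plan.hour_groups == [list(range(24))]

    def test_two_regimes_split_into_two_groups(self):
        rng = np.random.default_rng(11)
        n_days = 100
        a = rng.lognormal(0, 1, size=n_days)
        b = rng.lognormal(0, 1, size=n_days)
        vals = np.empty((1, n_days * 24))
        for d in range(n_days):
            vals[0, d * 24:d * 24 + 12] = a[d] * np.exp(
                0.01 * rng.standard_normal(12))
            vals[0, d * 24 + 12:(d + 1) * 24] = b[d] * np.exp(
                0.01 * rng.standard_normal(12))
        assert abs(np.corrcoef(a, b)[0, 1]) < 0.5   # regimes really independent
        plan = plan_hour_aggregation(make_raw(vals), tau=0.97)
        assert plan.hour_groups == [list(range(12)), list(range(12, 24))]

    def test_unattainable_tau_gives_singletons(self):
        raw = hourly_raw_from_day_pattern(np.ones(24), n_days=10)
        plan = plan_hour_aggregation(raw, tau=1.01)
        assert plan.hour_groups == [[h] for h in range(24)]

    def test_needs_at_least_two_days(self):
        raw = make_raw(np.ones((2, 20)))
        with pytest.raises(ValueError, match="2 days"):
            plan_hour_aggregation(raw, tau=0.97)

    def test_min_over_bins_is_more_conservative_than_pooled(self):
        # one noisy bin blocks the merge under 'min' but not necessarily pooled
        rng = np.random.default_rng(3)
        smooth = hourly_raw_from_day_pattern(np.ones(24), n_days=80,
                                             noise=0.001, seed=1)
        noisy = hourly_raw_from_day_pattern(np.ones(24), n_days=80,
                                            noise=1.0, seed=2)
        raw = make_raw(np.vstack([smooth.values, noisy.values]))
        plan_min = plan_hour_aggregation(raw, tau=0.97, method="min")
        n_groups_min = len(plan_min.hour_groups)
        plan_pooled = plan_hour_aggregation(raw, tau=0.97, method="pooled")
        assert n_groups_min >= len(plan_pooled.hour_groups)


class TestHourApplication:
    def test_averages_within_blocks(self):
        vals = np.arange(1, 25, dtype=float)[None, :]
        raw = make_raw(vals)
        plan = AggregationPlan(tau=0.9, hour_groups=[list(range(6)),
                                                     list(range(6, 24))])
        m = apply_hour_aggregation(raw, plan)
        np.testing.assert_allclose(m.values[0], [3.5, 15.5])
        np.testing.assert_array_equal(m.block_labels, [0, 1])

    def test_all_singleton_plan_keeps_hourly_data(self):
        raw = hourly_raw_from_day_pattern(np.arange(1.0, 25.0), n_days=2)
        plan = AggregationPlan(tau=0.9, hour_groups=[[h] for h in range(24)])
        m = apply_hour_aggregation(raw, plan)
        np.testing.assert_allclose(m.values, raw.values)

    def test_fully_missing_day_stays_missing(self):
        vals = np.ones((2, 48))
        mask = np.zeros((2, 48), dtype=bool)
        mask[:, :24] = True
        raw = make_raw(vals, mask=mask)
        plan = AggregationPlan(tau=0.9, hour_groups=[list(range(12)),
                                                     list(range(12, 24))])
        m = apply_hour_aggregation(raw, plan)
        assert m.missing_mask[:, :2].all()
        assert not m.missing_mask[:, 2:].any()

    def test_partial_block_averages_observed_hours_only(self):
        vals = np.array([[1.0, 2.0, 3.0, 4.0] + [0.0] * 20])
        mask = np.zeros((1, 24), dtype=bool)
        mask[0, 1] = True
        raw = make_raw(vals, mask=mask)
        plan = AggregationPlan(tau=0.9, hour_groups=[[0, 1, 2, 3],
                                                     list(range(4, 24))])
        m = apply_hour_aggregation(raw, plan)
        assert m.values[0, 0] == pytest.approx((1 + 3 + 4) / 3)

    def test_group_size_weighted_means_preserve_daily_mean(self):
        rng = np.random.default_rng(21)
        raw = make_raw(rng.lognormal(0, 1, size=(3, 24)))
        plan = AggregationPlan(tau=0.9, hour_groups=[[0, 1, 2], list(range(3, 10)),
                                                     list(range(10, 24))])
        m = apply_hour_aggregation(raw, plan)
        sizes = np.array([3, 7, 14])
        np.testing.assert_allclose((m.values * sizes).sum(axis=1) / 24,
                                   raw.values.mean(axis=1))


class TestReplaceZeros:
    def test_zero_becomes_half_minimum_nonzero(self):
        m = PNSDMatrix(times=pd.date_range("2019-01-25", periods=3, freq="3h"),
                       bin_labels=np.array([10.0]),
                       values=np.array([[0.0, 2.0, 4.0]]))
        out, n = replace_zeros(m)
        np.testing.assert_allclose(out.values, [[1.0, 2.0, 4.0]])
        assert n == 1

    def test_no_zeros_is_identity(self):
        m = PNSDMatrix(times=pd.date_range("2019-01-25", periods=2, freq="3h"),
                       bin_labels=np.array([10.0]), values=np.array([[5.0, 2.0]]))
        out, n = replace_zeros(m)
        assert n == 0
        np.testing.assert_array_equal(out.values, m.values)

    def test_minima_are_per_bin(self):
        m = PNSDMatrix(times=pd.date_range("2019-01-25", periods=2, freq="3h"),
                       bin_labels=np.array([10.0, 20.0]),
                       values=np.array([[0.0, 10.0], [5.0, 0.0]]))
        out, n = replace_zeros(m)
        np.testing.assert_allclose(out.values, [[5.0, 10.0], [5.0, 2.5]])
        assert n == 2

    def test_never_decreases_and_keeps_nonzero_entries(self):
        rng = np.random.default_rng(2)
        vals = rng.lognormal(0, 1, size=(4, 30))
        vals[vals < 0.4] = 0.0
        m = PNSDMatrix(times=pd.date_range("2019-01-25", periods=30, freq="3h"),
                       bin_labels=np.arange(1, 5) * 10.0, values=vals)
        out, _ = replace_zeros(m)
        assert np.all(out.values >= m.values)
        nz = m.values > 0
        np.testing.assert_array_equal(out.values[nz], m.values[nz])

    def test_all_zero_bin_is_an_error(self):
        m = PNSDMatrix(times=pd.date_range("2019-01-25", periods=2, freq="3h"),
                       bin_labels=np.array([10.0]), values=np.zeros((1, 2)))
        with pytest.raises(ValueError, match="10"):
            replace_zeros(m)


class TestWindImputation:
    def test_speed_mean_imputation(self):
        w = WindSeries(ws=np.array([2.0, np.nan, 4.0]),
                       wd=np.array([0.0, 10.0, 20.0]))
        out, (n_ws, n_wd) = impute_covariates_mean(w, warn_above=0.5)
        np.testing.assert_allclose(out.ws, [2.0, 3.0, 4.0])
        assert (n_ws, n_wd) == (1, 0)

    def test_no_missing_is_identity(self):
        w = WindSeries(ws=np.array([1.0, 2.0]), wd=np.array([10.0, 20.0]))
        out, counts = impute_covariates_mean(w)
        assert counts == (0, 0)
        np.testing.assert_array_equal(out.ws, w.ws)

    def test_direction_uses_arithmetic_mean_by_default(self):
        w = WindSeries(ws=np.array([1.0, 1.0, 1.0]),
                       wd=np.array([350.0, np.nan, 10.0]))
        out, _ = impute_covariates_mean(w, warn_above=0.5)
        assert out.wd[1] == pytest.approx(180.0)

    def test_circular_option_respects_wraparound(self):
        w = WindSeries(ws=np.array([1.0, 1.0, 1.0]),
                       wd=np.array([350.0, np.nan, 10.0]))
        out, _ = impute_covariates_mean(w, circular_direction=True,
                                        warn_above=0.5)
        assert out.wd[1] == pytest.approx(0.0, abs=1e-8)

    def test_all_missing_is_an_error(self):
        w = WindSeries(ws=np.array([np.nan, np.nan]), wd=np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            impute_covariates_mean(w)

    def test_warns_when_missingness_is_large(self):
        w = WindSeries(ws=np.array([1.0, np.nan, np.nan]),
                       wd=np.array([10.0, 20.0, 30.0]))
        with pytest.warns(UserWarning, match="missing"):
            impute_covariates_mean(w)
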