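"""Threshold-exceedance summaries and population correlation."""

import numpy as np
import pandas as pd
import pytest

from hydricniche import microclim as mc
from hydricniche.errors import (
    EmptyWindowError,
    InsufficientDataError,
    InvalidInputError,
    JoinError,
)


def make_series(psi_by_day, temp_by_day, start="2019-07-01", site_id="s1"):
    """30-min series with constant per-day values."""
    psi, temp, stamps = [], [], []
    for d, (p, t) in enumerate(zip(psi_by_day, temp_by_day)):
        day = pd.Timestamp(start) + pd.Timedelta(days=d)
        for k in range(48):
            stamps.append(day + pd.Timedelta(minutes=30 * k))
            psi.append(p)
            temp.append(t)
    return mc.SensorSeries.from_arrays(site_id, "riparian", stamps, psi, temp)


THRESHOLDS = dict(at=-50.0, t_opt=23.3, ct_max=29.6)


def summarize(series, **over):
    kw = dict(THRESHOLDS)
    kw.update(over)
    return mc.summarize_site_year(
        series, kw["at"], kw["t_opt"], kw["ct_max"], ("2019-07-01", "2020-07-01")
    )


class TestSummarize:
    def test_wet_series_has_no_at_exceedance(self):
        s = make_series([-10.0] * 20, [15.0] * 20)
        assert summarize(s).days_exceeding_at == 0

    def test_hand_counted_dry_days(self):
        # psi below -50 kPa on days 3-5 (0-based days 2..4) only
        psi = [-10, -20, -60, -70, -55, -30, -10, -5, -5, -5]
        s = make_series(psi, [15.0] * 10)
        out = summarize(s)
        assert out.days_exceeding_at == 3
        assert out.n_days_observed == 10
        assert out.prop_at == pytest.approx(0.3)

    def test_constant_hot_series(self):
        s = make_series([-10.0] * 10, [30.0] * 10)
        out = summarize(s)
        assert out.days_exceeding_ctmax == 10
        assert out.wt == pytest.approx(-0.4)
        assert out.t_hab_max == pytest.approx(30.0)

    def test_strict_inequality_at_threshold(self):
        # readings exactly at the thresholds do not count
        s = make_series([-50.0] * 5, [23.3] * 5)
        out = summarize(s)
        assert out.days_exceeding_at == 0
        assert out.days_exceeding_topt == 0

    def test_split_additivity_at_day_boundaries(self):
        rng = np.random.default_rng(7)
        psi = (-10 - 80 * rng.random(30)).tolist()
        temp = (10 + 22 * rng.random(30)).tolist()
        s = make_series(psi, temp)
        whole = summarize(s)
        for split_day in (1, 7, 13, 29):
            cut = pd.Timestamp("2019-07-01") + pd.Timedelta(days=split_day)
            left = mc.SensorSeries("s1", "riparian", s.data[s.data.index < cut])
            right = mc.SensorSeries("s1", "riparian", s.data[s.data.index >= cut])
            a, b = summarize(left), summarize(right)
            assert a.days_exceeding_at + b.days_exceeding_at == whole.days_exceeding_at
            assert (
                a.days_exceeding_topt + b.days_exceeding_topt
                == whole.days_exceeding_topt
            )

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(11)
        psi = (-10 - 80 * rng.random(30)).tolist()
        temp = (10 + 22 * rng.random(30)).tolist()
        s = make_series(psi, temp)
        at_days = [summarize(s, at=a).days_exceeding_at for a in (-30, -50, -70, -90)]
        assert all(x >= y for x, y in zip(at_days, at_days[1:]))
        topt_days = [
            summarize(s, t_opt=t).days_exceeding_topt for t in (28, 25, 22, 19)
        ]
        assert all(x <= y for x, y in zip(topt_days, topt_days[1:]))

    def test_removing_readings_never_increases_counts(self):
        rng = np.random.default_rng(23)
        psi = (-10 - 80 * rng.random(30)).tolist()
        s = make_series(psi, [15.0] * 30)
        full = summarize(s).days_exceeding_at
        data = s.data.copy()
        drop = rng.choice(len(data), size=len(data) // 3, replace=False)
        data.iloc[drop, data.columns.get_loc("psi")] = np.nan
        masked = summarize(mc.SensorSeries("s1", "riparian", data)).days_exceeding_at
        assert masked <= full

    def test_days_without_readings_drop_from_denominator(self):
        s = make_series([-60, -60, -10], [15, 15, 15])
        data = s.data.copy()
        day2 = data.index.normalize() == pd.Timestamp("2019-07-02")
        data.loc[day2, ["psi", "temp"]] = np.nan
        out = summarize(mc.SensorSeries("s1", "riparian", data))
        assert out.n_days_observed == 2
        assert out.days_exceeding_at == 1

    def test_empty_window_raises(self):
        s = make_series([-10.0] * 5, [15.0] * 5, start="2010-01-01")
        with pytest.raises(EmptyWindowError):
            summarize(s)

    def test_positive_psi_rejected(self):
        with pytest.raises(InvalidInputError):
            make_series([5.0], [15.0])


def _summary(site_id, days):
    return mc.SiteYearSummary(
        site_id=site_id, year_window="2019-20",
        days_exceeding_at=days, days_exceeding_topt=0, days_exceeding_ctmax=0,
        prop_at=0.0, prop_topt=0.0, prop_ctmax=0.0,
        t_hab_max=20.0, wt=9.6, n_days_observed=365,
    )


class TestPopulationCorrelation:
    # hand-ranked fixture with ties; rs computed by brute-force rank
    # arithmetic (average ranks, Pearson on ranks, two-sided t p-value)
    DAYS = [30, 25, 25, 18, 12, 9, 4, 0]
    MALES = [3, 5, 7, 7, 10, 12, 15, 15]

    def _inputs(self):
        summaries = [_summary(f"s{i}", d) for i, d in enumerate(self.DAYS)]
        pops = [
            mc.PopulationEstimate(f"s{i}", males)
            for i, males in enumerate(self.MALES)
        ]
        return summaries, pops

    def test_hand_ranked_fixture(self):
        summaries, pops = self._inputs()
        res = mc.exceedance_population_correlation(summaries, pops)
        assert res.rs == pytest.approx(-0.9757754965005868, rel=1e-9)
        assert res.p_value == pytest.approx(3.489639884612271e-05, rel=1e-6)
        assert res.n == 8

    def test_perfectly_monotone_pairs(self):
        summaries = [_summary(f"s{i}", 10 * i) for i in range(5)]
        pops = [mc.PopulationEstimate(f"s{i}", 50 - i) for i in range(5)]
        assert mc.exceedance_population_correlation(summaries, pops).rs == pytest.approx(-1.0)

    def test_order_invariance(self):
        summaries, pops = self._inputs()
        res1 = mc.exceedance_population_correlation(summaries, pops)
        res2 = mc.exceedance_population_correlation(summaries[::-1], pops[::-1])
        assert (res1.rs, res1.p_value) == (res2.rs, res2.p_value)

    def test_unmatched_sites_listed(self):
        summaries, pops = self._inputs()
        with pytest.raises(JoinError) as err:
            mc.exceedance_population_correlation(summaries[:-1], pops)
        assert "s7" in str(err.value)

    def test_too_few_pairs(self):
        summaries = [_summary(f"s{i}", i) for i in range(3)]
        pops = [mc.PopulationEstimate(f"s{i}", i) for i in range(3)]
        with pytest.raises(InsufficientDataError):
            mc.exceedance_population_correlation(summaries, pops)

    def test_population_doubles_calling_males(self):
        assert mc.PopulationEstimate("s", 17).estimated_size == 34


class TestMeanExceedance:
    def test_single_site(self):
        assert mc.mean_exceedance_days([_summary("a", 10)]) == 10.0

    def test_three_sites(self):
        sums = [_summary(s, d) for s, d in zip("abc", (0, 10, 20))]
        assert mc.mean_exceedance_days(sums) == pytest.approx(10.0)

    def test_eight_site_fixture(self):
        days = [30, 25, 25, 18, 12, 9, 4, 0]
        sums = [_summary(f"s{i}", d) for i, d in enumerate(days)]
        assert mc.mean_exceedance_days(sums) == pytest.approx(sum(days) / 8.0)

    def test_empty_rejected(self):
        with pytest.raises(InsufficientDataError):
            mc.mean_exceedance_days([])
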