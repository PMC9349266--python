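"""ITT metric arithmetic, censoring, and group statistics."""

import numpy as np
import pytest

from captrans.itt_analysis import (
    ITT_SAMPLE_TIMES,
    BGSeries,
    auc_bg,
    compare_groups,
    compute_metrics,
    cumulative_incidence,
    max_drop,
    normalize_bg,
    thickness_efficacy_correlation,
    time_to_drop,
)


def _series(glucose, times=None, **kw):
    times = np.asarray(times if times is not None else ITT_SAMPLE_TIMES[: len(glucose)])
    defaults = dict(animal_id="a0", group="ctrl", timepoint_week=0.0)
    defaults.update(kw)
    return BGSeries(times=times, glucose=np.asarray(glucose, float), **defaults)


class TestSeriesValidation:
    def test_requires_time_zero_start(self):
        with pytest.raises(ValueError):
            _series([150, 120], times=[5, 20])

    def test_requires_increasing_times(self):
        with pytest.raises(ValueError):
            _series([150, 120, 110], times=[0, 15, 10])

    def test_requires_positive_glucose(self):
        with pytest.raises(ValueError):
            _series([150, 0.0], times=[0, 15])


class TestNormalization:
    @pytest.mark.parametrize(
        "glucose, expected",
        [([150, 75], [100, 50]),
         ([120, 120, 120], [100, 100, 100]),
         ([120, 90, 60], [100, 75, 50])],
    )
    def test_percent_of_baseline(self, glucose, expected):
        s = _series(glucose)
        assert normalize_bg(s) == pytest.approx(expected)


class TestMaxDrop:
    def test_deep_drop(self):
        s = _series([150, 100, 45, 90])
        assert max_drop(s) == pytest.approx(70.0)

    def test_monotone_rise_gives_zero(self):
        s = _series([100, 110, 130])
        assert max_drop(s) == 0.0

    def test_worked_percent_series(self):
        s = _series([100, 80, 60, 70])
        assert max_drop(s) == pytest.approx(40.0)


class TestTimeToDrop:
    def test_interpolated_worked_example(self):
        # percent series 100, 80, 60 at 0, 15, 30 min crosses 70% at 22.5 min
        s = _series([100, 80, 60], times=[0, 15, 30])
        t, censored = time_to_drop(s, 30.0)
        assert not censored
        assert t == pytest.approx(22.5)

    def test_crossing_at_sample(self):
        s = _series([100, 70, 50], times=[0, 15, 30])
        t, censored = time_to_drop(s, 30.0)
        assert (t, censored) == (15.0, False)

    def test_censored_when_never_crossed(self):
        s = _series([100, 90, 85, 80, 80, 80, 80, 80])
        t, censored = time_to_drop(s, 30.0)
        assert censored and t == 120.0

    def test_monotone_in_required_drop(self):
        s = _series([150, 120, 90, 60, 75, 90, 100, 110])
        times = [time_to_drop(s, d)[0] for d in (10, 20, 30, 40, 50)]
        assert all(b >= a for a, b in zip(times, times[1:]))


class TestAUC:
    def test_constant_baseline(self):
        s = _series([100] * 8)
        assert auc_bg(s) == pytest.approx(12000.0)

    def test_linear_decline_to_zero(self):
        # percent falls linearly 100 -> ~0 over [0, 120]
        s = _series([100, 1e-6], times=[0, 120])
        assert auc_bg(s) == pytest.approx(6000.0, rel=1e-4)

    def test_single_trapezoid(self):
        s = _series([100, 50], times=[0, 120])
        assert auc_bg(s) == pytest.approx(9000.0)

    def test_short_series_warns(self):
        s = _series([100, 50], times=[0, 60])
        with pytest.warns(UserWarning, match="available span"):
            auc_bg(s)


class TestCumulativeIncidence:
    def test_all_events_reach_one(self):
        f = cumulative_incidence([(20.0, False), (40.0, False), (60.0, False)])
        assert f(120.0) == pytest.approx(1.0)

    def test_all_censored_stays_zero(self):
        f = cumulative_incidence([(120.0, True)] * 4)
        assert np.all(f(np.linspace(0, 120, 25)) == 0.0)

    def test_mixed_enumeration(self):
        f = cumulative_incidence([(20.0, False), (40.0, False), (120.0, True)])
        assert f(19.9) == pytest.approx(0.0)
        assert f(20.0) == pytest.approx(1 / 3)
        assert f(40.0) == pytest.approx(2 / 3)
        assert f(120.0) == pytest.approx(2 / 3)

    def test_non_decreasing_bounded(self):
        rng = np.random.default_rng(7)
        res = [(float(t), bool(c)) for t, c in
               zip(rng.uniform(0, 120, 20), rng.random(20) < 0.3)]
        vals = cumulative_incidence(res)(np.linspace(0, 120, 200))
        assert np.all(np.diff(vals) >= 0) and vals.max() <= 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cumulative_incidence([])


class TestCompareGroups:
    def test_identical_groups_not_significant(self):
        vals = np.array([50.0, 55.0, 60.0, 52.0])
        rep = compare_groups({"a": vals, "b": vals.copy()}, tails="two")
        c = rep.comparisons[0]
        assert c.t_stat == pytest.approx(0.0)
        assert not c.significant

    def test_bonferroni_threshold(self):
        groups = {"a": [1.0, 2.0, 3.0], "b": [1.5, 2.5, 4.0]}
        rep = compare_groups(groups, alpha=0.05, m_comparisons=5)
        assert rep.threshold == pytest.approx(0.01)

    def test_programmed_shift_detected(self):
        # 3-SD mean shift at n=10 per group: significant at alpha/5 in >= 95% of seeds
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            a = rng.normal(0.0, 1.0, 10)
            b = rng.normal(3.0, 1.0, 10)
            rep = compare_groups({"b": b, "a": a}, tails="one", direction="greater",
                                 m_comparisons=5)
            hits += rep.comparisons[0].significant
        assert hits >= 0.95 * n_seeds

    def test_zero_variance_group_skipped(self):
        rep = compare_groups({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
        assert rep.comparisons[0].skipped

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups({"a": [1.0], "b": [1.0, 2.0]})


class TestThicknessEfficacyCorrelation:
    def test_descending_line(self):
        x = np.array([0.1, 0.2, 0.3, 0.4])
        assert thickness_efficacy_correlation(x, 80 - 100 * x) == pytest.approx(-1.0)

    def test_ascending_line(self):
        x = np.array([0.1, 0.2, 0.3, 0.4])
        assert thickness_efficacy_correlation(x, 10 + 50 * x) == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            thickness_efficacy_correlation([0.1, 0.1, 0.1], [1.0, 2.0, 3.0])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            thickness_efficacy_correlation([0.1, 0.2], [1.0, 2.0])


class TestComputeMetrics:
    def test_bundles_all_metrics(self):
        s = _series([150, 120, 90, 75, 80, 90, 100, 110])
        m = compute_metrics(s, drop_pct=30.0)
        assert m.max_drop_pct == pytest.approx(50.0)
        assert not m.censored
        assert m.auc == pytest.approx(auc_bg(s))
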