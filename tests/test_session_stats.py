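"""Task-level SPR statistics, paired t-test, stress percentages and the
published-table fixtures."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from drivestress import session_stats as ss
from drivestress.core import EventSchedule, TrackEvent


@pytest.fixture()
def schedule():
    # tasks [60, 120) and [240, 300) s on a 600 s track at 120 km/h
    return EventSchedule(20.0, 120.0, [TrackEvent("a", 2.0, 4.0), TrackEvent("b", 8.0, 10.0)])


class TestLocalRms:
    def test_constant_signal(self, channel_factory):
        ch = channel_factory(np.full(500, -3.0))
        np.testing.assert_allclose(ss.local_rms(ch, 2.0).samples, 3.0)

    def test_sine_long_window(self, channel_factory):
        t = np.arange(50 * 60) / 50.0
        ch = channel_factory(np.sin(2 * np.pi * 2.0 * t))
        rms = ss.local_rms(ch, 10.0).samples
        interior = rms[500 : -500]
        np.testing.assert_allclose(interior, 1 / np.sqrt(2), atol=0.01)

    def test_matches_brute_force(self, channel_factory):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(200)
        ch = channel_factory(x, fs=10.0)
        win = 30  # 3 s at 10 Sa/s
        got = ss.local_rms(ch, 3.0).samples
        half_lo, half_hi = (win - 1) // 2, win - 1 - (win - 1) // 2
        for i in (0, 50, 120, 199):
            a, b = max(i - half_hi, 0), min(i + half_lo + 1, x.size)
            assert got[i] == pytest.approx(np.sqrt(np.mean(x[a:b] ** 2)), rel=1e-9)


class TestTaskNormalizedRms:
    def test_stationary_signal_near_one(self, channel_factory, schedule):
        rng = np.random.default_rng(1)
        ch = channel_factory(rng.standard_normal(600 * 50))
        vals = ss.task_normalized_rms(ch, schedule)
        for v in vals.values():
            assert v == pytest.approx(1.0, abs=0.05)

    def test_energy_concentrated_in_one_task(self, channel_factory, schedule):
        fs = 50.0
        x = np.zeros(int(600 * fs))
        x[int(60 * fs) : int(120 * fs)] = 1.0
        vals = ss.task_normalized_rms(channel_factory(x), schedule)
        assert vals["a"] > 1.0
        assert vals["b"] == pytest.approx(0.0, abs=1e-12)

    def test_brute_force_interval_oracle(self, channel_factory, schedule):
        rng = np.random.default_rng(2)
        fs = 50.0
        x = rng.standard_normal(int(600 * fs))
        vals = ss.task_normalized_rms(channel_factory(x), schedule)
        whole = np.sqrt(np.mean(x**2))
        for name, a, b in schedule.task_intervals_s():
            seg = x[int(a * fs) : int(b * fs)]
            assert vals[name] == pytest.approx(np.sqrt(np.mean(seg**2)) / whole, rel=1e-12)

    def test_zero_signal_rejected(self, channel_factory, schedule):
        with pytest.raises(ValueError, match="zero whole-track RMS"):
            ss.task_normalized_rms(channel_factory(np.zeros(600 * 50) + 0.0), schedule)


class TestStdRatio:
    def test_stationary_near_one(self, channel_factory, schedule):
        rng = np.random.default_rng(3)
        ch = channel_factory(rng.standard_normal(600 * 50))
        assert ss.std_ratio(ch, schedule) == pytest.approx(1.0, abs=0.05)

    def test_doubled_task_amplitude(self, channel_factory, schedule):
        rng = np.random.default_rng(4)
        fs = 50.0
        x = rng.standard_normal(int(600 * fs))
        mask = schedule.in_task(np.arange(x.size) / fs)
        x[mask] *= 2.0
        assert ss.std_ratio(channel_factory(x), schedule) == pytest.approx(2.0, abs=0.1)

    def test_brute_force_concatenation_oracle(self, channel_factory, schedule):
        rng = np.random.default_rng(5)
        fs = 50.0
        x = rng.standard_normal(int(600 * fs))
        mask = schedule.in_task(np.arange(x.size) / fs)
        expected = np.std(x[mask]) / np.std(x[~mask])
        assert ss.std_ratio(channel_factory(x), schedule) == pytest.approx(expected, rel=1e-12)


class TestPairedTtest:
    def test_closed_form_example(self):
        res = ss.paired_ttest([1.0, 2.0, 3.0], [1.0, 3.0, 5.0])
        assert res["t"] == pytest.approx(-np.sqrt(3), rel=1e-3)
        assert res["df"] == 2
        assert res["p"] == pytest.approx(0.2254, abs=1e-3)

    def test_zero_variance_differences_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            ss.paired_ttest([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])

    def test_antisymmetry(self):
        rng = np.random.default_rng(6)
        a, b = rng.standard_normal(10), rng.standard_normal(10)
        r1, r2 = ss.paired_ttest(a, b), ss.paired_ttest(b, a)
        assert r1["t"] == pytest.approx(-r2["t"], rel=1e-12)
        assert r1["p"] == pytest.approx(r2["p"], rel=1e-12)

    def test_matches_textbook_formula_on_random_vectors(self):
        rng = np.random.default_rng(7)
        a, b = rng.standard_normal(12), rng.standard_normal(12) + 0.5
        d = a - b
        t = np.mean(d) / (np.std(d, ddof=1) / np.sqrt(d.size))
        p = 2 * sstats.t.sf(abs(t), d.size - 1)
        res = ss.paired_ttest(a, b)
        assert res["t"] == pytest.approx(t, rel=1e-12)
        assert res["p"] == pytest.approx(p, rel=1e-12)


class TestStressPercentages:
    def _timeline(self, labels, subject="s01", scenario="manual"):
        n = len(labels)
        return pd.DataFrame(
            {
                "subject_id": subject,
                "scenario": scenario,
                "t_start_s": np.arange(n) * 5.0,
                "t_end_s": np.arange(n) * 5.0 + 15.0,
                "relabeled_label": labels,
            }
        )

    def test_four_of_ten_is_forty_pct(self):
        tl = self._timeline([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        out = ss.stress_percentages(tl)
        assert out.loc[0, "stress_pct"] == pytest.approx(40.0)

    def test_all_positive_is_hundred_pct(self):
        out = ss.stress_percentages(self._timeline([1, 1, 1]))
        assert out.loc[0, "stress_pct"] == pytest.approx(100.0)

    def test_percentages_bounded(self):
        rng = np.random.default_rng(8)
        tl = self._timeline(rng.integers(0, 2, size=50).tolist())
        out = ss.stress_percentages(tl)
        assert ((out["stress_pct"] >= 0) & (out["stress_pct"] <= 100)).all()

    def test_empty_timeline_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ss.stress_percentages(pd.DataFrame())


class TestPublishedTables:
    def test_stress_table_shape(self):
        t = ss.load_stress_pct_table()
        assert len(t) == 26
        assert set(t["scenario"]) == {"manual", "autonomous"}

    def test_stress_row_means(self):
        means = ss.table_row_means(ss.load_stress_pct_table(), "stress_pct", ["scenario"])
        by = dict(zip(means["scenario"], means["mean"]))
        assert by["manual"] == pytest.approx(52.99, abs=0.01)
        assert by["autonomous"] == pytest.approx(38.34, abs=0.01)

    def test_hr_table_consistency_flags(self):
        t = ss.load_mean_hr_table()
        assert len(t) == 156  # 2 scenarios x 6 rows x 13 subjects
        bad = t[~t["consistent"]]
        # exactly one printed row disagrees with its per-subject entries
        assert set(zip(bad["scenario"], bad["row_label"])) == {("manual", "task 2")}

    def test_hr_row_means_on_consistent_rows(self):
        t = ss.load_mean_hr_table()
        means = ss.table_row_means(t, "hr_bpm", ["scenario", "row_label"])
        by = {(r.scenario, r.row_label): r.mean for r in means.itertuples()}
        assert by[("manual", "whole track")] == pytest.approx(83.09, abs=0.01)
        assert by[("autonomous", "whole track")] == pytest.approx(75.35, abs=0.01)
        assert by[("manual", "task 1")] == pytest.approx(86.13, abs=0.01)
        assert by[("autonomous", "task 1")] == pytest.approx(75.05, abs=0.01)


class TestBuildReport:
    def test_report_contains_published_means(self):
        tables = ss.build_report()
        pub = tables["published_stress_means"]
        assert set(pub["scenario"]) == {"manual", "autonomous"}
        hr = tables["published_hr_means"]
        assert len(hr) == 12

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ss.build_report(timelines=pd.DataFrame())
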