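"""Tests for windowed entropy series, threshold profile, and flagging."""

from datetime import datetime, timedelta

import numpy as np
import pytest

from visitropy import (
    ActivitySequence,
    EntropyConfig,
    RunConfig,
    daily_profile,
    detect,
    entropy_series,
    indoor_mobility,
    overlap_fraction,
    run_preset,
)
from visitropy.detection import EntropyWindow
from visitropy.encoding import encode_events
from visitropy.entropy import EntropyResult
from visitropy.oracle import entropy_oracle

D = datetime(2025, 1, 6)


def day_seq(codes, start=D):
    return ActivitySequence(start=start, resolution=1, codes=np.asarray(codes))


def make_window(start, value, length=60, shift=0):
    res = EntropyResult(value, "fuzzyen", 2, 1.0, 2.0, length)
    return EntropyWindow(start=start, length=length, shift=shift, result=res)


CFG = EntropyConfig(measure="fuzzyen", m=2, r=1.0, n=2.0)


class TestEntropySeries:
    def test_window_count(self):
        days = [day_seq([1] * 1440)]
        assert len(entropy_series(days, CFG, 60, 0)) == 24
        assert len(entropy_series(days, CFG, 120, 0)) == 12
        assert len(entropy_series(days, CFG, 15, 0)) == 96

    def test_shift_drops_trailing_partial(self):
        days = [day_seq([1] * 1440)]
        windows = entropy_series(days, CFG, 60, 30)
        assert len(windows) == 23
        assert windows[0].start == D + timedelta(minutes=30)

    def test_constant_day_all_zero(self):
        windows = entropy_series([day_seq([3] * 1440)], CFG, 60, 0)
        assert all(w.value == pytest.approx(0.0, abs=1e-12) for w in windows)

    def test_high_transition_hour_dominates(self):
        codes = np.ones(1440, dtype=int)
        hour = 10
        rng = np.random.default_rng(3)
        codes[hour * 60 : hour * 60 + 60] = rng.choice([1, 3, 5, 7, 9], size=60)
        windows = entropy_series([day_seq(codes)], CFG, 60, 0)
        values = [w.value for w in windows]
        assert np.argmax(values) == hour
        # per-window values agree with the brute-force oracle
        expected, _ = entropy_oracle(codes[hour * 60 : hour * 60 + 60], CFG)
        assert values[hour] == pytest.approx(expected.value, abs=1e-10)

    def test_window_too_short_raises(self):
        with pytest.raises(ValueError):
            entropy_series([day_seq([1] * 1440, D)], EntropyConfig(m=2), 3, 0)

    def test_undefined_propagates(self):
        # a ramp has no SampEn matches at r << code gap
        codes = np.arange(1440) % 700
        cfg = EntropyConfig(measure="sampen", m=2, r=0.1)
        windows = entropy_series([day_seq(codes)], cfg, 60, 0)
        assert any(w.value is None for w in windows)


class TestDailyProfile:
    def test_identical_days_zero_sd(self):
        w = [make_window(D + timedelta(days=d, hours=h), 0.5)
             for d in range(3) for h in range(24)]
        prof = daily_profile(w, k=1.0)
        for slot in range(0, 1440, 60):
            assert prof.stats[slot] == (0.5, 0.0)
            assert prof.threshold(slot) == 0.5

    def test_two_day_arithmetic(self):
        v = 0.2
        w = [make_window(D, v), make_window(D + timedelta(days=1), v + 2)]
        prof = daily_profile(w, k=1.0, clip_passes=0)
        mean, sd = prof.stats[0]
        assert mean == pytest.approx(v + 1)
        assert sd == pytest.approx(1.0)
        assert prof.threshold(0) == pytest.approx(v + 2)

    def test_matches_independent_mean_sd_oracle(self):
        rng = np.random.default_rng(9)
        values = rng.uniform(0, 1, size=(7, 24))
        w = [make_window(D + timedelta(days=d, hours=h), values[d, h])
             for d in range(7) for h in range(24)]
        prof = daily_profile(w, k=1.5, clip_passes=0)
        for h in range(24):
            col = values[:, h]
            mean, sd = prof.stats[h * 60]
            assert mean == pytest.approx(col.mean())
            assert sd == pytest.approx(col.std(ddof=0))

    def test_sigma_clip_unmasks_weaker_anomaly(self):
        # two anomalous days in one slot: plain stats hide the weaker one,
        # the clipped profile flags both
        vals = [0.05] * 5 + [0.5, 0.30]
        w = [make_window(D + timedelta(days=d), v) for d, v in enumerate(vals)]
        plain = daily_profile(w, k=1.0, clip_passes=0)
        clipped = daily_profile(w, k=1.0, clip_passes=1)
        assert 0.30 <= plain.threshold(0)
        assert clipped.threshold(0) < 0.30

    def test_undefined_values_excluded(self):
        w = [make_window(D + timedelta(days=d), 0.1 if d else None) for d in range(4)]
        prof = daily_profile(w, k=1.0)
        mean, sd = prof.stats[0]
        assert mean == pytest.approx(0.1)
        assert sd == pytest.approx(0.0, abs=1e-15)

    def test_single_day_sd_zero_with_warning(self, caplog):
        w = [make_window(D, 0.3)]
        with caplog.at_level("WARNING"):
            prof = daily_profile(w, k=1.0)
        assert prof.stats[0] == (pytest.approx(0.3), 0.0)
        assert any("SD recorded as 0" in rec.message for rec in caplog.records)


class TestDetect:
    def test_values_at_mean_never_flag(self):
        w = [make_window(D + timedelta(days=d, hours=h), 0.4)
             for d in range(3) for h in range(24)]
        prof = daily_profile(w, k=1.0)
        assert not any(f.flag for f in detect(w, prof))

    def test_undefined_never_flags(self):
        w = [make_window(D + timedelta(days=d), 0.1) for d in range(3)]
        w.append(make_window(D + timedelta(days=3), None))
        prof = daily_profile(w, k=1.0)
        flags = detect(w, prof)
        assert flags[-1].flag is False

    def test_slot_mismatch_raises(self):
        w = [make_window(D + timedelta(days=d), 0.1) for d in range(2)]
        prof = daily_profile(w, k=1.0)
        with pytest.raises(KeyError):
            detect([make_window(D + timedelta(hours=1), 0.1)], prof)

    def test_k_monotonicity(self):
        """Raising the SD multiplier never flags more windows."""
        rng = np.random.default_rng(21)
        w = [make_window(D + timedelta(days=d, hours=h), float(rng.uniform(0, 1)))
             for d in range(7) for h in range(24)]
        counts = []
        for k in (0.25, 0.5, 1.0, 2.0, 3.0):
            prof = daily_profile(w, k=k)
            counts.append(sum(f.flag for f in detect(w, prof)))
        assert counts == sorted(counts, reverse=True)


class TestOverlapFraction:
    def test_partial_overlap(self):
        v0 = D.replace(hour=9, minute=20)
        v1 = D.replace(hour=9, minute=40)
        assert overlap_fraction(v0, v1, D.replace(hour=9), 60) == pytest.approx(100 * 20 / 60)

    def test_full_cover_and_disjoint(self):
        assert overlap_fraction(D, D + timedelta(hours=2), D, 60) == 100.0
        assert overlap_fraction(D, D + timedelta(hours=1), D + timedelta(hours=2), 60) == 0.0

    def test_matches_minute_sweep_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            a, b = sorted(int(x) for x in rng.integers(0, 600, size=2))
            if a == b:
                continue
            ws = int(rng.integers(0, 540))
            frac = overlap_fraction(
                D + timedelta(minutes=a), D + timedelta(minutes=b),
                D + timedelta(minutes=ws), 60,
            )
            sweep = sum(1 for t in range(ws, ws + 60) if a <= t < b)
            assert frac == pytest.approx(100 * sweep / 60)


class TestIndoorMobility:
    def test_constant_is_zero(self):
        assert indoor_mobility(day_seq([7] * 120)) == 0

    def test_worked_example_hour(self, worked_example_events, canonical_map):
        seq = encode_events(worked_example_events, canonical_map, D.replace(hour=9), 60)
        assert indoor_mobility(seq) == 4

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            codes = rng.choice([1, 3, 5, 7, 9], size=int(rng.integers(2, 200)))
            expected = sum(int(codes[i] != codes[i - 1]) for i in range(1, len(codes)))
            assert indoor_mobility(day_seq(codes)) == expected


class TestDetectionQuality:
    """End-to-end qualitative behavior on seeded synthetic runs."""

    def test_visit_windows_separate_from_matched_slots(self):
        """Median entropy of visit-overlapping windows exceeds the median
        of same-slot windows from other days, for all three measures."""
        from visitropy.evaluation import label_windows
        from visitropy.pipeline import encode_days
        from visitropy.simulate import simulate

        run = simulate("datasetB", 2)
        cfg = RunConfig(preset="datasetB", seed=2)
        days = encode_days(run.events, cfg.room_code_map(), days=run.days)
        for measure in ("apen", "sampen", "fuzzyen"):
            windows = entropy_series(days, EntropyConfig(measure=measure, m=2, r=1.0), 60, 0)
            truth = label_windows(windows, run.truth, 30.0)
            visit_slots = {w.slot for w, t in zip(windows, truth) if t}
            visit_vals = [w.value for w, t in zip(windows, truth) if t and w.value is not None]
            other_vals = [
                w.value for w, t in zip(windows, truth)
                if not t and w.slot in visit_slots and w.value is not None
            ]
            assert np.median(visit_vals) > np.median(other_vals)

    @pytest.mark.parametrize("variant", [dict(window_len=15), dict(shift=30)])
    def test_precision_degrades_off_the_hour_grid(self, variant):
        """Shorter windows and shifted grids create partially covered
        windows and lose precision relative to the aligned 60-min grid."""
        seeds = range(6)
        def mean_precision(**kw):
            ps = []
            for s in seeds:
                m = run_preset(RunConfig(preset="datasetB", seed=s, **kw))["metrics"]
                ps.append(100.0 if m.precision is None else m.precision)
            return float(np.mean(ps))
        assert mean_precision(**variant) < mean_precision()
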