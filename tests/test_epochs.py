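"""Epoch segmentation boundaries and the 66 summary statistics against
textbook-formula re-computation."""

import math

import numpy as np
import pytest

from finbeat import AccelStream, BehaviourEvent, derive_channels
from finbeat.epochs import (FEATURE_NAMES, MOMENT_STATS, QUANTILE_CHANNELS,
                            build_feature_table, segment_epochs,
                            summarize_epoch)
from finbeat.signals import CHANNELS


def _derived(n, seed=0, fs=10.0):
    rng = np.random.default_rng(seed)
    x, y, z = rng.normal(0, 0.4, size=(3, n))
    return derive_channels(AccelStream.from_arrays(np.arange(n) / fs, x, y, z,
                                                   sampling_rate=fs))


def test_feature_name_inventory():
    assert len(FEATURE_NAMES) == 66
    assert len(set(FEATURE_NAMES)) == 66
    assert sum(name.endswith(("_q10", "_q90")) for name in FEATURE_NAMES) == 12


class TestSegmentation:
    def test_event_tiling_and_remainder(self):
        d = _derived(70)
        events = [BehaviourEvent(0, "rest", 0.0, 7.0)]
        eps = segment_epochs(d, events, 2, 10)
        assert len(eps) == 3  # 70 = 3×20 + 10 discarded
        assert [e.start_index for e in eps] == [0, 20, 40]

    def test_short_event_yields_no_epoch(self):
        d = _derived(15)
        assert segment_epochs(d, [BehaviourEvent(0, "rest", 0.0, 1.5)], 2, 10) == []

    def test_no_epoch_crosses_event_boundary(self):
        d = _derived(75)
        events = [BehaviourEvent(0, "rest", 0.0, 3.4),
                  BehaviourEvent(1, "swim_column", 3.4, 7.5)]
        for e in segment_epochs(d, events, 2, 10):
            ev = events[e.event_id]
            assert e.start_index >= round(ev.start * 10)
            assert e.start_index + e.n_samples <= round(ev.end * 10)

    def test_excluded_labels_produce_no_epochs(self):
        d = _derived(100)
        events = [BehaviourEvent(0, "other", 0.0, 5.0),
                  BehaviourEvent(1, "out_of_camera", 5.0, 10.0)]
        assert segment_epochs(d, events, 1, 10) == []

    def test_stride_override_gives_overlap(self):
        d = _derived(40)
        eps = segment_epochs(d, [BehaviourEvent(0, "rest", 0.0, 4.0)], 2, 10,
                             stride=10)
        assert [e.start_index for e in eps] == [0, 10, 20]

    def test_non_integral_epoch_rejected(self):
        with pytest.raises(ValueError, match="integral"):
            segment_epochs(_derived(30), [BehaviourEvent(0, "rest", 0.0, 3.0)],
                           0.25, 10)


def _naive_stats(v):
    """Textbook formulas, plain Python."""
    n = len(v)
    mean = sum(v) / n
    sd = math.sqrt(sum((x - mean) ** 2 for x in v) / (n - 1))
    m2 = sum((x - mean) ** 2 for x in v) / n
    m3 = sum((x - mean) ** 3 for x in v) / n
    m4 = sum((x - mean) ** 4 for x in v) / n
    skew = m3 / m2**1.5 if m2 > 0 else 0.0
    kurt = m4 / m2**2 - 3 if m2 > 0 else 0.0
    return mean, sd, min(v), max(v), skew, kurt


def _naive_quantile(v, q):
    """Linear interpolation between order statistics."""
    s = sorted(v)
    h = (len(s) - 1) * q
    lo = math.floor(h)
    return s[lo] + (h - lo) * (s[min(lo + 1, len(s) - 1)] - s[lo])


class TestSummaries:
    def test_exactly_66_features(self):
        d = _derived(20)
        row = summarize_epoch(
            segment_epochs(d, [BehaviourEvent(0, "rest", 0.0, 2.0)], 2, 10)[0], d)
        feats = {k: v for k, v in row.items() if k not in ("label", "event_id")}
        assert set(feats) == set(FEATURE_NAMES)
        assert all(np.isfinite(v) for v in feats.values())

    def test_constant_epoch_degenerate_stats(self):
        fs = 10.0
        # binary-exact axis values keep the moving average exactly constant
        s = AccelStream.from_arrays(np.arange(20) / fs, [0.25] * 20, [-0.5] * 20,
                                    [0.9375] * 20, sampling_rate=fs)
        d = derive_channels(s)
        row = summarize_epoch(
            segment_epochs(d, [BehaviourEvent(0, "rest", 0.0, 2.0)], 2, 10)[0], d)
        for ch in CHANNELS:
            assert row[f"{ch}_sd"] == 0.0
            assert row[f"{ch}_skew"] == 0.0 and row[f"{ch}_kurt"] == 0.0
            assert row[f"{ch}_min"] == row[f"{ch}_max"] == row[f"{ch}_mean"]

    def test_matches_textbook_oracle(self):
        d = _derived(20, seed=5)
        row = summarize_epoch(
            segment_epochs(d, [BehaviourEvent(0, "swim_column", 0.0, 2.0)], 2, 10)[0], d)
        for ch in CHANNELS:
            v = list(d[ch])
            for stat, expected in zip(MOMENT_STATS, _naive_stats(v)):
                assert row[f"{ch}_{stat}"] == pytest.approx(expected, rel=1e-10), \
                    f"{ch}_{stat}"
        for ch in QUANTILE_CHANNELS:
            v = list(d[ch])
            assert row[f"{ch}_q10"] == pytest.approx(_naive_quantile(v, 0.1), rel=1e-10)
            assert row[f"{ch}_q90"] == pytest.approx(_naive_quantile(v, 0.9), rel=1e-10)

    def test_order_statistics_nested(self, table_2s):
        for ch in QUANTILE_CHANNELS:
            t = table_2s
            assert (t[f"{ch}_min"] <= t[f"{ch}_q10"] + 1e-12).all()
            assert (t[f"{ch}_q10"] <= t[f"{ch}_q90"] + 1e-12).all()
            assert (t[f"{ch}_q90"] <= t[f"{ch}_max"] + 1e-12).all()
            assert (t[f"{ch}_min"] <= t[f"{ch}_mean"]).all()
            assert (t[f"{ch}_mean"] <= t[f"{ch}_max"]).all()


class TestFeatureTable:
    def test_row_count_bounds_and_epoch_monotonicity(self, small_sessions,
                                                     table_1s, table_2s):
        total_seconds = sum(len(stream) for _, stream, _ in small_sessions) / 10
        assert len(table_2s) <= total_seconds / 2
        assert len(table_1s) >= len(table_2s)
        assert list(table_1s.columns) == list(FEATURE_NAMES) + ["label", "event_id",
                                                                "session"]

    def test_row_count_equals_per_event_epoch_sum(self, small_sessions, table_2s):
        expected = 0
        for _, stream, events in small_sessions:
            for ev in events:
                if ev.label in ("other", "out_of_camera"):
                    continue
                n = round(ev.end * 10) - round(ev.start * 10)
                expected += n // 20
        assert len(table_2s) == expected

    def test_rebuild_is_identical(self, small_sessions, table_2s):
        again = build_feature_table(small_sessions, 2)
        assert again.equals(table_2s)

    def test_vertical_swim_odba_exceeds_rest(self, table_2s):
        means = table_2s.groupby("label")["odba_mean"].mean()
        assert means["vertical_swim"] > means["rest"]
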