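"""Burst detection and burst-derived statistics."""

import numpy as np
import pandas as pd
import pytest

from burstpipe.bursts import (
    BurstDetectionParams,
    baseline_rates,
    bin_burst_rates,
    count_ssd_ssrt_bursts,
    cross_site_locked_rates,
    detect_bursts,
    first_burst_latencies,
    lock_bursts,
    summarize_bursts,
)
from burstpipe.spectral import WaveletSpec, channel_median_power, morlet_power
from burstpipe.synthetic import burst_waveform, one_over_f_noise

FS = 1000.0
WS = WaveletSpec()


def _detect(x, params=None):
    power, valid = morlet_power(x, FS, WS)
    med = channel_median_power(power)
    return detect_bursts(power, WS.freqs, FS, med, params, valid)


class TestDetectBursts:
    def test_zero_signal_rejected_degenerate_median(self):
        power, valid = morlet_power(np.zeros(3000), FS, WS)
        with pytest.raises(ValueError):
            detect_bursts(power, WS.freqs, FS, channel_median_power(power))

    def test_sustained_rhythm_yields_no_bursts(self):
        """A constant-amplitude beta sinusoid is its own median: the 6x
        threshold is never exceeded."""
        t = np.arange(60 * FS) / FS
        x = np.sin(2 * np.pi * 20 * t)
        assert len(_detect(x)) == 0

    def test_single_injected_event_recovered(self):
        rng = np.random.default_rng(4)
        x = one_over_f_noise(rng, 30000, FS, 1.0, 1.0)
        from burstpipe.synthetic import _band_rms

        amp = 10.0 * _band_rms(x, FS)
        wf = burst_waveform(FS, 20.0, 150.0, amp, 10.0)
        c = 15000
        x[c - len(wf) // 2 : c - len(wf) // 2 + len(wf)] += wf
        ev = _detect(x)
        near = ev[np.abs(ev["t_ms"] - 15000.0) <= 25.0]
        assert len(near) == 1
        assert abs(near["freq_hz"].iloc[0] - 20.0) <= 2.0
        assert near["duration_ms"].iloc[0] >= 100.0

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(5)
        x = one_over_f_noise(rng, 60000, FS, 1.0, 1.0)
        counts = [
            len(_detect(x, BurstDetectionParams(threshold_multiplier=m)))
            for m in (4.0, 6.0, 9.0)
        ]
        assert counts[0] >= counts[1] >= counts[2]

    def test_amplitude_scale_invariance(self):
        rng = np.random.default_rng(6)
        x = one_over_f_noise(rng, 40000, FS, 1.0, 1.0)
        a = _detect(x)
        b = _detect(x * 13.7)
        pd.testing.assert_frame_equal(a, b)

    def test_detected_bursts_satisfy_invariants(self):
        rng = np.random.default_rng(7)
        x = one_over_f_noise(rng, 60000, FS, 1.0, 1.0)
        ev = _detect(x)
        assert (ev["power_x_median"] > 6.0).all()
        assert ev["freq_hz"].between(15, 29).all()
        assert np.all(
            ev["duration_ms"] >= 2 * 1000.0 / ev["freq_hz"] - 1e-9
        )


def _trials(rows):
    defaults = {
        "trial_index": 0,
        "block": 0,
        "onset_go_ms": 1000.0,
        "trial_kind": "go",
        "ssd_ms": np.nan,
        "staircase_ssd_ms": 250.0,
        "rt_ms": np.nan,
        "hand": "left",
        "pressed": "",
        "outcome": "correct-go",
    }
    return pd.DataFrame([{**defaults, **r} for r in rows])


def _events(times_ms, freq=20.0):
    return pd.DataFrame(
        {
            "t_ms": times_ms,
            "freq_hz": [freq] * len(times_ms),
            "power_x_median": [8.0] * len(times_ms),
            "duration_ms": [120.0] * len(times_ms),
        }
    )


class TestLockAndBin:
    def test_single_burst_single_trial_rate(self):
        trials = _trials([{"trial_index": 0, "onset_go_ms": 1000.0}])
        locked, inc = lock_bursts(_events([1150.0]), trials, "go")
        rates = bin_burst_rates(locked, inc, 100.0, (-100.0, 900.0))
        r = rates.set_index("bin_start_ms")["rate"]
        assert r[100.0] == 1.0
        assert r.drop(100.0).sum() == 0.0

    def test_bookkeeping_identity(self):
        rng = np.random.default_rng(0)
        trials = _trials(
            [{"trial_index": i, "onset_go_ms": 1000.0 + 4000.0 * i} for i in range(50)]
        )
        times = rng.uniform(0, 201000, 300)
        locked, inc = lock_bursts(_events(times), trials, "go", (-100.0, 900.0))
        rates = bin_burst_rates(locked, inc, 100.0, (-100.0, 900.0))
        total = (rates["rate"] * rates["n_trials"]).sum()
        assert total == len(locked)

    def test_epoch_overlapping_mask_dropped(self):
        trials = _trials(
            [
                {"trial_index": 0, "onset_go_ms": 1000.0},
                {"trial_index": 1, "onset_go_ms": 5000.0},
            ]
        )
        mask = np.zeros(20000, dtype=bool)
        mask[5200:5300] = True  # inside trial 1's epoch
        locked, inc = lock_bursts(
            _events([1100.0, 5100.0]), trials, "go", (-500.0, 1000.0), mask, FS
        )
        assert list(inc["trial_index"]) == [0]
        assert list(locked["trial_index"]) == [0]

    def test_summarize_means(self):
        ev = pd.DataFrame(
            {"t_ms": [0, 1], "freq_hz": [18.0, 22.0],
             "power_x_median": [7, 8], "duration_ms": [100.0, 150.0]}
        )
        s = summarize_bursts(ev)
        assert s["mean_duration_ms"][0] == 125.0
        assert s["mean_freq_hz"][0] == 20.0
        with pytest.raises(ValueError):
            summarize_bursts(ev.iloc[:0])


class TestSsdSsrtCounts:
    def _setup(self):
        trials = _trials(
            [
                {"trial_index": 0, "trial_kind": "stop", "ssd_ms": 200.0,
                 "outcome": "successful-stop"},
            ]
        )
        return trials

    def test_burst_inside_window_counted(self):
        trials = self._setup()
        locked, inc = lock_bursts(_events([1210.0]), trials, "go")  # SSD+10
        out = count_ssd_ssrt_bursts(locked, inc, 300.0)
        assert out.loc[out["condition"] == "successful-stop", "mean_count"].iloc[0] == 1

    def test_burst_after_window_not_counted(self):
        trials = self._setup()
        locked, inc = lock_bursts(_events([1550.0]), trials, "go")  # SSD+350
        out = count_ssd_ssrt_bursts(locked, inc, 300.0)
        assert out.loc[out["condition"] == "successful-stop", "mean_count"].iloc[0] == 0

    def test_negative_ssrt_rejected(self):
        trials = self._setup()
        locked, inc = lock_bursts(_events([1210.0]), trials, "go")
        with pytest.raises(ValueError):
            count_ssd_ssrt_bursts(locked, inc, -10.0)

    def test_matched_go_uses_virtual_ssd(self):
        trials = _trials(
            [{"trial_index": 0, "outcome": "correct-go", "rt_ms": 600.0,
              "pressed": "left", "staircase_ssd_ms": 300.0}]
        )
        trials["go_speed"] = "fast"
        trials["virtual_ssd_ms"] = trials["staircase_ssd_ms"]
        locked, inc = lock_bursts(_events([1350.0]), trials, "go")  # virtual SSD+50
        out = count_ssd_ssrt_bursts(locked, inc, 300.0)
        assert out.loc[out["condition"] == "fast-go", "mean_count"].iloc[0] == 1


class TestBaselines:
    def test_no_bursts_zero(self):
        trials = _trials([{"trial_index": 0, "trial_kind": "stop", "ssd_ms": 250.0,
                           "outcome": "successful-stop"}])
        locked, inc = lock_bursts(_events([]), trials, "go")
        out = baseline_rates(locked, inc)
        assert (out[["pre_go_rate", "pre_stop_rate"]].to_numpy() == 0).all()

    def test_half_open_window_excludes_edge(self):
        trials = _trials([{"trial_index": 0}])
        # burst exactly 100 ms before go: excluded by [-100, 0) convention
        locked, inc = lock_bursts(_events([900.0]), trials, "go")
        out = baseline_rates(locked, inc)
        assert out["pre_go_rate"].iloc[0] == 1.0  # -100 is included (>= -100)
        locked2, inc2 = lock_bursts(_events([1000.0]), trials, "go")
        out2 = baseline_rates(locked2, inc2)
        assert out2["pre_go_rate"].iloc[0] == 0.0  # 0 is excluded (< 0)

    def test_homogeneous_rates_similar_across_windows(self):
        rng = np.random.default_rng(1)
        trials = _trials(
            [{"trial_index": i, "onset_go_ms": 1000.0 + 4000.0 * i,
              "trial_kind": "stop", "ssd_ms": 250.0, "outcome": "successful-stop"}
             for i in range(400)]
        )
        times = rng.uniform(0, 1601000, 3500)  # homogeneous Poisson-ish
        locked, inc = lock_bursts(_events(times), trials, "go", (-500.0, 1500.0))
        out = baseline_rates(locked, inc)
        assert abs(out["pre_go_rate"].iloc[0] - out["pre_stop_rate"].iloc[0]) < 0.05


class TestFirstBurstLatencies:
    def test_worked_example(self):
        trials = _trials([{"trial_index": 0, "trial_kind": "stop", "ssd_ms": 200.0,
                           "outcome": "successful-stop"}])
        locked, inc = lock_bursts(_events([1320.0]), trials, "stop")  # +120 post stop
        out = first_burst_latencies(locked, inc, ssrt=300.0)
        assert out["latency_stop_ms"].iloc[0] == pytest.approx(120.0)
        assert out["latency_ssrt_ms"].iloc[0] == pytest.approx(-180.0)

    def test_no_burst_missing(self):
        trials = _trials([{"trial_index": 0, "trial_kind": "stop", "ssd_ms": 200.0,
                           "outcome": "successful-stop"}])
        locked, inc = lock_bursts(_events([]), trials, "stop")
        out = first_burst_latencies(locked, inc, ssrt=300.0)
        assert np.isnan(out["latency_stop_ms"].iloc[0])

    def test_earliest_burst_selected(self):
        trials = _trials([{"trial_index": 0, "trial_kind": "stop", "ssd_ms": 200.0,
                           "outcome": "successful-stop"}])
        locked, inc = lock_bursts(_events([1500.0, 1300.0]), trials, "stop")
        out = first_burst_latencies(locked, inc, ssrt=300.0)
        assert out["latency_stop_ms"].iloc[0] == pytest.approx(100.0)


class TestCrossSiteLockedRates:
    def _stop_trials(self, n):
        return _trials(
            [{"trial_index": i, "onset_go_ms": 1000.0 + 4000.0 * i,
              "trial_kind": "stop", "ssd_ms": 200.0, "outcome": "successful-stop"}
             for i in range(n)]
        )

    def test_deterministic_coupling_bin_convention(self):
        trials = self._stop_trials(1)
        # stop at 1200; seed burst +100; target +150 -> delta exactly +50
        seed_locked, inc = lock_bursts(_events([1300.0]), trials, "stop")
        target_locked, _ = lock_bursts(_events([1350.0]), trials, "stop")
        out = cross_site_locked_rates(seed_locked, target_locked, inc)
        r = out.set_index("bin_start_ms")["rate"]
        assert r[50.0] == 1.0  # half-open: +50 falls in [50, 100)

    def test_no_target_bursts_all_zero(self):
        trials = self._stop_trials(3)
        seed_locked, inc = lock_bursts(_events([1300.0, 5300.0, 9300.0]), trials, "stop")
        target_locked, _ = lock_bursts(_events([]), trials, "stop")
        out = cross_site_locked_rates(seed_locked, target_locked, inc)
        assert (out["rate"] == 0).all()

    def test_trials_without_seed_excluded(self):
        trials = self._stop_trials(2)
        seed_locked, inc = lock_bursts(_events([1300.0]), trials, "stop")  # trial 0 only
        target_locked, _ = lock_bursts(_events([1350.0, 5350.0]), trials, "stop")
        out = cross_site_locked_rates(seed_locked, target_locked, inc)
        assert (out["n_seed_trials"] == 1).all()

    def test_independent_sites_roughly_flat(self):
        rng = np.random.default_rng(2)
        n = 300
        trials = self._stop_trials(n)
        stops = trials["onset_go_ms"].to_numpy() + 200.0
        seed_times = stops + rng.uniform(1, 500, n)
        target_times = stops + rng.uniform(-500, 1000, n)
        seed_locked, inc = lock_bursts(_events(seed_times), trials, "stop")
        target_locked, _ = lock_bursts(_events(target_times), trials, "stop")
        out = cross_site_locked_rates(seed_locked, target_locked, inc)
        rates = out["rate"].to_numpy()
        # Poisson-flat within Monte-Carlo tolerance
        assert rates.max() - rates.min() < 0.08
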