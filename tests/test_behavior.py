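"""Behavioral scoring, exclusions, SSRT and group comparison."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from burstpipe.behavior import (
    apply_exclusions,
    compare_groups,
    compute_ssrt,
    score_trials,
    split_matched_go,
)


def _trial(kind="go", hand="left", pressed="", rt=np.nan, block=0, ssd=np.nan, i=0):
    return {
        "trial_index": i,
        "block": block,
        "onset_go_ms": 1000.0 + 4000.0 * i,
        "trial_kind": kind,
        "ssd_ms": ssd,
        "staircase_ssd_ms": 250.0,
        "rt_ms": rt,
        "hand": hand,
        "pressed": pressed,
        "outcome": "",
    }


class TestScoreTrials:
    @pytest.mark.parametrize(
        "kind,hand,pressed,rt,expected",
        [
            ("go", "left", "left", 800.0, "correct-go"),
            ("go", "left", "right", 800.0, "wrong-go"),
            ("go", "left", "", np.nan, "go-omission"),
            ("stop", "left", "", np.nan, "successful-stop"),
            ("stop", "left", "left", 600.0, "failed-stop"),
            ("stop", "left", "right", 600.0, "failed-stop"),  # any press fails to stop
        ],
    )
    def test_outcomes(self, kind, hand, pressed, rt, expected):
        df = pd.DataFrame([_trial(kind, hand, pressed, rt, ssd=250.0)])
        assert score_trials(df)["outcome"].iloc[0] == expected

    def test_rt_beyond_deadline_rejected(self):
        df = pd.DataFrame([_trial(rt=2400.0, pressed="left")])
        with pytest.raises(ValueError):
            score_trials(df)


class TestExclusions:
    def _participant(self, block_specs):
        """block_specs: list of (n_correct_go, n_wrong_go, n_success_stop)."""
        rows = []
        i = 0
        for b, (n_ok, n_bad, n_ss) in enumerate(block_specs):
            for _ in range(n_ok):
                rows.append(_trial("go", "left", "left", 700.0, block=b, i=i)); i += 1
            for _ in range(n_bad):
                rows.append(_trial("go", "left", "right", 700.0, block=b, i=i)); i += 1
            for _ in range(n_ss):
                rows.append(_trial("stop", "left", "", np.nan, block=b, ssd=250.0, i=i)); i += 1
            rows.append(_trial("stop", "left", "left", 500.0, block=b, ssd=250.0, i=i)); i += 1
        return score_trials(pd.DataFrame(rows))

    def test_low_accuracy_block_excluded(self):
        # block 0: go accuracy 11/20 = 0.55 < 0.60 -> excluded; block 1 clean
        p = self._participant([(11, 9, 2), (20, 0, 2)])
        kept, report = apply_exclusions({"p1": p})
        assert set(kept["p1"]["block"]) == {1}
        assert "accuracy" in report["reason"].iloc[0]

    def test_block_without_successful_stop_excluded(self):
        p = self._participant([(20, 0, 0), (20, 0, 2)])
        kept, report = apply_exclusions({"p1": p})
        assert set(kept["p1"]["block"]) == {1}
        assert "successful stop" in report["reason"].iloc[0]

    def test_below_chance_participant_excluded(self):
        # 49/100 correct go overall -> participant removed entirely
        p = self._participant([(49, 51, 2)])
        kept, report = apply_exclusions({"p1": p})
        assert "p1" not in kept
        assert (report["participant"] == "p1").any()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            apply_exclusions({})


def _ssrt_oracle(rts, p, mean_ssd, deadline=2000.0):
    """Brute force: replace omissions, extract k-th smallest by repeated min."""
    vals = [deadline if (r is None or not np.isfinite(r)) else r for r in rts]
    k = math.ceil(len(vals) * p)
    pool = list(vals)
    for _ in range(k - 1):
        pool.remove(min(pool))
    return min(pool) - mean_ssd


class TestComputeSsrt:
    def test_worked_example_with_omissions(self):
        rts = [300, 400, 500, 600, 700, 800, 900, 1000, np.nan, np.nan]
        assert compute_ssrt(rts, 0.5, 200.0) == 500.0

    def test_p_one_max_rank(self):
        assert compute_ssrt([650.0] * 8, 1.0, 150.0) == 500.0

    def test_single_go_trial(self):
        assert compute_ssrt([600.0], 0.5, 100.0) == 500.0

    def test_p_zero_undefined(self):
        with pytest.raises(ValueError):
            compute_ssrt([500.0], 0.0, 100.0)

    def test_no_go_trials_rejected(self):
        with pytest.raises(ValueError):
            compute_ssrt([], 0.5, 100.0)

    def test_matches_bruteforce_on_random_inputs(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            n = rng.integers(1, 20)
            rts = rng.uniform(100, 1900, n).round(1).tolist()
            for j in range(len(rts)):
                if rng.random() < 0.15:
                    rts[j] = np.nan
            p = rng.uniform(0.05, 1.0)
            ssd = rng.uniform(0, 500)
            assert compute_ssrt(rts, p, ssd) == pytest.approx(
                _ssrt_oracle(rts, p, ssd)
            )

    @given(
        rts=st.lists(st.floats(50, 1999), min_size=1, max_size=15),
        p=st.floats(0.05, 1.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_adding_omission_never_decreases_ssrt(self, rts, p):
        base = compute_ssrt(rts, p, 0.0)
        with_omit = compute_ssrt(rts + [np.nan], p, 0.0)
        assert with_omit >= base - 1e-9


class TestMatchedGoSplit:
    def _go_trials(self, rts):
        rows = [
            _trial("go", "left", "left", r, i=i) for i, r in enumerate(rts)
        ]
        return score_trials(pd.DataFrame(rows))

    def test_even_split(self):
        out = split_matched_go(self._go_trials([400, 500, 600, 700]))
        assert out.set_index("rt_ms")["go_speed"].to_dict() == {
            400: "fast", 500: "fast", 600: "slow", 700: "slow"
        }

    def test_median_rt_goes_fast(self):
        out = split_matched_go(self._go_trials([400, 500, 600]))
        assert out.loc[out["rt_ms"] == 500, "go_speed"].iloc[0] == "fast"

    def test_all_equal_all_fast(self):
        out = split_matched_go(self._go_trials([500, 500, 500]))
        assert (out["go_speed"] == "fast").all()

    def test_partition_is_exact(self):
        rng = np.random.default_rng(3)
        trials = self._go_trials(rng.uniform(300, 900, 25).tolist())
        out = split_matched_go(trials)
        assert len(out) == 25
        assert set(out["go_speed"]) <= {"fast", "slow"}
        assert (out["virtual_ssd_ms"] == 250.0).all()

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            split_matched_go(self._go_trials([500]))


class TestCompareGroups:
    def test_identical_groups(self):
        res = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res["t"] == 0.0 and res["cohen_d"] == 0.0

    def test_closed_form_pooled_t(self):
        res = compare_groups([1, 2, 3], [4, 5, 6])
        assert res["t"] == pytest.approx(-3.674, abs=1e-3)
        assert res["df"] == 4

    def test_large_separation(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 40)
        b = rng.normal(10, 1, 40)
        assert compare_groups(a, b)["p"] < 1e-4
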