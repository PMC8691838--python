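"""Permutation RM-ANOVA, mixed ANOVA, Holm pairwise tests."""

from itertools import product

import numpy as np
import pandas as pd
import pytest

from burstpipe.stats import (
    holm_pairwise,
    mixed_anova_burst_timing,
    mixed_anova_f,
    perm_rm_anova,
    rm_anova_f,
    single_subject_burst_timing_test,
)


def _long(data):
    S, A, B = data.shape
    return pd.DataFrame(
        [
            {"subj": s, "A": a, "B": b, "y": data[s, a, b]}
            for s in range(S)
            for a in range(A)
            for b in range(B)
        ]
    )


class TestRmAnovaF:
    def test_matches_pingouin_oracle(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(0)
        for S, A, B in ((8, 2, 3), (6, 3, 4), (10, 2, 2)):
            data = rng.normal(0, 1, (S, A, B)) + rng.uniform(0, 1) * np.arange(A)[
                None, :, None
            ]
            ours = rm_anova_f(data)
            aov = pg.rm_anova(
                data=_long(data), dv="y", within=["A", "B"], subject="subj",
                detailed=True,
            ).set_index("Source")["F"]
            assert float(ours["a"]["F"]) == pytest.approx(aov["A"], rel=1e-9)
            assert float(ours["b"]["F"]) == pytest.approx(aov["B"], rel=1e-9)
            assert float(ours["ab"]["F"]) == pytest.approx(aov["A * B"], rel=1e-9)

    def test_identical_cells_give_zero_f(self):
        data = np.ones((5, 2, 3)) * 4.2
        res = perm_rm_anova(data, n_perm=200, seed=0)
        assert (res["F"] == 0).all()
        assert (res["p_perm"] > 0.9).all()
        assert not res["significant"].any()


class TestPermRmAnova:
    def test_agrees_with_exhaustive_sign_flip_oracle(self):
        """For a 2-level within factor, permutation p approximates the
        exhaustive sign-flip p of the paired differences."""
        rng = np.random.default_rng(3)
        for _ in range(2):
            S = 6
            data = rng.normal(0, 1, (S, 2, 2)) + 0.6 * np.arange(2)[None, :, None]
            res = perm_rm_anova(data, n_perm=4000, seed=1)
            p_perm = res.loc[res["effect"] == "a", "p_perm"].iloc[0]
            d = data[:, 1, :].mean(axis=1) - data[:, 0, :].mean(axis=1)
            obs = abs(d.mean()) / (d.std(ddof=1) / np.sqrt(S))
            hits = 0
            for signs in product([-1, 1], repeat=S):
                ds = d * np.array(signs)
                t = abs(ds.mean()) / (ds.std(ddof=1) / np.sqrt(S))
                hits += t >= obs - 1e-12
            p_flip = hits / 2**S
            assert p_perm == pytest.approx(p_flip, abs=0.08)

    def test_affine_invariance_of_p(self):
        rng = np.random.default_rng(4)
        data = rng.normal(0, 1, (7, 2, 3))
        a = perm_rm_anova(data, n_perm=500, seed=9)
        b = perm_rm_anova(3.5 * data - 12.0, n_perm=500, seed=9)
        pd.testing.assert_series_equal(a["p_perm"], b["p_perm"])

    def test_power_for_large_main_effect(self):
        rng = np.random.default_rng(5)
        hits = 0
        for _ in range(10):
            data = rng.normal(0, 1, (12, 2, 3))
            data[:, 1, :] += 2.0  # 2-SD main effect on factor A
            res = perm_rm_anova(data, n_perm=300, seed=int(rng.integers(2**31)))
            hits += bool(res.loc[res["effect"] == "a", "significant"].iloc[0])
        assert hits >= 9

    def test_type_one_error_roughly_calibrated(self):
        """Reduced-size calibration check (the full version runs in the
        acceptance suite)."""
        rng = np.random.default_rng(6)
        rejections = np.zeros(3)
        n_sim = 200
        for _ in range(n_sim):
            data = rng.normal(0, 1, (8, 2, 3))
            res = perm_rm_anova(data, n_perm=200, seed=int(rng.integers(2**31)))
            rejections += res["significant"].to_numpy()
        rates = rejections / n_sim
        assert np.all(rates < 0.10)
        assert np.all(rates > 0.005)

    def test_missing_cells_dropped_listwise(self):
        data = np.random.default_rng(7).normal(0, 1, (6, 2, 2))
        data[0, 0, 0] = np.nan
        with pytest.warns(UserWarning):
            res = perm_rm_anova(data, n_perm=100, seed=0)
        assert (res["n_subjects"] == 5).all()


class TestHolmPairwise:
    def test_hand_computed_adjustment(self):
        # contrasts engineered to produce increasing raw p's, then compare
        # Holm output to direct step-down computation on those p's
        rng = np.random.default_rng(8)
        base = rng.normal(0, 1, 20)
        contrasts = [
            ("c1", base, base + 1.2 + rng.normal(0, 0.2, 20)),
            ("c2", base, base + 0.8 + rng.normal(0, 0.4, 20)),
            ("c3", base, base + 0.3 + rng.normal(0, 0.6, 20)),
        ]
        res = holm_pairwise(contrasts)
        raw = res["p_raw"].to_numpy()
        order = np.argsort(raw)
        expected = np.empty(3)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (3 - rank) * raw[idx])
            expected[idx] = min(running, 1.0)
        assert np.allclose(res["p_holm"].to_numpy(), expected)
        assert (res["p_holm"] >= res["p_raw"] - 1e-12).all()

    def test_known_p_values_example(self):
        # family {.01, .02, .04} -> Holm {.03, .04, .04}
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([0.01, 0.02, 0.04], method="holm")[1]
        assert np.allclose(adj, [0.03, 0.04, 0.04])

    def test_single_contrast_unadjusted(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0, 1, 15)
        res = holm_pairwise([("only", x, x + 0.5)])
        assert res["p_holm"].iloc[0] == pytest.approx(res["p_raw"].iloc[0])

    def test_identical_samples(self):
        x = np.arange(10.0)
        res = holm_pairwise([("same", x, x.copy())])
        assert res["t"].iloc[0] == 0.0
        assert res["p_holm"].iloc[0] == 1.0

    def test_short_contrast_skipped(self):
        res = holm_pairwise([("tiny", [1.0], [2.0])])
        assert np.isnan(res["t"].iloc[0])


class TestMixedAnova:
    def test_matches_pingouin_oracle(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(10)
        vals = rng.normal(0, 1, (12, 2))
        groups = np.array([0] * 6 + [1] * 6)
        ours = mixed_anova_f(vals, groups)
        rows = [
            {"subj": s, "g": groups[s], "w": w, "y": vals[s, w]}
            for s in range(12)
            for w in range(2)
        ]
        aov = pg.mixed_anova(
            data=pd.DataFrame(rows), dv="y", within="w", between="g", subject="subj"
        ).set_index("Source")["F"]
        assert ours["between"]["F"] == pytest.approx(aov["g"], rel=1e-9)
        assert ours["within"]["F"] == pytest.approx(aov["w"], rel=1e-9)
        assert ours["interaction"]["F"] == pytest.approx(aov["Interaction"], rel=1e-9)

    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(11)
        rej = np.zeros(3)
        n_sim = 120
        for _ in range(n_sim):
            vals = rng.normal(0, 1, (10, 2))
            groups = np.array([0] * 5 + [1] * 5)
            res = mixed_anova_burst_timing(
                vals, groups, n_perm=200, seed=int(rng.integers(2**31))
            )
            rej += res["significant"].to_numpy()
        assert np.all(rej / n_sim < 0.12)

    def test_zero_variance_equal_means(self):
        vals = np.ones((8, 2)) * 3.0
        groups = np.array([0] * 4 + [1] * 4)
        res = mixed_anova_burst_timing(vals, groups, n_perm=100, seed=0)
        assert res.loc[res["effect"].str.startswith("subcortical"), "F"].iloc[0] == 0.0

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            mixed_anova_f(np.zeros((3, 2)), np.array([0, 0, 1]))


class TestSingleSubjectTiming:
    def test_large_shift_detected(self):
        rng = np.random.default_rng(12)
        b = rng.normal(200, 20, 30)
        a = b - 40
        res = single_subject_burst_timing_test(a, b)
        assert res["p"] < 0.001

    def test_identical_samples_boundary(self):
        x = np.linspace(100, 300, 20)
        res = single_subject_burst_timing_test(x, x.copy())
        assert res["p"] == pytest.approx(0.5)

    def test_wrong_direction_large_p(self):
        rng = np.random.default_rng(13)
        b = rng.normal(200, 20, 30)
        res = single_subject_burst_timing_test(b + 40, b)
        assert res["p"] > 0.5
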