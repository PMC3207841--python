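"""Window measures, entropy, distributional tests, and the mixed ANOVA."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from periotherm.stats import (
    MEASURES,
    PeriorbitalAnova,
    build_report,
    chi2_normality,
    mixed_anova,
    runs_test,
    shannon_entropy,
    summary_stats,
)


class TestSummaryStats:
    def test_hand_moments(self):
        ws = summary_stats([1.0, 2.0, 3.0, 4.0, 5.0])
        assert ws.range == 4.0
        assert ws.mean == 3.0
        assert ws.variance == pytest.approx(2.0)  # biased, 1/n
        assert ws.skewness == pytest.approx(0.0, abs=1e-12)
        assert ws.kurtosis == pytest.approx(1.7)  # Pearson scale

    def test_constant_window_degenerate(self):
        ws = summary_stats(np.full(31, 307.0))
        assert ws.range == 0.0 and ws.variance == 0.0
        assert math.isnan(ws.skewness) and math.isnan(ws.kurtosis)
        assert ws.degenerate

    def test_symmetric_window_zero_skew(self):
        x = np.concatenate([np.linspace(-1, 1, 16), -np.linspace(-1, 1, 16)])
        assert summary_stats(x + 300).skewness == pytest.approx(0.0, abs=1e-10)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            summary_stats([1.0, 2.0, 3.0])


class TestShannonEntropy:
    def test_constant_window_zero_bits(self):
        assert shannon_entropy(np.full(31, 5.0)) == 0.0

    def test_distinct_bins_log2_n(self):
        x = np.linspace(0.0, 30.0, 31)
        assert shannon_entropy(x) == pytest.approx(np.log2(31))

    def test_two_atoms_one_bit(self):
        x = np.array([0.0] * 16 + [1.0] * 15)
        p = np.array([16 / 31, 15 / 31])
        assert shannon_entropy(x) == pytest.approx(float(-(p * np.log2(p)).sum()))

    def test_max_value_counted_in_final_bin(self):
        # final bin closed: counts (1,1,1,2), so H = 3*(1/5)lg5 + (2/5)lg(5/2)
        x = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
        expected = 3 * 0.2 * np.log2(5) + 0.4 * np.log2(2.5)
        assert shannon_entropy(x, n_bins=4) == pytest.approx(expected)

    @given(st.integers(0, 2**32 - 1))
    def test_bounds(self, seed):
        x = np.random.default_rng(seed).normal(size=31)
        h = shannon_entropy(x)
        assert 0.0 <= h <= np.log2(31) + 1e-12
        distinct = len(np.unique(np.clip(((x - x.min()) / np.ptp(x) * 1000).astype(int), 0, 999)))
        if distinct == 31:
            assert h == pytest.approx(np.log2(31))

    def test_gaussian_windows_near_table_value(self, rng):
        h = np.mean([shannon_entropy(rng.normal(size=31)) for _ in range(3000)])
        assert h == pytest.approx(4.92, abs=0.03)


class TestChi2Normality:
    def test_gaussian_calibration(self):
        r = np.random.default_rng(42)
        rej = sum(chi2_normality(r.normal(size=31)).reject for _ in range(3000)) / 3000
        assert 0.03 <= rej <= 0.09  # slightly anti-conservative at n=31

    def test_bimodal_power(self):
        r = np.random.default_rng(43)
        rej = 0
        for _ in range(1000):
            modes = np.where(r.random(31) < 0.5, -2.0, 2.0)
            rej += chi2_normality(r.normal(modes, 1.0)).reject
        assert rej / 1000 > 0.35  # far above the 5% level

    def test_two_atom_sample_rejected(self):
        x = np.array([0.0, 1.0] * 16)
        assert chi2_normality(x).reject

    def test_zero_variance_flagged(self):
        res = chi2_normality(np.full(31, 2.0))
        assert res.reject and res.degenerate

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            chi2_normality(np.zeros(10))


class TestRunsTest:
    def test_ramp_two_runs(self):
        res = runs_test(np.linspace(0, 1, 100))
        assert res.n_runs == 2
        assert res.nonstationary

    def test_alternating_maximal_runs(self):
        x = np.tile([0.0, 1.0], 50)
        res = runs_test(x)
        assert res.n_runs == 100
        assert res.nonstationary  # too many runs is also non-random

    def test_iid_calibration(self):
        r = np.random.default_rng(44)
        rej = sum(runs_test(r.normal(size=450)).nonstationary for _ in range(3000))
        assert 0.03 <= rej / 3000 <= 0.07

    def test_indeterminate_flagged(self):
        res = runs_test(np.concatenate([np.full(40, 1.0), [2.0]]))
        assert res.indeterminate

    def test_median_ties_dropped(self):
        x = np.array([1.0, 2.0, 2.0, 2.0, 3.0] * 8)
        res = runs_test(x)
        assert res.n_above + res.n_below == 16  # the 2.0s are dropped


def balanced_table(rng, n_participants=4, n_trials=6, window_shift=0.0):
    rows = []
    for p in range(n_participants):
        base = 307.0 + rng.normal(0, 0.3)
        for t in range(n_trials):
            for side in ("left", "right"):
                pre = base + rng.normal(0, 0.02)
                rows.append(dict(participant=f"P{p}", trial=t, side=side,
                                 window="pre", mean=pre))
                rows.append(dict(participant=f"P{p}", trial=t, side=side,
                                 window="post", mean=pre + window_shift + rng.normal(0, 0.02)))
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_forced_effect_p_zero_with_flag(self, rng):
        t = balanced_table(rng)
        t.loc[t.window == "post", "mean"] = (
            t.loc[t.window == "pre", "mean"].to_numpy() + 1.0
        )
        res = mixed_anova(t, "mean")
        assert res.pvalues["window"] == 0.0
        assert any("window" in f for f in res.flags)

    def test_hand_worked_ems_decomposition(self):
        """2 participants x 2x2 cells (one trial each): F ratios equal the
        closed-form expected-mean-squares decomposition done by hand."""
        #            pre-L  pre-R  post-L post-R
        y = {("A", "pre", "left"): 1.0, ("A", "pre", "right"): 2.0,
             ("A", "post", "left"): 3.0, ("A", "post", "right"): 5.0,
             ("B", "pre", "left"): 2.0, ("B", "pre", "right"): 2.5,
             ("B", "post", "left"): 4.0, ("B", "post", "right"): 6.0}
        rows = [dict(participant=p, window=w, side=s, mean=v)
                for (p, w, s), v in y.items()]
        res = mixed_anova(pd.DataFrame(rows), "mean")
        arr = np.array([[[1.0, 2.0], [3.0, 5.0]],
                        [[2.0, 2.5], [4.0, 6.0]]])  # (participant, window, side)
        # hand decomposition via marginal means
        g = arr.mean()
        mw = arr.mean(axis=(0, 2)); ms = arr.mean(axis=(0, 1)); mp = arr.mean(axis=(1, 2))
        ss_w = 4 * ((mw - g) ** 2).sum()
        ss_s = 4 * ((ms - g) ** 2).sum()
        mwp = arr.mean(axis=2)
        ss_wp = 2 * ((mwp - mw[None, :] - mp[:, None] + g) ** 2).sum()
        msp = arr.mean(axis=1)
        ss_sp = 2 * ((msp - ms[None, :] - mp[:, None] + g) ** 2).sum()
        f_w = (ss_w / 1) / (ss_wp / 1)
        f_s = (ss_s / 1) / (ss_sp / 1)
        assert res.fvalues["window"] == pytest.approx(f_w)
        assert res.fvalues["side"] == pytest.approx(f_s)

    def test_sums_of_squares_additive(self, rng):
        t = balanced_table(rng)
        res = mixed_anova(t, "mean")
        model = PeriorbitalAnova(t, "mean")
        y = model.cell_means
        total = ((y - y.mean()) ** 2).sum()
        assert res.anova_table["ss"].sum() == pytest.approx(total, rel=1e-10)

    def test_against_statsmodels_anova_rm(self, rng):
        """Independent oracle: statsmodels repeated-measures ANOVA on the
        same cell means gives the same F for the within factors."""
        from statsmodels.stats.anova import AnovaRM

        t = balanced_table(rng, window_shift=0.01)
        res = mixed_anova(t, "mean")
        sm_res = AnovaRM(
            t, depvar="mean", subject="participant",
            within=["window", "side"], aggregate_func="mean",
        ).fit()
        sm_tbl = sm_res.anova_table
        assert res.fvalues["window"] == pytest.approx(sm_tbl.loc["window", "F Value"])
        assert res.fvalues["side"] == pytest.approx(sm_tbl.loc["side", "F Value"])
        assert res.fvalues["window:side"] == pytest.approx(
            sm_tbl.loc["window:side", "F Value"]
        )
        assert res.pvalues["window"] == pytest.approx(
            sm_tbl.loc["window", "Pr > F"], rel=1e-6
        )

    def test_missing_cell_named(self, rng):
        t = balanced_table(rng)
        t = t[~((t.participant == "P1") & (t.window == "post") & (t.side == "left"))]
        with pytest.raises(ValueError, match="P1"):
            mixed_anova(t, "mean")

    def test_two_participants_minimum(self, rng):
        t = balanced_table(rng, n_participants=1)
        with pytest.raises(ValueError):
            mixed_anova(t, "mean")

    def test_summary_renders(self, rng):
        s = mixed_anova(balanced_table(rng), "mean").summary()
        assert "window" in s and "participant" in s


class TestBuildReport:
    def make_study_table(self, rng, n_participants=4, shift=0.0, startle_frac=0.4):
        rows = []
        for p in range(n_participants):
            base = 307.0 + rng.normal(0, 0.3)
            for t in range(8):
                startle = rng.random() < startle_frac
                for side in ("left", "right"):
                    for window in ("pre", "post"):
                        v = base + rng.normal(0, 0.02) + (shift if window == "post" else 0)
                        rows.append(dict(
                            participant=f"P{p}", session=1, trial=t, side=side,
                            window=window, range=abs(rng.normal(0.05, 0.01)),
                            mean=v, variance=3e-4, skewness=0.0, kurtosis=2.2,
                            entropy=4.92, stimulus_flag=True,
                            formal_startle_flag=startle, usable_flag=True,
                        ))
        return pd.DataFrame(rows)

    def test_single_trial_means(self, rng):
        t = self.make_study_table(rng, n_participants=1).iloc[:4]
        rep = build_report(t)
        tbl = rep.tables["all usable stimulus trials"]
        pre_mean = float(tbl.loc["mean", "window=pre"].split(" ±")[0])
        assert pre_mean == pytest.approx(
            t[t.window == "pre"]["mean"].mean(), rel=1e-3
        )

    def test_null_study_unflagged(self, rng):
        rep = build_report(self.make_study_table(rng, shift=0.0))
        tbl = rep.tables["all usable stimulus trials"]
        assert "*" not in tbl.loc["mean", "window=pre"]

    def test_shifted_study_flagged(self, rng):
        rep = build_report(self.make_study_table(rng, shift=0.5))
        tbl = rep.tables["all usable stimulus trials"]
        assert tbl.loc["mean", "window=pre"].endswith("*")
        assert tbl.loc["mean", "window=post"].endswith("*")

    def test_empty_subset_marked(self, rng):
        t = self.make_study_table(rng, startle_frac=0.0)
        rep = build_report(t)
        assert "formal-startle subset" in rep.empty_subsets
        assert "no trials" in rep.to_markdown()

    def test_markdown_contains_all_measures(self, rng):
        md = build_report(self.make_study_table(rng)).to_markdown()
        for m in MEASURES:
            assert m in md
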