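"""Odds ratios, AUC, Kaplan-Meier, reclassification, follow-up."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from earlymet.evaluate import (
    ContingencyTable2x2,
    auc_with_ci,
    km_logrank,
    median_followup,
    multivariable_logistic,
    odds_ratio_2x2,
    reclassification_table,
    univariable_logistic_or,
)

cells = st.integers(min_value=1, max_value=60)


class TestOddsRatio2x2:
    @pytest.mark.parametrize(
        "table,expected",
        [
            # validation-cohort contingency tables and their published ORs/CIs
            ((42, 28, 21, 95), (6.79, 3.46, 13.29)),  # high vs low classifier risk
            ((35, 36, 28, 87), (3.02, 1.61, 5.68)),  # Gleason >= 8
            ((31, 35, 32, 88), (2.44, 1.30, 4.58)),  # seminal vesicle invasion
            ((30, 57, 33, 66), (1.05, 0.57, 1.93)),  # positive margins
            ((12, 15, 51, 108), (1.69, 0.74, 3.88)),  # nodal involvement
        ],
    )
    def test_reproduces_published_wald_intervals(self, table, expected):
        r = odds_ratio_2x2(ContingencyTable2x2(*table))
        assert round(r.or_, 2) == expected[0]
        assert round(r.ci_low, 2) == expected[1]
        assert round(r.ci_high, 2) == expected[2]

    def test_unit_table_symmetric_about_one(self):
        r = odds_ratio_2x2(ContingencyTable2x2(1, 1, 1, 1))
        assert r.or_ == pytest.approx(1.0)
        assert r.ci_low * r.ci_high == pytest.approx(1.0)

    @given(a=cells, b=cells, c=cells, d=cells)
    def test_row_swap_inverts(self, a, b, c, d):
        r1 = odds_ratio_2x2(ContingencyTable2x2(a, b, c, d))
        r2 = odds_ratio_2x2(ContingencyTable2x2(c, d, a, b))
        assert r2.or_ == pytest.approx(1 / r1.or_, rel=1e-9)
        assert r2.ci_low == pytest.approx(1 / r1.ci_high, rel=1e-9)
        assert r2.ci_high == pytest.approx(1 / r1.ci_low, rel=1e-9)

    @given(a=cells, b=cells, c=cells, d=cells)
    def test_transpose_invariant(self, a, b, c, d):
        r1 = odds_ratio_2x2(ContingencyTable2x2(a, b, c, d))
        r2 = odds_ratio_2x2(ContingencyTable2x2(a, c, b, d))
        assert r2.or_ == pytest.approx(r1.or_, rel=1e-9)

    def test_zero_cell_haldane_correction_flagged(self):
        r = odds_ratio_2x2(ContingencyTable2x2(5, 0, 3, 7))
        assert r.corrected
        assert np.isfinite(r.or_) and r.or_ > 0

    @pytest.mark.parametrize("table", [(0, 0, 3, 7), (0, 5, 0, 7)])
    def test_zero_margin_rejected(self, table):
        with pytest.raises(ValueError, match="undefined"):
            odds_ratio_2x2(ContingencyTable2x2(*table))

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 2, 3, 4)


class TestLogisticOR:
    def test_binary_covariate_matches_closed_form(self):
        a, b, c, d = 42, 28, 21, 95
        x = np.array([1] * (a + b) + [0] * (c + d))
        y = np.array([1] * a + [0] * b + [1] * c + [0] * d)
        rl = univariable_logistic_or(x, y)
        r2 = odds_ratio_2x2(ContingencyTable2x2(a, b, c, d))
        assert rl.or_ == pytest.approx(r2.or_, rel=1e-6)

    def test_per_10pct_transform(self):
        rng = np.random.default_rng(0)
        y = rng.random(300) < 0.4
        s = np.clip(0.4 + 0.25 * (y - 0.5) + 0.2 * rng.normal(size=300), 0, 1)
        unit = univariable_logistic_or(s, y, "identity")
        per10 = univariable_logistic_or(s, y, "per_10pct_score")
        assert per10.or_ == pytest.approx(unit.or_**0.1, rel=1e-4)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="variation"):
            univariable_logistic_or(np.ones(20), np.repeat([0, 1], 10))

    def test_separation_rejected(self):
        x = np.repeat([0.0, 1.0], 20)
        y = np.repeat([0, 1], 20)
        with pytest.raises(ValueError):
            univariable_logistic_or(x, y)


class TestMultivariableLogistic:
    def _data(self, n=400, seed=0):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(
            {
                "signal": rng.normal(size=n),
                "noise1": rng.normal(size=n),
                "noise2": rng.random(n) < 0.5,
            }
        )
        logit = -0.5 + 1.2 * X["signal"]
        y = rng.random(n) < 1 / (1 + np.exp(-logit))
        return X, y

    def test_adjusted_matches_univariable_under_independence(self):
        X, y = self._data()
        mva = multivariable_logistic(X, y)
        uva = univariable_logistic_or(X["signal"], y)
        assert mva.loc["signal", "or"] == pytest.approx(uva.or_, rel=0.15)
        assert mva.loc["signal", "ci_low"] < uva.or_ < mva.loc["signal", "ci_high"]

    def test_pure_noise_column_leaves_others_stable(self):
        X, y = self._data(seed=1)
        base = multivariable_logistic(X[["signal"]], y)
        with_noise = multivariable_logistic(X, y)
        assert with_noise.loc["signal", "or"] == pytest.approx(
            base.loc["signal", "or"], rel=0.1
        )

    def test_collinear_column_dropped_with_warning(self):
        X, y = self._data(seed=2)
        X["dup"] = 2 * X["signal"]
        with pytest.warns(UserWarning, match="rank-deficient"):
            mva = multivariable_logistic(X, y)
        assert "dup" not in mva.index

    def test_intercept_only_returns_empty(self):
        y = np.repeat([0, 1], 15)
        X = pd.DataFrame({"c": np.ones(30)})
        with pytest.warns(UserWarning, match="constant"):
            out = multivariable_logistic(X, y)
        assert out.empty

    def test_treatment_adjustment_requires_table(self):
        X, y = self._data(seed=3)
        with pytest.raises(ValueError, match="treatment"):
            multivariable_logistic(X, y, adjust_for_treatment=True)


class TestAUC:
    def test_brute_force_pair_counting(self):
        """Oracle: concordant case-control pairs / all pairs."""
        rng = np.random.default_rng(5)
        s = rng.normal(size=40)
        y = rng.random(40) < 0.4
        wins = sum(
            (1.0 if si > sj else 0.5 if si == sj else 0.0)
            for si in s[y]
            for sj in s[~y]
        )
        expect = wins / (y.sum() * (~y).sum())
        got = auc_with_ci(s, y, n_boot=10, seed=0).auc
        assert got == pytest.approx(expect, abs=1e-12)

    def test_known_small_example(self):
        r = auc_with_ci([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1], n_boot=50, seed=0)
        assert r.auc == pytest.approx(0.75)

    def test_perfect_separation(self):
        r = auc_with_ci([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0], n_boot=50, seed=0)
        assert r.auc == 1.0

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(7)
        s = rng.normal(size=800)
        y = rng.random(800) < 0.5
        r = auc_with_ci(s, y, n_boot=200, seed=1)
        assert abs(r.auc - 0.5) < 0.07
        assert r.ci_low <= 0.5 <= r.ci_high

    def test_complement_property(self):
        rng = np.random.default_rng(9)
        s = rng.permutation(100) / 100.0  # tie-free
        y = rng.random(100) < 0.4
        a1 = auc_with_ci(s, y, n_boot=10, seed=0).auc
        a2 = auc_with_ci(-s, y, n_boot=10, seed=0).auc
        assert a1 + a2 == pytest.approx(1.0)

    def test_all_tied_scores_give_half(self):
        r = auc_with_ci(np.ones(20), np.repeat([0, 1], 10), n_boot=10, seed=0)
        assert r.auc == pytest.approx(0.5)

    def test_delong_interval_contains_estimate(self):
        rng = np.random.default_rng(11)
        y = np.repeat([True, False], 50)
        s = np.where(y, 0.3, 0.0) + rng.normal(size=100)
        r = auc_with_ci(s, y, method="delong")
        assert r.ci_low <= r.auc <= r.ci_high
        assert 0 < r.ci_high - r.ci_low < 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            auc_with_ci([0.1, 0.2], [1, 1], n_boot=10, seed=0)


class TestKaplanMeier:
    def test_hand_computed_product_limit(self):
        """n=4, events at 1 and 2, censoring at 1.5 and 3:
        S = 1 -> 0.75 (t=1) -> 0.375 (t=2)."""
        r = km_logrank([1, 1.5, 2, 3], [True, False, True, False], ["g"] * 4)
        curve = r.curves["g"].set_index("time")["survival"]
        assert curve.loc[1.0] == pytest.approx(0.75)
        assert curve.loc[2.0] == pytest.approx(0.375)
        assert r.medians["g"] == pytest.approx(2.0)

    def test_no_events_flat_curve_median_undefined(self):
        r = km_logrank([1, 2, 3], [False] * 3, ["g"] * 3)
        assert (r.curves["g"]["survival"] == 1.0).all()
        assert np.isnan(r.medians["g"])

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(5, size=60).round(2)
        r = km_logrank(t, [True] * 60, ["g"] * 60)
        curve = r.curves["g"]
        for time, surv in zip(curve["time"], curve["survival"]):
            assert surv == pytest.approx((t > time).mean(), abs=1e-12)

    def test_identical_groups_logrank_null(self):
        t = np.array([1, 2, 3, 4, 5, 6], dtype=float)
        e = np.array([1, 0, 1, 1, 0, 1], dtype=bool)
        r = km_logrank(np.r_[t, t], np.r_[e, e], ["a"] * 6 + ["b"] * 6)
        assert r.logrank_p == pytest.approx(1.0, abs=1e-6)

    def test_separated_groups_small_p(self):
        ta = np.linspace(0.5, 2, 20)
        tb = np.linspace(8, 12, 20)
        r = km_logrank(np.r_[ta, tb], [True] * 40, ["a"] * 20 + ["b"] * 20)
        assert r.logrank_p < 1e-6

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            km_logrank([-1, 2], [True, True], ["g", "g"])


class TestReclassification:
    def test_all_low_scores_empty_high_column(self):
        gs = [6, 7, 8, 9, 7]
        tab = reclassification_table(gs, [0.1] * 5, [False] * 5, [False] * 5)
        high = tab.xs("GC>0.5", level="gc_risk")
        assert (high["n"] == 0).all()

    def test_counts_partition_cohort(self):
        rng = np.random.default_rng(1)
        n = 150
        gs = rng.integers(5, 11, size=n)
        sc = rng.random(n)
        met = rng.random(n) < 0.3
        pcsm = met & (rng.random(n) < 0.5)
        tab = reclassification_table(gs, sc, met, pcsm)
        assert tab["n"].sum() == n
        assert (tab["n_pcsm"] <= tab["n_met"]).all()
        assert (tab["n_met"] <= tab["n"]).all()

    def test_percentage_rounding_matches_report_style(self):
        gs = [6] * 18
        met = [True] * 2 + [False] * 16
        tab = reclassification_table(gs, [0.2] * 18, met, [False] * 18)
        assert tab.loc[("<=6", "GC<=0.5"), "pct_met"] == 11  # 2/18 -> 11%

    def test_gleason_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="2..10"):
            reclassification_table([11], [0.1], [False], [False])


def test_km_and_roc_plots_render():
    import matplotlib

    matplotlib.use("Agg")
    from earlymet.evaluate import plot_roc

    r = km_logrank([1, 2, 3, 4], [True, True, False, True], ["a", "a", "b", "b"])
    ax = r.plot()
    assert ax.get_ylabel() == "survival probability"
    ax2 = plot_roc([0.1, 0.9, 0.3, 0.7], [0, 1, 0, 1], label="gc")
    assert ax2.get_xlabel() == "1 - specificity"


class TestMedianFollowup:
    def test_no_deaths_is_plain_median(self):
        assert median_followup([1, 2, 3, 4, 5], [False] * 5) == pytest.approx(3.0)

    def test_all_deaths_not_reached(self):
        assert np.isnan(median_followup([1, 2, 3], [True] * 3))

    def test_hand_computed_reverse_km(self):
        """6 patients, deaths at 3 and 5 censored in the reverse curve:
        S_rev = 5/6 (t=2) -> 0.625 (t=4) -> 0.3125 (t=6); median 6."""
        t = [2, 3, 4, 5, 6, 7]
        dead = [False, True, False, True, False, False]
        assert median_followup(t, dead) == pytest.approx(6.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            median_followup([], [])
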