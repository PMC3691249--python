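"""Forest assembly, backward elimination, tuning, clinical and integrated
models, risk dichotomisation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import earlymet as em
from earlymet.classifier import (
    ClinicalClassifier,
    ForestConfig,
    GenomicClassifier,
    GenomicClassifierResults,
    IntegratedClassifier,
    backward_eliminate,
    classify_risk,
    risk_calls,
    train_gc,
    tune_forest,
)

FAST = ForestConfig(n_trees=60, cv_folds=5, tune_boot=5, seed=0)


def _signal_data(n_inf=6, n_null=14, n_per=40, shift=2.0, seed=0):
    rng = np.random.default_rng(seed)
    p = n_inf + n_null
    X = rng.normal(size=(p, 2 * n_per))
    y = np.array([True] * n_per + [False] * n_per)
    X[:n_inf, y] += shift
    ids = [f"INF{i}" if i < n_inf else f"NULL{i}" for i in range(p)]
    expr = pd.DataFrame(X, index=ids, columns=[f"S{j}" for j in range(2 * n_per)])
    return expr, y


class TestBackwardElimination:
    def test_two_candidates_curve_shape(self):
        expr, y = _signal_data(n_inf=2, n_null=0)
        curve = backward_eliminate(expr, y, list(expr.index), FAST)
        assert curve.sizes == [2, 1]
        assert curve.chosen_size in (1, 2)
        assert len(curve.chosen_features) == curve.chosen_size

    def test_chosen_mse_not_worse_than_full_set(self):
        expr, y = _signal_data(seed=3)
        curve = backward_eliminate(expr, y, list(expr.index), FAST)
        chosen_mse = curve.cv_mse[curve.sizes.index(curve.chosen_size)]
        assert chosen_mse <= curve.cv_mse[0]
        assert curve.sizes == sorted(curve.sizes, reverse=True)
        assert set(curve.chosen_features) <= set(expr.index)

    def test_curve_plot_renders(self):
        import matplotlib

        matplotlib.use("Agg")
        expr, y = _signal_data(n_inf=2, n_null=0)
        curve = backward_eliminate(expr, y, list(expr.index), FAST)
        ax = curve.plot()
        assert ax.get_ylabel() == "10-fold CV MSE"

    def test_empty_candidates_rejected(self):
        expr, y = _signal_data()
        with pytest.raises(ValueError, match="no candidate"):
            backward_eliminate(expr, y, [], FAST)

    def test_recovers_informative_markers_prunes_noise(self):
        """With k complementary markers among noise, the knee keeps (nearly)
        all informative features and discards most noise."""
        k, good = 6, 0
        for seed in range(4):
            expr, y = _signal_data(n_inf=k, n_null=24, n_per=60, shift=0.8,
                                   seed=40 + seed)
            curve = backward_eliminate(
                expr, y, list(expr.index), FAST.replace(seed=seed)
            )
            inf_kept = sum(f.startswith("INF") for f in curve.chosen_features)
            noise_kept = curve.chosen_size - inf_kept
            good += inf_kept >= k - 1 and noise_kept <= 8
        assert good >= 3


class TestTuneForest:
    def test_single_cell_grid_returned(self):
        expr, y = _signal_data()
        cfg = FAST.replace(mtry_grid=(3,), nodesize_grid=(2,))
        assert tune_forest(expr, y, list(expr.index), cfg) == (3, 2)

    def test_oversized_mtry_skipped_with_warning(self):
        expr, y = _signal_data(n_inf=3, n_null=0)
        cfg = FAST.replace(mtry_grid=(2, 50), nodesize_grid=(1,))
        with pytest.warns(UserWarning, match="mtry=50"):
            m, ns = tune_forest(expr, y, list(expr.index), cfg)
        assert m == 2

    def test_all_cells_skipped_raises(self):
        expr, y = _signal_data(n_inf=3, n_null=0)
        cfg = FAST.replace(mtry_grid=(50,))
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="skipped"):
                tune_forest(expr, y, list(expr.index), cfg)

    def test_degenerate_nodesize_never_wins(self):
        """A nodesize >= the fitting-set size produces majority-vote trees
        and loses to any informative cell on separable data."""
        expr, y = _signal_data(n_inf=4, n_null=2, shift=4.0, seed=9)
        cfg = FAST.replace(mtry_grid=(2,), nodesize_grid=(1, 500), tune_boot=10)
        _, ns = tune_forest(expr, y, list(expr.index), cfg)
        assert ns == 1

    def test_tie_breaks_deterministic(self):
        """On perfectly separable data many cells reach accuracy 1; the
        smallest nodesize then smallest mtry wins."""
        expr, y = _signal_data(n_inf=4, n_null=0, shift=8.0, seed=10)
        cfg = FAST.replace(mtry_grid=(1, 2, 4), nodesize_grid=(1, 2), tune_boot=5)
        assert tune_forest(expr, y, list(expr.index), cfg) == (1, 1)


class TestGenomicClassifier:
    def test_separable_training_scores(self):
        expr, y = _signal_data(n_inf=5, n_null=5, shift=4.0, seed=11)
        gc = train_gc(expr, y, list(expr.index), 3, 1, FAST)
        s = gc.predict(expr)
        assert (s[y] > 0.5).all() and (s[~y] < 0.5).all()
        assert s.between(0, 1).all()

    def test_deterministic_given_seed(self):
        expr, y = _signal_data(seed=12)
        s1 = train_gc(expr, y, list(expr.index), 4, 1, FAST).predict(expr)
        s2 = train_gc(expr, y, list(expr.index), 4, 1, FAST).predict(expr)
        pd.testing.assert_series_equal(s1, s2)

    def test_monotone_rescaling_invariance(self):
        """Affinely rescaling one feature in train and test leaves forest
        scores unchanged (tree splits adapt with the scale)."""
        expr, y = _signal_data(seed=13)
        s1 = train_gc(expr, y, list(expr.index), 4, 1, FAST).predict(expr)
        expr2 = expr.copy()
        expr2.loc["INF0"] = 3.0 * expr2.loc["INF0"] + 7.0
        s2 = train_gc(expr2, y, list(expr2.index), 4, 1, FAST).predict(expr2)
        assert np.allclose(s1.to_numpy(), s2.to_numpy())

    def test_single_class_rejected(self):
        expr, _ = _signal_data()
        with pytest.raises(ValueError, match="both classes"):
            train_gc(expr, np.ones(expr.shape[1], bool), list(expr.index), 2, 1, FAST)

    def test_model_round_trip(self, tmp_path):
        expr, y = _signal_data(seed=14)
        gc = train_gc(expr, y, list(expr.index), 4, 2, FAST)
        gc.save(tmp_path / "gc")
        back = GenomicClassifierResults.load(tmp_path / "gc")
        pd.testing.assert_series_equal(gc.predict(expr), back.predict(expr))
        assert back.features == gc.features and back.nodesize == 2

    def test_fit_pipeline_object(self):
        expr, y = _signal_data(n_inf=5, n_null=10, shift=2.5, seed=15)
        res = GenomicClassifier(expr, y, config=FAST).fit()
        assert res.elimination is not None
        assert set(res.features) == set(res.elimination.chosen_features)
        assert res.predict(expr).between(0, 1).all()
        assert "random forest" in res.summary()


class TestClinicalClassifier:
    def test_single_binary_covariate_matches_contingency_or(self):
        """Logistic OR on a lone binary covariate equals ad/(bc) exactly."""
        from tests.conftest import toy_annotation

        a, b, c, d = 20, 10, 10, 25
        annot = toy_annotation(svi_counts=(a, b, c, d))
        res = ClinicalClassifier(annot).fit()
        ors = res.odds_ratios()
        assert ors.loc["svi", "or"] == pytest.approx(a * d / (b * c), rel=1e-6)

    def test_constant_covariates_give_intercept_only(self):
        from tests.conftest import toy_annotation

        annot = toy_annotation(svi_counts=(15, 20, 0, 0))
        annot["svi"] = True  # now everything is constant
        res = ClinicalClassifier(annot).fit()
        assert res.odds_ratios().empty
        scores = res.predict(annot)
        assert np.allclose(scores, annot["is_case"].mean())

    def test_missing_ppsa_median_imputed_with_indicator(self):
        from tests.conftest import toy_annotation

        annot = toy_annotation()
        rng = np.random.default_rng(0)
        annot["ppsa"] = rng.permutation(np.linspace(2, 40, len(annot)))
        miss = [0, 1, 13, 14]  # two cases, two controls
        annot.iloc[miss, annot.columns.get_loc("ppsa")] = np.nan
        res = ClinicalClassifier(annot).fit()
        assert res.ppsa_median == pytest.approx(annot["ppsa"].median())
        assert "ppsa_missing" in res.covariates
        assert res.predict(annot).between(0, 1).all()

    def test_separation_raises_clear_error(self):
        from tests.conftest import toy_annotation

        annot = toy_annotation(svi_counts=(20, 0, 0, 20))  # svi == is_case
        with pytest.raises(ValueError, match="svi|separation"):
            ClinicalClassifier(annot).fit()


class TestIntegratedClassifier:
    def test_constant_cc_falls_back_to_gc(self):
        rng = np.random.default_rng(3)
        y = np.repeat([True, False], 30)
        gc = np.clip(0.5 + 0.3 * (y - 0.5) + 0.1 * rng.normal(size=60), 0, 1)
        cc = np.full(60, 0.4)
        with pytest.warns(UserWarning, match="no independent"):
            res = IntegratedClassifier(pd.Series(gc), pd.Series(cc), y).fit()
        s = res.predict(pd.Series(gc), pd.Series(cc))
        order = np.argsort(gc)
        assert (np.diff(s.to_numpy()[order]) >= -1e-12).all()

    def test_collinear_scores_handled(self):
        rng = np.random.default_rng(4)
        y = np.repeat([True, False], 25)
        gc = np.clip(0.5 + 0.25 * (y - 0.5) + 0.15 * rng.normal(size=50), 0, 1)
        with pytest.warns(UserWarning, match="no independent"):
            res = IntegratedClassifier(pd.Series(gc), pd.Series(gc.copy()), y).fit()
        assert res.dropped == "cc"
        assert res.predict(pd.Series(gc), pd.Series(gc)).between(0, 1).all()


class TestRiskCalls:
    @pytest.mark.parametrize(
        "score,expected", [(0.5, "low"), (0.51, "high"), (0.0, "low"), (1.0, "high")]
    )
    def test_threshold_boundaries(self, score, expected):
        assert classify_risk(score).risk == expected

    @pytest.mark.parametrize("score", [-0.1, 1.1])
    def test_out_of_range_rejected(self, score):
        with pytest.raises(ValueError):
            classify_risk(score)

    @given(st.floats(min_value=0.0, max_value=1.0))
    def test_risk_matches_strict_threshold(self, score):
        assert classify_risk(score).risk == ("high" if score > 0.5 else "low")

    def test_vectorised_matches_scalar(self):
        s = pd.Series([0.0, 0.5, 0.500001, 0.99])
        assert list(risk_calls(s)) == [classify_risk(v).risk for v in s]
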