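"""Correlative SDM: screening, evaluation metrics, RF training, prediction."""

import numpy as np
import pandas as pd
import pytest

import pestcast as pc
from pestcast.sdm import (
    PredictorTable,
    evaluate,
    extract_predictors,
    kappa_from_confusion,
    lasso_screen,
    pearson_filter,
    predict_raster,
    screen_predictors,
    train_rf_cv,
    tss_from_confusion,
)


def make_table(X, y, names=None):
    names = names or [f"bio{i+1}" for i in range(X.shape[1])]
    return PredictorTable(data=pd.DataFrame(X, columns=names), labels=y)


class TestPearsonFilter:
    def test_duplicated_column_dropped(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=50)
        X = np.column_stack([a, a.copy(), rng.normal(size=50)])
        y = np.r_[np.ones(25), np.zeros(25)].astype(int)
        kept = pearson_filter(make_table(X, y))
        assert kept == ["bio1", "bio3"]

    def test_uncorrelated_set_is_identity(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(200, 4))
        y = rng.integers(0, 2, 200)
        y[:2] = [0, 1]
        kept = pearson_filter(make_table(X, y))
        assert kept == ["bio1", "bio2", "bio3", "bio4"]

    def test_retained_set_matches_exhaustive_check(self):
        rng = np.random.default_rng(2)
        z = rng.normal(size=100)
        X = np.column_stack(
            [
                z,
                z + 0.1 * rng.normal(size=100),       # ~r=0.99 with col 1
                rng.normal(size=100),
                -z + 0.05 * rng.normal(size=100),      # ~r=-1 with col 1
                rng.normal(size=100),
            ]
        )
        y = np.r_[np.ones(50), np.zeros(50)].astype(int)
        table = make_table(X, y)
        kept = pearson_filter(table, threshold=0.8)
        # the retained set must be pairwise below threshold…
        sub = table.data[kept].to_numpy()
        corr = np.corrcoef(sub, rowvar=False)
        off = corr[~np.eye(len(kept), dtype=bool)]
        assert np.all(np.abs(off) <= 0.8)
        # …and every dropped column must conflict with an earlier retained one
        for name in table.variables:
            if name in kept:
                continue
            rs = [
                abs(np.corrcoef(table.data[name], table.data[k])[0, 1])
                for k in kept
                if table.variables.index(k) < table.variables.index(name)
            ]
            assert max(rs) > 0.8

    def test_constant_column_dropped_with_warning(self):
        X = np.column_stack([np.ones(30), np.random.default_rng(3).normal(size=30)])
        y = np.r_[np.ones(15), np.zeros(15)].astype(int)
        with pytest.warns(UserWarning, match="constant"):
            kept = pearson_filter(make_table(X, y))
        assert kept == ["bio2"]


class TestLassoScreen:
    def test_separating_variable_retained(self):
        rng = np.random.default_rng(4)
        x1 = rng.normal(size=300)
        X = np.column_stack([x1, rng.normal(size=300), rng.normal(size=300)])
        y = (x1 + 0.2 * rng.normal(size=300) > 0).astype(int)
        kept = lasso_screen(make_table(X, y), seed=4)
        assert "bio1" in kept

    def test_null_signal_falls_back_with_warning(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(120, 4))
        y = rng.integers(0, 2, 120)
        y[:2] = [0, 1]
        table = make_table(X, y)
        selected = lasso_screen(table, seed=5)
        if not selected:  # strong penalty zeroed everything
            with pytest.warns(UserWarning, match="falling back"):
                out = screen_predictors(table, seed=5)
            assert out == pearson_filter(table)
        else:  # weak-signal draw: screen output must still be a subset
            assert set(selected) <= set(table.variables)

    def test_single_class_rejected(self):
        X = np.random.default_rng(6).normal(size=(20, 3))
        table = make_table(X, np.r_[np.ones(18), np.zeros(2)].astype(int))
        table.labels[:] = 1
        with pytest.raises(ValueError):
            lasso_screen(table)


class TestEvaluate:
    def test_perfect_scores(self):
        y = np.r_[np.ones(10), np.zeros(10)].astype(int)
        auc, tss, kappa, _ = evaluate(y.astype(float), y)
        assert (auc, tss, kappa) == (1.0, 1.0, 1.0)

    def test_printed_confusion_hand_computation(self):
        # TP=40, FN=10, TN=45, FP=5: sens .8, spec .9
        assert tss_from_confusion(40, 10, 45, 5) == pytest.approx(0.7)
        assert kappa_from_confusion(40, 10, 45, 5) == pytest.approx(0.70)

    def test_reversed_scores_give_zero_auc(self):
        y = np.r_[np.ones(10), np.zeros(10)].astype(int)
        auc, _, _, _ = evaluate(1.0 - y, y)
        assert auc == 0.0

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(7)
        scores = rng.random(200)
        y = (scores + 0.3 * rng.normal(size=200) > 0.5).astype(int)
        auc1, *_ = evaluate(scores, y)
        auc2, *_ = evaluate(scores**3, y)
        auc3, *_ = evaluate(1 / (1 + np.exp(-8 * (scores - 0.4))), y)
        assert auc1 == pytest.approx(auc2) == pytest.approx(auc3)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            evaluate(np.array([0.2, 0.8]), np.array([1, 1]))


class TestTrainRF:
    def test_perfectly_separable_fixture(self):
        rng = np.random.default_rng(8)
        y = np.r_[np.ones(60), np.zeros(60)].astype(int)
        X = np.column_stack([y * 10 + rng.normal(0, 0.1, 120), rng.normal(size=120)])
        _, ev, imp = train_rf_cv(make_table(X, y), folds=5, n_trees=100, seed=8)
        assert ev.auc == 1.0
        assert ev.tss == 1.0
        assert ev.kappa == 1.0
        assert imp.contributions.sum() == pytest.approx(100.0, abs=0.1)
        assert imp.top(1) == ["bio1"]

    def test_importance_normalization_contract(self, small_bioclim):
        occ, _ = pc.sample_presences_logistic(
            small_bioclim, {"bio1": 2.0}, 40, 40, seed=9
        )
        table = extract_predictors(small_bioclim, occ)
        _, ev, imp = train_rf_cv(table, folds=3, n_trees=50, seed=9)
        assert imp.contributions.sum() == pytest.approx(100.0, abs=0.1)
        assert len(ev.auc_folds) == 3
        assert ev.auc == pytest.approx(np.mean(ev.auc_folds))


class TestPredictRaster:
    def test_probability_bounds_and_nodata(self, small_bioclim):
        occ, _ = pc.sample_presences_logistic(
            small_bioclim, {"bio1": 2.0}, 50, 50, seed=10
        )
        table = extract_predictors(small_bioclim, occ)
        model, _, _ = train_rf_cv(table, folds=3, n_trees=50, seed=10)
        grid = pc.BioclimGrid(
            lat_axis=small_bioclim.lat_axis,
            lon_axis=small_bioclim.lon_axis,
            layers={k: v.copy() for k, v in small_bioclim.layers.items()},
            valid=small_bioclim.valid.copy(),
        )
        for name in grid.layers:
            grid.layers[name][0, 0] = np.nan
        prob = predict_raster(model, grid, table.variables)
        assert np.isnan(prob[0, 0])
        finite = prob[np.isfinite(prob)]
        assert np.all((finite >= 0) & (finite <= 1))

    def test_missing_layer_is_named(self, small_bioclim):
        occ, _ = pc.sample_presences_logistic(small_bioclim, {"bio1": 2.0}, 30, 30, seed=11)
        table = extract_predictors(small_bioclim, occ)
        model, _, _ = train_rf_cv(table, folds=3, n_trees=20, seed=11)
        grid = pc.BioclimGrid(
            lat_axis=small_bioclim.lat_axis,
            lon_axis=small_bioclim.lon_axis,
            layers={"bio1": small_bioclim["bio1"]},
            valid=small_bioclim.valid,
        )
        with pytest.raises(ValueError, match="bio2"):
            predict_raster(model, grid, ["bio1", "bio2"])
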