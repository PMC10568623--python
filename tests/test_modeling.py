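import warnings
from math import comb

import numpy as np
import pandas as pd
import pytest

from eegcog.modeling import (
    FeatureRanking,
    ModelEvaluation,
    assign_bilateral,
    classify_laterality,
    composite_search,
    correlation_filter,
    count_composite_subsets,
    feature_columns,
    fit_loo_strict,
    fit_regressors_loo,
    r_squared,
    rank_importance,
    select_top_k,
    summarize_selection,
)
from eegcog.synth import GROUP_COL, OUTCOME_COL, gen_feature_table


def toy_table(n=30, n_features=5, planted=((0, 1.0),), noise=0.1, seed=0):
    return gen_feature_table(n, n_features, planted=list(planted),
                             noise_sd=noise, seed=seed)


class TestRSquared:
    def test_hand_fixture(self):
        # y=[1,2,3], yhat=[1.1,1.9,3.2] -> SS_res=0.06, SS_tot=2, R2=0.97
        r2, ss_res, ss_tot = r_squared([1, 2, 3], [1.1, 1.9, 3.2])
        assert ss_res == pytest.approx(0.06, abs=1e-12)
        assert ss_tot == pytest.approx(2.0, abs=1e-12)
        assert r2 == pytest.approx(0.97, abs=1e-12)

    def test_identity_invariant(self, rng):
        y = rng.standard_normal(50)
        y_hat = y + 0.1 * rng.standard_normal(50)
        ev = ModelEvaluation.from_predictions("m", y, y_hat)
        assert ev.r2 == pytest.approx(1 - ev.ss_res / ev.ss_tot, abs=1e-12)
        assert ev.r2 <= 1.0

    def test_perfect_prediction(self):
        r2, _, _ = r_squared([1.0, 2.0, 4.0], [1.0, 2.0, 4.0])
        assert r2 == 1.0


class TestCorrelationFilter:
    def test_outcome_copy_retained(self):
        df = toy_table(noise=0.0)
        df["copy"] = df[OUTCOME_COL]
        filtered, corr = correlation_filter(df, 0.3)
        assert "copy" in filtered.columns
        assert corr["copy"] == pytest.approx(1.0)

    def test_constant_feature_excluded(self):
        df = toy_table()
        df["const"] = 3.0
        filtered, corr = correlation_filter(df, 0.3)
        assert "const" not in filtered.columns
        assert np.isnan(corr["const"])

    def test_planted_recovered_among_noise(self):
        # 7 noiseless planted features, 23 noise features, n=200
        df = gen_feature_table(
            200, 30, planted=[(i, 1.0) for i in range(7)], noise_sd=0.0, seed=3
        )
        filtered, _ = correlation_filter(df, 0.3)
        kept = set(feature_columns(filtered))
        assert {f"f{i}" for i in range(7)} <= kept
        assert len(kept - {f"f{i}" for i in range(7)}) <= 2

    def test_min_subjects(self):
        with pytest.raises(ValueError):
            correlation_filter(toy_table(n=2), 0.3)


class TestRankImportance:
    def test_single_feature_importance_one(self):
        df = toy_table(n_features=1)
        ranking = rank_importance(df, seed=0, n_estimators=50)
        assert ranking.normalized_importance[0] == pytest.approx(1.0)

    def test_normalization_contract(self):
        df = toy_table(n_features=8)
        ranking = rank_importance(df, seed=0, n_estimators=50)
        assert ranking.normalized_importance.sum() == pytest.approx(1.0, abs=1e-9)
        assert (np.diff(ranking.normalized_importance) <= 1e-12).all()

    def test_dominant_feature_ranks_first(self):
        wins = 0
        for seed in range(10):
            df = gen_feature_table(
                80, 6, planted=[(2, 10.0), (4, 1.0)], noise_sd=0.0, seed=seed
            )
            ranking = rank_importance(df, seed=seed, n_estimators=100)
            wins += ranking.features[0] == "f2"
        assert wins >= 9

    def test_deterministic(self):
        df = toy_table()
        a = rank_importance(df, seed=7)
        b = rank_importance(df, seed=7)
        assert a.features == b.features
        assert np.array_equal(a.normalized_importance, b.normalized_importance)

    def test_no_features_raises(self):
        df = toy_table()[["subject_id", GROUP_COL, OUTCOME_COL]]
        with pytest.raises(ValueError):
            rank_importance(df)


class TestSelectTopK:
    def make_ranking(self, n):
        imp = np.linspace(1.0, 0.1, n)
        imp = imp / imp.sum()
        return FeatureRanking(
            features=[f"f{i}" for i in range(n)],
            raw_importance=imp, normalized_importance=imp,
        )

    def test_top_20_of_30(self):
        sel = select_top_k(self.make_ranking(30), 20)
        assert sel == [f"f{i}" for i in range(20)]

    def test_shortfall_warns(self):
        with pytest.warns(RuntimeWarning, match="only 5"):
            sel = select_top_k(self.make_ranking(5), 20)
        assert len(sel) == 5

    def test_k1(self):
        assert select_top_k(self.make_ranking(5), 1) == ["f0"]

    def test_k_zero_rejected(self):
        with pytest.raises(ValueError):
            select_top_k(self.make_ranking(5), 0)


class TestSummarizeSelection:
    def ranking_for(self, names):
        imp = np.ones(len(names)) / len(names)
        return FeatureRanking(features=list(names), raw_importance=imp,
                              normalized_importance=imp)

    def test_all_theta(self):
        names = [f"theta_clustering_ROI{k}" for k in range(1, 21)]
        s = summarize_selection(names, self.ranking_for(names))
        assert s.band_counts == {"theta": 20}
        frame = s.as_frame()
        theta = frame[(frame.axis == "band") & (frame.category == "theta")]
        assert theta["count_pct"].iloc[0] == pytest.approx(100.0)

    def test_partition_contract(self):
        names = ([f"theta_clustering_ROI{k}" for k in range(1, 14)]
                 + [f"alpha2_nodal_efficiency_ROI{k}" for k in range(41, 48)])
        s = summarize_selection(names, self.ranking_for(names))
        assert sum(s.band_counts.values()) == 20
        frame = s.as_frame()
        for axis in ("band", "lobe"):
            sub = frame[frame.axis == axis]
            assert sub["count_pct"].sum() == pytest.approx(100.0, abs=0.1)
            assert sub["importance_pct"].sum() == pytest.approx(100.0, abs=0.1)

    def test_13_frontal_of_20(self):
        # 13 frontal (ROI 1-20) + 7 parietal nodal features
        names = ([f"theta_clustering_ROI{k}" for k in range(1, 14)]
                 + [f"theta_clustering_ROI{k}" for k in range(41, 48)])
        s = summarize_selection(names, self.ranking_for(names))
        assert s.lobe_counts["frontal"] == 13
        frame = s.as_frame()
        frontal = frame[(frame.axis == "lobe") & (frame.category == "frontal")]
        assert frontal["count_pct"].iloc[0] == pytest.approx(65.0)

    def test_global_features_bucketed(self):
        names = ["theta_global_efficiency", "theta_modularity"]
        s = summarize_selection(names, self.ranking_for(names))
        assert s.lobe_counts == {"global": 2}


class TestLaterality:
    def separable_table(self, n=20):
        rng = np.random.default_rng(0)
        side = ["left"] * (n // 2) + ["right"] * (n // 2)
        x = np.where(np.array(side) == "left", -1.0, 1.0)
        return pd.DataFrame({
            "subject_id": [f"S{i}" for i in range(n)],
            GROUP_COL: side,
            OUTCOME_COL: rng.standard_normal(n),
            "feat": x + 0.01 * rng.standard_normal(n),
        })

    def test_separable_perfect_accuracy(self):
        model = classify_laterality(self.separable_table(), seed=0,
                                    n_estimators=50)
        assert model.loo_accuracy == 1.0
        assert model.loo_sensitivity == 1.0
        assert model.loo_specificity == 1.0

    def test_single_class_rejected(self):
        df = self.separable_table()
        df[GROUP_COL] = "left"
        with pytest.raises(ValueError, match="left.*right|right.*left"):
            classify_laterality(df)

    def test_assign_bilateral_partition(self):
        df = self.separable_table()
        df.loc[df.index[:4], GROUP_COL] = "bilateral"
        model = classify_laterality(df, seed=0, n_estimators=50)
        assigned = assign_bilateral(model, df)
        assert set(assigned) <= {"left", "right"}
        assert len(assigned) == len(df)
        # unilateral subjects keep their true label
        uni = df[GROUP_COL].isin(["left", "right"])
        assert (assigned[uni] == df.loc[uni, GROUP_COL]).all()

    def test_no_bilateral_identity(self):
        df = self.separable_table()
        model = classify_laterality(df, seed=0, n_estimators=50)
        assigned = assign_bilateral(model, df)
        assert (assigned == df[GROUP_COL]).all()

    def test_bilateral_near_left_centroid_assigned_left(self):
        df = self.separable_table()
        extra = df.iloc[[0]].copy()
        extra["subject_id"] = "B0"
        extra[GROUP_COL] = "bilateral"
        extra["feat"] = -1.0  # left-group centroid
        df2 = pd.concat([df, extra], ignore_index=True)
        model = classify_laterality(df2, seed=0, n_estimators=50)
        assigned = assign_bilateral(model, df2)
        assert assigned.iloc[-1] == "left"


class TestFitRegressorsLoo:
    def test_noiseless_linear_ridge(self):
        df = toy_table(n=30, n_features=3, planted=((0, 2.0), (1, -1.0)),
                       noise=0.0)
        evals = fit_regressors_loo(df, ["f0", "f1", "f2"], models=("ridge",))
        assert evals["ridge"].r2 >= 0.99

    def test_pure_noise_low_r2(self):
        r2s = []
        for seed in range(20):
            df = toy_table(n=30, n_features=3, planted=(), noise=1.0, seed=seed)
            ev = fit_regressors_loo(df, ["f0", "f1", "f2"], models=("ridge",),
                                    seed=seed)["ridge"]
            assert ev.r2 <= 1.0
            r2s.append(ev.r2)
        assert np.mean(r2s) <= 0.1

    def test_all_five_models_run(self):
        df = toy_table(n=15)
        evals = fit_regressors_loo(df, ["f0", "f1"])
        assert set(evals) == {"ridge", "lasso", "elasticnet", "svr", "adaboost"}

    def test_unknown_model_rejected(self):
        df = toy_table(n=10)
        with pytest.raises(ValueError, match="unknown model"):
            fit_regressors_loo(df, ["f0"], models=("xgboost",))

    def test_no_leakage(self):
        # perturbing subject i's outcome never changes subject i's LOO
        # prediction
        df = toy_table(n=20, seed=1)
        base = fit_regressors_loo(df, ["f0", "f1"], models=("ridge",))["ridge"]
        rng = np.random.default_rng(0)
        for _ in range(5):
            i = int(rng.integers(len(df)))
            mod = df.copy()
            mod.loc[mod.index[i], OUTCOME_COL] += rng.normal(0, 10)
            pert = fit_regressors_loo(mod, ["f0", "f1"], models=("ridge",))["ridge"]
            assert pert.y_hat[i] == pytest.approx(base.y_hat[i], abs=1e-10)

    def test_deterministic(self):
        df = toy_table(n=15)
        a = fit_regressors_loo(df, ["f0"], models=("adaboost",), seed=3)["adaboost"]
        b = fit_regressors_loo(df, ["f0"], models=("adaboost",), seed=3)["adaboost"]
        assert np.array_equal(a.y_hat, b.y_hat)


class TestStrictMode:
    def test_runs_and_bounded(self):
        df = gen_feature_table(25, 10, planted=[(0, 2.0)], noise_sd=0.5, seed=0)
        evals = fit_loo_strict(df, models=("ridge",), seed=0, n_estimators=25)
        assert evals["ridge"].r2 <= 1.0

    def test_recovers_strong_signal(self):
        df = gen_feature_table(40, 10, planted=[(0, 2.0)], noise_sd=0.1, seed=1)
        evals = fit_loo_strict(df, models=("ridge",), seed=0, n_estimators=25)
        assert evals["ridge"].r2 >= 0.5


class TestCompositeSearch:
    def ranking(self, n=20):
        imp = np.linspace(1, 0.1, n)
        imp /= imp.sum()
        return FeatureRanking(features=[f"f{i}" for i in range(n)],
                              raw_importance=imp, normalized_importance=imp)

    def test_count_single_subset(self):
        assert count_composite_subsets(5, 15, range(5, 6), 5) == 1

    def test_count_identity(self):
        expected = (comb(5, 3) * sum(comb(15, b) for b in range(8))
                    + comb(5, 4) * sum(comb(15, b) for b in range(7))
                    + comb(5, 5) * sum(comb(15, b) for b in range(6)))
        assert count_composite_subsets(5, 15, range(3, 6), 10) == expected

    def test_search_sorted_and_contains_best(self):
        df = gen_feature_table(25, 20, planted=[(0, 2.0), (1, 1.0)],
                               noise_sd=0.3, seed=0)
        rk = self.ranking(20)
        evals = composite_search(
            rk, df, top_pool=3, bottom_pool=4, top_take=range(2, 4),
            max_total=4, max_models=30, model="ridge", seed=0,
        )
        r2s = [e.r2 for e in evals]
        assert r2s == sorted(r2s, reverse=True)

    def test_superset_dominates_topk(self):
        # best composite R2 >= plain top-k model when top-k is in the space
        df = gen_feature_table(25, 20, planted=[(0, 2.0)], noise_sd=0.3, seed=2)
        rk = self.ranking(20)
        evals = composite_search(
            rk, df, top_pool=3, bottom_pool=3, top_take=range(3, 4),
            max_total=6, max_models=100, model="ridge", seed=0,
        )
        plain = fit_regressors_loo(df, rk.features[:3], models=("ridge",),
                                   seed=0)["ridge"]
        assert evals[0].r2 >= plain.r2 - 1e-12

    def test_empty_search_raises(self):
        df = gen_feature_table(10, 20, planted=[], noise_sd=1.0, seed=0)
        rk = self.ranking(20)
        with pytest.raises(ValueError, match="zero subsets"):
            composite_search(rk, df, top_pool=3, bottom_pool=3,
                             top_take=range(5, 6), max_total=10)

    def test_too_few_features(self):
        df = toy_table()
        rk = self.ranking(5)
        with pytest.raises(ValueError, match="need >="):
            composite_search(rk, df, top_pool=5, bottom_pool=15)

    def test_subsample_seeded(self):
        df = gen_feature_table(15, 20, planted=[(0, 1.0)], noise_sd=0.5, seed=0)
        rk = self.ranking(20)
        kwargs = dict(top_pool=4, bottom_pool=5, top_take=range(2, 4),
                      max_total=5, max_models=10, model="ridge")
        a = composite_search(rk, df, seed=3, **kwargs)
        b = composite_search(rk, df, seed=3, **kwargs)
        assert [e.features for e in a] == [e.features for e in b]
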