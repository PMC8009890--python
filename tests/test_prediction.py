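"""Tests for the classification and regression stages."""

import numpy as np
import pandas as pd
import pytest

from erpstates import (
    GaParams,
    bootstrap_ci,
    confusion_metrics,
    elasticnet_nested,
    evaluate_classifier,
    ga_select,
    shuffle_test,
    stratified_split,
    svm_cv_auc,
)
from erpstates.prediction import build_feature_table, feature_columns


def feature_frame(X, y=None, vabs=None):
    df = pd.DataFrame(X, columns=[f"f{i:02d}" for i in range(X.shape[1])])
    if y is not None:
        df["asd_outcome"] = y
    if vabs is not None:
        df["vabs_socialization"] = vabs
    return df


class TestStratifiedSplit:
    def test_cohort_sizes_match_the_70_30_design(self, rng):
        y = np.concatenate([np.ones(19, bool), np.zeros(72, bool)])
        df = feature_frame(rng.standard_normal((91, 4)), y)
        train, holdout = stratified_split(df, 0.7, seed=0)
        assert len(train) == 64 and len(holdout) == 27
        assert train["asd_outcome"].sum() in (13, 14)
        assert set(train.index).isdisjoint(holdout.index)
        assert len(train) + len(holdout) == 91

    def test_degenerate_fraction_rejected(self, rng):
        df = feature_frame(rng.standard_normal((20, 2)),
                           np.arange(20) < 5)
        with pytest.raises(ValueError):
            stratified_split(df, 1.0, seed=0)

    def test_tiny_class_rejected(self, rng):
        df = feature_frame(rng.standard_normal((10, 2)), np.arange(10) < 1)
        with pytest.raises(ValueError):
            stratified_split(df, 0.7, seed=0)

    def test_same_seed_same_partition(self, rng):
        df = feature_frame(rng.standard_normal((40, 3)), np.arange(40) < 10)
        a = stratified_split(df, 0.7, seed=5)
        b = stratified_split(df, 0.7, seed=5)
        pd.testing.assert_frame_equal(a[0], b[0])


class TestSvmCvAuc:
    def test_perfect_separation(self, rng):
        y = np.arange(60) < 20
        X = rng.standard_normal((60, 3))
        X[:, 1] = np.where(y, 5.0, -5.0) + 0.01 * rng.standard_normal(60)
        df = feature_frame(X, y)
        mask = np.array([False, True, False])
        assert svm_cv_auc(df, mask, folds=10, seed=0) == pytest.approx(1.0)

    def test_null_labels_near_chance(self, rng):
        n = 200
        aucs = [
            svm_cv_auc(
                feature_frame(rng.standard_normal((n, 5)),
                              rng.permutation(np.arange(n) < 70)),
                None, folds=10, seed=r,
            )
            for r in range(3)
        ]
        assert abs(np.mean(aucs) - 0.5) < 0.1

    def test_empty_mask_rejected(self, rng):
        df = feature_frame(rng.standard_normal((20, 3)), np.arange(20) < 8)
        with pytest.raises(ValueError):
            svm_cv_auc(df, np.zeros(3, bool))


class TestConfusionMetrics:
    def test_worked_case(self):
        m = confusion_metrics(tp=2, fn=3, tn=5, fp=0)
        assert m["sensitivity"] == pytest.approx(40.0)
        assert m["specificity"] == pytest.approx(100.0)
        assert m["ppv"] == pytest.approx(100.0)
        assert m["npv"] == pytest.approx(62.5)
        assert m["accuracy"] == pytest.approx(70.0)

    def test_all_negative_predictor(self):
        m = confusion_metrics(tp=0, fn=3, tn=7, fp=0)
        assert m["sensitivity"] == 0.0
        assert m["specificity"] == 100.0
        assert np.isnan(m["ppv"])


class TestEvaluateClassifier:
    def _separable(self, rng, n=60):
        y = np.arange(n) < n // 3
        X = rng.standard_normal((n, 4))
        X[:, 0] += np.where(y, 8.0, -8.0)
        return feature_frame(X, y)

    def test_holdout_equals_train_separable(self, rng):
        df = self._separable(rng)
        rep = evaluate_classifier(df, df, ["f00"], n_repetitions=20, seed=0)
        for name in ("auc", "sensitivity", "specificity", "ppv", "npv", "accuracy"):
            assert rep.metrics[name]["mean"] == pytest.approx(100.0)

    def test_metric_identities_with_stored_confusions(self, rng):
        y = np.arange(50) < 15
        X = rng.standard_normal((50, 3))
        X[:, 0] += np.where(y, 1.0, -0.2)
        df = feature_frame(X, y)
        train, hold = stratified_split(df, 0.7, seed=1)
        rep = evaluate_classifier(train, hold, ["f00", "f01"], n_repetitions=50, seed=2)
        recomputed = {
            k: [] for k in ("sensitivity", "specificity", "ppv", "npv", "accuracy")
        }
        for cm in rep.confusion_matrices:
            m = confusion_metrics(*cm)
            for k in recomputed:
                if not np.isnan(m[k]):
                    recomputed[k].append(m[k])
        for k, vals in recomputed.items():
            assert np.mean(vals) == pytest.approx(rep.metrics[k]["mean"])
            assert len(vals) == rep.n_repetitions - rep.metrics[k]["n_missing"]

    def test_ci_brackets_mean(self, rng):
        df = self._separable(rng, 90)
        train, hold = stratified_split(df, 0.7, seed=3)
        rep = evaluate_classifier(train, hold, ["f00", "f01"], n_repetitions=30, seed=4)
        for name, m in rep.metrics.items():
            if not np.isnan(m["mean"]):
                assert m["ci_low"] <= m["mean"] + 1e-9
                assert m["ci_high"] >= m["mean"] - 1e-9

    def test_empty_feature_set_rejected(self, rng):
        df = self._separable(rng)
        with pytest.raises(ValueError):
            evaluate_classifier(df, df, [], 10, 0)


class TestShuffleTest:
    def test_observed_below_all_nulls(self, rng):
        df = feature_frame(rng.standard_normal((30, 2)), np.arange(30) < 10)
        p = shuffle_test(-np.inf, lambda t: 0.5, df, n_shuffles=99, seed=0)
        assert p == pytest.approx(1.0)

    def test_observed_above_all_nulls(self, rng):
        df = feature_frame(rng.standard_normal((30, 2)), np.arange(30) < 10)
        p = shuffle_test(np.inf, lambda t: 0.5, df, n_shuffles=999, seed=0)
        assert p == pytest.approx(0.001)

    def test_minimum_shuffles_enforced(self, rng):
        df = feature_frame(rng.standard_normal((30, 2)), np.arange(30) < 10)
        with pytest.raises(ValueError):
            shuffle_test(0.5, lambda t: 0.5, df, n_shuffles=10)


class TestGaSelect:
    def test_planted_features_dominate(self, rng):
        n, p = 80, 10
        X = rng.standard_normal((n, p))
        y = rng.random(n) < 0.35
        X[y, 2] += 2.0
        X[y, 7] += 2.0
        df = feature_frame(X, y)
        params = GaParams(population_size=20, n_generations=15, n_evolutions=4,
                          patience=5, seed=0)
        out = ga_select(df, params)
        assert out.incidence["f02"] > 0.8
        assert out.incidence["f07"] > 0.8
        assert "f02" in out.optimal_set or "f07" in out.optimal_set

    def test_single_feature_table_rejected(self, rng):
        df = feature_frame(rng.standard_normal((30, 1)), np.arange(30) < 10)
        with pytest.raises(ValueError):
            ga_select(df, GaParams(seed=0))

    def test_reproducible(self, rng):
        X = rng.standard_normal((40, 5))
        df = feature_frame(X, np.arange(40) < 15)
        params = GaParams(population_size=10, n_generations=5, n_evolutions=2,
                          patience=3, seed=4)
        a = ga_select(df, params)
        b = ga_select(df, params)
        assert a.optimal_set == b.optimal_set
        assert a.incidence == b.incidence


class TestElasticNet:
    def test_relative_error_formula(self, rng):
        n = 30
        X = rng.standard_normal((n, 4))
        y = 100 + 5 * X[:, 0] + rng.standard_normal(n)
        rep = elasticnet_nested(feature_frame(X, vabs=y), inner_repeats=2, seed=0,
                                compute_ci=False)
        assert rep.relative_error == pytest.approx(100.0 * rep.rmse / np.ptp(y))

    def test_constant_outcome_rejected(self, rng):
        df = feature_frame(rng.standard_normal((30, 3)), vabs=np.full(30, 7.0))
        with pytest.raises(ValueError):
            elasticnet_nested(df, seed=0)

    def test_null_outcome_shrinks_coefficients(self, rng):
        n = 40
        X = rng.standard_normal((n, 6))
        y = 100 + 8 * rng.standard_normal(n)
        rep = elasticnet_nested(feature_frame(X, vabs=y), inner_repeats=2, seed=1,
                                compute_ci=False)
        base = float(np.sqrt(np.mean((y - y.mean()) ** 2)))
        assert rep.rmse >= 0.95 * base
        assert rep.coefficients["mean"].abs().max() < 1.0


class TestPlantedSignalRecovery:
    def test_attentive_map_features_rank_top_end_to_end(self):
        """With the outcome driven by the attentive map's FD strength and
        duration, the fitted-feature elastic net ranks those planted signals
        above every noise feature."""
        from erpstates import (
            CvParams, SimConfig, apply_inclusion, select_n_maps, simulate_cohort,
        )
        from erpstates.microstates import match_maps
        from erpstates.pipeline import microstate_feature_frame, retained_maps
        from erpstates.synthetic import records_frame

        cfg = SimConfig(
            group_sizes=(14, 14, 10),
            outcome_betas={"gfp_M4_FD": 12.0, "dur_M4_FD": 0.08, "sex_F": 2.0},
            outcome_noise_sd=4.0,
            seed=55,
        )
        records, erps, truth, planted = simulate_cohort(cfg)
        subjects = records_frame(records)
        ref = [erps[r.subject_id]["FD"] for r in records if r.group == "noFH-noASD"]
        sel = select_n_maps(ref, range(2, 6), CvParams(n_splits=6, seed=8))
        perm, cors = match_maps(sel.maps, planted.maps)
        assert cors.min() > 0.95
        ms = microstate_feature_frame(erps, sel.maps, (0, 794), (300, 794))
        table = build_feature_table(subjects, ms, retained_maps=retained_maps(ms))
        rep = elasticnet_nested(table, inner_repeats=2, seed=9, compute_ci=False)
        attentive = int(perm[3]) + 1
        co = rep.coefficients.set_index("feature")["mean"].abs()
        signal = {f"gfp_M{attentive}_FD", f"dur_M{attentive}_FD"}
        noise_feats = [f for f in co.index
                       if f not in signal | {"sex_F", "age_days", "msel_composite"}]
        assert co[f"gfp_M{attentive}_FD"] > co[noise_feats].max()


class TestBootstrapCi:
    def test_constant_statistic_degenerate_interval(self, rng):
        df = pd.DataFrame({"x": rng.standard_normal(30)})
        lo, hi = bootstrap_ci(lambda t: 3.25, df, n_boot=50, seed=0)
        assert lo == hi == 3.25

    def test_interval_narrows_with_n(self, rng):
        small = pd.DataFrame({"x": rng.standard_normal(20)})
        large = pd.DataFrame({"x": rng.standard_normal(200)})
        w_small = np.diff(bootstrap_ci(lambda t: t["x"].mean(), small, 200, seed=1))[0]
        w_large = np.diff(bootstrap_ci(lambda t: t["x"].mean(), large, 200, seed=1))[0]
        assert w_large < w_small

    def test_coverage_for_gaussian_mean(self, rng):
        hits = 0
        n_rep = 200
        for r in range(n_rep):
            x = rng.standard_normal(100)
            df = pd.DataFrame({"x": x})
            lo, hi = bootstrap_ci(lambda t: t["x"].mean(), df, n_boot=200, seed=r)
            hits += lo <= 0.0 <= hi
        assert abs(hits / n_rep - 0.95) < 0.04


class TestBuildFeatureTable:
    def test_twenty_one_features_with_three_maps(self, rng):
        n = 10
        subjects = pd.DataFrame(
            {
                "subject_id": [f"S{i}" for i in range(n)],
                "group": ["FH-noASD"] * n,
                "sex": ["F", "M"] * 5,
                "age_days": rng.integers(184, 351, n),
                "msel_composite": rng.normal(100, 15, n),
                "asd_outcome": [False] * n,
                "vabs_socialization": rng.normal(100, 10, n),
            }
        )
        rows = []
        for sid in subjects["subject_id"]:
            for cond in ("FD", "FA", "Noise"):
                for m in (1, 2, 3, 4):
                    rows.append({"subject_id": sid, "condition": cond, "map": m,
                                 "duration_ms": 100.0, "mean_gfp": 2.0, "present": True})
        ms = pd.DataFrame(rows)
        table = build_feature_table(subjects, ms, retained_maps=(1, 2, 4))
        cols = feature_columns(table)
        # sex + age + developmental level + 3 maps x 3 conditions x 2 measures
        assert len(cols) == 21

    def test_missing_gfp_imputed_as_zero(self, rng):
        subjects = pd.DataFrame(
            {"subject_id": ["a"], "group": ["FH-noASD"], "sex": ["F"],
             "age_days": [200], "msel_composite": [100.0],
             "asd_outcome": [False], "vabs_socialization": [95.0]}
        )
        ms = pd.DataFrame(
            [{"subject_id": "a", "condition": "FD", "map": 1,
              "duration_ms": 0.0, "mean_gfp": np.nan, "present": False}]
        )
        table = build_feature_table(subjects, ms, retained_maps=(1,), conditions=("FD",))
        assert table["gfp_M1_FD"].iloc[0] == 0.0
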