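"""Feature selection, dataset splitting, random-forest training and the
R^2 / RMSE evaluation contract."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from canopyvol.errors import ConfigError, DegenerateInputError, ValidationError
from canopyvol.prediction import (
    ModelConfig,
    default_mtry,
    evaluate,
    relative_change,
    run_strategy,
    select_by_correlation,
    select_features,
    split_dataset,
    train_cvp_model,
)
from canopyvol.reference import FEATURE_CVP_CORRELATIONS, SELECTED_FEATURES

from conftest import heterogeneous_params, homogeneous_params


class TestDefaultMtry:
    @pytest.mark.parametrize("n,expected", [(10, 3), (3, 1), (2, 1), (9, 3), (21, 7)])
    def test_one_third_floored_clamped(self, n, expected):
        assert default_mtry(n) == expected


class TestFeatureSelection:
    def test_reference_correlations_select_the_ten_reported_features(self):
        sel = select_by_correlation(FEATURE_CVP_CORRELATIONS, 0.5)
        assert len(sel.selected) == 10
        assert set(sel.selected) == set(SELECTED_FEATURES)
        # inclusive rule: |r| exactly 0.5 is kept, on both signs
        assert "EXG_before" in sel.selected and "NRI_after" in sel.selected

    def test_zero_correlations_select_nothing(self):
        sel = select_by_correlation({k: 0.0 for k in FEATURE_CVP_CORRELATIONS}, 0.5)
        assert sel.selected == ()

    def test_threshold_zero_selects_all_21(self):
        sel = select_by_correlation(FEATURE_CVP_CORRELATIONS, 0.0)
        assert len(sel.selected) == 21

    def test_computed_from_data_and_idempotent(self, rng):
        n = 50
        cvp = rng.uniform(0.5, 5, n)
        df = pd.DataFrame(
            {
                "cc": cvp + rng.normal(0, 0.2, n),
                "NGRDI_before": -cvp + rng.normal(0, 0.3, n),
                "GBRI_before": rng.normal(0, 1, n),  # unrelated
            }
        )
        sel = select_features(df, cvp, threshold=0.5)
        assert set(sel.selected) == {"cc", "NGRDI_before"}
        again = select_features(df[list(sel.selected)], cvp, threshold=0.5)
        assert again.selected == sel.selected

    def test_constant_column_excluded_with_warning(self, rng):
        cvp = rng.uniform(1, 4, 20)
        df = pd.DataFrame({"cc": cvp, "INT_before": np.ones(20)})
        with pytest.warns(UserWarning, match="INT_before"):
            sel = select_features(df, cvp, threshold=0.5)
        assert sel.selected == ("cc",)


class TestSplit:
    def test_240_samples_split_168_72(self):
        df = pd.DataFrame({"x": np.arange(240)})
        train, val = split_dataset(df, 0.7, seed=0)
        assert (len(train), len(val)) == (168, 72)

    def test_10_samples_split_7_3(self):
        df = pd.DataFrame({"x": np.arange(10)})
        train, val = split_dataset(df, 0.7, seed=1)
        assert (len(train), len(val)) == (7, 3)

    def test_determinism_and_seed_sensitivity(self):
        df = pd.DataFrame({"x": np.arange(100)})
        a1, _ = split_dataset(df, 0.7, seed=5)
        a2, _ = split_dataset(df, 0.7, seed=5)
        b, _ = split_dataset(df, 0.7, seed=6)
        assert list(a1.index) == list(a2.index)
        assert list(a1.index) != list(b.index)

    @pytest.mark.parametrize("strata", [None, "g"])
    def test_conservation(self, rng, strata):
        df = pd.DataFrame({"x": np.arange(53), "g": rng.integers(0, 4, 53)})
        train, val = split_dataset(df, 0.7, seed=2, strata=strata)
        assert len(train) + len(val) == 53
        assert set(train.index).isdisjoint(val.index)
        assert sorted([*train.index, *val.index]) == list(range(53))

    def test_stratification_balances_proportions(self):
        df = pd.DataFrame({"g": np.repeat(["a", "b", "c", "d"], 60)})
        train, _ = split_dataset(df, 0.7, seed=3, strata="g")
        counts = train["g"].value_counts()
        assert (counts == 42).all()

    def test_tiny_stratum_falls_back_with_warning(self):
        df = pd.DataFrame({"g": ["a"] * 9 + ["b"]})
        with pytest.warns(UserWarning, match="stratum"):
            train, val = split_dataset(df, 0.7, seed=0, strata="g")
        assert len(train) + len(val) == 10


class TestTrainModel:
    def test_noiseless_monotone_mapping_interpolates(self, rng):
        cc = rng.uniform(0.1, 0.9, 120)
        df = pd.DataFrame({"cc": cc, "cvp": 0.2 * np.exp(3.6 * cc)})
        train, val = split_dataset(df, 0.7, seed=0)
        cfg = ModelConfig(ntree=500, seed=0)
        model = train_cvp_model(train, ["cc"], cfg)
        r2, _ = evaluate(val["cvp"], model.predict(val[["cc"]].to_numpy()))
        assert r2 >= 0.95

    def test_constant_target_predicts_constant(self, rng):
        df = pd.DataFrame({"cc": rng.uniform(0, 1, 30), "cvp": 2.0})
        model = train_cvp_model(df, ["cc"], ModelConfig(ntree=50, seed=0))
        pred = model.predict(df[["cc"]].to_numpy())
        assert np.allclose(pred, 2.0)

    def test_predictions_bounded_by_training_targets(self, rng):
        df = pd.DataFrame({"cc": rng.uniform(0, 1, 60)})
        df["cvp"] = rng.uniform(1, 3, 60)
        model = train_cvp_model(df, ["cc"], ModelConfig(ntree=100, seed=1))
        grid = pd.DataFrame({"cc": np.linspace(0, 1, 50)})
        pred = model.predict(grid.to_numpy())
        assert pred.min() >= df["cvp"].min() - 1e-9
        assert pred.max() <= df["cvp"].max() + 1e-9

    def test_missing_feature_is_config_error(self, rng):
        df = pd.DataFrame({"cc": rng.uniform(0, 1, 10), "cvp": rng.uniform(1, 2, 10)})
        with pytest.raises(ConfigError):
            train_cvp_model(df, ["cc", "absent"], ModelConfig(ntree=10))


class TestEvaluate:
    def test_perfect_prediction(self):
        r2, rmse = evaluate([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (r2, rmse) == (1.0, 0.0)

    def test_mean_prediction_gives_r2_zero(self):
        y = np.array([1.0, 2.0, 3.0, 6.0])
        r2, _ = evaluate(y, np.full(4, y.mean()))
        assert r2 == pytest.approx(0.0)

    def test_hand_rmse(self):
        _, rmse = evaluate([1, 2, 3], [1, 2, 4])
        assert rmse == pytest.approx(np.sqrt(1 / 3))

    def test_constant_measured_undefined(self):
        with pytest.raises(DegenerateInputError):
            evaluate([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_r2_can_be_negative(self):
        r2, _ = evaluate([1.0, 2.0, 3.0], [3.0, 3.0, -2.0])
        assert r2 < 0


class TestRelativeChange:
    def test_reported_model_comparison_values(self):
        assert relative_change(0.81, 0.92, "increase") == 13.6
        assert relative_change(0.66, 0.44, "decrease") == 33.3

    def test_no_change_is_zero(self):
        assert relative_change(0.5, 0.5, "increase") == 0.0

    def test_zero_baseline_undefined(self):
        with pytest.raises(DegenerateInputError):
            relative_change(0.0, 1.0)


def _strategy_data(params, seed):
    from canopyvol.synthetic import DesignConfig, generate_dataset

    samples, feats, _ = generate_dataset(DesignConfig(), params, seed=seed)
    return samples.merge(feats, on="sample_id")


class TestRunStrategy:
    def test_report_metrics_recomputable_from_predictions(self):
        data = _strategy_data(heterogeneous_params(), seed=0)
        sel = select_features(data, data["cvp"])
        rep = run_strategy(data, sel.selected, ModelConfig(strategy="LPM", ntree=150, seed=0))
        va = rep.predictions[rep.predictions["set"] == "validation"]
        r2, rmse = evaluate(va["measured"], va["predicted"])
        assert r2 == pytest.approx(rep.validation_r2, abs=1e-12)
        assert rmse == pytest.approx(rep.validation_rmse, abs=1e-12)
        assert rep.n_validation == 72 and rep.n_train == 168
        assert set(rep.group_metrics) == {"SJ18", "SJ6", "LY16", "WYD4"}

    def test_seed_determinism_bitwise(self):
        data = _strategy_data(heterogeneous_params(), seed=3)
        sel = select_features(data, data["cvp"])
        cfg = ModelConfig(strategy="GPM", ntree=100, seed=3)
        r1 = run_strategy(data, sel.selected, cfg)
        r2 = run_strategy(data, sel.selected, cfg)
        assert r1.predictions.equals(r2.predictions)

    def test_homogeneous_groups_gpm_matches_lpm(self):
        data = _strategy_data(homogeneous_params(), seed=0)
        sel = select_features(data, data["cvp"])
        vals = {}
        for strat in ("GPM", "LPM"):
            rep = run_strategy(data, sel.selected, ModelConfig(strategy=strat, ntree=300, seed=0))
            vals[strat] = rep.validation_r2
        assert abs(vals["GPM"] - vals["LPM"]) < 0.05

    def test_heterogeneous_groups_favour_local_modelling(self):
        wins = 0
        for seed in range(3):
            data = _strategy_data(heterogeneous_params(), seed=seed)
            sel = select_features(data, data["cvp"])
            r = {
                s: run_strategy(data, sel.selected, ModelConfig(strategy=s, ntree=300, seed=seed)).validation_r2
                for s in ("GPM", "LPM")
            }
            wins += r["LPM"] > r["GPM"]
        assert wins >= 2

    def test_oracle_feature_reaches_r2_near_one(self):
        data = _strategy_data(homogeneous_params(), seed=1)
        data["cc"] = data["cvp"]  # leakage sanity check
        for strat in ("GPM", "LPM"):
            rep = run_strategy(data, ("cc",), ModelConfig(strategy=strat, mtry=1, ntree=150, seed=1))
            assert rep.validation_r2 > 0.97

    def test_bad_group_key_is_config_error(self):
        data = _strategy_data(homogeneous_params(), seed=0)
        sel = select_features(data, data["cvp"])
        with pytest.raises(ConfigError):
            run_strategy(data, sel.selected, ModelConfig(strategy="LPM", ntree=10, group_key="nope"))
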