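import numpy as np
import pandas as pd
import pytest

from strataclock.io import BetaMatrix, SampleMeta
from strataclock.model import (
    AgeModel,
    LocoEnsemble,
    ModelConfig,
    loco_train,
    make_design,
    predict_age,
    train_mlp,
    tune_hyperparameters,
)
from strataclock.selection import FeatureSet


def _design(n=120, f=6, seed=0, n_cohorts=3):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.uniform(size=(n, f)),
        columns=[f"cg{i}" for i in range(f - 1)] + ["sex"],
        index=[f"s{i}" for i in range(n)],
    )
    X["sex"] = (X["sex"] > 0.5).astype(float)
    ages = 20 + 60 * X["cg0"].to_numpy() + rng.normal(0, 1, n)
    cohorts = [f"c{i % n_cohorts}" for i in range(n)]
    return X, ages, cohorts


class TestMakeDesign:
    def _inputs(self):
        beta = BetaMatrix(
            ["cgA", "cgB", "cgC"],
            ["s1", "s2", "s3"],
            np.array([[0.1, 0.2, 0.3], [0.4, 0.5, 0.6], [0.7, 0.8, 0.9]]),
        )
        meta = SampleMeta(["s1", "s2", "s3"], np.array([30.0, 40.0, 50.0]),
                          np.array([0, 1, 0]), ["a", "a", "b"])
        return beta, meta

    def test_columns_in_contract_order(self):
        beta, meta = self._inputs()
        fs = FeatureSet(["cgC", "cgA"], {"cgC": {"x"}, "cgA": {"x"}}, {"cgC": 1.0, "cgA": 0.5})
        X, ages = make_design(beta, meta, fs)
        assert list(X.columns) == ["cgC", "cgA", "sex"]
        np.testing.assert_array_equal(X["cgC"], [0.7, 0.8, 0.9])
        np.testing.assert_array_equal(ages, meta.age)

    def test_rows_follow_meta_order(self):
        beta, meta = self._inputs()
        shuffled = meta.subset(np.array([2, 0, 1]))
        X, ages = make_design(beta, shuffled, ["cgA"])
        assert list(X.index) == ["s3", "s1", "s2"]
        np.testing.assert_array_equal(X["cgA"], [0.3, 0.1, 0.2])

    def test_missing_feature_named_in_error(self):
        beta, meta = self._inputs()
        with pytest.raises(KeyError, match="cgZ"):
            make_design(beta, meta, ["cgA", "cgZ"])

    def test_unknown_sex_rejected(self):
        beta, meta = self._inputs()
        meta.sex[0] = -1
        with pytest.raises(ValueError, match="unknown sex"):
            make_design(beta, meta, ["cgA"])


class TestTrainMlp:
    def test_deterministic_given_seed(self):
        X, ages, _ = _design()
        cfg = ModelConfig.test_default(seed=5)
        m1 = train_mlp(X, ages, cfg)
        m2 = train_mlp(X, ages, cfg)
        for w1, w2 in zip(m1.weights, m2.weights):
            np.testing.assert_array_equal(w1, w2)
        np.testing.assert_array_equal(m1.predict(X), m2.predict(X))

    def test_representable_function_learned(self):
        # age is an exact linear function of one beta: MAE < 0.5 y
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.uniform(size=(200, 3)), columns=["cg1", "cg2", "sex"])
        ages = 100 * X["cg1"].to_numpy()
        cfg = ModelConfig(n_hidden_layers=2, width=32, dropout=0.0, l2=0.0,
                          learning_rate=1e-2, epochs=2000, seed=0)
        model = train_mlp(X, ages, cfg)
        mae = np.mean(np.abs(model.predict(X) - ages))
        assert mae < 0.5

    def test_more_epochs_fit_better(self):
        X, ages, _ = _design(seed=2)
        short = train_mlp(X, ages, ModelConfig(n_hidden_layers=2, width=32, dropout=0.0,
                                               l2=0.0, learning_rate=1e-3, epochs=10, seed=3))
        long = train_mlp(X, ages, ModelConfig(n_hidden_layers=2, width=32, dropout=0.0,
                                              l2=0.0, learning_rate=1e-3, epochs=2000, seed=3))
        mae = lambda m: np.mean(np.abs(m.predict(X) - ages))
        assert mae(long) < mae(short)

    def test_divergence_raises_with_diagnostics(self):
        # overflowing inputs make the loss non-finite within a few epochs
        X, ages, _ = _design()
        cfg = ModelConfig(n_hidden_layers=2, width=32, dropout=0.0, l2=0.0,
                          learning_rate=1e-2, epochs=10, seed=0)
        with pytest.raises(FloatingPointError, match="learning rate"):
            with np.errstate(all="ignore"):
                train_mlp(X * 1e200, ages, cfg)

    def test_too_few_samples(self):
        X = pd.DataFrame([[0.5]], columns=["cg1"])
        with pytest.raises(ValueError, match="2 samples"):
            train_mlp(X, np.array([30.0]), ModelConfig.test_default())

    def test_save_load_round_trip(self, tmp_path):
        X, ages, _ = _design()
        model = train_mlp(X, ages, ModelConfig.test_default(seed=1))
        model.save(tmp_path / "m")
        back = AgeModel.load(tmp_path / "m")
        np.testing.assert_array_equal(model.predict(X), back.predict(X))
        assert back.feature_names == model.feature_names


class TestLoco:
    def test_one_submodel_per_heldout_cohort(self):
        X, ages, cohorts = _design(n_cohorts=3)
        ens = loco_train(X, ages, cohorts, ModelConfig.test_default())
        assert sorted(ens.submodels) == ["c0", "c1", "c2"]
        assert set(ens.held_out_mae) == {"c0", "c1", "c2"}

    def test_two_cohorts_two_submodels(self):
        X, ages, cohorts = _design(n_cohorts=2)
        ens = loco_train(X, ages, cohorts, ModelConfig.test_default())
        assert len(ens.submodels) == 2

    def test_always_train_cohort_never_held_out(self):
        X, ages, cohorts = _design(n_cohorts=4)
        ens = loco_train(X, ages, cohorts, ModelConfig.test_default(), always_train="c0")
        assert "c0" not in ens.submodels
        assert len(ens.submodels) == 3
        for held, trained_on in ens.train_cohorts.items():
            assert "c0" in trained_on
            assert held not in trained_on

    def test_single_cohort_error(self):
        X, ages, _ = _design()
        with pytest.raises(ValueError, match="2 cohorts"):
            loco_train(X, ages, ["only"] * len(X), ModelConfig.test_default())

    def test_heldout_label_corruption_leaves_weights_identical(self):
        X, ages, cohorts = _design(n_cohorts=3)
        cfg = ModelConfig.test_default(seed=9)
        ens = loco_train(X, ages, cohorts, cfg)
        corrupted = ages.copy()
        mask = np.array(cohorts) == "c1"
        corrupted[mask] = 999.0
        ens2 = loco_train(X, corrupted, cohorts, cfg)
        for w1, w2 in zip(ens.submodels["c1"].weights, ens2.submodels["c1"].weights):
            np.testing.assert_array_equal(w1, w2)
        for b1, b2 in zip(ens.submodels["c1"].biases, ens2.submodels["c1"].biases):
            np.testing.assert_array_equal(b1, b2)

    def test_ensemble_mae_within_2x_best_submodel_on_unseen_cohort(self):
        X, ages, cohorts = _design(n=160, n_cohorts=4, seed=7)
        seen = np.array(cohorts) != "c3"
        cfg = ModelConfig(n_hidden_layers=2, width=32, dropout=0.0, l2=1e-6,
                          learning_rate=1e-2, epochs=500, seed=0)
        ens = loco_train(X[seen], ages[seen], np.array(cohorts)[seen], cfg)
        unseen = ~seen
        ens_mae = np.mean(np.abs(ens.predict(X[unseen]) - ages[unseen]))
        best = min(
            np.mean(np.abs(m.predict(X[unseen]) - ages[unseen]))
            for m in ens.submodels.values()
        )
        assert np.isfinite(ens_mae)
        assert ens_mae <= 2 * best

    def test_save_load_round_trip(self, tmp_path):
        X, ages, cohorts = _design()
        ens = loco_train(X, ages, cohorts, ModelConfig.test_default())
        ens.save(tmp_path / "ens")
        back = LocoEnsemble.load(tmp_path / "ens")
        np.testing.assert_array_equal(ens.predict(X), back.predict(X))


class TestPredictAge:
    def test_ensemble_is_mean_of_submodels(self):
        X, ages, cohorts = _design()
        ens = loco_train(X, ages, cohorts, ModelConfig.test_default())
        per_model = np.array([m.predict(X) for m in ens.submodels.values()])
        np.testing.assert_allclose(predict_age(ens, X), per_model.mean(axis=0))

    def test_synthetic_mean_rule(self):
        # three constant submodels returning 40/50/60 -> ensemble 50
        def constant_model(value):
            return AgeModel(
                ModelConfig.test_default(), ["f0"],
                weights=[np.zeros((1, 1))], biases=[np.array([float(value)])],
            )

        ens = LocoEnsemble(
            submodels={c: constant_model(v) for c, v in zip("abc", (40, 50, 60))},
            feature_names=["f0"], held_out_mae={}, internal_test_mae={},
            config=ModelConfig.test_default(),
        )
        X = pd.DataFrame([[0.3]], columns=["f0"])
        assert predict_age(ens, X)[0] == pytest.approx(50.0)

    def test_single_model_passthrough(self):
        X, ages, _ = _design()
        model = train_mlp(X, ages, ModelConfig.test_default())
        np.testing.assert_array_equal(predict_age(model, X), model.predict(X))

    def test_permuted_columns_error_not_silent_reorder(self):
        X, ages, _ = _design()
        model = train_mlp(X, ages, ModelConfig.test_default())
        permuted = X[list(X.columns[::-1])]
        with pytest.raises(ValueError, match="contract"):
            predict_age(model, permuted)


class TestTuneHyperparameters:
    def test_single_trial_returned(self):
        X, ages, cohorts = _design(n=60)
        base = ModelConfig(n_hidden_layers=2, width=8, dropout=0.0, l2=1e-6,
                           learning_rate=1e-2, epochs=20, seed=0)
        space = {"n_hidden_layers": (1, 2), "width": (8, 16), "dropout": (0.0, 0.1),
                 "l2": (1e-6, 1e-5), "learning_rate": (1e-3, 1e-2), "epochs": (10, 30)}
        cfg, log = tune_hyperparameters(X, ages, cohorts, n_trials=1, seed=0,
                                        base_config=base, space=space)
        assert len(log) == 1
        assert cfg.epochs == log["epochs"].iloc[0]

    def test_argmin_of_mean_loco_mae(self):
        X, ages, cohorts = _design(n=60)
        base = ModelConfig.test_default()
        space = {"n_hidden_layers": (1, 2), "width": (8, 16), "dropout": (0.0, 0.1),
                 "l2": (1e-6, 1e-5), "learning_rate": (1e-3, 1e-2), "epochs": (10, 100)}
        cfg, log = tune_hyperparameters(X, ages, cohorts, n_trials=3, seed=1,
                                        base_config=base, space=space)
        best_row = log.loc[log["mean_loco_mae"].idxmin()]
        assert cfg.epochs == best_row["epochs"]
        assert cfg.width == best_row["width"]

    def test_deterministic_trial_sequence(self):
        X, ages, cohorts = _design(n=60)
        space = {"n_hidden_layers": (1, 2), "width": (8,), "dropout": (0.0, 0.1),
                 "l2": (1e-6, 1e-5), "learning_rate": (1e-3, 1e-2), "epochs": (10, 20)}
        _, log1 = tune_hyperparameters(X, ages, cohorts, n_trials=2, seed=4, space=space,
                                       base_config=ModelConfig.test_default())
        _, log2 = tune_hyperparameters(X, ages, cohorts, n_trials=2, seed=4, space=space,
                                       base_config=ModelConfig.test_default())
        pd.testing.assert_frame_equal(log1, log2)

    def test_zero_trials_error(self):
        X, ages, cohorts = _design(n=30)
        with pytest.raises(ValueError, match="n_trials"):
            tune_hyperparameters(X, ages, cohorts, n_trials=0)


class TestModelConfig:
    def test_production_default_matches_published_configuration(self):
        cfg = ModelConfig.production_default()
        assert cfg.n_hidden_layers == 2
        assert cfg.width == 1024
        assert cfg.dropout == 0.25
        assert cfg.l2 == pytest.approx(1.71e-5)
        assert cfg.learning_rate == pytest.approx(3.06e-5)
        assert cfg.epochs == 5000

    def test_invalid_dropout(self):
        with pytest.raises(ValueError):
            ModelConfig(dropout=1.0)

    def test_invalid_loss(self):
        with pytest.raises(ValueError):
            ModelConfig(loss="mae")
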