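import numpy as np
import pandas as pd
import pytest

import somnostage as ss
from somnostage.core import STAGES, Hypnogram, StageProbabilities
from somnostage.model import (
    DEFAULT_CLASS_WEIGHT_SPACE,
    Hyperparameters,
    class_weight_grid,
    feature_importance,
    fit,
    grid_search,
    load_model,
    predict,
    predict_proba,
    save_model,
    selection_loss,
)


def _separable_set(n_per=60, seed=0, noise_cols=0):
    """Five Gaussian blobs in 2 features, one per stage, linearly separable."""
    rng = np.random.default_rng(seed)
    feats, labels = [], []
    for i, s in enumerate(STAGES):
        x = rng.normal(loc=(3.0 * i, -2.0 * i), scale=0.2, size=(n_per, 2))
        feats.append(x)
        labels += [s] * n_per
    x = np.concatenate(feats)
    cols = {"f0": x[:, 0], "f1": x[:, 1]}
    for j in range(noise_cols):
        cols[f"noise{j}"] = rng.standard_normal(len(labels))
    return pd.DataFrame(cols), Hypnogram(np.array(labels, dtype="<U3"))


SMALL_HP = Hyperparameters(n_estimators=40, seed=1)


class TestHyperparameters:
    def test_tuned_defaults(self):
        hp = Hyperparameters()
        assert (hp.n_estimators, hp.max_depth, hp.num_leaves, hp.feature_fraction) == (
            500,
            5,
            90,
            0.60,
        )
        assert hp.class_weights == {"W": 1.0, "N1": 2.2, "N2": 1.0, "N3": 1.2, "R": 1.4}

    def test_config_hash_stable_and_sensitive(self):
        a, b = Hyperparameters(), Hyperparameters()
        assert a.config_hash() == b.config_hash()
        assert a.config_hash() != Hyperparameters(max_depth=6).config_hash()


class TestSelectionLoss:
    @pytest.mark.parametrize(
        "train,test,expected", [(1.0, 1.0, 0.0), (0.9, 0.8, 0.9), (0.8, 0.8, 0.8)]
    )
    def test_formula(self, train, test, expected):
        assert selection_loss(train, test) == pytest.approx(expected)

    def test_zero_only_at_perfection(self):
        assert selection_loss(0.99, 1.0) > 0

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError, match="acc_test"):
            selection_loss(0.5, 1.2)


class TestClassWeightGrid:
    def test_default_space_cardinality(self):
        assert len(class_weight_grid(DEFAULT_CLASS_WEIGHT_SPACE)) == 324

    def test_degenerate_single_combination(self):
        grid = class_weight_grid({s: [1.0] for s in STAGES})
        assert grid == [{s: 1.0 for s in STAGES}]

    def test_enumeration_oracle(self):
        grid = class_weight_grid({"a": [1, 2], "b": [1, 2, 3]})
        expected = [{"a": a, "b": b} for a in (1, 2) for b in (1, 2, 3)]
        assert grid == expected

    def test_empty_candidates_error(self):
        with pytest.raises(ValueError, match="empty"):
            class_weight_grid({"a": []})


class TestFitPredict:
    def test_separable_training_accuracy(self):
        x, y = _separable_set()
        m = fit(x, y, SMALL_HP)
        pred = predict(m, x)
        assert np.mean(pred.stages == y.stages) >= 0.99

    def test_probability_rows_sum_to_one(self):
        x, y = _separable_set()
        m = fit(x, y, SMALL_HP)
        probs = predict_proba(m, x)
        assert np.allclose(probs.probs.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(probs.confidence >= 0.2)

    def test_predict_is_argmax_of_proba(self):
        x, y = _separable_set()
        m = fit(x, y, SMALL_HP)
        assert np.array_equal(predict(m, x).stages, predict_proba(m, x).argmax_stages())

    def test_probability_tie_breaks_to_earlier_stage(self):
        probs = StageProbabilities(np.array([[0.3, 0.3, 0.2, 0.1, 0.1]]))
        assert probs.argmax_stages()[0] == "W"
        mid = StageProbabilities(np.array([[0.1, 0.2, 0.4, 0.2, 0.1]]))
        assert mid.argmax_stages()[0] == "N2"

    def test_duplicated_rows_leave_predictions_unchanged(self):
        x, y = _separable_set(n_per=30)
        m1 = fit(x, y, SMALL_HP)
        x2 = pd.concat([x, x], ignore_index=True)
        y2 = Hypnogram(np.concatenate([y.stages, y.stages]))
        m2 = fit(x2, y2, SMALL_HP)
        assert np.array_equal(predict(m1, x).stages, predict(m2, x).stages)

    def test_deterministic_given_seed(self):
        x, y = _separable_set()
        p1 = predict_proba(fit(x, y, SMALL_HP), x).probs
        p2 = predict_proba(fit(x, y, SMALL_HP), x).probs
        assert np.array_equal(p1, p2)

    def test_unscored_epochs_excluded_from_training(self):
        x, y = _separable_set(n_per=30)
        stages = y.stages.copy()
        stages[:10] = ss.UNSCORED
        m = fit(x, Hypnogram(stages), SMALL_HP)
        assert m is not None  # trains on the remaining scored epochs

    def test_single_class_rejected(self):
        x, _ = _separable_set(n_per=20)
        y = Hypnogram(np.array(["N2"] * len(x), dtype="<U3"))
        with pytest.raises(ValueError, match="two distinct"):
            fit(x, y, SMALL_HP)

    def test_length_mismatch_rejected(self):
        x, y = _separable_set(n_per=20)
        with pytest.raises(ValueError, match="length"):
            fit(x.iloc[:-1], y, SMALL_HP)

    def test_feature_name_mismatch_lists_diff(self):
        x, y = _separable_set()
        m = fit(x, y, SMALL_HP)
        bad = x.rename(columns={"f1": "g1"})
        with pytest.raises(ValueError, match="g1"):
            predict_proba(m, bad)

    def test_feature_order_insensitive(self):
        x, y = _separable_set()
        m = fit(x, y, SMALL_HP)
        assert np.array_equal(predict(m, x[["f1", "f0"]]).stages, predict(m, x).stages)


class TestClassWeightEffect:
    def test_upweighting_a_stage_does_not_reduce_its_recall(self, short_features, short_night):
        _rec, hyp = short_night
        lo = Hyperparameters(n_estimators=40, seed=1, class_weights={**{s: 1.0 for s in STAGES}, "N1": 0.3})
        hi = Hyperparameters(n_estimators=40, seed=1, class_weights={**{s: 1.0 for s in STAGES}, "N1": 4.0})
        n1 = hyp.stages == "N1"
        rec_lo = np.mean(predict(fit(short_features, hyp, lo), short_features).stages[n1] == "N1")
        rec_hi = np.mean(predict(fit(short_features, hyp, hi), short_features).stages[n1] == "N1")
        assert rec_hi >= rec_lo


class TestPersistence:
    def test_archive_round_trip(self, tmp_path):
        x, y = _separable_set()
        m = fit(x, y, SMALL_HP)
        path = tmp_path / "model.joblib"
        save_model(m, path)
        m2 = load_model(path)
        assert m2.feature_names == m.feature_names
        assert np.array_equal(predict(m2, x).stages, predict(m, x).stages)

    def test_version_mismatch_rejected(self, tmp_path):
        import joblib

        x, y = _separable_set(n_per=20)
        m = fit(x, y, SMALL_HP)
        path = tmp_path / "model.joblib"
        save_model(m, path)
        payload = joblib.load(path)
        payload["format_version"] = 999
        joblib.dump(payload, path)
        with pytest.raises(ValueError, match="version"):
            load_model(path)

    def test_signature_encodes_channels_and_meta(self):
        x, y = _separable_set()
        x = x.rename(columns={"f0": "eeg_std", "f1": "eog_std"})
        x["age"] = 30.0
        m = fit(x, y, SMALL_HP)
        assert m.signature() == "age+eeg+eog"


class TestFeatureImportance:
    def test_noise_feature_ranks_below_informative(self):
        x, y = _separable_set(noise_cols=1, seed=3)
        m = fit(x, y, SMALL_HP)
        scores = feature_importance(m, x)
        assert scores["noise0"] < scores["f0"]
        assert scores["noise0"] < scores["f1"]

    def test_scores_nonnegative(self):
        x, y = _separable_set()
        m = fit(x, y, SMALL_HP)
        assert all(v >= 0 for v in feature_importance(m, x).values())

    def test_duplicated_feature_splits_importance_mass(self):
        x, y = _separable_set(seed=5)
        base = feature_importance(fit(x, y, SMALL_HP), x)
        x2 = x.copy()
        x2["f0_copy"] = x2["f0"]
        dup = feature_importance(fit(x2, y, SMALL_HP), x2)
        combined = dup["f0"] + dup["f0_copy"]
        assert combined <= 2.0 * base["f0"] + 1e-9
        assert combined >= 0.25 * base["f0"]


class TestGridSearch:
    def test_small_grid_returns_best_and_report(self):
        x, y = _separable_set(n_per=40, seed=2)
        best, report = grid_search(
            x, y, {"n_estimators": [10, 30]}, n_folds=3, base_hp=SMALL_HP
        )
        assert len(report) == 2
        assert {"acc_train", "acc_test", "loss"} <= set(report.columns)
        assert best.n_estimators in (10, 30)
        assert report["loss"].min() == pytest.approx(
            selection_loss(
                report.loc[report["loss"].idxmin(), "acc_train"],
                report.loc[report["loss"].idxmin(), "acc_test"],
            )
        )
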