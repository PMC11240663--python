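"""Information gain, quartile banding and the random forest."""

import numpy as np
import pandas as pd
import pytest

from broileracc import errors
from broileracc.classify import (
    cross_validate,
    gain_ranking,
    info_gain,
    mdlp_thresholds,
    rank_and_band,
    task_labels,
    train_forest,
)
from broileracc.names import FEATURE_NAMES


def separable_table(n_per_class=60, delta=5.0, seed=0) -> pd.DataFrame:
    """3-class table whose class means differ by delta sd on every attribute."""
    rng = np.random.default_rng(seed)
    rows, feats = [], []
    for c, behaviour in enumerate(("sit", "stand", "walk")):
        feats.append(rng.normal(loc=c * delta, size=(n_per_class, 99)))
        rows += [
            {"bird_id": f"b{c}", "strain": "A", "window_start_s": float(i),
             "behaviour": behaviour, "purity": 1.0}
            for i in range(n_per_class)
        ]
    return pd.concat(
        [pd.DataFrame(rows),
         pd.DataFrame(np.vstack(feats), columns=FEATURE_NAMES)],
        axis=1,
    )


class TestInfoGain:
    def test_perfect_three_class_predictor_gains_log2_3(self):
        labels = np.repeat(["sit", "stand", "walk"], 100)
        attribute = np.repeat([0.0, 1.0, 2.0], 100)
        assert info_gain(attribute, labels) == pytest.approx(np.log2(3), abs=1e-9)

    def test_independent_attribute_gains_nothing(self):
        rng = np.random.default_rng(0)
        labels = rng.choice(["sit", "stand", "walk"], 10_000)
        attribute = rng.normal(size=10_000)
        assert info_gain(attribute, labels) < 0.02

    def test_clean_binary_split_gains_one_bit(self):
        labels = np.array(["a"] * 8 + ["b"] * 8)
        attribute = np.array([0.0] * 8 + [1.0] * 8)
        # hand-computed: H(1/2, 1/2) - 0 = 1 bit
        assert info_gain(attribute, labels) == pytest.approx(1.0)

    def test_invariant_under_strictly_monotone_transform(self):
        rng = np.random.default_rng(1)
        attribute = rng.normal(size=400)
        labels = np.where(attribute + rng.normal(scale=0.5, size=400) > 0, "sit", "walk")
        base = info_gain(attribute, labels)
        assert info_gain(np.exp(attribute), labels) == pytest.approx(base, abs=1e-12)
        assert info_gain(attribute**3, labels) == pytest.approx(base, abs=1e-12)

    def test_constant_labels_rejected(self):
        with pytest.raises(errors.ConstantLabels):
            info_gain(np.arange(10.0), np.repeat("sit", 10))

    def test_gain_is_nonnegative_on_noise(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            labels = rng.choice(["a", "b"], 60)
            assert info_gain(rng.normal(size=60), labels) >= 0.0


class TestMdlpDiscretisation:
    def test_mdl_criterion_entropy_arithmetic(self):
        # one clean cut: gain must clear (log2(n-1) + log2(3^k - 2) -
        # (k H - k1 H1 - k2 H2)) / n; with pure halves that is
        # (log2 15 + log2 7 - 2) / 16 = 0.295 < 1 bit, so the cut stands
        labels = np.array(["a"] * 8 + ["b"] * 8)
        values = np.arange(16.0)
        cuts = mdlp_thresholds(values, labels)
        assert cuts == [7.5]

    def test_uninformative_attribute_yields_no_cuts(self):
        rng = np.random.default_rng(3)
        assert mdlp_thresholds(rng.normal(size=2000), rng.choice(["a", "b"], 2000)) == []


class TestRankAndBand:
    def test_quartile_banding_on_distinct_gains(self):
        gains = pd.Series(np.arange(1.0, 100.0), index=FEATURE_NAMES)
        ranking = rank_and_band(gains, task="A")
        lq, uq = np.percentile(gains, [25, 75])
        low = set(ranking.index[ranking["band"] == "low"])
        high = set(ranking.index[ranking["band"] == "high"])
        assert low == set(gains.index[gains <= lq])
        assert high == set(gains.index[gains >= uq])
        assert abs(len(low) - 25) <= 1 and abs(len(high) - 25) <= 1

    def test_equal_gains_all_band_high(self):
        gains = pd.Series(np.full(99, 0.5), index=FEATURE_NAMES)
        ranking = rank_and_band(gains)
        assert (ranking["band"] == "high").all()  # high wins the LQ==UQ tie

    def test_band_assignment_is_order_invariant(self):
        rng = np.random.default_rng(4)
        gains = pd.Series(rng.uniform(size=99), index=FEATURE_NAMES)
        a = rank_and_band(gains).sort_index()
        b = rank_and_band(gains.sample(frac=1.0, random_state=0)).sort_index()
        pd.testing.assert_series_equal(a["band"], b["band"])

    def test_wrong_gain_count_rejected(self):
        with pytest.raises(ValueError):
            rank_and_band(pd.Series(np.ones(98)))

    def test_task_relabelling(self):
        behaviour = pd.Series(["sit", "stand", "walk", "sit"])
        labels_b, mask_b = task_labels(behaviour, "B")
        assert list(labels_b) == ["static", "static", "walk", "static"]
        assert mask_b.all()
        labels_c, mask_c = task_labels(behaviour, "C")
        assert list(mask_c) == [True, True, False, True]

    def test_ranking_on_separable_table_prefers_informative_attributes(self):
        table = separable_table(n_per_class=40)
        # corrupt one attribute into pure noise: it must not band high
        rng = np.random.default_rng(5)
        table[FEATURE_NAMES[0]] = rng.normal(size=len(table))
        ranking = gain_ranking(table, task="A")
        assert ranking.loc[FEATURE_NAMES[0], "band"] == "low"


class TestForest:
    def test_separable_classes_reach_99_percent_cv(self):
        # a nearest-centroid oracle already classifies this table
        # perfectly, so the forest must reach >= 99 % in CV
        table = separable_table()
        model = cross_validate(table, k=10, n_trees_grid=(100,), seed=0)
        assert model.cv_results["accuracy"][100] >= 0.99

    def test_permuted_labels_score_at_chance(self):
        rng = np.random.default_rng(6)
        table = separable_table(n_per_class=60)
        table["behaviour"] = rng.permutation(table["behaviour"].to_numpy())
        model = cross_validate(table, k=10, n_trees_grid=(100,), seed=0)
        assert model.cv_results["accuracy"][100] == pytest.approx(1 / 3, abs=0.05)

    def test_training_is_deterministic_given_seed(self):
        table = separable_table(n_per_class=30)
        probe = separable_table(n_per_class=10, seed=9)
        a = train_forest(table, n_trees=20, seed=7).predict(probe)
        b = train_forest(table, n_trees=20, seed=7).predict(probe)
        np.testing.assert_array_equal(a, b)

    def test_predictions_stay_in_training_label_set(self):
        table = separable_table(n_per_class=30)
        two_class = table[table["behaviour"] != "walk"]
        model = train_forest(two_class, n_trees=20, seed=0)
        assert set(model.predict(table)) <= {"sit", "stand"}

    def test_single_class_training_rejected(self):
        table = separable_table(n_per_class=10)
        with pytest.raises(errors.SingleClassTraining):
            train_forest(table[table["behaviour"] == "sit"], n_trees=5, seed=0)

    def test_cv_tie_selects_fewest_trees(self):
        table = separable_table(n_per_class=40)  # every setting reaches 1.0
        model = cross_validate(table, k=5, n_trees_grid=(100, 300), seed=0)
        assert model.cv_results["accuracy"][100] == model.cv_results["accuracy"][300]
        assert model.n_trees == 100

    def test_cv_folds_are_stratified(self):
        from sklearn.model_selection import StratifiedKFold

        table = separable_table(n_per_class=50)
        y = table["behaviour"].to_numpy()
        skf = StratifiedKFold(n_splits=10, shuffle=True, random_state=0)
        for _, test_idx in skf.split(np.zeros(len(y)), y):
            _, counts = np.unique(y[test_idx], return_counts=True)
            assert counts.max() - counts.min() <= 1

    def test_too_few_rows_for_cv_rejected(self):
        with pytest.raises(errors.TooFewRows):
            cross_validate(separable_table(n_per_class=2), k=10, seed=0)

    def test_model_roundtrip(self, tmp_path):
        table = separable_table(n_per_class=20)
        model = train_forest(table, n_trees=10, seed=1)
        model.save(tmp_path / "model.bin")
        loaded = type(model).load(tmp_path / "model.bin")
        np.testing.assert_array_equal(loaded.predict(table), model.predict(table))
        assert loaded.attributes == FEATURE_NAMES
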