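"""Indexing, splitting, class weights, augmentation, and metrics."""

from pathlib import Path

import numpy as np
import pytest
from PIL import Image

from histovote.data import (
    CATEGORIES,
    DatasetIndex,
    ImageRecord,
    augment,
    class_weights,
    evaluate,
    index_dataset,
    round_half_away,
    standardize,
    stratified_split,
    validation_carveout,
)

CLASS_TOTALS = dict(zip(CATEGORIES, (444, 3451, 1014, 626, 792, 560, 453, 569)))


def synthetic_index(totals=CLASS_TOTALS):
    records = [
        ImageRecord(Path(f"{cat}/img_{i}.png"), cat)
        for cat, n in totals.items()
        for i in range(n)
    ]
    return DatasetIndex(records)


class TestRounding:
    @pytest.mark.parametrize(
        "x,expected", [(35.5, 36), (35.4, 35), (355.2, 355), (-2.5, -3), (0.5, 1)]
    )
    def test_half_away_from_zero(self, x, expected):
        assert round_half_away(x) == expected


class TestStratifiedSplit:
    def test_published_census_reproduced(self):
        result = stratified_split(synthetic_index(), 0.8, seed=0)
        counts = result.per_class_counts
        assert counts["train"].tolist() == [355, 2761, 811, 501, 634, 448, 362, 455]
        assert counts["test"].tolist() == [89, 690, 203, 125, 158, 112, 91, 114]
        assert counts["train"].sum() == 6327
        assert counts["test"].sum() == 1582

    def test_partition_and_determinism(self):
        index = synthetic_index({c: 20 + i for i, c in enumerate(CATEGORIES)})
        a = stratified_split(index, 0.8, seed=5)
        b = stratified_split(index, 0.8, seed=5)
        assert [r.path for r in a.train] == [r.path for r in b.train]
        paths = [r.path for r in a.train] + [r.path for r in a.test]
        assert len(paths) == len(set(paths)) == len(index)

    def test_fraction_bounds(self):
        with pytest.raises(ValueError):
            stratified_split(synthetic_index(), 1.0)


class TestValidationCarveout:
    def test_ten_percent_of_adenosis_train(self):
        records = [ImageRecord(Path(f"a/{i}.png"), "A") for i in range(355)]
        train, val = validation_carveout(records, 0.10, seed=0)
        assert (len(val), len(train)) == (36, 319)  # round(35.5) -> 36

    def test_disjoint_partition(self):
        records = [ImageRecord(Path(f"a/{i}.png"), "A") for i in range(50)]
        train, val = validation_carveout(records, 0.2, seed=1)
        assert set(r.path for r in train).isdisjoint(r.path for r in val)
        assert len(train) + len(val) == 50

    @pytest.mark.parametrize("fraction", [0.0, 1.0])
    def test_fraction_bounds(self, fraction):
        with pytest.raises(ValueError):
            validation_carveout([], fraction)


class TestClassWeights:
    TRAIN = dict(zip(CATEGORIES, (355, 2761, 811, 501, 634, 448, 362, 455)))

    def test_published_two_decimal_values(self):
        w = class_weights(self.TRAIN)
        rounded = {c: round(v, 2) for c, v in w.items()}
        assert rounded == {
            "A": 2.23, "DC": 0.29, "F": 0.98, "LC": 1.58,
            "MC": 1.25, "PC": 1.77, "PT": 2.18, "TA": 1.74,
        }

    def test_tubular_adenoma_exact_formula(self):
        w = class_weights(self.TRAIN)
        assert w["TA"] == pytest.approx(6327 / (8 * 455))

    def test_balanced_counts_give_unit_weights(self):
        w = class_weights({c: 100 for c in CATEGORIES})
        assert all(v == 1.0 for v in w.values())

    def test_scale_invariance(self):
        w1 = class_weights(self.TRAIN)
        w2 = class_weights({c: 7 * n for c, n in self.TRAIN.items()})
        for c in CATEGORIES:
            assert w1[c] == pytest.approx(w2[c])

    def test_frequency_weighted_mean_is_one(self):
        w = class_weights(self.TRAIN)
        total = sum(self.TRAIN.values())
        mean = sum(w[c] * n / total for c, n in self.TRAIN.items())
        assert mean == pytest.approx(1.0)

    def test_zero_count_names_category(self):
        with pytest.raises(ZeroDivisionError, match="DC"):
            class_weights({"A": 10, "DC": 0})


class TestAugment:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_repeating_the_same_flips_is_identity(self, seed):
        img = np.random.default_rng(0).integers(0, 255, (8, 6, 3))
        once = augment(img, np.random.default_rng(seed))
        twice = augment(once, np.random.default_rng(seed))
        assert np.array_equal(twice, img)

    def test_pixel_multiset_preserved(self):
        rng = np.random.default_rng(1)
        img = rng.integers(0, 255, (16, 16, 3))
        out = augment(img, rng)
        assert sorted(img.reshape(-1)) == sorted(out.reshape(-1))

    def test_seeded_stream_reproducible(self):
        img = np.random.default_rng(2).integers(0, 255, (16, 16, 3))
        outs = [augment(img, np.random.default_rng(7)) for _ in range(2)]
        assert np.array_equal(outs[0], outs[1])


class TestStandardize:
    def test_resizes_arbitrary_input_to_target(self):
        img = Image.new("RGB", (700, 460), (10, 20, 30))
        assert standardize(img, 224).shape == (224, 224, 3)

    def test_white_maps_to_ones(self):
        img = Image.new("RGB", (64, 64), (255, 255, 255))
        np.testing.assert_allclose(standardize(img, 32), 1.0)

    def test_output_range(self):
        arr = np.random.default_rng(3).integers(0, 255, (50, 70, 3)).astype(np.uint8)
        out = standardize(arr, 48)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_rejects_non_image(self):
        with pytest.raises(TypeError):
            standardize("not an image", 32)


class TestIndexDataset:
    def test_flat_fixture_census(self, tmp_path):
        for cat in CATEGORIES:
            d = tmp_path / cat
            d.mkdir()
            for i in range(10):
                Image.new("RGB", (32, 32), (i, i, i)).save(d / f"{i}.png")
        index = index_dataset(tmp_path)
        assert len(index) == 80
        assert all(v == 10 for v in index.per_class_counts().values())

    def test_unknown_directory_named_in_error(self, tmp_path):
        bad = tmp_path / "mystery_class"
        bad.mkdir()
        Image.new("RGB", (32, 32)).save(bad / "x.png")
        with pytest.raises(ValueError, match="mystery_class"):
            index_dataset(tmp_path)

    def test_nested_layout_with_magnification_tags(self, tmp_path):
        d = tmp_path / "ductal_carcinoma" / "SOB_M_DC-14-10926" / "40X"
        d.mkdir(parents=True)
        Image.new("RGB", (32, 32)).save(d / "img.png")
        index = index_dataset(tmp_path, categories=("DC",))
        (rec,) = index.records
        assert rec.category == "DC"
        assert rec.magnification == "40X"
        assert rec.patient_id == "SOB_M_DC-14-10926"


class TestEvaluate:
    def test_perfect_predictions(self):
        truth = [0, 1, 2, 3, 4, 5, 6, 7]
        report = evaluate(truth, truth)
        assert report.accuracy == report.macro_precision == 1.0
        assert report.macro_recall == report.macro_f1 == 1.0
        assert np.array_equal(np.diag(report.confusion_matrix), np.ones(8))

    def test_hand_computed_three_class_example(self):
        report = evaluate([0, 1, 1, 1, 2, 0], [0, 0, 1, 1, 2, 2], categories="xyz")
        assert report.accuracy == pytest.approx(4 / 6)
        np.testing.assert_allclose(
            report.per_class["precision"], [1 / 2, 2 / 3, 1.0]
        )
        np.testing.assert_allclose(report.per_class["recall"], [1 / 2, 1.0, 1 / 2])
        assert report.macro_precision == pytest.approx(0.7222, abs=1e-4)
        assert report.macro_recall == pytest.approx(0.6667, abs=1e-4)

    def test_confusion_rows_are_true_labels(self):
        report = evaluate([1, 1], [0, 0], categories="ab")
        assert report.confusion_matrix[0, 1] == 2
        assert report.confusion_matrix[1, 0] == 0

    def test_never_predicted_class_contributes_zero_precision(self):
        report = evaluate([0, 0, 0], [0, 0, 1], categories="ab")
        assert report.per_class["precision"]["b"] == 0.0

    def test_accuracy_equals_mean_recall_only_when_balanced(self):
        balanced = evaluate([0, 1, 1, 0], [0, 1, 0, 1], categories="ab")
        assert balanced.accuracy == pytest.approx(balanced.macro_recall)
        imbalanced = evaluate([0, 0, 1, 1], [0, 0, 0, 1], categories="ab")
        assert imbalanced.accuracy != pytest.approx(imbalanced.macro_recall)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            evaluate([0, 1], [0])
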