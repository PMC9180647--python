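"""Split stratification, accuracy, and the gradient-saliency statistic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import grapesense as gs
from grapesense.dataset import SpectralDataset
from grapesense.evaluation import (
    EmptySaliencyError,
    LinearScoreModel,
    accuracy,
    saliency_map,
    split_dataset,
)


def labeled_ds(y, n_bands=6, seed=0):
    rng = np.random.default_rng(seed)
    y = np.asarray(y)
    return SpectralDataset(rng.standard_normal((len(y), n_bands)),
                           np.arange(n_bands, dtype=float), y,
                           np.array(["Red"] * len(y), object))


class TestSplitDataset:
    def test_single_stratum_exact_proportions(self):
        sp = split_dataset(labeled_ds(np.zeros(100, int)), seed=0)
        assert (sp.train.size, sp.val.size, sp.test.size) == (60, 20, 20)

    def test_study_dataset_per_level_fractions(self, default_dataset):
        sp = split_dataset(default_dataset, seed=1)
        assert sp.n_samples == 1071
        for level in range(4):
            n = (default_dataset.y == level).sum()
            n_train = np.isin(sp.train, np.flatnonzero(default_dataset.y == level)).sum()
            assert abs(n_train - 0.6 * n) <= 1

    def test_seeds_change_membership_not_sizes(self, default_dataset):
        a = split_dataset(default_dataset, seed=1)
        b = split_dataset(default_dataset, seed=2)
        assert a.train.size == b.train.size and a.test.size == b.test.size
        assert not np.array_equal(a.train, b.train)

    def test_label_multiset_is_conserved(self, default_dataset):
        sp = split_dataset(default_dataset, seed=5)
        combined = np.concatenate([default_dataset.y[sp.train],
                                   default_dataset.y[sp.val],
                                   default_dataset.y[sp.test]])
        np.testing.assert_array_equal(np.bincount(combined),
                                      np.bincount(default_dataset.y))

    def test_level_by_variety_stratification(self, default_dataset):
        sp = split_dataset(default_dataset, seed=0, stratify_on="level_x_variety")
        for variety in ("Cabernet", "Red", "Munage"):
            cell = np.flatnonzero((default_dataset.variety == variety)
                                  & (default_dataset.y == 0))
            in_train = np.isin(sp.train, cell).sum()
            assert abs(in_train - 0.6 * cell.size) <= 1

    def test_small_stratum_rejected(self):
        with pytest.raises(ValueError, match="stratum"):
            split_dataset(labeled_ds([0, 0, 0, 1, 1, 1, 1, 1]), seed=0)

    def test_round_trip_json(self, tmp_path, default_dataset):
        sp = split_dataset(default_dataset, seed=9)
        path = tmp_path / "split.json"
        sp.to_json(path)
        back = gs.SplitIndices.from_json(path)
        np.testing.assert_array_equal(back.train, sp.train)
        np.testing.assert_array_equal(back.test, sp.test)


class TestAccuracy:
    def test_simple_fractions(self):
        assert accuracy([1, 2, 3], [1, 2, 3]) == 1.0
        assert accuracy([0, 1, 2, 3], [0, 1, 2, 0]) == 0.75

    def test_random_predictions_near_chance(self):
        rng = np.random.default_rng(0)
        pred = rng.integers(0, 4, 10000)
        truth = rng.integers(0, 4, 10000)
        assert accuracy(pred, truth) == pytest.approx(0.25, abs=0.015)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.lists(st.integers(0, 3), min_size=1, max_size=50))
    def test_bounds_and_self_agreement(self, labels):
        arr = np.array(labels)
        assert accuracy(arr, arr) == 1.0
        other = (arr + 1) % 4
        assert accuracy(other, arr) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            accuracy([1, 2], [1])


class TestSaliencyMap:
    def test_linear_scorer_gives_exact_weight_rows(self):
        rng = np.random.default_rng(0)
        W = rng.standard_normal((4, 6))
        model = LinearScoreModel(weights=W, bias=np.zeros(4))
        ds = labeled_ds(np.argmax(rng.standard_normal((30, 6)) @ W.T, axis=1))
        ds = SpectralDataset(ds.X, ds.wavelengths_nm,
                             np.argmax(model.class_scores(ds.X), axis=1), ds.variety)
        prof = saliency_map(model, ds)
        # per-sample saliency is |W_c|; the aggregate is a max-normalized
        # class-count-weighted mean of |W_c| rows
        counts = np.bincount(ds.y, minlength=4)
        expected = (np.abs(W) * counts[:, None]).sum(0) / counts.sum()
        np.testing.assert_allclose(prof.importance, expected / expected.max(),
                                   atol=1e-12)
        for c, per_class in prof.per_class_profiles.items():
            np.testing.assert_allclose(per_class * expected.max(), np.abs(W[c]),
                                       atol=1e-12)

    def test_invariant_to_constant_score_shift(self):
        rng = np.random.default_rng(1)
        W = rng.standard_normal((4, 6))
        ds = labeled_ds(rng.integers(0, 4, 40), seed=2)
        base = LinearScoreModel(W, np.zeros(4))
        ds.y[:] = np.argmax(base.class_scores(ds.X), axis=1)
        shifted = LinearScoreModel(W, np.full(4, 13.0))
        np.testing.assert_allclose(saliency_map(base, ds).importance,
                                   saliency_map(shifted, ds).importance, atol=1e-12)

    def test_profile_is_max_normalized(self):
        rng = np.random.default_rng(2)
        W = rng.standard_normal((4, 9))
        model = LinearScoreModel(W, np.zeros(4))
        ds = labeled_ds(rng.integers(0, 4, 20), n_bands=9, seed=3)
        ds.y[:] = np.argmax(model.class_scores(ds.X), axis=1)
        prof = saliency_map(model, ds)
        assert prof.importance.max() == pytest.approx(1.0)
        assert prof.importance.size == 9
        assert np.all(prof.importance >= 0)

    def test_no_correct_predictions_raises(self):
        model = LinearScoreModel(np.eye(4, 6), np.zeros(4))
        ds = labeled_ds(np.zeros(10, int), seed=4)
        ds.y[:] = (np.argmax(model.class_scores(ds.X), axis=1) + 1) % 4  # all wrong
        with pytest.raises(EmptySaliencyError):
            saliency_map(model, ds)
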