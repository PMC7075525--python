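"""Feature assembly, group dispatch and network training."""

import numpy as np
import pytest

from protqa.nnscorer import (BLOCKS, BLOCK_ORDER, MANDATORY_COLS, N_FEATURES,
                             N_GROUPS, NNScorer, ResidueDataset, _MLP,
                             assemble_features, blend_datasets,
                             cross_validate, group_columns, group_of_rows,
                             mask_block, target_folds)
from protqa.pipeline import compute_features


def _random_X(rng, n=50, valid_blocks=None):
    X = rng.uniform(-1, 1, size=(n, N_FEATURES))
    if valid_blocks is not None:
        for name in BLOCK_ORDER:
            if name not in valid_blocks:
                X[:, list(BLOCKS[name])] = np.nan
    return X


class TestFeatureLayout:
    def test_group_ids_enumerate_all_16_subsets(self, rng):
        seen = set()
        for g in range(N_GROUPS):
            valid = {name for bit, name in enumerate(BLOCK_ORDER)
                     if g >> bit & 1}
            X = _random_X(rng, n=3, valid_blocks=valid)
            ids = group_of_rows(X)
            assert (ids == g).all()
            seen.add(g)
        assert seen == set(range(16))

    def test_group_columns_sizes(self):
        assert len(group_columns(15)) == N_FEATURES
        assert len(group_columns(0)) == len(MANDATORY_COLS) == 34
        # block sizes: torsion 1, ss 2, acc 2, disco 8
        assert len(group_columns(1)) == 35
        assert len(group_columns(8)) == 42

    def test_full_vector_on_pipeline_features(self, standard_corpus):
        bundles, checkpoints, dataset = standard_corpus
        assert dataset.X.shape[1] == N_FEATURES
        onehot = dataset.X[:, 27:47]
        assert np.allclose(onehot.sum(axis=1), 1.0)
        groups = group_of_rows(dataset.X)
        assert groups.max() == 15          # fully-valid residues exist
        # terminal residues lack torsion -> even group ids present
        assert (groups & 1 == 0).any()


class TestAssembleFeatures:
    def test_terminal_residues_lose_torsion_block(self, standard_corpus):
        bundles, checkpoints, _ = standard_corpus
        b = bundles[0]
        X = compute_features(b.native, checkpoints)
        assert np.isnan(X[0, 5]) and np.isnan(X[-1, 5])
        assert np.isfinite(X[2, 5])

    def test_no_templates_invalidates_disco_block(self, standard_corpus):
        bundles, checkpoints, _ = standard_corpus
        b = bundles[0]
        X = compute_features(b.native, checkpoints, ensemble=None)
        assert np.isnan(X[:, 11:19]).all()

    def test_mask_block_helper(self, rng):
        X = _random_X(rng, n=5)
        Xm = mask_block(X, "disco")
        assert np.isnan(Xm[:, 11:19]).all()
        assert np.isfinite(Xm[:, :11]).all()


class TestMLP:
    def test_hand_set_weights_forward_pass(self):
        net = _MLP([2, 2, 1], np.random.default_rng(0))
        net.weights = [np.array([[1.0, 0.0], [0.0, 1.0]]),
                       np.array([[1.0], [2.0]])]
        net.biases = [np.zeros(2), np.array([0.5])]
        x = np.array([[3.0, -4.0]])
        # relu([3, -4]) = [3, 0]; output = 3*1 + 0*2 + 0.5
        assert net.predict(x)[0] == pytest.approx(3.5)

    def test_training_reduces_loss(self, rng):
        x = rng.uniform(-1, 1, size=(500, 3))
        y = 0.5 + 0.3 * x[:, 0]
        net = _MLP([3, 8, 1], np.random.default_rng(1))
        before = np.mean((net.predict(x) - y) ** 2)
        net.train(x, y, epochs=50, batch_size=100, lr=1e-2,
                  optimizer="rmsprop", loss="mse",
                  rng=np.random.default_rng(2))
        after = np.mean((net.predict(x) - y) ** 2)
        assert after < before / 10


class TestNNScorer:
    def _recoverable_dataset(self, rng, n=3000):
        X = _random_X(rng, n=n)
        y = np.clip((X[:, 0] + X[:, 9] + X[:, 11]) / 3.0 + 0.5, 0, 1)
        return X, y

    def test_learns_recoverable_mapping(self, rng):
        X, y = self._recoverable_dataset(rng)
        scorer = NNScorer(seed=3, min_group_rows=100)
        scorer.fit(X[:2500], y[:2500])
        mse = np.mean((scorer.predict(X[2500:]) - y[2500:]) ** 2)
        assert mse < 0.01

    def test_same_seed_bit_identical(self, rng):
        X, y = self._recoverable_dataset(rng, n=1000)
        p1 = NNScorer(seed=11, epochs=20).fit(X, y).predict(X)
        p2 = NNScorer(seed=11, epochs=20).fit(X, y).predict(X)
        assert np.array_equal(p1, p2)

    def test_predictions_clamped_to_unit_interval(self, rng):
        X, y = self._recoverable_dataset(rng, n=1000)
        scorer = NNScorer(seed=5, epochs=10).fit(X, y)
        probe = _random_X(rng, n=200) * 50.0
        out = scorer.predict(probe)
        assert (out >= 0.0).all() and (out <= 1.0).all()

    def test_missing_group_falls_back_to_subset_network(self, rng):
        # train only on fully-valid rows: sparse groups fall back but
        # every validity pattern must still be scorable
        X = _random_X(rng, n=1200)
        y = np.clip(X[:, 0] + 0.5, 0, 1)
        scorer = NNScorer(seed=7, epochs=10, min_group_rows=100)
        scorer.fit(X, y)
        for g in range(N_GROUPS):
            valid = {name for bit, name in enumerate(BLOCK_ORDER)
                     if g >> bit & 1}
            probe = _random_X(rng, n=4, valid_blocks=valid)
            out = scorer.predict(probe)
            assert np.isfinite(out).all()

    def test_rows_of_rich_groups_train_poor_groups(self, rng):
        X = _random_X(rng, n=800)       # all rows fully valid
        y = np.clip(X[:, 0] + 0.5, 0, 1)
        scorer = NNScorer(seed=9, epochs=5, min_group_rows=400)
        scorer.fit(X, y)
        assert set(scorer.trained_groups_) == set(range(N_GROUPS))


class TestCrossValidation:
    def _dataset(self, rng, n_targets=10, rows_per_target=30):
        X = _random_X(rng, n=n_targets * rows_per_target)
        y = np.clip(X[:, 0] + 0.5, 0, 1)
        targets = np.repeat([f"t{i}" for i in range(n_targets)],
                            rows_per_target)
        models = np.repeat([f"t{i}_m" for i in range(n_targets)],
                           rows_per_target)
        return ResidueDataset(X, y, targets, models)

    def test_folds_partition_targets(self, rng):
        ds = self._dataset(rng)
        folds = target_folds(ds.target_ids, 5, seed=1)
        assert sorted(t for f in folds for t in f) == sorted(
            set(ds.target_ids))
        assert all(len(f) == 2 for f in folds)

    def test_no_target_leaks_between_train_and_validation(self, rng):
        ds = self._dataset(rng)
        preds, folds = cross_validate(ds, k=5, seed=1, epochs=5,
                                      min_group_rows=50)
        assert np.isfinite(preds).all()
        seen = [t for f in folds for t in f]
        assert len(seen) == len(set(seen))

    def test_fewer_targets_than_folds_is_error(self, rng):
        ds = self._dataset(rng, n_targets=3)
        with pytest.raises(ValueError):
            target_folds(ds.target_ids, 5)

    def test_blend_row_counts(self, rng):
        a = self._dataset(rng, n_targets=4)
        b = self._dataset(rng, n_targets=6)
        mixed = blend_datasets(a, b, fraction=0.5, seed=2)
        assert abs(len(mixed) - 0.5 * (len(a) + len(b))) <= 1
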