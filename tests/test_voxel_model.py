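import numpy as np
import pytest

from voxdose.aggregate import partition_subregions
from voxdose.grid import VolumeGrid, GridError
from voxdose.voxel_model import (
    CoefficientMap,
    coefficient_map,
    extract_features,
    fit_ridge,
    importance_summary,
    split_cohort,
    standardize,
    tune_ridge,
)


def _mask_100():
    vals = np.zeros((10, 10, 10), dtype=np.uint8)
    vals[2:7, 3:7, 4:9] = 1  # 5*4*5 = 100 voxels
    return VolumeGrid(vals, (1.0, 1.0, 1.0))


class TestExtractFeatures:
    def test_shape(self):
        mask = _mask_100()
        doses = [VolumeGrid(np.random.default_rng(i).random((10, 10, 10)) * 60, (1, 1, 1))
                 for i in range(10)]
        m = extract_features(doses, mask)
        assert m.values.shape == (10, 100)

    def test_uniform_row(self):
        mask = _mask_100()
        doses = [VolumeGrid(np.full((10, 10, 10), 60.0), (1, 1, 1))]
        m = extract_features(doses, mask)
        np.testing.assert_array_equal(m.values[0], 60.0)

    def test_round_trip(self, rng):
        mask = _mask_100()
        doses = [VolumeGrid(rng.random((10, 10, 10)) * 60, (1, 1, 1))]
        m = extract_features(doses, mask)
        vol = m.column_to_volume(m.values[0])
        flat_again = vol.values[tuple(m.voxel_index.T)]
        np.testing.assert_array_equal(flat_again, m.values[0])

    def test_grid_mismatch(self):
        mask = _mask_100()
        wrong = VolumeGrid(np.zeros((10, 10, 10)), (2.0, 2.0, 2.0))
        with pytest.raises(GridError):
            extract_features([wrong], mask)


class TestSplitCohort:
    def test_counts(self):
        y = np.array([0] * 60 + [1] * 40)
        train, test = split_cohort(list(range(100)), y, test_fraction=0.2, seed=0)
        assert len(train) == 80 and len(test) == 20

    def test_stratified(self):
        y = np.array([0] * 60 + [1] * 40)
        train, test = split_cohort(list(range(100)), y, test_fraction=0.2, seed=3)
        test_pos = sum(1 for i in test if y[i] == 1)
        assert test_pos == 8  # 20% of the 40 positives

    def test_deterministic(self):
        y = np.array([0, 1] * 25)
        a = split_cohort(list(range(50)), y, seed=7)
        b = split_cohort(list(range(50)), y, seed=7)
        assert a == b

    def test_too_few(self):
        with pytest.raises(ValueError):
            split_cohort(list(range(5)), np.array([0, 1, 0, 1, 0]))


class TestStandardize:
    def test_closed_form(self):
        X = np.array([[1.0], [2.0], [3.0]])
        Xs, _, params = standardize(X)
        expect = np.array([-1.22474487, 0.0, 1.22474487])
        np.testing.assert_allclose(Xs[:, 0], expect, atol=1e-8)

    def test_constant_column_maps_to_zero(self):
        X = np.array([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]])
        Xs, _, params = standardize(X)
        np.testing.assert_array_equal(Xs[:, 0], 0.0)
        assert params.zero_variance[0] and not params.zero_variance[1]

    def test_test_row_at_train_mean(self):
        X = np.array([[1.0, 10.0], [2.0, 20.0], [3.0, 30.0]])
        _, Xt, _ = standardize(X, X.mean(axis=0, keepdims=True))
        np.testing.assert_allclose(Xt, 0.0, atol=1e-12)

    def test_train_columns_zero_mean_unit_sd(self, rng):
        X = rng.random((50, 8)) * 40
        Xs, _, _ = standardize(X)
        np.testing.assert_allclose(Xs.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(Xs.std(axis=0), 1.0, atol=1e-10)


class TestTuneRidge:
    def _separable(self, rng, n=120, p=6):
        y = np.repeat([0, 1], n // 2)
        X = rng.standard_normal((n, p)) + 4.0 * y[:, None]
        return X, y

    def test_separable_clusters_high_cv_auc(self, rng):
        X, y = self._separable(rng)
        lam, stats = tune_ridge(X, y, seed=0, penalties=np.logspace(-3, 3, 10))
        assert stats["cv_auc_mean"] >= 0.95

    def test_deterministic(self, rng):
        X, y = self._separable(rng)
        a = tune_ridge(X, y, seed=4, penalties=np.logspace(-3, 3, 10))
        b = tune_ridge(X, y, seed=4, penalties=np.logspace(-3, 3, 10))
        assert a[0] == b[0]

    def test_single_class_rejected(self, rng):
        X = rng.random((30, 3))
        with pytest.raises(ValueError):
            tune_ridge(X, np.zeros(30, dtype=int))

    def test_shrinkage_monotone_in_penalty(self, rng):
        X, y = self._separable(rng, n=80)
        Xs, _, _ = standardize(X)
        norms = []
        for lam in np.logspace(-2, 5, 10):
            rep = fit_ridge(Xs, y, Xs, y, lam)
            norms.append(np.linalg.norm(rep.coefficients))
        assert all(a >= b - 1e-9 for a, b in zip(norms, norms[1:]))

    def test_huge_penalty_kills_coefficients(self, rng):
        X, y = self._separable(rng, n=80)
        rep = fit_ridge(X, y, X, y, penalty=1e8)
        assert np.abs(rep.coefficients).max() < 1e-3


class TestFitRidge:
    def test_null_labels_auc_band(self, rng):
        n = 200
        X = rng.standard_normal((n, 40))
        y = rng.integers(0, 2, n)
        tr, te = np.arange(0, 160), np.arange(160, 200)
        rep = fit_ridge(X[tr], y[tr], X[te], y[te], penalty=10.0)
        assert 0.35 <= rep.test_auc <= 0.65

    def test_planted_signal_recovered(self, rng):
        n, p = 200, 50
        X = rng.standard_normal((n, p)) * 10 + 40
        planted = X[:, :10].mean(axis=1)
        y = (planted > np.median(planted)).astype(int)
        tr, te = np.arange(0, 160), np.arange(160, 200)
        lam, stats = tune_ridge(X[tr], y[tr], seed=0, penalties=np.logspace(-2, 3, 8))
        rep = fit_ridge(X[tr], y[tr], X[te], y[te], lam, cv_stats=stats)
        assert rep.test_auc >= 0.8

    def test_metrics_at_threshold_half(self, rng):
        X, y = TestTuneRidge()._separable(rng)
        rep = fit_ridge(X, y, X, y, penalty=1.0)
        assert rep.accuracy >= 0.95 and rep.f1 >= 0.95


class TestCoefficientMap:
    def test_support_inside_mask(self, rng):
        mask = _mask_100()
        doses = [VolumeGrid(rng.random((10, 10, 10)) * 60, (1, 1, 1)) for _ in range(30)]
        m = extract_features(doses, mask)
        y = np.tile([0, 1], 15)
        rep = fit_ridge(m.values[:24], y[:24], m.values[24:], y[24:], penalty=10.0)
        cmap = coefficient_map(m, rep)
        outside = mask.values < 0.5
        np.testing.assert_array_equal(cmap.volume.values[outside], 0.0)


class TestImportanceSummary:
    def test_uniform_coefficients_proportional_shares(self, small_ref):
        part = partition_subregions(small_ref.pc_mask, small_ref.larynx_mask)
        vol = small_ref.pc_mask.copy_with(small_ref.pc_mask.values.astype(float))
        cmap = CoefficientMap(volume=vol, organ="pc")
        shares = importance_summary(cmap, part, q=100.0)
        pc_names = [n for n in part.region_names if n.startswith("pc_")]
        counts = {n: (part.labels == part.label_codes[n]).sum() for n in pc_names}
        total = sum(counts.values())
        for n in pc_names:
            assert shares[n] == pytest.approx(counts[n] / total, abs=1e-9)
        assert sum(shares.values()) == pytest.approx(1.0)

    def test_concentrated_top_voxels(self, small_ref):
        part = partition_subregions(small_ref.pc_mask, small_ref.larynx_mask)
        target = part.region_mask("pc_superior_midline").values.astype(float)
        vol = small_ref.pc_mask.copy_with(target * 5.0)
        cmap = CoefficientMap(volume=vol, organ="pc")
        n_region = int(target.sum())
        n_pc = int(small_ref.pc_mask.values.sum())
        q = 100.0 * n_region / n_pc * 0.5  # top half of the hot region
        shares = importance_summary(cmap, part, q=q)
        assert shares["pc_superior_midline"] == 1.0

    def test_invalid_q(self, small_ref):
        part = partition_subregions(small_ref.pc_mask, small_ref.larynx_mask)
        cmap = CoefficientMap(volume=small_ref.pc_mask.copy_with(
            small_ref.pc_mask.values.astype(float)), organ="pc")
        with pytest.raises(ValueError):
            importance_summary(cmap, part, q=0.0)
        with pytest.raises(ValueError):
            importance_summary(cmap, part, q=101.0)


class TestAugmentationPlacement:
    def test_augmented_rows_only_in_training_parts(self, rng):
        """A flipped twin whose source lands in validation must not leak:
        make augment rows perfect predictors; validation AUC must stay
        imperfect because augment rows never enter validation."""
        n = 60
        X = rng.standard_normal((n, 5))
        y = rng.integers(0, 2, n)
        y[:10], y[-10:] = 0, 1
        aug_X = np.tile(y[:, None].astype(float), (1, 5)) * 100  # trivially separable
        aug_src = np.arange(n)
        lam, stats = tune_ridge(
            X, y, seed=0, penalties=np.array([1.0]),
            augment_X=aug_X, augment_source=aug_src,
        )
        # if augmented rows leaked into validation, AUC would be ~1
        assert stats["cv_auc_mean"] < 0.95
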