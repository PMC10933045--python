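import numpy as np
import pandas as pd
import pytest

from voxdose.aggregate import (
    CLINICAL_MODEL_COVARIATES,
    REGION_NAMES,
    SubregionPartition,
    UnivariateResult,
    build_feature_tables,
    compare_models,
    partition_subregions,
    permutation_importance,
    regional_dose_features,
    repeated_trials,
    select_covariates,
    univariate_logistic,
)
from voxdose.grid import GridError, VolumeGrid


# -- partition -----------------------------------------------------------


class TestPartition:
    def test_thirds_rule(self):
        # pc slab spanning 60 z-slices: superior third = top 20 slices
        pc = np.zeros((20, 20, 70), dtype=np.uint8)
        pc[5:15, 5:15, 5:65] = 1
        lar = np.zeros((20, 20, 70), dtype=np.uint8)
        lar[5:15, 5:15, 0:4] = 1
        part = partition_subregions(
            VolumeGrid(pc, (1, 1, 1)), VolumeGrid(lar, (1, 1, 1)), midline_halfwidth_mm=4.0
        )
        sup = np.zeros_like(pc, dtype=bool)
        for lat in ("midline", "lateral"):
            sup |= part.region_mask(f"pc_superior_{lat}").values > 0
        z_with_sup = np.unique(np.argwhere(sup)[:, 2])
        np.testing.assert_array_equal(z_with_sup, np.arange(45, 65))

    def test_exact_partition_property(self, small_ref):
        part = partition_subregions(small_ref.pc_mask, small_ref.larynx_mask)
        organ = (small_ref.pc_mask.values > 0) | (small_ref.larynx_mask.values > 0)
        total = np.zeros(organ.shape, dtype=int)
        for name in part.region_names:
            total += part.region_mask(name).values.astype(int)
        assert np.all(total[organ] == 1)
        assert np.all(total[~organ] == 0)

    def test_eight_regions(self, small_ref):
        part = partition_subregions(small_ref.pc_mask, small_ref.larynx_mask)
        assert part.region_names == REGION_NAMES
        assert len(part.region_names) == 8

    def test_uniform_dose_equal_region_means(self, small_ref):
        part = partition_subregions(small_ref.pc_mask, small_ref.larynx_mask)
        dose = small_ref.grid.copy_with(np.full(small_ref.grid.shape, 47.5))
        feats = regional_dose_features(dose, part)
        assert set(feats) == set(REGION_NAMES)
        for v in feats.values():
            assert v == pytest.approx(47.5)

    def test_empty_region_rejected(self, small_ref):
        with pytest.raises(GridError):
            partition_subregions(
                small_ref.pc_mask, small_ref.larynx_mask, larynx_superior_fraction=0.0
            )


# -- univariate screening ------------------------------------------------


class TestUnivariate:
    def test_two_by_two_equals_cross_product_ratio(self):
        # exposed: 30 events / 70 non-events; unexposed: 10 / 90
        x = np.array([1] * 100 + [0] * 100, dtype=float)
        y = np.array([1] * 30 + [0] * 70 + [1] * 10 + [0] * 90)
        res = univariate_logistic(x, y)
        assert res.odds_ratio == pytest.approx((30 * 90) / (70 * 10), rel=1e-6)
        assert res.ci_low < res.odds_ratio < res.ci_high
        assert res.p_value < 0.01

    def test_null_covariate(self, rng):
        x = rng.standard_normal(1000)
        y = rng.integers(0, 2, 1000)
        res = univariate_logistic(x, y)
        assert 0.8 < res.odds_ratio < 1.25
        assert res.p_value > 0.001

    def test_small_n_rejected(self, rng):
        with pytest.raises(ValueError):
            univariate_logistic(rng.random(10), rng.integers(0, 2, 10))

    def test_separation_flagged(self):
        x = np.array([0.0] * 50 + [1.0] * 50)
        y = np.array([0] * 50 + [1] * 50)
        res = univariate_logistic(x, y)
        assert res.separated
        assert not np.isfinite(res.ci_high)


class TestSelectCovariates:
    # p-values mirroring the univariate screen's published ordering
    SCREEN = [
        ("treatment_setting", 1e-5), ("bilateral", 1e-5), ("chemotherapy", 0.001),
        ("baseline_weight", 0.01), ("adi", 0.02), ("dysphagia_grade0", 0.03),
        ("gender", 0.16), ("modality_proton", 0.17), ("smoker", 0.34), ("age", 0.39),
    ]

    def _results(self, pairs):
        return [UnivariateResult(n, 1.5, 1.0, 2.0, p) for n, p in pairs]

    def test_selects_the_six_significant(self):
        sel = select_covariates(self._results(self.SCREEN), alpha=0.05)
        assert set(sel) == {
            "treatment_setting", "bilateral", "chemotherapy",
            "baseline_weight", "adi", "dysphagia_grade0",
        }
        assert sel[-1] == "dysphagia_grade0"  # ascending p-order

    def test_none_selected(self):
        sel = select_covariates(self._results([("a", 0.2), ("b", 0.8)]))
        assert sel == []

    def test_boundary_p_excluded(self):
        sel = select_covariates(self._results([("a", 0.05), ("b", 0.049)]))
        assert sel == ["b"]


# -- feature tables ------------------------------------------------------


def _toy_tables(n=40, seed=0):
    rng = np.random.default_rng(seed)
    ids = [f"p{i}" for i in range(n)]
    clinical = pd.DataFrame({
        "id": ids,
        **{c: rng.random(n) for c in CLINICAL_MODEL_COVARIATES},
        "outcome": rng.integers(0, 2, n),
    })
    dvh = pd.DataFrame({"id": ids, **{m: rng.random(n) * 60 for m in (
        "pc_mean_dose", "larynx_mean_dose", "larynx_v50", "larynx_v60",
        "pc_v50", "pc_v55", "pc_v60")}})
    regional = pd.DataFrame({"id": ids, **{r: rng.random(n) * 60 for r in REGION_NAMES}})
    return clinical, dvh, regional


class TestBuildFeatureTables:
    def test_feature_counts(self):
        clinical, dvh, regional = _toy_tables()
        tables = build_feature_tables(clinical, dvh, regional)
        assert tables["clinical"].shape[1] == 6
        assert tables["dvh"].shape[1] == 13
        assert tables["regional"].shape[1] == 14

    def test_regional_names(self):
        clinical, dvh, regional = _toy_tables()
        tables = build_feature_tables(clinical, dvh, regional)
        dosimetric = [c for c in tables["regional"].columns
                      if c not in CLINICAL_MODEL_COVARIATES]
        assert tuple(dosimetric) == REGION_NAMES

    def test_missing_metric_raises_with_names(self):
        clinical, dvh, regional = _toy_tables()
        dvh = dvh.drop(index=3)  # patient p3 loses all dvh metrics
        with pytest.raises(ValueError, match="p3"):
            build_feature_tables(clinical, dvh, regional)

    def test_zero_dose_degrades_to_clinical(self):
        clinical, dvh, regional = _toy_tables()
        for c in dvh.columns[1:]:
            dvh[c] = 0.0
        tables = build_feature_tables(clinical, dvh, regional)
        assert (tables["dvh"].iloc[:, 6:] == 0).all().all()


# -- repeated trials and permutation importance --------------------------


def _signal_table(n=120, seed=0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame({
        "signal": rng.standard_normal(n),
        "noise1": rng.standard_normal(n),
        "noise2": rng.standard_normal(n),
    })
    p = 1 / (1 + np.exp(-2.5 * X["signal"]))
    y = (rng.random(n) < p).astype(int)
    return X, y.to_numpy()


class TestRepeatedTrials:
    def test_deterministic(self):
        X, y = _signal_table()
        pen = np.logspace(-2, 2, 5)
        a = repeated_trials(X, y, n_trials=6, seed=9, penalties=pen)
        b = repeated_trials(X, y, n_trials=6, seed=9, penalties=pen)
        np.testing.assert_array_equal(a.test_aucs, b.test_aucs)
        np.testing.assert_array_equal(a.f1s, b.f1s)

    def test_signal_gives_good_auc(self):
        X, y = _signal_table()
        dist = repeated_trials(X, y, n_trials=6, seed=1, penalties=np.logspace(-2, 2, 5))
        assert dist.mean >= 0.75

    def test_null_outcomes_chance_auc(self, rng):
        X, _ = _signal_table()
        y = rng.integers(0, 2, len(X))
        dist = repeated_trials(X, y, n_trials=6, seed=2, penalties=np.logspace(-2, 2, 5))
        assert 0.3 <= dist.mean <= 0.7


class TestPermutationImportance:
    def test_sole_signal_ranked_first(self):
        X, y = _signal_table()
        imp = permutation_importance(X, y, n_reps=15, seed=0,
                                     penalties=np.logspace(-2, 2, 5))
        ranked = imp.ranked()
        assert ranked.iloc[0]["feature"] == "signal"
        assert ranked.iloc[0]["mean_auc_loss"] < -0.05
        assert ranked.iloc[0]["p_value"] < 0.01

    def test_noise_features_near_zero(self):
        X, y = _signal_table()
        imp = permutation_importance(X, y, n_reps=15, seed=0,
                                     penalties=np.logspace(-2, 2, 5))
        tbl = imp.table.set_index("feature")
        for f in ("noise1", "noise2"):
            assert abs(tbl.loc[f, "mean_auc_loss"]) <= 0.01

    def test_constant_feature_zero_delta(self):
        X, y = _signal_table()
        X = X.copy()
        X["constant"] = 3.0
        imp = permutation_importance(X, y, n_reps=5, seed=0, penalty=1.0)
        tbl = imp.table.set_index("feature")
        assert tbl.loc["constant", "mean_auc_loss"] == 0.0


class TestCompareModels:
    def test_identical_samples(self):
        a = np.full(50, 0.8)
        assert compare_models(a, a)["p_value"] == 1.0

    def test_full_separation(self, rng):
        a = 0.9 + 0.01 * rng.random(50)
        b = 0.5 + 0.01 * rng.random(50)
        assert compare_models(a, b)["p_value"] < 1e-10

    def test_shuffled_same_sample(self, rng):
        a = rng.random(50)
        b = rng.permutation(a)
        assert compare_models(a, b)["p_value"] > 0.9

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            compare_models(np.ones(50), np.ones(40))
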