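"""Aggregated-feature models (Methodology 2).

Univariate logistic screening of clinical covariates, a clinical-only
baseline model, a DVH-metrics model, and a regional-dose model built on a
geometric partition of the reference organs, each run through the same
ridge logistic learner as the voxel models, with repeated-trial AUC
distributions, permutation feature importance, and Wilcoxon model
comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .dosimetry import mean_dose
from .endpoints import IneligibleCaseError, extract_endpoint  # noqa: F401  (re-export)
from .grid import GridError, VolumeGrid
from .voxel_model import fit_ridge, split_cohort, tune_ridge

log = logging.getLogger(__name__)

CLINICAL_MODEL_COVARIATES = (
    "treatment_setting",
    "bilateral",
    "chemotherapy",
    "baseline_weight",
    "adi",
    "dysphagia_grade0",
)

PC_REGION_NAMES = tuple(
    f"pc_{third}_{lat}"
    for third in ("superior", "middle", "inferior")
    for lat in ("midline", "lateral")
)
LARYNX_REGION_NAMES = ("larynx_superior", "larynx_inferior")
REGION_NAMES = PC_REGION_NAMES + LARYNX_REGION_NAMES


# -- subregion partition -------------------------------------------------


@dataclass
class SubregionPartition:
    """Exact partition of the two organ masks into 8 dosimetric regions:
    pc {superior,middle,inferior} x {midline,lateral} plus larynx
    {superior,inferior}."""

    labels: np.ndarray  # int codes, 0 = outside both organs
    label_codes: dict  # region name -> code
    grid: VolumeGrid  # geometry carrier

    @property
    def region_names(self) -> tuple:
        return tuple(self.label_codes)

    def region_mask(self, name: str) -> VolumeGrid:
        code = self.label_codes[name]
        return self.grid.copy_with((self.labels == code).astype(np.uint8))


def partition_subregions(
    pc_mask: VolumeGrid,
    larynx_mask: VolumeGrid,
    midline_halfwidth_mm: float = 10.0,
    larynx_superior_fraction: float = 1.0 / 3.0,
) -> SubregionPartition:
    """Partition the reference organs geometrically.

    The pc is cut into equal-extent cranio-caudal thirds and into midline
    (|x - organ midline| <= halfwidth) vs lateral; the larynx into a
    superior slab (top ``larynx_superior_fraction`` of its z extent) vs
    the rest.  Every organ voxel gets exactly one label; an empty region
    raises.
    """
    pc_mask.validate_mask()
    larynx_mask.validate_mask()
    if not pc_mask.same_grid(larynx_mask):
        raise GridError("organ masks must share the reference grid")
    labels = np.zeros(pc_mask.shape, dtype=np.int16)
    codes = {name: i + 1 for i, name in enumerate(REGION_NAMES)}

    pc = pc_mask.values > 0.5
    pc_idx = np.argwhere(pc)
    zs = pc_idx[:, 2]
    z_lo, z_hi = zs.min(), zs.max()
    # equal-extent thirds; superior = largest z
    t1 = z_lo + (z_hi - z_lo + 1) / 3.0
    t2 = z_lo + 2.0 * (z_hi - z_lo + 1) / 3.0
    xs_phys = pc_mask.origin[0] + pc_idx[:, 0] * pc_mask.spacing[0]
    midline_x = xs_phys.mean()
    is_mid = np.abs(xs_phys - midline_x) <= midline_halfwidth_mm
    third = np.where(zs >= t2, "superior", np.where(zs >= t1, "middle", "inferior"))
    for t in ("superior", "middle", "inferior"):
        for lat, sel_lat in (("midline", is_mid), ("lateral", ~is_mid)):
            sel = (third == t) & sel_lat
            labels[tuple(pc_idx[sel].T)] = codes[f"pc_{t}_{lat}"]

    lar = larynx_mask.values > 0.5
    lar_idx = np.argwhere(lar)
    lzs = lar_idx[:, 2]
    lz_lo, lz_hi = lzs.min(), lzs.max()
    cut = lz_hi - larynx_superior_fraction * (lz_hi - lz_lo + 1)
    sup = lzs > cut
    labels[tuple(lar_idx[sup].T)] = codes["larynx_superior"]
    labels[tuple(lar_idx[~sup].T)] = codes["larynx_inferior"]

    part = SubregionPartition(labels=labels, label_codes=codes, grid=pc_mask)
    for name in REGION_NAMES:
        if not (labels == codes[name]).any():
            raise GridError(f"subregion {name!r} has zero voxels")
    # exactness: organ voxels labeled, nothing else (larynx wins overlaps)
    organ = pc | lar
    if ((labels > 0) != organ).any():
        raise GridError("partition does not exactly cover the organ masks")
    return part


def regional_dose_features(dose: VolumeGrid, partition: SubregionPartition) -> dict[str, float]:
    """Mean dose (Gy) in each of the 8 subregions; dose must be on the
    reference grid (post-normalization)."""
    return {
        name: mean_dose(dose, partition.region_mask(name))
        for name in partition.region_names
    }


# -- univariate screening ------------------------------------------------


@dataclass
class UnivariateResult:
    variable: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    separated: bool = False


def univariate_logistic(
    covariate: np.ndarray, outcome: np.ndarray, name: str = "x"
) -> UnivariateResult:
    """Single-covariate logistic fit: OR = exp(slope), Wald 95% CI and p.

    Continuous covariates are per-unit; binary covariates per category.
    Complete separation is flagged with an unbounded CI.
    """
    x = np.asarray(covariate, dtype=float)
    y = np.asarray(outcome, dtype=int)
    if y.size < 20:
        raise ValueError("univariate screen needs n >= 20")
    if np.unique(y).size < 2:
        raise ValueError("outcome has a single class")
    X = sm.add_constant(x)
    try:
        import warnings

        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        beta = res.params[1]
        se = res.bse[1]
        if not np.isfinite(se) or se > 50:
            raise ValueError("separation")
        p = res.pvalues[1]
        lo, hi = np.exp(beta - 1.959964 * se), np.exp(beta + 1.959964 * se)
        return UnivariateResult(name, float(np.exp(beta)), float(lo), float(hi), float(p))
    except Exception:
        log.warning("univariate fit for %s separated or failed to converge", name)
        direction = np.inf if np.corrcoef(x, y)[0, 1] > 0 else 0.0
        return UnivariateResult(name, direction, 0.0, np.inf, 0.0, separated=True)


def univariate_table(df: pd.DataFrame, variables: list, outcome_col: str = "outcome") -> pd.DataFrame:
    rows = []
    for v in variables:
        r = univariate_logistic(df[v].to_numpy(float), df[outcome_col].to_numpy(int), name=v)
        rows.append(
            {
                "variable": r.variable,
                "odds_ratio": r.odds_ratio,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p_value": r.p_value,
                "separated": r.separated,
            }
        )
    return pd.DataFrame(rows).sort_values("p_value", kind="stable").reset_index(drop=True)


def select_covariates(results: list[UnivariateResult] | pd.DataFrame, alpha: float = 0.05) -> list[str]:
    """Names with p strictly below alpha, ordered by ascending p."""
    if isinstance(results, pd.DataFrame):
        results = [
            UnivariateResult(r.variable, r.odds_ratio, r.ci_low, r.ci_high, r.p_value)
            for r in results.itertuples()
        ]
    sel = sorted(
        (r for r in results if r.p_value < alpha), key=lambda r: r.p_value
    )
    if not sel:
        log.warning("no covariates pass the univariate screen at alpha=%.3g", alpha)
    return [r.variable for r in sel]


# -- model feature tables ------------------------------------------------


def build_feature_tables(
    clinical: pd.DataFrame,
    dvh_metrics: pd.DataFrame,
    regional_doses: pd.DataFrame,
    selected_covariates: list[str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Assemble the three model inputs, indexed by patient id.

    clinical-only: 6 covariates; dvh: + 7 DVH metrics (13 features);
    regional: + 8 regional mean doses (14 features).  Missing metrics
    raise naming the patient and metric.
    """
    cov = list(selected_covariates or CLINICAL_MODEL_COVARIATES)
    for c in cov:
        if c not in clinical.columns:
            raise KeyError(f"clinical table lacks covariate {c!r}")
    base = clinical.set_index("id") if "id" in clinical.columns else clinical
    dvh = dvh_metrics.set_index("id") if "id" in dvh_metrics.columns else dvh_metrics
    reg = regional_doses.set_index("id") if "id" in regional_doses.columns else regional_doses
    for name, tbl in (("dvh", dvh), ("regional", reg)):
        missing = tbl.reindex(base.index)
        bad = missing.isna()
        if bad.any().any():
            pid = missing.index[bad.any(axis=1)][0]
            metric = bad.columns[bad.loc[pid]][0]
            raise ValueError(f"missing {name} metric {metric!r} for patient {pid!r}")
    tables = {
        "clinical": base[cov].copy(),
        "dvh": pd.concat([base[cov], dvh.loc[base.index]], axis=1),
        "regional": pd.concat([base[cov], reg.loc[base.index]], axis=1),
    }
    return tables


# -- repeated trials -----------------------------------------------------


@dataclass
class TrialDistribution:
    test_aucs: np.ndarray
    f1s: np.ndarray

    @property
    def mean(self) -> float:
        return float(self.test_aucs.mean())

    @property
    def sd(self) -> float:
        return float(self.test_aucs.std())

    def to_dict(self) -> dict:
        return {
            "test_aucs": self.test_aucs.tolist(),
            "f1s": self.f1s.tolist(),
            "auc_mean": self.mean,
            "auc_sd": self.sd,
            "f1_mean": float(self.f1s.mean()),
            "f1_sd": float(self.f1s.std()),
        }


def _one_trial(X, y, seed, folds, penalties, test_fraction=0.2):
    ids = np.arange(len(y))
    train_ids, test_ids = split_cohort(ids, y, test_fraction=test_fraction, seed=seed)
    tr, te = np.asarray(train_ids), np.asarray(test_ids)
    lam, cv_stats = tune_ridge(X[tr], y[tr], folds=folds, seed=seed, penalties=penalties)
    return fit_ridge(X[tr], y[tr], X[te], y[te], lam, cv_stats=cv_stats)


def repeated_trials(
    feature_table: pd.DataFrame,
    outcomes: np.ndarray,
    n_trials: int = 50,
    folds: int = 5,
    seed: int = 0,
    penalties: np.ndarray | None = None,
) -> TrialDistribution:
    """Train ``n_trials`` times with fresh stratified 80/20 splits, each
    with 5-fold CV penalty tuning and fold-level standardization."""
    X = feature_table.to_numpy(dtype=float)
    y = np.asarray(outcomes, dtype=int)
    ss = np.random.SeedSequence(seed)
    trial_seeds = [int(s.generate_state(1)[0]) % (2**31) for s in ss.spawn(n_trials)]
    aucs, f1s, failures = [], [], 0
    for ts in trial_seeds:
        for retry in range(3):
            try:
                rep = _one_trial(X, y, ts + retry, folds, penalties)
                aucs.append(rep.test_auc)
                f1s.append(rep.f1)
                break
            except Exception as exc:  # pragma: no cover - rare degenerate splits
                failures += 1
                log.warning("trial failed (%s); retrying with a new seed", exc)
        if failures > 0.1 * n_trials * 3:
            raise RuntimeError("more than 10% of trials failed; aborting")
    return TrialDistribution(np.asarray(aucs), np.asarray(f1s))


# -- permutation importance ----------------------------------------------


@dataclass
class PermutationImportance:
    table: pd.DataFrame  # feature, mean_auc_loss, p_value

    def ranked(self) -> pd.DataFrame:
        return self.table.sort_values("mean_auc_loss", kind="stable").reset_index(drop=True)


def permutation_importance(
    feature_table: pd.DataFrame,
    outcomes: np.ndarray,
    n_reps: int = 50,
    folds: int = 5,
    seed: int = 0,
    penalty: float | None = None,
    penalties: np.ndarray | None = None,
    resample_folds: bool = True,
) -> PermutationImportance:
    """Mean validation-AUC change when one feature is shuffled.

    Each repetition runs stratified k-fold CV: the model is fit per fold
    on intact training data and evaluated on the intact validation part
    and on copies with one feature permuted.  Losses are signed deltas
    (negative = performance drop); the two-tailed Wilcoxon rank-sum test
    compares permuted vs intact AUC samples.  ``resample_folds=False``
    reuses one fold assignment across repetitions.
    """
    from sklearn.metrics import roc_auc_score
    from sklearn.model_selection import StratifiedKFold

    from .voxel_model import _make_model, standardize

    X = feature_table.to_numpy(dtype=float)
    y = np.asarray(outcomes, dtype=int)
    names = list(feature_table.columns)
    if penalty is None:
        penalty, _ = tune_ridge(X, y, folds=folds, seed=seed, penalties=penalties)
    rng = np.random.default_rng(seed)
    intact_aucs: list[float] = []
    perm_aucs: dict[str, list[float]] = {n: [] for n in names}
    constant = [n for n in names if np.unique(X[:, names.index(n)]).size == 1]
    if constant:
        log.warning("constant feature(s) %s: permutation delta defined as 0", constant)
    for rep in range(n_reps):
        skf_seed = seed + rep if resample_folds else seed
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=skf_seed)
        for tr_idx, va_idx in skf.split(X, y):
            if np.unique(y[va_idx]).size < 2:
                continue
            Xtr_s, Xva_s, params = standardize(X[tr_idx], X[va_idx])
            model = _make_model(penalty)
            model.fit(Xtr_s, y[tr_idx])
            auc0 = roc_auc_score(y[va_idx], model.predict_proba(Xva_s)[:, 1])
            intact_aucs.append(auc0)
            for j, name in enumerate(names):
                if name in constant:
                    perm_aucs[name].append(auc0)
                    continue
                Xp = Xva_s.copy()
                Xp[:, j] = rng.permutation(Xp[:, j])
                perm_aucs[name].append(
                    roc_auc_score(y[va_idx], model.predict_proba(Xp)[:, 1])
                )
    rows = []
    intact = np.asarray(intact_aucs)
    for name in names:
        perm = np.asarray(perm_aucs[name])
        delta = float(perm.mean() - intact.mean())
        if name in constant:
            p = 1.0
        else:
            p = float(stats.ranksums(perm, intact).pvalue)
        rows.append({"feature": name, "mean_auc_loss": delta, "p_value": p})
    table = (
        pd.DataFrame(rows).sort_values("mean_auc_loss", kind="stable").reset_index(drop=True)
    )
    return PermutationImportance(table)


# -- model comparison ----------------------------------------------------


def compare_models(auc_a: np.ndarray, auc_b: np.ndarray) -> dict:
    """Two-tailed Wilcoxon rank-sum comparison of per-trial test AUCs."""
    a = np.asarray(auc_a, dtype=float)
    b = np.asarray(auc_b, dtype=float)
    if a.size != b.size or a.size < 10:
        raise ValueError("need equal-length AUC samples of size >= 10")
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        stat, p = 0.0, 1.0
    else:
        res = stats.ranksums(a, b)
        stat, p = float(res.statistic), float(res.pvalue)
    return {
        "statistic": stat,
        "p_value": p,
        "mean_a": float(a.mean()),
        "sd_a": float(a.std()),
        "mean_b": float(b.mean()),
        "sd_b": float(b.std()),
    }
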