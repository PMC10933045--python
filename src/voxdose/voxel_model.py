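"""Ridge logistic modeling of voxel-wise dose (Methodology 1).

Dose to every reference-organ voxel is a feature; an L2-penalized logistic
model is tuned by stratified 5-fold cross-validation on ROC AUC, refit on
the full training set, and its coefficients are mapped back into the
reference frame as a spatial importance map.

The same ``tune_ridge``/``fit_ridge`` machinery is reused by the
aggregated (DVH / regional-dose) models, which are just small feature
tables run through an identical learner.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, f1_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .grid import GridError, VolumeGrid

log = logging.getLogger(__name__)

DEFAULT_PENALTIES = np.logspace(-4, 4, 50)
SOLVER_TOL = 1e-8
SOLVER_MAX_ITER = 10000


# -- feature extraction --------------------------------------------------


@dataclass
class VoxelFeatureMatrix:
    """Cohort x in-mask-voxel dose matrix tied to reference coordinates."""

    values: np.ndarray  # (n_patients, n_voxels), Gy, pre-standardization
    voxel_index: np.ndarray  # (n_voxels, 3) reference-grid voxel coords
    patient_ids: list
    organ: str
    ref_mask: VolumeGrid

    def __post_init__(self) -> None:
        if self.values.ndim != 2:
            raise GridError("feature matrix must be 2D")
        if self.values.shape[1] != self.voxel_index.shape[0]:
            raise GridError("column count must match voxel index")
        if not np.all(np.isfinite(self.values)):
            raise GridError("feature matrix contains non-finite values")

    def column_to_volume(self, col_values: np.ndarray) -> VolumeGrid:
        """Scatter per-voxel values back into the reference frame."""
        out = np.zeros(self.ref_mask.shape, dtype=np.float64)
        out[tuple(self.voxel_index.T)] = col_values
        return self.ref_mask.copy_with(out)


def extract_features(
    warped_doses: list[VolumeGrid],
    ref_mask: VolumeGrid,
    patient_ids: list | None = None,
    organ: str = "pc",
) -> VoxelFeatureMatrix:
    """One row per patient, one column per reference organ voxel (C scan
    order).  All doses must live on the reference grid."""
    ref_mask.validate_mask()
    voxel_index = np.argwhere(ref_mask.values > 0.5)
    sel = tuple(voxel_index.T)
    rows = []
    for d in warped_doses:
        if not d.same_grid(ref_mask):
            raise GridError("warped dose grid does not match the reference mask grid")
        rows.append(d.values[sel])
    ids = patient_ids if patient_ids is not None else list(range(len(warped_doses)))
    return VoxelFeatureMatrix(
        np.asarray(rows, dtype=np.float64), voxel_index, list(ids), organ, ref_mask
    )


# -- splitting and standardization --------------------------------------


def split_cohort(
    ids: list,
    outcomes: np.ndarray,
    test_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[list, list]:
    """Stratified train/test split of base patient ids.

    Augmented (flipped) rows are not passed here: they inherit their
    source patient's assignment, so a twin never straddles the split.
    Degenerate single-class training sets trigger a logged reshuffle.
    """
    ids = list(ids)
    y = np.asarray(outcomes)
    if len(ids) < 10:
        raise ValueError("need at least 10 patients to split")
    if len(ids) != len(y):
        raise ValueError("ids and outcomes length mismatch")
    for attempt in range(20):
        rng = np.random.default_rng(seed + attempt)
        test_idx: list[int] = []
        for cls in np.unique(y):
            cls_idx = np.flatnonzero(y == cls)
            n_test = int(round(test_fraction * cls_idx.size))
            test_idx.extend(rng.permutation(cls_idx)[:n_test])
        test_set = set(test_idx)
        train = [ids[i] for i in range(len(ids)) if i not in test_set]
        test = [ids[i] for i in sorted(test_set)]
        y_train = y[[i for i in range(len(ids)) if i not in test_set]]
        if np.unique(y_train).size > 1:
            if attempt:
                log.warning("split reshuffled %d time(s) to avoid a single-class training set", attempt)
            return train, test
    raise ValueError("could not form a two-class training set")


@dataclass
class StandardizationParams:
    mean: np.ndarray
    sd: np.ndarray  # population (n-denominator); zero-variance entries are 0
    zero_variance: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        sd = np.where(self.zero_variance, 1.0, self.sd)
        out = (X - self.mean) / sd
        out[:, self.zero_variance] = 0.0
        return out


def standardize(
    X_train: np.ndarray, X_other: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray | None, StandardizationParams]:
    """Zero-mean unit-sd transform fitted on training rows only.

    Population standard deviation; zero-variance features map to 0 and are
    retained so column/voxel alignment is stable.
    """
    X_train = np.asarray(X_train, dtype=np.float64)
    if X_train.shape[0] < 2:
        raise ValueError("need at least 2 training rows to standardize")
    mean = X_train.mean(axis=0)
    sd = X_train.std(axis=0)  # ddof=0
    zero = sd < 1e-12
    if zero.any():
        log.debug("standardize: %d zero-variance feature(s) mapped to 0", int(zero.sum()))
    params = StandardizationParams(mean, sd, zero)
    return (
        params.transform(X_train),
        None if X_other is None else params.transform(np.asarray(X_other, dtype=np.float64)),
        params,
    )


# -- ridge logistic fitting ----------------------------------------------


def _make_model(penalty: float) -> LogisticRegression:
    # default penalty is L2; C is the inverse penalty strength
    return LogisticRegression(
        C=1.0 / penalty,
        solver="lbfgs",
        tol=SOLVER_TOL,
        max_iter=SOLVER_MAX_ITER,
    )


def tune_ridge(
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 5,
    seed: int = 0,
    penalties: np.ndarray | None = None,
    augment_X: np.ndarray | None = None,
    augment_source: np.ndarray | None = None,
) -> tuple[float, dict]:
    """Select the L2 penalty maximizing mean validation AUC over stratified
    k-fold CV with fold-level standardization.

    ``augment_X``/``augment_source`` optionally supply augmented (flipped)
    rows and the base-row index each one mirrors; augmented rows join only
    the training part of each fold, never validation.

    Returns (penalty, trace) where the trace maps penalty -> per-fold AUCs.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("tuning requires both outcome classes")
    penalties = DEFAULT_PENALTIES if penalties is None else np.asarray(penalties, dtype=float)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_data = []
    for tr_idx, va_idx in skf.split(X, y):
        Xtr, ytr = X[tr_idx], y[tr_idx]
        if augment_X is not None:
            keep = np.isin(augment_source, tr_idx)
            Xtr = np.vstack([Xtr, augment_X[keep]])
            ytr = np.concatenate([ytr, y[augment_source[keep]]])
        Xtr_s, Xva_s, _ = standardize(Xtr, X[va_idx])
        fold_data.append((Xtr_s, ytr, Xva_s, y[va_idx]))
    trace: dict[float, list[float]] = {}
    for lam in penalties:
        aucs = []
        for Xtr_s, ytr, Xva_s, yva in fold_data:
            model = _make_model(lam)
            model.fit(Xtr_s, ytr)
            if np.unique(yva).size < 2:
                continue
            aucs.append(roc_auc_score(yva, model.predict_proba(Xva_s)[:, 1]))
        trace[float(lam)] = aucs
    means = {lam: (np.mean(a) if a else np.nan) for lam, a in trace.items()}
    # max mean AUC; ties resolve to the strongest regularization
    best = max(sorted(means, reverse=True), key=lambda lam: means[lam])
    return float(best), {"trace": trace, "cv_auc_mean": float(means[best]),
                         "cv_auc_sd": float(np.std(trace[best])) if trace[best] else float("nan")}


@dataclass
class RidgeModelReport:
    penalty: float
    cv_auc_mean: float
    cv_auc_sd: float
    train_auc: float
    test_auc: float
    accuracy: float
    f1: float
    intercept: float
    coefficients: np.ndarray
    train_auc_augmented: float | None = None

    def to_dict(self) -> dict:
        return {
            "penalty": self.penalty,
            "cv_auc_mean": self.cv_auc_mean,
            "cv_auc_sd": self.cv_auc_sd,
            "train_auc": self.train_auc,
            "test_auc": self.test_auc,
            "accuracy": self.accuracy,
            "f1": self.f1,
            "intercept": self.intercept,
            "train_auc_augmented": self.train_auc_augmented,
            "n_features": int(self.coefficients.size),
        }


@dataclass
class CoefficientMap:
    """Ridge coefficients scattered into the reference frame; nonzero
    support is confined to the reference organ mask."""

    volume: VolumeGrid
    organ: str


def fit_ridge(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    penalty: float,
    cv_stats: dict | None = None,
    augment_X: np.ndarray | None = None,
    augment_y: np.ndarray | None = None,
) -> RidgeModelReport:
    """Final fit on the full training data with the tuned penalty.

    Standardization parameters come from the training rows (augmented rows
    included when supplied, matching how the model is trained); metrics
    use probability threshold 0.5 with positive class = outcome 1.
    """
    Xtr = np.asarray(X_train, dtype=np.float64)
    ytr = np.asarray(y_train)
    if augment_X is not None:
        Xtr_full = np.vstack([Xtr, augment_X])
        ytr_full = np.concatenate([ytr, augment_y])
    else:
        Xtr_full, ytr_full = Xtr, ytr
    Xtr_s, Xte_s, params = standardize(Xtr_full, X_test)
    model = _make_model(penalty)
    model.fit(Xtr_s, ytr_full)
    if model.n_iter_[0] >= SOLVER_MAX_ITER:
        raise RuntimeError(
            f"ridge solver failed to converge in {SOLVER_MAX_ITER} iterations"
        )
    p_test = model.predict_proba(Xte_s)[:, 1]
    p_train_base = model.predict_proba(params.transform(Xtr))[:, 1]
    p_train_full = model.predict_proba(Xtr_s)[:, 1]
    yhat = (p_test >= 0.5).astype(int)
    return RidgeModelReport(
        penalty=float(penalty),
        cv_auc_mean=float(cv_stats["cv_auc_mean"]) if cv_stats else float("nan"),
        cv_auc_sd=float(cv_stats["cv_auc_sd"]) if cv_stats else float("nan"),
        train_auc=float(roc_auc_score(ytr, p_train_base)),
        test_auc=float(roc_auc_score(y_test, p_test)),
        accuracy=float(accuracy_score(y_test, yhat)),
        f1=float(f1_score(y_test, yhat, pos_label=1)),
        intercept=float(model.intercept_[0]),
        coefficients=model.coef_[0].copy(),
        train_auc_augmented=(
            float(roc_auc_score(ytr_full, p_train_full)) if augment_X is not None else None
        ),
    )


def coefficient_map(matrix: VoxelFeatureMatrix, report: RidgeModelReport) -> CoefficientMap:
    """Map fitted coefficients back through the voxel index; support is the
    reference organ mask by construction."""
    vol = matrix.column_to_volume(report.coefficients)
    return CoefficientMap(volume=vol, organ=matrix.organ)


def importance_summary(
    coef_map: CoefficientMap, partition, q: float = 5.0
) -> dict[str, float]:
    """Share of the top-q% |coefficient| voxels falling in each subregion.

    Only subregions of the map's organ participate; shares sum to 1.
    """
    if not 0 < q <= 100:
        raise ValueError(f"q must be in (0, 100], got {q}")
    organ_names = [n for n in partition.region_names if n.startswith(coef_map.organ + "_")]
    if not organ_names:
        raise ValueError(f"partition has no subregions for organ {coef_map.organ!r}")
    labels = partition.labels
    vals = np.abs(coef_map.volume.values)
    organ_sel = np.zeros(labels.shape, dtype=bool)
    for n in organ_names:
        organ_sel |= partition.region_mask(n).values > 0.5
    flat_idx = np.argwhere(organ_sel)
    mags = vals[tuple(flat_idx.T)]
    n_top = max(1, int(round(q / 100.0 * mags.size)))
    top = flat_idx[np.argsort(mags)[::-1][:n_top]]
    top_labels = labels[tuple(top.T)]
    shares = {}
    for n in organ_names:
        code = partition.label_codes[n]
        shares[n] = float((top_labels == code).sum()) / n_top
    return shares
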