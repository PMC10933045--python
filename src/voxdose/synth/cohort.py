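"""Synthetic cohort generation with a known outcome truth model.

Each patient is the reference anatomy warped by a smooth random
displacement plus affine jitter, irradiated by one or two analytic
high-dose blobs, and given clinical covariates and a binary FT/WL outcome
drawn from a logistic model whose dose term is the mean dose to a planted
organ subregion.  Because the generating warp is known, the exact
normalized (reference-frame) dose is available for every case, which the
tests use to separate model properties from registration accuracy.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from ..endpoints import extract_endpoint
from ..grid import VolumeGrid, save_nifti, load_nifti
from .anatomy import ReferenceAnatomy, make_reference
from .fields import (
    CoarseField,
    affine_params,
    compose_affine_with_field,
    invert_field,
    smooth_random_field,
)

log = logging.getLogger(__name__)

PRESCRIPTION_RANGE = (30.0, 81.6)

COVARIATE_NAMES = (
    "treatment_setting",
    "bilateral",
    "chemotherapy",
    "dysphagia_grade0",
    "baseline_weight",
    "adi",
    "gender",
    "smoker",
    "age",
)


@dataclass
class ClinicalCovariates:
    """Per-patient clinical/demographic covariates.

    Binary fields are 0/1 ints; ``treatment_setting=1`` means primary RT
    (no prior surgery), ``gender=1`` male, ``dysphagia_grade0=1`` means no
    baseline dysphagia.
    """

    treatment_setting: int
    bilateral: int
    chemotherapy: int
    dysphagia_grade0: int
    baseline_weight: float
    adi: float
    gender: int
    modality: str
    smoker: int
    age: float

    def __post_init__(self) -> None:
        if not 1 <= self.adi <= 100:
            raise ValueError(f"adi must be in [1, 100], got {self.adi}")
        if self.baseline_weight <= 0:
            raise ValueError("baseline_weight must be positive")
        if not 18 <= self.age <= 100:
            raise ValueError(f"age must be in [18, 100], got {self.age}")
        if self.modality not in ("photon", "proton"):
            raise ValueError(f"modality must be photon|proton, got {self.modality}")

    def to_dict(self) -> dict:
        return {
            **{k: getattr(self, k) for k in COVARIATE_NAMES},
            "modality": self.modality,
        }


@dataclass
class CovariateModel:
    """Marginal sampling distributions for the clinical covariates."""

    p_primary: float = 0.37
    p_bilateral: float = 0.55
    p_chemo: float = 0.675
    p_dysphagia_grade0: float = 0.70
    p_male: float = 0.82
    p_proton: float = 0.43
    p_smoker: float = 0.52
    weight_mean: float = 80.0
    weight_sd: float = 16.0
    adi_mean: float = 45.0
    adi_sd: float = 25.0
    age_mean: float = 60.9
    age_sd: float = 12.0

    def sample(self, rng: np.random.Generator) -> ClinicalCovariates:
        return ClinicalCovariates(
            treatment_setting=int(rng.random() < self.p_primary),
            bilateral=int(rng.random() < self.p_bilateral),
            chemotherapy=int(rng.random() < self.p_chemo),
            dysphagia_grade0=int(rng.random() < self.p_dysphagia_grade0),
            baseline_weight=float(np.clip(rng.normal(self.weight_mean, self.weight_sd), 45.0, 140.0)),
            adi=float(np.clip(np.round(rng.normal(self.adi_mean, self.adi_sd)), 1, 100)),
            gender=int(rng.random() < self.p_male),
            modality="proton" if rng.random() < self.p_proton else "photon",
            smoker=int(rng.random() < self.p_smoker),
            age=float(np.clip(rng.normal(self.age_mean, self.age_sd), 23.0, 89.0)),
        )


def default_covariate_effects() -> dict[str, float]:
    """Log-odds effects with the qualitative sign pattern of the study's
    univariate screen: primary setting, bilaterality, chemotherapy, weight
    and deprivation increase risk; absent baseline dysphagia decreases it."""
    return {
        "treatment_setting": 0.9,
        "bilateral": 1.0,
        "chemotherapy": 0.65,
        "dysphagia_grade0": -0.67,
        "baseline_weight": 0.014,
        "adi": 0.014,
        "gender": 0.2,
        "modality": -0.2,  # applied to indicator(proton)
        "smoker": -0.1,
        "age": -0.01,
    }


@dataclass
class OutcomeTruthModel:
    """Known logistic outcome process used to generate and later recover."""

    intercept: float = 0.0
    dose_effect: float = 0.15  # log-odds per Gy of planted-region mean dose
    planted_subregion: str = "pc_superior"
    covariate_effects: dict[str, float] = field(default_factory=default_covariate_effects)
    noise_seed: int = 0
    dose_center: float = 40.0  # Gy; dose term uses (mean_dose - center)
    covariate_centers: dict[str, float] = field(
        default_factory=lambda: {"baseline_weight": 80.0, "adi": 45.0, "age": 60.0}
    )

    def linear_predictor(self, planted_mean_dose: float, cov: ClinicalCovariates) -> float:
        eta = self.intercept + self.dose_effect * (planted_mean_dose - self.dose_center)
        for name, beta in self.covariate_effects.items():
            if name == "modality":
                val = 1.0 if cov.modality == "proton" else 0.0
            else:
                val = float(getattr(cov, name))
            eta += beta * (val - self.covariate_centers.get(name, 0.0))
        return eta

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "dose_effect": self.dose_effect,
            "planted_subregion": self.planted_subregion,
            "covariate_effects": dict(self.covariate_effects),
            "noise_seed": self.noise_seed,
            "dose_center": self.dose_center,
            "covariate_centers": dict(self.covariate_centers),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OutcomeTruthModel":
        return cls(**d)


@dataclass
class PatientCase:
    """One synthetic patient: volumes, covariates, endpoint ingredients."""

    id: str
    index: int
    pc_mask: VolumeGrid
    larynx_mask: VolumeGrid
    dose: VolumeGrid
    modality: str
    covariates: ClinicalCovariates
    prescription: float
    rt_end_day: float = 42.0
    ft_days: list = field(default_factory=list)
    weight_records: list = field(default_factory=list)
    outcome: int | None = None
    # generator internals (absent on cohorts loaded from disk)
    true_field: CoarseField | None = None  # reference -> patient pull-back
    dose_params: dict | None = None
    planted_mean_dose: float | None = None

    @property
    def ft_flag(self) -> bool:
        lo, hi = self.rt_end_day, self.rt_end_day + 90.0
        return any(lo < d <= hi for d in self.ft_days)


# -- analytic dose -------------------------------------------------------


def analytic_dose(points_mm: np.ndarray, params: dict) -> np.ndarray:
    """Evaluate the blob-superposition dose (Gy) at physical points.

    Dose is prescription x max over blobs of a Gaussian profile, so the
    global maximum equals the prescription exactly.
    """
    pts = np.asarray(points_mm, dtype=np.float64)
    out = np.zeros(pts.shape[:-1], dtype=np.float64)
    for center, sigma in zip(params["centers"], params["sigmas"]):
        q = ((pts - np.asarray(center)) / np.asarray(sigma)) ** 2
        np.maximum(out, np.exp(-0.5 * q.sum(axis=-1)), out=out)
    return params["prescription"] * out


def analytic_dose_grid(grid: VolumeGrid, params: dict) -> np.ndarray:
    """Fast separable evaluation of :func:`analytic_dose` on a full grid."""
    ax = grid.physical_coords()
    out = np.zeros(grid.shape, dtype=np.float64)
    for center, sigma in zip(params["centers"], params["sigmas"]):
        q = [((ax[a] - center[a]) / sigma[a]) ** 2 for a in range(3)]
        blob = np.exp(
            -0.5 * (q[0][:, None, None] + q[1][None, :, None] + q[2][None, None, :])
        )
        np.maximum(out, blob, out=out)
    return params["prescription"] * out


def sample_prescription(rng: np.random.Generator) -> float:
    return float(rng.uniform(*PRESCRIPTION_RANGE))


def _sample_dose_params(
    rng: np.random.Generator, ref: ReferenceAnatomy, bilateral: int, prescription: float
) -> dict:
    """Blob centers near the organ complex; laterality follows the
    bilateral covariate (bilateral -> mirrored blob pair)."""
    grid = ref.grid
    extent = np.array([grid.shape[a] * grid.spacing[a] for a in range(3)])
    center = extent / 2.0
    zc = center[2] + rng.uniform(-22.0, 26.0)  # sweeps inferior..superior organ
    yc = center[1] + rng.uniform(-2.0, 8.0)
    sigma = np.array(
        [rng.uniform(14.0, 24.0), rng.uniform(14.0, 24.0), rng.uniform(16.0, 28.0)]
    )
    if bilateral:
        off = rng.uniform(6.0, 16.0)
        centers = [
            np.array([center[0] - off, yc, zc]),
            np.array([center[0] + off, yc, zc]),
        ]
        sigmas = [sigma, sigma]
    else:
        off = rng.uniform(4.0, 14.0) * rng.choice([-1.0, 1.0])
        centers = [np.array([center[0] + off, yc, zc])]
        sigmas = [sigma]
    return {
        "prescription": prescription,
        "centers": [c.tolist() for c in centers],
        "sigmas": [s.tolist() for s in sigmas],
    }


# -- patient sampling ----------------------------------------------------


def sample_patient(
    ref: ReferenceAnatomy,
    cov_model: CovariateModel,
    seed: int,
    index: int = 0,
    max_disp_mm: float = 8.0,
    field_sigma_mm: float = 12.0,
    volumes: bool = True,
) -> PatientCase:
    """Draw one patient (outcome unset).  Deterministic for a fixed seed.

    The anatomy warp is generated in the normalization direction (a
    pull-back field ``u`` on the reference grid); patient masks are built
    with its numerical inverse, so reference voxel ``p`` corresponds to
    patient position ``p + u(p)`` exactly.

    ``volumes=False`` skips materializing patient-frame volumes (masks are
    shared with the reference, dose values are left empty); the analytic
    dose and the generating warp remain available, which is all the
    outcome model and reference-frame feature extraction need.  Covariate,
    prescription, and warp draws are identical in both modes.
    """
    rng = np.random.default_rng(seed)
    cov = cov_model.sample(rng)
    prescription = sample_prescription(rng)
    grid = ref.grid

    amplitude = rng.uniform(0.25, 1.0) * max_disp_mm
    for attempt in range(6):
        u_smooth = smooth_random_field(
            grid.shape, grid.spacing, grid.origin, rng,
            sigma_mm=field_sigma_mm, max_mm=amplitude,
        )
        if max_disp_mm > 0 or amplitude > 0:
            mat, shift = affine_params(rng)
        else:  # identity limit: no affine jitter either
            mat, shift = np.eye(3), np.zeros(3)
        extent = np.array([grid.shape[a] * grid.spacing[a] for a in range(3)])
        u = compose_affine_with_field(u_smooth, mat, shift, extent / 2.0)
        if not volumes:
            break
        v = invert_field(u)
        pc_vals, lar_vals = _warp_organ_masks(ref, v, headroom_mm=max_disp_mm + 12.0)
        if pc_vals.sum() > 0 and lar_vals.sum() > 0:
            break
        amplitude *= 0.5
        log.warning("patient %d: warp emptied a mask; retrying with amplitude %.2f mm",
                    index, amplitude)
    else:  # pragma: no cover - essentially unreachable with damping
        raise RuntimeError(f"patient {index}: could not generate non-empty masks")

    dose_params = _sample_dose_params(rng, ref, cov.bilateral, prescription)
    if volumes:
        dose_vals = analytic_dose_grid(grid, dose_params)
        pc_mask = grid.copy_with(pc_vals.astype(np.uint8))
        lar_mask = grid.copy_with(lar_vals.astype(np.uint8))
        dose = VolumeGrid(dose_vals.astype(np.float32), grid.spacing, grid.origin)
    else:
        pc_mask, lar_mask = ref.pc_mask, ref.larynx_mask
        dose = VolumeGrid(
            _shared_zeros(grid.shape), grid.spacing, grid.origin, {"placeholder": True}
        )
    return PatientCase(
        id=f"case_{index:04d}",
        index=index,
        pc_mask=pc_mask,
        larynx_mask=lar_mask,
        dose=dose,
        modality=cov.modality,
        covariates=cov,
        prescription=prescription,
        true_field=u,
        dose_params=dose_params,
    )


_ZEROS_CACHE: dict[tuple, np.ndarray] = {}


def _shared_zeros(shape: tuple) -> np.ndarray:
    """Read-only zero array shared across lightweight cases."""
    arr = _ZEROS_CACHE.get(shape)
    if arr is None:
        arr = np.zeros(shape, dtype=np.float32)
        arr.setflags(write=False)
        _ZEROS_CACHE[shape] = arr
    return arr


def _warp_organ_masks(
    ref: ReferenceAnatomy, field_: CoarseField, headroom_mm: float
) -> tuple[np.ndarray, np.ndarray]:
    """Warp both organ masks, sampling only a padded union bounding box."""
    from ..grid import mask_bounding_box
    from .fields import warp_masks_bbox

    grid = ref.grid
    union = grid.copy_with(
        ((ref.pc_mask.values > 0) | (ref.larynx_mask.values > 0)).astype(np.uint8)
    )
    lo, hi = mask_bounding_box(union)
    pad = np.ceil(headroom_mm / np.asarray(grid.spacing)).astype(int)
    lo = np.maximum(lo - pad, 0)
    hi = np.minimum(hi + pad, np.asarray(grid.shape) - 1)
    pc, lar = warp_masks_bbox(
        [ref.pc_mask.values, ref.larynx_mask.values], grid.spacing, field_, (lo, hi)
    )
    return pc, lar


def true_ref_dose_at(case: PatientCase, points_mm: np.ndarray) -> np.ndarray:
    """Exact reference-frame dose at physical points via the generating
    warp: analytic patient dose evaluated at ``p + u(p)``."""
    if case.true_field is None or case.dose_params is None:
        raise ValueError("case lacks generator internals; run registration instead")
    disp = case.true_field.sample_at_points(points_mm)
    return analytic_dose(points_mm + disp, case.dose_params)


def true_regional_doses(case: PatientCase, partition) -> dict[str, float]:
    """Mean reference-frame dose per subregion via the generating warp."""
    grid = case.dose
    out = {}
    for name in partition.region_names:
        idx = np.argwhere(partition.region_mask(name).values > 0.5).astype(np.float64)
        pts = np.asarray(grid.origin) + idx * np.asarray(grid.spacing)
        out[name] = float(true_ref_dose_at(case, pts).mean())
    return out


def reference_frame_organ_doses(
    cases: list[PatientCase], ref: ReferenceAnatomy
) -> dict[str, np.ndarray]:
    """Exact reference-frame dose matrices (cases x organ voxels, Gy) for
    both organs, via each case's generating warp.  Voxel order matches
    ``np.argwhere`` of the reference masks (C scan order), the same order
    :func:`voxdose.voxel_model.extract_features` uses."""
    out = {}
    grid = ref.grid
    for organ in ("pc", "larynx"):
        idx = np.argwhere(ref.organ(organ).values > 0.5).astype(np.float64)
        pts = np.asarray(grid.origin) + idx * np.asarray(grid.spacing)
        out[organ] = np.asarray([true_ref_dose_at(c, pts) for c in cases])
    return out


def true_normalized_dose(case: PatientCase) -> VolumeGrid:
    """Exact reference-frame dose via the generating warp (no registration).

    Reference voxel ``p`` takes the analytic patient dose at ``p + u(p)``.
    """
    if case.true_field is None or case.dose_params is None:
        raise ValueError("case lacks generator internals; run registration instead")
    grid = case.dose
    pts = grid.index_grid_physical()
    disp = case.true_field.sample_at_points(pts)
    vals = analytic_dose(pts + disp, case.dose_params)
    return VolumeGrid(vals.astype(np.float32), grid.spacing, grid.origin)


# -- outcome assignment --------------------------------------------------


def planted_region_mask(partition, label: str) -> np.ndarray:
    """Boolean reference-frame mask for a partition label or label prefix
    (e.g. ``pc_superior`` unions ``pc_superior_midline`` + ``..._lateral``)."""
    names = [n for n in partition.region_names if n == label or n.startswith(label + "_")]
    if not names:
        raise ValueError(
            f"{label!r} is not a partition label or prefix; have {partition.region_names}"
        )
    out = np.zeros(partition.labels.shape, dtype=bool)
    for n in names:
        out |= partition.region_mask(n).values > 0.5
    return out


def planted_mean_dose(case: PatientCase, partition, label: str) -> float:
    """Mean dose over the planted subregion, evaluated in the reference
    frame through the generating warp."""
    sel = planted_region_mask(partition, label)
    if not sel.any():
        raise ValueError(f"planted subregion {label!r} is empty")
    grid = case.dose
    idx = np.argwhere(sel).astype(np.float64)
    pts = np.asarray(grid.origin) + idx * np.asarray(grid.spacing)
    disp = case.true_field.sample_at_points(pts)
    vals = analytic_dose(pts + disp, case.dose_params)
    return float(vals.mean())


def assign_outcome(
    case: PatientCase, truth: OutcomeTruthModel, partition
) -> PatientCase:
    """Draw the FT/WL outcome and construct consistent endpoint records."""
    md = planted_mean_dose(case, partition, truth.planted_subregion)
    eta = truth.linear_predictor(md, case.covariates)
    p = 1.0 / (1.0 + np.exp(-eta))
    rng = np.random.default_rng(np.random.SeedSequence((truth.noise_seed, case.index)))
    outcome = int(rng.random() < p)

    base = case.covariates.baseline_weight
    base_day = float(rng.integers(-10, 8))
    end = case.rt_end_day
    follow_days = [end + 20.0, end + 50.0, end + 80.0]
    records = [(base_day, base)]
    ft_days: list[float] = []
    if outcome:
        mode = rng.choice(["ft", "wl", "both"], p=[0.13, 0.48, 0.39])
        if mode in ("ft", "both"):
            ft_days.append(end + float(rng.uniform(1.0, 90.0)))
        if mode in ("wl", "both"):
            nadir_day = end + float(rng.uniform(1.0, 90.0))
            loss = rng.uniform(0.10, 0.20)
            records.append((nadir_day, base * (1.0 - loss)))
        for d in follow_days:
            records.append((d, base * rng.uniform(0.92, 1.02)))
    else:
        for d in follow_days:
            records.append((d, base * rng.uniform(0.92, 1.02)))
    records.sort(key=lambda t: t[0])

    out = replace(
        case,
        ft_days=ft_days,
        weight_records=records,
        outcome=outcome,
        planted_mean_dose=md,
    )
    # consistency with the endpoint extractor is part of the contract
    assert extract_endpoint(ft_days, records, end) == bool(outcome)
    return out


# -- cohort --------------------------------------------------------------


@dataclass
class CohortConfig:
    shape: tuple[int, int, int] = (96, 96, 120)
    spacing: tuple[float, float, float] = (1.27, 1.27, 1.0)
    max_disp_mm: float = 8.0
    field_sigma_mm: float = 12.0
    covariates: CovariateModel = field(default_factory=CovariateModel)
    truth: OutcomeTruthModel | None = None
    midline_halfwidth_mm: float = 10.0
    larynx_superior_fraction: float = 1.0 / 3.0

    def to_dict(self) -> dict:
        return {
            "shape": list(self.shape),
            "spacing": list(self.spacing),
            "max_disp_mm": self.max_disp_mm,
            "field_sigma_mm": self.field_sigma_mm,
            "covariates": vars(self.covariates).copy(),
            "truth": None if self.truth is None else self.truth.to_dict(),
            "midline_halfwidth_mm": self.midline_halfwidth_mm,
            "larynx_superior_fraction": self.larynx_superior_fraction,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        d["shape"] = tuple(d.get("shape", (96, 96, 120)))
        d["spacing"] = tuple(d.get("spacing", (1.27, 1.27, 1.0)))
        if d.get("covariates") is not None and not isinstance(d["covariates"], CovariateModel):
            d["covariates"] = CovariateModel(**d["covariates"])
        if d.get("truth") is not None and not isinstance(d["truth"], OutcomeTruthModel):
            d["truth"] = OutcomeTruthModel.from_dict(d["truth"])
        return cls(**d)


def generate_cohort(
    n: int, config: CohortConfig | None = None, seed: int = 0, volumes: bool = True
) -> tuple[list[PatientCase], OutcomeTruthModel, ReferenceAnatomy]:
    """Generate ``n`` patients with outcomes from a known truth model.

    ``volumes=False`` produces a lightweight cohort (see
    :func:`sample_patient`) suitable for statistical and model-recovery
    experiments that work in the reference frame.
    """
    from ..aggregate import partition_subregions

    if n < 10:
        raise ValueError(f"cohort size must be >= 10, got {n}")
    config = config or CohortConfig()
    ss = np.random.SeedSequence(seed)
    ref_seed, truth_seed, *case_seeds = [
        int(s.generate_state(1)[0]) for s in ss.spawn(n + 2)
    ]
    ref = make_reference(config.shape, config.spacing, seed=ref_seed)
    truth = config.truth or OutcomeTruthModel(noise_seed=truth_seed)
    partition = partition_subregions(
        ref.pc_mask,
        ref.larynx_mask,
        midline_halfwidth_mm=config.midline_halfwidth_mm,
        larynx_superior_fraction=config.larynx_superior_fraction,
    )
    cases = []
    for i in range(n):
        case = sample_patient(
            ref, config.covariates, seed=case_seeds[i], index=i,
            max_disp_mm=config.max_disp_mm, field_sigma_mm=config.field_sigma_mm,
            volumes=volumes,
        )
        cases.append(assign_outcome(case, truth, partition))
    prev = float(np.mean([c.outcome for c in cases]))
    doses = [c.planted_mean_dose for c in cases]
    log.info(
        "cohort n=%d prevalence=%.3f planted dose mean=%.1f Gy range=[%.1f, %.1f]",
        n, prev, float(np.mean(doses)), float(np.min(doses)), float(np.max(doses)),
    )
    return cases, truth, ref


def sample_covariate_table(
    n: int,
    truth: OutcomeTruthModel,
    cov_model: CovariateModel | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Covariates + outcomes only (no volumes): a lightweight cohort for
    statistical recovery tests.  The dose term is held at its center."""
    cov_model = cov_model or CovariateModel()
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n):
        cov = cov_model.sample(rng)
        eta = truth.linear_predictor(truth.dose_center, cov)
        y = int(rng.random() < 1.0 / (1.0 + np.exp(-eta)))
        rows.append({**cov.to_dict(), "outcome": y})
    df = pd.DataFrame(rows)
    df["modality_proton"] = (df["modality"] == "proton").astype(int)
    return df


# -- persistence ---------------------------------------------------------


def write_cohort(cases, truth, ref, outdir, config: CohortConfig | None = None) -> None:
    """Write NIfTI volumes, the clinical CSV, and truth/config sidecars."""
    from pathlib import Path

    outdir = Path(outdir)
    (outdir / "cases").mkdir(parents=True, exist_ok=True)
    save_nifti(ref.pc_mask, outdir / "reference_pc.nii.gz")
    save_nifti(ref.larynx_mask, outdir / "reference_larynx.nii.gz")
    rows = []
    for c in cases:
        stem = outdir / "cases" / c.id
        save_nifti(c.pc_mask, f"{stem}_pc.nii.gz")
        save_nifti(c.larynx_mask, f"{stem}_larynx.nii.gz")
        save_nifti(c.dose, f"{stem}_dose.nii.gz")
        rows.append(
            {
                "id": c.id,
                **c.covariates.to_dict(),
                "prescription": round(c.prescription, 6),
                "rt_end_day": c.rt_end_day,
                "outcome": c.outcome,
                "ft_days": json.dumps([round(d, 4) for d in c.ft_days]),
                "weight_records": json.dumps(
                    [[round(d, 4), round(w, 4)] for d, w in c.weight_records]
                ),
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "clinical.csv", index=False)
    sidecar = {"truth": truth.to_dict()}
    if config is not None:
        sidecar["config"] = config.to_dict()
    with open(outdir / "truth.yaml", "w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=True)


def load_cohort(outdir) -> tuple[list[PatientCase], OutcomeTruthModel, ReferenceAnatomy]:
    """Load a written cohort.  Generator internals (true warp, analytic
    dose) are not persisted; downstream stages must use registration."""
    from pathlib import Path

    outdir = Path(outdir)
    ref = ReferenceAnatomy(
        pc_mask=_as_mask(load_nifti(outdir / "reference_pc.nii.gz")),
        larynx_mask=_as_mask(load_nifti(outdir / "reference_larynx.nii.gz")),
    )
    df = pd.read_csv(outdir / "clinical.csv")
    with open(outdir / "truth.yaml") as fh:
        sidecar = yaml.safe_load(fh)
    truth = OutcomeTruthModel.from_dict(sidecar["truth"])
    cases = []
    for i, row in df.iterrows():
        stem = outdir / "cases" / row["id"]
        cov = ClinicalCovariates(
            **{k: row[k] for k in COVARIATE_NAMES}, modality=row["modality"]
        )
        cases.append(
            PatientCase(
                id=row["id"],
                index=int(i),
                pc_mask=_as_mask(load_nifti(f"{stem}_pc.nii.gz")),
                larynx_mask=_as_mask(load_nifti(f"{stem}_larynx.nii.gz")),
                dose=load_nifti(f"{stem}_dose.nii.gz"),
                modality=row["modality"],
                covariates=cov,
                prescription=float(row["prescription"]),
                rt_end_day=float(row["rt_end_day"]),
                ft_days=json.loads(row["ft_days"]),
                weight_records=[tuple(r) for r in json.loads(row["weight_records"])],
                outcome=int(row["outcome"]),
            )
        )
    return cases, truth, ref


def _as_mask(vol: VolumeGrid) -> VolumeGrid:
    return vol.copy_with((vol.values > 0.5).astype(np.uint8))
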