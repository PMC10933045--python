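"""End-to-end orchestration: synth -> register -> dvh -> models -> report.

A single :class:`RunConfig` (YAML) drives every stage; all randomness
flows from one master seed through named substreams, so a rerun with the
same config reproduces every table, report, and volume.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, aggregate, dosimetry, voxel_model
from .grid import VolumeGrid, save_nifti
from .registration import RegistrationParams, flip_case, register, warp
from .synth import CohortConfig, generate_cohort, write_cohort

log = logging.getLogger(__name__)

UNIVARIATE_VARIABLES = (
    "treatment_setting",
    "bilateral",
    "chemotherapy",
    "baseline_weight",
    "adi",
    "dysphagia_grade0",
    "gender",
    "modality_proton",
    "smoker",
    "age",
)


class ConfigError(ValueError):
    pass


@dataclass
class ModelSettings:
    folds: int = 5
    trials: int = 50
    permutations: int = 50
    test_fraction: float = 0.2
    threshold: float = 0.5
    penalty_low: float = 1e-4
    penalty_high: float = 1e4
    penalty_num: int = 50
    importance_top_percent: float = 5.0

    def penalties(self) -> np.ndarray:
        return np.logspace(
            np.log10(self.penalty_low), np.log10(self.penalty_high), self.penalty_num
        )


@dataclass
class RunConfig:
    seed: int
    n: int
    out_dir: str
    cohort: CohortConfig = dc_field(default_factory=CohortConfig)
    registration: RegistrationParams = dc_field(default_factory=RegistrationParams)
    model: ModelSettings = dc_field(default_factory=ModelSettings)
    augment_flip: bool = True

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n": self.n,
            "out_dir": str(self.out_dir),
            "cohort": self.cohort.to_dict(),
            "registration": vars(self.registration).copy(),
            "model": vars(self.model).copy(),
            "augment_flip": self.augment_flip,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        for key in ("seed", "n", "out_dir"):
            if key not in d:
                raise ConfigError(f"config missing required key {key!r}")
        return cls(
            seed=int(d["seed"]),
            n=int(d["n"]),
            out_dir=str(d["out_dir"]),
            cohort=CohortConfig.from_dict(d.get("cohort", {})),
            registration=RegistrationParams(**d.get("registration", {})),
            model=ModelSettings(**d.get("model", {})),
            augment_flip=bool(d.get("augment_flip", True)),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _substream_seeds(master: int, names: list[str]) -> dict[str, int]:
    ss = np.random.SeedSequence(master)
    return {n: int(s.generate_state(1)[0]) % (2**31) for n, s in zip(names, ss.spawn(len(names)))}


def _volume_checksum(vol: VolumeGrid) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(vol.values.astype(np.float32)).tobytes())
    h.update(np.asarray(vol.spacing, dtype=np.float64).tobytes())
    h.update(np.asarray(vol.origin, dtype=np.float64).tobytes())
    return h.hexdigest()


def _file_checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def clinical_table(cases) -> pd.DataFrame:
    rows = []
    for c in cases:
        d = c.covariates.to_dict()
        d["id"] = c.id
        d["modality_proton"] = int(c.modality == "proton")
        d["outcome"] = int(c.outcome)
        rows.append(d)
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the run directory.

    Any stage failure raises with the stage name; a machine-readable
    error report is written to ``error.json`` in the run directory.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    seeds = _substream_seeds(config.seed, ["synth", "split", "voxel", "aggregate"])
    manifest: dict = {"version": __version__, "seeds": seeds, "checksums": {}, "stages": []}
    checks = manifest["checksums"]

    stage = "synth"
    try:
        cases, truth, ref = generate_cohort(config.n, config.cohort, seed=seeds["synth"])
        write_cohort(cases, truth, ref, out / "cohort", config=config.cohort)
        manifest["stages"].append(stage)
        checks["clinical.csv"] = _file_checksum(out / "cohort" / "clinical.csv")

        stage = "register"
        partition = aggregate.partition_subregions(
            ref.pc_mask,
            ref.larynx_mask,
            midline_halfwidth_mm=config.cohort.midline_halfwidth_mm,
            larynx_superior_fraction=config.cohort.larynx_superior_fraction,
        )
        qc_rows = []
        warped_dose: dict[str, dict[str, VolumeGrid]] = {"pc": {}, "larynx": {}}
        excluded: set[str] = set()
        reg_cases = list(cases)
        if config.augment_flip:
            reg_cases += [flip_case(c) for c in cases]
        for c in reg_cases:
            dose_scaled = dosimetry.rbe_scale(c.dose, c.modality)
            for organ in ("pc", "larynx"):
                moving = c.pc_mask if organ == "pc" else c.larynx_mask
                fld, qc = register(moving, ref.organ(organ), config.registration)
                qc_rows.append(
                    {
                        "id": c.id,
                        "organ": organ,
                        "dice_before": qc.dice_before,
                        "dice_after": qc.dice_after,
                        "pass": qc.pass_flag,
                    }
                )
                if qc.pass_flag:
                    warped_dose[organ][c.id] = warp(dose_scaled, fld, mode="linear")
                else:
                    excluded.add(c.id)
        qc_df = pd.DataFrame(qc_rows)
        qc_df.to_csv(out / "registration_qc.csv", index=False, float_format="%.6f")
        checks["registration_qc.csv"] = _file_checksum(out / "registration_qc.csv")
        if excluded:
            log.warning("%d case(s) failed registration QC and are excluded: %s",
                        len(excluded), sorted(excluded))
        manifest["qc_excluded"] = sorted(excluded)
        manifest["stages"].append(stage)

        stage = "dvh"
        dvh_rows = []
        for c in cases:
            dose_scaled = dosimetry.rbe_scale(c.dose, c.modality)
            dvh_rows.append(
                {"id": c.id, **dosimetry.dvh_feature_set(dose_scaled, c.pc_mask, c.larynx_mask)}
            )
        dvh_df = pd.DataFrame(dvh_rows)
        dvh_df.to_csv(out / "dvh_metrics.csv", index=False, float_format="%.8f")
        checks["dvh_metrics.csv"] = _file_checksum(out / "dvh_metrics.csv")
        manifest["stages"].append(stage)

        stage = "voxel_model"
        kept = [c for c in cases if c.id not in excluded and
                (not config.augment_flip or c.id + "_flip" not in excluded)]
        y = np.array([c.outcome for c in kept], dtype=int)
        ids = [c.id for c in kept]
        train_ids, test_ids = voxel_model.split_cohort(
            ids, y, test_fraction=config.model.test_fraction, seed=seeds["split"]
        )
        voxel_reports = {}
        for organ in ("pc", "larynx"):
            ref_mask = ref.organ(organ)
            matrix = voxel_model.extract_features(
                [warped_dose[organ][i] for i in ids], ref_mask, ids, organ=organ
            )
            id_pos = {i: k for k, i in enumerate(ids)}
            tr = np.array([id_pos[i] for i in train_ids])
            te = np.array([id_pos[i] for i in test_ids])
            aug_X = aug_src = None
            if config.augment_flip:
                aug_rows = [warped_dose[organ][i + "_flip"].values[
                    tuple(matrix.voxel_index.T)] for i in train_ids]
                aug_X = np.asarray(aug_rows)
                aug_src = np.array([id_pos[i] for i in train_ids])
            lam, cv_stats = voxel_model.tune_ridge(
                matrix.values[tr], y[tr], folds=config.model.folds, seed=seeds["voxel"],
                penalties=config.model.penalties(),
                augment_X=aug_X, augment_source=aug_src,
            )
            aug_y = y[aug_src] if aug_src is not None else None
            report = voxel_model.fit_ridge(
                matrix.values[tr], y[tr], matrix.values[te], y[te], lam,
                cv_stats=cv_stats, augment_X=aug_X, augment_y=aug_y,
            )
            cmap = voxel_model.coefficient_map(matrix, report)
            save_nifti(cmap.volume, out / f"coefficient_map_{organ}.nii.gz")
            checks[f"coefficient_map_{organ}.nii"] = _volume_checksum(cmap.volume)
            shares = voxel_model.importance_summary(
                cmap, partition, q=config.model.importance_top_percent
            )
            voxel_reports[organ] = {**report.to_dict(), "importance_shares": shares}
        with open(out / "voxel_model_reports.json", "w") as fh:
            json.dump(voxel_reports, fh, indent=2, sort_keys=True)
        checks["voxel_model_reports.json"] = _file_checksum(out / "voxel_model_reports.json")
        manifest["stages"].append(stage)

        stage = "aggregate_models"
        clin = clinical_table(cases)
        clin = clin[~clin["id"].isin({e.removesuffix("_flip") for e in excluded})]
        uni = aggregate.univariate_table(clin, list(UNIVARIATE_VARIABLES))
        uni.to_csv(out / "univariate.csv", index=False, float_format="%.6g")
        checks["univariate.csv"] = _file_checksum(out / "univariate.csv")
        selected = aggregate.select_covariates(uni) or list(
            aggregate.CLINICAL_MODEL_COVARIATES
        )
        regional_rows = []
        for c in kept:
            # regional doses from the organ-specific registrations
            pc_dose = warped_dose["pc"][c.id]
            lar_dose = warped_dose["larynx"][c.id]
            row = {"id": c.id}
            for name in partition.region_names:
                src = pc_dose if name.startswith("pc_") else lar_dose
                row[name] = dosimetry.mean_dose(src, partition.region_mask(name))
            regional_rows.append(row)
        reg_df = pd.DataFrame(regional_rows)
        reg_df.to_csv(out / "regional_doses.csv", index=False, float_format="%.8f")
        checks["regional_doses.csv"] = _file_checksum(out / "regional_doses.csv")

        clin_kept = clin[clin["id"].isin(ids)]
        tables = aggregate.build_feature_tables(
            clin_kept, dvh_df[dvh_df["id"].isin(ids)], reg_df, selected
        )
        y_kept = clin_kept.set_index("id").loc[tables["clinical"].index, "outcome"].to_numpy(int)
        trial_results = {}
        penalties = config.model.penalties()
        for name, table in tables.items():
            dist = aggregate.repeated_trials(
                table, y_kept, n_trials=config.model.trials, folds=config.model.folds,
                seed=seeds["aggregate"], penalties=penalties,
            )
            trial_results[name] = dist
        trials_df = pd.DataFrame(
            {f"{name}_auc": d.test_aucs for name, d in trial_results.items()}
            | {f"{name}_f1": d.f1s for name, d in trial_results.items()}
        )
        trials_df.to_csv(out / "trial_distributions.csv", index=False, float_format="%.8f")
        checks["trial_distributions.csv"] = _file_checksum(out / "trial_distributions.csv")

        importance = {}
        for name in ("dvh", "regional"):
            imp = aggregate.permutation_importance(
                tables[name], y_kept, n_reps=config.model.permutations,
                folds=config.model.folds, seed=seeds["aggregate"], penalties=penalties,
            )
            imp.table.to_csv(
                out / f"permutation_importance_{name}.csv", index=False, float_format="%.8f"
            )
            checks[f"permutation_importance_{name}.csv"] = _file_checksum(
                out / f"permutation_importance_{name}.csv"
            )
            importance[name] = imp
        if config.model.trials >= 10:
            comparisons = {
                "regional_vs_dvh": aggregate.compare_models(
                    trial_results["regional"].test_aucs, trial_results["dvh"].test_aucs
                ),
                "regional_vs_clinical": aggregate.compare_models(
                    trial_results["regional"].test_aucs, trial_results["clinical"].test_aucs
                ),
                "dvh_vs_clinical": aggregate.compare_models(
                    trial_results["dvh"].test_aucs, trial_results["clinical"].test_aucs
                ),
            }
        else:
            comparisons = {"note": "fewer than 10 trials: rank-sum comparison skipped"}
        with open(out / "model_comparisons.json", "w") as fh:
            json.dump(comparisons, fh, indent=2, sort_keys=True)
        checks["model_comparisons.json"] = _file_checksum(out / "model_comparisons.json")
        manifest["stages"].append(stage)

        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return out
    except Exception as exc:
        with open(out / "error.json", "w") as fh:
            json.dump({"stage": stage, "error": str(exc), "type": type(exc).__name__}, fh)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def report(run_dir) -> Path:
    """Human-readable summary of a completed run (tables + figures)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run_dir = Path(run_dir)
    required = [
        "manifest.json",
        "registration_qc.csv",
        "trial_distributions.csv",
        "univariate.csv",
        "voxel_model_reports.json",
    ]
    missing = [f for f in required if not (run_dir / f).exists()]
    if missing:
        raise FileNotFoundError(f"incomplete run; missing artifacts: {missing}")

    trials = pd.read_csv(run_dir / "trial_distributions.csv")
    qc = pd.read_csv(run_dir / "registration_qc.csv")
    with open(run_dir / "voxel_model_reports.json") as fh:
        voxel_reports = json.load(fh)

    auc_cols = [c for c in trials.columns if c.endswith("_auc")]
    fig, ax = plt.subplots(figsize=(6, 4))
    data = [trials[c] for c in auc_cols]
    ax.boxplot(data, tick_labels=[c.removesuffix("_auc") for c in auc_cols])
    n_trials = len(trials)
    title = "Test AUC over trials"
    if n_trials < 2:
        title += " (single trial: no spread shown)"
    ax.set_ylabel("test AUC")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(run_dir / "model_aucs.png", dpi=120)
    plt.close(fig)

    lines = ["# Run summary", ""]
    lines.append(f"- registrations: {len(qc)}, QC pass rate "
                 f"{qc['pass'].mean():.3f}, mean Dice {qc['dice_after'].mean():.3f}")
    for organ, rep in voxel_reports.items():
        lines.append(
            f"- voxel model [{organ}]: test AUC {rep['test_auc']:.3f}, "
            f"accuracy {rep['accuracy']:.3f}, F1 {rep['f1']:.3f} "
            f"(see voxel_model_reports.json)"
        )
    for c in auc_cols:
        name = c.removesuffix("_auc")
        sd_note = f" ± {trials[c].std(ddof=0):.3f}" if n_trials > 1 else " (sd omitted: 1 trial)"
        lines.append(f"- {name} model: mean test AUC {trials[c].mean():.3f}{sd_note}")
    lines.append("")
    lines.append("Tables: univariate.csv, permutation_importance_{dvh,regional}.csv, "
                 "trial_distributions.csv, registration_qc.csv")
    lines.append("Figures: model_aucs.png")
    (run_dir / "summary.md").write_text("\n".join(lines) + "\n")
    return run_dir / "summary.md"
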