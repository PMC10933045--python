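# voxdose

Voxel-based radiotherapy dose–outcome analysis for midline swallowing
structures, built around a synthetic cohort generator with a *planted*
radiosensitive subregion so every stage is testable offline.

The pipeline:

1. **synthetic cohort** (`voxdose.synth`) — reference anatomy (a
   pharyngeal-constrictor-like posterior shell and a larynx-like
   ellipsoid), per-patient smooth deformations + affine jitter, analytic
   dose blobs spanning 30–81.6 Gy prescriptions, clinical covariates, and
   a binary feeding-tube / >10%-weight-loss (FT/WL) outcome drawn from a
   known logistic truth model driven by mean dose to a chosen organ
   subregion.
2. **spatial normalization** (`voxdose.registration`) — rigid + affine +
   demons-style registration of organ masks (via signed distance
   transforms) into the reference frame, dose warping with the same
   deformation, Dice QC with a 0.7 gate, and left–right flip
   augmentation.
3. **dosimetry** (`voxdose.dosimetry`) — RBE scaling (×1.1 for protons,
   applied exactly once), mean dose, VxGy metrics (inclusive threshold),
   cumulative DVHs, and the 7-metric DVH feature set.
4. **voxel model** (`voxdose.voxel_model`) — patient × in-mask-voxel dose
   matrices, stratified 80/20 split, fold-level standardization, ridge
   logistic regression tuned by 5-fold CV on ROC AUC, coefficient maps in
   the reference frame, and top-|coefficient| subregion shares.
5. **aggregated models** (`voxdose.aggregate`) — univariate logistic
   screening (ORs, Wald CIs, p-values), clinical-only / DVH-metrics /
   regional-dose models on an 8-region geometric partition (6 pc + 2
   larynx), 50-trial repeated evaluation, permutation feature importance,
   and Wilcoxon rank-sum model comparison.
6. **pipeline** (`voxdose.pipeline`, `voxdose.cli`) — single-config
   orchestration with deterministic seed substreams and a checksum
   manifest.

## CLI

```bash
voxdose synth --n 60 --seed 1 --out runs/cohort
voxdose register --cohort runs/cohort --organ pc --out runs/reg
voxdose dvh --cohort runs/cohort --out runs/metrics.csv
voxdose train-voxel --cohort runs/cohort --organ pc --seed 1 --out runs/voxel
voxdose train-aggregate --cohort runs/cohort --model regional --trials 50 --seed 1 --out runs/regional.csv
voxdose compare --a runs/regional.csv --b runs/dvh.csv
voxdose run --config run.yaml      # full pipeline + summary report
```

A minimal `run.yaml`:

```yaml
seed: 1
n: 60
out_dir: runs/full
cohort: {shape: [64, 64, 80]}
model: {trials: 50, permutations: 50}
```

## Conventions

- Grids are `(x, y, z)` = (left–right, anterior–posterior,
  inferior–superior); physical coordinate of voxel `(i, j, k)` is
  `origin + (i, j, k) * spacing` (mm).
- Deformation fields use the pull-back convention: for each reference
  voxel at position `p`, the moving volume is sampled at
  `p + displacement(p)`.
- All randomness flows from explicit seeds; identical configs reproduce
  identical outputs (tables byte-for-byte, volumes voxel-for-voxel).
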