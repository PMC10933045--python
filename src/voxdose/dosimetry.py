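"""Dose metrics: RBE scaling, mean/regional dose, VxGy, cumulative DVHs."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import GridError, VolumeGrid

RBE_PROTON = 1.1

#: the seven dosimetric features of the DVH-metrics model
DVH_FEATURE_NAMES = (
    "pc_mean_dose",
    "larynx_mean_dose",
    "larynx_v50",
    "larynx_v60",
    "pc_v50",
    "pc_v55",
    "pc_v60",
)


class DoseError(ValueError):
    pass


def rbe_scale(dose: VolumeGrid, modality: str) -> VolumeGrid:
    """Scale proton physical dose by 1.1; photon dose is returned unchanged.

    The returned volume carries an ``rbe_scaled`` tag; scaling an
    already-scaled volume raises, so the factor is applied exactly once.
    """
    if modality not in ("photon", "proton"):
        raise DoseError(f"unknown modality {modality!r}")
    if np.any(dose.values < 0):
        raise DoseError("dose must be non-negative")
    if dose.tags.get("rbe_scaled"):
        raise DoseError("dose volume already RBE-scaled; refusing to scale twice")
    factor = RBE_PROTON if modality == "proton" else 1.0
    return dose.copy_with(dose.values * factor, rbe_scaled=True)


def _check_pair(dose: VolumeGrid, mask: VolumeGrid) -> np.ndarray:
    if not dose.same_grid(mask):
        raise GridError("dose and mask must share a grid")
    mask.validate_mask()
    return mask.values > 0.5


def mean_dose(dose: VolumeGrid, mask: VolumeGrid) -> float:
    """Arithmetic mean dose (Gy) over mask voxels."""
    sel = _check_pair(dose, mask)
    return float(dose.values[sel].mean())


def v_at_dose(dose: VolumeGrid, mask: VolumeGrid, x: float) -> float:
    """VxGy: percent of organ volume receiving ``x`` Gy or more (inclusive)."""
    if x < 0:
        raise DoseError(f"dose threshold must be non-negative, got {x}")
    sel = _check_pair(dose, mask)
    vals = dose.values[sel]
    return 100.0 * float((vals >= x).sum()) / vals.size


@dataclass
class DVHCurve:
    """Cumulative DVH: percent volume receiving at least each dose edge."""

    dose_edges: np.ndarray
    volume_percent: np.ndarray

    def __post_init__(self) -> None:
        self.dose_edges = np.asarray(self.dose_edges, dtype=float)
        self.volume_percent = np.asarray(self.volume_percent, dtype=float)
        if self.dose_edges.shape != self.volume_percent.shape:
            raise DoseError("edge/volume arrays must have equal length")
        if np.any(np.diff(self.dose_edges) <= 0):
            raise DoseError("dose edges must be strictly ascending")
        if np.any(np.diff(self.volume_percent) > 1e-12):
            raise DoseError("cumulative DVH must be non-increasing")


def cumulative_dvh(dose: VolumeGrid, mask: VolumeGrid, bin_width: float = 0.1) -> DVHCurve:
    """Cumulative DVH sampled at edges ``0, bin_width, ...`` past max dose."""
    if bin_width <= 0:
        raise DoseError(f"bin_width must be positive, got {bin_width}")
    sel = _check_pair(dose, mask)
    vals = np.sort(dose.values[sel].astype(float))
    top = vals[-1] + bin_width
    edges = np.arange(0.0, top + bin_width, bin_width)
    # percent of voxels with dose >= edge
    counts = vals.size - np.searchsorted(vals, edges, side="left")
    return DVHCurve(edges, 100.0 * counts / vals.size)


def dvh_feature_set_from_samples(
    pc_dose: np.ndarray, larynx_dose: np.ndarray
) -> dict[str, float]:
    """DVH-model metrics computed from in-mask dose samples directly.

    Equivalent to :func:`dvh_feature_set` when the sample vectors are the
    in-mask voxel doses; useful when only per-voxel dose vectors exist.
    """
    pc = np.asarray(pc_dose, dtype=float)
    lar = np.asarray(larynx_dose, dtype=float)
    if pc.size == 0 or lar.size == 0:
        raise DoseError("empty organ dose sample vector")

    def pct(vals: np.ndarray, x: float) -> float:
        return 100.0 * float((vals >= x).sum()) / vals.size

    return {
        "pc_mean_dose": float(pc.mean()),
        "larynx_mean_dose": float(lar.mean()),
        "larynx_v50": pct(lar, 50.0),
        "larynx_v60": pct(lar, 60.0),
        "pc_v50": pct(pc, 50.0),
        "pc_v55": pct(pc, 55.0),
        "pc_v60": pct(pc, 60.0),
    }


def dvh_feature_set(
    dose: VolumeGrid,
    pc_mask: VolumeGrid,
    larynx_mask: VolumeGrid,
    include_pc_v65: bool = False,
) -> dict[str, float]:
    """The DVH-metrics model's dosimetric features.

    Mean pc and larynx dose, larynx V50/V60 and pc V50/V55/V60 (percent).
    ``include_pc_v65`` optionally appends pc V65.
    """
    for name, m in (("pc", pc_mask), ("larynx", larynx_mask)):
        if m is None or (m.values > 0.5).sum() == 0:
            raise DoseError(f"missing or empty organ mask: {name}")
    feats = {
        "pc_mean_dose": mean_dose(dose, pc_mask),
        "larynx_mean_dose": mean_dose(dose, larynx_mask),
        "larynx_v50": v_at_dose(dose, larynx_mask, 50.0),
        "larynx_v60": v_at_dose(dose, larynx_mask, 60.0),
        "pc_v50": v_at_dose(dose, pc_mask, 50.0),
        "pc_v55": v_at_dose(dose, pc_mask, 55.0),
        "pc_v60": v_at_dose(dose, pc_mask, 60.0),
    }
    if include_pc_v65:
        feats["pc_v65"] = v_at_dose(dose, pc_mask, 65.0)
    return feats
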