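"""Volumetric grid primitives shared by all pipeline stages.

A :class:`VolumeGrid` couples a 3D scalar array with its voxel spacing and
physical origin.  The axis convention is fixed throughout the package:
axis 0 = x (left-right), axis 1 = y (anterior-posterior),
axis 2 = z (inferior-superior).  Physical coordinates of voxel ``(i, j, k)``
are ``origin + (i, j, k) * spacing`` (mm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage


class GridError(ValueError):
    """Raised for invalid grid geometry or incompatible grid operands."""


@dataclass
class VolumeGrid:
    """3D scalar volume with spacing/origin metadata.

    Parameters
    ----------
    values
        3D array.  Gy for dose volumes, {0, 1} for masks.
    spacing
        Per-axis voxel size in mm; all entries must be positive.
    origin
        Physical coordinate (mm) of the first voxel.
    tags
        Free-form provenance flags (e.g. ``rbe_scaled``).
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    tags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise GridError(f"values must be 3D, got ndim={self.values.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or len(self.origin) != 3:
            raise GridError("spacing and origin must have length 3")
        if any(s <= 0 for s in self.spacing):
            raise GridError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise GridError("values must be finite")

    # -- basic accessors -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def same_grid(self, other: "VolumeGrid", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def copy_with(self, values: np.ndarray, **tags) -> "VolumeGrid":
        return VolumeGrid(values, self.spacing, self.origin, {**self.tags, **tags})

    def is_mask(self) -> bool:
        return bool(np.isin(self.values, (0, 1)).all())

    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def physical_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis physical coordinate vectors (mm)."""
        return tuple(
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a]
            for a in range(3)
        )

    def index_grid_physical(self) -> np.ndarray:
        """Dense (nx, ny, nz, 3) array of physical voxel coordinates."""
        ax = self.physical_coords()
        return np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1)

    def validate_mask(self, allow_empty: bool = False) -> None:
        if not self.is_mask():
            raise GridError("expected a binary {0,1} mask volume")
        if not allow_empty and self.values.sum() == 0:
            raise GridError("mask is empty")


# -- overlap and geometry ------------------------------------------------


def dice(a: VolumeGrid, b: VolumeGrid) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|) of two masks on the same grid."""
    if not a.same_grid(b):
        raise GridError("dice requires masks on the same grid")
    av = a.values > 0.5
    bv = b.values > 0.5
    na, nb = int(av.sum()), int(bv.sum())
    if na + nb == 0:
        raise GridError("dice undefined: both masks empty")
    return 2.0 * int((av & bv).sum()) / (na + nb)


def mask_bounding_box(mask: VolumeGrid) -> tuple[np.ndarray, np.ndarray]:
    """Inclusive (lo, hi) voxel index bounds of the nonzero region."""
    nz = np.nonzero(mask.values > 0.5)
    if nz[0].size == 0:
        raise GridError("mask is empty")
    lo = np.array([int(n.min()) for n in nz])
    hi = np.array([int(n.max()) for n in nz])
    return lo, hi


def crop_to_organ(volume: VolumeGrid, mask: VolumeGrid, margin: float = 4.0) -> VolumeGrid:
    """Crop ``volume`` to the mask bounding box dilated by ``margin`` mm.

    The dilation per axis is ``ceil(margin / spacing)`` voxels, clipped to
    the volume extent.  Origin metadata is updated so physical coordinates
    are preserved.
    """
    if not volume.same_grid(mask):
        raise GridError("crop_to_organ requires volume and mask on the same grid")
    lo, hi = mask_bounding_box(mask)
    pad = np.array([math.ceil(margin / s) for s in volume.spacing])
    lo = np.maximum(lo - pad, 0)
    hi = np.minimum(hi + pad, np.array(volume.shape) - 1)
    sl = tuple(slice(int(a), int(b) + 1) for a, b in zip(lo, hi))
    new_origin = tuple(
        volume.origin[a] + int(lo[a]) * volume.spacing[a] for a in range(3)
    )
    return VolumeGrid(volume.values[sl].copy(), volume.spacing, new_origin, dict(volume.tags))


def resample(
    volume: VolumeGrid,
    target_spacing: tuple[float, float, float],
    mode: str = "linear",
) -> VolumeGrid:
    """Resample onto a grid with ``target_spacing``, preserving extent.

    ``mode='nearest'`` must be used for masks so outputs stay binary.
    """
    target_spacing = tuple(float(s) for s in target_spacing)
    if any(s <= 0 for s in target_spacing):
        raise GridError(f"target spacing must be positive, got {target_spacing}")
    if mode not in ("linear", "nearest"):
        raise GridError(f"unknown resampling mode {mode!r}")
    order = 1 if mode == "linear" else 0
    new_shape = tuple(
        max(1, int(round(volume.shape[a] * volume.spacing[a] / target_spacing[a])))
        for a in range(3)
    )
    # sample points expressed in source voxel index coordinates
    idx = [
        np.arange(new_shape[a]) * target_spacing[a] / volume.spacing[a]
        for a in range(3)
    ]
    coords = np.meshgrid(*idx, indexing="ij")
    out = ndimage.map_coordinates(
        volume.values.astype(float), np.stack(coords), order=order, mode="nearest"
    )
    if volume.is_mask():
        out = (out > 0.5).astype(volume.values.dtype) if order == 0 else out
    return VolumeGrid(out, target_spacing, volume.origin, dict(volume.tags))


def flip_lr(volume: VolumeGrid) -> VolumeGrid:
    """Mirror a volume about its own left-right (x) center plane.

    Involution: ``flip_lr(flip_lr(v)) == v`` voxel-exactly.  The origin is
    unchanged: mirroring is about the grid's central x plane, so the volume
    occupies the same physical box.
    """
    return VolumeGrid(
        volume.values[::-1, :, :].copy(), volume.spacing, volume.origin, dict(volume.tags)
    )


def mask_centroid(mask: VolumeGrid) -> np.ndarray:
    """Physical-coordinate centroid (mm) of a mask."""
    idx = np.argwhere(mask.values > 0.5)
    if idx.size == 0:
        raise GridError("mask is empty")
    return np.asarray(mask.origin) + idx.mean(axis=0) * np.asarray(mask.spacing)


# -- NIfTI I/O -----------------------------------------------------------


def _affine(volume: VolumeGrid) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = volume.spacing
    aff[:3, 3] = volume.origin
    return aff


def save_nifti(volume: VolumeGrid, path) -> None:
    img = nib.Nifti1Image(np.asarray(volume.values, dtype=np.float32), _affine(volume))
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def load_nifti(path) -> VolumeGrid:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    aff = img.affine
    spacing = tuple(float(abs(aff[a, a])) for a in range(3))
    origin = tuple(float(aff[a, 3]) for a in range(3))
    return VolumeGrid(data, spacing, origin)
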