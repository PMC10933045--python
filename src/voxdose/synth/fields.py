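"""Smooth random displacement fields for synthetic anatomy generation.

Fields are stored at a coarse stride over the full grid (they are
band-limited by construction, so a stride-2 representation is lossless in
practice) and interpolated on demand.  Displacements are in mm and follow
the pull-back convention used throughout the package: a field ``u`` on a
grid maps voxel physical position ``p`` to the sampling position
``p + u(p)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass
class CoarseField:
    """Displacement field (mm) sampled on a strided copy of a full grid."""

    disp: np.ndarray  # (cx, cy, cz, 3) float32, mm
    stride: int
    spacing: tuple[float, float, float]  # full-resolution spacing, mm
    origin: tuple[float, float, float]
    full_shape: tuple[int, int, int]

    def sample_at_voxels(self, vox: np.ndarray) -> np.ndarray:
        """Interpolate displacement (mm) at full-resolution voxel indices.

        ``vox``: (..., 3) float array of full-resolution (possibly
        fractional) voxel indices.
        """
        coarse_idx = np.moveaxis(vox, -1, 0) / self.stride
        out = np.empty(vox.shape, dtype=np.float64)
        for c in range(3):
            out[..., c] = ndimage.map_coordinates(
                self.disp[..., c].astype(np.float64),
                coarse_idx,
                order=1,
                mode="nearest",
            )
        return out

    def sample_at_points(self, points_mm: np.ndarray) -> np.ndarray:
        vox = (points_mm - np.asarray(self.origin)) / np.asarray(self.spacing)
        return self.sample_at_voxels(vox)


def smooth_random_field(
    full_shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    origin: tuple[float, float, float],
    rng: np.random.Generator,
    sigma_mm: float = 12.0,
    max_mm: float = 8.0,
    stride: int = 3,
) -> CoarseField:
    """Band-limited random displacement: Gaussian-smoothed white noise.

    White-noise vector components are smoothed with a Gaussian kernel of
    ``sigma_mm`` and the field is rescaled so its largest displacement
    magnitude equals ``max_mm``.
    """
    cshape = tuple(int(np.ceil(s / stride)) for s in full_shape)
    csp = tuple(s * stride for s in spacing)
    noise = rng.standard_normal(size=(*cshape, 3))
    disp = np.empty_like(noise)
    sig_vox = [sigma_mm / s for s in csp]
    for c in range(3):
        disp[..., c] = ndimage.gaussian_filter(noise[..., c], sigma=sig_vox, mode="nearest")
    mag = np.sqrt((disp**2).sum(axis=-1))
    peak = mag.max()
    if peak > 0:
        disp *= max_mm / peak
    else:  # degenerate: no noise
        disp[:] = 0.0
    return CoarseField(disp.astype(np.float32), stride, tuple(spacing), tuple(origin), tuple(full_shape))


def affine_params(
    rng: np.random.Generator,
    rot_deg_sd: float = 3.0,
    scale_sd: float = 0.03,
    trans_mm_sd: float = 3.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Random small affine jitter: z-rotation, anisotropic scale, shift."""
    theta = np.deg2rad(rng.normal(0.0, rot_deg_sd))
    scales = 1.0 + rng.normal(0.0, scale_sd, size=3)
    rot = np.array(
        [
            [np.cos(theta), -np.sin(theta), 0.0],
            [np.sin(theta), np.cos(theta), 0.0],
            [0.0, 0.0, 1.0],
        ]
    )
    mat = rot @ np.diag(scales)
    shift = rng.normal(0.0, trans_mm_sd, size=3)
    return mat, shift


def compose_affine_with_field(
    field: CoarseField,
    mat: np.ndarray,
    shift: np.ndarray,
    center_mm: np.ndarray,
) -> CoarseField:
    """Total displacement for the map p -> A(p - c) + c + t + s(p).

    Returned as a coarse displacement field (the affine part is linear, so
    stride interpolation is exact for it).
    """
    cshape = field.disp.shape[:3]
    csp = np.asarray(field.spacing) * field.stride
    ax = [field.origin[a] + np.arange(cshape[a]) * csp[a] for a in range(3)]
    pts = np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1)
    rel = pts - center_mm
    aff_disp = rel @ mat.T + center_mm + shift - pts
    total = field.disp.astype(np.float64) + aff_disp
    return CoarseField(
        total.astype(np.float32), field.stride, field.spacing, field.origin, field.full_shape
    )


def invert_field(field: CoarseField, iters: int = 8) -> CoarseField:
    """Fixed-point inverse displacement: v(p) = -u(p + v(p)).

    Accurate for smooth, moderate-amplitude fields (the generator's
    regime); convergence is geometric when ||∇u|| < 1.
    """
    cshape = field.disp.shape[:3]
    csp = np.asarray(field.spacing) * field.stride
    base_vox = np.stack(
        np.meshgrid(*[np.arange(n, dtype=np.float64) for n in cshape], indexing="ij"),
        axis=-1,
    )  # coarse voxel indices
    v = np.zeros_like(field.disp, dtype=np.float64)
    for _ in range(iters):
        # full-resolution voxel index of p + v(p)
        shifted_vox = base_vox * field.stride + v / np.asarray(field.spacing)
        v = -field.sample_at_voxels(shifted_vox)
    return CoarseField(
        v.astype(np.float32), field.stride, field.spacing, field.origin, field.full_shape
    )


def warp_masks_bbox(
    masks: list[np.ndarray],
    spacing: tuple[float, float, float],
    field: CoarseField,
    bbox: tuple[np.ndarray, np.ndarray],
) -> list[np.ndarray]:
    """Pull-back warp of binary masks, evaluated only inside a bounding
    box (voxel index lo/hi, inclusive); everything outside is 0.

    The displacement is sampled once and shared across masks.
    """
    lo, hi = bbox
    full_shape = field.full_shape
    ax = [np.arange(lo[a], hi[a] + 1, dtype=np.float64) for a in range(3)]
    vox = np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1)
    disp = field.sample_at_voxels(vox)
    sample_vox = np.moveaxis(vox + disp / np.asarray(spacing), -1, 0)
    out = []
    for m in masks:
        warped = ndimage.map_coordinates(
            m.astype(np.float32), sample_vox, order=1, mode="constant", cval=0.0
        )
        full = np.zeros(full_shape, dtype=np.uint8)
        full[lo[0]: hi[0] + 1, lo[1]: hi[1] + 1, lo[2]: hi[2] + 1] = warped > 0.5
        out.append(full)
    return out


def warp_volume_values(
    values: np.ndarray,
    spacing: tuple[float, float, float],
    origin: tuple[float, float, float],
    field: CoarseField,
    order: int = 1,
) -> np.ndarray:
    """Pull-back warp of a full-resolution array through a coarse field.

    Output voxel ``p`` takes the value of ``values`` at ``p + field(p)``.
    """
    full_shape = field.full_shape
    vox = np.stack(
        np.meshgrid(*[np.arange(n, dtype=np.float64) for n in full_shape], indexing="ij"),
        axis=-1,
    )
    disp = field.sample_at_voxels(vox)
    sample_vox = vox + disp / np.asarray(spacing)
    out = ndimage.map_coordinates(
        values.astype(np.float64),
        np.moveaxis(sample_vox, -1, 0),
        order=order,
        mode="constant",
        cval=0.0,
    )
    return out
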