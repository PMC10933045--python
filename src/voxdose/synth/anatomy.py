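"""Reference anatomy: midline tubular and ellipsoidal organ masks.

The reference frame carries two organs used throughout the analysis:

* a pharyngeal-constrictor-like structure (``pc``): a curved posterior
  half-shell spanning most of the superior-inferior extent;
* a larynx-like structure (``larynx``): an ellipsoid sitting anterior and
  inferior, overlapping the pc's z-range at its lower end.

Both are exactly midline-symmetric before voxelization.  All sizes are in
mm so the same organs fit any sufficiently large grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..grid import GridError, VolumeGrid

# organ dimensions (mm); jittered slightly by seed in make_reference
_PC_HEIGHT = 48.0
_PC_Z_OFFSET = 4.0  # pc z-center sits this far superior of the grid z-center
_PC_RADIUS_SUP = 9.0
_PC_RADIUS_INF = 11.5
_PC_THICKNESS = 4.5
_LAR_SEMI = (13.0, 10.0, 16.0)
_LAR_Y_SHIFT = -7.0  # anterior of grid center
_LAR_Z_SHIFT = -7.0  # inferior of grid center

# margin for organ + crop margin + deformation headroom
_REQUIRED_EXTENT_MM = (52.0, 56.0, 72.0)


class SizingError(GridError):
    """Grid too small to contain the reference organs plus margin."""


@dataclass
class ReferenceAnatomy:
    """Reference organ masks on a shared grid."""

    pc_mask: VolumeGrid
    larynx_mask: VolumeGrid

    @property
    def grid(self) -> VolumeGrid:
        return self.pc_mask

    def organ(self, name: str) -> VolumeGrid:
        if name == "pc":
            return self.pc_mask
        if name == "larynx":
            return self.larynx_mask
        raise KeyError(f"unknown organ {name!r}; expected 'pc' or 'larynx'")


def make_reference(
    shape: tuple[int, int, int] = (96, 96, 120),
    spacing: tuple[float, float, float] = (1.27, 1.27, 1.0),
    seed: int = 0,
) -> ReferenceAnatomy:
    """Build the reference anatomy on the requested grid.

    Deterministic for a fixed seed; raises :class:`SizingError` when the
    physical extent cannot contain the organs with margin.
    """
    shape = tuple(int(s) for s in shape)
    spacing = tuple(float(s) for s in spacing)
    extent = tuple(shape[a] * spacing[a] for a in range(3))
    if any(extent[a] < _REQUIRED_EXTENT_MM[a] for a in range(3)):
        need = tuple(
            int(np.ceil(_REQUIRED_EXTENT_MM[a] / spacing[a])) for a in range(3)
        )
        raise SizingError(
            f"grid extent {extent} mm too small for reference organs; "
            f"need at least {_REQUIRED_EXTENT_MM} mm "
            f"({need} voxels at spacing {spacing})"
        )

    rng = np.random.default_rng(seed)
    pc_height = _PC_HEIGHT + rng.uniform(-2.0, 2.0)
    r_sup = _PC_RADIUS_SUP + rng.uniform(-0.5, 0.5)
    r_inf = _PC_RADIUS_INF + rng.uniform(-0.5, 0.5)
    thickness = _PC_THICKNESS + rng.uniform(-0.3, 0.3)
    lar_semi = np.array(_LAR_SEMI) + rng.uniform(-0.5, 0.5, size=3)

    ax = [np.arange(shape[a]) * spacing[a] for a in range(3)]
    center = np.array([a[-1] / 2.0 for a in ax])
    x, y, z = np.meshgrid(*ax, indexing="ij")

    # pc: posterior half-shell around a gently curving tube axis
    z0 = center[2] + _PC_Z_OFFSET - pc_height / 2.0
    z1 = z0 + pc_height
    frac = np.clip((z - z0) / pc_height, 0.0, 1.0)
    yc = center[1] + 8.0 + 3.0 * np.sin(np.pi * frac)  # posterior, bulging mid
    radius = r_inf + (r_sup - r_inf) * frac
    rad_dist = np.sqrt((x - center[0]) ** 2 + (y - yc) ** 2)
    pc = (
        (z >= z0)
        & (z <= z1)
        & (np.abs(rad_dist - radius) <= thickness / 2.0)
        & (y >= yc - 1.0)
    )

    # larynx: ellipsoid anterior-inferior of the pc
    lc = center + np.array([0.0, _LAR_Y_SHIFT, _LAR_Z_SHIFT])
    lar = (
        ((x - lc[0]) / lar_semi[0]) ** 2
        + ((y - lc[1]) / lar_semi[1]) ** 2
        + ((z - lc[2]) / lar_semi[2]) ** 2
    ) <= 1.0

    pc_mask = VolumeGrid(pc.astype(np.uint8), spacing, (0.0, 0.0, 0.0))
    lar_mask = VolumeGrid(lar.astype(np.uint8), spacing, (0.0, 0.0, 0.0))
    pc_mask.validate_mask()
    lar_mask.validate_mask()
    return ReferenceAnatomy(pc_mask=pc_mask, larynx_mask=lar_mask)
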