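"""Synthetic density grids and the real-space correlation coefficient.

The RSCC compares "observed" density with density calculated from a
model over the voxels near a residue; a low value flags a model that
does not explain its density.  Crystallographic map synthesis is far out
of desk scale, so calculated density here is a sum of unit-height
isotropic Gaussians at the atom centres -- sufficient for the masked
Pearson correlation to behave like the real metric (a model in the
wrong ring conformation scores lower against density generated from the
right one), but not numerically comparable to values from refinement
pipelines.

Grids are axis-aligned with per-axis spacing and can be exchanged with
other software as CCP4/MRC maps.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .cif_io import MonomerCoordinates

#: Gaussian width (standard deviation, Angstrom) of a calculated atom
GAUSSIAN_WIDTH = 0.9
#: default mask radius (Angstrom) around atoms for the RSCC
MASK_RADIUS = 2.5


class UndefinedRsccError(ValueError):
    """Masked density has zero variance; the correlation is undefined."""


@dataclass
class DensityGrid:
    """Axis-aligned orthogonal density grid.

    ``origin`` is the Cartesian position of voxel (0,0,0); ``spacing``
    the per-axis step in Angstrom; ``values`` a 3-D array.
    """

    origin: np.ndarray
    spacing: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, float)
        self.spacing = np.asarray(self.spacing, float)
        self.values = np.asarray(self.values, float)
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ValueError("spacing must be three positive numbers")
        if self.values.ndim != 3 or not np.all(np.isfinite(self.values)):
            raise ValueError("values must be a finite 3-D array")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin[i] + self.spacing[i] * np.arange(self.shape[i])
            for i in range(3)
        )

    def like(self, values: np.ndarray) -> "DensityGrid":
        return DensityGrid(self.origin.copy(), self.spacing.copy(), values)

    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))


def make_grid(
    c: MonomerCoordinates,
    spacing: float = 0.3,
    padding: float = 3.0,
) -> DensityGrid:
    """Empty grid covering the atoms of ``c`` with a margin."""
    pts = c.array(c.atoms())
    lo = pts.min(axis=0) - padding
    hi = pts.max(axis=0) + padding
    shape = np.maximum(np.ceil((hi - lo) / spacing).astype(int) + 1, 2)
    return DensityGrid(lo, np.full(3, float(spacing)), np.zeros(shape))


def calc_density(
    c: MonomerCoordinates,
    template: DensityGrid,
    width: float = GAUSSIAN_WIDTH,
) -> DensityGrid:
    """Model density: unit-peak isotropic Gaussians at the atom centres.

    Atoms outside the grid contribute whatever tail falls inside it.
    """
    if width <= 0:
        raise ValueError("width must be > 0")
    ax, ay, az = template.axes()
    out = np.zeros(template.shape)
    inv2w2 = 1.0 / (2.0 * width * width)
    for name in c.atoms():
        x, y, z = c[name]
        dx2 = (ax - x) ** 2
        dy2 = (ay - y) ** 2
        dz2 = (az - z) ** 2
        out += np.exp(
            -(dx2[:, None, None] + dy2[None, :, None] + dz2[None, None, :])
            * inv2w2
        )
    return template.like(out)


def atom_mask(
    grid: DensityGrid, centre: MonomerCoordinates, radius: float
) -> np.ndarray:
    """Boolean mask of voxels within ``radius`` of any atom of ``centre``."""
    ax, ay, az = grid.axes()
    mask = np.zeros(grid.shape, dtype=bool)
    r2 = radius * radius
    for name in centre.atoms():
        x, y, z = centre[name]
        d2 = (
            (ax - x)[:, None, None] ** 2
            + (ay - y)[None, :, None] ** 2
            + (az - z)[None, None, :] ** 2
        )
        mask |= d2 <= r2
    return mask


def rscc(
    obs: DensityGrid,
    calc: DensityGrid,
    mask_centre: MonomerCoordinates,
    mask_radius: float = MASK_RADIUS,
) -> float:
    """Masked Pearson correlation of observed vs calculated density.

    The mask selects voxels within ``mask_radius`` of any atom of
    ``mask_centre``.  Invariant under affine rescaling of either map.
    """
    if obs.shape != calc.shape or not np.allclose(obs.spacing, calc.spacing) \
            or not np.allclose(obs.origin, calc.origin):
        raise ValueError("observed and calculated grids must share geometry")
    mask = atom_mask(obs, mask_centre, mask_radius)
    n = int(mask.sum())
    if n < 2:
        raise ValueError(f"mask selects only {n} voxel(s)")
    a = obs.values[mask]
    b = calc.values[mask]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedRsccError("zero variance inside the mask")
    return float(np.corrcoef(a, b)[0, 1])


# ---------------------------------------------------------------------------
# CCP4/MRC interchange


def write_ccp4(grid: DensityGrid, path: str | Path) -> None:
    """Write the grid as a CCP4/MRC map (P1 cell sized to the grid)."""
    import gemmi

    nx, ny, nz = grid.shape
    cell = gemmi.UnitCell(
        nx * grid.spacing[0], ny * grid.spacing[1], nz * grid.spacing[2],
        90, 90, 90,
    )
    fg = gemmi.FloatGrid(np.ascontiguousarray(grid.values, dtype=np.float32))
    fg.set_unit_cell(cell)
    fg.spacegroup = gemmi.SpaceGroup("P1")
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = fg
    ccp4.update_ccp4_header()
    ccp4.write_ccp4_map(str(path))


def read_ccp4(path: str | Path, origin: np.ndarray | None = None) -> DensityGrid:
    """Read a CCP4/MRC map written by :func:`write_ccp4`."""
    import gemmi

    ccp4 = gemmi.read_ccp4_map(str(path))
    g = ccp4.grid
    values = np.array(g, copy=True, dtype=float)
    cell = g.unit_cell
    spacing = np.array(
        [cell.a / g.nu, cell.b / g.nv, cell.c / g.nw]
    )
    if origin is None:
        origin = np.zeros(3)
    return DensityGrid(origin, spacing, values)
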