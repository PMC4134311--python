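"""Core spatial containers: sampling grids, 4D volumes, NIfTI round-trips.

Everything downstream (simulation, preprocessing, ICA, statistics) works on an
axis-aligned grid in a common stereotaxic space with coordinates in mm
(x: left-right, y: anterior-posterior, z: dorsal-ventral).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["Grid", "Volume4D", "default_grid", "brain_mask"]


@dataclass(frozen=True)
class Grid:
    """Axis-aligned 3-D sampling grid.

    Parameters
    ----------
    origin : (3,) array
        mm coordinate of voxel index (0, 0, 0).
    voxel_mm : float
        Isotropic voxel edge length in mm.
    shape : (3,) tuple of int
        Number of voxels along x, y, z.
    """

    origin: tuple[float, float, float]
    voxel_mm: float
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.voxel_mm <= 0:
            raise ValueError("voxel_mm must be positive")
        if any(s < 1 for s in self.shape):
            raise ValueError("grid shape must be positive")

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_mm] * 3 + [1.0])
        aff[:3, 3] = self.origin
        return aff

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def axis_coords(self) -> list[np.ndarray]:
        """mm coordinates along each axis."""
        return [
            self.origin[i] + self.voxel_mm * np.arange(self.shape[i])
            for i in range(3)
        ]

    def coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Dense mm coordinate arrays (each of shape ``self.shape``)."""
        ax = self.axis_coords()
        return tuple(np.meshgrid(*ax, indexing="ij"))

    def contains_mm(self, point_mm) -> bool:
        p = np.asarray(point_mm, dtype=float)
        lo = np.asarray(self.origin)
        hi = lo + self.voxel_mm * (np.asarray(self.shape) - 1)
        return bool(np.all(p >= lo - 1e-9) and np.all(p <= hi + 1e-9))

    def nearest_voxel(self, point_mm) -> tuple[int, int, int]:
        p = np.asarray(point_mm, dtype=float)
        idx = np.round((p - np.asarray(self.origin)) / self.voxel_mm).astype(int)
        idx = np.clip(idx, 0, np.asarray(self.shape) - 1)
        return tuple(int(i) for i in idx)

    def voxel_to_mm(self, idx) -> np.ndarray:
        return np.asarray(self.origin) + self.voxel_mm * np.asarray(idx, dtype=float)


@dataclass
class Volume4D:
    """A 4-D intensity array (x, y, z, t) with grid metadata and TR.

    ``data`` may be float32 or float64; operations preserve the dtype where
    numerically safe.
    """

    data: np.ndarray
    grid: Grid
    tr_s: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("Volume4D data must be 4-dimensional (x, y, z, t)")
        if tuple(self.data.shape[:3]) != tuple(self.grid.shape):
            raise ValueError("data spatial shape does not match grid shape")
        if self.data.shape[3] < 1:
            raise ValueError("need at least one time point")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def duration_s(self) -> float:
        return self.n_volumes * self.tr_s

    def copy_with(self, data: np.ndarray) -> "Volume4D":
        return Volume4D(data=data, grid=self.grid, tr_s=self.tr_s)

    def to_nifti(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), self.grid.affine)
        img.header.set_zooms((self.grid.voxel_mm,) * 3 + (self.tr_s,))
        return img

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path, tr_s: float | None = None) -> "Volume4D":
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float32)
        if data.ndim == 3:
            data = data[..., None]
        aff = img.affine
        if not np.allclose(aff[:3, :3], np.diag(np.diag(aff[:3, :3]))):
            raise ValueError("only axis-aligned volumes are supported")
        voxel = float(aff[0, 0])
        grid = Grid(origin=tuple(aff[:3, 3]), voxel_mm=voxel, shape=data.shape[:3])
        if tr_s is None:
            zooms = img.header.get_zooms()
            tr_s = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
        return cls(data=data, grid=grid, tr_s=tr_s)


def save_mask(mask: np.ndarray, grid: Grid, path) -> None:
    img = nib.Nifti1Image(mask.astype(np.uint8), grid.affine)
    nib.save(img, str(path))


def load_mask(path, grid: Grid | None = None) -> np.ndarray:
    img = nib.load(str(path))
    mask = np.asarray(img.dataobj) > 0
    if grid is not None and tuple(mask.shape) != tuple(grid.shape):
        raise ValueError("mask shape does not match grid")
    return mask


# Default analysis space: a 3-mm grid over a box wide enough for a whole
# adult head in standard stereotaxic coordinates.
_BOX_LO = (-60.0, -90.0, -40.0)
_BOX_HI = (60.0, 70.0, 75.0)

# "Brain" mask: a super-ellipsoid (exponent 3, boxier than an ellipsoid so
# that lateral temporal and parietal peaks fall inside) whose size matches a
# typical whole-brain mask at 3 mm (~60k voxels).
_MASK_CENTER = (0.0, -12.0, 12.0)
_MASK_SEMIAXES = (62.0, 80.0, 58.0)
_MASK_EXPONENT = 3.0


def default_grid(voxel_mm: float = 3.0) -> Grid:
    """The standard analysis grid (isotropic, default 3 mm)."""
    lo = np.asarray(_BOX_LO)
    hi = np.asarray(_BOX_HI)
    shape = tuple(int(np.floor((hi[i] - lo[i]) / voxel_mm)) + 1 for i in range(3))
    return Grid(origin=tuple(lo), voxel_mm=voxel_mm, shape=shape)


def brain_mask(grid: Grid) -> np.ndarray:
    """Boolean whole-brain mask on ``grid`` (~60k voxels at 3 mm)."""
    X, Y, Z = grid.coords()
    c, s, p = _MASK_CENTER, _MASK_SEMIAXES, _MASK_EXPONENT
    r = (
        np.abs((X - c[0]) / s[0]) ** p
        + np.abs((Y - c[1]) / s[1]) ** p
        + np.abs((Z - c[2]) / s[2]) ** p
    )
    return r <= 1.0
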