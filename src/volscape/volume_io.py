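"""Density-map I/O and grid arithmetic.

Volumes are held as :class:`VoxelGrid`: a 3D float32 array indexed ``[x, y, z]``
with an isotropic voxel size in Angstrom and an origin offset. Maps are read and
written through gemmi in MRC/CCP4 2014 format (mode 2, float32); binary masks
are stored as 0/1 float maps on the same grids.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np

__all__ = [
    "VoxelGrid",
    "BinaryMask",
    "MapFormatError",
    "DegenerateInputError",
    "read_map",
    "write_map",
    "read_mask",
    "write_mask",
    "low_pass",
    "normalize",
]


class MapFormatError(ValueError):
    """Raised when a file is not a usable MRC/CCP4 map."""


class DegenerateInputError(ValueError):
    """Raised when an operation receives input it cannot meaningfully process."""


@dataclass
class VoxelGrid:
    """A 3D scalar density on a cubic lattice.

    Parameters
    ----------
    data
        3D array of densities, axes ``(x, y, z)``. Stored as float32.
    voxel_size
        Edge length of a voxel in Angstrom (isotropic).
    origin
        Position of voxel ``(0, 0, 0)`` in Angstrom.
    """

    data: np.ndarray
    voxel_size: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        if min(self.data.shape) < 8:
            raise ValueError(f"grid too small: shape {self.data.shape}, need >= 8 per axis")
        if not self.voxel_size > 0:
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")
        self.origin = tuple(float(v) for v in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def center_voxel(self) -> np.ndarray:
        """Geometric box center in voxel coordinates."""
        return (np.asarray(self.shape, dtype=float) - 1.0) / 2.0

    def same_grid(self, other: "VoxelGrid", tol: float = 1e-4) -> bool:
        return self.shape == other.shape and abs(self.voxel_size - other.voxel_size) <= tol

    def require_same_grid(self, other: "VoxelGrid") -> None:
        if not self.same_grid(other):
            raise ValueError(
                f"grid mismatch: {self.shape}@{self.voxel_size} vs {other.shape}@{other.voxel_size}"
            )

    def with_data(self, data: np.ndarray) -> "VoxelGrid":
        return VoxelGrid(np.asarray(data, dtype=np.float32), self.voxel_size, self.origin)

    def copy(self) -> "VoxelGrid":
        return self.with_data(self.data.copy())


@dataclass
class BinaryMask:
    """Boolean region on the same lattice as its parent :class:`VoxelGrid`."""

    data: np.ndarray
    voxel_size: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data) > 0.5
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D mask, got ndim={self.data.ndim}")
        if not self.data.any():
            raise ValueError("mask has no true voxels")
        self.origin = tuple(float(v) for v in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def __and__(self, other: "BinaryMask") -> "BinaryMask":
        self._check(other)
        return BinaryMask(self.data & other.data, self.voxel_size, self.origin)

    def __or__(self, other: "BinaryMask") -> "BinaryMask":
        self._check(other)
        return BinaryMask(self.data | other.data, self.voxel_size, self.origin)

    def _check(self, other: "BinaryMask") -> None:
        if self.shape != other.shape or abs(self.voxel_size - other.voxel_size) > 1e-4:
            raise ValueError("incompatible masks")


def _grid_from_gemmi(m: gemmi.Ccp4Map, path: str) -> VoxelGrid:
    arr = np.array(m.grid, copy=True).astype(np.float32)
    cell = m.grid.unit_cell
    vx = np.array([cell.a, cell.b, cell.c]) / np.array(arr.shape, dtype=float)
    mean_vx = float(vx.mean())
    if mean_vx <= 0:
        raise MapFormatError(f"{path}: non-positive voxel size")
    if np.any(np.abs(vx - mean_vx) > 0.01 * mean_vx):
        raise MapFormatError(
            f"{path}: anisotropic voxel size {tuple(np.round(vx, 4))} exceeds 1% tolerance"
        )
    origin = tuple(float(m.header_float(w)) for w in (50, 51, 52))
    return VoxelGrid(arr, mean_vx, origin)


def read_map(path) -> VoxelGrid:
    """Read an MRC/CCP4 density map.

    Density values are returned untouched (no normalisation). Extended headers
    are ignored; only isotropic voxel sizes (within 1%) are supported.
    """
    path = Path(path)
    if not path.exists():
        raise MapFormatError(f"no such map file: {path}")
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise MapFormatError(f"cannot read MRC/CCP4 map {path}: {exc}") from exc
    return _grid_from_gemmi(m, str(path))


def write_map(grid: VoxelGrid, path) -> None:
    """Write ``grid`` as an MRC mode-2 (float32) map.

    Cell dimensions are ``shape * voxel_size``; the origin goes into the
    standard ORIGIN header words.
    """
    path = Path(path)
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(np.ascontiguousarray(grid.data, dtype=np.float32))
    m.grid.unit_cell.set(
        grid.shape[0] * grid.voxel_size,
        grid.shape[1] * grid.voxel_size,
        grid.shape[2] * grid.voxel_size,
        90.0,
        90.0,
        90.0,
    )
    m.grid.spacegroup = gemmi.SpaceGroup("P1")
    m.update_ccp4_header()
    for w, v in zip((50, 51, 52), grid.origin):
        m.set_header_float(w, float(v))
    try:
        m.write_ccp4_map(str(path))
    except (RuntimeError, OSError) as exc:
        raise OSError(f"cannot write map {path}: {exc}") from exc


def read_mask(path) -> BinaryMask:
    """Read a 0/1 float map as a binary mask (threshold at 0.5)."""
    g = read_map(path)
    return BinaryMask(g.data > 0.5, g.voxel_size, g.origin)


def write_mask(mask: BinaryMask, path) -> None:
    write_map(VoxelGrid(mask.data.astype(np.float32), mask.voxel_size, mask.origin), path)


def _radial_frequency(shape: tuple[int, int, int], voxel_size: float) -> np.ndarray:
    fx = np.fft.fftfreq(shape[0], d=voxel_size)
    fy = np.fft.fftfreq(shape[1], d=voxel_size)
    fz = np.fft.rfftfreq(shape[2], d=voxel_size)
    return np.sqrt(fx[:, None, None] ** 2 + fy[None, :, None] ** 2 + fz[None, None, :] ** 2)


def low_pass(grid: VoxelGrid, resolution: float, edge_shells: float = 2.0) -> VoxelGrid:
    """Low-pass filter to ``resolution`` (A) with a soft cosine edge.

    The transfer function is 1 below the cutoff frequency ``1/resolution``
    minus ``edge_shells`` Fourier shells, falls as a half-cosine across the
    edge, and is exactly 0 beyond the cutoff. The DC term (mean density) is
    always preserved.
    """
    if resolution < 2.0 * grid.voxel_size:
        raise ValueError(
            f"resolution {resolution} A is below Nyquist ({2 * grid.voxel_size} A)"
        )
    f = _radial_frequency(grid.shape, grid.voxel_size)
    fc = 1.0 / resolution
    width = min(fc, edge_shells / (min(grid.shape) * grid.voxel_size))
    h = np.ones_like(f)
    ramp = (f > fc - width) & (f <= fc)
    h[ramp] = 0.5 * (1.0 + np.cos(np.pi * (f[ramp] - (fc - width)) / width))
    h[f > fc] = 0.0
    out = np.fft.irfftn(np.fft.rfftn(grid.data) * h, s=grid.shape, axes=(0, 1, 2))
    return grid.with_data(out)


def normalize(grid: VoxelGrid) -> VoxelGrid:
    """Scale the density to zero mean and unit standard deviation."""
    data = grid.data.astype(np.float64)
    sd = data.std()
    if sd < 1e-12:
        raise DegenerateInputError("constant density cannot be normalized")
    return grid.with_data((data - data.mean()) / sd)
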