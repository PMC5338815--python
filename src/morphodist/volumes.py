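"""Grid-aligned 3D volume containers and NIfTI-1 I/O.

All volumes in an analysis live on a common voxel grid described by integer
dimensions, physical voxel spacing (mm) and a world origin (mm).  Scalar
volumes hold image intensities or integer region labels; vector volumes hold
stationary velocity fields or displacement fields, stored as ``(nx, ny, nz, 3)``
arrays whose components are world-axis-aligned millimetre quantities.

A deformation field with displacement ``d`` realises the (pull-back) spatial
map ``x -> x + d(x)``; the identity map has zero displacement everywhere.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "ImageVolume",
    "LabelVolume",
    "VelocityField",
    "DeformationField",
    "GridMismatchError",
    "read_image",
    "read_labels",
    "read_vector_field",
]


class GridMismatchError(ValueError):
    """Two volumes expected on the same grid disagree in dims or spacing."""


def _as_triple(x) -> tuple[float, float, float]:
    a, b, c = x
    return (float(a), float(b), float(c))


@dataclass
class Grid:
    """Voxel lattice geometry shared by all volumes of one subject/analysis."""

    dims: tuple[int, int, int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.dims = tuple(int(d) for d in self.dims)
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        if any(d < 1 for d in self.dims):
            raise ValueError(f"grid dims must be positive, got {self.dims}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing}")

    def same_as(self, other: "Grid", atol: float = 1e-6) -> bool:
        return self.dims == other.dims and np.allclose(
            self.spacing, other.spacing, atol=atol
        )

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def world_extent(self) -> float:
        """Length of the grid diagonal in mm."""
        return float(
            np.linalg.norm([(d - 1) * s for d, s in zip(self.dims, self.spacing)])
        )


def _check_same_grid(a: "_GridVolume", b: "_GridVolume") -> None:
    if not a.grid.same_as(b.grid):
        raise GridMismatchError(
            f"grids differ: {a.grid.dims}@{a.grid.spacing} vs {b.grid.dims}@{b.grid.spacing}"
        )


@dataclass
class _GridVolume:
    data: np.ndarray
    grid: Grid = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.grid is None:
            self.grid = Grid(self.data.shape[:3])
        if tuple(self.data.shape[:3]) != self.grid.dims:
            raise ValueError(
                f"data shape {self.data.shape[:3]} does not match grid dims {self.grid.dims}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.grid.dims

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.grid.spacing


@dataclass
class ImageVolume(_GridVolume):
    """Scalar 3D intensity volume (arbitrary units)."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D scalar data, got shape {self.data.shape}")
        self.data = self.data.astype(np.float64, copy=False)

    def save(self, path: str | Path) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), self.grid.affine), str(path))


@dataclass
class LabelVolume(_GridVolume):
    """Integer ROI-label volume; 0 is background."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D label data, got shape {self.data.shape}")
        if not np.issubdtype(self.data.dtype, np.integer):
            rounded = np.rint(self.data)
            if not np.allclose(self.data, rounded):
                raise ValueError("label volume contains non-integer values")
            self.data = rounded
        self.data = self.data.astype(np.int32, copy=False)

    def save(self, path: str | Path) -> None:
        img = nib.Nifti1Image(self.data.astype(np.int16), self.grid.affine)
        nib.save(img, str(path))


@dataclass
class _VectorVolume(_GridVolume):
    def __post_init__(self) -> None:
        super().__post_init__()
        if self.data.ndim != 4 or self.data.shape[3] != 3:
            raise ValueError(
                f"expected (nx, ny, nz, 3) vector data, got shape {self.data.shape}"
            )
        self.data = self.data.astype(np.float64, copy=False)

    def save(self, path: str | Path) -> None:
        # NIfTI vector convention: 5D with dim[5] = 3, intent code 'vector'
        arr = self.data[:, :, :, np.newaxis, :].astype(np.float32)
        img = nib.Nifti1Image(arr, self.grid.affine)
        img.header.set_intent("vector")
        nib.save(img, str(path))

    def magnitude(self) -> np.ndarray:
        return np.sqrt(np.sum(self.data**2, axis=-1))


@dataclass
class VelocityField(_VectorVolume):
    """Stationary velocity field v (mm); the deformation is phi = exp(v)."""

    def negate(self) -> "VelocityField":
        return VelocityField(-self.data, self.grid)


@dataclass
class DeformationField(_VectorVolume):
    """Displacement field d (mm) realising the map x -> x + d(x)."""


def _load(path: str | Path) -> tuple[np.ndarray, Grid]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    zooms = img.header.get_zooms()[:3]
    origin = tuple(np.asarray(img.affine[:3, 3], dtype=float))
    grid = Grid(data.shape[:3], tuple(float(z) for z in zooms), origin)
    return data, grid


def read_image(path: str | Path) -> ImageVolume:
    data, grid = _load(path)
    return ImageVolume(np.squeeze(data).astype(np.float64), grid)


def read_labels(path: str | Path) -> LabelVolume:
    data, grid = _load(path)
    return LabelVolume(np.rint(np.squeeze(data)).astype(np.int32), grid)


def read_vector_field(path: str | Path, kind: str = "velocity"):
    data, grid = _load(path)
    data = np.squeeze(data)
    if data.ndim != 4 or data.shape[-1] != 3:
        raise ValueError(f"{path}: not a 3-vector volume (shape {data.shape})")
    cls = VelocityField if kind == "velocity" else DeformationField
    return cls(data.astype(np.float64), grid)


__all__.append("Grid")
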