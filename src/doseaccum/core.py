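"""Core spatial containers shared by every stage of the workflow.

All volumes live on axis-aligned grids with a voxel-center world mapping:
the world coordinate (mm) of 0-based voxel index ``i`` along an axis is
``origin + i * spacing``.  Array axes are ordered ``(x, y, z)`` and carry the
anatomical labels ``(RL, AP, SI)`` — right-left, anterior-posterior,
superior-inferior.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from scipy.ndimage import map_coordinates

#: Anatomical labels of array axes 0, 1, 2.
AXES = ("RL", "AP", "SI")


class GeometryError(ValueError):
    """A structure or grid request is geometrically inconsistent."""


@dataclass(frozen=True)
class GridDescriptor:
    """Axis-aligned 3D sampling lattice.

    Parameters
    ----------
    shape
        Number of voxels along (x, y, z).
    spacing_mm
        Voxel size along each axis in mm; strictly positive.
    origin_mm
        World coordinate (mm) of the center of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise GeometryError(f"grid shape must be three positive ints, got {self.shape}")
        if any(s <= 0 for s in self.spacing_mm):
            raise GeometryError(f"voxel spacing must be positive, got {self.spacing_mm}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        object.__setattr__(self, "origin_mm", tuple(float(o) for o in self.origin_mm))

    # -- unit helpers -------------------------------------------------
    @property
    def spacing(self) -> np.ndarray:
        return np.asarray(self.spacing_mm, dtype=float)

    @property
    def origin(self) -> np.ndarray:
        return np.asarray(self.origin_mm, dtype=float)

    @property
    def voxel_volume_cc(self) -> float:
        """Volume of one voxel in cm^3 (1 cc = 1000 mm^3)."""
        return float(np.prod(self.spacing)) / 1000.0

    @property
    def extent_mm(self) -> np.ndarray:
        """World coordinates of the first and last voxel centers, (2, 3)."""
        last = self.origin + (np.asarray(self.shape) - 1) * self.spacing
        return np.stack([self.origin, last])

    # -- coordinate transforms ---------------------------------------
    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return self.origin + idx * self.spacing

    def world_to_index(self, world: np.ndarray) -> np.ndarray:
        world = np.asarray(world, dtype=float)
        return (world - self.origin) / self.spacing

    def world_coords(self, sparse: bool = True) -> tuple[np.ndarray, ...]:
        """Per-axis world coordinates of all voxel centers (open meshgrid)."""
        axes = [self.origin[a] + np.arange(self.shape[a]) * self.spacing[a] for a in range(3)]
        return tuple(np.meshgrid(*axes, indexing="ij", sparse=sparse))

    def axis_coords(self, axis: int) -> np.ndarray:
        return self.origin[axis] + np.arange(self.shape[axis]) * self.spacing[axis]

    def same_geometry(self, other: "GridDescriptor", tol_mm: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol_mm)
            and np.allclose(self.origin, other.origin, atol=tol_mm)
        )


@dataclass
class ImageVolume:
    """Scalar volume (MR intensity, dose in Gy, or soft mask) on a grid."""

    data: np.ndarray
    grid: GridDescriptor

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.shape != self.grid.shape:
            raise GeometryError(
                f"data shape {self.data.shape} does not match grid shape {self.grid.shape}"
            )

    def copy(self) -> "ImageVolume":
        return ImageVolume(self.data.copy(), self.grid)

    def astype(self, dtype) -> "ImageVolume":
        return ImageVolume(self.data.astype(dtype), self.grid)


@dataclass
class StructureSet:
    """Named binary masks sharing one grid."""

    masks: dict[str, np.ndarray]
    grid: GridDescriptor

    def __post_init__(self) -> None:
        for name, m in self.masks.items():
            m = np.asarray(m)
            if m.shape != self.grid.shape:
                raise GeometryError(f"mask '{name}' shape {m.shape} != grid {self.grid.shape}")
            self.masks[name] = m.astype(bool)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def __iter__(self) -> Iterator[str]:
        return iter(self.masks)

    @property
    def names(self) -> list[str]:
        return list(self.masks)

    def volume_cc(self, name: str) -> float:
        return float(np.count_nonzero(self.masks[name])) * self.grid.voxel_volume_cc

    def copy(self) -> "StructureSet":
        return StructureSet({k: v.copy() for k, v in self.masks.items()}, self.grid)


@dataclass
class DisplacementField:
    """Per-voxel displacement vectors (mm) on the planning grid.

    Pull-back convention: a planning-frame point ``p`` corresponds to the
    daily-frame point ``p + u(p)``.  Resampling daily data onto the planning
    grid therefore evaluates the daily volume at ``p + u(p)``.
    """

    vectors_mm: np.ndarray  # (3, nx, ny, nz)
    grid: GridDescriptor

    def __post_init__(self) -> None:
        self.vectors_mm = np.asarray(self.vectors_mm, dtype=float)
        if self.vectors_mm.shape != (3, *self.grid.shape):
            raise GeometryError(
                f"field shape {self.vectors_mm.shape} != (3, *{self.grid.shape})"
            )
        if not np.all(np.isfinite(self.vectors_mm)):
            raise GeometryError("displacement field contains non-finite values")

    @classmethod
    def identity(cls, grid: GridDescriptor) -> "DisplacementField":
        return cls(np.zeros((3, *grid.shape)), grid)

    @property
    def magnitude_mm(self) -> np.ndarray:
        return np.sqrt(np.sum(self.vectors_mm**2, axis=0))

    @property
    def max_magnitude_mm(self) -> float:
        return float(self.magnitude_mm.max())

    def mapped_points_index(self, target_grid: GridDescriptor) -> np.ndarray:
        """Fractional voxel indices on ``target_grid`` of ``p + u(p)``, (3, ...)."""
        xs = self.grid.world_coords(sparse=True)
        out = np.empty((3, *self.grid.shape))
        for a in range(3):
            world = xs[a] + self.vectors_mm[a]
            out[a] = (world - target_grid.origin[a]) / target_grid.spacing[a]
        return out

    def jacobian_determinant(self) -> np.ndarray:
        """det(I + du/dx) by central differences; > 0 means locally invertible."""
        J = np.empty((3, 3, *self.grid.shape))
        for i in range(3):
            for a in range(3):
                J[i, a] = np.gradient(self.vectors_mm[i], self.grid.spacing[a], axis=a)
            J[i, i] += 1.0
        det = (
            J[0, 0] * (J[1, 1] * J[2, 2] - J[1, 2] * J[2, 1])
            - J[0, 1] * (J[1, 0] * J[2, 2] - J[1, 2] * J[2, 0])
            + J[0, 2] * (J[1, 0] * J[2, 1] - J[1, 1] * J[2, 0])
        )
        return det


def sample_volume(
    vol: ImageVolume,
    index_coords: np.ndarray,
    mode: str = "linear",
    cval: float = 0.0,
    edge: str = "constant",
) -> np.ndarray:
    """Sample a volume at fractional voxel indices.

    ``index_coords`` has shape (3, ...) in the volume's own index space.
    ``mode`` is ``linear`` (trilinear) or ``nearest``; points outside the
    support get ``cval`` when ``edge='constant'`` or the clamped edge value
    when ``edge='nearest'``.
    """
    order = {"linear": 1, "nearest": 0}[mode]
    return map_coordinates(
        np.asarray(vol.data, dtype=float),
        index_coords,
        order=order,
        mode=edge,
        cval=cval,
        prefilter=False,
    )
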