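"""Core geometric data model: axis-aligned 3-D grids in world millimetres.

Conventions used throughout the package
---------------------------------------
* World frame is DICOM-style LPS (+x patient-left, +y posterior, +z superior),
  in millimetres.
* Array index order is ``(x, y, z)``: ``values[ix, iy, iz]``.
* A voxel's value is located at the voxel CENTER; the center of voxel
  ``(0, 0, 0)`` is at ``origin``.
* Grids are axis-aligned (no direction cosines); rotations live in
  :class:`RigidTransform`.
* Interpolation is trilinear for scalar dose/CT, nearest-neighbour for masks.
  Points outside the voxel-center bounding box take a fill value
  (0 for dose, -1000 HU for CT, ``False`` for masks).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "GeometryError",
    "GridGeometry",
    "ImageGrid",
    "VectorField",
    "RigidTransform",
    "StructureSet",
    "world_to_index",
    "index_to_world",
    "sample_trilinear",
    "sample_nearest",
    "resample_to_grid",
]


class GeometryError(ValueError):
    """Raised when grid geometries are invalid or incompatible."""


@dataclass(frozen=True)
class GridGeometry:
    """Shape + placement of an axis-aligned voxel lattice (no pixel data)."""

    shape: tuple[int, int, int]
    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    frame_id: str = ""

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) < 2 for n in self.shape):
            raise GeometryError(f"grid must be 3-D with every dim >= 2, got shape {self.shape}")
        if len(self.spacing) != 3 or any(not (s > 0) for s in self.spacing):
            raise GeometryError(f"spacing must be strictly positive, got {self.spacing}")
        if len(self.origin) != 3 or not all(np.isfinite(self.origin)):
            raise GeometryError(f"origin must be a finite mm triple, got {self.origin}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        object.__setattr__(self, "spacing", tuple(float(v) for v in self.spacing))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def same_lattice(self, other: "GridGeometry", tol: float = 1e-9) -> bool:
        """True when the two lattices coincide point-for-point (frame ignored)."""
        return (
            self.shape == other.shape
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.spacing, other.spacing, atol=tol)
        )

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of every voxel center, shape ``(nx*ny*nz, 3)``,
        in C order matching ``values.reshape(-1)``."""
        axes = [
            self.origin[k] + self.spacing[k] * np.arange(self.shape[k])
            for k in range(3)
        ]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    def with_frame(self, frame_id: str) -> "GridGeometry":
        return GridGeometry(self.shape, self.origin, self.spacing, frame_id)


def world_to_index(geom: GridGeometry, p: np.ndarray) -> np.ndarray:
    """Map world-mm points to continuous voxel indices: ``(p - origin) / spacing``.

    Out-of-bounds indices are legal outputs.  Accepts shape ``(3,)`` or ``(N, 3)``.
    """
    p = np.asarray(p, dtype=np.float64)
    return (p - np.asarray(geom.origin)) / np.asarray(geom.spacing)


def index_to_world(geom: GridGeometry, idx: np.ndarray) -> np.ndarray:
    """Inverse of :func:`world_to_index`."""
    idx = np.asarray(idx, dtype=np.float64)
    return idx * np.asarray(geom.spacing) + np.asarray(geom.origin)


# ---------------------------------------------------------------------------
# Shared interpolation kernels.  One hand-written trilinear gather is used for
# every pull-back resampling in the package so that the optimized gamma search
# and its exhaustive oracle share identical arithmetic.
# ---------------------------------------------------------------------------

def _trilinear_values(values: np.ndarray, idx: np.ndarray, fill: float) -> np.ndarray:
    """Trilinear interpolation of ``values`` at continuous indices ``idx`` (N, 3).

    Points outside ``[0, n_k - 1]`` on any axis return ``fill``.
    """
    n = values.shape
    inside = (
        (idx[:, 0] >= 0) & (idx[:, 0] <= n[0] - 1)
        & (idx[:, 1] >= 0) & (idx[:, 1] <= n[1] - 1)
        & (idx[:, 2] >= 0) & (idx[:, 2] <= n[2] - 1)
    )
    c = np.empty_like(idx)
    np.clip(idx[:, 0], 0, n[0] - 1, out=c[:, 0])
    np.clip(idx[:, 1], 0, n[1] - 1, out=c[:, 1])
    np.clip(idx[:, 2], 0, n[2] - 1, out=c[:, 2])
    i0 = c.astype(np.int64)
    np.minimum(i0[:, 0], n[0] - 2, out=i0[:, 0])
    np.minimum(i0[:, 1], n[1] - 2, out=i0[:, 1])
    np.minimum(i0[:, 2], n[2] - 2, out=i0[:, 2])
    f = c - i0
    x0, y0, z0 = i0[:, 0], i0[:, 1], i0[:, 2]
    fx, fy, fz = f[:, 0], f[:, 1], f[:, 2]
    gx, gy, gz = 1.0 - fx, 1.0 - fy, 1.0 - fz

    v = values
    out = (
        v[x0, y0, z0] * (gx * gy * gz)
        + v[x0 + 1, y0, z0] * (fx * gy * gz)
        + v[x0, y0 + 1, z0] * (gx * fy * gz)
        + v[x0, y0, z0 + 1] * (gx * gy * fz)
        + v[x0 + 1, y0 + 1, z0] * (fx * fy * gz)
        + v[x0 + 1, y0, z0 + 1] * (fx * gy * fz)
        + v[x0, y0 + 1, z0 + 1] * (gx * fy * fz)
        + v[x0 + 1, y0 + 1, z0 + 1] * (fx * fy * fz)
    )
    if not inside.all():
        out = np.where(inside, out, fill)
    return out


def _nearest_values(values: np.ndarray, idx: np.ndarray, fill) -> np.ndarray:
    n = values.shape
    inside = (
        (idx[:, 0] >= -0.5) & (idx[:, 0] <= n[0] - 0.5)
        & (idx[:, 1] >= -0.5) & (idx[:, 1] <= n[1] - 0.5)
        & (idx[:, 2] >= -0.5) & (idx[:, 2] <= n[2] - 0.5)
    )
    i = np.rint(idx).astype(np.int64)
    for k in range(3):
        np.clip(i[:, k], 0, n[k] - 1, out=i[:, k])
    out = values[i[:, 0], i[:, 1], i[:, 2]]
    if not inside.all():
        out = np.where(inside, out, fill)
    return out


@dataclass
class ImageGrid:
    """3-D scalar field (HU for CT, cGy for dose) on an axis-aligned lattice."""

    values: np.ndarray
    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    frame_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise GeometryError(f"ImageGrid values must be 3-D, got ndim={self.values.ndim}")
        # geometry validation
        self.geometry  # noqa: B018

    @property
    def geometry(self) -> GridGeometry:
        return GridGeometry(self.values.shape, tuple(self.origin), tuple(self.spacing), self.frame_id)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def copy(self) -> "ImageGrid":
        return ImageGrid(self.values.copy(), tuple(self.origin), tuple(self.spacing), self.frame_id)

    @classmethod
    def from_geometry(cls, geom: GridGeometry, values: np.ndarray) -> "ImageGrid":
        values = np.asarray(values, dtype=np.float64)
        if values.shape != geom.shape:
            raise GeometryError(f"values shape {values.shape} != geometry shape {geom.shape}")
        return cls(values, geom.origin, geom.spacing, geom.frame_id)


@dataclass
class VectorField:
    """Displacement field (mm, world frame) on a grid; fixed PULL convention.

    ``displacements[ix, iy, iz]`` is the mm 3-vector added to that voxel's
    world position before sampling the source volume:
    ``out(x) = src(x + d(x))``.
    """

    displacements: np.ndarray
    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    frame_id: str = ""

    def __post_init__(self) -> None:
        self.displacements = np.asarray(self.displacements, dtype=np.float64)
        if self.displacements.ndim != 4 or self.displacements.shape[-1] != 3:
            raise GeometryError(
                f"VectorField must have shape (nx, ny, nz, 3), got {self.displacements.shape}"
            )
        if not np.isfinite(self.displacements).all():
            raise GeometryError("VectorField contains non-finite displacements")
        self.geometry  # noqa: B018  (validates origin/spacing)

    @property
    def geometry(self) -> GridGeometry:
        return GridGeometry(
            self.displacements.shape[:3], tuple(self.origin), tuple(self.spacing), self.frame_id
        )

    def max_magnitude(self) -> float:
        return float(np.sqrt((self.displacements ** 2).sum(axis=-1)).max())

    def sample(self, pts: np.ndarray) -> np.ndarray:
        """Trilinear displacement at world points, edge-clamped outside the grid.

        Edge clamping (rather than a zero fill) keeps fixed-point inversion
        stable near the boundary.
        """
        idx = world_to_index(self.geometry, pts)
        n = self.geometry.shape
        for k in range(3):
            idx[:, k] = np.clip(idx[:, k], 0.0, n[k] - 1.0)
        out = np.empty_like(pts, dtype=np.float64)
        for k in range(3):
            out[:, k] = _trilinear_values(self.displacements[..., k], idx, 0.0)
        return out

    @classmethod
    def zeros(cls, geom: GridGeometry) -> "VectorField":
        return cls(np.zeros(geom.shape + (3,)), geom.origin, geom.spacing, geom.frame_id)


class RigidTransform:
    """4x4 homogeneous world-to-world transform (rotation + translation, mm).

    ``apply`` maps points of the frame the transform is *read in* (here: the
    reference frame during propagation) to the source/session frame, matching
    the pull-back sampling used everywhere in the package.
    """

    __slots__ = ("matrix",)

    def __init__(self, matrix: np.ndarray):
        m = np.asarray(matrix, dtype=np.float64)
        if m.shape != (4, 4):
            raise GeometryError(f"rigid transform must be 4x4, got {m.shape}")
        if not np.allclose(m[3], [0.0, 0.0, 0.0, 1.0], atol=1e-10):
            raise GeometryError("last row of a rigid transform must be [0, 0, 0, 1]")
        r = m[:3, :3]
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-8):
            raise GeometryError("rotation block is not orthonormal")
        if np.linalg.det(r) < 0:
            raise GeometryError("rotation block has determinant -1 (reflection)")
        self.matrix = m

    # -- constructors -------------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4))

    @classmethod
    def from_translation(cls, t) -> "RigidTransform":
        m = np.eye(4)
        m[:3, 3] = np.asarray(t, dtype=np.float64)
        return cls(m)

    @classmethod
    def from_rotation_z(cls, angle_deg: float, center=(0.0, 0.0, 0.0)) -> "RigidTransform":
        a = np.deg2rad(angle_deg)
        c, s = np.cos(a), np.sin(a)
        r = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        center = np.asarray(center, dtype=np.float64)
        m = np.eye(4)
        m[:3, :3] = r
        m[:3, 3] = center - r @ center
        return cls(m)

    @classmethod
    def compose(cls, first: "RigidTransform", then: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``first`` to a point, then ``then``."""
        return cls(then.matrix @ first.matrix)

    # -- operations ---------------------------------------------------------
    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=np.float64)
        return pts @ self.matrix[:3, :3].T + self.matrix[:3, 3]

    def inverse(self) -> "RigidTransform":
        r = self.matrix[:3, :3]
        t = self.matrix[:3, 3]
        m = np.eye(4)
        m[:3, :3] = r.T
        m[:3, 3] = -r.T @ t
        return RigidTransform(m)

    def is_identity(self, tol: float = 1e-12) -> bool:
        return bool(np.allclose(self.matrix, np.eye(4), atol=tol))

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3].copy()

    def to_list(self) -> list[list[float]]:
        return [[float(v) for v in row] for row in self.matrix]

    @classmethod
    def from_list(cls, rows) -> "RigidTransform":
        return cls(np.asarray(rows, dtype=np.float64))

    def __repr__(self) -> str:  # pragma: no cover
        return f"RigidTransform({self.matrix!r})"


@dataclass
class StructureSet:
    """Named binary masks sharing one grid geometry, with optional priorities.

    Priorities follow the TPS convention: 1 is the highest (targets),
    larger integers are lower (organs at risk).
    """

    masks: dict[str, np.ndarray]
    geometry: GridGeometry
    priorities: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, m in self.masks.items():
            m = np.asarray(m, dtype=bool)
            if m.shape != self.geometry.shape:
                raise GeometryError(
                    f"mask {name!r} shape {m.shape} != geometry shape {self.geometry.shape}"
                )
            if not m.any():
                raise GeometryError(f"mask {name!r} is empty")
            self.masks[name] = m

    @property
    def names(self) -> list[str]:
        return list(self.masks)

    def centroid(self, name: str) -> np.ndarray:
        """World-mm centroid of a mask."""
        idx = np.argwhere(self.masks[name]).mean(axis=0)
        return index_to_world(self.geometry, idx)

    def volume_cc(self, name: str) -> float:
        return float(self.masks[name].sum()) * self.geometry.voxel_volume_mm3 / 1000.0


# ---------------------------------------------------------------------------
# Sampling / resampling operations
# ---------------------------------------------------------------------------

def sample_trilinear(grid: ImageGrid, p: np.ndarray, fill: float = 0.0) -> np.ndarray:
    """Trilinearly sample ``grid`` at world point(s) ``p`` (mm).

    Returns ``fill`` for points outside the voxel-center bounding box.
    Scalar in, scalar out; ``(N, 3)`` in, ``(N,)`` out.
    """
    p = np.asarray(p, dtype=np.float64)
    single = p.ndim == 1
    pts = p[None, :] if single else p
    idx = world_to_index(grid.geometry, pts)
    out = _trilinear_values(grid.values, idx, float(fill))
    return float(out[0]) if single else out


def sample_nearest(values: np.ndarray, geom: GridGeometry, p: np.ndarray, fill) -> np.ndarray:
    """Nearest-neighbour sampling (used for binary masks)."""
    p = np.asarray(p, dtype=np.float64)
    single = p.ndim == 1
    pts = p[None, :] if single else p
    idx = world_to_index(geom, pts)
    out = _nearest_values(values, idx, fill)
    return out[0] if single else out


def resample_to_grid(
    src: ImageGrid,
    target: GridGeometry,
    fill: float = 0.0,
    order: str = "linear",
) -> ImageGrid:
    """Resample ``src`` onto ``target``: each output voxel takes the interpolated
    value of ``src`` at the output voxel center.

    Resampling onto the identical lattice is short-circuited to an exact copy so
    that identity pipelines are bit-preserving.
    """
    if src.geometry.same_lattice(target):
        return ImageGrid(src.values.copy(), target.origin, target.spacing, target.frame_id)
    pts = target.voxel_centers()
    idx = world_to_index(src.geometry, pts)
    if order == "linear":
        vals = _trilinear_values(src.values, idx, float(fill))
    elif order == "nearest":
        vals = _nearest_values(src.values, idx, fill)
    else:
        raise ValueError(f"unknown interpolation order {order!r}")
    return ImageGrid(vals.reshape(target.shape), target.origin, target.spacing, target.frame_id)
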