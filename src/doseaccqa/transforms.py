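"""Rigid and deformable warping of dose grids — the manual accumulation primitives.

The manual QA procedure applies the exported rigid transformation matrix to the
session dose first, then applies the deformable vector field (DVF); both legs
are pull-back resamplings.  A composed single-resampling variant is provided to
avoid double interpolation, and a fixed-point DVF inverter supports round-trip
testing and push->pull convention conversion.
"""

from __future__ import annotations

import numpy as np

from .grid import (
    GeometryError,
    GridGeometry,
    ImageGrid,
    RigidTransform,
    VectorField,
    _nearest_values,
    _trilinear_values,
    world_to_index,
)

__all__ = [
    "apply_rigid",
    "apply_dvf",
    "compose_rigid_then_dvf",
    "invert_dvf",
    "jacobian_determinant",
    "convert_convention",
    "warp_mask",
    "DVFInversionError",
]


class DVFInversionError(RuntimeError):
    """Fixed-point DVF inversion failed to reach tolerance."""

    def __init__(self, residual_mm: float, max_iter: int):
        self.residual_mm = residual_mm
        self.max_iter = max_iter
        super().__init__(
            f"DVF inversion did not converge: residual {residual_mm:.4f} mm "
            f"after {max_iter} iterations"
        )


def apply_rigid(
    dose: ImageGrid,
    transform: RigidTransform,
    target: GridGeometry | None = None,
    fill: float = 0.0,
    order: str = "linear",
) -> ImageGrid:
    """Pull-back resample under a rigid transform: ``out(x) = dose(T(x))``.

    ``T`` maps target-frame points into the frame ``dose`` lives in.  An
    identity transform onto the same lattice is an exact copy.
    """
    if target is None:
        target = dose.geometry
    if transform.is_identity() and dose.geometry.same_lattice(target):
        return ImageGrid(dose.values.copy(), target.origin, target.spacing, target.frame_id)
    pts = transform.apply(target.voxel_centers())
    idx = world_to_index(dose.geometry, pts)
    if order == "linear":
        vals = _trilinear_values(dose.values, idx, float(fill))
    else:
        vals = _nearest_values(dose.values, idx, fill)
    return ImageGrid(vals.reshape(target.shape), target.origin, target.spacing, target.frame_id)


def apply_dvf(
    dose: ImageGrid,
    dvf: VectorField,
    fill: float = 0.0,
    order: str = "linear",
) -> ImageGrid:
    """Pull-convention deformable warp: ``out(x) = dose(x + d(x))``.

    The output lives on the DVF's grid.  A zero field on the dose's own lattice
    reproduces the input exactly.
    """
    geom = dvf.geometry
    if not np.any(dvf.displacements):
        if not dose.geometry.same_lattice(geom):
            raise GeometryError(
                "zero DVF applied across mismatched lattices; resample the dose first"
            )
        return ImageGrid(dose.values.copy(), geom.origin, geom.spacing, geom.frame_id)
    pts = geom.voxel_centers() + dvf.displacements.reshape(-1, 3)
    idx = world_to_index(dose.geometry, pts)
    if order == "linear":
        vals = _trilinear_values(dose.values, idx, float(fill))
    else:
        vals = _nearest_values(dose.values, idx, fill)
    return ImageGrid(vals.reshape(geom.shape), geom.origin, geom.spacing, geom.frame_id)


def warp_mask(mask: np.ndarray, mask_geom: GridGeometry, dvf: VectorField,
              transform: RigidTransform | None = None) -> np.ndarray:
    """Warp a binary mask with nearest-neighbour sampling.

    ``out(x) = mask(T(x + d(x)))`` — the same pull chain used for dose, so a
    warped session structure lands where its propagated dose lands.
    """
    pts = dvf.geometry.voxel_centers() + dvf.displacements.reshape(-1, 3)
    if transform is not None:
        pts = transform.apply(pts)
    idx = world_to_index(mask_geom, pts)
    out = _nearest_values(mask.astype(np.float64), idx, 0.0)
    return (out > 0.5).reshape(dvf.geometry.shape)


def compose_rigid_then_dvf(transform: RigidTransform, dvf: VectorField) -> VectorField:
    """Fuse the two pull-back legs into one field: ``e(x) = T(x + d(x)) - x``.

    Applying ``e`` once (``apply_dvf``) samples the session dose at
    ``T(x + d(x))``, matching the two-step rigid-then-DVF chain with a single
    interpolation.
    """
    geom = dvf.geometry
    pts = geom.voxel_centers()
    warped = transform.apply(pts + dvf.displacements.reshape(-1, 3))
    e = (warped - pts).reshape(geom.shape + (3,))
    return VectorField(e, geom.origin, geom.spacing, geom.frame_id)


def _interior_slices(dvf: VectorField) -> tuple[slice, slice, slice]:
    """Interior region guaranteed unaffected by edge clamping during inversion."""
    margin = [
        min(int(np.ceil(dvf.max_magnitude() / s)) + 1, n // 3)
        for s, n in zip(dvf.spacing, dvf.geometry.shape)
    ]
    return tuple(slice(m, n - m) for m, n in zip(margin, dvf.geometry.shape))  # type: ignore[return-value]


def invert_dvf(dvf: VectorField, max_iter: int = 50, tol_mm: float = 0.1) -> VectorField:
    """Invert a (diffeomorphic) pull field by fixed-point iteration.

    Iterates ``d_inv(x) <- -d(x + d_inv(x))`` until the interior residual
    ``max |d_inv(x) + d(x + d_inv(x))|`` drops below ``tol_mm``.  Raises
    :class:`DVFInversionError` (carrying the residual) on non-convergence.
    """
    geom = dvf.geometry
    pts = geom.voxel_centers()
    d_inv = -dvf.displacements.reshape(-1, 3).copy()
    interior = np.zeros(geom.shape, dtype=bool)
    interior[_interior_slices(dvf)] = True
    interior = interior.ravel()
    residual = np.inf
    for _ in range(max_iter):
        d_at = dvf.sample(pts + d_inv)
        resid_vec = d_inv + d_at
        residual = float(np.sqrt((resid_vec[interior] ** 2).sum(axis=1)).max())
        if residual < tol_mm:
            return VectorField(
                d_inv.reshape(geom.shape + (3,)), geom.origin, geom.spacing, geom.frame_id
            )
        d_inv = -d_at
    raise DVFInversionError(residual, max_iter)


def convert_convention(dvf: VectorField, max_iter: int = 50, tol_mm: float = 0.1) -> VectorField:
    """Convert a displacement field between push and pull dialects.

    A push field moves source points forward (``y = x + d_push(x)``); the
    equivalent pull field is the displacement of the inverse mapping, i.e. the
    fixed-point inverse.  The operation is its own inverse (pull -> push uses
    the same call).
    """
    return invert_dvf(dvf, max_iter=max_iter, tol_mm=tol_mm)


def jacobian_determinant(dvf: VectorField) -> ImageGrid:
    """Voxelwise ``det(grad(x + d(x)))`` by central finite differences.

    Values near 1 indicate local volume preservation; any non-positive value
    flags folding (loss of invertibility).  Edge voxels use one-sided
    differences (numpy.gradient).
    """
    geom = dvf.geometry
    jac = np.empty(geom.shape + (3, 3))
    for comp in range(3):
        grads = np.gradient(dvf.displacements[..., comp], *geom.spacing)
        for ax in range(3):
            jac[..., comp, ax] = grads[ax]
    for k in range(3):
        jac[..., k, k] += 1.0
    det = (
        jac[..., 0, 0] * (jac[..., 1, 1] * jac[..., 2, 2] - jac[..., 1, 2] * jac[..., 2, 1])
        - jac[..., 0, 1] * (jac[..., 1, 0] * jac[..., 2, 2] - jac[..., 1, 2] * jac[..., 2, 0])
        + jac[..., 0, 2] * (jac[..., 1, 0] * jac[..., 2, 1] - jac[..., 1, 1] * jac[..., 2, 0])
    )
    return ImageGrid(det, geom.origin, geom.spacing, geom.frame_id)
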