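"""Synthetic phantoms, structures, session doses, DVFs and QA scenarios.

Two phantom families are generated:

* a cylindrical electron-density phantom with removable inserts at clock
  positions (target contoured on the 6 o'clock insert, re-contoured at 7 and
  5 o'clock across adaptive fractions, with the displaced organ-at-risk
  contour taking over the vacated 6 o'clock slot), and
* an anthropomorphic pelvis surrogate whose planning CT is perturbed by a
  Gaussian displacement field centred inside the bladder or rectum.

Clock convention (documented; tests depend on it): 12 o'clock is anterior
(-y in LPS), hours increase clockwise when the phantom is viewed from the
feet, so hour ``h`` sits at angle ``30 * h`` degrees from anterior and the
6 o'clock insert is posterior (+y).

All generators are pure functions of (spec, seed): the same inputs reproduce
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
from scipy import ndimage

from .grid import (
    GeometryError,
    GridGeometry,
    ImageGrid,
    RigidTransform,
    StructureSet,
    VectorField,
    index_to_world,
)
from .transforms import apply_dvf

__all__ = [
    "EDPhantomSpec",
    "GaussianDVFSpec",
    "FractionData",
    "ScenarioBundle",
    "make_ed_phantom",
    "make_pelvis_phantom",
    "make_gaussian_dvf",
    "make_insert_swap_dvf",
    "synth_session_dose",
    "make_scenario",
    "clock_position",
    "PTV_MARGIN_MM",
    "AIR_HU",
]

AIR_HU = -1000.0
PTV_MARGIN_MM = 5.0
#: diffeomorphism guard: the max derivative of a Gaussian bump field is
#: |peak| * exp(-1/2) / sigma, which must stay below 1 to avoid folding.
GAUSSIAN_GUARD = 1.6

_DEFAULT_CLOCKS = (6, 7, 5, 9, 10, 11, 12, 1)
_DEFAULT_HU = {6: 40.0, 7: -55.0, 5: -35.0, 9: 990.0, 10: -800.0, 11: 230.0, 12: 50.0, 1: -95.0}


def clock_position(hour: float, radius: float) -> np.ndarray:
    """World (x, y) offset of a clock position (z = 0)."""
    phi = np.deg2rad(30.0 * hour)
    return np.array([radius * np.sin(phi), -radius * np.cos(phi), 0.0])


def _clock_angle_deg(xy: np.ndarray) -> float:
    """Clock angle (deg from anterior, clockwise-from-feet) of an (x, y) point."""
    return float(np.rad2deg(np.arctan2(xy[0], -xy[1])) % 360.0)


@dataclass(frozen=True)
class EDPhantomSpec:
    """Geometry of the cylindrical electron-density phantom (mm)."""

    body_radius: float = 90.0
    insert_ring_radius: float = 60.0
    insert_radius: float = 15.0
    insert_clock_positions: tuple[int, ...] = _DEFAULT_CLOCKS
    insert_hu: dict = field(default_factory=lambda: dict(_DEFAULT_HU))
    spacing: float = 2.0
    length: float = 100.0

    def __post_init__(self) -> None:
        if self.insert_ring_radius + self.insert_radius >= self.body_radius:
            raise GeometryError("insert ring + insert radius must fit inside the body")
        hours = list(self.insert_clock_positions)
        if len(set(hours)) != len(hours) or any(not 1 <= h <= 12 for h in hours):
            raise GeometryError("clock positions must be distinct integers in 1..12")

    def validate_separation(self) -> None:
        """Reject specs whose inserts would overlap."""
        hours = sorted(self.insert_clock_positions)
        for a in hours:
            for b in hours:
                if a >= b:
                    continue
                dh = min(b - a, 12 - (b - a))
                gap = 2.0 * self.insert_ring_radius * np.sin(np.deg2rad(15.0 * dh))
                if gap < 2.0 * self.insert_radius:
                    raise GeometryError(
                        f"inserts at {a} and {b} o'clock overlap "
                        f"(center gap {gap:.1f} mm < {2 * self.insert_radius:.1f} mm)"
                    )

    def grid_geometry(self, frame_id: str) -> GridGeometry:
        h_xy = self.body_radius + 3.0 * self.spacing
        h_z = self.length / 2.0 + 2.0 * self.spacing
        n_xy = 2 * int(round(h_xy / self.spacing)) + 1
        n_z = 2 * int(round(h_z / self.spacing)) + 1
        half_xy = (n_xy - 1) / 2.0 * self.spacing
        half_z = (n_z - 1) / 2.0 * self.spacing
        return GridGeometry(
            (n_xy, n_xy, n_z),
            (-half_xy, -half_xy, -half_z),
            (self.spacing,) * 3,
            frame_id,
        )


@dataclass(frozen=True)
class GaussianDVFSpec:
    """Isotropic Gaussian displacement bump: ``d(x) = peak * exp(-|x-c|^2 / 2 sigma^2)``."""

    center: tuple[float, float, float]
    sigma: float
    peak: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise GeometryError("sigma must be positive")

    @property
    def peak_magnitude(self) -> float:
        return float(np.linalg.norm(self.peak))


# ---------------------------------------------------------------------------
# Electron-density phantom
# ---------------------------------------------------------------------------

def _phantom_coords(geom: GridGeometry, setup: RigidTransform | None) -> np.ndarray:
    """Phantom-intrinsic coordinates of every voxel center.

    ``setup`` maps reference/phantom coordinates to the session frame; shapes
    are evaluated at ``setup^-1(x)`` so the generated volume shows the phantom
    under that setup offset without any resampling noise.
    """
    pts = geom.voxel_centers()
    if setup is not None and not setup.is_identity():
        pts = setup.inverse().apply(pts)
    return pts


def _ed_ct(spec: EDPhantomSpec, geom: GridGeometry, setup: RigidTransform | None) -> ImageGrid:
    q = _phantom_coords(geom, setup)
    r2 = q[:, 0] ** 2 + q[:, 1] ** 2
    in_z = np.abs(q[:, 2]) <= spec.length / 2.0
    body = (r2 <= spec.body_radius ** 2) & in_z
    hu = np.where(body, 0.0, AIR_HU)
    for hour in spec.insert_clock_positions:
        c = clock_position(hour, spec.insert_ring_radius)
        d2 = (q[:, 0] - c[0]) ** 2 + (q[:, 1] - c[1]) ** 2
        ins = (d2 <= spec.insert_radius ** 2) & in_z
        hu[ins] = spec.insert_hu.get(hour, 0.0)
    return ImageGrid.from_geometry(geom, hu.reshape(geom.shape))


def _cylinder_mask(q: np.ndarray, center_xy: np.ndarray, radius: float, half_len: float,
                   shape) -> np.ndarray:
    d2 = (q[:, 0] - center_xy[0]) ** 2 + (q[:, 1] - center_xy[1]) ** 2
    m = (d2 <= radius ** 2) & (np.abs(q[:, 2]) <= half_len)
    return m.reshape(shape)


def _dilate_mm(mask: np.ndarray, geom: GridGeometry, margin_mm: float) -> np.ndarray:
    """Euclidean dilation by a world-mm margin (exact distance transform)."""
    dist = ndimage.distance_transform_edt(~mask, sampling=geom.spacing)
    return dist <= margin_mm


def _ed_structures(
    spec: EDPhantomSpec,
    geom: GridGeometry,
    assignment: dict[str, int],
    setup: RigidTransform | None,
) -> StructureSet:
    q = _phantom_coords(geom, setup)
    half = spec.length / 2.0
    masks: dict[str, np.ndarray] = {}
    for name, hour in assignment.items():
        c = clock_position(hour, spec.insert_ring_radius)
        masks[name] = _cylinder_mask(q, c, spec.insert_radius, half, geom.shape)
    gtv_center = clock_position(assignment["GTV"], spec.insert_ring_radius)
    masks["boost"] = _cylinder_mask(q, gtv_center, 0.45 * spec.insert_radius, half * 0.8, geom.shape)
    masks["PTV"] = _dilate_mm(masks["GTV"], geom, PTV_MARGIN_MM)
    r2 = q[:, 0] ** 2 + q[:, 1] ** 2
    masks["BODY"] = ((r2 <= spec.body_radius ** 2) & (np.abs(q[:, 2]) <= half)).reshape(geom.shape)
    priorities = {n: (1 if n in ("GTV", "boost", "PTV") else 2) for n in masks}
    priorities["BODY"] = 4
    return StructureSet(masks, geom, priorities)


def _default_assignment(spec: EDPhantomSpec) -> dict[str, int]:
    hours = list(spec.insert_clock_positions)
    if 6 not in hours:
        raise GeometryError("the reference target insert must be at 6 o'clock")
    oars = [h for h in hours if h != 6]
    assignment = {"GTV": 6}
    for i, h in enumerate(oars, start=1):
        assignment[f"OAR{i}"] = h
    return assignment


def make_ed_phantom(
    spec: EDPhantomSpec | None = None,
    assignment: dict[str, int] | None = None,
    setup: RigidTransform | None = None,
    frame_id: str = "pCT",
) -> tuple[ImageGrid, StructureSet]:
    """Cylindrical electron-density phantom CT plus contoured structures.

    The CT always shows all physical inserts; ``assignment`` (structure name ->
    clock hour) controls where the contours are drawn, which is how the
    insert-swap adaptive sessions are emulated.  ``setup`` applies a rigid
    setup offset (session frames).
    """
    spec = spec or EDPhantomSpec()
    spec.validate_separation()
    geom = spec.grid_geometry(frame_id)
    ct = _ed_ct(spec, geom, setup)
    structures = _ed_structures(spec, geom, assignment or _default_assignment(spec), setup)
    return ct, structures


# ---------------------------------------------------------------------------
# Anthropomorphic pelvis surrogate
# ---------------------------------------------------------------------------

_PELVIS = {
    "body_axes": (120.0, 90.0),
    "prostate": {"center": (0.0, 0.0, -5.0), "radii": (16.0, 14.0, 14.0)},
    "bladder": {"center": (0.0, -36.0, 22.0), "radii": (28.0, 24.0, 22.0)},
    "rectum": {"center_xy": (0.0, 34.0), "radius": 12.0, "z": (-40.0, 40.0)},
    "bowel": {"center": (0.0, -8.0, 36.0), "radii": (44.0, 26.0, 12.0)},
    "femur_x": 78.0,
    "femur_y": 8.0,
    "femur_radius": 16.0,
    "z_range": (-48.0, 52.0),
    "hu": {"body": 30.0, "prostate": 45.0, "bladder": 10.0, "rectum": -60.0,
           "bowel": -30.0, "femur": 700.0},
}


def _ellipsoid(q: np.ndarray, center, radii, shape) -> np.ndarray:
    u = (q - np.asarray(center)) / np.asarray(radii)
    return ((u ** 2).sum(axis=1) <= 1.0).reshape(shape)


def pelvis_geometry(spacing: float = 2.0, frame_id: str = "pCT") -> GridGeometry:
    ax, ay = _PELVIS["body_axes"]
    z0, z1 = _PELVIS["z_range"]
    nx = 2 * int(round((ax + 3 * spacing) / spacing)) + 1
    ny = 2 * int(round((ay + 3 * spacing) / spacing)) + 1
    nz = int(round((z1 - z0) / spacing)) + 1
    half_x = (nx - 1) / 2.0 * spacing
    half_y = (ny - 1) / 2.0 * spacing
    return GridGeometry((nx, ny, nz), (-half_x, -half_y, z0), (spacing,) * 3, frame_id)


def make_pelvis_phantom(
    spacing: float = 2.0,
    setup: RigidTransform | None = None,
    frame_id: str = "pCT",
) -> tuple[ImageGrid, StructureSet]:
    """Elliptical pelvis surrogate with prostate, bladder, rectum, bowel, femurs.

    Organ masks are built in a fixed order and carved against one another so
    they are always pairwise disjoint; the PTV is a 5 mm Euclidean expansion of
    the prostate and may graze adjacent organs, as planning volumes do.
    """
    geom = pelvis_geometry(spacing, frame_id)
    q = _phantom_coords(geom, setup)
    p = _PELVIS
    ax, ay = p["body_axes"]
    body = (((q[:, 0] / ax) ** 2 + (q[:, 1] / ay) ** 2) <= 1.0).reshape(geom.shape)

    prostate = _ellipsoid(q, **{k: p["prostate"][k] for k in ("center", "radii")}, shape=geom.shape)
    bladder = _ellipsoid(q, p["bladder"]["center"], p["bladder"]["radii"], geom.shape) & ~prostate
    rx = p["rectum"]
    rectum = (
        ((q[:, 0] - rx["center_xy"][0]) ** 2 + (q[:, 1] - rx["center_xy"][1]) ** 2
         <= rx["radius"] ** 2)
        & (q[:, 2] >= rx["z"][0]) & (q[:, 2] <= rx["z"][1])
    ).reshape(geom.shape) & ~prostate & ~bladder
    bowel = (
        _ellipsoid(q, p["bowel"]["center"], p["bowel"]["radii"], geom.shape)
        & ~prostate & ~bladder & ~rectum
    )
    fr, fx_, fy = p["femur_radius"], p["femur_x"], p["femur_y"]
    femur_l = ((q[:, 0] - fx_) ** 2 + (q[:, 1] - fy) ** 2 <= fr ** 2).reshape(geom.shape)
    femur_r = ((q[:, 0] + fx_) ** 2 + (q[:, 1] - fy) ** 2 <= fr ** 2).reshape(geom.shape)

    hu = np.full(q.shape[0], AIR_HU).reshape(geom.shape)
    hu[body] = p["hu"]["body"]
    for name, m in (("prostate", prostate), ("bladder", bladder), ("rectum", rectum),
                    ("bowel", bowel), ("femur", femur_l | femur_r)):
        hu[m] = p["hu"][name]

    masks = {
        "prostate": prostate,
        "PTV": _dilate_mm(prostate, geom, PTV_MARGIN_MM),
        "bladder": bladder,
        "rectum": rectum,
        "bowel": bowel,
        "femur_l": femur_l,
        "femur_r": femur_r,
        "BODY": body,
    }
    priorities = {n: 2 for n in masks}
    priorities.update({"prostate": 1, "PTV": 1, "BODY": 4})
    ct = ImageGrid.from_geometry(geom, hu)
    return ct, StructureSet(masks, geom, priorities)


# ---------------------------------------------------------------------------
# Displacement fields
# ---------------------------------------------------------------------------

def make_gaussian_dvf(spec: GaussianDVFSpec, geom: GridGeometry) -> VectorField:
    """Gaussian displacement bump on ``geom``; rejects folding specs.

    The field is diffeomorphic iff ``|peak| * e^{-1/2} / sigma < 1``, i.e.
    ``|peak| / sigma < e^{1/2} ~ 1.649``; the guard uses 1.6 for headroom.
    """
    ratio = spec.peak_magnitude / spec.sigma
    if ratio >= GAUSSIAN_GUARD:
        raise GeometryError(
            f"|peak|/sigma = {ratio:.3f} >= {GAUSSIAN_GUARD}: the Gaussian bump would fold "
            "(max displacement gradient |peak|*exp(-1/2)/sigma must stay below 1)"
        )
    pts = geom.voxel_centers()
    r2 = ((pts - np.asarray(spec.center)) ** 2).sum(axis=1)
    w = np.exp(-r2 / (2.0 * spec.sigma ** 2))
    disp = w[:, None] * np.asarray(spec.peak, dtype=np.float64)
    return VectorField(disp.reshape(geom.shape + (3,)), geom.origin, geom.spacing, geom.frame_id)


def _annulus_window(r: np.ndarray, ring_radius: float, core_half_width: float,
                    falloff: float) -> np.ndarray:
    """Flat-top radial window: 1 on the insert ring annulus, cosine to 0 outside."""
    dr = np.abs(r - ring_radius)
    w = np.zeros_like(r)
    w[dr <= core_half_width] = 1.0
    trans = (dr > core_half_width) & (dr < core_half_width + falloff)
    w[trans] = 0.5 * (1.0 + np.cos(np.pi * (dr[trans] - core_half_width) / falloff))
    return w


def make_insert_swap_dvf(
    structures_ref: StructureSet,
    structures_session: StructureSet,
    geom: GridGeometry,
    core_half_width: float = 20.0,
    falloff: float = 20.0,
) -> VectorField:
    """Target-matching rotation field emulating priority-guided deformation.

    A rotation about the phantom axis by the target's clock-hour change
    (snapped to 30-degree multiples, which absorbs setup offsets of a few mm),
    windowed radially to the insert-ring annulus.  Because the rotation angle
    depends on radius only, the field is exactly volume-preserving; every
    ring structure is dragged along with the target, which is what scrambles
    the dose history of the organ-at-risk contours that traded places with it.
    """
    for s in (structures_ref, structures_session):
        if "GTV" not in s.masks:
            raise GeometryError("both structure sets must contain a GTV")
    c_ref = structures_ref.centroid("GTV")
    c_sess = structures_session.centroid("GTV")
    dphi = _clock_angle_deg(c_sess) - _clock_angle_deg(c_ref)
    dphi = (dphi + 180.0) % 360.0 - 180.0
    dphi = 30.0 * round(dphi / 30.0)
    if dphi == 0.0:
        return VectorField.zeros(geom)
    ring_radius = float(np.hypot(c_ref[0], c_ref[1]))

    pts = geom.voxel_centers()
    r = np.hypot(pts[:, 0], pts[:, 1])
    ang = np.deg2rad(dphi) * _annulus_window(r, ring_radius, core_half_width, falloff)
    ca, sa = np.cos(ang), np.sin(ang)
    # clock rotation by +dphi (clockwise-from-feet) maps (x, y) with the
    # standard 2-D rotation in this axis convention
    x, y = pts[:, 0], pts[:, 1]
    disp = np.zeros_like(pts)
    disp[:, 0] = ca * x - sa * y - x
    disp[:, 1] = sa * x + ca * y - y
    return VectorField(disp.reshape(geom.shape + (3,)), geom.origin, geom.spacing, geom.frame_id)


# ---------------------------------------------------------------------------
# Session dose synthesizer
# ---------------------------------------------------------------------------

def synth_session_dose(
    structures: StructureSet,
    rx_per_fraction: float = 220.0,
    penumbra_sigma: float = 4.0,
    noise_sd: float = 2.0,
    seed: int = 0,
    scatter_floor: float = 4.0,
    aperture_margin_mm: float = 10.0,
) -> ImageGrid:
    """Conformal per-fraction dose surrogate (cGy) for an adapted plan.

    The prescription is delivered to the PTV through an aperture expanded by
    ``aperture_margin_mm`` (the 50% penumbra line sits outside the PTV, as an
    optimized plan would place it), blurred with a Gaussian penumbra, riding on
    a small in-body scatter floor, then normalised so that the PTV D98 equals
    the prescription.  Seeded Gaussian noise is added inside the body and the
    result is clipped at zero.
    """
    if rx_per_fraction <= 0:
        raise ValueError(f"prescription must be positive, got {rx_per_fraction}")
    if "PTV" not in structures.masks:
        raise GeometryError("structure set has no PTV; cannot synthesize a session dose")
    if "BODY" not in structures.masks:
        raise GeometryError("structure set has no BODY contour")
    geom = structures.geometry
    sig_vox = [penumbra_sigma / s for s in geom.spacing]
    aperture = _dilate_mm(structures.masks["PTV"], geom, aperture_margin_mm)
    primary = ndimage.gaussian_filter(aperture.astype(np.float64), sigma=sig_vox)
    body = ndimage.gaussian_filter(structures.masks["BODY"].astype(np.float64), sigma=sig_vox)
    base = scatter_floor * body + (rx_per_fraction - scatter_floor) * primary
    ptv_vals = np.sort(base[structures.masks["PTV"]])
    d98 = float(np.quantile(ptv_vals, 0.02))  # coldest 2% boundary = D98
    base *= rx_per_fraction / d98
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=geom.shape) if noise_sd > 0 else 0.0
    dose = np.clip(base + noise * structures.masks["BODY"], 0.0, None)
    return ImageGrid.from_geometry(geom, dose)


# ---------------------------------------------------------------------------
# Scenario bundles
# ---------------------------------------------------------------------------

@dataclass
class FractionData:
    """One delivered adaptive fraction, in its own session frame."""

    frame_id: str
    session_ct: ImageGrid
    session_structures: StructureSet
    session_dose: ImageGrid
    rigid: RigidTransform  # maps reference-frame points to the session frame
    dvf: VectorField       # pull field on the reference grid
    target_hour: int | None = None


@dataclass
class ScenarioBundle:
    """Reference anatomy plus per-fraction session data for one QA scenario."""

    kind: str
    seed: int
    rx_per_fraction: float
    reference_ct: ImageGrid
    reference_structures: StructureSet
    fractions: list[FractionData]
    swapped_structures: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.fractions) < 1:
            raise ValueError("a scenario bundle needs at least one fraction")

    @property
    def n_fractions(self) -> int:
        return len(self.fractions)


def _random_setup(rng: np.random.Generator, max_shift_mm: float = 3.0,
                  max_rot_deg: float = 2.0) -> RigidTransform:
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    shift = direction * rng.uniform(0.0, max_shift_mm)
    angle = rng.uniform(-max_rot_deg, max_rot_deg)
    return RigidTransform.compose(
        RigidTransform.from_rotation_z(angle), RigidTransform.from_translation(shift)
    )


_SWAP_TARGET_HOURS = (7, 5)  # fraction 1 re-contoured at 7 o'clock, fraction 2 at 5

GAUSSIAN_SIGMA_MM = 15.0
GAUSSIAN_PEAK_MM = 8.0
_GAUSSIAN_CENTERS = {"bladder": (0.0, -20.0, 8.0), "rectum": (0.0, 30.0, -2.0)}


def _insert_swap_scenario(n_fractions: int, seed: int, rx: float) -> ScenarioBundle:
    rng = np.random.default_rng(seed)
    spec = EDPhantomSpec()
    ref_ct, ref_structs = make_ed_phantom(spec, frame_id="pCT")
    home = _default_assignment(spec)
    hour_to_oar = {h: name for name, h in home.items() if name != "GTV"}
    fractions = []
    swapped: list[str] = []
    for i in range(n_fractions):
        target = _SWAP_TARGET_HOURS[i % len(_SWAP_TARGET_HOURS)]
        assignment = dict(home)
        assignment["GTV"] = target
        displaced = hour_to_oar.get(target)
        if displaced is not None:
            assignment[displaced] = home["GTV"]  # displaced OAR re-drawn at 6 o'clock
            if displaced not in swapped:
                swapped.append(displaced)
        setup = _random_setup(rng)
        frame = f"fraction{i + 1}"
        sess_ct, sess_structs = make_ed_phantom(spec, assignment, setup=setup, frame_id=frame)
        dose_seed = int(rng.integers(0, 2 ** 31 - 1))
        sess_dose = synth_session_dose(sess_structs, rx_per_fraction=rx, seed=dose_seed)
        dvf = make_insert_swap_dvf(ref_structs, sess_structs, ref_ct.geometry)
        fractions.append(FractionData(frame, sess_ct, sess_structs, sess_dose, setup, dvf, target))
    return ScenarioBundle("insert_swap", seed, rx, ref_ct, ref_structs, fractions,
                          tuple(swapped))


def _pelvis_scenario(kind: str, n_fractions: int, seed: int, rx: float,
                     deform_organ: str = "bladder") -> ScenarioBundle:
    rng = np.random.default_rng(seed)
    base_ct, base_structs = make_pelvis_phantom(frame_id="phantom")
    geom = base_ct.geometry.with_frame("pCT")

    if kind == "pelvis_control":
        gauss = VectorField.zeros(geom)
        ref_ct = ImageGrid(base_ct.values.copy(), geom.origin, geom.spacing, geom.frame_id)
        ref_structs = StructureSet(
            {n: m.copy() for n, m in base_structs.masks.items()}, geom,
            dict(base_structs.priorities),
        )
    else:
        center = np.asarray(_GAUSSIAN_CENTERS[deform_organ])
        spec = GaussianDVFSpec(tuple(center), GAUSSIAN_SIGMA_MM, _peak_toward_prostate(center))
        gauss = make_gaussian_dvf(spec, geom)
        ref_ct = apply_dvf(base_ct, gauss, fill=AIR_HU)
        ref_masks = {}
        pts = geom.voxel_centers() + gauss.displacements.reshape(-1, 3)
        from .grid import sample_nearest  # local import to avoid cycle at module load

        for name, m in base_structs.masks.items():
            warped = sample_nearest(m.astype(np.float64), base_structs.geometry, pts, 0.0)
            ref_masks[name] = (warped > 0.5).reshape(geom.shape)
        ref_masks["PTV"] = _dilate_mm(ref_masks["prostate"], geom, PTV_MARGIN_MM)
        ref_structs = StructureSet(ref_masks, geom, dict(base_structs.priorities))

    fractions = []
    for i in range(n_fractions):
        frame = f"fraction{i + 1}"
        if kind == "pelvis_control":
            setup = RigidTransform.identity()
        else:
            setup = _random_setup(rng)
        sess_ct, sess_structs = make_pelvis_phantom(setup=setup, frame_id=frame)
        dose_seed = int(rng.integers(0, 2 ** 31 - 1))
        sess_dose = synth_session_dose(sess_structs, rx_per_fraction=rx, seed=dose_seed)
        fractions.append(FractionData(frame, sess_ct, sess_structs, sess_dose, setup, gauss))
    return ScenarioBundle(kind, seed, rx, ref_ct, ref_structs, fractions)


def _peak_toward_prostate(center: np.ndarray) -> tuple[float, float, float]:
    target = np.asarray(_PELVIS["prostate"]["center"])
    d = target - center
    d = d / np.linalg.norm(d) * GAUSSIAN_PEAK_MM
    return (float(d[0]), float(d[1]), float(d[2]))


def make_scenario(
    kind: str,
    n_fractions: int = 2,
    seed: int = 0,
    rx_per_fraction: float = 220.0,
    deform_organ: str = "bladder",
) -> ScenarioBundle:
    """Build a fully populated QA scenario, deterministic under ``seed``.

    Kinds:

    * ``insert_swap`` — electron-density phantom, target re-contoured at 7 then
      5 o'clock with the displaced OAR taking the 6 o'clock slot, small random
      rigid setup offsets (<= 3 mm, <= 2 deg), target-matching rotation DVFs.
    * ``pelvis_gaussian`` — planning CT deformed by a Gaussian bump centred
      inside ``deform_organ`` (bladder or rectum); sessions show the original
      anatomy under small setup offsets.
    * ``pelvis_control`` — identity rigid + zero DVF; sessions identical to the
      reference.
    """
    if n_fractions < 1:
        raise ValueError("n_fractions must be >= 1")
    if kind == "insert_swap":
        return _insert_swap_scenario(n_fractions, seed, rx_per_fraction)
    if kind in ("pelvis_gaussian", "pelvis_control"):
        if deform_organ not in _GAUSSIAN_CENTERS:
            raise ValueError(f"deform_organ must be one of {sorted(_GAUSSIAN_CENTERS)}")
        return _pelvis_scenario(kind, n_fractions, seed, rx_per_fraction, deform_organ)
    raise ValueError(f"unknown scenario kind {kind!r}")
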