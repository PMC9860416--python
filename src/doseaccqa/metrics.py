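"""DVH metrics, planning-objective checks, and mean-dose tolerance verdicts.

Metric definitions (standard DVH notation):

* ``D_x%`` — minimum dose delivered to the hottest x% of the structure volume;
  computed by linear interpolation of the cumulative (voxel-counting) DVH.
* ``D_max`` — maximum structure dose.
* ``V_x%`` — percent of structure volume receiving at least x% of the
  prescription.
* ``V(t cGy)`` in cc — absolute volume above a dose threshold, using voxel
  volume = product of grid spacings (no sub-voxel weighting).

The tolerance check applies the QA action levels suggested for routine dose
accumulation QA: +/-2% on mean-dose differences for target structures, +/-3%
for organs at risk, with structures that traded places with the target
reported but excluded from the pass/fail verdict.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import GeometryError, ImageGrid

__all__ = [
    "DVHMetrics",
    "ToleranceVerdict",
    "dvh_metrics",
    "dvh_curve",
    "Objective",
    "check_objectives",
    "tolerance_check",
    "ED_OBJECTIVES",
    "PELVIS_OBJECTIVES",
    "TARGET_TOLERANCE_PCT",
    "OAR_TOLERANCE_PCT",
]

TARGET_TOLERANCE_PCT = 2.0
OAR_TOLERANCE_PCT = 3.0


@dataclass
class DVHMetrics:
    structure: str
    mean_cgy: float
    d_max_cgy: float
    d_levels_cgy: dict[float, float] = field(default_factory=dict)   # x% -> D_x% (cGy)
    v_levels_pct: dict[float, float] = field(default_factory=dict)   # x% -> V_x% (%)
    v_abs_cc: dict[float, float] = field(default_factory=dict)       # cGy -> cc

    def d(self, x: float) -> float:
        return self.d_levels_cgy[x]

    def v(self, x: float) -> float:
        return self.v_levels_pct[x]


def _d_percent(sorted_desc: np.ndarray, x: float) -> float:
    """D_x%: linear interpolation of the descending-sorted voxel doses.

    Rank positions follow the linear-interpolation percentile convention
    (rank k of n sits at volume fraction k / (n - 1)).
    """
    n = sorted_desc.size
    if n == 1:
        return float(sorted_desc[0])
    pos = (x / 100.0) * (n - 1)
    lo = int(np.floor(pos))
    hi = min(lo + 1, n - 1)
    frac = pos - lo
    return float(sorted_desc[lo] * (1.0 - frac) + sorted_desc[hi] * frac)


def dvh_metrics(
    dose: ImageGrid,
    mask: np.ndarray,
    rx_cgy: float,
    structure: str = "",
    d_levels: tuple[float, ...] = (98.0, 99.0, 50.0, 2.0),
    v_levels: tuple[float, ...] = (50.0, 65.0, 80.0),
    v_abs_thresholds_cgy: tuple[float, ...] = (),
) -> DVHMetrics:
    """DVH summary of ``dose`` inside ``mask`` (voxel-counting DVH)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dose.shape:
        raise GeometryError("mask and dose grids have different shapes")
    vals = dose.values[mask]
    if vals.size == 0:
        raise GeometryError(f"empty mask for structure {structure!r}")
    sorted_desc = np.sort(vals)[::-1]
    voxel_cc = dose.geometry.voxel_volume_mm3 / 1000.0
    return DVHMetrics(
        structure=structure,
        mean_cgy=float(vals.mean()),
        d_max_cgy=float(vals.max()),
        d_levels_cgy={x: _d_percent(sorted_desc, x) for x in d_levels},
        v_levels_pct={
            x: 100.0 * float((vals >= (x / 100.0) * rx_cgy).sum()) / vals.size
            for x in v_levels
        },
        v_abs_cc={t: float((vals >= t).sum()) * voxel_cc for t in v_abs_thresholds_cgy},
    )


def dvh_curve(dose: ImageGrid, mask: np.ndarray, n_bins: int = 200) -> np.ndarray:
    """Cumulative DVH as an ``(n_bins, 2)`` array of (dose cGy, volume %)."""
    vals = dose.values[np.asarray(mask, dtype=bool)]
    if vals.size == 0:
        raise GeometryError("empty mask")
    edges = np.linspace(0.0, float(vals.max()) + 1e-9, n_bins)
    volume = [(100.0 * float((vals >= e).sum()) / vals.size) for e in edges]
    return np.column_stack([edges, volume])


@dataclass(frozen=True)
class Objective:
    """One planning-objective rule, e.g. D_98% >= 100% or V_65% < 30 cc.

    ``metric`` is one of ``"D%"`` (level = x of D_x%), ``"Dmax"``,
    ``"V%"`` (level = x of V_x%, bound in % volume) or ``"Vcc"`` (level = x of
    V_x%, bound in cc).  Dose bounds are percent of prescription.  ``op`` is
    taken literally (boundary semantics follow the objective string).
    """

    structure: str
    metric: str
    level: float | None
    op: str
    bound: float
    priority: int = 1

    def label(self) -> str:
        if self.metric == "D%":
            lhs = f"D_{self.level:g}%"
        elif self.metric == "Dmax":
            lhs = "D_max"
        else:
            lhs = f"V_{self.level:g}%"
        unit = "cc" if self.metric == "Vcc" else "%"
        return f"{self.structure}: {lhs} {self.op} {self.bound:g}{unit}"


_OPS = {"<": np.less, "<=": np.less_equal, ">": np.greater, ">=": np.greater_equal}

#: Planning objectives used for the electron-density phantom plans.
ED_OBJECTIVES = (
    Objective("PTV", "D%", 98.0, ">=", 100.0, 1),
    Objective("PTV", "Dmax", None, "<", 110.0, 1),
    Objective("GTV", "D%", 99.0, ">=", 100.0, 1),
    Objective("boost", "D%", 99.0, ">=", 100.0, 1),
    Objective("OAR1", "Dmax", None, "<", 50.0, 2),
    Objective("OAR2", "Dmax", None, "<", 50.0, 2),
    Objective("OAR7", "Dmax", None, "<", 50.0, 2),
    Objective("OAR3", "Dmax", None, "<", 25.0, 2),
    Objective("OAR4", "Dmax", None, "<", 25.0, 2),
    Objective("OAR5", "Dmax", None, "<", 25.0, 2),
    Objective("OAR6", "Dmax", None, "<", 25.0, 2),
)

#: Planning objectives used for the pelvis phantom plans.
PELVIS_OBJECTIVES = (
    Objective("PTV", "D%", 98.0, ">=", 100.0, 1),
    Objective("PTV", "Dmax", None, "<=", 110.0, 1),
    Objective("bladder", "V%", 50.0, "<", 30.0, 2),
    Objective("bladder", "V%", 80.0, "<", 8.0, 2),
    Objective("rectum", "V%", 50.0, "<", 17.0, 2),
    Objective("rectum", "V%", 80.0, "<", 7.0, 2),
    Objective("bowel", "Vcc", 65.0, "<", 30.0, 2),
    Objective("femur_l", "V%", 65.0, "<", 5.0, 2),
    Objective("femur_r", "V%", 65.0, "<", 5.0, 2),
)


def check_objectives(
    metrics: dict[str, DVHMetrics],
    objectives: tuple[Objective, ...],
    rx_cgy: float,
) -> list[dict]:
    """Evaluate each objective against the matching structure's DVH metrics.

    Missing structures are reported (``value None, passed None``), never
    silently skipped.
    """
    report = []
    for obj in objectives:
        m = metrics.get(obj.structure)
        if m is None:
            report.append({"rule": obj.label(), "value": None, "bound": obj.bound,
                           "passed": None, "note": "structure missing"})
            continue
        if obj.metric == "D%":
            value = 100.0 * m.d(obj.level) / rx_cgy
        elif obj.metric == "Dmax":
            value = 100.0 * m.d_max_cgy / rx_cgy
        elif obj.metric == "V%":
            value = m.v(obj.level)
        elif obj.metric == "Vcc":
            value = m.v_abs_cc[(obj.level / 100.0) * rx_cgy]
        else:  # pragma: no cover
            raise ValueError(f"unknown objective metric {obj.metric!r}")
        passed = bool(_OPS[obj.op](value, obj.bound))
        report.append({"rule": obj.label(), "value": float(value), "bound": obj.bound,
                       "passed": passed, "note": ""})
    return report


@dataclass
class ToleranceVerdict:
    structure: str
    percent_diff: float | None
    threshold_pct: float | None
    passed: bool | None
    category: str  # target | oar | swapped_oar_excluded | undefined


_TARGET_NAMES = frozenset({"GTV", "boost", "PTV", "prostate"})


def tolerance_check(
    rows: list[dict],
    swapped_structures: tuple[str, ...] = (),
    target_tol_pct: float = TARGET_TOLERANCE_PCT,
    oar_tol_pct: float = OAR_TOLERANCE_PCT,
) -> list[ToleranceVerdict]:
    """Apply the QA action levels to a mean-dose-difference table.

    Targets are checked at +/-2%, organs at risk at +/-3%; structures whose
    contours traded places with the target are reported but excluded from the
    verdict (their large discrepancies are an expected consequence of
    priority-guided deformation, not a failure of the accumulation run).
    """
    verdicts = []
    for row in rows:
        name = row["structure"]
        pct = row["percent_diff"]
        if pct is None:
            verdicts.append(ToleranceVerdict(name, None, None, None, "undefined"))
            continue
        if name in swapped_structures:
            verdicts.append(ToleranceVerdict(name, pct, None, None, "swapped_oar_excluded"))
            continue
        if name in _TARGET_NAMES:
            tol, cat = target_tol_pct, "target"
        else:
            tol, cat = oar_tol_pct, "oar"
        verdicts.append(ToleranceVerdict(name, pct, tol, bool(abs(pct) <= tol), cat))
    return verdicts
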