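"""DVH metrics against a sort-based oracle; objective and tolerance checks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from doseaccqa import (
    ED_OBJECTIVES,
    GeometryError,
    ImageGrid,
    check_objectives,
    dvh_curve,
    dvh_metrics,
    tolerance_check,
)
from doseaccqa.metrics import Objective


def grid_from(vals):
    vals = np.asarray(vals, dtype=float)
    return ImageGrid(vals, (0, 0, 0), (2.0, 2.0, 2.0))


def brute_force_dvh(vals, mask, rx, d_levels, v_levels):
    """Independent sort-based oracle using numpy percentile semantics."""
    v = np.asarray(vals)[mask]
    return {
        "mean": v.mean(),
        "dmax": v.max(),
        "d": {x: np.percentile(v, 100.0 - x) for x in d_levels},
        "v": {x: 100.0 * np.count_nonzero(v >= x / 100.0 * rx) / v.size for x in v_levels},
    }


class TestDVHMetrics:
    def test_uniform_dose(self):
        vals = np.full((6, 6, 6), 220.0)
        mask = np.zeros((6, 6, 6), bool)
        mask[1:5, 1:5, 1:5] = True
        m = dvh_metrics(grid_from(vals), mask, 220.0, d_levels=(98.0,), v_levels=(50.0,))
        assert m.mean_cgy == m.d(98.0) == m.d_max_cgy == 220.0
        assert m.v(50.0) == 100.0

    def test_two_voxel_mask(self):
        vals = np.zeros((4, 4, 4))
        mask = np.zeros((4, 4, 4), bool)
        mask[0, 0, 0] = mask[1, 0, 0] = True
        vals[0, 0, 0], vals[1, 0, 0] = 100.0, 200.0
        m = dvh_metrics(grid_from(vals), mask, 200.0, v_levels=(80.0,))
        assert m.mean_cgy == 150.0
        assert m.d_max_cgy == 200.0
        assert m.v(80.0) == 50.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_matches_sort_based_oracle(self, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(4, 12, 3))
        vals = rng.uniform(0, 300, shape)
        mask = rng.random(shape) < 0.6
        if not mask.any():
            mask[0, 0, 0] = True
        d_levels = (98.0, 50.0, 2.0)
        v_levels = (50.0, 80.0)
        m = dvh_metrics(grid_from(vals), mask, 220.0, d_levels=d_levels, v_levels=v_levels)
        oracle = brute_force_dvh(vals, mask, 220.0, d_levels, v_levels)
        assert m.mean_cgy == pytest.approx(oracle["mean"], abs=1e-9)
        assert m.d_max_cgy == oracle["dmax"]
        for x in d_levels:
            assert m.d(x) == pytest.approx(oracle["d"][x], abs=1e-9)
        for x in v_levels:
            assert m.v(x) == pytest.approx(oracle["v"][x], abs=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_monotonicity_and_ordering(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.uniform(0, 250, (8, 8, 8))
        mask = np.ones((8, 8, 8), bool)
        levels = (2.0, 50.0, 98.0, 100.0)
        m = dvh_metrics(grid_from(vals), mask, 220.0, d_levels=levels,
                        v_levels=(30.0, 50.0, 80.0))
        d_vals = [m.d(x) for x in levels]
        assert all(a >= b for a, b in zip(d_vals, d_vals[1:]))  # D_x% non-increasing in x
        v_vals = [m.v(x) for x in (30.0, 50.0, 80.0)]
        assert all(a >= b for a, b in zip(v_vals, v_vals[1:]))  # V_x% non-increasing in x
        assert m.d(100.0) <= m.mean_cgy <= m.d_max_cgy

    def test_empty_mask_rejected(self):
        with pytest.raises(GeometryError, match="empty"):
            dvh_metrics(grid_from(np.ones((4, 4, 4))), np.zeros((4, 4, 4), bool), 100.0)

    def test_dvh_curve_monotone(self):
        rng = np.random.default_rng(3)
        curve = dvh_curve(grid_from(rng.uniform(0, 100, (6, 6, 6))), np.ones((6, 6, 6), bool))
        assert np.all(np.diff(curve[:, 1]) <= 0)


class TestObjectives:
    def metrics_for_uniform(self, structs_dose, rx):
        out = {}
        for name, frac in structs_dose.items():
            vals = np.full((4, 4, 4), frac * rx / 100.0)
            out[name] = dvh_metrics(grid_from(vals), np.ones((4, 4, 4), bool), rx,
                                    structure=name, d_levels=(98.0, 99.0),
                                    v_levels=(50.0, 65.0, 80.0),
                                    v_abs_thresholds_cgy=(0.65 * rx,))
        return out

    def test_boundary_inclusive_pass(self):
        metrics = self.metrics_for_uniform({"PTV": 100.0}, 220.0)
        rules = (Objective("PTV", "D%", 98.0, ">=", 100.0),)
        assert check_objectives(metrics, rules, 220.0)[0]["passed"] is True

    def test_dmax_over_110_fails(self):
        metrics = self.metrics_for_uniform({"PTV": 111.0}, 220.0)
        rules = (Objective("PTV", "Dmax", None, "<", 110.0),)
        assert check_objectives(metrics, rules, 220.0)[0]["passed"] is False

    def test_missing_structure_reported_not_skipped(self):
        report = check_objectives({}, (Objective("PTV", "Dmax", None, "<", 110.0),), 220.0)
        assert report[0]["passed"] is None
        assert "missing" in report[0]["note"]

    def test_conformal_plan_meets_ed_objectives(self, ed_phantom, ed_dose):
        """The synthetic plan covers the targets and spares distal inserts."""
        _, structs = ed_phantom
        metrics = {
            name: dvh_metrics(ed_dose, structs.masks[name], 220.0, structure=name,
                              d_levels=(98.0, 99.0), v_levels=(50.0,))
            for name in structs.names if name != "BODY"
        }
        report = {r["rule"]: r for r in check_objectives(metrics, ED_OBJECTIVES, 220.0)}
        for rule, r in report.items():
            if rule.startswith(("PTV", "GTV", "boost")) or rule.startswith(
                ("OAR3", "OAR4", "OAR5", "OAR6")
            ):
                assert r["passed"] is True, (rule, r["value"])


class TestToleranceCheck:
    ROWS = [
        {"structure": "GTV", "percent_diff": 0.0},
        {"structure": "OAR7", "percent_diff": 2.3},
        {"structure": "OAR1", "percent_diff": 92.0},
        {"structure": "OAR4", "percent_diff": -3.4},
        {"structure": "OAR5", "percent_diff": None},
    ]

    def test_classification_and_verdicts(self):
        verdicts = {v.structure: v for v in tolerance_check(self.ROWS, ("OAR1",))}
        assert verdicts["GTV"].category == "target" and verdicts["GTV"].passed
        assert verdicts["GTV"].threshold_pct == 2.0
        assert verdicts["OAR7"].category == "oar" and verdicts["OAR7"].passed
        assert verdicts["OAR1"].category == "swapped_oar_excluded"
        assert verdicts["OAR1"].passed is None  # excluded, not a failure
        assert verdicts["OAR4"].passed is False
        assert verdicts["OAR5"].category == "undefined"

    def test_target_checked_at_two_percent(self):
        rows = [{"structure": "GTV", "percent_diff": 2.5}]
        assert tolerance_check(rows)[0].passed is False
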