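"""End-to-end QA report: mean-dose table, tolerance verdicts, and GPR rows.

The report mirrors the two tables a physicist reads during dose-accumulation
QA: a per-structure table of manually summed vs accumulated mean doses with
percent differences, and gamma passing rates comparing the two accumulation
routes (and rigid-only vs deformable propagation).
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict
from pathlib import Path

from . import __version__
from .accumulate import accumulate, fraction_structure_means, mean_dose_difference_table
from .gamma import GammaCriteria, gamma_map
from .metrics import ToleranceVerdict, tolerance_check
from .phantoms import ScenarioBundle

__all__ = ["build_qa_report", "save_report", "load_report", "report_csv_rows"]

REPORT_SCHEMA = 1

_REPORT_KEYS = {
    "schema", "tool_version", "scenario", "seed", "n_fractions",
    "rx_per_fraction_cgy", "gamma_criteria", "mean_dose_table",
    "tolerance_verdicts", "gpr_rows", "all_passed",
}


def build_qa_report(bundle: ScenarioBundle,
                    criteria: GammaCriteria | None = None) -> dict:
    """Run the full QA pipeline on a scenario bundle and assemble the report.

    * mean-dose table: manual per-fraction structure means (session frames)
      summed, vs the deformably accumulated dose read on the reference
      structures; percent difference per structure;
    * tolerance verdicts: +/-2% targets, +/-3% OARs, swapped contours excluded;
    * GPR rows: the two accumulation routes compared at the gamma criteria
      (two-step "manual" route as reference, composed route as evaluated),
      and rigid-only accumulation against the deformable one.
    """
    criteria = criteria or GammaCriteria()
    manual_means = fraction_structure_means(bundle)
    acc_twostep = accumulate(bundle, "rigid_plus_dvf", composed=False)
    acc_composed = accumulate(bundle, "rigid_plus_dvf", composed=True)
    acc_rigid = accumulate(bundle, "rigid_only")

    table = mean_dose_difference_table(acc_twostep, bundle.reference_structures, manual_means)
    verdicts = tolerance_check(table, bundle.swapped_structures)

    gpr_routes = gamma_map(acc_twostep.accumulated, acc_composed.accumulated, criteria)
    gpr_rigid = gamma_map(acc_twostep.accumulated, acc_rigid.accumulated, criteria)
    gpr_rows = [
        {
            "comparison": "manual (two-step) vs composed accumulation",
            "registration": "deformable",
            "gpr_pct": gpr_routes.pass_rate_pct,
            "n_evaluated": gpr_routes.n_evaluated,
        },
        {
            "comparison": "rigid-only vs deformable accumulation",
            "registration": "rigid",
            "gpr_pct": gpr_rigid.pass_rate_pct,
            "n_evaluated": gpr_rigid.n_evaluated,
        },
    ]

    checked = [v for v in verdicts if v.passed is not None]
    return {
        "schema": REPORT_SCHEMA,
        "tool_version": __version__,
        "scenario": bundle.kind,
        "seed": bundle.seed,
        "n_fractions": bundle.n_fractions,
        "rx_per_fraction_cgy": bundle.rx_per_fraction,
        "gamma_criteria": asdict(criteria),
        "mean_dose_table": table,
        "tolerance_verdicts": [asdict(v) for v in verdicts],
        "gpr_rows": gpr_rows,
        "all_passed": bool(all(v.passed for v in checked)),
    }


def report_csv_rows(report: dict) -> list[list]:
    """Flatten the mean-dose table into CSV rows with familiar column names."""
    n_fx = report["n_fractions"]
    header = (
        ["Structure"]
        + [f"Fraction {i + 1} dose, cGy" for i in range(n_fx)]
        + ["Manual sum of delivered dose, cGy", "Accumulated dose, cGy", "Difference, %"]
    )
    rows: list[list] = [header]
    for r in report["mean_dose_table"]:
        pct = r["percent_diff"]
        rows.append(
            [r["structure"]]
            + [f"{v:.1f}" for v in r["fraction_means_cgy"]]
            + [f"{r['manual_sum_cgy']:.1f}", f"{r['accumulated_cgy']:.1f}",
               "undefined" if pct is None else f"{pct:.1f}"]
        )
    rows.append([])
    rows.append(["Comparison", "GPR after applying rigid registration",
                 "GPR after applying deformable registration"])
    by_reg = {g["registration"]: g for g in report["gpr_rows"]}
    rows.append([
        "accumulated dose",
        f"{by_reg['rigid']['gpr_pct']:.2f}%" if "rigid" in by_reg else "",
        f"{by_reg['deformable']['gpr_pct']:.2f}%" if "deformable" in by_reg else "",
    ])
    return rows


def save_report(report: dict, json_path: str | Path, csv_path: str | Path | None = None) -> None:
    Path(json_path).write_text(json.dumps(report, indent=2, sort_keys=True))
    if csv_path is not None:
        with open(csv_path, "w", newline="") as fh:
            csv.writer(fh).writerows(report_csv_rows(report))


def load_report(json_path: str | Path) -> dict:
    """Load a QA report, rejecting unknown schema versions or fields."""
    report = json.loads(Path(json_path).read_text())
    if report.get("schema") != REPORT_SCHEMA:
        raise ValueError(f"unsupported report schema {report.get('schema')!r}")
    unknown = set(report) - _REPORT_KEYS
    if unknown:
        raise ValueError(f"unknown report fields: {sorted(unknown)}")
    return report
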