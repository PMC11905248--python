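"""Dose-volume histograms, institutional constraint evaluation, and the
adaptive-replanning trigger.

Conventions (documented dialect):

* masks are binary — a voxel is in or out, no partial-volume weighting;
* cumulative DVHs use uniform bins (default 0.01 Gy); Dx metrics are
  linearly interpolated between bin edges, giving sub-bin accuracy without
  per-voxel sorting;
* ``Dx%`` is the minimum dose received by the hottest x% of the structure,
  ``Dx cc`` the same on an absolute-volume scale, and ``Vx Gy`` the volume
  (in % or cc) receiving at least x Gy;
* each constraint's percent deviation is signed toward its violating
  direction, so one scalar per constraint feeds the +/-3% replanning rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .core import ImageVolume

DEFAULT_BIN_GY = 0.01


class DVHError(ValueError):
    pass


# ---------------------------------------------------------------------------
# curves


@dataclass
class DVHCurve:
    """Cumulative DVH: volume receiving at least each bin-edge dose."""

    dose_gy: np.ndarray  # bin edges, uniform, starting at 0
    cum_volume_cc: np.ndarray
    total_volume_cc: float
    structure: str = ""

    @property
    def cum_volume_pct(self) -> np.ndarray:
        return 100.0 * self.cum_volume_cc / self.total_volume_cc


def compute_dvh(
    dose: ImageVolume,
    mask: np.ndarray,
    bin_gy: float = DEFAULT_BIN_GY,
    structure: str = "",
) -> DVHCurve:
    """Cumulative >=-dose histogram of the in-mask voxels."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dose.grid.shape:
        raise DVHError(f"mask shape {mask.shape} != dose grid {dose.grid.shape}")
    if not mask.any():
        raise DVHError(f"structure '{structure or '<unnamed>'}' has an empty mask")
    voxvol = dose.grid.voxel_volume_cc
    values = np.asarray(dose.data, dtype=float)[mask]
    n_bins = int(np.ceil((values.max() + bin_gy) / bin_gy)) + 1
    edges = np.arange(n_bins + 1) * bin_gy
    counts, _ = np.histogram(values, bins=edges)
    # cum[i] = volume with dose >= edges[i]
    cum = np.concatenate([np.cumsum(counts[::-1])[::-1], [0]]) * voxvol
    return DVHCurve(
        dose_gy=edges,
        cum_volume_cc=cum,
        total_volume_cc=float(values.size) * voxvol,
        structure=structure,
    )


def dvh_metric(curve: DVHCurve, metric: str, arg: float, unit: str = "") -> float:
    """Evaluate a DVH point metric on a curve.

    ``metric`` is ``"D_pct"`` (arg in %), ``"D_cc"`` (arg in cc) or
    ``"V_Gy"`` (arg in Gy, reported in ``unit`` = ``"pct"`` or ``"cc"``).
    """
    dose = curve.dose_gy
    if metric in ("D_pct", "D_cc"):
        vol = curve.cum_volume_pct if metric == "D_pct" else curve.cum_volume_cc
        top = 100.0 if metric == "D_pct" else curve.total_volume_cc
        if not (0 <= arg <= top):
            raise DVHError(f"{metric} argument {arg} outside [0, {top}]")
        if arg == 0:
            return float(dose[np.nonzero(curve.cum_volume_cc)[0][-1]])
        # vol is monotone non-increasing in dose; interpolate dose at volume=arg
        return float(np.interp(-arg, -vol, dose))
    if metric == "V_Gy":
        if arg < 0:
            raise DVHError("V_Gy argument must be >= 0")
        v_cc = float(np.interp(arg, dose, curve.cum_volume_cc))
        if unit == "cc":
            return v_cc
        if unit in ("pct", "%", ""):
            return 100.0 * v_cc / curve.total_volume_cc
        raise DVHError(f"unknown V_Gy unit '{unit}'")
    raise DVHError(f"unknown metric '{metric}'")


# ---------------------------------------------------------------------------
# constraints


@dataclass(frozen=True)
class Constraint:
    """One row of a dose-volume constraint template.

    ``direction`` is the required relation achieved-vs-bound: ``"ge"``
    (coverage) or ``"le"`` (sparing).
    """

    structure: str
    metric: str  # D_pct | D_cc | V_Gy
    arg: float
    bound: float
    direction: str  # "ge" | "le"
    unit: str = ""  # for V_Gy: "pct" or "cc"; Dx metrics are Gy

    def label(self) -> str:
        if self.metric == "D_pct":
            core = f"D{self.arg:g}%"
        elif self.metric == "D_cc":
            core = f"D{self.arg:g}cc"
        else:
            core = f"V{self.arg:g}Gy[{self.unit or 'pct'}]"
        rel = ">=" if self.direction == "ge" else "<="
        return f"{self.structure} {core} {rel} {self.bound:g}"


#: Institutional dose-volume constraint template for 5 x 7.25 Gy prostate
#: SBRT.  Femoral-head rows are applied to each femur individually.
DEFAULT_CONSTRAINTS: tuple[Constraint, ...] = (
    Constraint("PTV_eval", "V_Gy", 36.25, 95.0, "ge", "pct"),
    Constraint("PTV_eval", "V_Gy", 34.40, 98.0, "ge", "pct"),
    Constraint("PTV_eval", "V_Gy", 38.78, 20.0, "le", "cc"),
    Constraint("PTV_eval", "V_Gy", 43.50, 0.03, "le", "cc"),
    Constraint("PTV_eval", "V_Gy", 33.70, 99.0, "ge", "pct"),
    Constraint("rectum", "V_Gy", 38.06, 0.03, "le", "cc"),
    Constraint("rectum", "V_Gy", 34.40, 3.00, "le", "cc"),
    Constraint("rectum", "V_Gy", 32.60, 10.0, "le", "pct"),
    Constraint("rectum", "V_Gy", 29.00, 20.0, "le", "pct"),
    Constraint("rectum", "V_Gy", 18.13, 50.0, "le", "pct"),
    Constraint("bladder", "V_Gy", 38.06, 0.03, "le", "cc"),
    Constraint("bladder", "V_Gy", 18.12, 10.0, "le", "pct"),
    Constraint("urethra_PRV", "V_Gy", 38.78, 0.03, "le", "cc"),
    Constraint("femur_left", "V_Gy", 19.90, 10.0, "le", "cc"),
    Constraint("femur_right", "V_Gy", 19.90, 10.0, "le", "cc"),
    Constraint("penile_bulb", "V_Gy", 36.25, 0.03, "le", "cc"),
    Constraint("penile_bulb", "V_Gy", 19.90, 3.0, "le", "cc"),
)


def load_constraints(path: str | Path) -> list[Constraint]:
    """Constraint template from YAML/JSON: a list of row mappings."""
    rows = yaml.safe_load(Path(path).read_text())
    return [Constraint(**row) for row in rows]


def save_constraints(constraints: Sequence[Constraint], path: str | Path) -> None:
    rows = [
        {
            "structure": c.structure,
            "metric": c.metric,
            "arg": c.arg,
            "bound": c.bound,
            "direction": c.direction,
            "unit": c.unit,
        }
        for c in constraints
    ]
    Path(path).write_text(yaml.safe_dump(rows, sort_keys=False))


@dataclass
class ConstraintResult:
    constraint: Constraint
    achieved: float | None
    passed: bool | None
    deviation_pct: float | None  # signed toward violation; None if not evaluated
    evaluated: bool = True


@dataclass
class ConstraintReport:
    results: list[ConstraintResult] = field(default_factory=list)

    @property
    def all_evaluated_pass(self) -> bool:
        return all(r.passed for r in self.results if r.evaluated)

    def to_records(self) -> list[dict]:
        return [
            {
                "constraint": r.constraint.label(),
                "structure": r.constraint.structure,
                "achieved": r.achieved,
                "bound": r.constraint.bound,
                "passed": r.passed,
                "deviation_pct": r.deviation_pct,
                "evaluated": r.evaluated,
            }
            for r in self.results
        ]


def _signed_deviation_pct(achieved: float, c: Constraint) -> float:
    """Percent deviation relative to the bound, positive toward violation."""
    if c.bound == 0:
        return float("inf") if achieved > 0 and c.direction == "le" else 0.0
    dev = (achieved - c.bound) / abs(c.bound) * 100.0
    return dev if c.direction == "le" else -dev


def evaluate_template(
    doses: Mapping[str, tuple[ImageVolume, np.ndarray]],
    template: Sequence[Constraint] = DEFAULT_CONSTRAINTS,
    bin_gy: float = DEFAULT_BIN_GY,
) -> ConstraintReport:
    """Evaluate a constraint template against per-structure (dose, mask) pairs.

    Structures missing from ``doses`` are reported as not-evaluated rather
    than failing the whole report.
    """
    curves: dict[str, DVHCurve] = {}
    report = ConstraintReport()
    for c in template:
        if c.structure not in doses:
            report.results.append(ConstraintResult(c, None, None, None, evaluated=False))
            continue
        if c.structure not in curves:
            dose, mask = doses[c.structure]
            curves[c.structure] = compute_dvh(dose, mask, bin_gy, structure=c.structure)
        achieved = dvh_metric(curves[c.structure], c.metric, c.arg, c.unit)
        dev = _signed_deviation_pct(achieved, c)
        passed = achieved >= c.bound if c.direction == "ge" else achieved <= c.bound
        report.results.append(ConstraintResult(c, achieved, passed, dev))
    return report


def percent_volume_discrepancy(v_accum: float, v_planned: float) -> float:
    """(V_accumulated - V_planned) x 100 / V_planned."""
    if v_planned == 0:
        raise DVHError("percent discrepancy undefined for zero planned value")
    return (v_accum - v_planned) * 100.0 / v_planned


def adaptation_flag(
    report: ConstraintReport, tolerance_pct: float = 3.0
) -> tuple[bool, list[ConstraintResult]]:
    """Replanning trigger: any constraint deviating *more than* the
    tolerance (strictly) into violation trips the flag."""
    violators = [
        r
        for r in report.results
        if r.evaluated and r.deviation_pct is not None and r.deviation_pct > tolerance_pct
    ]
    return bool(violators), violators
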