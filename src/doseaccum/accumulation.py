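"""Dose warping and the fraction-by-fraction progressive composite.

After each treatment the delivered fraction dose (on the daily grid) is
pulled back to the planning frame through the registration field and
replaces that fraction's share of the planned dose:

    composite(k) = sum_{i<=k} delivered_i(warped) + (N - k)/N * planned_total

so composite(0) is the plan and composite(N) the fully accumulated
delivered dose.  Warping is direct trilinear dose mapping — no Jacobian
energy/mass correction — matching common commercial DIR-based accumulation;
see the methods note for the implications.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import DisplacementField, GridDescriptor, ImageVolume
from .registration import _warp


class AccumulationError(ValueError):
    pass


def scale_to_one_fraction(total_dose: ImageVolume, n_fractions: int) -> ImageVolume:
    """Voxelwise ``total / n`` — e.g. 36.25 Gy over 5 fractions -> 7.25 Gy."""
    if n_fractions < 1:
        raise AccumulationError(f"n_fractions must be >= 1, got {n_fractions}")
    return ImageVolume(np.asarray(total_dose.data, dtype=float) / n_fractions, total_dose.grid)


def warp_dose(
    daily_dose: ImageVolume,
    field_: DisplacementField,
    planning_grid: GridDescriptor | None = None,
) -> tuple[ImageVolume, float]:
    """Pull a daily dose back to the planning grid through the field.

    Returns the warped dose and the coverage fraction: the proportion of
    planning voxels whose mapped point lies inside the daily dose support
    (outside points receive 0 Gy).
    """
    if planning_grid is not None and not field_.grid.same_geometry(planning_grid):
        raise AccumulationError("field must live on the planning grid")
    warped = _warp(field_, daily_dose, "linear")
    idx = field_.mapped_points_index(daily_dose.grid)
    inside = np.ones(field_.grid.shape, dtype=bool)
    for a in range(3):
        inside &= (idx[a] >= 0) & (idx[a] <= daily_dose.grid.shape[a] - 1)
    coverage = float(inside.mean())
    return ImageVolume(warped, field_.grid), coverage


@dataclass
class FractionRecord:
    """One delivered fraction: daily dose, its field, and the warped dose."""

    fraction_index: int
    delivered_dose_daily: ImageVolume
    field: DisplacementField
    delivered_dose_planning: ImageVolume | None = None
    coverage: float = 1.0

    def __post_init__(self) -> None:
        if np.any(self.delivered_dose_daily.data < 0):
            raise AccumulationError("delivered dose must be non-negative")
        if self.delivered_dose_planning is None:
            self.delivered_dose_planning, self.coverage = warp_dose(
                self.delivered_dose_daily, self.field
            )


@dataclass
class CompositeState:
    """Progressive composite bookkeeping over N fractions."""

    planned_total: ImageVolume
    n_fractions: int
    delivered: list[FractionRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_fractions < 1:
            raise AccumulationError("n_fractions must be >= 1")

    @property
    def k(self) -> int:
        return len(self.delivered)

    @property
    def composite(self) -> ImageVolume:
        """sum of delivered (warped) fractions + remaining planned share."""
        data = (
            (self.n_fractions - self.k) / self.n_fractions
            * np.asarray(self.planned_total.data, dtype=float)
        )
        for rec in self.delivered:
            data = data + rec.delivered_dose_planning.data
        return ImageVolume(data, self.planned_total.grid)


def progressive_composite(state: CompositeState, record: FractionRecord) -> CompositeState:
    """Fold one more delivered fraction into the running composite."""
    if any(r.fraction_index == record.fraction_index for r in state.delivered):
        raise AccumulationError(f"duplicate fraction index {record.fraction_index}")
    if not (1 <= record.fraction_index <= state.n_fractions):
        raise AccumulationError(
            f"fraction index {record.fraction_index} outside 1..{state.n_fractions}"
        )
    if not record.delivered_dose_planning.grid.same_geometry(state.planned_total.grid):
        raise AccumulationError("warped fraction dose is not on the planning grid")
    return CompositeState(
        planned_total=state.planned_total,
        n_fractions=state.n_fractions,
        delivered=[*state.delivered, record],
    )
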