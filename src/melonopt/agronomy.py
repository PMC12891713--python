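"""Planting geometry and water productivity.

Plant density follows directly from in-row planting distance and row spacing;
the projected stand per 10 a (1,000 m2) is the rounded product. Planting
distances that are truncated decimals of exact fractions (33.3 cm is 100/3 cm)
must be supplied exactly — 1000 / (0.333 m x 1.5 m) rounds to 2002 plants,
not the intended 2000 — hence geometry accepts `fractions.Fraction` inputs.

Water productivity WP = Y / V_ir (kg of fruit per m3 of irrigation water) is
the trial's resource-efficiency objective.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from numbers import Real

from .exceptions import DomainError

Number = Real | Fraction


def plant_density(planting_distance: Number, row_spacing: Number) -> float:
    """Plants per m2 for an in-row distance and row spacing, both in cm.

    Exact quotient 1/(d*r) with d, r in metres; reporting rounds to 1 decimal.
    """
    if planting_distance <= 0 or row_spacing <= 0:
        raise DomainError("planting distance and row spacing must be > 0")
    return float(1.0 / (float(planting_distance) / 100.0 * float(row_spacing) / 100.0))


def plants_per_10a(planting_distance: Number, row_spacing: Number) -> int:
    """Projected stand per 10 a: round(1000 m2 x unrounded density)."""
    density = plant_density(planting_distance, row_spacing)
    return int(round(1000.0 * density))


def water_productivity(total_yield: float, irrigation_volume: float) -> float:
    """WP = Y / V_ir, kg fruit per m3 irrigation water (per 10 a basis)."""
    if irrigation_volume <= 0:
        raise DomainError(f"irrigation_volume must be > 0, got {irrigation_volume}")
    if total_yield < 0:
        raise DomainError(f"total_yield must be >= 0, got {total_yield}")
    return total_yield / irrigation_volume


@dataclass(frozen=True)
class PlantingGeometry:
    """Geometry row: distances in cm, density in plants/m2, stand per 10 a."""

    planting_distance: float
    row_spacing: float
    plants_per_m2: float
    plants_per_10a: int

    @classmethod
    def from_spacing(
        cls, planting_distance: Number, row_spacing: Number = 150
    ) -> "PlantingGeometry":
        return cls(
            planting_distance=float(planting_distance),
            row_spacing=float(row_spacing),
            plants_per_m2=plant_density(planting_distance, row_spacing),
            plants_per_10a=plants_per_10a(planting_distance, row_spacing),
        )
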