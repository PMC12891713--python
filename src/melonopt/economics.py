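"""Quality-tier revenue, production costs, net profit and ROI.

Revenue applies grade-dependent wholesale prices (USD/kg) to the production in
each market tier. Costs are a seven-component structure per 10 a; net profit
is revenue minus total cost and ROI is net profit over total cost, in percent.

Default cost structures vary only with substrate volume (substrate cost) and
planting density (fertilizer, seedlings): substrate 1085.4 USD/10a at 10 L vs
1392.9 at 20 L; fertilizer 804.8 at 3 plants/slab vs 1085.4 at 4; seedlings
proportional to plant count (1306.2 vs 1741.6). Labor, maintenance, energy and
fixed costs (4001.6 in total) are density- and volume-invariant. These
defaults reproduce the survey-based system totals of 7,198 USD/10a for the
cheapest system (10 L, 3 plants/slab) and 8,221.5 for the dearest (20 L, 4).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .core_io import CostStructure, PriceTable
from .exceptions import DomainError, FixtureLookupError

#: Common (volume/density invariant) cost block: labor, maintenance, energy, fixed.
_COMMON = {"labor": 2000.0, "maintenance": 600.0, "energy": 800.0, "fixed": 601.6}

_SUBSTRATE_COST = {10.0: 1085.4, 20.0: 1392.9}
_FERTILIZER_COST = {3: 804.8, 4: 1085.4}
_SEEDLING_COST = {3: 1306.2, 4: 1741.6}  # proportional to plant count


@dataclass(frozen=True)
class EconomicResult:
    """Revenue, cost, net profit (USD/10a) and ROI (%) for one treatment."""

    total_revenue: float
    total_cost: float
    net_profit: float
    roi: float

    @classmethod
    def from_revenue_cost(cls, total_revenue: float, cost: float) -> "EconomicResult":
        return cls(
            total_revenue=total_revenue,
            total_cost=cost,
            net_profit=total_revenue - cost,
            roi=roi(total_revenue, cost),
        )


def default_cost_structure(substrate_volume: float, plants_per_slab: int) -> CostStructure:
    """Survey-calibrated cost structure for a substrate volume / density system."""
    try:
        substrate = _SUBSTRATE_COST[float(substrate_volume)]
        fertilizer = _FERTILIZER_COST[int(plants_per_slab)]
        seedlings = _SEEDLING_COST[int(plants_per_slab)]
    except KeyError as exc:
        raise FixtureLookupError(
            f"no default costs for substrate {substrate_volume} L, "
            f"{plants_per_slab} plants/slab"
        ) from exc
    return CostStructure(
        substrate=substrate,
        seedlings=seedlings,
        fertilizer=fertilizer,
        **_COMMON,
    )


def revenue(
    production_by_tier: Mapping[str, float],
    prices: PriceTable,
    price_stat: str = "mean",
) -> float:
    """Sum of tier production (kg/10a) times the tier price (USD/kg)."""
    total = 0.0
    for tier, kg in production_by_tier.items():
        if kg < 0:
            raise DomainError(f"production for tier {tier!r} must be >= 0, got {kg}")
        total += kg * prices.price(tier, price_stat)
    return total


def total_cost(costs: CostStructure) -> float:
    """Sum of the seven cost components, USD per 10 a."""
    return costs.total


def roi(total_revenue: float, cost: float) -> float:
    """Return on investment: 100 x (revenue - cost) / cost, percent."""
    if cost <= 0:
        raise DomainError(f"total cost must be > 0, got {cost}")
    return 100.0 * (total_revenue - cost) / cost


def percent_change(reference: float, comparison: float) -> float:
    """Relative change from reference to comparison, percent."""
    if reference <= 0:
        raise DomainError(f"reference must be > 0, got {reference}")
    return 100.0 * (comparison - reference) / reference
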