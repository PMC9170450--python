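"""Direct valuation estimators for individual ecosystem services.

Four standard estimators, each returning yuan:

* direct market value — Σ S_i·Y_i·P_i over marketed materials
  (area × yield × price);
* shadow project — Σ X_i, the construction cost of an engineered substitute
  delivering the same function;
* equivalence factor — area-weighted standard unit values VC scaled by a
  regional biomass factor;
* runoff regulation (shadow engineering) — Q_max × C, reservoir construction
  cost per m³ of the maximum safe flood regulation and storage capacity.

All estimators are nonnegative, additive over disjoint inputs, and homogeneous
of degree 1 in prices/costs. Their identifiers double as the evaluation-method
dummy codes of the coupling regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .data_model import ValidationError

#: Evaluation-method codes usable as X_m dummy categories.
METHOD_CODES = (
    "direct_market",
    "shadow_project",
    "equivalence_factor",
    "shadow_engineering",
    "travel_cost",
    "other",
)


@dataclass(frozen=True)
class MaterialLine:
    """One marketed material: production area S (hm²), yield Y (units/hm²), price P (yuan/unit)."""

    material_id: str
    area: float
    yield_per_area: float
    price: float

    def __post_init__(self) -> None:
        if self.area < 0 or self.yield_per_area < 0 or self.price < 0:
            raise ValidationError(f"material {self.material_id}: S, Y, P must all be >= 0")


@dataclass(frozen=True)
class ShadowProject:
    """Component costs (yuan) of an engineered substitute project."""

    components: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        for cid, cost in self.components:
            if cost < 0:
                raise ValidationError(f"shadow-project component {cid}: cost must be >= 0")


@dataclass
class EquivalenceTable:
    """Ecosystem-type × service unit values VC (yuan/(hm²·yr)) with a biomass factor.

    The regional adjustment is a single multiplicative scalar applied to every
    VC entry (the local basic-farmland biomass factor).
    """

    vc: pd.DataFrame
    biomass_factor: float = 1.0

    def __post_init__(self) -> None:
        if (self.vc.to_numpy() < 0).any():
            raise ValidationError("equivalence-table unit values must be >= 0")
        if not (self.biomass_factor > 0):
            raise ValidationError("biomass_factor must be > 0")


@dataclass(frozen=True)
class RunoffSpec:
    """Flood-storage capacity Q_max (m³) and reservoir unit cost (yuan/m³)."""

    q_max: float
    unit_cost: float

    def __post_init__(self) -> None:
        if self.q_max < 0 or self.unit_cost < 0:
            raise ValidationError("q_max and unit_cost must both be >= 0")


def direct_market_value(lines: list[MaterialLine]) -> float:
    """V = Σ S_i · Y_i · P_i (yuan)."""
    return float(sum(l.area * l.yield_per_area * l.price for l in lines))


def shadow_project_value(p: ShadowProject) -> float:
    """V = U = Σ X_i (yuan)."""
    return float(sum(cost for _, cost in p.components))


def equivalence_value(
    areas: dict[str, float], t: EquivalenceTable, per_service: bool = False,
):
    """ESV = Σ_i S_i × biomass_factor × VC_i, totalled or per service.

    ``areas`` maps ecosystem-type codes (rows of the VC table) to hm².
    """
    for eco in areas:
        if eco not in t.vc.index:
            raise ValidationError(f"ecosystem type {eco!r} not in equivalence table")
    per = {
        str(svc): float(sum(
            areas[eco] * t.biomass_factor * float(t.vc.loc[eco, svc]) for eco in areas
        ))
        for svc in t.vc.columns
    }
    if per_service:
        return per
    return float(sum(per.values()))


def runoff_regulation_value(r: RunoffSpec) -> float:
    """V = Q_max × C (yuan), the shadow-engineering value of runoff regulation."""
    return float(r.q_max * r.unit_cost)
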