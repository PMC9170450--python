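"""Domain types, schema validation, and tabular I/O for the valuation pipeline.

The pipeline operates on five kinds of tabular input:

* a valuation-case database — one row per observed unit value (yuan/(hm²·yr))
  for one ecosystem service at one wetland, with its evaluation method,
  base year, area and named covariate vectors;
* a wetland-type × service-type supply matrix (see :mod:`wetval.supply_matrix`);
* a consumer-price-index series used to deflate values to a common base year;
* AHP pairwise-comparison matrices (see :mod:`wetval.ahp`);
* a target-wetland inventory to which fitted models transfer values.

All monetary quantities are yuan/(hm²·yr) for unit values and yuan/yr for
totals; areas are hectares (hm²). Covariate vectors are open-schema named
maps because the attribute-indicator families (natural, environmental,
socioeconomic) are not a closed set. A missing covariate is a hard error,
never imputed: the coupling model defines no missing-data mechanism.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import pandas as pd


# ---------------------------------------------------------------------------
# Errors

class WetvalError(Exception):
    """Base class for all package errors."""


class SchemaError(WetvalError):
    """An input table is missing a required column or has a malformed layout."""


class ValidationError(WetvalError):
    """A record violates a domain invariant (non-positive value, unknown code...)."""


class NumericalError(WetvalError):
    """A numerical precondition failed (rank deficiency, no residual dof...)."""


# ---------------------------------------------------------------------------
# Domain types

@dataclass(frozen=True)
class ServiceType:
    """An ecosystem service, e.g. flood regulation or leisure tourism."""

    code: str
    label: str = ""


@dataclass(frozen=True)
class WetlandType:
    """A wetland/land-cover class, e.g. river, salt pan, muddy tidal flat."""

    code: str
    label: str = ""


@dataclass
class ValuationCase:
    """One observed unit value for one service at one wetland.

    ``value_raw`` is in yuan/(hm²·yr) at ``base_year`` prices; ``area`` in hm².
    ``natural`` holds the wetland's natural covariates (scale, patch metrics),
    ``environment`` the environmental/socioeconomic covariates of its setting
    (GDP, population density, industry structure).
    """

    case_id: str
    wetland_id: str
    wetland_type: str
    service: str
    method: str
    base_year: int
    value_raw: float
    area: float
    natural: dict[str, float] = field(default_factory=dict)
    environment: dict[str, float] = field(default_factory=dict)
    province: str | None = None

    def validate(self, cpi: "CpiSeries | None" = None, row: int | None = None) -> None:
        where = "" if row is None else f" (row {row})"
        if not (self.value_raw > 0):
            raise ValidationError(
                f"case {self.case_id}{where}: value_raw must be > 0 "
                f"(log is taken), got {self.value_raw!r}"
            )
        if not (self.area > 0):
            raise ValidationError(
                f"case {self.case_id}{where}: area must be > 0, got {self.area!r}"
            )
        if not math.isfinite(self.value_raw) or not math.isfinite(self.area):
            raise ValidationError(f"case {self.case_id}{where}: non-finite value or area")
        if cpi is not None and self.base_year not in cpi.index_by_year:
            raise ValidationError(
                f"case {self.case_id}{where}: base_year {self.base_year} "
                f"not present in CPI series"
            )


@dataclass
class CpiSeries:
    """Consumer-price-index series: ``index_by_year`` maps year → positive index.

    Values observed in year *t* are deflated to ``base_year`` prices by the
    ratio ``index(base_year) / index(t)``.
    """

    base_year: int
    index_by_year: dict[int, float]

    def __post_init__(self) -> None:
        if self.base_year not in self.index_by_year:
            raise ValidationError(
                f"CPI series has no index for its base year {self.base_year}"
            )
        for year, idx in self.index_by_year.items():
            if not (idx > 0):
                raise ValidationError(f"CPI index for {year} must be > 0, got {idx!r}")

    def index(self, year: int) -> float:
        try:
            return self.index_by_year[year]
        except KeyError:
            raise ValidationError(f"year {year} not present in CPI series") from None


@dataclass
class WetlandUnit:
    """One target wetland unit: type, area (hm²) and covariate vectors."""

    unit_id: str
    wetland_type: str
    area: float
    natural: dict[str, float] = field(default_factory=dict)
    environment: dict[str, float] = field(default_factory=dict)


@dataclass
class WetlandInventory:
    """Inventory of target wetland units to which the model transfers values."""

    units: list[WetlandUnit]

    def validate(self, wetland_types: set[str] | None = None) -> None:
        for u in self.units:
            if not (u.area > 0):
                raise ValidationError(f"unit {u.unit_id}: area must be > 0, got {u.area!r}")
            if wetland_types is not None and u.wetland_type not in wetland_types:
                raise ValidationError(
                    f"unit {u.unit_id}: wetland_type {u.wetland_type!r} "
                    f"not a supply-matrix row"
                )

    def unit(self, unit_id: str) -> WetlandUnit:
        for u in self.units:
            if u.unit_id == unit_id:
                return u
        raise ValidationError(f"unit {unit_id!r} not in inventory")


@dataclass(frozen=True)
class CaseSchema:
    """Maps CSV columns to the named covariate vectors of a case table.

    ``natural`` columns are routed into ``ValuationCase.natural`` and
    ``environment`` columns into ``ValuationCase.environment``; columns not
    named by the schema are ignored.
    """

    natural: tuple[str, ...] = ()
    environment: tuple[str, ...] = ()


CASE_COLUMNS = (
    "case_id", "wetland_id", "wetland_type", "service", "method",
    "base_year", "value_raw", "area",
)


# ---------------------------------------------------------------------------
# Readers / writers

def _require_columns(df: pd.DataFrame, required, what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing required column(s) {missing}")


def read_cases(path, schema: CaseSchema) -> list[ValuationCase]:
    """Read a valuation-case CSV into validated :class:`ValuationCase` records.

    One row per (case, service, method) observation; row order is preserved.
    """
    df = pd.read_csv(path)
    _require_columns(df, CASE_COLUMNS + schema.natural + schema.environment, "case table")
    cases: list[ValuationCase] = []
    for i, row in enumerate(df.itertuples(index=False)):
        rec = row._asdict()
        case = ValuationCase(
            case_id=str(rec["case_id"]),
            wetland_id=str(rec["wetland_id"]),
            wetland_type=str(rec["wetland_type"]),
            service=str(rec["service"]),
            method=str(rec["method"]),
            base_year=int(rec["base_year"]),
            value_raw=float(rec["value_raw"]),
            area=float(rec["area"]),
            natural={c: float(rec[c]) for c in schema.natural},
            environment={c: float(rec[c]) for c in schema.environment},
            province=(str(rec["province"]) if "province" in rec and pd.notna(rec["province"]) else None),
        )
        case.validate(row=i)
        cases.append(case)
    return cases


def cases_to_frame(cases: list[ValuationCase], schema: CaseSchema) -> pd.DataFrame:
    rows = []
    for c in cases:
        rec = {k: getattr(c, k) for k in CASE_COLUMNS}
        rec.update({k: c.natural[k] for k in schema.natural})
        rec.update({k: c.environment[k] for k in schema.environment})
        if c.province is not None:
            rec["province"] = c.province
        rows.append(rec)
    return pd.DataFrame(rows)


def write_cases(cases: list[ValuationCase], path, schema: CaseSchema) -> None:
    cases_to_frame(cases, schema).to_csv(path, index=False)


def read_cpi(path, base_year: int = 2013) -> CpiSeries:
    """Read a CPI CSV with columns ``year,index``."""
    df = pd.read_csv(path)
    _require_columns(df, ("year", "index"), "CPI series")
    return CpiSeries(
        base_year=base_year,
        index_by_year={int(y): float(v) for y, v in zip(df["year"], df["index"])},
    )


def write_cpi(cpi: CpiSeries, path) -> None:
    years = sorted(cpi.index_by_year)
    pd.DataFrame({"year": years, "index": [cpi.index_by_year[y] for y in years]}).to_csv(
        path, index=False
    )


def read_inventory(path, schema: CaseSchema) -> WetlandInventory:
    """Read a target-wetland inventory CSV (unit_id, wetland_type, area + covariates)."""
    df = pd.read_csv(path)
    _require_columns(
        df, ("unit_id", "wetland_type", "area") + schema.natural + schema.environment,
        "inventory",
    )
    units = [
        WetlandUnit(
            unit_id=str(r["unit_id"]),
            wetland_type=str(r["wetland_type"]),
            area=float(r["area"]),
            natural={c: float(r[c]) for c in schema.natural},
            environment={c: float(r[c]) for c in schema.environment},
        )
        for r in df.to_dict("records")
    ]
    inv = WetlandInventory(units=units)
    inv.validate()
    return inv


def read_inventory_geojson(path, schema: CaseSchema) -> WetlandInventory:
    """Read an inventory from a GeoJSON FeatureCollection.

    Only feature ``properties`` are used; geometry is ignored.
    """
    with open(path, encoding="utf-8") as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise SchemaError("GeoJSON inventory must be a FeatureCollection")
    units = []
    for feat in gj.get("features", []):
        props = feat.get("properties", {})
        for col in ("unit_id", "wetland_type", "area") + schema.natural + schema.environment:
            if col not in props:
                raise SchemaError(f"GeoJSON feature missing property {col!r}")
        units.append(
            WetlandUnit(
                unit_id=str(props["unit_id"]),
                wetland_type=str(props["wetland_type"]),
                area=float(props["area"]),
                natural={c: float(props[c]) for c in schema.natural},
                environment={c: float(props[c]) for c in schema.environment},
            )
        )
    inv = WetlandInventory(units=units)
    inv.validate()
    return inv


def inventory_to_frame(inv: WetlandInventory, schema: CaseSchema) -> pd.DataFrame:
    rows = []
    for u in inv.units:
        rec = {"unit_id": u.unit_id, "wetland_type": u.wetland_type, "area": u.area}
        rec.update({k: u.natural[k] for k in schema.natural})
        rec.update({k: u.environment[k] for k in schema.environment})
        rows.append(rec)
    return pd.DataFrame(rows)


def write_inventory(inv: WetlandInventory, path, schema: CaseSchema) -> None:
    inventory_to_frame(inv, schema).to_csv(path, index=False)


def write_results(table: pd.DataFrame, path) -> None:
    """Write any pipeline result table as CSV (UTF-8, header row).

    Text-representable numbers round-trip at full precision
    (``repr``-level float formatting).
    """
    try:
        table.to_csv(path, index=False, float_format=None)
    except OSError as exc:
        raise WetvalError(f"cannot write results to {path}: {exc}") from exc
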