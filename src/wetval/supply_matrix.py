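"""Wetland-type × service supply matrix and the aggregate supply score X_d.

The supply matrix N scores each wetland/land-cover type's relative capacity to
provide each ecosystem service as an integer 0–10, obtained by max-scaling a
raw capacity table (the maximal capacity along the normalization axis maps to
10). A wetland unit of type *i* and area A (hm²) then contributes the supply
score

    X_d = Σ_j N_ij · A

summed over the requested services — the spatial covariate of the coupling
regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import ValidationError, WetlandInventory

#: Normalization axes: relative capacity within a service column, or globally.
AXES = ("per_service", "global")


@dataclass
class SupplyMatrix:
    """Integer capacity matrix with wetland-type rows and service columns."""

    n: pd.DataFrame  # index: wetland-type codes, columns: service codes, int cells

    def __post_init__(self) -> None:
        vals = self.n.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise ValidationError("supply matrix entries must be integers")
            self.n = self.n.astype(int)
            vals = self.n.to_numpy()
        if vals.min() < 0 or vals.max() > 10:
            raise ValidationError("supply matrix entries must lie in [0, 10]")
        for row in self.n.index:
            if (self.n.loc[row] == 0).all():
                raise ValidationError(f"supply matrix row {row!r} is all zero")
        for col in self.n.columns:
            if (self.n[col] == 0).all():
                raise ValidationError(f"supply matrix column {col!r} is all zero")

    @property
    def wetland_types(self) -> list[str]:
        return [str(i) for i in self.n.index]

    @property
    def services(self) -> list[str]:
        return [str(c) for c in self.n.columns]

    def capacity(self, wetland_type: str, service: str) -> int:
        return int(self.n.loc[wetland_type, service])


def normalize_capacities(raw: pd.DataFrame, axis: str = "per_service") -> SupplyMatrix:
    """Normalize a raw nonnegative capacity table to the 0–10 integer scale.

    ``per_service`` scales each service column by its own maximum (capacity is
    relative within a service); ``global`` scales by the overall maximum.
    Rounding is half-up to the nearest integer.
    """
    if axis not in AXES:
        raise ValidationError(f"unknown normalization axis {axis!r}; use one of {AXES}")
    vals = raw.to_numpy(dtype=float)
    if vals.min() < 0:
        raise ValidationError("raw capacities must be >= 0")
    if axis == "per_service":
        colmax = vals.max(axis=0)
        for j, col in enumerate(raw.columns):
            if colmax[j] <= 0:
                raise ValidationError(f"service column {col!r} is all zero; "
                                      f"cannot normalize")
        scaled = 10.0 * vals / colmax
    else:
        if vals.max() <= 0:
            raise ValidationError("raw capacity table is all zero; cannot normalize")
        scaled = 10.0 * vals / vals.max()
    # half-up rounding (np.round would round ties to even)
    n = np.floor(scaled + 0.5).astype(int)
    n = np.clip(n, 0, 10)
    return SupplyMatrix(n=pd.DataFrame(n, index=raw.index, columns=raw.columns))


def unit_supply_score(
    wetland_type: str, area: float, sm: SupplyMatrix,
    services: list[str] | None = None,
) -> float:
    """Supply score of a single unit: area × Σ over services of N_ij."""
    if wetland_type not in sm.n.index:
        raise ValidationError(f"wetland type {wetland_type!r} not a supply-matrix row")
    cols = sm.services if services is None else list(services)
    for s in cols:
        if s not in sm.n.columns:
            raise ValidationError(f"service {s!r} not a supply-matrix column")
    return float(sum(sm.capacity(wetland_type, s) * area for s in cols))


def supply_score(
    inv: WetlandInventory, sm: SupplyMatrix,
    services: list[str] | None = None,
    per_service: bool = False,
):
    """Aggregate supply score X_d = Σ N_ij A_ij for every inventory unit.

    Returns a ``unit_id → X_d`` dict, or a (unit × service) DataFrame when
    ``per_service`` is requested.
    """
    cols = sm.services if services is None else list(services)
    if per_service:
        rows = {
            u.unit_id: {s: unit_supply_score(u.wetland_type, u.area, sm, [s]) for s in cols}
            for u in inv.units
        }
        return pd.DataFrame.from_dict(rows, orient="index")[cols]
    return {u.unit_id: unit_supply_score(u.wetland_type, u.area, sm, cols)
            for u in inv.units}


def read_supply_matrix(path) -> SupplyMatrix:
    """Read a supply-matrix CSV: first column wetland-type code, rest service codes."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return SupplyMatrix(n=df)


def write_supply_matrix(sm: SupplyMatrix, path) -> None:
    sm.n.to_csv(path, index_label="wetland_type")
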