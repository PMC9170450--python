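"""Synthetic inputs with known ground truth for the whole valuation pipeline.

The generator emulates the structure of a coastal-wetland valuation-case
database — 62 source studies ("cases") yielding 349 unit-value observations
spread over 6 wetland types, 8 final services and 4 evaluation methods — plus
the auxiliary inputs the pipeline needs: a supply matrix, a CPI series, an
AHP hierarchy with a known composite weight vector, and a target-wetland
inventory. Observed values are drawn from the coupling model's own forward
process: the design matrix is built exactly as in calibration, multiplied by
a known coefficient vector, perturbed with ln-normal noise, and de-deflated
to each observation's nominal year through the inverse CPI ratio; optional
outliers are planted as fixed ln-scale shifts. The emitted truth record
(coefficients, true weights, planted-outlier rows) makes parameter-recovery
and outlier-detection tests exact.

Covariate distributions are stated modelling assumptions, not estimates from
the real database: areas and GDP-like covariates are ln-normal, index-like
covariates normal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import ahp as ahp_mod
from . import coupling_model as cm
from . import data_model as dm
from . import supply_matrix as sm_mod

WETLAND_TYPE_CODES = ("river", "pond", "salt_pan", "culture_zone",
                      "sandy_beach", "mudflat")
SERVICE_CODES = ("material_production", "flood_regulation", "carbon_sequestration",
                 "atmospheric_regulation", "climate_regulation", "wave_protection",
                 "land_promotion", "leisure_tourism")
METHOD_CODES = ("direct_market", "shadow_project", "equivalence_factor",
                "shadow_engineering")
LEVEL_CODES = ("local", "provincial", "national", "global")

NATURAL_COVARIATES = ("ln_area", "patch_density", "shape_index")
ENVIRONMENT_COVARIATES = ("ln_gdp", "ln_pop_density", "industry_index")


@dataclass
class GeneratorConfig:
    """Study-condition knobs of the synthetic database.

    Defaults mirror the emulated case study: 62 cases, 349 observations,
    6 wetland types, 8 services, 4 methods, observation years 1995–2013
    deflated to 2013, ln-scale noise sd 0.3. ``beta_truth`` may fix the full
    coefficient vector (ordered as the design's column_spec); when None the
    coefficients are drawn once from the seeded generator and reported in the
    truth record.
    """

    n_cases: int = 62
    n_observations: int = 349
    n_wetland_types: int = 6
    n_services: int = 8
    n_methods: int = 4
    n_inventory_units: int = 20
    beta_truth: list[float] | None = None
    sigma_log: float = 0.3
    outlier_fraction: float = 0.0
    outlier_shift: float = 10.0  # ln-scale shift in units of sigma_log
    seed: int = cm.DEFAULT_SEED
    year_range: tuple[int, int] = (1995, 2013)
    base_year: int = 2013
    cpi_drift: float = 0.025
    cpi_noise_sd: float = 0.01
    area_ln_mean: float = 6.0   # ln hm² → median area ≈ 400 hm²
    area_ln_sd: float = 1.0
    gdp_ln_mean: float = 10.0
    gdp_ln_sd: float = 0.8
    pop_ln_mean: float = 5.5
    pop_ln_sd: float = 0.7
    industry_mean: float = 0.5
    industry_sd: float = 0.15
    ahp_jitter: float = 0.05
    intercept_truth: float = 8.0
    coef_scale: float = 0.5

    def __post_init__(self) -> None:
        if self.n_observations < self.n_cases:
            raise dm.ValidationError(
                f"n_observations ({self.n_observations}) must be >= n_cases "
                f"({self.n_cases}): every case contributes at least one observation"
            )
        for name in ("n_cases", "n_observations", "n_wetland_types", "n_services",
                     "n_methods", "n_inventory_units"):
            if getattr(self, name) < 1:
                raise dm.ValidationError(f"{name} must be >= 1")
        if self.sigma_log < 0:
            raise dm.ValidationError("sigma_log must be >= 0")
        if not (0 <= self.outlier_fraction < 1):
            raise dm.ValidationError("outlier_fraction must lie in [0, 1)")


@dataclass
class TruthRecord:
    """Ground truth of one generated bundle."""

    beta: dict[str, float]
    sigma_log: float
    composite_weights: dict[str, float]
    outlier_rows: list[int]
    seed: int

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


@dataclass
class Bundle:
    """Everything the pipeline consumes, plus the ground truth."""

    cases: list[dm.ValuationCase]
    supply: sm_mod.SupplyMatrix
    cpi: dm.CpiSeries
    hierarchy: ahp_mod.AhpHierarchy
    inventory: dm.WetlandInventory
    truth: TruthRecord
    schema: dm.CaseSchema
    design_spec: cm.DesignSpec


def _consistent_jittered(items: list[str], w: np.ndarray, rng, tau: float,
                         name: str) -> ahp_mod.PairwiseMatrix:
    """a[i][j] = (w_i/w_j)·exp(ε), ε ~ N(0, τ²), reciprocity enforced."""
    n = len(items)
    a = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a[i, j] = (w[i] / w[j]) * np.exp(rng.normal(0.0, tau))
            a[j, i] = 1.0 / a[i, j]
    return ahp_mod.PairwiseMatrix(items=items, a=a, name=name)


def _make_hierarchy(services: list[str], rng, tau: float):
    levels = list(LEVEL_CODES)
    level_w = rng.dirichlet(np.full(len(levels), 8.0))
    service_w = {lv: rng.dirichlet(np.full(len(services), 8.0)) for lv in levels}
    hierarchy = ahp_mod.AhpHierarchy(
        level_matrix=_consistent_jittered(levels, level_w, rng, tau, "levels"),
        service_matrices={
            lv: _consistent_jittered(services, service_w[lv], rng, tau, f"services[{lv}]")
            for lv in levels
        },
    )
    composite = {
        s: float(sum(level_w[k] * service_w[lv][i] for k, lv in enumerate(levels)))
        for i, s in enumerate(services)
    }
    total = sum(composite.values())
    return hierarchy, {s: v / total for s, v in composite.items()}


def _make_cpi(cfg: GeneratorConfig, rng) -> dm.CpiSeries:
    y0, y1 = cfg.year_range
    idx = {y0: 100.0}
    for y in range(y0 + 1, y1 + 1):
        growth = 1.0 + cfg.cpi_drift + rng.normal(0.0, cfg.cpi_noise_sd)
        idx[y] = idx[y - 1] * max(growth, 0.5)
    scale = 100.0 / idx[cfg.base_year]
    return dm.CpiSeries(base_year=cfg.base_year,
                        index_by_year={y: v * scale for y, v in idx.items()})


def generate(cfg: GeneratorConfig | None = None) -> Bundle:
    """Generate a full synthetic input bundle with known ground truth.

    Deterministic in ``cfg.seed``: regenerating with the same config yields a
    byte-identical bundle.
    """
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)

    wetland_types = list(WETLAND_TYPE_CODES[: cfg.n_wetland_types])
    if cfg.n_wetland_types > len(WETLAND_TYPE_CODES):
        wetland_types += [f"type_{k}" for k in range(len(WETLAND_TYPE_CODES),
                                                     cfg.n_wetland_types)]
    services = list(SERVICE_CODES[: cfg.n_services])
    if cfg.n_services > len(SERVICE_CODES):
        services += [f"service_{k}" for k in range(len(SERVICE_CODES), cfg.n_services)]
    methods = list(METHOD_CODES[: cfg.n_methods])
    if cfg.n_methods > len(METHOD_CODES):
        methods += [f"method_{k}" for k in range(len(METHOD_CODES), cfg.n_methods)]

    # (1) supply matrix from a raw ln-normal capacity table
    raw = pd.DataFrame(
        rng.lognormal(0.0, 0.6, size=(len(wetland_types), len(services))),
        index=wetland_types, columns=services,
    )
    supply = sm_mod.normalize_capacities(raw, axis="per_service")

    # (2) CPI with multiplicative drift, (3) AHP hierarchy with known composite
    cpi = _make_cpi(cfg, rng)
    hierarchy, composite = _make_hierarchy(services, rng, cfg.ahp_jitter)

    # (4) source wetlands (cases) with covariates
    def draw_wetland(k: int):
        area = float(rng.lognormal(cfg.area_ln_mean, cfg.area_ln_sd))
        return {
            "wetland_id": f"W{k:03d}",
            "wetland_type": wetland_types[int(rng.integers(len(wetland_types)))],
            "area": area,
            "natural": {
                "ln_area": float(np.log(area)),
                "patch_density": float(rng.normal(5.0, 2.0)),
                "shape_index": float(rng.normal(1.5, 0.3)),
            },
            "environment": {
                "ln_gdp": float(rng.normal(cfg.gdp_ln_mean, cfg.gdp_ln_sd)),
                "ln_pop_density": float(rng.normal(cfg.pop_ln_mean, cfg.pop_ln_sd)),
                "industry_index": float(rng.normal(cfg.industry_mean, cfg.industry_sd)),
            },
        }

    wetlands = [draw_wetland(k) for k in range(cfg.n_cases)]

    # (5) observation allocation: at least one per case, remainder multinomial
    counts = np.ones(cfg.n_cases, dtype=int)
    extra = cfg.n_observations - cfg.n_cases
    if extra > 0:
        counts += rng.multinomial(extra, np.full(cfg.n_cases, 1.0 / cfg.n_cases))

    skeleton: list[dm.ValuationCase] = []
    for c in range(cfg.n_cases):
        w = wetlands[c]
        for _ in range(counts[c]):
            skeleton.append(dm.ValuationCase(
                case_id=f"C{c:03d}",
                wetland_id=w["wetland_id"],
                wetland_type=w["wetland_type"],
                service=services[int(rng.integers(len(services)))],
                method=methods[int(rng.integers(len(methods)))],
                base_year=int(rng.integers(cfg.year_range[0], cfg.year_range[1] + 1)),
                value_raw=1.0,  # placeholder until the forward model runs
                area=w["area"],
                natural=dict(w["natural"]),
                environment=dict(w["environment"]),
            ))

    # (6) forward model: lnV = X·β + ε at base-year prices, then de-deflate
    design_spec = cm.DesignSpec(natural=NATURAL_COVARIATES,
                                environment=ENVIRONMENT_COVARIATES)
    design = cm.build_design_matrix(skeleton, supply, design_spec)
    X = design.X.to_numpy(dtype=float)
    p = X.shape[1]
    if cfg.beta_truth is not None:
        beta = np.asarray(cfg.beta_truth, dtype=float)
        if beta.shape != (p,):
            raise dm.ValidationError(
                f"beta_truth has length {beta.shape[0]}; design has {p} columns "
                f"({design.columns})"
            )
    else:
        beta = rng.uniform(-cfg.coef_scale, cfg.coef_scale, size=p)
        beta[0] = cfg.intercept_truth

    ln_v = X @ beta + rng.normal(0.0, cfg.sigma_log, size=len(skeleton))

    n_out = int(round(cfg.outlier_fraction * len(skeleton)))
    outlier_rows = sorted(
        int(i) for i in rng.choice(len(skeleton), size=n_out, replace=False)
    ) if n_out else []
    for i in outlier_rows:
        sign = 1.0 if rng.random() < 0.5 else -1.0
        ln_v[i] += sign * cfg.outlier_shift * max(cfg.sigma_log, 1e-12)

    base_idx = cpi.index(cfg.base_year)
    for i, case in enumerate(skeleton):
        v_base = float(np.exp(ln_v[i]))
        case.value_raw = v_base * cpi.index(case.base_year) / base_idx
        case.validate(cpi=cpi, row=i)

    # (7) target inventory, drawn from the same covariate distributions
    inv_units = []
    for k in range(cfg.n_inventory_units):
        w = draw_wetland(1000 + k)
        inv_units.append(dm.WetlandUnit(
            unit_id=f"U{k:03d}", wetland_type=w["wetland_type"], area=w["area"],
            natural=dict(w["natural"]), environment=dict(w["environment"]),
        ))
    inventory = dm.WetlandInventory(units=inv_units)
    inventory.validate(set(supply.wetland_types))

    truth = TruthRecord(
        beta=dict(zip(design.columns, beta.tolist())),
        sigma_log=cfg.sigma_log,
        composite_weights=composite,
        outlier_rows=outlier_rows,
        seed=cfg.seed,
    )
    schema = dm.CaseSchema(natural=NATURAL_COVARIATES,
                           environment=ENVIRONMENT_COVARIATES)
    return Bundle(cases=skeleton, supply=supply, cpi=cpi, hierarchy=hierarchy,
                  inventory=inventory, truth=truth, schema=schema,
                  design_spec=design.spec)


def worked_example() -> Bundle:
    """Tiny fixed bundle for hand verification: 3 wetland types, 2 services,
    12 observations, 2 methods, 2 target units. Regenerates identically."""
    return generate(GeneratorConfig(
        n_cases=8, n_observations=12, n_wetland_types=3, n_services=2,
        n_methods=2, n_inventory_units=2, sigma_log=0.1, seed=42,
    ))


def write_bundle(bundle: Bundle, outdir) -> dict[str, str]:
    """Write the full CSV/JSON bundle plus truth.json; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "cases": str(outdir / "cases.csv"),
        "supply_matrix": str(outdir / "supply_matrix.csv"),
        "cpi": str(outdir / "cpi.csv"),
        "inventory": str(outdir / "inventory.csv"),
        "weights_true": str(outdir / "weights_true.csv"),
        "truth": str(outdir / "truth.json"),
    }
    dm.write_cases(bundle.cases, paths["cases"], bundle.schema)
    sm_mod.write_supply_matrix(bundle.supply, paths["supply_matrix"])
    dm.write_cpi(bundle.cpi, paths["cpi"])
    dm.write_inventory(bundle.inventory, paths["inventory"], bundle.schema)
    ahp_mod.write_weights(
        ahp_mod.WeightVector(weights=bundle.truth.composite_weights),
        paths["weights_true"],
    )
    bundle.truth.to_json(paths["truth"])
    for level, m in [("levels", bundle.hierarchy.level_matrix),
                     *bundle.hierarchy.service_matrices.items()]:
        path = outdir / f"ahp_{level}.csv"
        pd.DataFrame(m.a, index=m.items, columns=m.items).to_csv(path)
        paths[f"ahp_{level}"] = str(path)
    return paths
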