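"""Log-linear coupling meta-regression for wetland ecosystem-service value transfer.

The model regresses the log of the CPI-deflated unit value of an observation
(service *i* evaluated at wetland *j*) on three covariate groups:

    ln V_ij = β0 + βw·X_wj + βc·(X_dj ⊙ X_cj) + βm·X_mi + U_ij

* X_w — the wetland's natural covariates (scale, patch metrics);
* X_d ⊙ X_c — the scalar supply score X_d = Σ N·A multiplying each
  environmental/socioeconomic covariate element-wise (the spatial–attribute
  interaction);
* X_m — one-hot indicators for the observation's service type and evaluation
  method, with one reference category dropped per group (the raw 0/1 coding
  would be collinear with the intercept).

Continuous covariates (natural and interaction columns) are z-scored on the
training sample for conditioning; stored means/scales make predictions
invariant to affine rescaling of the inputs. Calibration is ordinary least
squares; outliers are removed in a single fit–filter–refit pass on internally
studentized residuals (default threshold 2.5); out-of-sample error is
estimated by leave-one-out cross-validation via the exact hat-matrix shortcut
e_i/(1 − h_i). Back-transformation from the log scale uses Duan's smearing
estimator (mean of exponentiated residuals) by default.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm_api
from statsmodels.stats.outliers_influence import OLSInfluence

from .data_model import (
    CpiSeries,
    NumericalError,
    ValidationError,
    ValuationCase,
    WetlandInventory,
)
from .supply_matrix import SupplyMatrix, unit_supply_score

#: Log-retransformation modes.
RETRANSFORMS = ("smearing", "naive", "normal")

#: Default outlier threshold on |studentized residual|.
OUTLIER_THRESHOLD = 2.5

#: Package-wide default seed for stochastic routines.
DEFAULT_SEED = 20130101

CONST_COL = "const"


# ---------------------------------------------------------------------------
# CPI deflation

def cpi_adjust(value: float, year: int, cpi: CpiSeries) -> float:
    """Deflate ``value`` observed at ``year`` prices to base-year prices.

    Returns value × index(base_year) / index(year).
    """
    return value * cpi.index(cpi.base_year) / cpi.index(year)


# ---------------------------------------------------------------------------
# Design matrix

@dataclass(frozen=True)
class DesignSpec:
    """Names the covariates entering each coefficient group.

    ``natural`` columns come from ``case.natural`` (the βw group);
    ``environment`` columns from ``case.environment`` and are multiplied by the
    supply score X_d (the βc group). Reference categories default to the
    alphabetically first service/method.
    """

    natural: tuple[str, ...]
    environment: tuple[str, ...]
    reference_service: str | None = None
    reference_method: str | None = None
    xd_services: tuple[str, ...] | None = None  # None → total over all services
    standardize: bool = True


@dataclass
class Design:
    """A ready-to-fit design: response, named regressors, and provenance."""

    y: np.ndarray
    X: pd.DataFrame  # includes the constant column
    row_ids: list[int]  # positions in the original case list
    case_ids: list[str]
    groups: dict[str, list[str]]  # "w" | "c" | "m" → column names
    standardization: dict[str, tuple[float, float]]  # column → (mean, sd)
    services: list[str]
    methods: list[str]
    spec: DesignSpec

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def columns(self) -> list[str]:
        return list(self.X.columns)

    def subset(self, keep: np.ndarray) -> "Design":
        keep = np.asarray(keep)
        return Design(
            y=self.y[keep],
            X=self.X.iloc[keep].reset_index(drop=True),
            row_ids=[self.row_ids[i] for i in np.flatnonzero(keep)] if keep.dtype == bool
            else [self.row_ids[i] for i in keep],
            case_ids=[self.case_ids[i] for i in np.flatnonzero(keep)] if keep.dtype == bool
            else [self.case_ids[i] for i in keep],
            groups=self.groups,
            standardization=self.standardization,
            services=self.services,
            methods=self.methods,
            spec=self.spec,
        )


def _dummy_columns(values: list[str], categories: list[str], reference: str,
                   prefix: str) -> pd.DataFrame:
    cols = {}
    for cat in categories:
        if cat == reference:
            continue
        cols[f"{prefix}:{cat}"] = [1.0 if v == cat else 0.0 for v in values]
    return pd.DataFrame(cols)


def build_design_matrix(
    cases: list[ValuationCase], sm: SupplyMatrix, spec: DesignSpec,
) -> Design:
    """Assemble the regressor matrix X (no response) for a list of cases.

    Separated from :func:`build_design` so that forward simulation can reuse
    the exact training design without observed values.
    """
    if not cases:
        raise ValidationError("no cases supplied")
    services = sorted({c.service for c in cases})
    methods = sorted({c.method for c in cases})
    ref_svc = spec.reference_service or services[0]
    ref_mth = spec.reference_method or methods[0]
    if ref_svc not in services:
        raise ValidationError(f"reference service {ref_svc!r} not among case services")
    if ref_mth not in methods:
        raise ValidationError(f"reference method {ref_mth!r} not among case methods")

    xd_services = None if spec.xd_services is None else list(spec.xd_services)
    blocks: dict[str, list[float]] = {}
    w_cols = [f"xw:{name}" for name in spec.natural]
    c_cols = [f"xc_xd:{name}" for name in spec.environment]
    for col in w_cols + c_cols:
        blocks[col] = []
    for k, case in enumerate(cases):
        xd = unit_supply_score(case.wetland_type, case.area, sm, xd_services)
        for name in spec.natural:
            if name not in case.natural:
                raise ValidationError(
                    f"case {case.case_id}: missing natural covariate {name!r}"
                )
            blocks[f"xw:{name}"].append(case.natural[name])
        for name in spec.environment:
            if name not in case.environment:
                raise ValidationError(
                    f"case {case.case_id}: missing environment covariate {name!r}"
                )
            blocks[f"xc_xd:{name}"].append(xd * case.environment[name])

    X = pd.DataFrame(blocks)
    standardization: dict[str, tuple[float, float]] = {}
    if spec.standardize:
        for col in X.columns:
            mu = float(X[col].mean())
            sd = float(X[col].std(ddof=0))
            if sd == 0.0 or not math.isfinite(sd):
                raise ValidationError(
                    f"covariate column {col!r} has zero variance; cannot standardize"
                )
            X[col] = (X[col] - mu) / sd
            standardization[col] = (mu, sd)

    svc_dum = _dummy_columns([c.service for c in cases], services, ref_svc, "svc")
    mth_dum = _dummy_columns([c.method for c in cases], methods, ref_mth, "mth")
    m_cols = list(svc_dum.columns) + list(mth_dum.columns)

    X.insert(0, CONST_COL, 1.0)
    X = pd.concat([X, svc_dum, mth_dum], axis=1)

    return Design(
        y=np.full(len(cases), np.nan),
        X=X,
        row_ids=list(range(len(cases))),
        case_ids=[c.case_id for c in cases],
        groups={"w": w_cols, "c": c_cols, "m": m_cols},
        standardization=standardization,
        services=services,
        methods=methods,
        spec=DesignSpec(
            natural=tuple(spec.natural),
            environment=tuple(spec.environment),
            reference_service=ref_svc,
            reference_method=ref_mth,
            xd_services=spec.xd_services,
            standardize=spec.standardize,
        ),
    )


def build_design(
    cases: list[ValuationCase], sm: SupplyMatrix, cpi: CpiSeries, spec: DesignSpec,
) -> Design:
    """Full design: ln of the CPI-deflated unit value plus the regressor matrix."""
    design = build_design_matrix(cases, sm, spec)
    y = np.empty(len(cases))
    for k, case in enumerate(cases):
        case.validate(cpi=cpi, row=k)
        y[k] = math.log(cpi_adjust(case.value_raw, case.base_year, cpi))
    design.y = y
    return design


# ---------------------------------------------------------------------------
# Fitting

@dataclass
class CouplingModel:
    """A fitted coupling regression, sufficient to transfer values to new wetlands."""

    params: dict[str, float]
    bse: dict[str, float]
    sigma2: float
    smearing: float
    n_used: int
    n_removed: int
    column_spec: list[str]
    groups: dict[str, list[str]]
    standardization: dict[str, tuple[float, float]]
    services: list[str]
    methods: list[str]
    reference_service: str
    reference_method: str
    natural: list[str]
    environment: list[str]
    xd_services: list[str] | None = None
    retransform: str = "smearing"

    @property
    def beta0(self) -> float:
        return self.params[CONST_COL]

    @property
    def beta_w(self) -> dict[str, float]:
        return {c: self.params[c] for c in self.groups["w"]}

    @property
    def beta_c(self) -> dict[str, float]:
        return {c: self.params[c] for c in self.groups["c"]}

    @property
    def beta_m(self) -> dict[str, float]:
        return {c: self.params[c] for c in self.groups["m"]}

    def coefficients(self, scale: str = "standardized") -> dict[str, float]:
        """Coefficients on the training (standardized) or original covariate scale."""
        if scale == "standardized":
            return dict(self.params)
        if scale != "original":
            raise ValidationError(f"unknown coefficient scale {scale!r}")
        out = dict(self.params)
        b0 = out[CONST_COL]
        for col, (mu, sd) in self.standardization.items():
            out[col] = self.params[col] / sd
            b0 -= self.params[col] * mu / sd
        out[CONST_COL] = b0
        return out

    def _retransform_factor(self) -> float:
        if self.retransform == "smearing":
            return self.smearing
        if self.retransform == "naive":
            return 1.0
        if self.retransform == "normal":
            return math.exp(self.sigma2 / 2.0)
        raise ValidationError(f"unknown retransformation mode {self.retransform!r}")

    # -- serialization -----------------------------------------------------
    def to_json(self, path=None) -> str:
        payload = {
            "params": self.params,
            "bse": self.bse,
            "sigma2": self.sigma2,
            "smearing": self.smearing,
            "n_used": self.n_used,
            "n_removed": self.n_removed,
            "column_spec": self.column_spec,
            "groups": self.groups,
            "standardization": {k: list(v) for k, v in self.standardization.items()},
            "services": self.services,
            "methods": self.methods,
            "reference_service": self.reference_service,
            "reference_method": self.reference_method,
            "natural": self.natural,
            "environment": self.environment,
            "xd_services": self.xd_services,
            "retransform": self.retransform,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "CouplingModel":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source, encoding="utf-8") as fh:
                payload = json.load(fh)
        payload["standardization"] = {
            k: tuple(v) for k, v in payload["standardization"].items()
        }
        return cls(**payload)


def _find_collinear(X: np.ndarray, columns: list[str]) -> list[str]:
    """Name columns that do not increase the rank when appended left-to-right."""
    bad, rank = [], 0
    for j in range(X.shape[1]):
        r = np.linalg.matrix_rank(X[:, : j + 1])
        if r == rank:
            bad.append(columns[j])
        rank = r
    return bad


def fit(design: Design, retransform: str = "smearing") -> CouplingModel:
    """Ordinary-least-squares calibration of the coupling model.

    Stores the residual variance RSS/(n − p) and Duan's smearing factor
    (mean of exp(residuals)) for log-retransformation.
    """
    if retransform not in RETRANSFORMS:
        raise ValidationError(f"unknown retransformation mode {retransform!r}")
    X = design.X.to_numpy(dtype=float)
    y = np.asarray(design.y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValidationError("design response contains non-finite values")
    n, p = X.shape
    if n <= p:
        raise NumericalError(
            f"need more rows than columns for residual degrees of freedom "
            f"(n = {n}, p = {p})"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        bad = _find_collinear(X, design.columns)
        raise NumericalError(f"design is rank deficient; collinear column(s): {bad}")

    res = sm_api.OLS(y, X).fit()
    resid = y - X @ res.params
    sigma2 = float(resid @ resid / (n - p))
    return CouplingModel(
        params=dict(zip(design.columns, res.params.tolist())),
        bse=dict(zip(design.columns, res.bse.tolist())),
        sigma2=sigma2,
        smearing=float(np.mean(np.exp(resid))),
        n_used=n,
        n_removed=0,
        column_spec=design.columns,
        groups=design.groups,
        standardization=design.standardization,
        services=design.services,
        methods=design.methods,
        reference_service=design.spec.reference_service,
        reference_method=design.spec.reference_method,
        natural=list(design.spec.natural),
        environment=list(design.spec.environment),
        xd_services=None if design.spec.xd_services is None
        else list(design.spec.xd_services),
        retransform=retransform,
    )


# ---------------------------------------------------------------------------
# Outlier rejection

def studentized_residuals(design: Design) -> np.ndarray:
    """Internally studentized residuals of an OLS fit of the design."""
    X = design.X.to_numpy(dtype=float)
    res = sm_api.OLS(np.asarray(design.y, dtype=float), X).fit()
    return np.asarray(OLSInfluence(res).resid_studentized_internal)


def remove_outliers(
    design: Design, threshold: float = OUTLIER_THRESHOLD, iterate: bool = False,
) -> tuple[Design, list[int]]:
    """Single fit–filter pass on internally studentized residuals.

    Rows with |r| > ``threshold`` under a preliminary fit are removed; the
    reduced design is returned together with the removed rows' positions in
    the original case list. ``iterate`` repeats the pass until no row exceeds
    the threshold (off by default: the rule names one cut, not a loop).
    """
    if not (threshold > 0):
        raise ValidationError("outlier threshold must be > 0")
    current = design
    removed: list[int] = []
    while True:
        if math.isinf(threshold):
            break
        r = studentized_residuals(current)
        mask = np.abs(r) <= threshold
        if mask.all():
            break
        if not mask.any():
            raise ValidationError("outlier removal would empty the design")
        removed.extend(rid for rid, keep in zip(current.row_ids, mask) if not keep)
        current = current.subset(mask)
        if not iterate:
            break
    return current, removed


# ---------------------------------------------------------------------------
# Leave-one-out cross-validation

@dataclass
class CvReport:
    """Leave-one-out diagnostics of the fitted coupling model."""

    loo_rmse_log: float
    loo_mape: float  # mean absolute transfer error on the value scale, percent
    residuals: np.ndarray = field(repr=False)  # per-row LOO residuals, log scale
    case_ids: list[str] = field(default_factory=list, repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"case_id": self.case_ids, "loo_residual_log": self.residuals})


def loo_residuals_brute(design: Design) -> np.ndarray:
    """Literal n-refit LOO residuals (oracle for the hat-matrix shortcut)."""
    X = design.X.to_numpy(dtype=float)
    y = np.asarray(design.y, dtype=float)
    n = len(y)
    out = np.empty(n)
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        beta, *_ = np.linalg.lstsq(X[keep], y[keep], rcond=None)
        out[i] = y[i] - X[i] @ beta
    return out


def loo_cv(design: Design) -> CvReport:
    """Exact leave-one-out residuals via the hat-matrix identity e_i/(1 − h_i)."""
    X = design.X.to_numpy(dtype=float)
    y = np.asarray(design.y, dtype=float)
    n, p = X.shape
    if n <= p + 1:
        raise NumericalError(f"leave-one-out needs n > p + 1 (n = {n}, p = {p})")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise NumericalError(
            f"design is rank deficient; collinear column(s): {_find_collinear(X, design.columns)}"
        )
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ y)
    resid = y - X @ beta
    h = np.einsum("ij,jk,ik->i", X, xtx_inv, X)
    loo = resid / (1.0 - h)
    # value-scale transfer error: |exp(ŷ_(−i)) − V_i| / V_i
    mape = float(np.mean(np.abs(np.expm1(-loo))) * 100.0)
    return CvReport(
        loo_rmse_log=float(np.sqrt(np.mean(loo**2))),
        loo_mape=mape,
        residuals=loo,
        case_ids=list(design.case_ids),
    )


# ---------------------------------------------------------------------------
# Value transfer and aggregation

def predict_value(
    model: CouplingModel,
    inv: WetlandInventory,
    sm: SupplyMatrix,
    services: list[str] | None = None,
    method_code: str | None = None,
) -> pd.DataFrame:
    """Transfer the fitted model to target wetlands.

    Returns one row per (unit, service) with the predicted unit value
    (yuan/(hm²·yr)), back-transformed with the model's retransformation mode.
    ``method_code`` defaults to the training reference method.
    """
    services = model.services if services is None else list(services)
    method_code = model.reference_method if method_code is None else method_code
    for s in services:
        if s not in model.services:
            raise ValidationError(f"service {s!r} was not in the training data")
    if method_code not in model.methods:
        raise ValidationError(f"method {method_code!r} was not in the training data")

    factor = model._retransform_factor()
    rows = []
    for u in inv.units:
        xd = unit_supply_score(u.wetland_type, u.area, sm, model.xd_services)
        lin_base = model.beta0
        for name in model.natural:
            if name not in u.natural:
                raise ValidationError(f"unit {u.unit_id}: missing natural covariate {name!r}")
            col = f"xw:{name}"
            x = u.natural[name]
            if col in model.standardization:
                mu, sd = model.standardization[col]
                x = (x - mu) / sd
            lin_base += model.params[col] * x
        for name in model.environment:
            if name not in u.environment:
                raise ValidationError(
                    f"unit {u.unit_id}: missing environment covariate {name!r}"
                )
            col = f"xc_xd:{name}"
            x = xd * u.environment[name]
            if col in model.standardization:
                mu, sd = model.standardization[col]
                x = (x - mu) / sd
            lin_base += model.params[col] * x
        mth_col = f"mth:{method_code}"
        lin_base += model.params.get(mth_col, 0.0)
        for svc in services:
            lin = lin_base + model.params.get(f"svc:{svc}", 0.0)
            rows.append({"unit_id": u.unit_id, "service": svc,
                         "value": factor * math.exp(lin)})
    return pd.DataFrame(rows)


@dataclass
class TotalsReport:
    """Per-service and grand totals (yuan/yr) with an optional weighted composite."""

    per_service: dict[str, float]
    total: float
    composite: float | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [{"service": s, "total_value_yuan_per_yr": v}
                for s, v in self.per_service.items()]
        rows.append({"service": "__total__", "total_value_yuan_per_yr": self.total})
        if self.composite is not None:
            rows.append({"service": "__weighted_composite__",
                         "total_value_yuan_per_yr": self.composite})
        return pd.DataFrame(rows)


def aggregate_total(
    pred_table: pd.DataFrame, inv: WetlandInventory, weights=None,
) -> TotalsReport:
    """Accumulate predicted unit values over areas.

    Per-service total = Σ_units value × area (yuan/yr); grand total sums the
    services. With a weight vector, also emits the weighted composite index
    Σ_s w_s × (per-service total); weights are renormalized to sum 1 first.
    """
    areas = {u.unit_id: u.area for u in inv.units}
    for uid in pred_table["unit_id"].unique():
        if str(uid) not in areas:
            raise ValidationError(f"predicted unit {uid!r} not in inventory")
    per_service: dict[str, float] = {}
    for svc, grp in pred_table.groupby("service", sort=True):
        per_service[str(svc)] = float(
            sum(v * areas[str(u)] for u, v in zip(grp["unit_id"], grp["value"]))
        )
    total = float(sum(per_service.values()))
    composite = None
    if weights is not None:
        wnorm = weights.normalized().weights
        missing = [s for s in per_service if s not in wnorm]
        if missing:
            raise ValidationError(f"weight vector lacks service(s) {missing}")
        composite = float(sum(wnorm[s] * per_service[s] for s in per_service))
    return TotalsReport(per_service=per_service, total=total, composite=composite)


def config_digest(payload: dict) -> str:
    """Stable hash of a JSON-serializable configuration (provenance)."""
    text = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:16]
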