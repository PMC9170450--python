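"""Coupling meta-regression: CPI deflation, design construction, OLS calibration,
outlier rejection, LOO cross-validation, value transfer and aggregation."""

import math

import numpy as np
import pandas as pd
import pytest

import wetval as wv
import wetval.coupling_model as cm


# ---------------------------------------------------------------------------
# CPI deflation

def test_cpi_adjust_identity_and_ratio():
    cpi = wv.CpiSeries(base_year=2013, index_by_year={2000: 100.0, 2013: 110.0})
    assert cm.cpi_adjust(50.0, 2013, cpi) == 50.0
    assert cm.cpi_adjust(100.0, 2000, cpi) == pytest.approx(110.0)


def test_cpi_adjust_homogeneous_in_index():
    cpi = wv.CpiSeries(base_year=2013, index_by_year={2000: 100.0, 2013: 110.0})
    halved = wv.CpiSeries(base_year=2013, index_by_year={2000: 50.0, 2013: 110.0})
    assert cm.cpi_adjust(100.0, 2000, halved) == pytest.approx(
        2 * cm.cpi_adjust(100.0, 2000, cpi))


def test_cpi_adjust_inverse_roundtrip():
    cpi = wv.CpiSeries(base_year=2013, index_by_year={2005: 83.0, 2013: 104.5})
    adjusted = cm.cpi_adjust(123.4, 2005, cpi)
    back = adjusted * cpi.index(2005) / cpi.index(2013)
    assert back == pytest.approx(123.4, rel=1e-12)


def test_cpi_adjust_missing_year_named():
    cpi = wv.CpiSeries(base_year=2013, index_by_year={2013: 100.0})
    with pytest.raises(wv.ValidationError, match="1997"):
        cm.cpi_adjust(1.0, 1997, cpi)


# ---------------------------------------------------------------------------
# Design construction

def _case(case_id="C0", value=100.0, service="s1", method="m1", env=2.0,
          area=1.0, year=2013):
    return wv.ValuationCase(
        case_id=case_id, wetland_id="W0", wetland_type="marsh", service=service,
        method=method, base_year=year, value_raw=value, area=area,
        natural={"shape": 1.0}, environment={"x": env},
    )


def test_interaction_column_is_xd_times_environment(small_supply, flat_cpi):
    # X_d = (3+5)*area; with area=0.625, X_d=5 and x_c=2 -> interaction 10
    spec = cm.DesignSpec(natural=("shape",), environment=("x",), standardize=False)
    d = cm.build_design([_case(area=0.625)], small_supply, flat_cpi, spec)
    assert d.X.loc[0, "xc_xd:x"] == pytest.approx(10.0)
    assert d.y[0] == pytest.approx(math.log(100.0))


def test_constant_covariate_standardization_rejected(small_supply, flat_cpi):
    spec = cm.DesignSpec(natural=("shape",), environment=("x",))
    cases = [_case("C0"), _case("C1")]  # identical covariates -> zero variance
    with pytest.raises(wv.ValidationError, match="zero variance"):
        cm.build_design(cases, small_supply, flat_cpi, spec)


def test_missing_covariate_is_hard_error(small_supply, flat_cpi):
    case = _case()
    del case.environment["x"]
    spec = cm.DesignSpec(natural=("shape",), environment=("x",), standardize=False)
    with pytest.raises(wv.ValidationError, match="'x'"):
        cm.build_design([case], small_supply, flat_cpi, spec)


def test_design_dimensions_match_generator_contract():
    bundle = wv.generate(wv.GeneratorConfig(seed=11))
    d = cm.build_design(bundle.cases, bundle.supply, bundle.cpi, bundle.design_spec)
    assert d.n == 349
    assert d.columns == list(bundle.truth.beta)
    # one-hot with dropped reference: 8 services -> 7, 4 methods -> 3
    assert len(d.groups["m"]) == 7 + 3
    assert all(set(d.X[c].unique()).issubset({0.0, 1.0}) for c in d.groups["m"])


# ---------------------------------------------------------------------------
# Fitting

def test_noise_free_recovery_small():
    bundle = wv.generate(wv.GeneratorConfig(
        n_cases=20, n_observations=80, sigma_log=0.0, seed=2))
    d = cm.build_design(bundle.cases, bundle.supply, bundle.cpi, bundle.design_spec)
    model = cm.fit(d)
    for col in d.columns:
        assert model.params[col] == pytest.approx(bundle.truth.beta[col], abs=1e-8)
    assert model.smearing == pytest.approx(1.0, abs=1e-10)


def test_duplicate_column_rank_error(small_supply, flat_cpi, rng):
    spec = cm.DesignSpec(natural=("shape",), environment=("x",), standardize=False)
    cases = [_case(f"C{k}", value=float(rng.lognormal(4, 1)), env=float(rng.normal(2, 1)),
                   service="s1" if k % 2 else "s2") for k in range(10)]
    d = cm.build_design(cases, small_supply, flat_cpi, spec)
    d.X["xw:shape_copy"] = d.X["xw:shape"]
    with pytest.raises(wv.NumericalError, match="collinear"):
        cm.fit(d)


def test_saturated_design_rejected(small_supply, flat_cpi, rng):
    spec = cm.DesignSpec(natural=(), environment=("x",), standardize=False)
    cases = [_case(f"C{k}", value=float(rng.lognormal(4, 1)),
                   env=float(rng.normal(2, 1))) for k in range(2)]
    d = cm.build_design(cases, small_supply, flat_cpi, spec)  # n = p = 2
    with pytest.raises(wv.NumericalError, match="degrees of freedom"):
        cm.fit(d)


def test_original_scale_coefficients_reproduce_predictions():
    bundle = wv.worked_example()
    d = cm.build_design(bundle.cases, bundle.supply, bundle.cpi, bundle.design_spec)
    model = cm.fit(d)
    orig = model.coefficients("original")
    # rebuild the unstandardized design and check identical fitted values
    raw = cm.build_design(bundle.cases, bundle.supply, bundle.cpi,
                          cm.DesignSpec(natural=bundle.design_spec.natural,
                                        environment=bundle.design_spec.environment,
                                        standardize=False))
    yhat_std = d.X.to_numpy() @ np.array([model.params[c] for c in d.columns])
    yhat_orig = raw.X.to_numpy() @ np.array([orig[c] for c in raw.columns])
    assert np.allclose(yhat_std, yhat_orig, atol=1e-8)


def test_model_json_roundtrip(tmp_path):
    bundle = wv.worked_example()
    d = cm.build_design(bundle.cases, bundle.supply, bundle.cpi, bundle.design_spec)
    model = cm.fit(d)
    path = tmp_path / "model.json"
    model.to_json(path)
    back = wv.CouplingModel.from_json(path)
    assert back == model


# ---------------------------------------------------------------------------
# Outlier rejection

def test_clean_data_nothing_removed():
    bundle = wv.generate(wv.GeneratorConfig(
        n_cases=30, n_observations=120, sigma_log=0.05, seed=4))
    d = cm.build_design(bundle.cases, bundle.supply, bundle.cpi, bundle.design_spec)
    d2, removed = cm.remove_outliers(d, threshold=6.0)
    assert removed == [] and d2.n == d.n


def test_infinite_threshold_is_identity():
    bundle = wv.worked_example()
    d = cm.build_design(bundle.cases, bundle.supply, bundle.cpi, bundle.design_spec)
    d2, removed = cm.remove_outliers(d, threshold=math.inf)
    assert removed == [] and d2.n == d.n


def test_planted_outlier_detected():
    bundle = wv.generate(wv.GeneratorConfig(
        n_cases=40, n_observations=200, sigma_log=0.3,
        outlier_fraction=1 / 200, outlier_shift=10.0, seed=9))
    assert len(bundle.truth.outlier_rows) == 1
    d = cm.build_design(bundle.cases, bundle.supply, bundle.cpi, bundle.design_spec)
    d2, removed = cm.remove_outliers(d, threshold=2.5)
    assert bundle.truth.outlier_rows[0] in removed
    assert d2.n == d.n - len(removed)


def test_never_removes_rows_below_threshold():
    bundle = wv.generate(wv.GeneratorConfig(
        n_cases=40, n_observations=200, sigma_log=0.3, seed=13))
    d = cm.build_design(bundle.cases, bundle.supply, bundle.cpi, bundle.design_spec)
    r = cm.studentized_residuals(d)
    exceed = {d.row_ids[i] for i in np.flatnonzero(np.abs(r) > 2.5)}
    _, removed = cm.remove_outliers(d, threshold=2.5)
    assert set(removed) == exceed  # single pass removes exactly the exceeders


# ---------------------------------------------------------------------------
# Leave-one-out cross-validation

def test_loo_shortcut_equals_brute_force(rng):
    n, p = 30, 5
    X = pd.DataFrame(rng.normal(size=(n, p)),
                     columns=[f"x{k}" for k in range(p)])
    X.insert(0, "const", 1.0)
    y = rng.normal(size=n)
    d = cm.Design(y=y, X=X, row_ids=list(range(n)),
                  case_ids=[f"r{k}" for k in range(n)],
                  groups={"w": [], "c": [], "m": []}, standardization={},
                  services=[], methods=[],
                  spec=cm.DesignSpec(natural=(), environment=()))
    report = cm.loo_cv(d)
    brute = cm.loo_residuals_brute(d)
    assert np.allclose(report.residuals, brute, atol=1e-8)


def test_noise_free_loo_rmse_is_zero():
    bundle = wv.generate(wv.GeneratorConfig(
        n_cases=20, n_observations=80, sigma_log=0.0, seed=6))
    d = cm.build_design(bundle.cases, bundle.supply, bundle.cpi, bundle.design_spec)
    assert cm.loo_cv(d).loo_rmse_log == pytest.approx(0.0, abs=1e-8)


def test_loo_needs_spare_degrees_of_freedom(small_supply, flat_cpi, rng):
    spec = cm.DesignSpec(natural=(), environment=("x",), standardize=False)
    cases = [_case(f"C{k}", value=float(rng.lognormal(4, 1)),
                   env=float(rng.normal(2, 1))) for k in range(3)]
    d = cm.build_design(cases, small_supply, flat_cpi, spec)
    with pytest.raises(wv.NumericalError, match="n > p"):
        cm.loo_cv(d)


# ---------------------------------------------------------------------------
# Value transfer

def _null_model(small_supply):
    return wv.CouplingModel(
        params={"const": 0.0, "xw:shape": 0.0, "xc_xd:x": 0.0},
        bse={}, sigma2=0.0, smearing=1.0, n_used=10, n_removed=0,
        column_spec=["const", "xw:shape", "xc_xd:x"],
        groups={"w": ["xw:shape"], "c": ["xc_xd:x"], "m": []},
        standardization={}, services=["s1"], methods=["m1"],
        reference_service="s1", reference_method="m1",
        natural=["shape"], environment=["x"],
    )


def test_zero_model_predicts_one(small_supply):
    model = _null_model(small_supply)
    inv = wv.WetlandInventory(units=[
        wv.WetlandUnit("u0", "marsh", 2.0, {"shape": 1.3}, {"x": 4.0}),
        wv.WetlandUnit("u1", "marsh", 5.0, {"shape": 0.3}, {"x": -1.0}),
    ])
    pred = cm.predict_value(model, inv, small_supply)
    assert pred["value"].tolist() == pytest.approx([1.0, 1.0])


def test_prediction_matches_hand_linear_algebra(small_supply):
    model = _null_model(small_supply)
    model.params = {"const": 1.0, "xw:shape": 0.5, "xc_xd:x": 0.1}
    model.smearing = 1.2
    inv = wv.WetlandInventory(units=[
        wv.WetlandUnit("u0", "marsh", 2.0, {"shape": 1.0}, {"x": 0.25}),
        wv.WetlandUnit("u1", "marsh", 0.5, {"shape": -2.0}, {"x": 1.0}),
    ])
    pred = cm.predict_value(model, inv, small_supply)
    # u0: X_d = 8*2 = 16; lin = 1 + 0.5*1 + 0.1*(16*0.25) = 1.9
    # u1: X_d = 8*0.5 = 4; lin = 1 - 1.0 + 0.1*4 = 0.4
    assert pred["value"].tolist() == pytest.approx(
        [1.2 * math.exp(1.9), 1.2 * math.exp(0.4)])


def test_unseen_service_or_method_rejected(small_supply):
    model = _null_model(small_supply)
    inv = wv.WetlandInventory(units=[
        wv.WetlandUnit("u0", "marsh", 1.0, {"shape": 1.0}, {"x": 1.0})])
    with pytest.raises(wv.ValidationError, match="s9"):
        cm.predict_value(model, inv, small_supply, services=["s9"])
    with pytest.raises(wv.ValidationError, match="m9"):
        cm.predict_value(model, inv, small_supply, method_code="m9")


def test_prediction_invariant_to_affine_covariate_rescaling():
    base = wv.generate(wv.GeneratorConfig(n_cases=25, n_observations=100,
                                          sigma_log=0.2, seed=8))
    d = cm.build_design(base.cases, base.supply, base.cpi, base.design_spec)
    pred0 = cm.predict_value(cm.fit(d), base.inventory, base.supply)

    # affine map of a natural covariate applied to cases and inventory alike
    def remap(v):
        return 3.5 * v - 7.0
    for c in base.cases:
        c.natural["shape_index"] = remap(c.natural["shape_index"])
    for u in base.inventory.units:
        u.natural["shape_index"] = remap(u.natural["shape_index"])
    d2 = cm.build_design(base.cases, base.supply, base.cpi, base.design_spec)
    pred1 = cm.predict_value(cm.fit(d2), base.inventory, base.supply)
    assert np.allclose(pred0["value"], pred1["value"], rtol=1e-8)


# ---------------------------------------------------------------------------
# Aggregation

def test_aggregate_hand_example():
    inv = wv.WetlandInventory(units=[wv.WetlandUnit("u0", "marsh", 2.0)])
    pred = pd.DataFrame({"unit_id": ["u0"], "service": ["s1"], "value": [5.0]})
    rep = cm.aggregate_total(pred, inv)
    assert rep.per_service == {"s1": 10.0} and rep.total == 10.0


def test_aggregate_linear_in_area():
    inv = wv.WetlandInventory(units=[wv.WetlandUnit("u0", "marsh", 2.0),
                                     wv.WetlandUnit("u1", "marsh", 3.0)])
    pred = pd.DataFrame({"unit_id": ["u0", "u1"], "service": ["s1", "s1"],
                         "value": [5.0, 7.0]})
    base = cm.aggregate_total(pred, inv)
    doubled_inv = wv.WetlandInventory(units=[
        wv.WetlandUnit(u.unit_id, u.wetland_type, 2 * u.area) for u in inv.units])
    assert cm.aggregate_total(pred, doubled_inv).total == pytest.approx(2 * base.total)


def test_weighted_composite_with_published_weights():
    weights = wv.published_weights()
    T = 123.0
    inv = wv.WetlandInventory(units=[wv.WetlandUnit("u0", "marsh", 1.0)])
    pred = pd.DataFrame({
        "unit_id": ["u0"] * 10,
        "service": list(weights.weights),
        "value": [T] * 10,
    })
    rep = cm.aggregate_total(pred, inv, weights=weights)
    # weights renormalized to sum 1 => composite of equal totals is that total
    assert rep.composite == pytest.approx(T, rel=1e-12)
    assert rep.total == pytest.approx(10 * T)


def test_aggregate_unknown_unit_rejected():
    inv = wv.WetlandInventory(units=[wv.WetlandUnit("u0", "marsh", 1.0)])
    pred = pd.DataFrame({"unit_id": ["ghost"], "service": ["s1"], "value": [1.0]})
    with pytest.raises(wv.ValidationError, match="ghost"):
        cm.aggregate_total(pred, inv)
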