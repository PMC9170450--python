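# wetval

Value transfer for wetland ecosystem services.

Primary valuation of every wetland is infeasible at regional scale, so
practitioners predict ("transfer") service values from a statistical model
calibrated on previously published valuation cases. `wetval` implements such
a pipeline for coastal-wetland ecosystem services:

* **AHP weighting** — comprehensive service-function weights from multi-level
  pairwise-comparison questionnaires (principal eigenvector, consistency
  ratio CR = CI/RI with CI = (λ_max − n)/(n − 1));
* **supply-matrix scoring** — a wetland-type × service table of integer
  capacities N ∈ [0, 10], giving each wetland unit the spatial supply score
  X_d = Σ N_ij · A (A in hm²);
* **direct valuation estimators** — direct market value Σ S_i·Y_i·P_i, shadow
  project Σ X_i, equivalence-factor ESV = Σ S_i·VC_i with a regional biomass
  factor, and shadow-engineering runoff regulation Q_max × C;
* **a log-linear coupling meta-regression**

  ```
  ln V_ij = β0 + βw·X_wj + βc·(X_dj ⊙ X_cj) + βm·X_mi + U_ij
  ```

  where V_ij is the CPI-deflated unit value (yuan/(hm²·yr)) of service *i*
  observed at wetland *j*, X_w are natural covariates, X_d ⊙ X_c is the
  supply score interacting with environmental/socioeconomic covariates, and
  X_m are one-hot service and evaluation-method indicators. Calibration is
  OLS with a 2.5σ studentized-residual outlier rule, leave-one-out
  cross-validation (exact hat-matrix shortcut), and Duan smearing for the
  back-transformation from the log scale.

A synthetic-data module generates the whole input bundle (case database,
supply matrix, CPI series, AHP hierarchy, target inventory) with known ground
truth, emulating a 62-case / 349-observation calibration database.

## Worked example

```python
import wetval as wv
import wetval.coupling_model as cm

bundle = wv.worked_example()           # 3 wetland types, 2 services, 12 observations
design = cm.build_design(bundle.cases, bundle.supply, bundle.cpi, bundle.design_spec)
model = cm.fit(design)
report = cm.loo_cv(design)
pred = cm.predict_value(model, bundle.inventory, bundle.supply)
weights = wv.composite_weights(bundle.hierarchy)
totals = cm.aggregate_total(pred, bundle.inventory, weights=weights)
print(round(report.loo_rmse_log, 4), round(report.loo_mape, 2))
print(pred.round(2))
print(round(totals.total, 1), round(totals.composite, 1))
```

prints

```
0.1024 9.22
  unit_id              service     value
0    U000     flood_regulation  10493.90
1    U000  material_production  15897.63
2    U001     flood_regulation   1526.03
3    U001  material_production   2311.85
10839318.6 5423829.8
```

The leave-one-out RMSE of 0.1024 on the ln scale (9.22 % mean absolute
transfer error on the value scale) reflects the example's ln-noise sd of 0.1.
The four predictions are unit values in yuan/(hm²·yr) for the two target
wetlands and two services; multiplied by the units' areas and accumulated
they give a grand total of 1.084 × 10⁷ yuan/yr, and 5.42 × 10⁶ yuan/yr as the
AHP-weighted composite index.

The same chain runs from the shell:

```sh
wetval run --seed 42 --out results/      # simulate → fit → cv → predict → total
```

writing the fitted model JSON, CV report, prediction and totals tables, and a
provenance log (config hash, seed, package version) that makes the run
byte-for-byte reproducible.

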