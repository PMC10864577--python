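# specfe

Feature engineering and stacked OLS regression for predicting fruit soluble
solids content (SSC, % Brix) from Vis-NIR reflectance spectra (450–1000 nm).

Spectra from intact fruit are high-dimensional, strongly collinear, and
corrupted by scatter, baseline drift and sensor noise, while the chemistry
of interest shows up only as shallow absorption features. This package
implements the standard chemometric answer — *feature engineering before a
deliberately simple model* — as a tested, reusable library for people
building non-destructive quality-assessment pipelines:

- **Pre-processing** (`specfe.preprocessing`): standard normal variate
  (SNV), polynomial detrend (DC), Savitzky–Golay smoothing (SG), and direct
  orthogonal signal correction (DOSC, with proper fit/apply separation).
- **Feature selection** (`specfe.selection`): projections (PCA, kernel PCA,
  SVD), univariate rankers (F-test, Pearson |r| (PPMCC), mutual
  information), and iterative searchers (RFE, the successive projections
  algorithm SPA, and competitive adaptive reweighted sampling CARS) behind
  one fit/apply `Selector` contract.
- **Evaluation protocol** (`specfe.model_eval`): SPXY (joint X–Y distance
  Kennard–Stone) calibration/prediction partitioning, minimum-norm OLS, and
  a seeded 5-fold cross-validation protocol reporting

  ```
  RMSE = sqrt(1/N · Σ (y_i − ŷ_i)²)
  MAPE = 1/N · Σ |y_i − ŷ_i| / y_i          (a fraction)
  RPD  = SD(y) / RMSE                        (sample SD, N−1)
  ```

  as a cross-validated calibration triple plus a single-shot prediction
  triple.
- **Orthogonal grid** (`specfe.experiment`): all 5 × 10 combinations of
  pre-processor and selector evaluated against one shared split, with a
  best-frequency tally (per group and metric, which selector wins) and
  CSV/JSON reporting.
- **Stacking** (`specfe.stacking`): two base pipelines combined by an OLS
  meta-model trained on out-of-fold base predictions.
- **Synthetic data** (`specfe.synthetic`): a generator that emulates the
  statistical structure of such studies — 116 samples, SSC ≈ N(13.148,
  1.025²), low reflectance variance below 500 nm and high above 750 nm,
  planted SSC-informative absorption bands, scatter/drift/noise
  disturbances — with a ground-truth sidecar so selector recovery is
  testable.

## Worked example

```python
from specfe import (
    GeneratorConfig, PipelineSpec, compute_metrics, evaluate_pipeline,
    generate_dataset, spxy_split,
)
from specfe.stacking import DEFAULT_BASE_SPECS, stack_fit, stack_predict

dataset = generate_dataset(GeneratorConfig(seed=7))
split = spxy_split(dataset.reflectance, dataset.ssc, ratio="3:1")
print(f"calibration {split.cal_idx.size}, prediction {split.pred_idx.size}")

for spec in (PipelineSpec(select="none"), PipelineSpec(preprocess="sg", select="cars")):
    row = evaluate_pipeline(spec, dataset, split, seed=1)
    print(f"{spec.preprocess}-{spec.select}: n={row.n} "
          f"RMSE_c={row.rmse_c:.3f} RPD_c={row.rpd_c:.3f} "
          f"RMSE_p={row.rmse_p:.3f} MAPE_p={row.mape_p:.3f} RPD_p={row.rpd_p:.3f}")

Xc, yc = dataset.reflectance[split.cal_idx], dataset.ssc[split.cal_idx]
Xp, yp = dataset.reflectance[split.pred_idx], dataset.ssc[split.pred_idx]
model = stack_fit(DEFAULT_BASE_SPECS, Xc, yc, dataset.wavelengths, seed=1)
m = compute_metrics(yp, stack_predict(model, Xp))
print(f"stack(dc-cars, sg-cars): RMSE_p={m.rmse:.3f} MAPE_p={m.mape:.3f} RPD_p={m.rpd:.3f}")
```

Output:

```
calibration 87, prediction 29
none-none: n=None RMSE_c=0.968 RPD_c=1.039 RMSE_p=0.915 MAPE_p=0.058 RPD_p=0.637
sg-cars: n=12 RMSE_c=1.330 RPD_c=0.862 RMSE_p=0.855 MAPE_p=0.053 RPD_p=0.682
stack(dc-cars, sg-cars): RMSE_p=0.580 MAPE_p=0.034 RPD_p=1.006
```

The 3:1 SPXY split of 116 samples gives exactly 87 calibration and 29
prediction samples. The no-engineering baseline regresses SSC on all 221
wavelengths (minimum-norm OLS) and generalizes poorly (RPD_p 0.64, i.e.
worse than predicting the mean-level spread). The SG–CARS pipeline keeps 12
wavelengths; stacking it with the DC–CARS pipeline cuts prediction RMSE
from 0.855 to 0.580 % Brix. Prediction-set RPD values run low here because
SPXY concentrates the extreme samples in the calibration set, shrinking the
prediction set's SD.

The same workflow is available from a shell:

```bash
specfe simulate --out spectra.csv --truth truth.json --seed 7
specfe run-grid --spectra spectra.csv --out results/ --seed 1
specfe report --results results/ --out report/
specfe stack --spectra spectra.csv --bases dc-cars,sg-cars --out stack.json
```

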