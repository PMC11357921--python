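# ctrwdwi

Continuous-time random-walk (CTRW) modelling of multi-b-value
diffusion-weighted MRI (DWI), built for studies that grade tumours — the
reference use case is bladder urothelial carcinoma — from quantitative
diffusion parameters.

Conventional DWI summarises tissue with a single apparent diffusion
coefficient (ADC) from the mono-exponential model `S = S0 e^{-b·ADC}`.
Tumour tissue is heterogeneous and its signal decay is not
mono-exponential, especially at high b-values.  The CTRW model

S = S0 · E_α\[ −(bD)^β \]

describes the decay with three parameters: an anomalous diffusion
coefficient **D** (mm²/s, related to cellularity) and two heterogeneity
exponents, **α** (temporal) and **β** (spatial), both in (0, 1].
`E_α` is the Mittag-Leffler function `E_α(z) = Σ_k z^k / Γ(αk+1)`; at
α = β = 1 the model reduces to the mono-exponential with D = ADC.

The package provides, as library modules and a thin `ctrwdwi` CLI:

* `mittag_leffler` — a validated double-precision `E_α` evaluator
  (Taylor series + parabolic-contour Laplace inversion; abs. error
  ≤ 1e-12 on the model's domain) with an arbitrary-precision reference;
* `diffusion_models` — CTRW and mono-exponential forward models, and the
  two-point (b = 0/800 s/mm²) ADC;
* `model_fitting` — the segmented voxelwise fit (mono-exponential D from
  b ≤ 1000 s/mm², then α, β by bounded trust-region least squares with D
  fixed), producing D/α/β/ADC NIfTI maps with fit diagnostics;
* `synthetic_data` — phantoms with Rician noise and per-b excitation
  averaging, an enrollment funnel (107 screened → 81 analysable), and an
  81-lesion cohort whose group-wise parameter distributions are
  log-normals calibrated to published bladder-cancer medians/IQRs;
* `roi_analysis` — ROI means, two-reader averaging, interobserver
  ICC(2,1) with 95% CI and agreement bands;
* `group_stats` — normality-gated group tests, ROC with Youden operating
  points and DeLong CIs, paired DeLong AUC comparison, and logistic
  combination of markers (`run_study_analysis` orchestrates the whole
  grade/variant analysis).

See `docs/methods.md` for the model, numerical choices and the
emulation's fidelity limits.

## Worked example

Simulate a cohort of 81 lesions (15 low-grade / 66 high-grade, 30 with
variant histology) and run the grading analysis:

```
$ ctrwdwi simulate cohort --seed 7 --out demo/
wrote cohort of 81 lesions to demo/cohort.csv
$ ctrwdwi analyze --cohort demo/cohort.csv --contrast grade --out demo/report/
contrast  marker      auc   ci_low  ci_high   cutoff  sensitivity_pct  specificity_pct  accuracy_pct
   grade     adc 0.891919 0.823101 0.960738 1.101258            77.27           100.00         81.48
   grade       d 0.888889 0.793684 0.984094 1.357845            96.97            73.33         92.59
   grade   alpha 0.926263 0.857147 0.995379 0.846917            87.88            86.67         87.65
   grade    beta 0.504040 0.320070 0.688011 0.930681            89.39            26.67         77.78
   grade d+alpha 0.977778 0.951647 1.000000 1.258203            93.94            93.33         93.83
wrote report to demo/report
```

Each row is one marker's ability to separate high- from low-grade
lesions: `auc` is the area under the empirical ROC curve (with a DeLong
95% CI), `cutoff` the Youden-optimal threshold in the marker's units
(×10⁻³ mm²/s for ADC and D; lower values indicate high grade), and the
percentages are measured at that cutoff.  The pattern mirrors clinical
findings with this model: α discriminates grade best among single
parameters, β is at chance (its group medians nearly coincide), and the
logistic combination of D and α beats any single marker.
`demo/report/report.json` holds the full machine-readable report,
including group medians/IQRs, test p-values and the DeLong comparison of
the combined marker against ADC.

The same pipeline runs on images: `ctrwdwi simulate phantom` writes a
4-D DWI NIfTI plus b-table, and `ctrwdwi fit` produces the parameter
maps with a JSON sidecar of the fit configuration.

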