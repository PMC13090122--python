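# ppgage

**How much chronological age can a single photoplethysmography (PPG) pulse
actually predict?**

Consumer wearables have been claimed to estimate age from PPG to within ~3
years, yet the largest open cohort (UK Biobank finger PPG: one 100-sample
pulse per subject, ages 40–70) supports errors closer to 5–7 years — barely
better than predicting the mean age. `ppgage` packages everything needed to
study this *age-predictability ceiling* without any gated data download:

* a **calibrated synthetic cohort generator** whose extracted arterial
  stiffness index (ASI) distribution by age reproduces the published UK
  Biobank summary statistics (median 7.3 m/s at age 40, 8.4 at 50, 9.9 at
  70; Q3 of 8.8 m/s at age 40), with an explicit `signal_strength` dial for
  parameter-recovery experiments;
* **ASI extraction**: systolic / reflected peak detection and
  ASI = stature / Δt, where Δt is the peak-to-peak transit time;
* a **ladder of age predictors** in a statsmodels-style Model → `fit()` →
  Results API: mean baseline, univariate linear ASI model, penalized
  B-spline GAM, a learned-kernel (SMoLK-style) network and a small 1-D
  residual network (both pure NumPy, CPU-friendly, bit-reproducible);
* a shared **fivefold cross-validation harness** producing the mean ± SD
  MSE / MAE / Spearman-ρ comparison table;
* **morphology diagnostics**: cross-bucket similarity groups (near-identical
  pulses drawn from different 5-year age buckets) and per-bucket overlays;
* a **Bayes-error oracle** that computes the best achievable MAE from the
  generator's known conditional law — the floor every fitted model is
  judged against;
* an **embedding projection** (UMAP) with a scalar age-gradient score.

## The quantities at the core

For a pulse with systolic peak at time `t_s` and reflected peak at `t_r`,

```
ASI = stature / (t_r − t_s)        [m/s]
```

rises with vascular aging. The synthetic generator draws a latent true ASI
from a log-normal law whose median follows the piecewise-linear calibration
curve through (40, 7.3), (50, 8.4), (70, 9.9) m/s and whose log-scale SD
σ = ln(8.8/7.3)/0.6745 ≈ 0.277 reproduces the published within-age spread;
the pulse is rendered as two Gaussian bumps separated by
Δt = stature / ASI, rounded to the sample grid.

Because the within-age spread is large, the Bayes-optimal ASI→age predictor
achieves only ≈ 7.0 years MAE against ≈ 7.5 years for predicting the mean
of a uniform 40–70 cohort: the ceiling is low by construction, exactly the
pattern reported on the real cohort.

## Worked example

```python
import numpy as np
from ppgage import (CohortConfig, generate_cohort, extract_asi_table,
                    run_comparison, ModelSpec)

cfg = CohortConfig(n=5000, seed=0)            # default calibration
subjects, waveforms = generate_cohort(cfg)

table = extract_asi_table(waveforms, subjects)
print(np.median(table["asi"]).round(2))        # population ASI median

specs = [ModelSpec("mean_baseline", "mean"),
         ModelSpec("asi_linear", "linear"),
         ModelSpec("asi_gam", "gam")]
metrics = run_comparison(subjects, waveforms, specs, k=5, seed=0)
print(metrics.summary())
```

Output:

```
8.67
Model                 MSE (years²)     MAE (years)    Spearman ρ
----------------------------------------------------------------
mean_baseline         75.68 ± 1.49     7.54 ± 0.11           N/A
asi_linear            70.42 ± 1.77     7.19 ± 0.13   0.28 ± 0.03
asi_gam               69.98 ± 2.14     7.15 ± 0.15   0.28 ± 0.03
(ASI extraction attrition: 0 of 5000 waveforms rejected)
```

The ASI-only models beat the mean baseline by well under half a year of MAE
while still showing a clearly positive rank correlation — age is *present*
in the pulse but cannot be pinned down: the predictability ceiling. The
mean-baseline row reports Spearman ρ as `N/A` because a constant prediction
vector has no rank ordering.

The same analysis runs end-to-end from the shell:

```
ppgage pipeline --config config.yaml --out runs/exp1
```

writing the cohort, ASI table, metrics tables, cross-bucket similarity
groups, the 2-D projection, and a manifest with seeds, config hash and
per-stage timing.

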