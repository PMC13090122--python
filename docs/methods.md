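# Methods

This note documents the models and procedures implemented in `ppgage`, the
assumptions behind them, the parameters that matter, and what the synthetic
experiments do and do not show about real single-pulse PPG cohorts.

## 1. The synthetic cohort generator

### What it emulates

The generator mimics the structure of the largest open single-pulse PPG
resource: one stabilized pulse of 100 samples per subject, subjects aged
40–70, with stature and sex on record. Its calibration targets are the
published summary statistics of the arterial stiffness index (ASI) in that
cohort: medians of 7.3, 8.4 and 9.9 m/s at ages 40, 50 and 70, and a third
quartile of 8.8 m/s at age 40.

### The latent model

For a subject of age *a*:

1. **Median curve.** `median_asi_curve(a)` interpolates piecewise-linearly
   through the anchors (40, 7.3), (50, 8.4), (70, 9.9) m/s. No functional
   form beyond the printed medians is assumed, so interpolation is the
   least-committal choice; ages outside the anchor range are a hard error
   rather than an extrapolation.
2. **True ASI.** `true_asi ~ LogNormal(ln median(a), σ)` with
   σ = ln(8.8/7.3)/0.6745 ≈ 0.277, the unique log-scale SD for which the
   age-40 Q3/median ratio matches 8.8 vs 7.3. A log-normal is the natural
   positive, right-skewed family for a ratio quantity; with one printed
   quartile there is nothing to fit a heavier-tailed law to.
3. **Transit time.** `true_dt = stature / true_asi` (seconds), with stature
   drawn from sex-specific normal laws (female 1.62 ± 0.06 m, male
   1.76 ± 0.07 m — conventional anthropometric values, configurable).
4. **Waveform.** Two Gaussian bumps on a 1-s, 100-sample grid: a systolic
   bump (peak fixed at 0.15 s) and a reflected bump whose centre lags it by
   `true_dt` rounded to the nearest sample. The noiseless sum is min-max
   normalized to [0, 1] (the systolic peak is the global maximum by
   construction), then white Gaussian noise of SD `noise_sd` (default 0.02)
   is added.

`signal_strength ∈ [0, 1]` blends the age-specific median toward the
mid-range median: at 1 the calibration holds exactly; at 0 the ASI law is
identical at every age, so any model's apparent skill on such a cohort is
overfitting. This dial exists purely for parameter-recovery and null tests.

### Morphology classes

Each subject carries a class label that selects bump widths and the
reflected amplitude from a fixed one-parameter family (systolic width
0.018–0.024 s, reflected width 0.036–0.042 s, reflected amplitude
0.42–0.38). Classes never perturb peak *timing*, so pulse shape is
age-orthogonal by construction: two subjects with the same class, lag and
stature produce identical noiseless waveforms regardless of age. This is
what produces the cohort's signature pattern — large morphological variance
within an age group and near-identical pulses across distant ages.

The family endpoints were chosen so that at every renderable lag the
reflected peak remains a local maximum with at least four times the
detector's 1% prominence threshold. This is a co-design constraint: the
generator must, by construction, satisfy the round-trip guarantee that
noise-free extraction recovers the true ASI to within one sample of lag
discretization for *every* subject.

### Feasibility and its cost

Lags below 9 samples (merged bumps) or beyond the pulse window cannot be
rendered; such subjects have their ASI redrawn. Under default calibration
this truncates roughly the top 1% of the ASI law at age 70 and shifts that
median down by ~0.5%; all calibration checks pass within their 2%
Monte-Carlo tolerance with this effect included.

### The deterministic (parameter-recovery) regime

`CohortConfig.deterministic(n, seed)` switches off every source of
dispersion: ASI spread (σ = 0), additive noise, and stature (fixed at the
1.69 m mid-sex reference). Only then does age fully determine the lag and
hence the waveform. This is deliberate: with stochastic stature, the lag
carries an irreducible ~5.7% log-dispersion that no waveform-only model can
remove (a Bayes floor of roughly 4 years MAE), so recovery experiments that
expect near-exact inversion must use the fully degenerate configuration.
In this regime the only information loss is the one-sample rounding of the
lag — about 7 distinct lags span ages 40–70 — which caps recovery accuracy
at roughly 1–1.5 years MAE.

## 2. ASI extraction

The systolic peak is the earliest global maximum. The reflected peak is the
most prominent local maximum strictly after it (SciPy peak finding,
prominence ≥ 1% of the amplitude range). If no candidate qualifies, the
detector falls back to the *inflection shoulder*: the most concave-down
point (minimum of the second difference) of the post-systolic decay,
searched only after the curvature first turns convex so the systolic bump's
own core cannot capture it; such pulses are flagged `shoulder_fallback`.
Flat signals, or decays with no concave structure, are `rejected` — counted
in an attrition log and excluded from downstream ASI analyses, never
silently dropped.

ASI = stature / ((reflected − systolic) × dt_sample). No sub-sample
interpolation is applied by default (`refine=True` enables parabolic
refinement of the lag); quartiles use linear interpolation between order
statistics. The per-age-bucket summary removes values outside
[Q1 − 3·IQR, Q3 + 3·IQR] (bounds computed on the raw values) and reports
quartiles of the retained values plus the retained count. On continuous
unimodal data this removal is idempotent; the tests check that property on
log-normal draws shaped like the ASI law.

## 3. Age predictors

All predictors follow a Model → `fit()` → Results pattern; prediction is a
pure function of the fitted parameters.

* **Mean baseline** — predicts the training-fold mean age everywhere. Its
  fold MAE (≈ 7.5 years for uniform ages on 40–70) is the no-skill level.
* **Linear ASI model** — ordinary least squares of age on ASI
  (statsmodels OLS; coefficient standard errors carried in the results).
* **Spline GAM** — penalized cubic B-spline of age on ASI: 20 knots at
  training-ASI quantiles, curvature penalty ∫ s″(x)² dx evaluated on a fine
  grid, smoothing weight chosen by generalized cross-validation
  (n·RSS/(n − edf)²) over a log-spaced grid spanning 1e−3 to 1e8. The
  penalty's null space is exactly the straight lines, so the infinite-
  penalty limit reproduces the OLS fit (verified to 1e−9); predictions
  outside the training ASI range extrapolate as constants.
* **SMoLK-style network** — 32 learnable kernels of lengths {8, 16, 32}
  (split evenly), ReLU, global average pooling per kernel, linear head.
  Each pooled feature is one kernel's mean activation over the pulse, so
  the kernels are directly inspectable templates.
* **ResNet-style network** — a 1-D conv stem (16 channels, kernel 7), four
  residual blocks (conv-ReLU-conv + identity, kernel 5), global average
  pooling, linear head.

Both networks are implemented directly in NumPy with hand-written
reverse-mode gradients, checked against central finite differences. The
input stage standardizes each pulse to zero mean and unit variance, making
predictions invariant to positive amplitude rescaling; targets are
standardized internally for conditioning. Training uses Adam (lr 3e−3,
batch 64), squared-error loss, and early stopping (patience 15) on a 10%
tuning split carved from the training fold — never the validation fold.
All randomness (init, shuffling, splits) flows from one integer seed, so
training is bit-reproducible on a single machine. These are small-scale
architectures sized to 100-sample inputs; every width, depth and training
knob is exposed in the config objects.

## 4. Cross-validation harness

Subjects are shuffled once per seed and dealt round-robin into k folds
(sizes differ by at most one); every model sees the identical assignment,
so rows of the comparison table differ only by model. Per-(model, fold)
seeds derive from the global seed and a stable hash of the model
specification — two registered copies of the same specification produce
identical rows. Metrics are MSE, MAE and Spearman's ρ (average ranks for
ties); a constant prediction vector has undefined ρ, reported as N/A rather
than zero. Aggregates are the mean and sample (n−1) SD over folds. Models
are compared on the subjects whose ASI extraction was accepted, so all
models share one subject set; the attrition count is attached to the table.
No stratification by age is applied by default.

## 5. The Bayes-error oracle

Because the generator's conditional law of ASI given age is known in closed
form, the Bayes-optimal MAE of any ASI-based predictor is computable: the
posterior median of age given ASI under the cohort's age prior, evaluated
by quadrature on an age grid and averaged over Monte-Carlo draws that share
random numbers across configurations (so the floor is monotone in σ by
construction, a property the tests check). At the calibrated σ = 0.277 the
floor is ≈ 7.05 years against ≈ 7.5 for the mean baseline: even a perfect
ASI model can only be ~6% better than no model at all. Fitted models are
required to sit *above* this floor — a model that beat it would be evidence
of leakage, not skill. Note the fitted GAM approaches the floor closely, so
its lift over the mean baseline (~5%) runs near the boundary of the "only
slightly better than the mean" band used in the acceptance checks.

## 6. Morphology similarity and projection

Waveforms are min-max normalized and compared by Euclidean distance, making
every morphology analysis amplitude-invariant. Cross-bucket groups (one
member per 5-year age bucket, minimal mean pairwise distance) are found by
a greedy seed-and-extend search — every waveform seeds a candidate built
from its nearest neighbour in each other bucket — followed by coordinate-
descent refinement; selected groups must be mutually dissimilar (mean
inter-group distance > 2× their intra-group spread, configurable). An
exhaustive search over all one-per-bucket combinations serves as the
reference on small instances (≤ 30 waveforms), where the refined greedy
search matches it on every tested instance.

Network embeddings (the pooled pre-head representation) are projected to
2-D with UMAP at fixed seed; duplicate embedding rows are collapsed before
fitting and share coordinates afterwards, so the projection is a function
of the embedding. The `age_gradient_score` — the larger |Spearman ρ|
between either projected axis and age — summarizes whether age dominates
the representation (1 = one axis orders subjects by age; ≈ 0 = no monotone
gradient).

## 7. Problem sizes used in the checks

The shipped tests and the acceptance script use cohorts of 300–20,000
subjects: 10,000 per fixed-age calibration cohort (Monte-Carlo tolerance
2%), 2,000 for the deterministic parameter-recovery run, 20,000 for the
ceiling-pattern comparison, and 4,000 for the no-signal null. These sizes
put Monte-Carlo error comfortably inside each check's tolerance while
keeping a full run to a few minutes on one CPU core.

## 8. What passing tests do and do not show

The generator reproduces the *published summary statistics* of the real
cohort — medians, one quartile, the 100-sample format, and the qualitative
morphology structure. It does not attempt hemodynamic realism: no dicrotic
notch physiology, respiration, motion artifacts, beat-to-beat variability,
heavy-tailed measurement error, or site (finger vs wrist) effects; the
real cohort's age distribution is not uniform; and real within-age ASI
dispersion mixes measurement noise with genuine physiological covariates
(lifestyle, comorbidity) that the log-normal law collapses into one term.
Consequently, passing tests show that the *pipeline* — extraction, models,
harness, diagnostics — behaves correctly and that the ceiling pattern
follows from the published dispersion; they do not certify performance
numbers on real PPG. The published cross-validated results from the gated
cohort are carried in `ppgage.reference` as annotations for orientation,
not as targets this package can or does reproduce.

## 9. Known limitations

* Lag discretization (100 samples/s) injects a 1–3% multiplicative error
  into every extracted ASI; at fixed age this slightly biases medians
  (≲ 1%, inside calibration tolerance).
* The greedy group search is a heuristic; its optimality is verified only
  on small instances against exhaustive search.
* The record importer supports single-channel format-16 header/signal
  pairs only — a minimal bridge, not a general waveform-database client.
* GAM smoothing is selected by GCV on a fixed grid; no uncertainty is
  propagated from the smoothing choice.
* The networks are deliberately small; they are not tuned for, and should
  not be read as upper bounds on, real-data performance.
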