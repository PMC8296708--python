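# myoshift

Quantitative analysis toolkit for preclinical muscular-dystrophy efficacy
studies: it answers the question *"did the treatment change the myofiber
size distribution additively or multiplicatively, and by how much?"* and
carries the surrounding study arithmetic — tissue pharmacokinetics,
histopathology scoring and functional-test metrics — in one tested package.
It is aimed at researchers analysing dystrophic mouse models (*mdx*,
D2.B10) where muscle morphometry, drug exposure and strength/endurance
readouts are collected together.

## The distribution-shift model

Fiber cross-sectional areas (CSA, μm²) are pooled per group and muscle and
summarised by their nine interior deciles. Treated deciles are regressed on
control deciles on two scales:

- natural: `CSA_treated = b · CSA_control + a`
- log10:   `log(CSA_treated) = a + b · log(CSA_control)`

If the slope *b* is compatible with 1 (two-sided t-test, n−2 df) while the
intercept *a* differs from 0, the treatment acts as a pure location shift on
that scale: an **additive** effect `CSA_treated = CSA_control + S` on the
natural scale, or a **multiplicative** effect `CSA_treated = K · CSA_control`
with `K = 10^a` on the log scale. The shift parameter is then estimated by
minimising the sum of squared differences (SSQ) between the observed treated
quantiles and the transformed control quantiles,

```
SSQ(θ) = Σ_p [ Q_treated(p) − T_θ(Q_control(p)) ]²,   T_θ = (+S) or (×K),
```

with a bounded 1-D scalar minimiser. Under a multiplicative effect the
treated quantile function is exactly `K` times the control one, so the
noise-free optimum is exact.

Around this core the package provides:

- **synthetic data** — lognormal fiber-CSA pairs with known S or K,
  one-compartment oral PK curves, histology fixtures with an exact
  fibrosis-red pixel fraction, grip and treadmill study tables;
- **pharmacokinetics** — Cmax/Tmax/AUC (linear trapezoid) on mean curves,
  residual-blood correction of muscle-homogenate concentrations to ng/g,
  matrix-to-matrix AUC ratios, dose-response tables;
- **histopathology** — Sirius-Red fibrosis % by HSV pixel classification,
  centralized-nuclei percentages, weighted severity score
  (Σ severity × extension over five lesion parameters);
- **functional tests** — body-weight-normalized grip strength (FNmax, best
  of 5 trials), treadmill distance under the 5 m/min + 1 m/min-per-minute
  exhaustion ramp with shock-cap censoring, drinking-water dose estimation;
- **pipeline** — an end-to-end synthetic study (`run_study`) plus one-way
  ANOVA with Bonferroni pairwise tests and two-factor ANOVA.

## Worked example

```python
from myoshift import CSAGenConfig, gen_csa_samples, analyze_pair

cfg = CSAGenConfig(
    n_fibers=500, median_um2=500, sigma_log=0.5,
    effect_kind="multiplicative", effect_value=1.72,   # ground truth K
    noise_frac=0.05, seed=7,
)
control, treated = gen_csa_samples(cfg)
report = analyze_pair(control, treated)
fit = report.fit_log10
print(f"log10 fit : slope={fit.slope:.3f} (p vs 1: {fit.p_slope_vs_1:.3f}), "
      f"intercept={fit.intercept:.4f} (p vs 0: {fit.p_intercept_vs_0:.2e})")
print(f"selected  : {report.model}")
print(f"K-hat     : {report.estimate.parameter:.3f}  (SSQ={report.estimate.ssq:.1f})")
```

prints

```
log10 fit : slope=0.961 (p vs 1: 0.082), intercept=0.3607 (p vs 0: 1.97e-04)
selected  : multiplicative
K-hat     : 1.792  (SSQ=3374.9)
```

The log-scale slope is statistically compatible with 1 and the intercept is
clearly non-zero, so the multiplicative model is selected; the SSQ estimate
K̂ = 1.79 recovers the generating factor 1.72 within the sampling noise of
two independent 500-fiber draws (the naive back-transform `10^intercept`
would overshoot here because the slope absorbed part of the shape
variability — the SSQ step is what makes the estimate stable).

A shell entry point mirrors the library
(`myoshift csa|pk|histol|functional|run|simulate`), e.g.

```sh
myoshift simulate --seed 1 --out sim/
myoshift csa --control sim/fibers.tsv --treated sim/fibers.tsv --out report.json
```

## Layout

```
src/myoshift/
  synthetic.py          study-data generators (all inputs, seeded)
  csa_shift.py          decile Q-Q regression + SSQ shift estimation
  pharmacokinetics.py   NCA, residual-blood correction, AUC ratios
  histopathology.py     fibrosis %, centralized nuclei, severity score
  functional_tests.py   FNmax, treadmill ramp distance, water dosing
  pipeline.py           run_study orchestration + ANOVA statistics
  cli.py                thin click CLI over the above
```

See `docs/methods.md` for the statistical model, parameter defaults and
known limitations.
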