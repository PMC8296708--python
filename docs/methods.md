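# Methods

## The CSA distribution-shift model

Muscle regeneration and atrophy reshape the distribution of myofiber
cross-sectional areas (CSA) rather than shifting a single mean, so the
package compares the *whole* treated and control distributions through
their quantiles. Fibers from all animals of a group are pooled (the
per-mouse annotation workflow contributes ~100 fibers per muscle per
animal); a per-mouse stratification is available but not the default.

**Quantile convention.** All quantiles use linear interpolation between
order statistics with fractional rank h = (n − 1)p + 1 (numpy's `linear`
method). The regression and the SSQ objective default to the nine interior
deciles p = 0.1 … 0.9; any strictly increasing grid in (0, 1) can be
passed, e.g. percentiles 0.01 … 0.99.

**Dual-scale Q-Q regression.** Treated deciles are regressed on control
deciles by ordinary least squares on the natural scale and after a log10
transform. The two hypotheses per scale are H0: b = 1 (shape unchanged) and
H0: a = 0 (no shift), tested with two-sided t statistics on n_points − 2
degrees of freedom. log10 is used throughout the log model so that the
back-transform of the intercept is K = 10^a. When the regression residuals
are numerically zero (exactly transformed data) the standard errors are
zero; the t statistic is then defined as 0 (p = 1) when the estimate equals
the null and ±∞ (p = 0) otherwise, which keeps the noise-free cases exact.

**Model selection.** A shift model is *admissible* on a scale when
p(slope vs 1) > α and p(intercept vs 0) ≤ α (α = 0.05 by default). Natural
admissibility nominates the additive model, log admissibility the
multiplicative one; when both are admissible the family with the lower
minimised SSQ wins. The default (unforced) rule returns "none" when neither
scale is admissible. A `force=True` mode always attributes a family by
lower SSQ; it is intended for data where a shift is known or assumed to
exist and only its form is in question.

*A calibration caveat that shaped this design:* the slope t-test treats the
nine decile points as independent observations, but empirical quantile
errors are strongly correlated (Brownian-bridge-like), so the naive OLS
standard error understates the slope's true sampling variability. With two
*independent* lognormal samples the empirical log-scale Q-Q slope is
essentially the ratio of the two sample log-SDs (SD ≈ 0.055 at n = 500,
σ_log = 0.5), and the test declares this ordinary sampling variability a
significant shape change in roughly 40% of replicates — at any n, because
both the deviation and the naive SE scale as 1/√n. The unforced rule is
therefore conservative (it reports "none" in a substantial minority of
replicates even when a clean shift is present), while the SSQ *estimate* of
S or K is unaffected and recovers the truth with <3% bias at the default
simulation settings. Monte-Carlo characterisation (seeded, reproduced in
the test suite): with a true K = 1.72 the forced attribution picks the
multiplicative family in 500/500 replicates; with a true S = 140 μm² on a
median-700 μm² lognormal it picks additive in ~91% — the remainder are
genuinely well-approximated by K ≈ 1.2 on that draw, an identifiability
limit of the additive-vs-multiplicative question itself when S is a modest
fraction of the median.

**SSQ estimation.** Given a family, the parameter minimises
SSQ(θ) = Σ_p [Q_t(p) − T_θ(Q_c(p))]² over the quantile grid, with T_θ the
shift (+S) or scaling (×K) map. A bounded scalar minimiser (Brent /
golden-section) is used with S ∈ [−max(control), +max(treated)],
K ∈ [0.1, 10], parameter tolerance 1e−8, iteration budget 200. Both
objectives are quadratic in θ, so the bounded minimiser is exact to
tolerance; tests cross-check against dense grid searches and, for the
multiplicative family, against 10^intercept on noise-free pairs. Quantile
vectors — not binned histograms — enter the objective: they are monotone,
binning-free, and make the noise-free optimum exactly zero.

## Synthetic data

The generators emulate the statistical structure the analyses assume, not
the underlying biology (no degeneration/regeneration dynamics, no TGF-β
signalling).

- **Fiber CSA**: lognormal, parameterised by median (μm²) and log-scale SD;
  positivity and the peaked right-skewed shape of real fiber-size
  histograms motivate the family. Defaults: n = 500 fibers/arm (≈100 fibers
  × 5 mice), median 500 μm² (gastrocnemius-like; 700 μm² is the
  tibialis-anterior-like setting), σ_log = 0.5, which spans roughly
  180–1400 μm² between the 1st and 9th deciles — the range seen in adult
  dystrophic hindlimb muscle. Treatment effects are applied to an
  independent re-draw of the control law (separate animals); a paired mode
  reuses the control draw and exists for exact-recovery tests. Measurement
  noise multiplies each treated fiber by (1 + N(0, noise_frac)); 5% is the
  default regime. An optional between-mouse lognormal random effect
  (`mouse_sd_log`) exposes the within/between variance split; it defaults
  to 0 because no empirical decomposition is available to calibrate it.
- **PK**: one-compartment first-order-absorption curves
  C(t) = D·ka/(V/F·(ka−ke))·(e^{−ke·t} − e^{−ka·t}), sampled on the
  0.5–6 h grid; defaults ka = 2 h⁻¹, ke = 0.5 h⁻¹, V/F = 5 L/kg give a
  Tmax near 1 h and full decay within the sampling window. Noise is
  multiplicative lognormal with unit mean (assay CV is relative and
  concentrations stay positive); ka = ke is rejected rather than
  special-cased.
- **Histology fixtures**: exactly `round(red_fraction · W · H)` pixels of a
  fixed fibrosis-red RGB triplet (178, 34, 52) on a pale eosin-like
  background (235, 220, 225), placed uniformly at random. The exact triplet
  makes fixture arithmetic bit-exact; it is not a stain model.
- **Grip/treadmill**: mean force rises linearly to a peak week (default
  week 3, +15%) then declines exponentially (3%/week), mimicking the
  early-gain-then-decline course of dystrophic mice qualitatively — no
  quantitative fidelity to any particular study is claimed. Five lognormal
  trials per mouse-week (CV 10%) and a linear body-weight trend. Treadmill
  exhaustion times are lognormal (CV 25%, mean 12 min vehicle); shocks
  accrue as a Poisson process (10/min) and a session reaching the cap
  (600 or 150, when enabled) is truncated at the cap's expected arrival
  time and flagged `capped`.

Passing tests on these generators show the *procedures* are correct under
the assumed shapes; they do not validate the lognormal family, the
variance structure, or the noise model against real sections, assays or
force transducers.

## Pharmacokinetics

NCA is deliberately minimal, matching an analysis of mean curves to the
last observed sample: Cmax/Tmax are the observed maximum (earliest time on
ties) and AUC0–tlast is the linear trapezoid with no λz extrapolation and
no log-linear segments. A (0,0) anchor is prepended only on request. The
residual-blood correction converts homogenate concentration to tissue
ng/g:

```
tissue = (C_homog · dilution · m − C_blood · v_res · m) / m
```

with dilution = 10 mL/g (from 1:10 w/v homogenisation; buffer volume only,
tissue volume ignored) and v_res the residual blood volume per gram of
muscle. No consensus value for v_res exists in this package's scope; the
default 0.01 mL/g is a literature-scale placeholder and should be set
explicitly. Negative corrected values clamp to zero with a `clamped` flag.

## Histopathology

Fibrosis is the percentage of pixels classified red in HSV space (hue
≥ 0.92 or ≤ 0.08, saturation ≥ 0.30), relative to the full image by
default or to a luminance-masked tissue area on request; real Sirius-Red
colour deconvolution is out of scope. Per-muscle fibrosis averages 1–3
field values. The severity score combines five lesion parameters
(degeneration/necrosis, regeneration, inflammatory infiltrate, interstitial
reaction, adipose deposition), each graded severity 1–3 and extension 1–3.
The grading scales are standard; the combination operator is a package
convention: **score = Σ severity × extension**, chosen because it is the
common weighted-histopathology practice and is monotone in both axes
(maximum 45). Absent findings contribute 0. Group MTS is the mean of
animal scores.

## Functional tests

FNmax = max of the 5 trial forces / body weight (force units per gram;
unit-agnostic). The treadmill ramp runs 5 m/min for 5 min, then the speed
during minute n > 5 is 5 + (n − 5) m/min; speed changes at integer minutes
and a partial final minute is prorated linearly (sub-minute behaviour is a
convention — the protocol defines speeds only per whole minute). Distance
is therefore continuous, piecewise linear and strictly increasing.
Cap-truncated treadmill sessions are censored observations; group summaries
include them with an `n_capped` count by default, or drop them on request.
Drinking-water dosing: dose [mg/kg/day] = concentration [mg/mL] × intake
[mL/day] / BW [kg], with 4 mL/mouse/day the customary intake estimate.

## Routine statistics

One-way ANOVA (scipy) with pairwise two-sample t-tests, Bonferroni-adjusted
by the family size; the default family is every group versus the control
(all-pairs optional). The two-factor ANOVA is the plain fixed-effects
type-II decomposition (statsmodels); repeated-measures structure over time
is *not* modelled, which will overstate residual df for longitudinal
readouts — a deliberate simplification. A single-level second factor
degenerates to the one-way model.

## Problem sizes and reproducibility

Every stochastic routine takes an explicit integer seed; the pipeline
derives per-stage seeds from the study seed via `SeedSequence`, making the
full report bundle byte-reproducible. The package's own simulation studies
use 20 replicates for parameter recovery (n = 500 fibers/arm), 200–500
replicates for calibration and selection-rate Monte-Carlos, and 600-point
grids for AUC convergence checks — sizes at which all reported quantities
are stable to well within their tolerance bands while the full suite runs
in seconds.

## Known limitations

- No mixed-effects modelling of mouse-level clustering and no bootstrap
  confidence intervals for S/K.
- The unforced model-selection rule inherits the miscalibrated slope test
  described above; treat "none" under independent sampling as "no
  *detectable* shift under a conservative rule", not as evidence of
  absence.
- Additive vs multiplicative attribution is weakly identified when
  S ≪ median (a small shift resembles a factor near 1).
- NCA on mean curves ignores between-animal variability in exposure.
- The severity-score operator and the residual-blood volume are documented
  conventions, not measured quantities.
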