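# Methods

This note documents the model equations, the numerical and design choices
behind them, what the synthetic-data generator does and does not emulate,
and the known limitations of the package.

## Thermal submodels

**Development.** Median development time per immature stage (egg, nymph,
puparium) follows the Janisch catenary in rate form,
`r(T) = [(D_min/2)(e^{k(T−T_opt)} + e^{−k(T−T_opt)})]^{-1}` (1/day).
Packaged constants (D_min days, T_opt °C, k 1/°C): egg (4.98, 27.4, 0.15),
nymph (9.94, 25.4, 0.11), puparium (3.46, 23.0, 0.24). Rates are floored
at 1e−9/day so reciprocal times stay finite at extreme temperatures.
Degree-day summaries (lower threshold `T0 = −intercept/slope`, thermal
constant `K = 1/slope`) come from ordinary least squares of rate on
temperature after discarding points at or above 28 °C, where the rate
curve bends down; the linear model is provided for comparison only, the
simulator always uses the nonlinear curve.

**Immature mortality.** The published algebra of the mortality curve is
typographically garbled in its source table; the form implemented here,

```
m_i(T) = 1 − exp(−H_i (1 + e^{−(T−T_opt)/B_i}) (1 + e^{(T−T_opt)/B_i})),
```

was chosen because, with the published stage constants, it reproduces the
observed egg mortalities at both temperature extremes (0.84 vs 0.87 at
10 °C, 0.27 vs 0.24 at 32 °C) and the pupal minimum (≈0.07), whereas
literal readings of the printed expression evaluate near 1 at the optimum.
The literal ratio reading remains available via
`immature_mortality(..., form="literal")` for comparison. The curve is
symmetric around a single optimum (21.8 °C, shared across stages),
has minimum `1 − e^{−4H}` there, and is clipped to [0, 1]. Joint refitting
of the three stages with a shared optimum on the published mortalities
yields 21.4 °C — 0.4 °C below the published 21.8 °C, a residual we attribute
to the unrecoverable original algebra; no reweighting was applied to force
agreement.

**Adult timing.** Median oviposition time is `1/(intercept · e^{slope·T})`
(intercept 0.068 1/day, slope 0.0405 1/°C); female and male survival
medians multiply this baseline by `e^{factor}` (factors −0.0106 and
−0.3615 on log time), so the male/female ratio is constant in temperature
and males live ≈25 % shorter, while female survival and oviposition time
are statistically indistinguishable — females lay throughout life.

**Fecundity.** Mean lifetime fecundity is parameterized on the
`ln(1+eggs)` scale,

```
ln(1 + F(T)) = H / [(1 + e^{−(T−Tl)/Bl})(1 + e^{−(Tl−T)/Bh})],
```

an asymmetric unimodal curve with peak near 20 °C. The `ln(1+·)` transform
(the same one used for the variance-stabilized analysis of the raw egg
counts) makes fecundity approach zero, not one, at temperature extremes.
Because the published constants for this curve are also corrupted, the
packaged values (H 8.925, Tl 14.69 °C, Bl 1.63 °C, Bh 19.75 °C) are a
least-squares refit to the five published mean fecundities
(15→10.3, 18→36.4, 20→40.1, 25→26.9, 28→19.2 eggs/female), which the
family fits with R² = 99.98 % on the fitted scale. The hot flank is only
weakly constrained by data ending at 28 °C and declines gently; population
growth above ~32 °C is limited by mortality, not by the fecundity curve.

**Fluctuating-temperature adjustment.** Constant-temperature rearing
understates vitality under natural fluctuation. `apply_adjustment` widens
each stage's mortality window (B ×1.3), doubles adult survival and
oviposition medians (intercept halved), and quadruples fecundity
(multiplier ×4), returning a new bundle and leaving the original intact.
These factors are empirical calibration constants carried in the bundle,
not re-estimated by this package.

## Distribution links and AFT fitting

Between-individual variation in every event time is a two-parameter
distribution in normalized age `x = t / median`: log-logistic
`F(x)=1−1/(1+x^α)`, Weibull `F(x)=1−e^{−ln2·x^α}`, or lognormal
`F(x)=Φ(ln x/δ)`, with `α=1/δ`. All three are median-normalized so
`F(1)=0.5` exactly; the `ln 2` factor in the Weibull enforces this (the
published convention states it only for the log-logistic). Packaged
scales: egg 0.044 and nymph 0.072 (log-logistic), puparium 0.298
(Weibull), adult survival 0.9271 and oviposition 0.7741 (lognormal).

`fit_aft` maximizes the interval-censored likelihood
`Σ ln[F(u/med_g) − F(l/med_g)]` over per-group log-medians, an optional
additive sex coefficient, and one common log-scale, using Nelder–Mead
followed by BFGS polish (tolerance 1e−10 on the log-likelihood) from
interval-midpoint starting values. Right-censored records enter with
`upper = ∞`. The deviance table compares intercept-only, per-group and
saturated models, the last being the multinomial over distinct observed
intervals within each group; the heterogeneity factor `H = deviance/df`
(df = saturated cells − model parameters, floored at 1) inflates the
t-based confidence limits of the medians — the df for the t quantile is
that same residual df, a choice the source leaves open. Family selection
is by maximum likelihood across the three candidates. Standard errors come
from the finite-difference observed information.

## Cohort simulation

Rate summation uses the native series step (hourly for sinusoidal or
logged series, daily allowed for constant) with piecewise-constant rates
and linear interpolation inside the final step, so constant-temperature
results equal the closed forms to floating-point accuracy. The sinusoidal
constructor is `T(t) = mean − A·cos(2πt/24)`, hitting mean±A exactly.

Per individual: sex is a uniform draw against the 0.5 sex ratio (no
temperature dependence); each immature stage draws a development quantile
`x* = Q(u)` of its link and completes when accumulated normalized age
reaches `x*`; a single uniform per stage kills the individual when the
accumulated mortality `1 − Π(1−m(T))^{Δx}` exceeds it, with
`Δx = r(T)Δt/x*` the fraction of the stage completed in the step — the
unique per-step form that reduces exactly to `m(T)` for a constant-
temperature stage. Mortality is capped just below 1 so its logarithm stays
finite.

Females draw a lifetime fecundity from a lognormal with mean
`F̄(T̄)` — T̄ the mean series temperature over the female's adult span
(a documented choice; emergence-day temperature differs only under strong
trends) — and log-scale spread equal to the fecundity fit's residual
standard error (0.016), the stochastic component the simulation recipe
prescribes; a lognormal respects non-negativity and the right skew of
observed egg counts. Each female's oviposition *period* is itself an AFT
event time: she draws an oviposition quantile and lays her lifetime total
across her own window following the normalized cumulative reproduction
curve, truncated by death. The alternative reading — population-level
ΔCDF increments truncated at the drawn window — leaves part of the drawn
total unlaid even for surviving females and depresses the finite rate of
increase at the 24 °C optimum to 1.12 (vs the published ≈1.14); the
rescaled-window reading reproduces both the published rate (we obtain
≈1.16) and doubling time (≈4.7 vs 5 d), and is the one implemented.
Fecundity is drawn once per female, not redrawn daily.

Schedules use daily age classes over the initial *female* egg cohort:
`l_x` is the fraction of females alive at the start of age class x, `m_x`
the eggs laid per living female that day times the 0.5 sex ratio.
Replicates pool by summing alive counts and egg counts before dividing.
All randomness flows from one seeded `numpy` generator; identical seeds
give bit-identical cohorts.

## Life-table statistics

`R0 = Σ l_x m_x`, `GRR = Σ m_x`. The Euler–Lotka rate solves
`Σ e^{−r(x+0.5)} l_x m_x = 1` by bracketed Brent root-finding (residual
< 1e−10); the approximate method uses `T = Σ(x+0.5) l_x m_x / R0` and
`r = ln R0 / T`. The half-day shift places reproduction at class
midpoints in both methods — the consistent discretization for daily
classes. `λ = e^r` and `Dt = ln2/r` hold to machine precision by
construction; `R0 = 0` reports `r = −∞`, `λ = 0`, `Dt = ∞` rather than
failing. Observed-versus-simulated comparisons use
`z = (obs − mean_sim)/sd_sim` with a two-sided p from the t-distribution
on (replicates − 1) df; with the typical 4 replicates these p-values are
indicative, not exact.

## Synthetic cohorts

`generate_synthetic_cohort` emulates the rearing design behind the
calibration data: a fixed number of eggs per constant temperature observed
daily (so every event is interval-censored to consecutive checks),
binomial stage attrition at the model mortality, sexed adults with
right-censoring past the follow-up horizon, and per-female lifetime egg
counts. It does **not** emulate observation error in sexing or egg counts,
host-plant or humidity effects, within-chamber temperature drift, or
between-cohort heterogeneity beyond the model's own stochasticity — so
recovery tests demonstrate internal consistency of the estimators
(generate → fit returns the generating parameters), not robustness to
real-data artifacts.

## Problem sizes used in the test and acceptance runs

Calibration targets use the published summaries directly (7 egg medians,
19 mortality points, 5 fecundity means). Simulation-based checks use
4 × 100 individuals at constant 24 °C (the published validation design),
1,500–2,000 individuals where distributional convergence is asserted, and
20–50 replicates for model-selection frequency checks.

## Known limitations

- Temperature is the only driver; no host plant, humidity, photoperiod,
  density dependence, parasitism or migration.
- Single-cohort life tables; multi-generation dynamics are left to
  composition by the user.
- The mortality and fecundity equations are reconstructions of corrupted
  published algebra; the shared mortality optimum refit lands at 21.4 °C
  versus the published 21.8 °C.
- The published egg degree-day threshold (6.9 °C) is not recoverable from
  the published medians (re-computation gives ≈8.4 °C); the regression's
  original inputs are unknown, so the degree-day module is validated on
  synthetic data only.
- Jackknife/bootstrap confidence intervals for r_m are out of scope; only
  point estimates and z-score comparisons are provided.
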