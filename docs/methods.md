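# Methods

## Model

Whole-body EE is taken to follow a zero-intercept power law of body mass,
`EE = c·M^k`, within a species and physiological state. Over a restricted
mass range `[M_lo, M_hi]` around a reference mass `M0`, the curve is locally
linear, and its first-order Taylor expansion

```
EE ≈ a + b·M,   a = c·M0^k·(1−k),   b = c·k·M0^(k−1)
```

is what an ordinary linear regression of EE on mass estimates when `M0` is
the sample mean mass. The inversion

```
k = b·M0/(a + b·M0),   c = b/(k·M0^(k−1))
```

is exact for the tangent line and is used as a plug-in estimator for fitted
(a, b). Assumptions: the latent relationship really is a single power law
over the sampled range; the fitted line's mean mass is a sensible expansion
point; b > 0 and a + b·M0 > 0 (otherwise no positive power law has that
tangent, and the conversion raises). The recovered (k̂, ĉ) are *reasonable*
rather than formally unbiased estimators: the inversion is nonlinear in
(a, b), so noise propagates asymmetrically (visible as the small positive
bias of ĉ in the simulation study).

The multi-organ model writes resting EE as a sum of per-organ power laws of
*total* mass, `REE = Σ c_i·M^(k_i)`, with lumped exponents
`k_i = p_i + q_i` combining the scaling of mass-specific organ REE and of
organ mass. Linearization is additive, so the aggregate regression
intercept is `Σ c_i·(1−k_i)·M0^(k_i)` — strictly positive whenever all
`k_i < 1`. Useful exact identities (all tested):

* sum rule: linearizing the sum = summing the per-organ linearizations;
* weighted-exponent identity: inverting the aggregate tangent returns the
  REE-share-weighted mean of the organ exponents;
* intercept decomposition: aggregate a = REE(M0)·(1 − k_agg);
* each organ's intercept contribution is `c_i · g(k_i)` with multiplier
  `g(k) = (1−k)·M0^k`, maximized at `k* = 1 − 1/ln M0`.

`g` (hence `k*`, and all sensitivity percentages) depends on the numerical
value of `M0`, i.e. on the mass unit — `M^k` is not unit-invariant. The API
therefore requires explicit units on every object; sensitivity and
multiplier analyses follow the gram convention, under which `k*(30 g) =
0.706` and the liver results below hold. Coefficients convert between units
by `c' = c·r^(−k)` (r = ratio of unit sizes), which leaves predictions
invariant.

## Parameters and defaults

| quantity | default | units | rationale |
|---|---|---|---|
| linearization reference M0 | sample mean mass | mass unit | matches what a fitted regression centers on |
| reduction grid | 201 equally spaced masses | mass unit | dense enough that RSS is grid-stable; logged because RSS depends on it |
| nonlinear fit convergence | rel. step < 1e-10, ≤ 200 iterations | — | deterministic damped Gauss–Newton from the tangent-sum initializer |
| simulation noise | multiplicative lognormal, CV 5% | — | metabolic measurements are CV-stable; additive Gaussian available |
| simulation cohort | n = 100, masses uniform 25–35 g, 1000 reps | — | typical phenotyping group sizes at mouse scale |

Float tolerances: closed-form identities are tested at 1e-9 relative
(round-trip, tangency, share sums), algebraic identities at 1e-12, fitted
quantities at 1e-6.

## Reconstructed fixtures

The five-organ mouse instantiation (`mouse5`) pins every anchored value —
liver (c = 0.36 kcal·d⁻¹·g⁻⁰·⁶, k = 0.6; 22.6 in kg units), aggregate
tangent (a, b) = (1.66, 123.73 kg-units) at 0.03 kg, remainder REE share
0.27 — and fills the remaining freedom with chosen values: brain, heart and
kidneys split the residual REE share equally with exponents 0.44, 0.80,
0.80 (brain scales weakly with body mass, heart and kidneys more nearly
proportionally), and the remainder exponent (≈ 0.874) is solved from the
weighted-exponent identity, which makes the aggregate exact by
construction. Mass fractions (liver 5%, brain 1.6%, heart 0.6%, kidneys
1.2%, remainder balance) are plausible mouse values. The fixture is a
synthetic reconstruction: it reproduces the anchored aggregate behaviour —
liver ≈ 52% of REE and ≈ 67% of the intercept at 30 g, +18.5% liver REE and
+9.6% whole-body REE when liver k moves 0.6 → 0.65 — not any published
per-organ table. `fig1_curve` (k = 0.67 through 5 kcal/d at 26 g) and
`ravussin_linear` (597 + 26.5·FFM, reference FFM required from the caller)
are likewise labelled reconstructed.

## Reducing a sum of power laws to one power law

A sum of power laws is not exactly a power law; three identification routes
are provided and scored on one objective, the RSS in original EE units on a
shared equally spaced mass grid: (i) tangent-sum — linearize each organ at
the grid midpoint, sum, invert in closed form; (ii) log-log OLS; (iii)
nonlinear least squares initialized from (i). On the mouse fixture over
20–40 g all three land within 0.2% of each other in (c, k), and
RSS(nls) ≤ RSS(loglog) < RSS(taylor_sum). The last inequality is
structural: when the sum is very close to a power law (relative residuals
~0.1% here), the midpoint tangent leaves an approximately quadratic
residual whose squared norm any two-parameter least-squares fit reduces by
a roughly universal factor ≈ 0.49, for every fixture in the
anchor-respecting family. The tangent-sum route's value is its simplicity
and closed form, not optimality of fit.

## What the simulation does and does not show

The generator draws masses (uniform or lognormal), evaluates the true power
law, and applies multiplicative lognormal noise (σ chosen so the factor's
CV equals the requested value) or additive Gaussian noise truncated to
positive EE. Replicates use RNG streams spawned per replicate from the
master seed, so results are independent of execution order and individually
reproducible. At the default mouse-scale settings the study shows mean k̂
within 0.001 of truth and ĉ within ~2% — i.e. the tangent inversion is a
sound estimator *under the generating assumptions*. Real cohorts add
features the generator omits: body-composition heterogeneity (FFM vs fat
mass), measurement error in mass itself, group structure, and possible
departure of the true mass–EE relationship from a single power law. Passing
tests therefore validate the algebra and the estimator's behaviour under
clean allometric sampling, not the biological adequacy of the power-law
model for any particular dataset.

## Numerical and design choices

* Canonical conversions are closed-form only; the iterative root-solve of
  the tangency system exists solely as an independent test oracle.
* k is not clamped: k > 1 (negative intercept) is legal and produces a
  logged warning, since sub-linear scaling is the typical case.
* The nonlinear fit is an in-package damped Gauss–Newton (Levenberg
  damping, step accepted only if RSS does not increase, c kept positive);
  failure to converge raises an error carrying diagnostics rather than
  returning a silent fallback.
* Log-log fits report RSS/r² after back-transforming to original units so
  that method comparisons share one metric; on noiseless power-law data the
  log-log and nonlinear fits agree exactly, on heteroscedastic data they
  differ (by design, not asserted).
* Intercept shares are reported as absent (not NaN) when the aggregate
  intercept is numerically zero; the multiplier maximizer reports values
  ≤ 0 for M0 ≤ e as "no interior maximum" and raises for M0 ≤ 1.
* Ratio-confound correlation defaults to Pearson (Spearman optional).
* Units travel inside data files; CLI unit flags only validate, never
  convert.

## Known limitations

* The tangent inversion requires the (often unpublished) sample mean mass;
  where a source omits it, it must be supplied as an explicit argument.
* No standard errors are propagated through the nonlinear transformation to
  (k̂, ĉ); the Monte Carlo study is the uncertainty statement.
* Two mass units (g, kg) are supported; EE units are labels, converted only
  by the caller.
* No ANCOVA/group-comparison machinery: regression-based adjustment remains
  the right tool for inference between groups; this package supplies the
  scaling parameters and normalization constructs.
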