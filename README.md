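# alloscale

Tools linking the **linear** energy-expenditure (EE) regressions used in
metabolic phenotyping to the **allometric** power laws that underlie them.

## The problem

Over broad ranges of body mass, metabolic rate scales as a zero-intercept
power law,

```
EE = c · M^k            (k dimensionless; c carries units)
```

with exponents *k* typically below one within mammals. But phenotyping
studies work with narrow within-group mass ranges, where EE is routinely
modelled as a straight line,

```
EE = a + b · M
```

almost always with a *positive* y-intercept *a* of debated origin. The two
facts are one fact: over a restricted range, the linear regression estimates
the first-order Taylor expansion of the latent power law about the sample
mean mass M₀,

```
a = c · M₀^k · (1 − k)        b = c · k · M₀^(k−1)
```

which inverts in closed form:

```
k = b·M₀ / (a + b·M₀)         c = b / (k · M₀^(k−1))
```

So a positive intercept is exactly what sub-linear scaling (k < 1) predicts,
and any published linear EE equation (plus its sample mean mass) can be
converted into allometric parameters — useful for estimating scaling in
metabolic states the allometric literature never covered, and for
normalizing EE by "metabolic body size" M^k instead of the biased simple
ratio EE/M (whose expectation a/M + b falls with M whenever a > 0).

The same tangent algebra applied to an organ-compartment model of resting
EE (liver, brain, heart, kidneys, remainder — each a power law of total
body mass) shows the regression intercept is the sum of per-organ terms
`c_i · (1 − k_i) · M₀^(k_i)`, all positive when every organ scales
sub-linearly: modelling individual organs decomposes the intercept but does
not remove it. The per-organ multiplier `(1 − k)·M₀^k` peaks at
`k* = 1 − 1/ln M₀`, which is why a small organ with a large coefficient and
a moderately sub-linear exponent (the liver, in a mouse) can dominate both
the intercept and whole-body REE.

Audience: researchers doing indirect-calorimetry phenotyping, EE
normalization, or organ-level REE modelling.

## Worked example

Convert a classic published human regression of 24 h EE on fat-free mass,
`EE (kcal/d) = 597 + 26.5·FFM`, to its latent power law. The sample mean
FFM is not printed in that source, so it must be supplied (here 60 kg):

```python
from alloscale import LinearEEModel, linear_to_allometric

m = LinearEEModel(a=597.0, b=26.5, M0=60.0, mass_unit="kg", mass_kind="ffm")
p = linear_to_allometric(m)
print(f"k = {p.k:.3f}, c = {p.c:.1f}")
```

```
k = 0.727, c = 111.5
```

i.e. adult human 24 h EE scales with FFM^0.73 — close to the classic 3/4
exponent — even though the source only ever reported a straight line.

The Monte Carlo study validates the whole pipeline (simulate a noisy
allometric cohort → fit a line → invert the tangent) at mouse scale:

```python
from alloscale import SimulationConfig, recovery_study

print(recovery_study(SimulationConfig(seed=1)).summary())
```

```
Allometric recovery study: 1000/1000 replicates succeeded (0 failures)
  generating model: EE = 60.6 * M^0.69 [kcal/d; mass in kg], n=100, noise=multiplicative_lognormal
  k: mean 0.6903  sd 0.0521  bias +0.0003 (+0.04%)   [true 0.69]
  c: mean 61.7093  sd 11.3541  bias +1.1093 (+1.83%)   [true 60.6]
```

The exponent is recovered essentially without bias at 5% measurement noise,
and the coefficient to within ~2%.

Everything is also available from the shell:

```
alloscale lin2allo --a 1.66 --b 123.73 --m0 0.03 --mass-unit kg
alloscale fixtures make --name mouse5 --outdir .
alloscale organs summarize --table mouse5_organs.csv --m0 30 --mass-unit g
alloscale organs sensitivity --table mouse5_organs.csv --organ liver --k-new 0.65 --m0 30
alloscale fit loglog --data cohort.csv --mass-unit kg
alloscale simulate --config sim.yaml
alloscale normalize --data cohort.csv --mass-unit kg --k auto --method eq_tangent
```

Units are explicit everywhere (the coefficient's numerical value depends on
whether mass is in grams or kilograms); unit mismatches are errors, never
silent conversions.

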