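# traitagg

Order-aware aggregation of individual-level trait measurements.

When individual measurements are collapsed to species means and a
non-linear transformation (most often the log) is applied somewhere in the
pipeline, the *order* of the two steps changes the result: by Jensen's
inequality, the mean of transformed values and the transform of the mean
differ whenever within-species variance is positive.  Trait–trait
relationships fitted on species-level values inherit that difference as
biased slopes, deflated R², and inflated standard errors.  `traitagg` is a
toolkit for ecologists and biostatisticians working with trait databases
(TRY-style long-format individual records) who want to

* quantify the per-species **Jensen gap** and approximate it from summary
  statistics alone,
* **correct** species means when only `(mean, SD, n)` survive,
* **decompose exactly** how much an aggregation-order choice moves a slope
  or correlation, and
* **simulate** realistic individual-level tables to probe all of the above.

## The statistics in brief

For species measurements `x_1 … x_n`, mean `x̄`, population variance
`s² = Σ(x_j − x̄)²/n`, and a transformation `f`:

```
Jensen gap      mean(f(x_j)) − f(x̄)  ≈  f''(x̄) · s²/2        (log: −s²/(2x̄²))
corrected mean  f(x̄) + f''(x̄) · s²/2  ≈  mean(f(x_j))
```

With species-level vectors `x, y` (transform-then-aggregate) and `x*, y*`
(aggregate-then-transform), bias vectors `θ = x − x*`, `ω = y − y*`, the
slope of the starred regression decomposes exactly:

```
b(x*,y*) = [cov(x,y) − cov(x,ω) − cov(θ,y) + cov(θ,ω)]
           / [var(x) + var(θ) − 2 cov(x,θ)]
```

(and analogously for the correlation), so the order effect is governed
entirely by the variance–covariance structure of `(x, y, θ, ω)`.

The built-in demonstration uses three fine-root traits.  Under cylindrical
root geometry, specific root length (SRL), root tissue density (RTD) and
diameter (D) obey, per individual,

```
SRL = 4/(π · RTD · D²)     ⇔     ln SRL = ln(4/π) − ln RTD − 2 ln D,
```

so averaging *logs* per species keeps the regression of mean-ln SRL on
mean-ln RTD and mean-ln D exact — intercept ln(4/π) ≈ 0.2416, slopes −1 and
−2, R² = 1 — while averaging raw values first visibly distorts all of it.

## Worked example

Simulate a table at the demonstration scale (368 species, 1920 individuals
of D and RTD, heterogeneous within-species spread), then run the root-trait
comparison:

```sh
$ traitagg simulate --config sim.yaml --out traits.csv
$ traitagg demo-srl --input traits.csv --output report/
transform-first trivariate: R^2 = 1.000000; intercept = 0.241564, lnRTD = -1.000000, lnD = -2.000000
aggregate-first trivariate: R^2 = 0.901908; intercept = 1.234460, lnRTD = -0.908602, lnD = -1.529212
```

with `sim.yaml`:

```yaml
n_species: 368
total_individuals: 1920
seed: 42
n_per_species: [1, 10]
traits:
  D:   {between_log_mean: -1.05, between_log_sd: 0.45, within_log_sd: [0.05, 0.6]}
  RTD: {between_log_mean: -1.39, between_log_sd: 0.40, within_log_sd: [0.05, 0.6]}
```

The first line is the identity recovered to machine precision: averaging
log values preserves the individual-level geometry, so the fit returns the
theoretically expected parameters regardless of the data.  The second line
is the same regression after averaging raw values first: R² drops to 0.90,
the intercept quintuples, and both slopes are attenuated — a pure artefact
of aggregation order, since both fits summarise the *same* measurements.
`report/trivariate.csv` and `report/pairwise.csv` hold the full
coefficient/SE/R² tables, including the three pairwise regressions
(SRL~RTD, SRL~D, RTD~D) under each order.

The same machinery is available as a library:

```python
>>> import traitagg as ta
>>> log = ta.get_transform("log")
>>> ta.jensen_gap([1.0, 7.389056], log)          # species {1, e^2}
JensenGapResult(exact_gap=-0.4337808..., approx_gap=-0.2900128...)
>>> ta.corrected_transformed_mean(4.194528, 3.194528, n=2, t=log)
1.1437679...
```

Other subcommands: `jensen-gap` (per-species gap table), `correct`
(quadratic correction of a `(mean, sd, n)` summary CSV), `compare-orders`
(the full ten-component slope/correlation decomposition between orders).
Logs go to stderr, data to files, exit codes are 0/1/2
(success / data error / usage error).

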