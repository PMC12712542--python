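# Methods

## The problem

Trait-based ecology routinely collapses individual-level measurements to one
value per species before analysis, and routinely log-transforms trait values
somewhere along the way.  The order of those two steps matters.  For a
species with measurements `x_1 … x_n` and a non-linear transformation `f`,

* **transform-then-aggregate (TTA)** produces `mean(f(x_j))`,
* **aggregate-then-transform (ATT)** produces `f(mean(x_j))`,

and by Jensen's inequality the two disagree whenever the within-species
(intraspecific) variance is positive: for concave `f` (log, square root)
`mean(f(x)) ≤ f(mean(x))`, with equality only at zero spread.  Because
mechanisms that couple traits — geometry, physiology, selection against
unfavourable combinations — act on individuals, relationships that are
exactly linear after transformation at the individual level are preserved by
TTA and perturbed by ATT.  This package quantifies that perturbation, offers
an approximate correction when only species-level summaries survive, and
demonstrates the effect on a root-trait identity where the true parameters
are known a priori.

## Jensen gap and quadratic correction

The package defines the per-species **Jensen gap** as

```
gap = mean(f(x_j)) − f(x̄),        x̄ = mean(x_j),
```

so the gap is negative for concave transforms (the direction pins the sign
convention; a printed form with the opposite orientation is recovered as
`f(x̄) + gap`).  A second-order Taylor expansion of `f` about `x̄` gives

```
gap ≈ f''(x̄) · s² / 2,            s² = Σ(x_j − x̄)² / n,
```

the *quadratic approximation*.  `s²` is the population (divide-by-n)
variance — that is the convention of the expansion, and it is what
`var_raw_pop` stores; sample variance input is converted via `(n−1)/n`.
For the log transform the approximation reads `−s²/(2x̄²)`: the distortion
scales with the squared coefficient of variation within species.  The
remainder of the approximation is controlled by third and higher central
moments, so contracting a value set about its mean by a factor `c` shrinks
the error at least as `c³` (as `c⁴` for sets symmetric about the mean); the
test suite asserts the ≥4× shrink per halving.

`corrected_transformed_mean` applies the correction in the practical
direction: given only `(mean, SD, n)` per species — the shape of most
database summaries — it estimates the TTA value as
`f(mean) + f''(mean)·var_pop/2`.  No higher-order (skewness/kurtosis)
refinement is offered; for strongly skewed species samples the quadratic
correction is a first-order repair, not an exact one.

## The species-specific offset

If the individual-level law `f(y_j) = a + b·g(x_j)` holds exactly, the TTA
species values satisfy it exactly too (when both traits are measured on the
same individuals; approximately otherwise, since means estimate
expectations).  Substituting the quadratic correction into both sides shows
the ATT species values instead satisfy

```
f(ȳ) ≈ a + b·g(x̄) + C,
C = b·g''(x̄)·var_x/2 − f''(ȳ)·var_y/2,
```

with `var` the population within-species variances.  `C` depends on each
species' own means and variances: it is a species-specific perturbation,
generally correlated with `g(x̄)`, so it bends the species-level relation
away from linearity rather than adding exchangeable noise.

## Exact decomposition of the slope and correlation difference

Let `x, y` be the species-level values under the reference order (TTA by
default; the labelling is a parameter) and `x*, y*` under the other order,
aligned by species.  With bias vectors `θ = x − x*` and `ω = y − y*`,
bilinearity of the covariance gives, exactly,

```
b(x*,y*) = cov(x*,y*)/var(x*)
         = [cov(x,y) − cov(x,ω) − cov(θ,y) + cov(θ,ω)]
           / [var(x) + var(θ) − 2·cov(x,θ)]
```

and the analogous ratio for the Pearson correlation.  Two things follow:
the difference between the orders depends only on the variance–covariance
structure of `(x, y, θ, ω)` — a constant (mean) bias cancels — and the
identity holds for any common covariance divisor.  The implementation uses
n−1 throughout, matching OLS conventions, and always computes the direct
and reconstructed routes independently; their agreement to 1e-10 is a
standing test, not an assumption.

Sign convention: since `θ = x − x*` implies `x* = x − θ`, the cross terms
enter with minus signs.  A rendering of the same decomposition as
`cov(x+θ, y+ω)/var(x+θ)` circulates; it is consistent only with the
opposite orientation of the bias vectors, and this package does not adopt
it (the direct-vs-reconstructed agreement test would catch the sign error
immediately).

## The root-trait demonstration

Under cylindrical fine-root geometry, specific root length (length per unit
dry mass), root tissue density (dry mass per volume) and fine-root diameter
obey, per root segment,

```
SRL = 4 / (π · RTD · D²)        ⇔        ln SRL = ln(4/π) − ln RTD − 2 ln D.
```

The identity is exact at the individual level, so averaging *log* values
per species preserves it exactly, and the OLS fit of mean-ln SRL on
mean-ln RTD and mean-ln D returns intercept `ln(4/π) ≈ 0.241564`,
coefficients −1 (lnRTD) and −2 (lnD), and R² = 1 for *any* non-degenerate
table in which SRL was derived from the other two traits — a
data-independent algebraic fact, useful precisely because it makes the
theoretical parameters known.  Fitting the same regression on
log-of-species-means instead degrades R² and biases all three parameters;
the size of the degradation depends on the within-species variance
structure, and the pipeline reports both fits plus the six pairwise
regressions (three trait pairs × two orders) side by side.

Coefficients are bound to predictor *names* (`lnRTD`, `lnD`), never to
positions: the theoretical values are −1 on lnRTD and −2 on lnD, and
positional labels are an easy source of transposition errors.

Units: the caller must supply mutually consistent units (e.g. D in cm, RTD
in g cm⁻³, SRL in cm g⁻¹).  Unit changes are linear, so they shift only the
intercept, never the slopes or R².

A `split_individuals` flag summarises SRL from the second half of each
species' individuals and the predictors from the first half (odd individual
to the predictors), emulating traits compiled from disjoint individual
sets; the exact fit then becomes approximate, and the pipeline makes no
claim about how closely it holds — with independently measured traits the
sampling errors of each trait would further loosen it.

## The synthetic-data generator

`simulate_trait_table` draws a hierarchical lognormal table: species
log-means from `Normal(between_log_mean, between_log_sd)`, individual
values as `exp(log-mean + within-species deviation + measurement noise)`.
Values are strictly positive by construction, so log-analysis is always
valid.  Defaults describe the demonstration scale and realistic fine-root
trait distributions:

| parameter | default | why |
|---|---|---|
| `n_species` | 368 | demonstration scale |
| `total_individuals` | 1920 | demonstration scale |
| D: between log-mean / log-SD | ln(0.35 mm), 0.45 | typical fine-root diameter range ≈ 0.15–0.8 mm |
| RTD: between log-mean / log-SD | ln(0.25 g cm⁻³), 0.40 | typical tissue-density range ≈ 0.1–0.6 g cm⁻³ |
| within-species log-SD | 0.15 (D), 0.20 (RTD) | intraspecific CV of 15–20%, common for root traits |
| `n_per_species` | uniform 1–10 | strongly unequal sampling, as in database extracts |
| `measurement_noise_log_sd` | 0 | identity preserved unless noise is requested |

Per-species counts are drawn from the configured range, rescaled to hit the
exact total by largest-remainder rounding, and floored at one individual;
species with n = 1 are *kept* (their gap and correction are zero) because
silently dropping them would change every downstream regression.  All draws
come from one seeded generator consumed in a documented order (count
allocation; per-species trait log-means; per-individual deviations), so a
seed fixes the table byte-for-byte.

Heterogeneous mode (`within_log_sd = (lo, hi)`) assigns each species a
within-species log-SD of `lo + (hi−lo)·rank`, where `rank` is the
percentile rank of the species' latent log-mean.  Larger species means then
carry larger intraspecific spread — the configuration under which the
between-species variation of the bias vectors, and with it the slope
distortion, is largest.  The default heterogeneous range is (0.05, 0.60).

`simulate_coupled_traits` adds a response `y = a·xᵇ` per individual,
optionally with lognormal noise, so individual-level log-linearity is exact
at zero noise; disjoint mode keeps x records for the first half of each
species' individuals and y records for the second half.

What the generator does **not** emulate: phylogenetic signal among species
means, correlated between-species structure across traits (traits are
drawn independently unless coupled by the power law), spatial or temporal
sampling structure, heavy-tailed or skew-free raw noise, censoring, and
unit heterogeneity.  Passing tests on synthetic tables therefore show that
the algebra and its implementation are correct under the stated lognormal
hierarchy — not that any particular real dataset has biases of a given
size.  On real extracts the magnitude of the order effect is an empirical
question the decomposition is designed to answer case by case.

## Numerical choices

* **Strict open domains.** Transform inputs at or beyond a domain bound
  raise a `DomainError` naming the index/species and value; NaN/−∞ never
  enter covariances.
* **Zero-spread short-circuit.** A species whose values are bit-identical
  gets `var_raw_pop = 0` and exactly equal TTA/ATT values, avoiding
  floating-point dust (~1e-33) from the mean subtraction.
* **OLS via QR.** Coefficients come from an orthogonal decomposition, never
  an explicit inverse of X'X; perfect fits then report R² = 1 with standard
  errors at float noise (~1e-16), unclamped.  Saturated designs (n = p)
  interpolate with zero residual variance.  Rank deficiency relative to
  machine precision raises a `SingularDesignError`.
* **Alignment and ordering.** Species alignment is by identifier
  intersection, sorted lexicographically; excluded species are logged.
  Results are order-stable across runs and platforms.
* **"Arcsine" means arcsin(√x)** on the open interval (0, 1) — the
  variance-stabilising form used on proportions.  Plain `arcsin(x)` is not
  aliased to it; a user who wants it can register a custom transform.

## Known limitations

* The quadratic correction ignores moments above the second; it
  under-corrects strongly skewed species samples.
* No delta-method standard errors accompany the corrected transformed mean.
* The OLS unit is classical (homoskedastic) by design; no robust, weighted
  or standardised-major-axis variants, although SMA is common in trait
  allometry.
* The decomposition reports components; it does not correct
  errors-in-variables attenuation.
* Box–Cox estimation of an optimal transform and automatic differentiation
  of user transforms are out of scope.
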