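# Methods

## Model

The quantity of interest is the functional response of habitat
selection at the home-range (third-order) scale: the expected
proportional use `π_i(x)` of land-cover category `i` as a function of
its relative availability `x` within an individual's monthly home
range.  Estimation is a two-step procedure.

**Step 1 — baseline-category logits.**  With `K` categories and a
reference category `K` (conventionally the most prevalent one), each
non-reference category gets a binary dataset: fixes in category `i`
(`present = 1`) against fixes in the reference (`present = 0`).  Every
row carries the focal category's availability in the recording
animal-month — also for reference fixes.  The linear predictor of the
binomial logit is

```
f_i(x) = α_i + β_i·sex + te_i(hour, month) + s_i(x) + log(x) + ε_id + γ_year
```

with `log(x)` an offset (coefficient fixed at 1).  Under the offset
alone, the odds of using `i` over the reference grow proportionally
with availability — the "no functional response" null.  Any estimated
deviation `s_i(x)` (a linear term in `log x`, or a penalized spline) is
the functional response on the log-odds-ratio scale.

**Step 2 — multinomial link and Holling fits.**  The fitted log odds
ratios combine into choice probabilities via the multinomial logit
link, `π_i = exp(f_i) / (1 + Σ_s exp(f_s))` with `f_K = 0`; because the
choice set is exhaustive and fixes are temporally independent, the
choice probability equals proportional use.  Sweeping the focal
availability over its observed range traces a use curve, to which the
three Holling forms are fitted by bounded least squares; the smallest
residual sum of squares selects the type.

### Assumptions

* Fixes are independent within animal-months (appropriate for
  telemetry thinned to long inter-fix intervals, where the whole home
  range is reachable between fixes); no movement model.
* Proportional use is driven by each category's own availability; the
  influence of the other categories enters only through the simplex
  constraint (backgrounds rescale proportionally as the focal
  availability varies).
* Random intercepts capture individual- and year-level prevalence
  differences; curves are reported at the population level (random
  effects at zero).
* The uncertainty of the two-step chain is not propagated: no
  confidence bands on use curves or Holling parameters (a known
  limitation of the procedure; a one-step hierarchical model would be
  needed to overcome it).

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| MCP level | 95% | fraction of fixes kept when peeling the home range; convention for telemetry MCPs |
| home-range cut-off | per-sex 90th percentile of monthly areas | removes dispersal-inflated ranges; absolute per-sex thresholds (e.g. 182 ha females / 459 ha males, in map units²) can be configured instead, and the percentile can be applied per animal-month or per individual |
| min fixes per animal-month | 5 | minimum for a non-degenerate 2-D hull |
| smoothing parameter λ | 2 | fixed (not estimated) penalty on the availability spline and the temporal tensor smooth |
| availability basis | 8 cubic B-splines on the observed range, 2nd-difference penalty | flexible but stable deviation curve |
| temporal basis | 8 (hour, period 24) × 6 (month, period 12) wrapped cubic B-splines, cyclic 2nd-difference penalties | diurnal × seasonal surface, continuous across midnight and New Year |
| random-intercept SD grid | 0.05 … 2.2 (12 log-spaced values) | Laplace-approximate marginal-likelihood grid search per grouping factor |
| CV folds | 10, grouped by animal | guards against pseudo-replication of individuals across folds |
| reporting slots | months {6, 12} × hours {0, 12} | summer/winter × midnight/noon contrasts |
| x grid | 200 points between the 1st and 99th percentile of observed focal availability | avoids spline extrapolation at the range edges |
| Holling bounds | a, b ∈ [0, 1] for all types | proportions cannot exceed 1; for type I the slope bound also keeps use ≤ availability-scale |

## Synthetic data: what it emulates, what it does not

The generator draws, per animal-month, an availability simplex from a
symmetric Dirichlet(1) (rejecting vectors with reference availability
< 0.05 so the reference offset stays finite), computes each
non-reference category's use from its Holling truth curve times
optional hour/month and sex modifiers, lets the reference absorb the
remaining probability mass (failing loudly if that mass is not
positive), applies mean-zero normal random intercepts on the log-odds
scale (defaults: SD 0.3 between individuals, 0.1 between years —
mild, realistic heterogeneity), and draws each fix's category from the
resulting multinomial.  Because the shifts are mean-zero on the
log-odds scale, the population-median use curve is exactly the truth
curve, which is what the population-level estimate targets.

It does **not** simulate movement autocorrelation, GPS error, spatially
contiguous home ranges tied to a shared raster, or availability-
dependent home-range placement.  Passing recovery tests therefore
demonstrate that the estimation chain is correct for its own estimand
under temporally independent fixes — not that field data meet those
assumptions.

The standard recovery scenario used in the tests and the acceptance
script is 20 animals per sex × 8 months × 50 fixes (≈ 16,000 fixes per
replicate), a size at which recovery tolerances of ±0.05 on `a` and
±0.03 on `b` hold with margin while the whole chain runs in seconds.

## Numerical choices

* **Penalized IRLS.**  All logit variants are fitted by one engine:
  iteratively reweighted least squares on the penalized binomial
  deviance, with step halving (unpenalized spline directions can make
  plain Newton overshoot).  Unpenalized specifications reproduce an
  ordinary GLM (checked against statsmodels in the tests).
* **Identifiability of smooths.**  The constant function lies in both
  the span and the penalty null space of every B-spline basis, so each
  smooth block is reparameterized through the null space of its
  column-mean vector (a sum-to-zero constraint); interactions with sex
  reuse the base block's constraint.
* **Random intercepts** are ridge-penalized group indicators with one
  variance per factor, chosen by a coordinate-wise grid search on a
  Laplace approximation to the marginal likelihood.  Factors with a
  single level are dropped with a warning; a singular fit falls back to
  no random effects, logged.
* **Holling optimization.**  Type I has the closed-form bounded
  solution.  Types II/III use L-BFGS-B inside [0,1]² from a 3×3 grid of
  starts plus a profile start (dense grid over `b` with the optimal `a`
  in closed form per `b` — RSS is quadratic in `a`).  Tests verify the
  result never exceeds an exhaustive 0.001-step grid minimum by more
  than 1e-9.
* **Ties and degenerate cases.**  Equal-RSS ties between types go to
  the lower type number.  `a/b` at `b = 0` is reported as +infinity.
  The report writer prints `x* = 0` when no identity crossing exists
  (the regime column keeps the distinction between "no crossing" and a
  genuine crossing at 0).  `h_II` and `h_III` at `b = 0, x = 0` take
  their limit value 0.  MCP distance ties during peeling are broken by
  input order (earlier fixes kept).  Raster cell centers exactly on the
  polygon boundary count as inside.
* **Zero-availability rows** are dropped (and counted), never floored:
  the log offset is undefined and flooring would fabricate
  availability.

## Open design choices made here

* The candidate set for structure selection is the full grid of
  availability terms × temporal terms with a sex main effect, plus the
  legal availability-by-sex interactions and three no-year-intercept
  variants — 18 candidates, fully configurable.
* Background availabilities along a use curve are the per-sex mean
  observed availability vector rescaled to `1 − x`; only the simplex
  constraint is dictated by the model, the rescaling rule is this
  package's convention (recorded in the run manifest).
* The home-range size cut-off can be computed over monthly areas or
  per individual (both interpretations are defensible); monthly is the
  default.
* Smooths are P-splines (uniform-knot B-spline bases with difference
  penalties, wrapped for periodic covariates) rather than
  cyclic cubic regression splines; at fixed λ the two families give
  near-identical fits and P-splines are simpler to construct and
  serialize.
* Raster input is the plain-text ESRI ASCII grid format (single band,
  integer codes, legend supplied in the config).

## Known limitations

* No uncertainty quantification for use curves or Holling parameters.
* Model-structure choice by CV is per category; the chosen structure
  may differ between categories and runs with few animals.
* Categories that are rare everywhere yield short availability ranges;
  Holling types are then weakly identified (the fit is honest about RSS
  but the type call can be unstable).
* Planar coordinates only; no geodesic home ranges.
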