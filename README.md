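# habresp

Holling-type functional responses in the habitat selection of large
herbivores, estimated from GPS telemetry and a categorical land-cover
map.

## The problem

Within its home range, an animal does not use a land-cover type in
simple proportion to how much of it is available: meadows may be
visited heavily when they are scarce and ignored once they are
abundant.  This availability dependence of use — the *functional
response* of habitat selection, by analogy with Holling's predator
functional response — is usually described phenomenologically.
`habresp` instead estimates the relationship and classifies it with
Holling's own equations, which makes the parameters ecologically
interpretable:

* type I (linear): `h_I(x) = a·x`
* type II (saturating): `h_II(x) = a·x / (b + x)` (Michaelis–Menten)
* type III (sigmoid): `h_III(x) = a·x² / (b² + x²)`

where `x` is the relative availability of a land-cover type in the
monthly home range, `a` is the maximum proportional use, and `b` the
availability at half-maximum use — small `b` means the type is
attractive even when rare.  Derived diagnostics include the tipping
point `x* = a − b` (type II, `a > b`), where use switches from
disproportionately high to disproportionately low, the identity
crossings `x₁,₂ = a/2 ± sqrt((a/2)² − b²)` and the inflection point
`b/√3` for type III, and the attraction ratio `a/b`.

## The estimation chain

1. **Availability** — monthly 95% minimum convex polygon home ranges
   per individual; relative availability of each category from the
   cells of a rasterized land-cover map whose centers fall inside the
   polygon.  Animal-months with implausibly large ranges (dispersal)
   are screened out by a per-sex 90th-percentile area cut-off.
2. **Baseline-category logits** — for each category `i` versus a common
   reference `K`, a binomial model of the fixes with a fixed offset
   `log(x_i)` (the null of proportional use), an optional parametric or
   penalized-spline deviation in availability (smoothing parameter
   λ = 2), a cyclic tensor-product smooth in (hour, month), sex
   effects, and random intercepts for individual and year.  Candidate
   structures can be ranked by animal-grouped 10-fold cross-validation.
3. **Use distribution** — the fitted log odds ratios `f_i(x)` combine
   through the multinomial logit link
   `π_i = exp(f_i) / (1 + Σ_s exp(f_s))`, `f_K = 0`, giving
   proportional-use curves over the observed availability range.
4. **Holling fits** — each curve is fitted by bounded least squares
   (`a, b ∈ [0, 1]`, multi-start) for all three types; the smallest
   residual sum of squares selects the type.

A synthetic-data module generates multi-animal telemetry whose
per-category use follows known Holling truth curves, so the whole chain
is testable without field data.

## Worked example

Simulate 40 roe-deer-like animals tracked for 8 months (50 fixes per
animal-month) over heterogeneous home ranges where the focal category
"meadow" follows a type-II truth curve with `a = 0.3`, `b = 0.05`, then
recover the curve:

```python
import numpy as np
import habresp as hr

scen = hr.SimScenario(n_individuals=20, n_months=8, fixes_per_month=50,
                      categories=("meadow", "old_mixed"),
                      reference_category="old_mixed", seed=1)
truth = hr.TruthCurve("meadow", "II", a=0.3, b=0.05)
telemetry, _ = hr.generate_telemetry(scen, [truth])
availability = hr.generate_availability_vectors(scen)

data, _ = hr.build_pairwise_dataset(telemetry, availability, "meadow", "old_mixed")
results = hr.fit_logodds_model(data, hr.ModelSpec(temporal_term="none"))
print(results.summary())

mean_bg = availability.groupby("category")["proportion"].mean().to_dict()
curve = hr.use_curve([results], hour=0, month=6, sex="female", focal="meadow",
                     x_grid=np.linspace(0.01, 0.9, 200), mean_background=mean_bg,
                     reference_category="old_mixed", extrapolate=True)
print(hr.HollingModel(curve.x, curve.use).fit().summary())
```

which prints

```
Focal-vs-reference logit: meadow
==============================================
spec:       smooth+none+re(id,year)
n obs:      16000   deviance: 18680.98   edf: 39.80
avail range: [0.0065, 0.9404]  (offset log(avail) fixed at 1)
  intercept              +0.0513
  s(avail)               penalized (7 basis fns, lambda=2)
  re(id)                 sigma = 0.270

Holling functional-response fit
==================================
type:        II
a (max use): 0.3263
b (half-sat): 0.0434
a/b:          7.5170
rss:         0.0147323  (n=200)
tipping point x* = a - b = 0.2829
regime:      switch_at_x_star
```

The type-II truth is identified and `(a, b)` are recovered close to
(0.3, 0.05); meadows would be over-used relative to availability up to
the tipping point `x* ≈ 0.28` and under-used beyond it.

The same chain runs from the shell: `habresp simulate`, `habresp
availability` (telemetry + ESRI ASCII raster), `habresp fit`, `habresp
combine`, `habresp holling`, or end-to-end with `habresp run --config
config.yaml`, which writes per-stage CSVs, a diagnostics summary table
and a JSON run manifest.

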