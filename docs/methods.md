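# Methods

This note documents the models implemented in `healtheff`, the numerical
choices behind them, what the synthetic data generator does and does not
emulate, and the design decisions taken where the methodology was open.

## Efficiency measurement

### The two-stage SBM protocol

Efficiency of a decision-making unit (DMU) is measured non-radially from
slacks: input excesses `s^−`, desirable-output shortfalls `s^+`, and
undesirable-output excesses `s^b`, each normalized by the DMU's own level,
so scores are invariant to the units in which any column is measured (a
property the test suite checks). Two fractional programs are involved.

The **standard** program evaluates the DMU against a reference technology
that includes it, yields `ρ* ∈ (0, 1]`, and equals 1 exactly for frontier
units. The **super-efficiency** program excludes the DMU from its
reference set and scores frontier units above 1 by how far they could
deteriorate (inputs up, outputs down, bads up) while remaining efficient.
The super program alone assigns 1 to every dominated DMU — it can only
discriminate *above* the frontier — so the published sub-unity scores
require the standard companion. `efficiency_score` therefore runs the
standard program first and escalates to the super program only for units
scoring 1 (within tolerance). This two-stage protocol is the package's
central reconstruction decision: published tables of "comprehensive
efficiency" mixing values below and above 1 are only producible this way.

Undesirable outputs enter both programs as technology outputs whose excess
is penalized in the denominator symmetrically with desirable-output
shortfall (`undesirable_mode="eq1"`); `"none"` drops them for sensitivity
runs.

### Linearization and numerics

Both fractional programs are linearized exactly by the Charnes–Cooper
transformation: multiply all variables by a scaling factor `t > 0` chosen
so the denominator equals 1, solve the resulting LP (scipy's HiGHS), and
recover `λ = Λ/t`, `s = S/t`. Numerical guards:

* `denominator_floor` (default 1e-9) bounds `t` away from 0, protecting
  the back-transformation; solutions at the floor are flagged
  `degenerate`, not silently accepted;
* LP feasibility/duality tolerances default to 1e-7;
* scores within 1e-6 of 1 are snapped to exactly 1.0, stabilizing the
  standard-to-super switch (without the snap, roundoff at the frontier
  would route borderline units arbitrarily);
* super-efficiency infeasibility (possible under VRS, or with a single
  DMU) is reported as `status="infeasible"` with an undefined score.
  Summaries exclude and count such records; nothing is imputed.

### Returns to scale and frontier scope

VRS adds the convexity constraint `Σλ = 1` (scaled form `ΣΛ = t`) to
either program. `decompose_scale` reports `crste` (CRS score), `vrste`
(VRS score) and `scale = crste/vrste`. The decomposition honors the
`super` flag: with the super stage disabled all scores are capped at 1 and
`scale ∈ (0, 1]` holds exactly; with it enabled, frontier units carry
super scores in both columns, matching published decomposition tables
whose efficient units exceed 1. Whether published CRS/VRS columns come
from radial (CCR/BCC) or SBM models is generally unstated in applied
work; this package uses SBM under both returns-to-scale assumptions, and
the radial scores are available independently through the distance
functions of the Malmquist module.

The default reference technology is **contemporaneous** — each year's
DMUs form that year's frontier — because published year-by-year scores
are naturally year-relative. A **global** frontier pooling all
unit-periods is available as a configuration option; pooled-form program
statements in the applied literature are ambiguous on this point, so both
are first-class.

## Malmquist productivity change

Output-oriented radial (Shephard) distances `D^s(x, y)` are computed by
LP against the period-`s` frontier; the Malmquist index between
consecutive periods is the geometric mean of the two single-frontier
ratios, decomposed as `Mi = effch × techch` with `effch = pech × sech`.
Conventions:

* Shephard **output** orientation, so `Mi > 1` means improvement;
* `pech` is the VRS analogue of `effch` (two further LPs); `sech` is
  defined residually as `effch/pech`, making both identities exact by
  construction — the tests assert them to machine precision;
* undesirable outputs enter the distance technology as inputs
  (`bad_mode="as_input"`, the standard reduction when a directional
  -distance variant is out of scope) or are ignored;
* cross-period VRS programs can be genuinely infeasible; affected
  components are left undefined and counted, never substituted by CRS
  values.

Aggregation uses **geometric** means for all Malmquist components (the
standard choice for index numbers), per unit over period pairs and per
group/period over units; ranks order units by mean `Mi` descending.
Efficiency scores, by contrast, are averaged **arithmetically** in the
reporting module — verified against the packaged published table, whose
printed per-city averages are reproduced by arithmetic row means under
3-decimal rounding.

## Second-stage Tobit regression

Because the two-stage score is bounded below at 0 while super-efficiency
removes the upper bound, the second stage treats the score as
left-censored at 0 only (`CensorSpec(lower=0, upper=+inf)`), not the
common `[0, 1]` two-sided convention. The pooled censored-normal
likelihood mixes boundary mass `Φ((L − x'β)/σ)` with interior density.
The random-effects panel variant integrates a unit effect
`u_i ~ N(0, σ_u²)` out of each unit's likelihood by Gauss–Hermite
quadrature (default 12 nodes; doubling the nodes moves the default
panel's log-likelihood by < 1e-4, asserted in the tests).

Numerics: parameters are `(β, log σ_u, log σ_e)`; optimization is
L-BFGS-B (monotone under its line search — the iteration trace is
asserted non-decreasing) from least-squares starting values (slopes,
residual SD, `σ_u = 0.1 σ_e`), with `log σ_u` bounded in `[−8, 5]` so a
zero-variance truth drives the estimate to the boundary rather than
overflowing. Standard errors come from the inverse observed information
(numerical Hessian); the β block is parametrization-invariant, and σ
standard errors use the delta method. The Wald statistic is
`b'V⁻¹b` over the restricted coordinates (all slopes by default) against
a χ² reference; p-values for individual coefficients are two-sided
normal. No multiple-testing adjustment is applied. Identification limits
are surfaced, not patched: all-censored responses raise an error, and
with one observation per unit only `σ_u² + σ_e²` is identified (the fit
matches the pooled slopes; the variance split is arbitrary).

Both pooled and random-effects variants are provided; random effects is
the default for panels, pooled the degenerate case.

## Synthetic data generator

The generator emulates the structure the pipeline assumes, with every
piece of ground truth retained:

* inputs `x` log-normal around persistent unit-size levels (SD 0.3 on the
  log scale — administrative capacity varies more across cities than
  within a city over six years);
* a Cobb–Douglas frontier `F_it = drift^t · Π_j x_j^{α_j}` with fixed
  decreasing exponent shares summing to the configured returns-to-scale
  degree (default 1.0) and technology drift 1.03 per period;
* latent efficiency `θ_it = logistic(z_it'β + u_i + ε_it)`, linking
  efficiency to `p = 8` standard-normal covariates through known
  coefficients `β` (defaults mix strong positive, strong negative and
  exact-zero effects), a unit random effect (σ_u = 0.2) and noise
  (σ_e = 0.15) — exactly the random-effects Tobit structure, so the
  second stage is estimating a correctly specified model;
* outputs `y = F·θ` times per-output levels and multiplicative log-normal
  noise (SD 0.05); one undesirable output proportional to production with
  its own noise (SD 0.05);
* `anchor_frontier` (default on) rescales each period's efficiencies by
  the period maximum, so the best unit has `θ = 1` exactly and its output
  noise is suppressed — each period then contains a unit that is both
  truly and measurably efficient.

Default dimensions (41 units × 6 periods, m=3, q=2, h=1, p=8) mirror the
benchmark study's panel. A single integer seed feeds one
`numpy.random.default_rng` stream; regeneration is bit-identical.

What the generator does **not** emulate: spatial correlation between
neighboring cities, serial correlation in covariates, measurement error
correlated with size, heavy-tailed indicators, or any calibration to the
actual yearbook magnitudes (which are not machine-retrievable). Passing
tests therefore demonstrate internal correctness — that the estimators
recover a known truth of the assumed structure at realistic noise — not
that the published city scores would be reproduced from the real inputs.

## Validation strategy and problem sizes

* **Published-aggregation check**: city means, ranks and region averages
  recomputed from the packaged matrix of printed yearly scores match the
  printed Average/Rank columns (±0.001, the printed rounding; three city
  means sit on exact decimal ties that the source rounds down while this
  package rounds half-up — the difference is exactly one unit in the
  third decimal). Ranks match 41/41.
* **Oracle equivalence**: on random instances with n ≤ 4 and m+q+h ≤ 3,
  the LP scores are compared against an independent minimizer of the
  original fractional program. Both SBM stages are piecewise
  linear-fractional in λ once slacks take their constraint-determined
  values, so the oracle enumerates all vertices of the λ-space hyperplane
  arrangement exactly (supplemented by random sampling with Nelder–Mead
  polish); agreement is required within 1e-4 and observed at ~1e-14.
* **Analytic instances**: hand-derived closed forms (dominated score 0.5,
  bad-output score 0.8, super score 2.0, CRS/VRS/scale 0.5/1.0/0.5).
* **Identities and limits**: Malmquist decomposition identities to
  machine precision, output-doubling limit (2, 1, 2), period-swap
  inversion, proportional-frontier-shift recovery.
* **Tobit calibration**: uncensored MLE equals least squares (rel. 1e-4);
  100-replicate recovery at 60 units × 4 periods within 3 Monte-Carlo
  SEs, plus one full-scale 200 × 6 fit within 3 sampling SDs; Wald = z²
  for single restrictions; type-I error of the null z-test within
  binomial bounds of 5%.
* **End-to-end**: the 41 × 6 pipeline completes with Spearman rank
  correlation > 0.8 between true and estimated efficiency (observed
  ≈ 0.92) and byte-identical reruns.

Replicate counts and panel sizes in the test suite (e.g. 60 × 4 panels
with 8 quadrature nodes for the replicate study) are chosen as the
smallest sizes at which the Monte-Carlo bounds are informative; the
full-scale fits use the study dimensions.

## Known limitations

* Super-efficiency under VRS can be infeasible; affected summaries report
  exclusion counts rather than scores.
* The SBM/radial distinction for published CRS/VRS decompositions is an
  open interpretation; only the SBM variant is implemented.
* The Malmquist module implements the contemporaneous-frontiers index
  only (no global, biennial or sequential variants, and no
  Malmquist–Luenberger directional-distance treatment of bads).
* Fixed-effects Tobit is deliberately absent (incidental-parameters
  bias), as are bootstrap/Simar–Wilson second stages.
* The Tobit quadrature is non-adaptive; responses on very different
  scales should be standardized first (an overflow raises an explicit
  error advising this).
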