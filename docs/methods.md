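# Methods

## Effect size and sampling variance

For a control arm (mean `m_C`, SD `s_C`, n `n_C`) and treatment arm
(`m_T`, `s_T`, `n_T`) the effect size is the log response ratio
`lnRR = ln(m_T / m_C)` with the first-order delta-method variance

```
v = s_T² / (n_T m_T²) + s_C² / (n_C m_C²)
```

(Hedges, Gurevitch & Curtis's standard form). Both the signed value and
its magnitude are carried; decline analyses default to magnitude, since
the question is whether effect *strength* shrinks over time, and a signed
analysis is available via `response="signed"`. No small-sample bias
correction is applied, and no other effect-size family is offered.

A property test cross-checks `v` against a numerically propagated
(finite-difference) delta method to four significant figures.

## Zero replacement on bounded scales

`ReplacementPolicy(percentage_c, proportion_c, symmetric_upper=True)`
substitutes `c` for means of exactly 0 and — because a mean pinned at the
ceiling is the mirror-image degeneracy — `bound − c` for means of exactly
100 (or 1). Replacement touches **means only**: SDs are left as reported,
because a bound-valued mean typically comes with SD 0 and the pooling
stage handles that case explicitly (below). Percentage and proportion
scales keep separate constants rather than being rescaled to a common
scale, so each preset's constants can differ per scale. Continuous-scale
records pass through untouched; a continuous mean of exactly 0 makes lnRR
genuinely undefined and raises with instructions to screen the record out.

Interior values are never modified, which yields the key structural
property the sensitivity analysis relies on: on a corpus without bound
values, all policies produce identical effect tables.

## Screening

Rules are pure predicates on flags carried in the corpus (`is_sham`,
`is_fluctuating_co2`, `is_procedural_control`, `direction_opposite`,
`co2_uatm`); the engine never re-derives expert judgements from text.
Exclusions are attributed to the first matching rule in the fixed order
sham → fluctuating CO₂ → procedural control → CO₂ threshold →
opposite-direction, so the audit report reconciles exactly:
`n_input = n_included + Σ per-rule exclusions`. Opposite-direction
handling is an inclusion toggle, not a sign transformation — the signed
lnRR already encodes direction. Procedural-control removal is an
independent toggle: it is enabled in the `unscreened` preset and
disabled in the `screened` presets, so its effect can be isolated rather
than presumed.

## Pooling

Within each publication year (online year by default; print year by
config) effects are pooled by inverse variance. Fixed-effect weights are
`1/v_i`; random-effects mode estimates the between-study variance τ² with
the DerSimonian–Laird moment estimator

```
Q = Σ w_i (y_i − ȳ_w)²,   τ̂² = max(0, (Q − (k−1)) / (Σw − Σw²/Σw))
```

and pools with weights `1/(v_i + τ̂²)`; 95% CIs use normal quantiles.
Random effects is the default because species, behaviours and protocols
differ genuinely across studies; fixed mode is retained and is what the
brute-force oracle tests target. The DL implementation is cross-checked
against `metafor::rma(method="DL")` in the test suite.

Records whose two arms both have SD 0 (typically forced 0-vs-bound
contrasts) carry `v = 0`, which would mean infinite weight. Such
variances are floored to the smallest positive variance in the table; the
flooring is logged and counted (`DeclineTrend.n_floored`). This is a
deliberate, visible choice — any alternative (dropping the records,
imputing SDs) would silently change exactly the records at the heart of
the zero-replacement question.

## Trend and decline metrics

The loess curve (statsmodels `lowess`, degree-1 local linear, default
span 0.75) is fit to the response against year on a 101-point grid; 95%
bands come from percentile bootstrap over records (default 1,000
resamples, default seed 20221122, fully reproducible). Decline strength
is summarised two ways:

* `decline_ratio` — pooled effect over the first two observed years
  divided by the pooled effect over the last two (> 1 = decline). The
  early/late windows are this package's own summary statistic, chosen as
  the smallest window robust to a single anomalous year.
* `weighted_slope` — closed-form weighted least squares slope of the
  response on year with meta-analytic weights `1/(v_i + τ̂²)` (τ̂² from a
  single DL fit over all effects).

`DeclineTrend` requires ≥ 10 effects over ≥ 3 distinct years; smaller
inputs raise with the threshold stated.

## Sensitivity grid

`run_grid` executes screen → effects → trend for every (policy, ruleset)
cell and ranks cells by decline ratio. Each cell's bootstrap seed is
`sha256(master_seed | cell_name) mod 2³¹`, so cells are independent of
grid order and adding a cell never perturbs existing ones. Cells that
empty (or fall below the trend-fit minimum) after screening are marked
degenerate in the comparison table rather than aborting the run.

## Synthetic corpus generator

The generator emulates a decade (2009–2019) of OA fish-behaviour
experiments: 8 studies per year with 2–6 contrasts each (~350 records,
the scale of a ~90-study literature), per-arm n uniform 6–30, coefficient
of variation uniform 0.15–0.5, CO₂ levels uniform 500–1,300 µatm, scale
mix 60% percentage / 20% proportion / 20% continuous.

Each record draws a latent true lnRR `N(μ(year), τ_true²)` independently
(τ_true = 0.3, so random-effects pooling has real heterogeneity to
estimate); sham records draw `N(0, 0.05²)`, fluctuating-CO₂ records are
attenuated ×0.3, and opposite-direction records are negated. The control
mean is drawn uniformly from a baseline interval (5–60% of the bound; the
lower end keeps ratios moderate so tiny *non-zero* values stay rare) and
the treatment mean is `control · exp(latent)`.

Two numerical choices matter here:

* **Bound feasibility by baseline truncation.** When a positive latent
  effect would push the treatment past the ceiling, the baseline interval
  is truncated to the feasible range and the control redrawn — the latent
  draw is kept. Conditioning the baseline rather than the effect leaves
  the latent lnRR marginal exactly `N(μ, τ²)`; rejecting or clamping
  instead would bias accepted effects downward (≈ −0.08 at μ = 1) and
  seed the corpus with spurious bound values. Schedules too extreme for
  any baseline raise after a bounded retry count.
* **Zeros by forcing, with zero spread.** With probability
  `zero_prevalence(year)` (preset: linear 0.4 → 0.02, zeros common early
  and rare late) the smaller bounded-scale mean is forced to exactly 0,
  and with probability 0.3 the larger to the full bound; a forced arm
  gets SD 0, as a saturated assay would. Zeros therefore arise as floor
  effects on an interpretable latent effect, not from a separate
  point-mass model.

The default truth schedule is a gentle linear decline (2.2 → 0.7), the
realistic residual trend for a field testing progressively more species
and behaviours; fixtures for the artifact demonstration use a *constant*
μ = 1 so any measured decline is attributable to zero handling alone.

What the generator deliberately does **not** emulate: study-level
clustering of effects (records are exchangeable given year), sampling
noise on the reported arm means (each record's computed lnRR equals its
latent effect, so pipeline output can be compared to truth exactly),
real-world species/behaviour composition, and publication bias. Passing
tests therefore certify the pipeline's arithmetic and the
zero-replacement mechanism — not that any real corpus is free of those
further complications.

## Numerical and degenerate-input conventions

CSV output uses Python's shortest round-trip float representation, so
write→read is lossless and identical inputs give byte-identical files.
Row validation rejects (with row-level diagnostics) rather than repairs;
missing flags default to False (a record is presumed a genuine OA
contrast unless flagged). SE-vs-SD is declared in the schema config and
SEs are converted at load (`SD = SE·√n`). Years outside the configured
window (default 2009–2019) are rejected at load. Pooling of an empty set,
a comparison over fewer than two shared years, and a trend fit on too few
effects all raise immediately with the violated threshold in the message.

## Known limitations

* Yearly means come from per-year pooling, not a single meta-regression
  with year as moderator; the two differ when years share τ².
* No publication-bias diagnostics (funnel/Egger), no moderators, no
  multilevel (study-nested) models.
* The DL estimator's CIs are mildly anticonservative for very small k;
  the per-year k of the default generator (~30) keeps coverage near
  nominal, as the recovery tests verify.
* The decline metrics are descriptive summaries, not tests; no p-value
  for "decline effect present" is offered.
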