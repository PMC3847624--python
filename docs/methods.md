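# Methods

## Model

listlite projects the percent change in under-five mortality implied by a
change in intervention coverage between a 2010 baseline and a 2013
scenario. The engine is a cause-structured residual model in the Lives
Saved Tool tradition, reduced to its ratio core:

* Under-five deaths are partitioned by cause with fractions `f_c` summing
  to 1; an explicit `other` residual absorbs whatever the named causes
  (malaria, pneumonia, diarrhea, neonatal) leave. The bundled structure is
  malaria 24%, pneumonia 18%, diarrhea 12%, neonatal 22%, other 24%.
* Each (intervention, cause) pair has a potency
  `p = effectiveness × affected_fraction ∈ [0,1]`: the share of that
  cause's deaths the intervention averts among children it reaches.
  At coverage `C` the cause's mortality is multiplied by `1 − p·C`.
* Interventions on one cause combine multiplicatively on residual risk
  (independent action — the standard convention; an assumption, not a
  finding). The scenario-vs-baseline cause multiplier is
  `M_c = Π_i (1 − p_ic C_i^scen) / (1 − p_ic C_i^base)`, the total
  multiplier `M = Σ_c f_c M_c`, and the reported quantity
  `R = 100(1 − M)`.

The ratio formulation makes two properties exact rather than approximate:
`R = 0` whenever scenario coverage equals baseline coverage (the
fixed-coverage scenario), and baseline saturation (`1 − p·C ≤ 0`) is an
explicit error instead of a silent negative death count. `R` may be
negative under coverage decline and is bounded above by
`100 · Σ_{addressed c} f_c`.

There is a single under-five age pool: no month-by-month cohort
demography, no age bands, no birth projections. The engine reproduces
total 2010→2013 percent reductions structurally; absolute deaths averted
would additionally need births and the U5MR anchor (default 184 per 1,000
live births) and are not part of any reported quantity.

## Survey harmonization

Inputs are point estimates (no survey weights, clustering or variance):
up to three anchors per (unit, intervention) — DHS-like 2003, MICS-like
2006, program baseline 2010. Rules, applied in order:

1. **Reference selection.** Among pre-2010 anchors the MICS-like (2006)
   value is preferred as more recent; DHS-like (2003) is the fallback. Two
   estimates from the same source are an error, not a choice.
2. **SBA recomputation.** Skilled birth attendance is recomputed as the
   sum of doctor + nurse + midwife fractions, excluding auxiliary midwives
   and matrones (trained traditional attendants), when a provider
   breakdown is supplied. The category list is configurable; the rule is
   generic even though the shipped config applies it once.
3. **Conflict rule.** If the reference exceeds the 2010 baseline, the
   apparent decline is treated as a sampling-frame artifact (national
   rural reference vs district rural baseline) and the pre-2010 trend is
   flattened at the 2010 value. Equality is not a conflict (flat either
   way). A unit with no reference anchor at all gets the same flat
   fallback.
4. **Interpolation.** Linear between anchors, exact at anchors, on integer
   calendar years (a year value means mid-year status); queries outside
   the anchor span are errors — extrapolation beyond 2010 belongs to the
   scenario builder. Units lacking their own pre-2010 anchors borrow the
   national (`all`) reference with their own 2010 baseline.
5. **Proxy coverage.** Interventions not measurable in household surveys
   can be assigned the coverage of a measured contact indicator (ANC4+ or
   SBA) times a factor in [0,1], default 1.0 — the reference software's
   linkage coefficients are not public, so the identity is a documented
   placeholder.

Coverage is a fraction in [0,1] internally; all CSV I/O and rendered
tables use percent, avoiding unit drift in the engine.

## Scenarios (2010–2013, annual, linear)

* **fixed**: constant at the 2010 value.
* **scale_up**: program interventions below target follow the straight
  line hitting the target exactly in 2013 (the endpoint is assigned, not
  interpolated, so no float drift). Pre-achieved targets continue at the
  pre-2010 annual rate, floored at zero (never decreasing) and ceilinged
  at max(cap, baseline) — the cap is reused here for consistency even
  though the continuation rule alone does not state one. Non-program
  interventions are held at 2010 values.
* **secular_trend**: `c(t) = clamp(c2010 + r·(t−2010), 0, max(cap, c2010))`
  with `r = (c2010 − c_ref)/(2010 − ref_year)` from the resolved anchors
  (flattened conflicts give r = 0). The cap defaults to 0.90. Negative
  rates are permitted and floor at zero: scenario math is total even
  though the conflict rule removes most declines upstream.
* **Rate substitution**: a map `intervention → donor` replaces an
  uninformative pre-2010 rate with the donor's; shipped config:
  ACT ← oral antibiotics (an antimalarial drug-policy transition made the
  ACT history meaningless). The operation is idempotent.

Scenario endpoints (2010, 2013) are what the engine consumes; trajectories
are emitted at integer years for reporting only.

## Decompositions

* **Attributable reduction**: `R(scale_up) − R(secular)` in percentage
  points, per unit; may be negative.
* **Isolation**: each intervention moved alone, all others at baseline.
  Isolation values need not sum to the joint R (interventions sharing a
  cause compete for the same deaths; the joint R is sub-additive).
* **Simultaneous shares**: each cause's log-multiplier is exactly additive
  over interventions, so it is shared out proportionally to each
  intervention's own log-multiplier on that cause and mapped back through
  the cause's contribution `100·f_c(1 − M_c)`. Shares sum to the joint R
  to machine precision; a cause whose total log-multiplier is zero
  contributes nothing and its (zero) deficit is not attributed.

## Microsimulation oracle

An independent check on the closed-form engine, embodying the same
assumptions child by child: `n` potential death events per arm are
allocated to causes multinomially by `f_c`; within a cause each acting
intervention is received independently with probability equal to its
coverage and, if received, independently averts the death with probability
`p`. Because `f_c` describes *baseline* deaths, arms are compared cause by
cause: the estimate is `100(1 − Σ_c f_c · ratio_c)` with `ratio_c` the
simulated scenario/baseline death ratio. (Pooling causes before taking the
ratio would re-weight causes by their baseline coverage and converge to a
different quantity — this was caught by the oracle-vs-engine test during
development.) The standard error combines per-cause delta-method variances
of binomial ratios, with death probabilities floored at one pseudo-event
so the SE stays finite on small samples. Seeded `numpy` generator;
identical seeds give bit-identical results.

## Synthetic studies and what they show

`listlite.synthetic` generates complete studies shaped like the emulated
evaluation design: default 9 districts in 2 regions plus two pooled
intervention-group strata and an all-districts unit (14 units), 8 generic
interventions, three anchors per unit. Per (unit, intervention) it draws a
2010 baseline (default U(0.10, 0.60)), a pre-2010 rate (default
U(0, 0.05)/yr), and with probability 0.2 inverts the 2006 anchor above the
2010 value so the conflict rule is routinely exercised; anchors are
back-computed on the drawn line and clipped to [0,1], with the effective
rate recomputed from the clipped anchor. Targets default to U(0.50, 0.90);
effectiveness entries cycle the four named causes with effectiveness
U(0.3, 0.7) and affected fraction U(0.5, 1.0). Ground-truth reductions are
computed with self-contained closed-form arithmetic in the generator —
deliberately not by calling the scenario or impact modules — so the
pipeline-vs-ground-truth comparison is a dual-route check, exact to 1e-9.

What passing these tests does *not* show: anything about survey noise,
design effects, nonresponse, district correlation structure, nonlinear
scale-up shapes (e.g. step-function bed-net campaigns), vaccine herd
effects, or the accuracy of any particular effectiveness value. The
generator produces point estimates because the emulated analysis consumes
point estimates.

## Bundled study

The packaged 14-unit study carries the published pooled baselines and 2013
targets and the published cause structure. Synthetic, clearly labeled
parts: the 2003/2006 national-rural anchors (mild positive trends, one
deliberate vitamin-A conflict), the ANC4+/SBA pooled baselines (34%, 54%),
per-district variation (Normal(0, 0.06) jitter around pooled values from a
fixed internal seed, clipped to [0.02, 0.95]), and the whole effectiveness
table (literature-magnitude approximations). Where two published tables
disagree on the antibiotics target (50% vs 60%) the fixture follows the
table whose gap arithmetic the tests reproduce (60%). The four
neonatal-care interventions that real LiST proxies from ANC/SBA are
carried with their printed baseline→target pairs rather than chained
dynamically to the ANC/SBA trajectories, since the linkage coefficients
are unpublished. Consequently mortality outputs on this study are
structural reproductions (fixed R = 0; scale-up > secular everywhere;
treatment interventions ranked ACT > ORS > antibiotics; raising all
targets to 90% nearly doubles the joint reduction), not numeric ones.

## Numerical choices

* Exactness where the model promises it: fixed-scenario R, scale-up
  targets in 2013, anchor values under interpolation — assigned, not
  recomputed through float arithmetic.
* Tolerances: 1e-9 for conservation/recovery assertions, 1e-12 for pure
  identities, 3 Monte Carlo SE for oracle agreement.
* Tie-breaks: reference-vs-baseline equality is not a conflict;
  `resolve_decline` uses strict inequality. Scenario ordering in all
  outputs is fixed, scale_up, secular_trend; units keep input order.
* Degenerate inputs are errors, not silent defaults: empty reference
  sets, duplicate sources, out-of-span interpolation, missing substitution
  donors, baseline saturation, non-unit cause sums (beyond 1e-9).

## Problem sizes

Defaults used throughout the tests and examples: 14 units × 14 (bundled)
or 8 (synthetic) interventions, 11-year horizon; oracle checks at
n = 10⁶ children per arm over 20 random configurations; recovery over 10
seeds. The full suite runs in a few seconds on one CPU.
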