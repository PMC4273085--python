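# Methods

This note documents the model implemented by `avert`, the assumptions
behind it, the choices made where the design was genuinely open, and
what the synthetic-data generator does and does not emulate.

## The counterfactual decomposition

The analysis splits observed injury burden in each stratum (age group ×
sex × super-region × cause) into a surgically avertable part and a
non-avertable remainder. The counterfactual state is full population
access to a basic surgical package; it is operationalised empirically as
the best outcome observed anywhere across epidemiologic regions, on the
argument that inter-regional differences in case fatality and in
disability per case — after removing prehospital mortality — reflect
gaps in surgical care rather than differences in injury severity.

### Fatal burden

Let `CFR = deaths / incident cases` in a stratum and `π` the proportion
of injury deaths occurring before hospital arrival. The decomposition

    CFR = d + (1 − d)·h,   d = CFR·π,   h = CFR·(1 − π) / (1 − CFR·π)

splits overall case fatality into the prehospital death rate per
incident case `d` and the in-hospital case-fatality rate among arrivals
`h`. Both components lie in [0, 1] whenever `CFR ∈ [0, 1]` and
`π ∈ (0, 1)`, and `d + (1 − d)·h` recomposes `CFR` exactly.

The counterfactual CFR keeps the target's own prehospital mortality
(those deaths are not amenable to surgical care) and substitutes the
cross-region minimum in-hospital rate:

    h*(age, sex, cause) = min over regions of h
    CFR′ = d + (1 − d)·h*

Three choices deserve comment:

- The minimum is taken on `h`, after decomposition, not on the raw CFR.
  Comparing raw CFRs would conflate prehospital mortality differences
  with care quality, defeating the purpose of the adjustment.
- The minimum is element-wise per (age, sex, cause) cell over all
  regions, not a single globally best region; regions are compared at
  the resolution the data support.
- The target super-region's own aggregate `h` participates in the
  minimum. This guarantees `CFR′ ≤ CFR` structurally (the case-weighted
  aggregation of member regions could otherwise interact with the π
  weighting in pathological inputs), and is a no-op whenever some region
  is uniformly best.

Counterfactual deaths are `cases × CFR′`; counterfactual YLLs multiply
by standard remaining life expectancy at the age group's label (age
groups are closed-open intervals labelled by lower bound, and the life
table is keyed by the same labels, avoiding midpoint ambiguity).
Avertable = observed − counterfactual, floored at zero; causes in the
non-amenable set (drowning, poisoning, self-harm, venomous animal
contact, other intentional injury — overridable via config) are forced
to zero avertable burden. Cells observed in a single region only get
`CFR′ = CFR` (zero avertable) with a warning; strata without incident
cases are skipped silently.

### Prehospital proportions

Study-level records (prehospital deaths / all deaths) are pooled on the
logit scale with delta-method variances `1/e + 1/(t − e)`; studies with
zero or all events receive a 0.5 continuity correction on both cells.
Between-study variance τ² uses the DerSimonian–Laird moment estimator
generalised to a regression design (residual Q from the fixed-effect
weighted fit, scaled by the trace of the weighted projection
complement), followed by a second weighted pass with weights
`1/(v + τ²)`. Covariates: super-region (sum-to-zero coding, so the
intercept is a global mean and regions without data predict from the
intercept alone), sex (±1/2 male/female contrast; "both" sits at the
intercept), and centred study age. Constant covariates are dropped — the
design would be singular — with a warning for an explicitly coded
constant sex. Predictions are clamped to (1e-6, 1 − 1e-6). Pooling is
cause-specific when at least three studies report a cause group, with an
all-injury model as fallback; this threshold is a pragmatic minimum for
a random-effects fit and is configurable.

This estimator is a transparent stand-in for a full Bayesian
meta-regression: it preserves the role of the pooling step (shrinkage
across studies, covariate structure, extrapolation to regions without
data) in a closed form that can be verified against textbook formulas.

### Nonfatal burden

YLDs are organised by nature of injury. For each (age, sex, nature) cell
the counterfactual YLD per case is the minimum over regions of
`YLD / cases warranting care`; counterfactual YLD is that minimum times
the stratum's cases. Which natures "warrant care" is an explicit flag
per nature, defaulting to all — the data do not identify the subset, so
the assumption is kept visible and testable.

Because no cause-to-nature matrix exists for the avertable component,
avertable YLDs return to external causes through proportional
allocation: each super-region's avertable fraction
`A = (ΣYLD − ΣYLD′) / ΣYLD` (computed over natures) multiplies the
region's all-cause YLD total, and the pool is distributed over amenable
causes proportionally to their observed YLDs. Non-amenable causes
receive nothing, which implicitly redistributes their share to amenable
causes. The allocation conserves the pool and gives every amenable cause
in a region the same avertable-YLD share — the signature visible in
published tables where one percentage repeats down a region's YLD
column.

`A` is computed at super-region level by default. A finer
region × age × sex granularity is available, but only the region-level
fraction reproduces the equal-shares signature, so it is the default.
A cap-and-respread pass guards the invariant `allocated ≤ observed` per
cause: any excess over a cause's observed YLD is capped and re-spread
over the remaining amenable causes (at most one pass per cause). With
weights proportional to observed YLDs the cap cannot actually trigger
below the saturation boundary (the share ratio is uniform across
causes), so this is a safety net for alternative weightings; a pool
exceeding the total amenable YLD is an error, as it indicates inputs
where non-amenable causes dominate nonfatal burden beyond what the
allocation rule can absorb.

### Assembly and reporting

DALY = YLL + YLD in each of the observed, counterfactual and avertable
states, enforced at construction to 1e-9 relative. Avertable proportions
are avertable/observed at any margin (cell, region, cause, overall);
margins sum numerator and denominator before dividing, so aggregation
and proportion-taking commute. Zero observed burden yields a missing
proportion, never zero. Presentation rounding — burden to 0.1 million,
proportions to whole percent, decimal half-up — lives in one function
and never feeds back into computation. Report files are deterministic:
identical inputs give byte-identical CSV/JSON.

## Numerical choices

- Avertable values in `[−1e-9 · max(1, observed), 0]` are clamped to
  zero (floating-point residue of the decompose/recompose cycle); larger
  negatives raise, since they indicate an invariant violation. The
  tolerance is relative because burden magnitudes span ~10 orders.
- Ties in headline rankings break lexicographically with an explicit
  tie flag.
- Rounding is decimal half-up, isolated in `reporting.round_half_up`.

## The synthetic generator

`avert.synthetic` generates complete input bundles with analytically
known avertable burden. In-hospital CFR is `base × age × sex × cause
profiles × γ_r`, with care-gap factors γ_r ≥ 1 and one designated best
region at γ = 1, so the cross-region minimum is attained by a known
region and the ground truth is closed-form. Observed CFR follows from
`CFR = h / (1 − π(1 − h))`. Prehospital proportions are logit-normal
across super-regions (τ = 0.3 about a mean near 45%) with a +0.25 logit
male–female contrast — additive on the logit scale, matching the
meta-regression's structure. YLD per case varies by region through
δ_r ≥ 1 with the same best region. Cause-to-nature matrices are
symmetric-Dirichlet rows (concentration 5). Incident cases are expected
values, not sampled — the pipeline is deterministic given rates, so
stochasticity enters only through the binomial study records, where the
real analysis had an estimation step. Amenable causes carry 80% of
incident cases by construction; together with δ ≤ 2 (so A ≤ 0.5) this
guarantees the avertable YLD pool always fits inside the amenable causes
that receive it.

Default scale: 21 regions in 7 super-regions, 6 broad age bands labelled
by lower bound (0, 5, 15, 30, 45, 60) with a standard life table
(86.0 → 27.8 remaining years), 11 causes (6 amenable), 10 natures, 8
studies of 200 deaths per super-region × sex stratum. The broad age
bands keep tables compact while exercising the age-specific life-table
and minimum-taking logic; the statistical-recovery checks use 50 studies
of 500 deaths, a scale at which the meta-regression pins π tightly.

What the generator does **not** emulate: real GBD magnitudes or age
patterns, missing strata and ragged region coverage, correlation between
care gaps and prehospital mortality, cause-specific π patterns,
uncertainty intervals, and model misspecification of the π surface (the
true π is exactly additive on the logit scale). Passing recovery tests
therefore demonstrates correctness of the decomposition arithmetic and
the estimation plumbing under a well-specified model — not robustness to
the messiness of real extracts.

A note on the "zero gap ⇒ zero avertable" invariant: with the
meta-model bypassed it holds exactly (up to the clamp); with fitted
proportions, finite-sample error in π̂ perturbs the decomposed h across
super-regions, leaving a strictly positive but vanishing avertable
residue (≪ 1e-6 of observed deaths at default scale). Tests assert
exact zero in bypass mode and a small absolute bound in fitted mode.

## The published-estimates fixture

`avert/data/published_avertable.csv` transcribes a published grid of
avertable deaths, YLLs, YLDs and DALYs (six LMIC super-regions × six
amenable causes) with printed avertable percentages and margins. The
observed denominators are not published; where needed they are
reconstructed as `avertable / (percent/100)` — precise only to the
whole-percent rounding of the source, and only valid from margin rows
for region-level totals (the source omits non-amenable causes, so cell
sums understate a region's all-injury burden). Consistency checks
verify cell-sum/margin agreement (within 3 units) and YLL + YLD = DALY
per cell (within 2 units, reflecting independent rounding of the
printed components).

## Known limitations

- The lowest observed rate may itself fall short of the true
  full-access counterfactual; the estimate is conservative in that
  direction but assumes regional rate differences are attributable to
  care access.
- Proportional YLD allocation can over- or under-assign avertable
  nonfatal burden between causes; region totals are unaffected.
- No uncertainty propagation: all quantities are point estimates.
- The DerSimonian–Laird stand-in ignores estimation error in τ² and has
  no spline age pattern; cause-specific pooling needs ≥3 studies.
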