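# Methods

## The estimation problem

Dental age (DA) is the developmental age implied by the state of the
permanent dentition, read from a panoramic radiograph. Two estimators are
implemented. Both consume *observations* (apex status, root fractions,
formation stages) — staging teeth from images is out of scope.

### Stepwise apexification ladder

Permanent teeth are grouped by eruption timing into an ordered ladder
(groups G1…G8 plus two excluded groups); each assessed group carries a DA
value or range. Root apex closure — the disappearance of the apical
papilla — follows functional eruption by roughly three years and is the
least ambiguous landmark on a radiograph. The estimate is the DA of the
last group in which every assessable member tooth shows a closed apex.

Decisions the published procedure leaves open, and how this package takes
them (all configurable):

* **Group closure** requires *all* assessable member teeth closed; any open
  member blocks the group. A group with no assessable member is `unknown`.
* **Bilateral fallback** (default on): an unassessable tooth inherits its
  contralateral partner's status — dental development is strongly
  symmetric. With both sides unassessable the group stays unknown.
* **Unknown groups are skipped** when extending the closed prefix (G2
  unknown but G1 and G3 closed → answer from G3, flagged
  `incomplete_data`). Refusing to estimate on any missing tooth would make
  the method clinically unusable; the flag preserves auditability.
* **Inconsistent sequences** (a closed group above an open one) return the
  closed-prefix answer with an `inconsistent_sequence` flag rather than an
  error; such dentitions occur under reading noise and atypical development.
* **Range collapse**: a range rung (e.g. 12–13 y) is reported as its
  midpoint by default (`collapse="low"|"mid"|"high"`); the procedure's
  source never states its own collapsing rule.
* **Excluded groups** (maxillary lateral incisors; mandibular second
  premolars) never affect the result under defaults. The maxillary laterals
  can be assessed on request (`include_maxillary_laterals`), adding a
  10.5–11 y rung — useful when they are the last closed set.

The ladder validates on construction (indices 1..n, strictly increasing DA
midpoints, non-decreasing endpoints) and round-trips through CSV so other
populations' eruption data can be dropped in without code changes. Note the
printed DA values make `da_low` only *non*-strictly increasing (9, 9, 9.5,
…); midpoints are what is strictly ordered.

### Sub-nine fallback

If G1 (mandibular central incisors) is open, the subject is below the
ladder's floor and the estimate interpolates root fractions: tooth *t* with
fraction *f* contributes `root_start_t + f · (apex_t − root_start_t)`; the
estimate is the mean over contributing teeth, always flagged
`low_confidence`, and `sub_nine` exactly when the whole contribution range
lies below 9 y. Default anchors derive from the ladder: `apex_t` = group DA
midpoint and `root_start_t = apex_t − 6`. The 6-year linear root span puts
the root at one-half length three years before closure, i.e. at functional
eruption, consistent with teeth erupting with one-half to two-thirds of
their final root. Anchors are an editable table (population-specific
replacement is the intended use).

### Demirjian staging engine

A pure table engine: per-sex stage scores for teeth 31–37 (stages A–H plus
UNFORMED = 0) are summed into a maturity score and converted to DA by
piecewise-linear interpolation on per-sex (score, age) knots. Published
standards interpolate percentile *curves*; linear interpolation between
published knots is the standard practical reading. Validation enforces
non-decreasing scores across stages, strictly increasing conversion knots in
both coordinates, and an all-H total ≤ 100. Scores outside the curve's
support clamp to the end knots with `low_confidence`. A missing tooth is a
hard error — the method defines no substitution.

The packaged table (`data/maturity_table_synthetic.csv`) is **synthetic**:
its stage scores are smooth self-weighted fractions of per-tooth maxima
summing to 100, and its conversion knots invert the simulator's default
staging thresholds so that simulated cohorts map back to roughly their
simulated ages. It exists so the pipeline runs and is testable; any real
analysis must supply a published population standard.

## Comparison statistics

* **Bias tables**: strata are (floor(CA), sex) — flooring into integer age
  groups is an assumption, stated here because reporting conventions vary.
  Means and sample SDs (n−1); difference columns are computed from
  *unrounded* means; single-subject strata report an undefined SD; empty
  strata are emitted with n = 0. Per-stratum Wilcoxon p-values are raw — no
  multiplicity adjustment, matching the reporting style of the tables this
  layout mirrors. p-values render to 3 decimals with `<0.001` flooring.
* **Wilcoxon signed rank**: W⁺ with midranks; zero differences are
  discarded by default (Wilcoxon's policy; Pratt available). Exact
  two-sided p for n ≤ 25 by convolution over the 2^n sign assignments
  (midranks are doubled to integers, so ties are handled exactly); above
  that, the normal approximation with tie correction (Σr²/4 as the variance)
  and a 0.5 continuity correction toward the mean. The exact and
  approximate branches agree to < 0.02 in p around the cutoff, and the
  approximation's null rejection rate at α = 0.05 sits within the binomial
  99% band for 2000 replicates (both under test).
* **Correlation/regression**: `scipy.stats` Pearson r (t-based p, n−2 df)
  and OLS. Slope equality between two methods on the same subjects is the
  interaction term of a stacked `y ~ x * method` OLS fit (statsmodels);
  identical outcome vectors short-circuit to p = 1 since the interaction is
  identically zero and its standard error degenerates.
* **ICC**: `pingouin.intraclass_corr` supplies the six-form
  McGraw–Wong/Shrout–Fleiss panel. The default report is ICC3 single
  (two-way mixed, consistency): examiners are fixed and named, and a level
  offset between them is reported separately (ICC2 captures absolute
  agreement) rather than silently degrading reproducibility. Missing cells
  are an error — no imputation. Tests pin the estimator to a from-scratch
  two-way ANOVA mean-squares oracle.

## The simulator

What it emulates: a cross-sectional cohort on an age×sex design (default:
377 subjects, ages 8–15, the study-style cell counts), with

* CA ~ Uniform(age, age+1) within each integer cell;
* a shared per-subject maturation tempo δ ~ N(0, σ_subj), σ_subj = 0.5 y —
  the minimal structure making both method-bias and reliability simulations
  meaningful;
* per-tooth closure `μ_t − 0.25·[female] + δ + ε_t − Δ`, ε_t ~ N(0, 0.35 y);
  females run 0.25 y ahead by default; Δ > 0 models a systematically
  advanced population (default 0);
* default μ_t anchored to the ladder midpoints; teeth outside the ladder
  (maxillary laterals 10.75 y, second premolars 13.75 y) get closure ages
  between neighbouring rungs;
* open teeth expose a root fraction growing linearly over 6 y to closure
  (the same geometry the sub-nine anchors assume, so that path is exactly
  calibrated);
* Demirjian stages entered at fixed offsets (−9…−2, 0 y) before each
  tooth's closure — stage H coincides with apex closure;
* rater noise: within ±1 y of a tooth's closure age the reading flips with
  probability p_err (default 0.05); a closed→open misread carries fraction
  1.0 (a just-open apex on a full root). Staged teeth independently slip
  one stage with probability p_err. Raters may carry a persistent bias on
  perceived closure ages (σ = `rater_bias_sd`, default 0), which separates
  intra- from inter-rater reliability.

Randomness: one master seed; every subject draws from a
`SeedSequence(seed, spawn_key=(domain, age, sex, index-in-cell, …))`
stream, so enlarging one design cell never perturbs any other cell.

**What the simulator does not emulate**, hence what passing tests do not
show about real data: real closure-age distributions (the defaults anchor
to the ladder's own DA values, which is circular by design — it tests the
machinery, not the population), left/right asymmetry, correlated stage
misreads, missing teeth, or image quality. Simulator-based results validate
the pipeline's mechanics and sensitivities, not clinical accuracy.

### A structural note on ladder bias

With closure ages set exactly to the ladder midpoints, the ladder estimate
is the last rung at or below the subject's (noisy) maturation age — a step
function. Because the rungs are unevenly spaced (nothing between 10 and
12–13), subjects aged ~10–12.5 are necessarily read as DA 10, and the mean
bias over the default design is ≈ −0.7 y. No parameter setting of this
faithful mechanism removes that: it is a property of the coarse ladder, not
an implementation defect. What *is* recoverable — and is asserted in the
acceptance suite — is the differential effect: injecting a Δ = +1.0 y
population advancement shifts the mean ladder bias by +1.0 ± 0.25 y
(measured +0.88 y at the default noise levels), the mechanism by which an
advanced population produces the overestimation such studies observe.

## Problem sizes and numerical choices

Test and acceptance runs use: all 3^8 = 6561 group-state vectors for the
rule-engine oracle and monotonicity sweeps; 2000 null replicates at n = 30
for Wilcoxon type-I calibration; 500 subjects × 6 replicate ratings for ICC
recovery (the 6-rater panel narrows the ICC sampling error enough to
resolve a ±0.05 band at ρ = 0.5); the full 377-subject design for the
Δ-recovery check. Results round-trip CSV at 6 decimals. Floating-point ties
in the ladder (CA exactly at a closure age) read as closed (`>=`).

## Known limitations

* The ladder saturates at 15 y and is silent below ~9 y; estimates outside
  8–16 y are out of its design range.
* The sub-nine path is subjective in real use; the linear-root model is a
  first-order account and its anchors must be recalibrated per population.
* The packaged maturity table is synthetic; Demirjian outputs are only as
  good as the table supplied.
* No population recalibration is *estimated* anywhere — users supply new
  ladder/anchor/maturity tables; the package does not fit them.
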