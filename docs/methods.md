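# Methods

`trialae` quantifies how adverse-event (AE) burden in clinical trials
varies with participant age, using only arm-level summary counts of the
kind public trial registries publish.  This note records the statistical
model, the conventions chosen where the problem was genuinely open, what
the synthetic-data generator does and does not emulate, and the numerical
details a maintainer would need.

## Units of analysis

The registry reports AEs per **trial arm**: for each event, the number of
participants affected and at risk.  Individual participants are not
identifiable, so everything here is computed at arm (or trial) level.

Arms are assigned to eight age bins by their reported mean age: seven
10-year bins `[0,10), [10,20), …, [60,70)` and a terminal closed bin
`[70,100]`.  Half-open bins are our convention for decade boundaries (a
mean age of exactly 30 falls in 30-39); the terminal bin includes 100.
Arms with no reported mean age, or a mean age outside `[0,100]`, are
excluded from group analyses and enumerated in an exclusions report.
Binning uses the arm-level mean age because every downstream statistic is
arm-level; no re-weighting for within-arm age spread is attempted.

## Incidence

Within an age group the headline rate is the **micro-average** (pooled
proportion)

    p̂_g = Σ_arms affected / Σ_arms enrolled ,

with a Wald 95% CI `p̂ ± 1.96·sqrt(p̂(1−p̂)/N)`.  The z multiplier is fixed
at 1.96 for the 95% level (matching the printed arithmetic of the
summaries we reproduce); other levels use the exact normal quantile.

The per-arm "affected overall" numerator uses the registry total when
reported.  When absent, the fallback is the **maximum** `subjects_affected`
over the arm's events — a true lower bound (participants counted for one
event are certainly affected overall; overlap between events cannot be
recovered from arm-level tables).  The provenance flag
(`reported`/`lower_bound`) is carried with the value.

Groups are contrasted against a reference group (default 20-29 years, the
lowest-incidence group; configurable) by:

* **risk difference** of micro-averages, `p̂_a − p̂_b`, with
  `SE = sqrt(p̂_a(1−p̂_a)/N_a + p̂_b(1−p̂_b)/N_b)`;
* **rate ratio** `p̂_a / p̂_b` (undefined, reported as NaN, for a zero
  reference);
* a two-sided **Welch t-test** on the per-arm incidence values, with
  Welch–Satterthwaite degrees of freedom.  Welch was chosen over the
  pooled-variance test because group arm counts and variances differ by an
  order of magnitude; a config switch (`unit="trial"`) first averages arms
  within a trial for an incidence-per-study reading.

No multiplicity correction is applied across the seven group-vs-reference
tests; the group contrasts are descriptive.

## Diversity

The **diversity** of an arm is its number of distinct AE types: an arm
reporting heart failure, dizziness and nausea has diversity 3.
Distinctness is decided on canonical term strings — lower-cased,
punctuation replaced by spaces, whitespace collapsed — so spelling variants
of one term count once.  Concept-level synonymy (two different words for
one condition) is out of scope for the normalizer; the term table can alias
synonyms by mapping them to the same organ class, and the limitation is
inherited by every diversity number.

Group diversity is the arm-level mean with `SE = sd/√n_arms` and a Wald
95% CI; a single-arm group reports its mean with SE and CI flagged
unavailable.

The per-organ-system view maps each distinct term to one of the 26 MedDRA
system organ classes (SOCs) through an exact-match lookup table; a
registry-provided SOC code on the event wins over the table, and unmapped
terms go to an `UNCLASSIFIED` diagnostic row kept outside the 26-row
matrix.  This makes the decomposition conservative and exact: per arm,
total diversity = Σ per-SOC diversities + unclassified count.  Cell
(s, g) of the matrix is the mean over **all** of group g's arms of the
distinct-type count in SOC s (arms with no events in s contribute 0).
Support is the number of distinct **trials** (not arms) with ≥1 event of
the SOC in the group; cells under 30 trials are flagged low-support.

Rankings within each age group use competition ("min") ranking by
descending diversity — tied values share the smallest applicable rank and
are flagged.  The total rank orders SOCs by the unweighted mean of their
eight group values; rank-sum is available as an alternative reading but
the unweighted mean is the default.

The shipped 26-name SOC vocabulary predates the 2016 addition of "Product
issues"; no events map to that class here.

## Per-event group contrasts

For each (event, age group) pair, the **target** sample is the set of
trials whose in-group arms report the event, each contributing its mean
event incidence (affected/at-risk averaged over those arms); the
**comparison** sample is the set of trials reporting the same event only
through arms outside the group.  A trial with arms on both sides is
assigned to the target side exclusively — disjointness is required for a
valid two-sample test.  Within a trial, arms are averaged (not pooled by
participants); pooling is a config alternative.

The two samples are compared with the same Welch t-test; events with
`p < α` (default .01) whose target mean exceeds the comparison mean are
ranked within each group by ascending p, ties broken by descending target
incidence, after removing terms on a user-supplied filter list of commonly
shared nonserious events.  The packaged filter list is a small placeholder
(headache, fatigue, nausea, nasopharyngitis, diarrhea) that illustrates
the mechanism; real analyses should supply their own.  An optional
Benjamini–Hochberg correction is deliberately off by default, matching the
raw-threshold selection this analysis descends from.

**Small-sample caveat.**  For rarely reported events the per-trial
incidence sample is small and skewed (trials enter only if they report the
event), and the t approximation is anticonservative: in null simulations,
pairs backed by 2-4 trials per side reject at ~10× the nominal 1% level,
while pairs backed by ≥30 trials are calibrated.  The calibration suite
therefore runs at a registry-like scale (1,500-trial cohorts) where tested
pairs have adequate support; selections backed by a handful of trials
should not be taken at face value.

## Synthetic cohorts

The generator emulates the registry data structure: trials with 1+ arms;
per-arm enrollment (uniform integer in a configurable range, default
50-200) and mean age (uniform inside the drawn age bin, so bin recovery is
exact by construction); per-event affected/at-risk counts; a serious flag
per term; and optionally the registry convention of omitting nonserious
events that never exceed a 5% frequency in any arm of a trial.

Mechanics are participant-level per arm: an enrollment × events Bernoulli
matrix with the arm's group-specific event probabilities.  Column sums give
`subjects_affected`; the rows with any event give a consistent
`overall_affected`; zero-count events are omitted.  Events are independent
across participants and types — no comorbidity correlation — so the
pipeline's statistics are exactly recoverable but correlation-driven
features of real data (event co-occurrence, overdispersion beyond
binomial) are not represented.  Passing tests demonstrate correctness of
the computations, not realism of trial-to-trial heterogeneity.

When a per-group overall incidence `p_g` is configured, event
probabilities are rescaled by a common factor (bisection to machine
precision) so that `1 − Π_j(1 − q_j) = p_g` exactly, preserving relative
differences between events.  The ground-truth file records the resolved
per-event probabilities, the exact overall incidence, and the expected arm
diversity `E[Σ_j (1 − (1−q_j)^n)]` averaged over the enrollment range —
sufficient to score parameter recovery without re-deriving anything.

Defaults are illustrative, not calibrated to any corpus: ~80 common AE
terms spread over the 26 SOCs with base probabilities from 0.2% to 10%;
group weights skewed toward middle-aged adult trials; an incidence profile
peaking in young children and the fifties with a trough in young adults;
and rare-event multipliers rising with age so diversity grows across
groups at comparable incidence.  The serious fraction defaults to 0.10 and
the reporting threshold to 0 (off); 0.05 reproduces the registry
convention.

## Numerical and testing choices

* All computation is done at full precision; reports round percentages and
  ratios to 2 decimals (CSV cells to 6).
* Degenerate t-test inputs (a side with <2 values, or zero variance in
  both) yield flagged results without p-values rather than NaNs.
* Determinism: one `numpy` generator seeded from the config; identical
  inputs and configuration produce byte-identical cohorts and reports (the
  run manifest contains no timestamps).
* Test problem sizes: oracle-equivalence checks use 100 ten-trial cohorts;
  parameter recovery uses one 200-trial cohort (all eight groups within 3
  SEs); Welch calibration uses 1,000 two-sample replicates; the null
  event-discovery suite uses 50 cohorts of 1,500 trials; the spiked-event
  power check uses 12 replicates of 200-trial cohorts.  These sizes give
  each check comfortable statistical resolution while keeping the full
  suite to a few minutes.

## Known limitations

* Diversity is arm-level by necessity; per-patient event multiplicity is
  unobservable in registry summaries.
* The max-over-events fallback for missing overall-affected totals is a
  lower bound and is flagged, but mixes of reported and bounded arms will
  bias a group's micro-average downward.
* Exact-match term mapping cannot classify unseen spellings or synonyms;
  coverage is whatever the supplied table provides.
* The per-event t-test miscalibration on tiny trial samples described
  above.
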