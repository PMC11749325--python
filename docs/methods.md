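# Methods

This note documents the statistical procedures, parameter choices, and
limitations of the `neohai` analysis pipeline.

## Case definitions and reference standard

Each suspected-HAI episode is labelled from its blood culture, CRP, and
antibiotic course:

* **Proven HAI** — a known pathogen isolated from blood collected after 72 h
  of admission with clinical signs; or coagulase-negative staphylococci
  (CoNS) adjudicated as infection: two positive cultures 24–48 h apart, or a
  single positive culture with CRP ≥ 10 mg/L and clinical signs.
* **Presumed HAI** — negative (non-probative) culture, CRP ≥ 10 mg/L,
  antibiotics continued ≥ 5 days.
* **No HAI** — negative culture, CRP < 10 mg/L, short-lived symptoms,
  antibiotics stopped within 48–72 h.

"Any HAI" (proven ∪ presumed) is the reference standard for all accuracy
metrics. The definitions cite the *serum* (laboratory) CRP, so the episode
schema carries an optional `lab_crp` column; when it is absent the
point-of-care t0 value stands in. Contaminant organisms — including CoNS
adjudicated as contamination — make the culture *non-probative* and route
the episode through the culture-negative branches. The three definitions do
not partition every conceivable field combination (e.g. CRP ≥ 10 with
antibiotics stopped early); such episodes are returned as an explicit
unclassifiable outcome with the conflicting fields, counted, and excluded
from accuracy denominators. Every record enrolled is by construction an
investigated suspected-HAI episode, so "clinical symptoms of infection" in
the presumed branch is implied by enrolment rather than a separate flag.

## Candidate tests and the decision tool

All threshold comparisons are inclusive (≥) with no tolerance band: CRP
positivity is value ≥ 10 mg/L (cutoff configurable), NeoHoP positivity is
total ≥ 2 (threshold configurable 1–5). Tests return a tri-state; a missing
measurement yields *not evaluable* rather than a default side of the cutoff,
and not-evaluable calls are excluded from denominators. Specifically:

* serial CRP (`crp_t0_and_t24_combined`) is positive if either time point is
  ≥ cutoff, negative only when both are measured and below, not evaluable
  otherwise (e.g. t0 negative with t24 missing) — which is why its evaluable
  n is smaller than the cohort;
* the tool rule (`neohop_t0_and_crp_t24_combined`) is positive at score
  ≥ 2, negative at score 0, and defers to the t24 CRP at score 1.

The decision tool maps directly onto the latter: score 0 → no antibiotics
(theoretical LOT 0 days), score 1 → start and re-assess at 24 h (stop → 1
day; continue → observed LOT), score ≥ 2 → full course (observed LOT). Where
the tool recommends continuing but the clinician never started antibiotics,
the theoretical LOT copies the observed 0 — there is no course to extend;
this conservative reading is a package decision, logged per episode. Score-1
episodes with a missing t24 CRP are not evaluable and are excluded pairwise
from observed-vs-theoretical comparisons, with counts reported.

## Diagnostic accuracy

Metrics use the standard identities (sens = TP/(TP+FN), spec = TN/(TN+FP),
PPV, NPV, accuracy, NLR = (1−sens)/spec, PLR = sens/(1−spec)). Display
rounding is half-away-from-zero — one decimal for percentages, two for
likelihood ratios — computed on exact integer fractions via decimal
arithmetic, so e.g. 77/80 prints as 96.3 rather than a binary-float 96.2.
Zero-denominator metrics (and the PLR of a perfectly specific test) are
*undefined*, never coerced to 0. Binomial confidence intervals are Wilson or
Clopper–Pearson (statsmodels). ROC AUC is computed from rank sums,
AUC = U/(n₊·n₋) with midranks for ties (the trapezoidal convention).

## Exhaustive CHAID

The tree builder implements the exhaustive variant of chi-squared automatic
interaction detection for nominal predictors. At a node, each predictor's
categories are merged pairwise — always the least significantly different
pair by a 2×k Pearson chi-square — all the way down to two groups; every
grouping along the merge sequence is tested against the outcome and
Bonferroni-adjusted by the number of ways to partition the c original
categories into g groups (the Stirling number of the second kind S(c, g)).
The node splits on the predictor with the smallest adjusted p ≤ α_split,
with deterministic tie-breaking (raw p, then chi-square, then name).

Defaults: α_split = 0.05 (the analysis-wide alpha), min_parent_size = 20,
min_child_size = 7, max_depth = 3 — small-cohort-sane values, all
configurable. The chi-square is Pearson without continuity correction (a
likelihood-ratio variant sits behind `use_likelihood_ratio`). Two deliberate
simplifications: a predictor is used at most once per root-to-leaf path (the
analysis has two predictors and shallow depth), and a predictor whose best
grouping would create a child below min_child_size is skipped at that node
rather than re-merged. `alpha_merge` is retained in the configuration for
interface completeness but is advisory: the exhaustive scan replaces early
stopping of the merge sequence. Bit-exact replication of any particular
commercial CHAID implementation is not promised; the test surface is
structural (the NeoHoP-band / CRP-t24 two-variable tree on calibrated data)
and oracle equivalence on small tables.

In the pipeline the predictors are the score band {0, 1, ≥2} and the t24 CRP
band {lt_cutoff, ge_cutoff, missing}, with missingness as an explicit
category.

## Summaries and group comparisons

Non-normal quantities are summarised as median and IQR using **Tukey
hinges** (the median of each half of the sorted data, halves including the
middle observation at odd n), configurable to linear interpolation; at the
integer-valued LOT summaries involved the two conventions rarely differ.

The Mann-Whitney U test uses midranks for ties. The exact two-sided p is the
null probability of a U at least as far from n₁n₂/2 as observed over all
equally likely group assignments, computed by subset-sum dynamic programming
over doubled midranks — arithmetically identical to full enumeration but
feasible to a combined n of ~40 (the default bound; larger samples are
directed to the normal approximation with tie-corrected variance and a
continuity correction that is clamped so a zero-effect comparison reports
p = 1). The observed-vs-theoretical LOT comparison runs Mann-Whitney on the
two vectors even though they are paired, matching the analysis toolbox the
design names; a Wilcoxon signed-rank alternative is available via
`test="wilcoxon"`.

## Synthetic cohort: what it emulates, and what it does not

The generator reproduces the *marginal* structure of the reference cohort:

* n = 214 episodes; class probabilities 22/214, 56/214, 136/214
  (proven/presumed/none), sampled independently per episode;
* per-test positivity calibrated from the published count quadruples:
  P(pos | any HAI) = TP/(TP+FN) and P(pos | no HAI) = FP/(TN+FP) — e.g.
  60/79 and 0/135 for CRP t0;
* NeoHoP's four clinical components are Bernoulli, independent given class,
  with a per-class prevalence solved numerically (Brent) so that
  P(score ≥ 2 | class) matches the calibrated NeoHoP positivity given the
  class's CRP-component rate;
* CRP values are log-normal with location at the 10 mg/L cutoff and log-scale
  0.6; the *side* of the cutoff is drawn as the calibrated Bernoulli and the
  magnitude from the matching truncated tail, so exceedance probabilities are
  exact while the distribution shape is cosmetic. Point-of-care values are
  censored to the device range 1.0–200 mg/L and reported to 0.1 mg/L,
  rounded away from the cutoff so reporting precision never flips a call;
* observed LOT per class is gamma, with shape/scale fitted by Nelder–Mead to
  the published median/IQR targets (proven 9 (7–14), presumed 7 (5–9), none
  3 (2.5–3) days), discretized to half-days, and truncated for definitional
  consistency (≥ 5 days when antibiotics were continued; 0.5–3 days in the
  no-HAI class);
* t24 CRP is missing with probability 9/214; the definition (laboratory) CRP
  is drawn on the side of the cutoff the sampled class requires, which
  guarantees the round-trip property: every generated episode re-classifies
  to its sampled label with zero unclassifiable outcomes;
* half of proven episodes are CoNS (60% of those via paired cultures), and
  5% of culture-negative episodes carry a contaminant organism.

Deliberate non-goals: no within-episode correlation between t0 and t24 CRP
beyond class conditioning, no correlation among clinical components, no
demographic structure (birth weight, gestation), no repeat-episode
dependence within subjects beyond shared identifiers, and no episodes where
antibiotics were never started. Consequently, passing tests demonstrate that
the pipeline recovers the structure it was calibrated to — test positivities
to within sampling error (±2 percentage points at n = 10,000), class mix,
LOT summaries — not that it would reproduce patient-level results from the
real cohort, whose record-level data are not publicly available. The
published headline medians (overall observed 3 → theoretical 1 day) are
therefore *not* asserted anywhere; the corresponding property on synthetic
cohorts (theoretical ≤ observed in the no-HAI stratum across seeds, p-values
far below 0.001 at the study size) is.

Two internal inconsistencies of the published table are carried as
documented exceptions rather than reproduced: the narrative accuracy of
98.3% for the tool (its counts give 210/214 = 98.1%) and the CRP t0
sensitivity printed as 76.0 (its counts give 60/79 = 75.9 under the rounding
that reproduces every other cell). The counts govern.

## Problem sizes and determinism

Simulation-based checks use 200 study-sized cohorts for the seed-fraction
property and a single n = 10,000 cohort for calibration recovery and the
classification round trip — sizes at which binomial noise is comfortably
inside the stated tolerances. All randomness flows from a single integer
seed through `numpy.random.default_rng`; identical configuration and seed
give identical cohorts and byte-identical metric tables.
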