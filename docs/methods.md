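# Methods

This note documents the models, conventions and design choices behind
`dischargesat`: what the scoring rules and statistical procedures are,
what the synthetic-cohort generator does and does not emulate, and which
numerical decisions were genuinely open.

## 1. The instrument and the score model

The instrument has 17 questions; 14 are scored and grouped into three
items (logistics: Q2–Q5, Q11C–E; continuity of care: Q7, Q9, Q10;
impressions: Q11A, Q11B, Q11F, Q11G), and 3 (Q1, Q6, Q8) are
documentation-only and never scored. Each scored response maps to a value
in [0, 1]: binary questions score 1/0 with the polarity of the wording
(Q11E asks about *difficulties*, so "Yes" scores 0), Q11C/Q11D score
"Reasonable" 1 / "Too long" 0, and Q7 is graded 1 / 0.75 / 0.25 / 0 with
"No information given" also scoring 0.

**Not-applicable answers.** "Not concerned" (Q7, Q11C, Q11D, Q11E) and
"I don't have a primary care physician" (Q9) remove the question from
both the numerator and the denominator of its subscore. Although the
printed score table lists a "Not concerned" row only for Q11D/Q11E, the
reported denominators (676/737 for the Q11C waiting-time question, with
18/755 not concerned) show the code was in use for Q11C as well, so the
package includes it in Q11C's vocabulary.

**Subscores and total.** The item subscore is the equal-weight mean of
the applicable question scores; the total is the mean of the three
subscores. Internally scores are exact rationals (`fractions.Fraction`),
so lattice values such as 7/12 are bit-reproducible; reports round
half-up to 2 decimals. A subscore is UNDEFINED only when *every* question
of its item is not applicable — impossible under the default instrument,
since each item contains always-applicable questions, but supported for
custom instruments — and the total is then UNDEFINED too, rather than a
mean of the remaining items. This is the conservative reading of "mean of
the 3 subscores"; the alternative (mean of defined subscores) would
silently reweight items.

**Completeness.** A record is complete iff no *scored* question is
missing; NA-type answers count as answered. Missing documentation-only
questions do not exclude a record, because they feed no score and the
exclusion rule exists for the score analyses. Incomplete questionnaires
are excluded from scoring and from the response-rate numerator but are
preserved in the flow accounting (included = complete + incomplete +
nonresponders, per arm).

Exhaustive enumeration of all no-NA response combinations (432 logistics,
48 continuity, 16 impressions) confirms the attainable subscore lattices
— {k/7} for logistics, {k/4} for impressions, {(a+b)/3, a ∈ {0, .25, .75,
1}, b ∈ {0, 1, 2}} for continuity — and that the published percentile
levels (0.25, 0.33, 0.58, 0.67, 0.92, 1 for continuity) are attainable
values after 2-decimal rounding.

## 2. The statistical battery

All tests are two-sided.

* **Fisher's exact test** (2×2): the p-value sums hypergeometric
  probabilities ≤ that of the observed table (the convention of R's
  `fisher.test`). Verified against an exact rational enumeration oracle
  and against scipy.
* **Mann-Whitney-Wilcoxon**: for combined n ≤ 20, full permutation
  enumeration of all C(m+n, m) allocations of the pooled midranks —
  exact under ties; the two-sided p is the probability of a |U − mn/2|
  deviation at least as large as observed (the permutation distribution
  of U is symmetric, so this equals the doubled-tail convention). Beyond
  n = 20, a normal approximation with tie-corrected variance
  mn/12·((N+1) − Σ(t³−t)/(N(N−1))) and a 0.5 continuity correction.
* **Wilcoxon signed-rank**: zeros dropped (reduced-sample method); for
  ≤ 15 nonzero differences, enumeration of all 2ⁿ sign assignments of the
  midranks of |d|; otherwise the tie-corrected normal approximation
  n(n+1)(2n+1)/24 − Σ(t³−t)/48 with continuity correction. An all-zero
  difference vector is flagged degenerate with p = 1.
* **Bonferroni**: the significance threshold is divided by the number of
  comparisons (α/2 = 0.025 when the telephone arm is compared with both
  other arms); raw p-values are always reported alongside the adjusted
  threshold, since dividing α and multiplying p are equivalent decisions
  but not equivalent reports.
* **Percentile tables** use linear interpolation of order statistics at
  h = (n−1)p + 1 (numpy's default): this is the convention under which
  lattice-valued scores produce non-lattice table entries such as 0.43.
  The method is configurable (any numpy quantile method name).

**Approximation accuracy.** At m = n = 8 on score-like 5-point lattice
data, the tie-corrected normal approximation tracks the exact permutation
p to within ~0.02 wherever the exact p ≤ .05 — i.e., where decisions are
made. In the far interior (exact p around 0.7–0.9) the absolute gap can
reach ~0.1; this is inherent to the normal approximation at N = 16 (scipy's
asymptotic path returns the identical value) and is immaterial because the
exact path is always used at such sample sizes.

**Type-I error.** Monte Carlo null calibrations (1000 replicates): the
Mann-Whitney comparison of total scores at 400 per arm under a no-effect
scenario rejects at a rate within 3 MC standard errors of 0.05; Fisher
(200 per arm, p = 0.5) and signed-rank (n = 60 continuous differences)
behave likewise, though both are mildly conservative by construction.

**Item ordering.** The within-patient comparison tests logistics −
continuity and impressions − logistics with the signed-rank test and
reports the *direction* of the median paired difference. Under the
packaged scenario at the trial's size, the published ordering
(continuity < logistics < impressions) is reproduced — both directions
positive — in ≥ 95% of replicates. Reproduction is defined by direction,
not joint significance: the logistics-vs-impressions gap implied by the
published marginals (~0.84 vs ~0.85 in expectation under
question-independence) is real but small, and a test powered at ≥ 95%
for it at n ≈ 755 would require a correlation structure the marginals do
not pin down.

## 3. The synthetic-cohort generator

The simulator emulates the structure of a randomized
mode-of-administration trial: eligible patients (home Internet access)
split ~1:1 into Internet and telephone arms with unit (department)
labels, a noneligible arm at 1:4 of the eligible count, per-arm response
probabilities optionally logistic in age, and per-question categorical
responses over the instrument vocabularies.

The packaged default scenario (`default_trial_scenario`) fixes every
marginal the reference study prints: arm sizes 430/437/274; response
rates 0.391/0.872/0.752; favorable-response proportions such as Q2
664/755, Q3 354/755, Q11A 642/755; NA rates 18/755 (Q11C), 35/755
(Q11E), 36/755 (Q7). Where no value was printed, a single plausible
choice was fixed up front and not revisited:

| quantity | default | basis |
|---|---|---|
| Q11D split (of 755) | 510 / 90 / 155 NA | waiting-time satisfaction near Q11C's; NA ≈ 20% covers non-vehicle transport |
| Q9 "no primary care physician" | 10/755 | small no-PCP fraction typical of adult inpatients; leaves Yes = 443 |
| Q7 Highly/Satisfied split | 262 / 262 | even split of the 524 satisfied-or-better |
| response-age slope | 0.02 logit/year | responders older than nonresponders, qualitatively |
| age model | log-normal matched to median/IQR per arm, truncated [18, 100] | right skew typical of adult inpatients |
| stay duration | log-normal per hospitalization type (7, 4–11 standard; 3, 2–3 weekday), ≥ 2 days | printed medians/IQRs |
| completion delay | log-normal per arm (6, 3–16 / 7, 7–9 / 7, 7–8 days) | printed medians/IQRs |
| unit weights | 0.356/0.20/0.17/0.14/0.134 | unit contributions ranged 13.4–35.6%; interior weights illustrative |
| Q1/Q6/Q8 distributions | see source | documentation-only; Q6 gives 153/755 a summary and/or physician letter |

The logistic-in-age response model solves its intercept on the drawn ages
(Brent root-finding) so the marginal arm response rate equals the
configured value exactly in expectation; the same calibration keeps the
per-question favorable frequencies unbiased when the optional latent
satisfaction propensity (`latent_sd`, a shared per-patient logit shift
across all favorable-response probabilities) is switched on. The latent
field is off by default: questions are sampled independently given the
arm, the minimal assumption when no joint structure is reported. Effects
(`inject_effect`) shift an arm's favorable probabilities on the
probability scale, renormalizing the other applicable responses and
holding NA mass fixed; shifts that push any probability outside [0, 1]
are rejected before sampling.

**What the simulator does not emulate** — and hence what passing tests do
not establish about real data: within-patient correlation between
questions (beyond the optional single latent factor), item-level joint
distributions, reminder dynamics in the Internet arm, unit-level
response-rate heterogeneity (the per-unit comparison is property-level
only, since per-unit sizes were not published), incomplete questionnaires
(simulated responders always complete; incompleteness is exercised via
the CSV path and unit tests), and 1-day stays (out of the study
population).

**The deterministic reference fixture** (`reference_cohort`) is distinct
from the simulator: it assigns responses in deterministic blocks so that
every published marginal count is *exact* (168/430, 676/737, …), at the
price of an artificial joint distribution. It exists to verify count
accounting and rounding bit-exactly; distributional claims are checked on
the stochastic simulator instead. Its unpublished per-question fills are
synthetic and marked as such in the source.

## 4. Numerical conventions

* Percentages: decimal half-up rounding, 1 decimal (2 decimals for the
  overall completion rate, matching the mixed precision of the reference
  report); every printed percentage is recomputed from counts at access
  time.
* Midranks are doubled to integers inside the exact test paths so tie
  handling is exact; enumeration comparisons use a 1e-9 relative guard.
* Education is a 4-level ordinal in rank tests; "do not wish to answer"
  rows appear in descriptive tables but are excluded from comparisons.
* Degenerate inputs (all-identical samples, all-zero differences,
  single-sex cohorts) yield flagged degenerate results rather than
  errors; empty samples raise.
* Problem sizes in the packaged checks: null calibration 400/arm × 1000
  replicates; marginal recovery at 100,000 included patients; item
  ordering 200 replicates at the trial's own size (~755 responders);
  oracle sweeps over ~1000 datasets with total n ≤ 8.

## 5. Known limitations

* The reference study's score-distribution numbers (percentile tables,
  e.g. median total 0.83) derive from undeposited patient data; the
  package reproduces their *attainable-value structure* exactly and their
  magnitudes approximately through the scenario simulator, but they are
  not exact targets.
* Question-independence makes simulated subscore distributions somewhat
  narrower than real ones; the latent-propensity option mitigates but
  does not calibrate this.
* The exact Mann-Whitney path is O(C(m+n, m)) and is capped at combined
  n = 20; the signed-rank enumeration at n = 15. Both caps are arguments,
  not constants.
* The instrument is scored as defined; no psychometric validation
  (reliability, factor structure) is attempted.
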