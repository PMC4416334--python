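# Methods

## The classification model

Each cause of death is defined by a boolean *expert algorithm* over the
verbal-autopsy interview: a nested and/or/not expression whose leaves test a
sign's tri-state answer (yes / no / missing), an optional minimum or maximum
duration in days, an onset-order rank from the single illness-ordering item,
the pregnancy duration in months, or the illness onset day of life. Three
semantics choices shape everything downstream:

- **Missing is never "no"** in the data model, and a predicate on a missing
  answer is false. Expert VA algorithms are designed specificity-first;
  treating missingness as evidence would let incomplete interviews create
  diagnoses. The flip side is that negated predicates (`not rash`) pass when
  the answer is missing — absence of evidence of the sign, not evidence of
  absence — which is the conventional reading of exclusion criteria.
- **The hierarchy is a total order**, so primary-cause selection is the
  minimum rank over the set of firing rules and ties are impossible by
  construction. Every other firing cause flagged co-morbid-capable is
  reported as co-morbid. An empty set yields `unspecified`.
- **Possible tiers are suppressed by their probable counterparts**: a
  sensitive "possible X" rule is eligible only when "probable X" did not
  fire, and must rank below it. Reporting merges possible into probable, so
  counts are conserved: #probable X + #possible X = #reporting X.

The default neonatal and child rule sets in `src/vasakit/data/` are
*reconstructions*: the exact published criteria for every cause are not
available in full, so the YAML encodes the criteria that are documented —
neonatal meningitis requiring (bulging fontanelle or convulsions) *and*
(lethargy or unconsciousness); child meningitis requiring stiff neck or
bulging fontanelle; preterm delivery as pregnancy < 8 months or < 9 months
with respiratory-distress signs, placed last in the neonatal hierarchy so it
is primary only as the sole condition; minimum breathing-sign durations for
probable pneumonia; possible malaria as fever with no other infectious
diagnosis; a CDC-style clinical case definition for pertussis — and fills
the remainder from the VA validation literature. The hierarchy orders
follow the conventional principles (measles above pneumonia, diarrhea above
pneumonia, meningitis above sepsis, malnutrition high as an underlying
cause, all possible tiers below their probable counterparts). The child
possible tiers are placed below the residual other-infections rule, since
their role is to claim otherwise-unspecified deaths. Rule sets are
schema-validated at load; unknown sign keys are configuration errors at
load time, never evaluation-time surprises.

## Certificates

Death certificates are consumed as data; the package does not simulate
physician judgment. The underlying cause is the lowest child entry of
part 1, the underlying maternal cause (neonates) the lowest maternal entry,
with the invariant that maternal entries never sit above child entries.
The combined physician cause is the deduplicated union of part-1 child
causes and part-2 contributors. The minimal-criteria audit checks each
certified cause against a configurable diagnostic floor (e.g. pneumonia
requiring at least fast or difficult breathing) on the matching interview;
causes without a configured floor are reported uncheckable.

## Statistics

**Weighted CSMF.** proportion(X) = Σ weights of deaths with cause X / Σ all
weights; counts stay unweighted. The paper-style tables give no CI method
for weighted proportions, so the package uses a Wilson interval on the Kish
effective sample size n_eff = (Σw)²/Σw², which respects cluster weighting
without requiring replicate weights and is swappable behind `weighted_csmf`.

**Two-proportion test.** The statistic is the uncorrected two-sample Pearson
chi-square with pooled p̄; this reproduces every recomputable published
worked value to the printed precision. A two-sided exact mid-p variant of
the p-value (hypergeometric tables no more probable than the observed one,
the observed table counted at half weight) is available by flag and labeled
in the result; the statistic is unchanged. Degenerate pooled proportions
(p̄ ∈ {0,1}) return statistic 0, p = 1.

**Kappa.** κ = (pₒ−pₑ)/(1−pₑ) with the large-sample standard error
√(pₒ(1−pₒ)/n)/(1−pₑ) for the 95% CI, truncated to [−1, 1]. Grades use
strictly-greater thresholds at 0.80/0.60/0.40/0.20. Degenerate margins
(pₑ = 1) yield κ = 1 only under perfect agreement, otherwise an error.
Weighted cells feed the same formula when weights are supplied; unweighted
counts are the default because published agreement cells are unweighted.

**Ranks.** Dense ranks by descending proportion over the causes shared by
both distributions, unspecified excluded; ties keep cause-list order and
are flagged rather than broken silently.

## Plausibility analyses

The onset association builds, per cause group (meningitis, pneumonia,
sepsis, the three combined, and early-severe vs all other deaths), a 2×2 of
onset stratum (illness onset < 2 days vs ≥ 2 days) against the EAVA
maternal-infection flag and applies the two-proportion chi-square; weighted
percentages are reported alongside the unweighted test. Missing onset days
fall into a `not_applicable` stratum that is reported but not tested, and
empty strata flag the row instead of failing.

The regional comparison puts each region's VA meningitis-specific
proportional mortality (weighted share of that region's child VA deaths
attributed to meningitis) against the region's share of national
surveillance cases and deaths. The published argument is qualitative; the
Spearman rank correlation reported here is an explicit artifact-level
addition, and regions with fewer than 20 VA deaths are flagged as unstable
denominators.

## The synthetic cohort generator

The generator emulates a two-stage cluster mortality survey: 453 neonatal
and 620 child deaths by default, 80 clusters assigned to 8 regions with
probabilities proportional to the survey frame's regional death counts, and
lognormal cluster weights (σ = 0.3; σ = 0 gives exact equal weights). Causes
are drawn from a configured CSMF; signs are conditionally independent
Bernoulli given the cause, with explicit co-morbidity couplings (a
meningitis death also shows the sepsis signature with probability 0.9, and
so on) so the hierarchy's co-morbidity logic is actually exercised.
Durations are Poisson around cause-specific means; 5% of answers are
missing by default. The default CSMFs are deliberately round numbers for a
high-mortality, malaria-endemic setting — the generator is *not* fitted to
any observed cause distribution, which would be circular given that the
classifier is then run on its output.

Maternal infection has a 15% baseline; for severe-infection deaths with
onset before day 2 the probability is tilted on the odds scale by a
configurable multiplier m (m = 1: no association, the null). Physician
certificates are generated from the truth plus behaviour noise — correct
underlying cause with probability 0.75, otherwise a clinically adjacent
confusion; optional direct-cause chain lines; part-2 contributors sampled
from the true co-morbids; an optional extra diagnosis at the
minimal-criteria floor — rather than by re-running the rules, so
algorithm-vs-physician kappas are nontrivial and tunable.

What passing tests on this generator do **not** show: real interviews have
correlated symptom reporting, recall decay over multi-year windows,
informant effects and translation artifacts, none of which the
conditional-independence model emulates. Recovery results here demonstrate
the pipeline's correctness, not field validity of the rules.

## Problem sizes and numerical choices

The test suite's Monte-Carlo checks use: exhaustive enumeration of all 2¹²
records of a 12-sign toy vocabulary against a brute-force oracle; CSMF
recovery at n = 5000 with noise-free deterministic profiles and a ±0.02
per-cause band (≈3 binomial standard errors at the largest fraction); and
1000 replicate cohorts of 453 neonates for the null calibration of the
onset test with an acceptance band of 0.05 ± 0.02. The calibration draws
causes, onsets and maternal flags from the generator's neonatal model and
feeds truth-derived assignments to the test, which is equivalent to
classifying noise-free records (asserted separately) and keeps a thousand
replicates cheap.

Known limitations: the default rule content is a documented reconstruction,
not a verbatim transcription; published *weighted* statistics cannot be
reproduced exactly because the survey's cluster weights are not public
(unweighted recomputation agrees in direction and significance, and this is
what the tests assert); and the mid-p construction used for the published
p-values is underdetermined, so printed p-values are compared only
qualitatively while printed chi-square statistics are reproduced exactly.
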