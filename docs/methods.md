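# Methods

This note documents the models, conventions and calibration behind
`famschool`: what the pipeline computes, what the synthetic-data generator
does and does not emulate, and the choices made where the design was open.

## Survey model and scoring

Seven instruments are modelled, all scored as plain item sums with no
reverse-keyed items:

| scale            | items | range | α target |
|------------------|------:|:-----:|---------:|
| family cohesion  | 16    | 1–5   | 0.82 |
| family conflict  | 9     | 0–1   | 0.63 |
| financial strain | 5     | 1–4   | 0.75 |
| teacher support  | 7     | 1–4   | 0.80 |
| peer support     | 13    | 1–4   | 0.81 |
| autonomy support | 5     | 1–4   | 0.76 |
| DSRSC            | 18    | 0–2   | 0.84 |

The α targets are the reliabilities reported for the motivating survey,
except financial strain, whose item structure is unreported there; the
package fixes it at 5 items scored 1–4 (only its quartiles matter
downstream) with a typical-for-short-scales α of 0.75.

Cronbach's α uses sample variances (n − 1 denominators):
`α = k/(k−1) · (1 − Σ_i var(item_i) / var(total))`.  It is undefined (an
error) when the total score has zero variance.

Missing data are handled by complete-case filtering only; any record with a
missing or out-of-range item response is dropped before scoring.  School
stage is always derived from grade (5–6 primary, 7–9 middle), never stored.

## Discretization

- **Percentiles** use the nearest-rank convention: `P_q` is the value at
  1-based position `ceil(q·n)` of the sorted totals.  Cutoffs are computed
  on the pooled analytic sample by default (`cutoff_scope="pooled"`); a
  per-stratum variant is available but changes the meaning of an item across
  strata and is off by default.
- **Criteria are inclusive**: risk items fire at total ≤ P25 (or ≥ P75 for
  conflict/strain), protective items at the opposite tail, also inclusive.
  Consequently at least 25% of the sample receives each quartile item, more
  under ties.
- **Degenerate scales** (P25 = P75) emit no items in either mode and are
  logged; otherwise a participant can never hold both tails of one scale.
- **Outcome**: `depression` iff DSRSC total ≥ 15 (the screening threshold is
  applied inclusively; the source convention does not state inclusivity, and
  the inclusive reading is documented here as the package's choice).  Every
  transaction carries exactly one outcome item.
- The left-behind variable has one underlying state with mode-specific item
  labels ("separation from parents" in risk mode, "non-left-behind
  children" in protective mode); academic ranking contributes its level item
  in both modes with no polarity (exploratory); gender and school-stage
  items exist for both levels and survive only if mining keeps them.
- The **stratifying variable is excluded** from its own analysis's item
  universe: within a stratum its item would have 100% support and lift
  exactly 1, contributing nothing.

## Mining

Apriori is implemented from scratch over exact transaction bitsets: frequent
1-itemsets, then candidate k-itemsets joined from frequent (k−1)-itemsets
sharing a (k−2)-prefix in a fixed lexicographic order, pruned by
anti-monotonicity and counted exactly.  `min_sup` applies to the support of
the full itemset `X ∪ {Y}` with the stratum's transaction count as
denominator.  Threshold comparisons: support ≥ min_sup and confidence ≥
min_conf (both inclusive), lift > min_lift (exclusive).  Rules are ordered
by confidence descending, ties by support descending, then lexicographic
LHS; metrics are kept at full precision and rounded (half-up, 2 decimals)
only in reports.  No maximum itemset size is imposed by default.

Default thresholds: risk mode min_sup 5% with min_conf 70% (gender and
age-group analyses) or 80% (left-behind analysis); protective mode min_sup
20% with min_conf 80% everywhere; min_lift 1 in all analyses.

The testing oracle enumerates all non-empty subsets of the item catalog
(guarded at 20 items) and must agree exactly with Apriori on itemsets and
counts; this equivalence is asserted over randomized instances in the suite.

## Synthetic-data generator

The generator emulates the study conditions so the pipeline is testable
without the undeposited survey data.  Stages run on independent,
deterministically derived sub-streams of one integer seed, so adding a stage
never perturbs earlier draws.

**Demographics** are drawn independently from the documented marginals:
P(female) = 0.528, P(middle school) = 1281/2445 with the published
within-stage grade distributions, P(left-behind) = 0.356.  Marginals the
motivating survey does not report are fixed once at realistic values:
P(intact family) = 0.85, P(low parental education) = 0.40, academic ranking
(top-10, average, last-10) = (0.25, 0.55, 0.20), school resources
(psychology courses 0.60, counselors 0.50, counseling rooms 0.55).

**Scale levels** come from a Gaussian copula over the six predictor scales.
The default correlation matrix encodes the expected structure — cohesion
against conflict (−0.45) and strain (−0.20), cohesion with the school
supports (+0.25 to +0.30), the three school-climate scales mutually +0.40 to
+0.45 — and is validated as symmetric, unit-diagonal and positive
semi-definite.

**Item responses** are compound-symmetric: item latents load on the scale
level with loading √λ and are thresholded into equiprobable categories.
The inter-item correlation target ρ comes from inverting
`α = kρ / (1 + (k−1)ρ)`; because discretizing a latent normal into c
equiprobable categories attenuates correlations by
`r_c² = (Σ_j φ(τ_j))² / ((c²−1)/12)` (τ_j the c-quantile thresholds; r_2² =
2/π ≈ 0.64 for dichotomous items), the generator uses λ = ρ / r_c².  Without
this correction the dichotomous conflict scale would land near α ≈ 0.50
instead of 0.63.  Simulated α lands within ±0.02 of each target at n = 2445
(the suite asserts ±0.05 averaged over seeds).

**Outcome.** Depression status is Bernoulli with logit
`β₀ + Σ β_m·1[risk item m] + β_int·1[low cohesion ∧ high conflict]`, where
the risk indicators are computed from the quartile/flag criteria on the
synthetic cohort itself.  Defaults: β = 1.1 for low cohesion and high
conflict, 0.5 for low peer and low teacher support, interaction 0.8, and
β₀ = −2.05 calibrated by Monte Carlo so marginal prevalence ≈ 0.30 (a value
between the subgroup base rates implied by the published tables, which never
print prevalence directly).  This joint calibration places the flagship
combination {low family cohesion, high family conflict} ⇒ depression at
lift ≈ 2.6 with confidence ≈ 0.79 — inside the published 2.5–3.0 lift band
and comfortably above the 70% confidence threshold, so planted-signal
recovery is a property of the model rather than of seed luck.  (Weaker
mains of 0.9 with a 0.6 interaction were evaluated first and give lift ≈ 2.4
with confidence straddling 0.70; they were rejected because recovery then
depends on sampling noise.)

**DSRSC totals** are drawn conditional on status from rounded truncated
normals — N(10, 2.8²) on [0, 14] for non-depressed, N(18, 2.8²) on [15, 36]
for depressed — and decomposed into 18 item scores by giving each item the
base ⌊t/18⌋ and distributing the remainder to a uniformly chosen item
subset.  This low-noise composition yields DSRSC α ≈ 0.84 at the default
prevalence; only the total is analysed downstream.

**Missingness** is completely at random at the row level (default 0 at
n = 2445, the analytic sample); recruitment-style attrition is emulated with
n = 2800 and rate 0.127, retaining ≈ 2445 complete cases.

**The Monte-Carlo oracle** estimates a planted rule's support, confidence
and lift by direct counting on replicate cohorts, bypassing the mining code
entirely, and returns means with standard errors.  Mined and oracle lifts
must agree within combined sampling error — a cross-validation of two
independent code paths.

**What the generator does not emulate:** dependence among demographics
(gender × stage × left-behind are independent by default; a joint table can
be configured), item-level effects (differential functioning, reverse
keying, acquiescence), non-Gaussian dependence between scales, informative
missingness, and any school-level clustering from the original cluster
sampling.  Passing tests therefore demonstrate correctness of the pipeline
and recoverability of planted effects under these idealized conditions, not
properties of the real survey population.

## Packaged reference tables

The six published stratified rule tables are shipped as verbatim TSV
transcriptions (risk and protective × gender, age group, left-behind
status), including their printed quirks: one duplicated LHS with differing
metrics in the left-behind risk table (flagged as an erratum, kept
verbatim) and inconsistent label spellings.  `check-tables` recomputes
per-part summaries, cross-part metric ranges and the implied-base-rate
diagnostic `confidence / lift`, which must be near-constant within a
stratum (CV < 1.5% is enforced for the risk tables; observed ≈ 0.1%).
Where a table's computed itemset-size decomposition or metric range
disagrees with its accompanying running text (it does for the left-behind
risk table and the protective lift ranges), the tables are authoritative
here and the summaries simply report what the rows give.

## Problem sizes and runtime

Default analyses run at the study scale (n = 2445; strata of roughly
1150–1300).  The test suite exercises oracle equivalence on 50 random
instances of ≤ 12 items × ≤ 300 transactions, generator calibration over 20
seeded cohorts, and planted-rule recovery and null control over 100 seeded
stratified analyses each; the full suite and the acceptance script each
complete in well under a minute on one CPU.

## Known limitations

- Association rules are descriptive co-occurrence statements; no causal or
  longitudinal interpretation is supported, and no significance testing or
  redundancy pruning beyond the support/confidence/lift thresholds is done.
- Quartile discretization discards within-quartile variation and makes item
  prevalence tie-dependent.
- The generator's published-value calibration (marginals, α, prevalence
  band) does not make mined rule tables numerically match the published
  ones — that would require the original data; the packaged transcriptions
  exist precisely to keep the summary/diagnostic layer honest.
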