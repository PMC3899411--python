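# Methods

## Problem setting

A death certificate lists an immediate cause (Part I, top line), the chain of
intermediate causes beneath it, and contributory conditions (Part II) outside
the causal chain. Countries with multiple-cause coding tabulate every mention;
countries with underlying-cause-only coding keep just one code per death.
This package implements (1) role-stratified tabulation of certificate
mentions and (2) an extrapolation of multiple-cause death counts for an
underlying-cause-only country, using Parkinson's disease (PD, ICD-10 G20) as
the motivating disease. Both analyses generalize: the cause-category scheme,
the mention label vocabulary, and the age partition are configurable.

## Cause categories and ICD-10 handling

Underlying causes are grouped into six strata: ischemic heart disease
(I20–I25), malignant neoplasm (C00–C75), cerebrovascular disease (I60–I69),
pneumonia (J10–J18), PD (G20), and a complement category `other`. Categories
are block-level ICD-10 ranges; four-character subcodes (I21.9, or dot-less
I219 as in US multiple-cause files) are classified by their three-character
block, since the group definitions carry no finer resolution. Named
categories must be pairwise disjoint (validated exhaustively over all 2600
letter+two-digit blocks); `other` guarantees totality. Range notation accepts
both the typographic en-dash and the plain hyphen. The scheme is not a
validator against the official ICD-10 tabular list: syntactically well-formed
but unassigned codes classify as `other`.

## Role tabulation

Each mention maps to exactly one role per placement: Part I line 1 →
immediate, later Part I lines → intermediate, Part II → contributory.
Tabulation counts *certificates* mentioning each label per role (a label may
occur at most once per role per certificate), ranks rows by descending count
with alphabetical tie-break, and reports percentages with the number of
certificates as denominator, rounded half-up to one decimal — the convention
that reproduces every cell of the published table (19/477 → 4.0, 106/477 →
22.2). Any-role prevalence counts a certificate once even when the label
appears in several roles; the published 4.8% dementia figure corresponds to
the any-role definition (23 distinct certificates of 477).

### Fixture construction

The confidential microdata behind the published comorbidity table are
emulated by a deterministic builder: immediate-cause labels fill certificates
contiguously (the published immediate counts sum to 357 < 477; the remaining
120 certificates receive "Parkinson's disease" on line 1, which the default
tabulation excludes — consistent with every sampled decedent having PD as
underlying cause); intermediate and contributory labels are dealt round-robin
so that each label lands on distinct certificates across roles. Consequently
the tabulation round-trips the count specification exactly and any-role
prevalences equal summed role counts. Sex is assigned to match the sampled
marginals (208 men, 269 women) and ages are drawn from sex-specific normal
moments (men 80.1 ± 7.2, women 82.7 ± 6.9 years, clipped to [0, 110]); only
these demographic draws consume the seed. The published table transcription
merges a duplicated contributory row (two "Lung diseases" entries, 10 and 4)
into a single 14-count row, since a role tabulation is one row per label.

## Extrapolation model

Strata j are sex × age-band cells; the default partition is the nine bands of
the published tables (0–14, …, 75–84, 85+). For reference-country data the
conditional mention proportion is P̂_ref,j(G20|D_i) = mentions_ij / N_ref,ij.
The target country's proportion is modelled as proportional to the
reference's, rescaled by the ratio of the stratum-specific PD
underlying-cause death rates:

    P_tgt,j(G20|D_i) = P_ref,j(G20|D_i) · R_tgt,j / R_ref,j,   P(G20|G20) ≡ 1.

Estimated cells M_ij = N_tgt,ij · P_tgt,j are kept real-valued through the
stratum sums M_j = Σ_i M_ij; rounding (half-up, integers for counts, one
decimal for rates per 100 000) happens only in report writers.

Assumptions worth stating plainly: the rate ratio is taken as an adequate
proxy for *all* cross-country differences in mention propensity — it cannot
absorb differences in certification practice, comorbidity prevalence, or
diagnostic culture; a misspecification experiment (below) quantifies the
consequence when it fails. The reference proportions are treated as known,
though they are themselves sample ratios.

### Degenerate-cell policies

* Adjusted proportions must remain probabilities: values above 1 are capped
  at 1 and flagged `capped`.
* A reference cell with zero underlying deaths yields proportion 0, flagged
  `imputed_zero`.
* Equal rates (including the 0/0 limit where neither country has PD deaths
  in a stratum) leave the reference proportion unchanged — the continuous
  limit of the ratio, and the property that makes the estimator exact when
  reference and target are the same population.
* R_tgt,j = 0 with R_ref,j > 0 gives proportion 0 (no PD deaths, no
  mentions under the model).
* R_ref,j = 0 with R_tgt,j > 0 is undefined: a hard error by default, or a
  documented fallback to the unadjusted reference proportion
  (`zero_reference_rate="unadjusted"`), flagged in the audit log.

Every cap, imputation and fallback is appended to a machine-readable audit
log carried on the results object — no policy is applied silently.

### Collapsed mode

Published aggregates often lack cause-stratified reference counts. With
`collapse=True` all non-PD categories merge into `other`, and the stratum
estimate reduces to the closed form
M_j = N_pd,tgt,j + N_other,tgt,j · (mentions_j / N_other,ref,j) · (R_tgt,j /
R_ref,j), which the test suite verifies to 1e-9 relative tolerance against
the general implementation.

### Properties

* Lower bound: M_j ≥ N_pd,tgt,j in every stratum.
* Self-referential exactness: with reference = target, M_j equals the
  directly counted multiple-cause total to machine precision.
* Neutral-ratio reduction: equal rates reproduce the reference proportions
  with an empty audit log.
* Monotonicity: M_j is non-decreasing in the rate ratio until caps bind, at
  which point it saturates at the stratum's total deaths.

## Synthetic cohorts

The generator draws, per stratum, a fixed number of deaths (Poisson mode
optional) with underlying categories multinomial over a configured
distribution; each non-PD death mentions PD independently with a configured
per-(stratum, category) probability, and PD-underlying deaths mention PD by
definition. The true multiple-cause count is therefore known per stratum, and
tables are recountable from the record list. Only the PD mention is
simulated — the estimator uses no richer certificate structure; the
certificate fixture builder covers multi-condition needs.

Default conditions: two sexes × four elderly bands (55–64 … 85+) with death
fractions 0.08/0.24/0.40/0.28 of a 100 000-death cohort split evenly by sex;
PD underlying share rising with age (1.5%, 2.5%, 3.5%, 4.0%); non-PD mix
dominated by `other` (47%) and malignant neoplasms (25%); PD-mention
probabilities between 1% (malignant neoplasms) and 5% (pneumonia);
population 10⁶ per stratum. The shares are deliberately larger than
whole-population figures so that a desk-scale cohort preserves the
per-stratum PD death counts (hundreds to thousands) of the real national
tables, whose denominators are millions of deaths; stratum rate ratios would
otherwise be too noisy to be informative at this size. What passing recovery
tests show is that the *estimator* is consistent and correctly implemented
under its own assumptions — not that the rate-ratio assumption holds for any
real country pair.

A model-consistent target scales, per stratum, the reference PD share and
all mention probabilities by a chosen rate ratio (0.7 by default, a
moderate cross-country difference), renormalizing the non-PD shares. The
recovery experiment simulates both countries, runs the estimator on the
target's underlying table plus the reference tables only, and compares with
the target's true total: at 100 000 deaths per country the mean absolute
relative error over 20 seeds is ≈1.2% (reported by the test suite; scales as
1/√n). Setting `mention_scale=2` misspecifies the target's true mention
probabilities at twice the model-implied values; the estimator then
underestimates by about half the excess mentions (≈−31% under the default
conditions, matching the analytic expectation) — the quantitative version of
the caveat that the rate-ratio adjustment cannot absorb genuine differences
in comorbidity structure.

All randomness flows through `numpy.random.default_rng`; experiment seeds
derive from a single `SeedSequence`, so runs are reproducible from config +
seed alone.

## Packaged aggregates

Transcriptions of the published tables ship with the package: sampled-
decedent demographics, Japan 2008 and US 2006 PD deaths and rates by sex and
age band, and the role-stratified mention counts. Two transcription
anomalies are preserved deliberately: the US table's near-zero multiple-cause
rows (25–34, 35–44) are internally inconsistent as printed, and the Japan 85+
multiple-cause sex cells (911 + 1549) differ by one from the printed total
(2461) because the original estimates were rounded independently — tests
therefore assert additivity only where counts are exact tallies. The
published real-data multiple-cause estimates themselves (7434 total) are not
reproducible from printed data: they require cause-stratified national counts
and reference-country microdata that were never published, so they serve as
context, not as targets.

## Known limitations

* The method transfers mention propensities across countries up to a single
  stratum-level scalar; racial, clinical and certification differences beyond
  that scalar bias the estimate (see the misspecification experiment).
* No uncertainty quantification: the published method reports point
  estimates only, and this implementation follows it.
* Age standardization, ICD-9/ICD-11 mapping, and WHO underlying-cause
  selection rules are out of scope; the underlying cause is taken as coded.
* The fixture builder reproduces marginal counts, not the (unpublished)
  joint structure of comorbidity mentions.
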