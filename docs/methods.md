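# Methods

## The screening model

The pipeline operates on a patient × item matrix of 1–4 Likert
responses with missing cells, plus per-patient debriefing records.
Stages: reverse-recode → per-item statistics → eight-criterion screen →
keep rule → (scale reliability) → expert-decision bookkeeping. The
screen never deletes anything: it emits a verdict per item, and the
final roster comes only from recorded panel decisions, which may
legitimately override the screen — the package reports such
discordances rather than treating them as errors.

### Denominators

Two conventions are forced by the arithmetic of the published per-item
table and are hard-wired:

- Category and debriefing fractions use the **enrolled cohort** as
  denominator. In every published row the two category fractions sum
  to the compliance value (e.g. item s68: 0.38 + 0.30 = 0.68), which
  is only possible if missing responses count in neither category.
  Internally, compliance is *defined* as `frac_low + frac_high`, so
  the identity holds exactly in floating point rather than to within
  rounding of two separately computed ratios.
- The **item mean uses only non-missing responses**: a
  cohort-denominator mean would fall below the scale minimum for
  low-compliance items, contradicting published values (s69: mean 2.2
  at compliance 0.43).

Whether the study used completers or the full cohort as the
denominator of the debriefing fractions is not stated; the package
uses the enrolled cohort, consistent with the category fractions.

### Inequality strictness and the boundary rows

Criteria 1–7 use strict inequalities and criterion 8 uses ≥, exactly
as the published rule is written. The boundary row s08 (compliance
0.96 > 0.95 → pass) confirms the compliance direction. Published
fractions are rounded to two decimals, so recomputing flags from them
can disagree with the printed flags at a rounded boundary. It does so
for exactly one row: s69's upsetting fraction prints as 0.05 yet its
acceptability criterion passed, meaning the unrounded value was below
5%. The packaged table therefore stores the printed flags as data
(they are the study's record), and the test suite asserts that strict
recomputation reproduces them for 68 of 69 items with s69 the known
divergence. Row s34 (difficult fraction 0.05, criterion failed) is
consistent with the strict rule.

### Degenerate items

An item with zero non-missing responses has undefined mean and range.
It fails criteria 1–4, keeps its (defined) debriefing criteria, and is
flagged degenerate, so screening completes on arbitrary cohorts; the
CLI escalates degenerate items to exit code 3 only under `--strict`.

## Cronbach's alpha

alpha = k/(k−1) · (1 − Σ var(itemᵢ) / var(total)), with sample (n−1)
variances over listwise-complete patients; equivalently
k/(k−1)·(1 − tr S / 1ᵀS1) for the item covariance matrix S, the closed
form the tests pin the implementation to (and cross-check against
pingouin). Listwise deletion is the conventional default for alpha and
the only policy implemented; the `missing_policy` parameter leaves
room for alternatives. Alpha is undefined (NaN, never an exception in
table context) with fewer than 3 complete patients or zero total-score
variance. Scale memberships are configuration: the study named eleven
constructs (fatigue, infections, other symptoms, physical/role/
emotional functioning, stigmatisation, body image, social support,
fear of progression, illness intrusiveness) without publishing their
item lists, and its reported alphas (0.63–0.92) are therefore
documented context, not reproducible targets.

## Synthetic cohorts

For patient p and item i in scale s:

    x_pi = mu_s + lambda_s · F_ps + sqrt(1 − lambda_s²) · eps_pi

with F and eps independent standard normals. The marginal of x is
N(mu_s, 1); items of one scale correlate r = lambda². The ordinal
response is the category of x under three strictly increasing cut
points; cells are then made missing completely at random; reverse-coded
items are emitted on the reversed scale so the pipeline must recode
them. Debriefing flags are independent Bernoulli draws, independent of
responses. These choices are the minimal structure that makes
hypothesised scales and alpha meaningful and analytically checkable:
continuous-score alpha converges to the Spearman–Brown form
k·r/(1+(k−1)·r), category fractions to normal-CDF masses, completion
to 1 − missingness. One seeded NumPy Generator drives all randomness;
a fixed seed reproduces the cohort byte for byte.

Defaults emulate the study conditions: 48 patients, 69 items in the
eleven named scales (sizes 9/4/7/7/6/8/7/8/6/4/3, assigned here since
the real memberships are unpublished), the eight reverse-coded items
(s25, s27, s45, s46, s49, s66, s67, s68), cut points (−0.75, 0.25,
1.25) giving category masses ≈ (0.23, 0.37, 0.30, 0.11) — item mean
≈ 2.3 and frac_high ≈ 0.40, a typical published row — loading 0.7
(population alpha ≈ 0.75–0.90 across the default scale sizes, matching
the reported 0.63–0.92 band), missingness 0.03 (typical compliance
0.96–1.00), debriefing flag rates 0.005/0.01/0.01 per patient-item,
and log-normal completion times with a 10-minute median clipped to
5–20 minutes.

What the generator does *not* emulate: informative missingness,
differential item functioning, response styles, dependence of
debriefing flags on responses, or multi-factor scales. Tests passing
on synthetic cohorts therefore validate the pipeline's arithmetic and
contracts under a clean measurement model, not the behaviour of any of
those real-data complications.

## Numerical and reporting choices

- Fractions are carried at full precision; rounding to two decimals
  happens only at rendering. The CSV report mirrors unrounded values
  in `*_full` columns; markdown and CSV show identical rounded content.
- Cohort-summary percentages round half away from zero to integers
  (21/48 → 44%), matching the published characteristics table.
- The median of an even number of completion times is the midpoint of
  the two central values.
- Problem sizes in tests: closed-form recovery checks use n = 5 000
  patients (alpha within ±0.03 of the Spearman–Brown value) and
  n = 10 000 for binomial/CDF concentration checks (±0.02, and
  completion within ±0.01 of 1 − m); these sizes put Monte-Carlo error
  comfortably inside the asserted tolerances while each check runs in
  well under a second.

## Limitations

- The pre-phase reduction from 77 to 69 items, the qualitative panel
  deliberation, and translation are outside the pipeline; only their
  recorded outcomes are modelled.
- No imputation, no item-total correlations or alpha-if-item-deleted,
  no confidence intervals for alpha, no similarity metric for
  near-duplicate items (the panel's "too similar" judgements are
  recorded strings).
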