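# Methods

This note documents the models and conventions behind `cogprof`, the
design choices made where the published analysis conventions were open,
and what the synthetic-data experiments do and do not demonstrate.

## Normative scoring

T scores are normative standardized scores (mean 50, SD 10 in the
reference population), direction-harmonized so higher T always means
better performance: for scores where a higher raw value is worse
(completion times, error counts) the raw→T transformation flips sign.
T scores are not clipped; the banding handles tails.

**T → percentile.** The percentile convention is the normal-CDF mapping
`Pc = 100·Φ((T − 50)/10)`. This is the standard convention for T metrics
(which are normalized by construction); discrete instrument-specific
lookup tables would be supplied by the user through the normative-table
interface instead. Percentiles are kept continuous internally and rounded
to 2 decimals only in reports (round-half-even).

**Bands.** The seven consensus ranges are printed over integer
percentiles and leave the open intervals (8, 9), (24, 25), (74, 75),
(90, 91), (97, 98) unassigned for non-integer percentiles. We close them
with right-closed intervals, symmetric at both tails:

    [0, 2)  (2, 8]*  (8, 24]  (24, 74]  (74, 90]  (90, 98]  (98, 100]

(*the second band is `[2, 8]`.) This preserves every printed integer
label and makes the three-category scheme an exact coarsening:
*impaired* `Pc ≤ 8`, *low average* `(8, 24]`, *average plus* `(24, 100]`.
The scheme is a value object (`BandScheme`) and can be replaced.

## Domain structure

Domains are derived from the data: PCA on the correlation matrix of the
cohort's **percentile** scores (the published analysis used percentiles;
configurable), retaining `n_factors` components; `variance_explained` is
the retained components' eigenvalue share *before* rotation (rotation
redistributes but does not change the total).

**Rotation.** Direct oblimin (γ = 0, i.e. quartimin) via the
gradient-projection algorithm on the oblique manifold, implemented in
`_rotation.py` because no installed package provides oblique rotations.
Convergence tolerance 1e-6, at most 500 iterations, identity plus 10
seeded random starts (keeping the lowest criterion); the sign
indeterminacy is resolved by forcing the largest-magnitude loading per
factor positive. The implementation is validated by planted-structure
recovery (Tucker congruence ≥ 0.95) and by checking the solution's
criterion against random oblique rotations.

**Assignment.** Each score goes to the factor of its maximal absolute
pattern loading when that loading reaches the threshold (default 0.40, a
conventional cutoff consistent with the smallest retained published
loading, 0.43); ties break deterministically toward the lowest factor
index with a warning; sub-threshold scores are flagged unassigned.
Factors are anonymous, so they are *named* by maximum-congruence matching
against anchor scores (the strongest published markers of each construct,
e.g. RAVLT delayed recall for L+LTM, CPT-II omissions for attention).
Anchors only name factors — they never move a score, so rederivation of
the reference map from synthetic data is a genuine test.

**Regrouping rules.** Content-based overrides applied after assignment,
mirroring how mixed batteries are curated in practice: digit spans →
ST/WM, Coding and Symbol Search → processing speed, every CPT-II subscore
→ attention, ROCFT delayed recall → L+LTM. The rules are idempotent and
record `manual_override` provenance only when they change an assignment.

Missing cells are handled by complete-case deletion by default (optional
mean imputation), documented because published practice is usually silent
here. The built-in reference map carries 33 scores in 7 domains
(6/4/2/2/3/12/4); the MoCA is deliberately excluded as a multi-domain
screening instrument and is treated as a clinical covariate instead.
Stroop word-reading is accepted as an optional extra input but is not
part of the reference map.

## Impairment rule

A domain is affected when, over its observed scores, the impaired
fraction is ≥ 0.50, or the impaired fraction is ≥ 0.30 **and** the
low-average fraction is ≥ 0.30. Published phrasings distinguish
multi-score from single-score instruments, but the two clauses state the
same 50% threshold; we therefore apply one rule over all constituent
scores of a domain, which is the only reading that covers every domain.
Thresholds are inclusive ("at least") and configurable. The "percentile
between 9 and 24" clause maps to the low-average band `(8, 24]` for
consistency with the band closure.

Missing scores leave the denominator (per-score `n` in the distribution
table is likewise the number of observed values). A domain with no
observed scores is *unevaluable*, never "unaffected", and a minimum
coverage of 50% of a domain's scores (configurable) guards against
classifying a 12-score domain from one observation.

The cohort χ² for single vs multi-domain impairment is a 1-df
goodness-of-fit against an even split among impaired patients, without
continuity correction, implemented by definition.

One published distribution row (RAVLT–Recognition) is internally
inconsistent: its printed counts (16/3/44 of 63) imply different
percentages than the printed ones (which imply a denominator of 60). The
package always computes from counts; the consistency checker
(`check_against_published`) flags exactly that row.

## Clinical correlates

Composites are arithmetic means of a patient's observed,
direction-harmonized T scores per domain (coverage-guarded, NaN when
undefined; missing scores dropped, never imputed). Correlations are
Pearson with pairwise deletion and two-tailed p from the t distribution
with n−2 df; no multiple-testing correction by default (mirroring common
practice in this literature) with an optional Holm column. The ANCOVA is
a one-covariate linear model; the group F is the squared t of the group
coefficient, with df (1, n−3). Contingency tests dichotomize a score's
band (impaired-only, low-average-only, or combined ≤ 24) against a binary
group, χ² without Yates correction by default, warning when an expected
count falls below 5. The per-score group-comparison loop is exploratory
and multiplicity-uncorrected by design; its output table says so.

## Synthetic cohorts

The generator emulates the cohort structure the pipeline targets: 63
patients by default, ~52.4% hospitalized, hospitalized patients about 9
years older (55.9 vs 46.7), ~187 ± 99 days from diagnosis to assessment,
log-normal biomarkers uncorrelated with severity by default (associations
in such cohorts are mostly null), and MoCA drawn per hospitalization
group (15.8 ± 3.8 vs 17.8 ± 2.5).

Scores follow a single-factor-per-domain model calibrated to the
published rotated loadings (unprinted loadings default to 0.6):

    T = 50 + 10·λ·f − shift·affected + ε,   f ~ N(0, 1)

where `affected` is a per-domain Bernoulli draw (default prevalences
Attention .60, EF .43, L+LTM .30, Language .15, ST/WM .15, VVA .10,
processing speed .10, chosen once so the implied profile mix is roughly
60% multi-domain) and `shift` defaults to 20 T units (2 SD). The planted
deficit displaces **every score** of an affected domain by the full
shift; the loadings shape the correlation structure, not the effect size
— a deficit attenuated by a 0.43 loading would be undetectable by
construction and would say nothing about the classifier. By default the
residual SD keeps the factor-model identity `sd = 10·√(1 − λ²)` so
unaffected scores are marginally N(50, 10) and the impaired band captures
its 8% base rate; a numeric `residual_sd` overrides this uniformly.
Missingness is MCAR per score (default: the three scores observed in 61
of 63 patients in the reference table).

What the simulator does *not* emulate: non-normal raw-score
distributions and lookup-table norms, practice/retest effects,
instrument-specific floors and ceilings, informative missingness, and
premorbid-ability adjustment. Passing recovery tests therefore shows the
*rule and pipeline* behave as specified under the assumed latent
structure, not that the battery has these operating characteristics in
real patients.

**Recovery operating characteristics.** With a 2-SD planted shift,
residual SD 5 and n = 500, the rule's specificity is ≈ 0.94 and its
sensitivity ≈ 0.87 (≈ 0.99 at a 3-SD near-separable shift). Sensitivity
is bounded by the shared premorbid factor: a patient whose underlying
ability f sits 1–2 SD above the mean can absorb a genuine 2-SD deficit
without crossing the normative impaired cut, and no normative (as opposed
to change-score) classifier can see it. This is a property of the
generative model, not a tuning target.

The simulated 5-factor variance explained (~73%) sits below the published
80.3% because unprinted loadings default conservatively to 0.6 and
residuals are independent; the printed figure is not recomputable without
the patient data.

## Determinism and numerics

All randomness flows through `numpy.random.default_rng` seeds;
replicate sub-seeds are drawn from the parent generator, and two pipeline
runs with the same config and seed produce byte-identical CSVs. Problem
sizes in the test-suite experiments (n = 500 cohorts, 1000-replicate
type-I calibration, exhaustive rule enumeration to domain size 12) were
chosen to keep Monte-Carlo error well inside the asserted tolerances.
Percentages render to 2 decimals with round-half-even; identifiers
normalize en-dashes to ASCII hyphens; CSVs are UTF-8 with '.' decimal.
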