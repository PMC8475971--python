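# Methods

## Problem and approach

Registered clinical studies publish through three channels: registration
metadata, basic summary results deposited in the registry, and journal
result articles. `trialpub` tracks the third channel for a condition
cohort using only *structured* trial–article links — the registry's
result-reference field and the bibliographic secondary-identifier
(DataBank) field — and prioritizes the resulting list. Articles that are
never linked by either route are invisible to this method by design
(see Limitations).

The pipeline is: ingest → cohort selection → link discovery and
misclassification filtering → merging and accounting → intervention
aggregation and significance scoring → attention scoring, ranking,
shortlisting → surveillance tables and report.

## Record model and dates

Both registry dialects (API v2 JSON, legacy public XML) and PubMed EFetch
XML map into one shared domain model; the synthetic generator emits
through the inverse serializers, and round-trip equality is enforced by
tests for every field. The AACT relational mirror is deliberately not
parsed: it re-exposes the same registry XML fields.

Registry and article dates can be year- or month-precision. Partial dates
are imputed (month → day 1, year → January 1) but always carry a precision
flag, so interval arithmetic can run on imputed values while reports can
footnote them, and no computation ever consumes a *missing* date — missing
anchors route to explicit `undetermined`/`undatable` states. Day-level
first-posted dates before a configurable era floor (default 1999-01-01)
are rejected as data errors.

Neither public dialect carries the registry record's version history
length, but record-update activity is an input to prioritization; the
record version count is therefore consumed as provided metadata through an
extension field (`versionCount` in JSON, `<version_count>` in XML),
defaulting to 1. The pipeline never crawls historical record versions.

## Cohort rules

A study enters the cohort when any configured lowercase keyword occurs in
its conditions or titles, and its status is eligible. "Active or ended"
eligibility is interpreted as {recruiting, active-not-recruiting,
enrolling-by-invitation, completed, terminated}. The shipped COVID-19
keyword list is representative configuration, not code.

Derived labels:

- **Effective phase**: combined phases promote to the higher phase
  (2/3 → 3, 1/2 → 2); early phase 1 groups with phase 1 (a choice — the
  level is otherwise unaddressed); not-applicable → 0.
- **Registration timing**: *prior* when first-posted ≤ start (same-day
  registration counts as prior), *after* when a completion date (primary
  preferred, else overall) precedes first posting, *during* otherwise,
  *undetermined* on missing anchors.
- **Termination category**: lowercase-substring lexicon over the
  free-text stop reason (recruitment / safety / futility /
  external-results / other / unspecified), checked in that order, first
  match wins. The lexicon is an editable config.
- **Vaccine trial**: case-insensitive keyword (default "vaccine") in the
  brief title; the registry has no vaccine intervention type.

## Link discovery and filtering

Registry links come only from result-type references; background and
derived references are ignored. A registry link is removed as
misclassified iff the article's (resolved) publication date is *strictly*
before the trial's start date — a same-day publication is kept, and links
whose article or study cannot be dated are conservatively kept and
flagged, preserving recall. Removed links stay in an audit list and are
excluded from all downstream counting and scoring. Abstract links are
never date-filtered: citing the accession in the abstract is the author's
own claim of relevance.

Merging deduplicates on (NCT, PMID) and unions route sets; the same
article linked to several trials intentionally stays one link per trial
(counts are reported in trial–article–route combinations), with distinct
articles counted separately. The accounting identities
`abstract + registry = combinations` and
`abstract + registry − both = distinct pairs` hold by construction and
are asserted on every corpus.

Article class: a protocol signal (publication type containing "protocol",
or "study protocol" in the title) always wins; otherwise
editorial/comment/letter/review/news types map to *other*; everything
else is a *result* article.

## Scores

**Intervention significance.** Free-text intervention names are
normalized (lowercase, punctuation → space, whitespace collapse,
leading/trailing dose tokens stripped, synonym map last) and aggregated
per intervention into per-phase trial counts. The score adds, for each
phase level with at least one trial, the phase value plus 0.01 per trial
in that level. The unphased (N/A) level contributes at base value 1: this
weight is *derived* — it is the unique value consistent with every
published per-phase count row we reproduce — not stated anywhere.
Arithmetic is done in integer hundredths so two-decimal printed values
reproduce exactly; tables print two decimals.

**Attention score.** The published construct names its inputs (recency,
phase, intervention significance, record updates, US site, article type)
but not a functional form; the form shipped here is this package's own
explicit parameterization:

```
type_weight[class] × ( effective_phase
                      + us_bonus · 1[focus-country site]
                      + min(update_unit · (version_count − 1), update_cap)
                      + recency_weight · exp(−age_days / recency_scale)
                      + intervention_weight · normalized_significance )
```

Defaults: type weights 1.0 / 0.5 / 0.25 (result / protocol / other),
us_bonus 0.5, update_unit 0.01 per update capped at 0.25, recency_weight
0.25 with a 180-day e-folding scale, intervention_weight 0.1. Rationale:
the phase term (0–4) dominates, mirroring the published emphasis on late
phase; each secondary signal contributes at most ~0.5 so no combination
of secondaries outweighs a one-phase difference; recency is continuous
(banding would create arbitrary cliffs). All weights are config, and the
per-term breakdown is exported so users can re-weight without rescoring
internals. Published per-article attention values are not reproducible
from the text and are not targeted.

Ranking is by score descending with deterministic tie-breaks
(publication date descending, then PMID ascending — invented for
determinism). The shortlist keeps result articles from effective-phase-3
trials with a focus-country site and at least 2 updates beyond initial
registration (version_count ≥ 3), configurable.

## Reporting

Percentages are rounded half-up to one decimal; the review-time estimate
is `(n_full − n_short) × minutes_per_abstract / 60` hours (default 2
minutes per abstract). Publication lag is anchored on trial start (many
registry completion dates are anticipated, not actual) and averaged over
non-protocol links with both dates; pre-completion publications are
result-class links whose trial's completion date (primary preferred) is
missing or after the reference date. The deposition cross-tab partitions
the cohort into deposit-only / deposit-and-article / article-only /
neither, where "article" means at least one kept result-class link.
Zero-information studies have no links and a single record version.

## Synthetic corpus generator

The generator is first-class, tested code. It emulates: keyword hits,
status/phase/update-count/registration-timing mixes, the two link routes
with overlap, backdated (misclassified) registry references, protocol and
editorial article types, vaccine titles, focus-country sites, result
deposition, shared articles citing two trials, non-cohort citations and
unlinked background articles. Rate parameters that define ground truth
are planted exactly (`round(rate × pool)` members chosen by the seeded
stream); categorical mixes are drawn per record. One stream per record
category is spawned from the master seed, so enlarging one category does
not perturb another's draws.

Default conditions: 2000 interventional / 300 observational / 50 registry
studies; registration-timing mix 44.9 / 43.3 / 11.8 (prior/during/after);
publication lags truncated-normal with mean 149 days, sd 40, minimum 1
day; route rates 0.30 registry (raw references), 0.16 abstract, 0.005
both, with 55% of raw registry references backdated — choices that
reproduce the published route mix (≈55:45 kept abstract:registry, ≈1.5%
overlap, and a removed-reference count of the same order as the kept
registry links). Reference date ("as of") 2021-08-15. Offsets between
registration, start and completion are kept ≥ 32 days so month-precision
imputation can never flip a planted timing label, and a month-imputed
publication date is promoted back to day precision when imputation would
make a true link look backdated.

What passing tests show — and do not. Exact recovery of planted links,
misclassified references, cohorts and categories demonstrates the
pipeline's logic is correct under clean identifiers and well-formed
records. Real registries add free-text noise the generator does not
model: misspelled intervention strings beyond the synonym map, inaccurate
or retrospectively edited dates, and result articles with no structured
link at all. Recovery rates here are therefore upper bounds on real-data
behaviour.

## Numerical and degenerate-input choices

- Significance scores computed in integer hundredths (exact two-decimal
  reproduction); stored at full precision, printed to 2 decimals.
- Percentage and hours rounding: decimal half-up, one decimal.
- Empty cohort / empty link list: empty outputs, not errors; percentage
  with a zero denominator raises.
- Articles dated after the reference date get age 0 (no negative-age
  boost).
- Unknown publication-type strings are preserved verbatim and classified
  as result unless a protocol/other signal matches.
- Normalization that empties a name (e.g. pure punctuation) rejects that
  name with the original string; the study still counts for other names.

## Test and acceptance problem sizes

The default suite exercises a 250-study corpus end to end plus targeted
2000-study (link recovery) and 800-study (lag recovery, 400 links) runs —
sizes at which planted-count arithmetic is exact and recovery claims are
meaningful, while the whole suite stays fast.

## Known limitations

- Unlinked result articles are invisible; prior work suggests structured
  links can miss a large fraction of result articles.
- Single registry family (NCT accessions); no EUCTR/ChiCTR, no
  multi-registry deduplication.
- Intervention normalization is string-based; distinct strings for the
  same agent beyond the synonym map fragment the profile.
- The attention score's functional form is this package's
  parameterization of a published list of inputs; rankings under other
  reasonable forms will differ in detail.
- The monthly-refresh/publication workflow around the original analysis
  is out of scope; this package is the computational core only.
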