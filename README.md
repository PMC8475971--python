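# trialpub

Link registered clinical studies to their result publications, and rank
what to read first.

During fast-moving disease outbreaks (COVID-19 being the motivating case)
thousands of trials are registered and the literature quickly outgrows what
any reader can review. Most of that literature, however, can be tied back
to a registered study through two *structured* routes, with no text mining:

- **registry link** — the study team lists a result reference (with PMID)
  inside the ClinicalTrials.gov study record;
- **abstract link** — the article abstract cites the trial's NCT accession,
  which PubMed exposes as a searchable *secondary identifier* (DataBank
  entry).

`trialpub` parses both record families (ClinicalTrials.gov API v2 JSON and
legacy XML; PubMed EFetch XML), selects a condition cohort by keyword,
discovers links through both routes, removes misclassified registry
references (a "result" reference published *before* the trial started
cannot report its results), merges everything into a deduplicated master
list, and then prioritizes it with two scores:

**Intervention significance score.** For an intervention with per-phase
trial counts $n_p$ (phase levels $p \in \{0,1,2,3,4\}$, combined phases
promoted to the higher phase, unphased trials at level 0 with base value 1):

$$S = \sum_{p\,:\,n_p>0} \left( v_p + 0.01\,n_p \right), \qquad
v_p = \max(p, 1)$$

so an intervention with 12 phase-3 trials gains 3.12 from phase 3 alone.

**Publication attention score.** Each trial–article link is scored

$$A = w_{\text{type}} \times \Big( \text{phase} + b_{US}\,\mathbb{1}[\text{US site}]
+ \min(u\,(\text{versions}-1),\, c) + r\,e^{-\text{age}/\tau}
+ w_I\, \tilde S \Big)$$

where $w_{\text{type}}$ down-weights protocols (0.5) and
editorials/comments (0.25) relative to result articles (1.0), and
$\tilde S$ is the intervention score normalized by the corpus maximum.
Every weight is configuration, and each score ships with its per-term
breakdown. A shortlist keeps result articles from phase-3 trials with a US
site and multiple record updates.

A seeded synthetic-corpus generator (`trialpub.synthetic`) emits both
registry dialects and EFetch article sets with exact ground-truth sidecars,
so the whole pipeline is testable offline.

## Worked example

```python
from trialpub.scoring import build_intervention_profiles
from trialpub.reporting import build_intervention_table
from trialpub.synthetic import make_paper_fixture

profiles = build_intervention_profiles(make_paper_fixture())
print(build_intervention_table(profiles, top_n=5).to_string(index=False))
```

```
      intervention  trial_count  phase_1  phase_2  phase_3  phase_4  phase_na  significance_score  sponsor_count  publication_count
hydroxychloroquine          120        3       36       54       16        11               12.20             12                  0
        remdesivir           43        1       10       26        3         3               11.43             12                  0
       tocilizumab           40        1       18       12        3         6               11.40             12                  0
     dexamethasone           24        0        2       13        7         2               10.24             12                  0
         mrna 1273            9        3        2        4        0         0                6.09              9                  0
```

The fixture materializes free-text trial records (dose suffixes, synonyms,
case variants) whose normalized aggregation yields these per-phase counts;
the scores follow from the formula above — e.g. hydroxychloroquine:
$1.03 + 2.36 + 3.54 + 4.16 + 1.11 = 12.20$.

An end-to-end run on a synthetic corpus:

```python
from trialpub import AppConfig, CorpusSpec, generate_corpus, run_pipeline

spec = CorpusSpec(n_interventional=500, n_observational=80, n_registry=20, seed=42)
corpus = generate_corpus(spec)
res = run_pipeline(corpus.studies, corpus.articles, AppConfig(), spec.as_of)
a = res.summary.accounting
print(a.n_combinations, a.n_abstract, a.n_registry, a.n_both,
      a.n_distinct_pairs, a.n_removed_misclassified)
```

prints `132 72 60 2 130 74`: 132 (link, route) combinations from 72
abstract and 60 registry links, 2 pairs found by both routes (hence 130
distinct pairs), and 74 registry references removed as misclassified.
Route counts always satisfy the inclusion–exclusion identity
`abstract + registry − both = distinct pairs`.

The same pipeline is available from a shell:

```bash
trialpub simulate --seed 42 --out-dir corpus/
trialpub run corpus/studies_api.json corpus/articles.xml \
    --as-of 2021-08-15 --out-dir out/
```

which writes the trial tables, the master publication list per study-type
scope, the ranked/shortlisted article list with score components, the
per-intervention phase-count table and a markdown run report. Exit codes:
0 success, 2 configuration error, 3 input parse error. See
`examples/config.yaml` for the configuration schema.

## Documentation

`docs/methods.md` describes the model, its assumptions, the parameter
defaults (and why), what the synthetic generator does and does not
emulate, and known limitations.
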