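"""Link extraction, misclassification filtering, merging and accounting."""

import datetime as dt

import pytest
from hypothesis import given
from hypothesis import strategies as st

from trialpub.cohort import select_cohort
from trialpub.config import AppConfig
from trialpub.linkage import (
    classify_article,
    extract_registry_links,
    filter_misclassified,
    find_abstract_links,
    merge_links,
)
from trialpub.models import (
    ArticleClass,
    ArticleRecord,
    LinkSource,
    PartialDate,
    Reference,
    ReferenceType,
    SecondaryId,
    StudyRecord,
    TrialArticleLink,
)
from trialpub.synthetic import CorpusSpec, generate_corpus


def study(nct="NCT04000001", **kw) -> StudyRecord:
    base = dict(nct_id=nct, brief_title="T")
    base.update(kw)
    return StudyRecord(**base)


def article(pmid="100", **kw) -> ArticleRecord:
    base = dict(pmid=pmid, title="A")
    base.update(kw)
    return ArticleRecord(**base)


def link(nct, pmid, source) -> TrialArticleLink:
    return TrialArticleLink(nct_id=nct, pmid=pmid, sources=frozenset({source}))


def test_extract_registry_links_uses_only_result_references():
    s = study(
        references=[
            Reference(pmid="1", reference_type=ReferenceType.RESULT_REFERENCE),
            Reference(pmid="2", reference_type=ReferenceType.BACKGROUND),
            Reference(pmid="3", reference_type=ReferenceType.DERIVED),
            Reference(pmid=None, reference_type=ReferenceType.RESULT_REFERENCE),
        ]
    )
    out = extract_registry_links(s)
    assert [(l.nct_id, l.pmid) for l in out] == [("NCT04000001", "1")]
    assert out[0].sources == frozenset({LinkSource.REGISTRY})
    assert extract_registry_links(study(references=[])) == []


def test_filter_misclassified_strict_boundary_and_undatable():
    s = study(start_date=PartialDate.from_parts(2020, 3, 1))
    arts = {
        "1": article("1", publication_date=PartialDate.from_parts(2019, 5, 1)),
        "2": article("2", publication_date=PartialDate.from_parts(2020, 3, 1)),
        "3": article("3"),  # no date
    }
    links = [link(s.nct_id, p, LinkSource.REGISTRY) for p in ("1", "2", "3")]
    kept, removed = filter_misclassified(links, arts, {s.nct_id: s})
    assert [l.pmid for l in removed] == ["1"]
    assert removed[0].removed_as_misclassified
    assert [l.pmid for l in kept] == ["2", "3"]
    assert not kept[0].undatable and kept[1].undatable
    # idempotent and contained in input
    kept2, removed2 = filter_misclassified(kept, arts, {s.nct_id: s})
    assert removed2 == [] and {l.pmid for l in kept2} == {l.pmid for l in kept}


def test_abstract_links_multiplicity_and_cohort_restriction():
    cohort = {"NCT04000001", "NCT04000002", "NCT04000003"}
    multi = article(
        "9",
        secondary_ids=[
            SecondaryId(databank="ClinicalTrials.gov", accession=n)
            for n in ("NCT04000001", "NCT04000002", "NCT04000003")
        ],
    )
    outside = article(
        "10",
        secondary_ids=[SecondaryId(databank="ClinicalTrials.gov", accession="NCT09999999")],
    )
    other_bank = article(
        "11", secondary_ids=[SecondaryId(databank="GenBank", accession="AB123")]
    )
    out = find_abstract_links([multi, outside, other_bank], cohort)
    assert {(l.nct_id, l.pmid) for l in out} == {(n, "9") for n in cohort}


@pytest.mark.parametrize(
    "types, title, expected",
    [
        (["Randomized Controlled Trial", "Journal Article"], "x", ArticleClass.RESULT),
        (["Editorial"], "x", ArticleClass.OTHER),
        (["Journal Article"], "Trial X: a Study Protocol", ArticleClass.PROTOCOL),
        (["Clinical Trial Protocol", "Editorial"], "x", ArticleClass.PROTOCOL),
        (["Letter"], "x", ArticleClass.OTHER),
        ([], "x", ArticleClass.RESULT),
    ],
)
def test_classify_article_precedence(types, title, expected):
    assert classify_article(article(publication_types=types, title=title)) is expected


def test_merge_links_unions_sources_and_counts_once():
    reg = [link("NCT04000001", "5", LinkSource.REGISTRY)]
    abs_ = [link("NCT04000001", "5", LinkSource.ABSTRACT)]
    master, acc = merge_links(reg, abs_)
    assert len(master) == 1
    assert master[0].sources == frozenset({LinkSource.REGISTRY, LinkSource.ABSTRACT})
    assert (acc.n_both, acc.n_distinct_pairs, acc.n_combinations) == (1, 1, 2)


def test_merge_links_set_arithmetic():
    # abstract route finds {1,2}, registry route {2,3}; overlap is {2}
    reg = [link("NCT04000001", p, LinkSource.REGISTRY) for p in ("2", "3")]
    abs_ = [link("NCT04000001", p, LinkSource.ABSTRACT) for p in ("1", "2")]
    master, acc = merge_links(reg, abs_)
    assert {l.pmid for l in master} == {"1", "2", "3"}
    assert acc.n_both == 1 and acc.n_distinct_pairs == 3


@given(
    reg=st.sets(st.integers(0, 60), max_size=40),
    abs_=st.sets(st.integers(0, 60), max_size=40),
)
def test_merge_accounting_conservation(reg, abs_):
    """n_abstract + n_registry − n_both equals the master-list size."""
    reg_links = [link("NCT04000001", str(p + 1), LinkSource.REGISTRY) for p in reg]
    abs_links = [link("NCT04000001", str(p + 1), LinkSource.ABSTRACT) for p in abs_]
    master, acc = merge_links(reg_links, abs_links)
    assert acc.n_abstract + acc.n_registry - acc.n_both == len(master)
    assert acc.n_distinct_articles <= acc.n_distinct_pairs


def test_pipeline_recovers_ground_truth_links(small_corpus, small_result):
    gt = small_corpus.ground_truth
    recovered = {
        (l.nct_id, l.pmid): frozenset(s.value for s in l.sources)
        for l in small_result.links
    }
    assert recovered == dict(gt.true_links)
    assert {(l.nct_id, l.pmid) for l in small_result.removed} == gt.planted_misclassified
    for pmid, cls in gt.article_classes.items():
        for l in small_result.links:
            if l.pmid == pmid:
                assert l.article_class is cls


def test_noise_free_corpus_recovers_exactly():
    spec = CorpusSpec(
        n_interventional=120, n_observational=20, n_registry=5,
        p_misclassified_backdate=0.0, seed=11,
    )
    corpus = generate_corpus(spec)
    from trialpub.pipeline import run_pipeline

    res = run_pipeline(corpus.studies, corpus.articles, AppConfig(), spec.as_of)
    assert {(l.nct_id, l.pmid) for l in res.links} == set(corpus.ground_truth.true_links)
    assert res.removed == []


def test_merge_matches_brute_force_oracle(small_corpus, small_result, default_config):
    """Master list equals an independent nested-loop construction."""
    studies = small_corpus.studies
    articles = small_corpus.articles
    cohort = select_cohort(studies, default_config.cohort)
    cohort_ncts = {s.nct_id for s in cohort}
    art_by_pmid = {a.pmid: a for a in articles}

    expected: dict[tuple[str, str], set[str]] = {}
    for s in cohort:
        for ref in s.references:
            if ref.reference_type is not ReferenceType.RESULT_REFERENCE or ref.pmid is None:
                continue
            a = art_by_pmid.get(ref.pmid)
            pub = a.publication_date if a else None
            if pub is not None and s.start_date is not None and pub.value < s.start_date.value:
                continue  # misclassified
            expected.setdefault((s.nct_id, ref.pmid), set()).add("registry")
    for a in articles:
        for nct in a.nct_accessions():
            if nct in cohort_ncts:
                expected.setdefault((nct, a.pmid), set()).add("abstract")

    got = {
        (l.nct_id, l.pmid): {s.value for s in l.sources} for l in small_result.links
    }
    assert got == expected
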