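"""Aggregate tables, percentages, timing analytics and output files."""

import datetime as dt

import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from trialpub.models import (
    ArticleClass,
    InterventionProfile,
    LinkSource,
    OverallStatus,
    PartialDate,
    StudyRecord,
    TrialArticleLink,
)
from trialpub.reporting import (
    build_intervention_table,
    deposit_crosstab,
    percentage,
    pre_completion_publications,
    publication_lag_stats,
    render_report,
    review_time_saved,
    write_outputs,
)

AS_OF = dt.date(2021, 8, 15)


def study(nct="NCT04000001", **kw):
    base = dict(nct_id=nct, brief_title="T")
    base.update(kw)
    return StudyRecord(**base)


def link(nct, pmid, cls=ArticleClass.RESULT, pub=None):
    return TrialArticleLink(
        nct_id=nct,
        pmid=pmid,
        sources=frozenset({LinkSource.ABSTRACT}),
        article_class=cls,
        publication_date=pub,
    )


@pytest.mark.parametrize(
    "n, d, expected",
    [
        (419, 2669, 15.7),
        (418, 760, 55.0),
        (40, 290, 13.8),  # 13.793 rounds half-up to one decimal
        (0, 10, 0.0),
        (1, 8, 12.5),
        (1, 16, 6.3),  # 6.25 -> half-up
    ],
)
def test_percentage_half_up(n, d, expected):
    assert percentage(n, d) == expected


def test_percentage_rejects_zero_denominator():
    with pytest.raises(ValueError):
        percentage(1, 0)


@pytest.mark.parametrize(
    "full, short, minutes, expected",
    [(760, 58, 2, 23.4), (100, 100, 2, 0.0), (10, 0, 6, 1.0)],
)
def test_review_time_saved(full, short, minutes, expected):
    assert review_time_saved(full, short, minutes) == expected


def test_review_time_saved_rejects_longer_shortlist():
    with pytest.raises(ValueError):
        review_time_saved(5, 6)


def profile(name, score, trials, counts=None):
    counts = counts if counts is not None else {3: trials}
    return InterventionProfile(
        canonical_name=name,
        trial_count=sum(counts.values()),
        phase_counts=counts,
        significance_score=score,
    )


def test_intervention_table_sort_and_truncation():
    profiles = [
        profile("b drug", 11.43, 20, {3: 20}),
        profile("a drug", 11.43, 25, {3: 25}),
        profile("c drug", 12.2, 10, {3: 10}),
        profile("d drug", 11.43, 20, {3: 20}),
    ]
    df = build_intervention_table(profiles, top_n=3)
    assert list(df["intervention"]) == ["c drug", "a drug", "b drug"]
    empty = build_intervention_table([], top_n=5)
    assert list(empty.columns)[0] == "intervention" and empty.empty
    single = build_intervention_table([profile("x", 3.01, 1, {3: 1})], top_n=10)
    assert len(single) == 1


def test_publication_lag_example_and_protocol_exclusion():
    s = study(start_date=PartialDate.from_parts(2020, 3, 2))
    links = [
        link(s.nct_id, "1", pub=PartialDate.from_parts(2020, 7, 30)),
        link(s.nct_id, "2", cls=ArticleClass.PROTOCOL, pub=PartialDate.from_parts(2020, 4, 1)),
        link(s.nct_id, "3"),  # undatable
    ]
    stats = publication_lag_stats(links, {s.nct_id: s}, AS_OF)
    assert stats.lags == [150]
    assert stats.mean_days == 150
    assert stats.n == 1 and stats.n_undatable == 1


def test_lag_recovery_on_planted_corpus(small_corpus, small_result):
    gt = small_corpus.ground_truth
    by_nct = {s.nct_id: s for s in small_corpus.studies}
    stats = publication_lag_stats(small_result.links, by_nct, AS_OF)
    expected = [
        gt.lags[(l.nct_id, l.pmid)]
        for l in small_result.links
        if l.article_class is not ArticleClass.PROTOCOL
    ]
    assert sorted(stats.lags) == sorted(expected)


def test_pre_completion_publications_rules():
    future = study("NCT04470427", primary_completion_date=PartialDate.from_parts(2022, 10, 27))
    done = study("NCT04000002", completion_date=PartialDate.from_parts(2020, 6, 1))
    links = [
        link(future.nct_id, "33378609", pub=PartialDate.from_parts(2020, 12, 1)),
        link(done.nct_id, "2", pub=PartialDate.from_parts(2021, 1, 1)),
        link(future.nct_id, "3", cls=ArticleClass.PROTOCOL),
    ]
    n, hits, n_trials = pre_completion_publications(
        links, {s.nct_id: s for s in (future, done)}, AS_OF
    )
    assert n == 1 and n_trials == 1
    assert hits[0].pmid == "33378609"


def test_pre_completion_matches_ground_truth(small_corpus, small_result):
    gt = small_corpus.ground_truth
    by_nct = {s.nct_id: s for s in small_corpus.studies}
    n, hits, _ = pre_completion_publications(small_result.links, by_nct, AS_OF)
    assert {(l.nct_id, l.pmid) for l in hits} == gt.pre_completion_links


def test_deposit_crosstab_examples_and_partition(small_corpus, small_result):
    dep = study("NCT04000001", has_deposited_results=True)
    both = study("NCT04000002", has_deposited_results=True)
    art = study("NCT04000003")
    none = study("NCT04000004")
    links = [link(both.nct_id, "1"), link(art.nct_id, "2")]
    cells = deposit_crosstab([dep, both, art, none], links)
    assert cells == {
        "deposit_only": 1, "deposit_and_article": 1, "article_only": 1, "neither": 1,
    }
    # partition on a full synthetic cohort
    cohort_cells = deposit_crosstab(small_result.cohort, small_result.links)
    assert sum(cohort_cells.values()) == len(small_result.cohort)


@given(
    st.lists(
        st.tuples(st.booleans(), st.booleans()), min_size=0, max_size=40
    )
)
def test_deposit_crosstab_partitions_any_cohort(flags):
    studies, links = [], []
    for i, (deposited, has_article) in enumerate(flags):
        s = study(f"NCT{4_100_000 + i:08d}", has_deposited_results=deposited)
        studies.append(s)
        if has_article:
            links.append(link(s.nct_id, str(100 + i)))
    cells = deposit_crosstab(studies, links)
    assert sum(cells.values()) == len(studies)


def test_summary_percentages_are_self_consistent(small_result):
    s = small_result.summary
    assert s.pct_with_any_result_article == percentage(
        s.n_with_any_result_article, s.n_cohort
    )
    assert s.n_deposit_only + s.n_deposit_and_article == s.n_deposited_results
    a = s.accounting
    assert a.n_abstract + a.n_registry - a.n_both == a.n_distinct_pairs


def test_write_outputs_and_csv_round_trip(tmp_path, small_corpus, small_result):
    """The stored intervention table reloads equal to the in-memory one."""
    written = write_outputs(
        tmp_path, "proj", small_corpus.studies, small_result.cohort,
        small_result.links, small_result.removed, small_result.profiles,
        small_result.ranked, small_result.summary,
    )
    names = {p.name for p in written}
    assert {
        "proj_trials_all.csv", "proj_trials_int.csv",
        "proj_publication_list_all.csv", "proj_publication_list_int.csv",
        "proj_Master.csv", "proj_intervention-phase_cnts_int.csv",
        "proj_report.md",
    } <= names
    table = build_intervention_table(small_result.profiles, len(small_result.profiles))
    reloaded = pd.read_csv(tmp_path / "proj_intervention-phase_cnts_int.csv")
    pd.testing.assert_frame_equal(reloaded, table.reset_index(drop=True))
    report = (tmp_path / "proj_report.md").read_text()
    assert str(small_result.accounting.n_distinct_pairs) in report


def test_render_report_mentions_key_quantities(small_result):
    text = render_report("proj", small_result.summary)
    assert "distinct (trial, article) pairs" in text
    assert str(small_result.summary.n_cohort) in text
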