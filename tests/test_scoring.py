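"""Intervention normalization, significance scoring, attention ranking."""

import datetime as dt
import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from trialpub.models import (
    ArticleClass,
    AttentionWeights,
    LinkSource,
    PartialDate,
    Phase,
    StudyRecord,
    TrialArticleLink,
)
from trialpub.scoring import (
    attention_score,
    build_intervention_profiles,
    intervention_norms,
    intervention_significance_score,
    normalize_intervention,
    rank_publications,
    shortlist,
)

AS_OF = dt.date(2021, 8, 15)


# ---------------------------------------------------------------------------
# normalization


@pytest.mark.parametrize(
    "raw, expected",
    [
        ("Hydroxychloroquine 200mg", "hydroxychloroquine"),
        ("Remdesivir", "remdesivir"),
        ("HCQ", "hydroxychloroquine"),
        ("Anti-SARS-CoV-2 Convalescent Plasma", "convalescent plasma"),
        ("Vitamin D 50000 IU", "vitamin d"),
        ("Lopinavir/Ritonavir", "lopinavir ritonavir"),
        ("  tocilizumab  8 mg ", "tocilizumab"),
    ],
)
def test_normalize_intervention(raw, expected):
    assert normalize_intervention(raw) == expected


def test_normalize_rejects_empty_results():
    with pytest.raises(ValueError):
        normalize_intervention("!!!")


@given(st.text(alphabet=st.characters(whitelist_categories=("Ll", "Lu", "Nd", "Po", "Zs")), min_size=1, max_size=30))
def test_normalize_is_idempotent(raw):
    try:
        once = normalize_intervention(raw)
    except ValueError:
        return
    assert normalize_intervention(once) == once


# ---------------------------------------------------------------------------
# significance score


@pytest.mark.parametrize(
    "counts, expected",
    [
        ({3: 12}, 3.12),
        ({1: 3, 2: 2, 3: 4}, 6.09),
        ({1: 3, 2: 36, 3: 54, 4: 16, 0: 11}, 12.2),
        ({}, 0.0),
        ({2: 0, 3: 1}, 3.01),  # zero-count levels contribute nothing
        ({0: 7}, 1.07),
    ],
)
def test_intervention_significance_score(counts, expected):
    assert intervention_significance_score(counts) == expected


def test_significance_score_rejects_bad_inputs():
    with pytest.raises(ValueError):
        intervention_significance_score({3: -1})
    with pytest.raises(ValueError):
        intervention_significance_score({5: 1})


phase_counts_st = st.dictionaries(
    st.integers(0, 4), st.integers(0, 60), max_size=5
)


@given(phase_counts_st, st.integers(0, 4))
def test_score_monotone_in_trial_counts(counts, level):
    """+0.01 for one more trial in an existing phase; value + 0.01 for a
    trial opening a new phase level."""
    base = intervention_significance_score(counts)
    bumped = dict(counts)
    bumped[level] = bumped.get(level, 0) + 1
    new = intervention_significance_score(bumped)
    delta = round(new - base, 2)
    if counts.get(level, 0) > 0:
        assert delta == 0.01
    else:
        value = 1 if level == 0 else level
        assert delta == round(value + 0.01, 2)


def test_profiles_from_worked_example_fixture(paper_fixture_studies):
    """Free-text trial records aggregate to the published score profiles."""
    profiles = {
        p.canonical_name: p for p in build_intervention_profiles(paper_fixture_studies)
    }
    assert profiles["hydroxychloroquine"].phase_counts == {1: 3, 2: 36, 3: 54, 4: 16, 0: 11}
    assert profiles["hydroxychloroquine"].significance_score == 12.2
    assert profiles["remdesivir"].significance_score == 11.43
    assert profiles["tocilizumab"].significance_score == 11.4
    assert profiles["dexamethasone"].significance_score == 10.24
    assert profiles["mrna 1273"].significance_score == 6.09
    # every profile's stored score recomputes from its own phase counts
    for p in profiles.values():
        assert p.significance_score == intervention_significance_score(p.phase_counts)


# ---------------------------------------------------------------------------
# attention score


def make_link(pmid="100", cls=ArticleClass.RESULT, pub=None):
    return TrialArticleLink(
        nct_id="NCT04000001",
        pmid=pmid,
        sources=frozenset({LinkSource.ABSTRACT}),
        article_class=cls,
        publication_date=pub,
    )


def make_study(**kw):
    base = dict(
        nct_id="NCT04000001",
        brief_title="T",
        phase=Phase.PHASE_3,
        site_countries=["United States"],
        version_count=11,
    )
    base.update(kw)
    return StudyRecord(**base)


def test_attention_score_default_formula():
    """Phase-3 US result article, 10 updates, age 0, top intervention."""
    link = make_link(pub=PartialDate.from_parts(2021, 8, 15))
    sp = attention_score(link, make_study(), None, 1.0, AttentionWeights(), AS_OF)
    assert sp.attention_score == pytest.approx(3.95)
    protocol = make_link(cls=ArticleClass.PROTOCOL, pub=PartialDate.from_parts(2021, 8, 15))
    sp2 = attention_score(protocol, make_study(), None, 1.0, AttentionWeights(), AS_OF)
    assert sp2.attention_score == pytest.approx(1.975)


def test_attention_score_vanishes_without_any_signal():
    link = make_link(pub=PartialDate.from_parts(2000, 1, 1))
    s = make_study(phase=Phase.NA, site_countries=[], version_count=1)
    sp = attention_score(link, s, None, 0.0, AttentionWeights(), AS_OF)
    assert sp.attention_score == pytest.approx(0.0, abs=1e-8)


def test_attention_score_monotonicities():
    w = AttentionWeights()
    pub = PartialDate.from_parts(2021, 1, 1)

    def score(**kw):
        return attention_score(make_link(pub=pub), make_study(**kw), None, 0.5, w, AS_OF).attention_score

    assert score(phase=Phase.PHASE_2) < score(phase=Phase.PHASE_3)
    assert score(version_count=2) < score(version_count=10)
    # update term caps at `update_cap`
    assert score(version_count=26) == score(version_count=40)
    assert score(site_countries=[]) < score(site_countries=["United States"])
    old = attention_score(
        make_link(pub=PartialDate.from_parts(2020, 1, 1)), make_study(), None, 0.5, w, AS_OF
    ).attention_score
    new = attention_score(
        make_link(pub=PartialDate.from_parts(2021, 8, 1)), make_study(), None, 0.5, w, AS_OF
    ).attention_score
    assert old < new
    low = attention_score(make_link(pub=pub), make_study(), None, 0.1, w, AS_OF)
    high = attention_score(make_link(pub=pub), make_study(), None, 0.9, w, AS_OF)
    assert low.attention_score < high.attention_score


def test_attention_score_structural_zero_limit():
    """With all structural weights zero the score collapses to
    type_weight × effective phase."""
    w = AttentionWeights(
        us_bonus=0.0, update_unit=0.0, update_cap=0.0,
        recency_weight=0.0, intervention_weight=0.0,
    )
    for cls, tw in ((ArticleClass.RESULT, 1.0), (ArticleClass.PROTOCOL, 0.5)):
        sp = attention_score(
            make_link(cls=cls, pub=PartialDate.from_parts(2021, 1, 1)),
            make_study(), None, 1.0, w, AS_OF,
        )
        assert sp.attention_score == pytest.approx(tw * 3)


def test_scoring_removed_link_is_refused():
    link = make_link().model_copy(update={"removed_as_misclassified": True})
    with pytest.raises(ValueError):
        attention_score(link, make_study(), None, 0.0, AttentionWeights(), AS_OF)


# ---------------------------------------------------------------------------
# ranking and shortlist


def scored(pmid, score, pub=None):
    from trialpub.models import ScoredPublication

    return ScoredPublication(
        link=make_link(pmid=pmid, pub=pub),
        attention_score=score,
        effective_phase=3,
        has_us_site=True,
        version_count=5,
    )


def test_rank_orders_by_score_then_date_then_pmid():
    items = [
        scored("1", 2.0),
        scored("2", 3.0),
        scored("3", 1.0),
        scored("4", 2.0, pub=PartialDate.from_parts(2021, 5, 1)),
        scored("5", 2.0, pub=PartialDate.from_parts(2020, 5, 1)),
    ]
    ranked = rank_publications(items)
    assert [r.link.pmid for r in ranked] == ["2", "4", "5", "1", "3"]
    assert [r.rank for r in ranked] == [1, 2, 3, 4, 5]


def test_rank_matches_brute_force_oracle_on_1000():
    import numpy as np

    rng = np.random.default_rng(123)
    items = [
        scored(
            str(10_000 + i),
            float(rng.choice([1.0, 2.0, 2.5, 3.0])),
            pub=PartialDate.from_parts(2020, 1 + int(rng.integers(12)), 1),
        )
        for i in range(1000)
    ]
    ranked = rank_publications(items)
    oracle = sorted(
        items,
        key=lambda sp: (
            -sp.attention_score,
            -(sp.link.publication_date.value.toordinal() if sp.link.publication_date else 0),
            int(sp.link.pmid),
        ),
    )
    assert [r.link.pmid for r in ranked] == [o.link.pmid for o in oracle]
    assert [r.rank for r in ranked] == list(range(1, 1001))


def test_shortlist_filters_and_preserves_order():
    keep = scored("1", 3.0)
    wrong_class = scored("2", 3.0).model_copy(
        update={"link": make_link(pmid="2", cls=ArticleClass.PROTOCOL)}
    )
    wrong_phase = scored("3", 3.0).model_copy(update={"effective_phase": 2})
    no_us = scored("4", 3.0).model_copy(update={"has_us_site": False})
    few_updates = scored("5", 3.0).model_copy(update={"version_count": 2})
    ranked = rank_publications([keep, wrong_class, wrong_phase, no_us, few_updates])
    out = shortlist(ranked, min_updates=2)
    assert [sp.link.pmid for sp in out] == ["1"]
    assert out[0].on_shortlist
    # idempotent
    assert [sp.link.pmid for sp in shortlist(out, min_updates=2)] == ["1"]


def test_shortlist_recovers_planted_qualifying_links(small_corpus, small_result):
    gt = small_corpus.ground_truth
    by_nct = {s.nct_id: s for s in small_corpus.studies}
    expected = set()
    for (nct, pmid) in gt.true_links:
        s = by_nct[nct]
        from trialpub.cohort import effective_phase

        if (
            gt.article_classes[pmid].value == "result"
            and effective_phase(s.phase) == 3
            and "United States" in s.site_countries
            and s.version_count >= 3
        ):
            expected.add((nct, pmid))
    got = {(sp.link.nct_id, sp.link.pmid) for sp in small_result.shortlisted}
    assert got == expected
    ranks = [sp.rank for sp in small_result.shortlisted]
    assert ranks == sorted(ranks)
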