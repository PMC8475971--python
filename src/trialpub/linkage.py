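"""Trial–article link discovery, misclassification filtering and merging.

Links arise through two structured routes:

* **registry route** — the study team lists a result reference (with PMID)
  inside the registry study record;
* **abstract route** — the article abstract cites the trial accession,
  which the bibliographic database exposes as a searchable secondary
  identifier (DataBank entry).

Registry result references are known to sometimes be mislabelled: a
reference published *before* the trial started cannot report its results.
Such links are removed (strict ``<`` comparison on resolved dates; a
same-day publication is kept) but retained in an audit list.  Undatable
links are conservatively kept and flagged.  The two routes are then merged
into a deduplicated master list with full route accounting.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

from .models import (
    ArticleClass,
    ArticleRecord,
    LinkAccounting,
    LinkSource,
    StudyRecord,
    TrialArticleLink,
)

log = logging.getLogger(__name__)

#: Publication types that mark a non-result, non-protocol article.
_OTHER_TYPES = {
    "editorial", "comment", "letter", "review", "news",
    "published erratum", "retraction of publication",
}


def extract_registry_links(study: StudyRecord) -> list[TrialArticleLink]:
    """One link per result reference in the study record.

    Background and derived references are ignored; a result reference
    without a PMID is skipped with a warning.
    """
    links: list[TrialArticleLink] = []
    for ref in study.references:
        if ref.reference_type.value != "result_reference":
            continue
        if ref.pmid is None:
            log.warning("%s: result reference without PMID skipped", study.nct_id)
            continue
        links.append(
            TrialArticleLink(
                nct_id=study.nct_id,
                pmid=ref.pmid,
                sources=frozenset({LinkSource.REGISTRY}),
            )
        )
    return links


def filter_misclassified(
    links: Sequence[TrialArticleLink],
    articles: Mapping[str, ArticleRecord],
    studies: Mapping[str, StudyRecord],
) -> tuple[list[TrialArticleLink], list[TrialArticleLink]]:
    """Split registry links into (kept, removed-as-misclassified).

    A link is removed iff the article's publication date is strictly
    before the trial's start date.  Links whose article or study cannot be
    dated are kept and flagged ``undatable``.  Abstract links must never be
    passed through this filter.
    """
    kept: list[TrialArticleLink] = []
    removed: list[TrialArticleLink] = []
    for link in links:
        article = articles.get(link.pmid)
        study = studies.get(link.nct_id)
        pub = article.publication_date if article is not None else None
        start = study.start_date if study is not None else None
        if pub is None or start is None:
            kept.append(link.model_copy(update={"undatable": True}))
            continue
        if pub.value < start.value:
            removed.append(link.model_copy(update={"removed_as_misclassified": True}))
        else:
            kept.append(link)
    return kept, removed


def find_abstract_links(
    articles: Iterable[ArticleRecord], cohort_ncts: set[str]
) -> list[TrialArticleLink]:
    """One link per (article, cited cohort accession) pair.

    An article citing *k* cohort trials yields *k* links; citations of
    accessions outside the cohort yield none.
    """
    links: list[TrialArticleLink] = []
    for article in articles:
        for nct in article.nct_accessions():
            if nct in cohort_ncts:
                links.append(
                    TrialArticleLink(
                        nct_id=nct,
                        pmid=article.pmid,
                        sources=frozenset({LinkSource.ABSTRACT}),
                    )
                )
    return links


def classify_article(article: ArticleRecord) -> ArticleClass:
    """Classify an article as result, protocol or other.

    A protocol tag (publication type containing "protocol", or "study
    protocol" in the title) always wins; editorial/comment/letter/review
    types map to ``other``; everything else is a result article.
    """
    types = {t.lower() for t in article.publication_types}
    if any("protocol" in t for t in types) or "study protocol" in article.title.lower():
        return ArticleClass.PROTOCOL
    if types & _OTHER_TYPES:
        return ArticleClass.OTHER
    return ArticleClass.RESULT


def annotate_links(
    links: Iterable[TrialArticleLink], articles: Mapping[str, ArticleRecord]
) -> list[TrialArticleLink]:
    """Attach article class and publication date to each link."""
    out = []
    for link in links:
        article = articles.get(link.pmid)
        update: dict = {}
        if article is not None:
            update["article_class"] = classify_article(article)
            update["publication_date"] = article.publication_date
        out.append(link.model_copy(update=update))
    return out


def _dedupe(links: Sequence[TrialArticleLink]) -> dict[tuple[str, str], TrialArticleLink]:
    out: dict[tuple[str, str], TrialArticleLink] = {}
    for link in links:
        if link.key in out:
            out[link.key] = out[link.key].model_copy(
                update={"sources": out[link.key].sources | link.sources}
            )
        else:
            out[link.key] = link
    return out


def merge_links(
    registry_kept: Sequence[TrialArticleLink],
    abstract_links: Sequence[TrialArticleLink],
    n_removed_misclassified: int = 0,
) -> tuple[list[TrialArticleLink], LinkAccounting]:
    """Merge the two routes into a deduplicated master list.

    A (trial, article) pair present in both routes appears once with
    ``sources = {registry, abstract}``.  The accounting identities
    ``n_abstract + n_registry == n_combinations`` and
    ``n_distinct_pairs == n_abstract + n_registry - n_both`` hold by
    construction.
    """
    registry = _dedupe(registry_kept)
    abstract = _dedupe(abstract_links)
    both_keys = registry.keys() & abstract.keys()

    master: dict[tuple[str, str], TrialArticleLink] = {}
    for key, link in registry.items():
        master[key] = link
    for key, link in abstract.items():
        if key in master:
            master[key] = master[key].model_copy(
                update={
                    "sources": master[key].sources | link.sources,
                    # prefer the annotation-bearing copy's fields if set
                    "undatable": master[key].undatable and link.undatable,
                }
            )
        else:
            master[key] = link

    master_list = list(master.values())
    accounting = LinkAccounting(
        n_combinations=len(registry) + len(abstract),
        n_abstract=len(abstract),
        n_registry=len(registry),
        n_both=len(both_keys),
        n_distinct_pairs=len(master_list),
        n_distinct_articles=len({pmid for (_, pmid) in master}),
        n_removed_misclassified=n_removed_misclassified,
    )
    return master_list, accounting
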