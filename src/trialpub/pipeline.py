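"""End-to-end orchestration: cohort → links → scores → summary."""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .cohort import classify_studies, select_cohort
from .config import AppConfig
from .linkage import (
    annotate_links,
    extract_registry_links,
    filter_misclassified,
    find_abstract_links,
    merge_links,
)
from .models import (
    ArticleRecord,
    InterventionProfile,
    LinkAccounting,
    ScoredPublication,
    StudyClassification,
    StudyRecord,
    TrialArticleLink,
)
from .reporting import SurveillanceSummary, build_summary
from .scoring import (
    attention_score,
    build_intervention_profiles,
    intervention_norms,
    normalize_intervention,
    rank_publications,
    shortlist,
)


@dataclass
class PipelineResult:
    cohort: list[StudyRecord]
    classifications: dict[str, StudyClassification]
    links: list[TrialArticleLink]
    removed: list[TrialArticleLink]
    accounting: LinkAccounting
    profiles: list[InterventionProfile]
    ranked: list[ScoredPublication]
    shortlisted: list[ScoredPublication]
    summary: SurveillanceSummary
    config: AppConfig = field(repr=False, default_factory=AppConfig)


def run_pipeline(
    studies: Sequence[StudyRecord],
    articles: Sequence[ArticleRecord],
    config: Optional[AppConfig] = None,
    as_of: Optional[dt.date] = None,
) -> PipelineResult:
    """Run the full surveillance pipeline on parsed records.

    Steps: select the condition cohort; extract registry result-reference
    links and filter misclassified (pre-start) ones; find abstract
    secondary-identifier links; merge and annotate the master link list;
    aggregate intervention profiles and significance scores; attention-score
    and rank every link; build the shortlist and the aggregate summary.
    """
    if config is None:
        config = AppConfig()
    if as_of is None:
        as_of = dt.date.today()

    cohort = select_cohort(studies, config.cohort)
    cohort_index = {s.nct_id: s for s in cohort}
    article_index = {a.pmid: a for a in articles}

    registry_raw = [
        link for s in cohort for link in extract_registry_links(s)
    ]
    registry_kept, removed = filter_misclassified(
        registry_raw, article_index, cohort_index
    )
    abstract = find_abstract_links(articles, set(cohort_index))
    links, accounting = merge_links(
        registry_kept, abstract, n_removed_misclassified=len(removed)
    )
    links = annotate_links(links, article_index)
    removed = annotate_links(removed, article_index)

    profiles = build_intervention_profiles(cohort, links, config.synonyms)
    norms = intervention_norms(profiles)

    scored = []
    for link in links:
        study = cohort_index[link.nct_id]
        norm = 0.0
        for iv in study.interventions:
            try:
                name = normalize_intervention(iv.name, config.synonyms)
            except ValueError:
                continue
            norm = max(norm, norms.get(name, 0.0))
        scored.append(
            attention_score(
                link,
                study,
                article_index.get(link.pmid),
                norm,
                config.weights,
                as_of,
                focus_country=config.cohort.focus_country or "United States",
            )
        )
    ranked = rank_publications(scored)
    short = shortlist(ranked, config.shortlist_min_updates)

    classifications = classify_studies(
        studies, config.cohort, set(cohort_index), config.termination_lexicon
    )
    timing = {
        nct: c.registration_timing for nct, c in classifications.items()
    }
    summary = build_summary(
        studies,
        cohort,
        links,
        accounting,
        short,
        as_of,
        timing=timing,
        minutes_per_abstract=config.minutes_per_abstract,
    )
    return PipelineResult(
        cohort=cohort,
        classifications=classifications,
        links=links,
        removed=removed,
        accounting=accounting,
        profiles=profiles,
        ranked=ranked,
        shortlisted=short,
        summary=summary,
        config=config,
    )
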