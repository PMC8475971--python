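"""Seeded synthetic registry/article corpora with ground-truth annotations.

The generator emulates the statistical structure the surveillance pipeline
assumes: condition keyword hits among registry studies, status and phase
mixes, two trial–article link routes (registry result references and
abstract secondary identifiers) with a configurable overlap, registry
references backdated before trial start (the misclassification the filter
must remove), protocol/editorial article types, vaccine-flagged titles,
US-site planting, record-update activity and publication lags.

Counts implied by rates are planted deterministically (``round(rate × n)``
members chosen by the seeded generator), so every corpus ships an exact
:class:`GroundTruth` sidecar that the test suite compares pipeline output
against.  One pseudo-random stream is derived from the master seed per
record category, so enlarging one category does not perturb the draws of
another.

Not emulated: covariance between sponsor identity and publication
behaviour, real title/abstract text, and multi-registry records.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .models import (
    ArticleClass,
    ArticleRecord,
    Intervention,
    OverallStatus,
    PartialDate,
    Phase,
    Reference,
    ReferenceType,
    RegistrationTiming,
    SecondaryId,
    StudyRecord,
    StudyType,
    TerminationCategory,
)
from .serialize import (
    articles_to_efetch_xml,
    study_to_api_json,
    study_to_legacy_xml_bytes,
)

_COVID_CONDITIONS = ["COVID-19", "SARS-CoV-2 Infection", "Covid-19 Pneumonia"]
_OTHER_CONDITIONS = ["Influenza", "Diabetes Mellitus", "Asthma", "Hypertension"]
_COUNTRIES = [
    "United Kingdom", "France", "Germany", "Brazil", "India", "China",
    "Spain", "Italy", "Canada", "Egypt", "Mexico", "Turkey",
]
_SPONSORS = [
    "University Hospital A", "National Research Institute", "BioPharma One",
    "City Medical Center", "Global Health Trust", "Vaccine Works Inc",
    "Academic Consortium B", "Provincial Health Authority", "TherapeuTech",
    "Institute of Infectious Disease", "Metro University", "CarePath Labs",
]
_JOURNALS = [
    "Journal of Clinical Investigation Reports", "Trials and Methods",
    "Infectious Disease Letters", "Global Medicine", "Clinical Science Weekly",
]

#: Termination phrase pool keyed by the category each phrase plants.  The
#: ``other`` phrases deliberately match no lexicon term.
_TERMINATION_PHRASES: dict[TerminationCategory, list[str]] = {
    TerminationCategory.RECRUITMENT: [
        "Unable to recruit participants",
        "Slow enrollment due to declining case counts",
        "Study halted for poor accrual",
        "Difficulty enrolling eligible patients",
    ],
    TerminationCategory.SAFETY: [
        "Stopped due to safety concerns",
        "Excess adverse events in the treatment arm",
        "Interim review found unacceptable toxicity",
    ],
    TerminationCategory.FUTILITY: [
        "Terminated for futility at interim analysis",
        "Lack of efficacy observed at interim look",
        "Intervention showed no benefit; stopped early",
    ],
    TerminationCategory.EXTERNAL_RESULTS: [
        "Results from other trials made continuation unnecessary",
        "Stopped after external evidence of benefit emerged",
        "Treatment landscape changed following approval of an alternative",
    ],
    TerminationCategory.OTHER: [
        "Sponsor decision",
        "Funding was not renewed",
        "Site closure for administrative reasons",
    ],
}

#: Free-text intervention pool: canonical name -> registry-entry variants.
DEFAULT_INTERVENTION_POOL: dict[str, list[str]] = {
    "hydroxychloroquine": ["Hydroxychloroquine", "Hydroxychloroquine 200mg", "HCQ"],
    "remdesivir": ["Remdesivir", "Remdesivir 100 mg"],
    "ivermectin": ["Ivermectin", "ivermectin"],
    "azithromycin": ["Azithromycin"],
    "tocilizumab": ["Tocilizumab", "Tocilizumab 8mg"],
    "dexamethasone": ["Dexamethasone"],
    "convalescent plasma": [
        "Convalescent Plasma",
        "Anti-SARS-CoV-2 Convalescent Plasma",
    ],
    "favipiravir": ["Favipiravir"],
    "colchicine": ["Colchicine"],
    "vitamin d": ["Vitamin D", "Vitamin D 50000 IU"],
    "lopinavir ritonavir": ["Lopinavir/Ritonavir"],
    "placebo": ["Placebo"],
}


class CorpusSpec(BaseModel):
    """Parameters of a synthetic corpus.

    Rates are planted deterministically where they define ground truth
    (keyword hits, vaccine titles, US sites, link routes, backdating,
    article classes); categorical mixes (status, phase, update counts,
    registration timing) are drawn per record from the seeded stream.
    """

    n_interventional: int = 2000
    n_observational: int = 300
    n_registry: int = 50
    keyword_hit_rate: float = 0.9
    status_distribution: dict[OverallStatus, float] = Field(
        default_factory=lambda: {
            OverallStatus.RECRUITING: 0.40,
            OverallStatus.ACTIVE_NOT_RECRUITING: 0.10,
            OverallStatus.ENROLLING_BY_INVITATION: 0.02,
            OverallStatus.COMPLETED: 0.28,
            OverallStatus.TERMINATED: 0.05,
            OverallStatus.SUSPENDED: 0.01,
            OverallStatus.WITHDRAWN: 0.05,
            OverallStatus.NOT_YET_RECRUITING: 0.07,
            OverallStatus.UNKNOWN: 0.02,
        }
    )
    phase_distribution: dict[Phase, float] = Field(
        default_factory=lambda: {
            Phase.NA: 0.35,
            Phase.EARLY_PHASE_1: 0.02,
            Phase.PHASE_1: 0.10,
            Phase.PHASE_1_2: 0.08,
            Phase.PHASE_2: 0.20,
            Phase.PHASE_2_3: 0.05,
            Phase.PHASE_3: 0.12,
            Phase.PHASE_4: 0.08,
        }
    )
    timing_mix: dict[RegistrationTiming, float] = Field(
        default_factory=lambda: {
            RegistrationTiming.PRIOR: 0.449,
            RegistrationTiming.DURING: 0.433,
            RegistrationTiming.AFTER: 0.118,
        }
    )
    intervention_pool: dict[str, list[str]] = Field(
        default_factory=lambda: {
            k: list(v) for k, v in DEFAULT_INTERVENTION_POOL.items()
        }
    )
    p_registry_link: float = 0.30
    p_abstract_link: float = 0.16
    p_both: float = 0.005
    p_misclassified_backdate: float = 0.55
    p_protocol_article: float = 0.15
    p_other_article: float = 0.08
    p_shared_article: float = 0.06
    p_noncohort_citation: float = 0.05
    n_unlinked_articles: int = 10
    vaccine_title_rate: float = 0.11
    us_site_rate: float = 0.25
    deposit_rate: float = 0.05
    update_count_distribution: dict[int, float] = Field(
        default_factory=lambda: {1: 0.17, 2: 0.13, 3: 0.20, 4: 0.15, 6: 0.15, 9: 0.10, 12: 0.10}
    )
    lag_mean_days: float = 149.0
    lag_sd_days: float = 40.0
    p_month_precision_start: float = 0.05
    p_month_precision_pubdate: float = 0.05
    as_of: dt.date = dt.date(2021, 8, 15)
    seed: int = 0

    @model_validator(mode="after")
    def _feasible(self) -> "CorpusSpec":
        probs = [
            self.keyword_hit_rate, self.p_registry_link, self.p_abstract_link,
            self.p_both, self.p_misclassified_backdate, self.p_protocol_article,
            self.p_other_article, self.p_shared_article, self.p_noncohort_citation,
            self.vaccine_title_rate, self.us_site_rate, self.deposit_rate,
            self.p_month_precision_start, self.p_month_precision_pubdate,
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all rates must lie in [0, 1]")
        if self.p_both > min(self.p_registry_link, self.p_abstract_link):
            raise ValueError(
                "p_both may not exceed either single-route probability"
            )
        for name, dist in (
            ("status_distribution", self.status_distribution),
            ("phase_distribution", self.phase_distribution),
            ("timing_mix", self.timing_mix),
            ("update_count_distribution", self.update_count_distribution),
        ):
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1, got {total}")
        return self


@dataclass
class GroundTruth:
    """Exact per-record annotations emitted alongside a corpus."""

    true_links: dict[tuple[str, str], frozenset[str]] = field(default_factory=dict)
    planted_misclassified: set[tuple[str, str]] = field(default_factory=set)
    article_classes: dict[str, ArticleClass] = field(default_factory=dict)
    cohort_ncts: set[str] = field(default_factory=set)
    vaccine_ncts: set[str] = field(default_factory=set)
    us_ncts: set[str] = field(default_factory=set)
    termination_categories: dict[str, TerminationCategory] = field(default_factory=dict)
    registration_timing: dict[str, RegistrationTiming] = field(default_factory=dict)
    lags: dict[tuple[str, str], int] = field(default_factory=dict)
    pre_completion_links: set[tuple[str, str]] = field(default_factory=set)


@dataclass
class GeneratedCorpus:
    studies: list[StudyRecord]
    articles: list[ArticleRecord]
    ground_truth: GroundTruth
    paths: dict[str, Path] = field(default_factory=dict)


def _plant(rng: np.random.Generator, pool: list, rate: float) -> set:
    """Choose exactly ``round(rate·|pool|)`` members of ``pool``."""
    k = round(rate * len(pool))
    if k <= 0:
        return set()
    idx = rng.choice(len(pool), size=min(k, len(pool)), replace=False)
    return {pool[i] for i in idx}


def _draw(rng: np.random.Generator, dist: dict):
    keys = list(dist.keys())
    probs = np.asarray([dist[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=probs / probs.sum())]


_ELIGIBLE = {
    OverallStatus.RECRUITING,
    OverallStatus.ACTIVE_NOT_RECRUITING,
    OverallStatus.ENROLLING_BY_INVITATION,
    OverallStatus.COMPLETED,
    OverallStatus.TERMINATED,
}


def _partial(date: dt.date, month_precision: bool) -> PartialDate:
    if month_precision:
        return PartialDate.from_parts(date.year, date.month)
    return PartialDate.from_parts(date.year, date.month, date.day)


def _gen_study_category(
    spec: CorpusSpec,
    rng: np.random.Generator,
    study_type: StudyType,
    n: int,
    base_accession: int,
    gt: GroundTruth,
) -> list[StudyRecord]:
    indices = list(range(n))
    hit_idx = _plant(rng, indices, spec.keyword_hit_rate)
    us_idx = _plant(rng, indices, spec.us_site_rate)
    pool = sorted(spec.intervention_pool)

    studies: list[StudyRecord] = []
    vaccine_candidates: list[int] = []
    for i in indices:
        nct = f"NCT{base_accession + i:08d}"
        status = _draw(rng, spec.status_distribution)
        phase = (
            _draw(rng, spec.phase_distribution)
            if study_type is StudyType.INTERVENTIONAL
            else Phase.NA
        )
        ended = status in (OverallStatus.COMPLETED, OverallStatus.TERMINATED)

        start = spec.as_of - dt.timedelta(days=int(rng.integers(80, 590)))
        start_month_prec = rng.random() < spec.p_month_precision_start
        completion: Optional[dt.date] = None
        primary_completion: Optional[dt.date] = None
        if ended:
            completion = start + dt.timedelta(days=int(rng.integers(90, 400)))
        elif rng.random() < 0.6:
            completion = start + dt.timedelta(days=int(rng.integers(300, 900)))
        if completion is not None:
            slack = max(1, min(60, (completion - start).days - 65))
            primary_completion = completion - dt.timedelta(days=int(rng.integers(0, slack)))

        timing = _draw(rng, spec.timing_mix)
        if timing is RegistrationTiming.AFTER and completion is None:
            timing = RegistrationTiming.DURING
        if timing is RegistrationTiming.PRIOR:
            first_posted = start - dt.timedelta(days=int(rng.integers(32, 90)))
        elif timing is RegistrationTiming.AFTER:
            first_posted = completion + dt.timedelta(days=int(rng.integers(32, 90)))
        else:
            anchor = primary_completion or completion
            hi = 120 if anchor is None else max(33, (anchor - start).days - 32)
            first_posted = start + dt.timedelta(days=int(rng.integers(32, min(hi, 120) + 1)))
        last_update = first_posted + dt.timedelta(days=int(rng.integers(0, 200)))

        conditions = [
            _COVID_CONDITIONS[int(rng.integers(len(_COVID_CONDITIONS)))]
            if i in hit_idx
            else _OTHER_CONDITIONS[int(rng.integers(len(_OTHER_CONDITIONS)))]
        ]
        interventions = []
        if study_type is StudyType.INTERVENTIONAL:
            for _ in range(int(rng.integers(1, 3))):
                canonical = pool[int(rng.integers(len(pool)))]
                variants = spec.intervention_pool[canonical]
                interventions.append(
                    Intervention(
                        name=variants[int(rng.integers(len(variants)))],
                        intervention_type="drug",
                    )
                )

        countries = []
        if i in us_idx:
            countries.append("United States")
        if rng.random() < 0.7:
            countries.append(_COUNTRIES[int(rng.integers(len(_COUNTRIES)))])

        why_stopped = None
        if status is OverallStatus.TERMINATED:
            category = list(_TERMINATION_PHRASES)[
                int(rng.integers(len(_TERMINATION_PHRASES)))
            ]
            phrases = _TERMINATION_PHRASES[category]
            why_stopped = phrases[int(rng.integers(len(phrases)))]
            gt.termination_categories[nct] = category

        study = StudyRecord(
            nct_id=nct,
            brief_title=f"Study {nct[-5:]} of {interventions[0].name if interventions else 'Natural History'} in {conditions[0]}",
            official_title=None,
            study_type=study_type,
            overall_status=status,
            phase=phase,
            start_date=_partial(start, start_month_prec),
            primary_completion_date=(
                _partial(primary_completion, False) if primary_completion else None
            ),
            completion_date=_partial(completion, False) if completion else None,
            first_posted_date=_partial(first_posted, False),
            last_update_date=_partial(last_update, False),
            version_count=int(_draw(rng, spec.update_count_distribution)),
            interventions=interventions,
            conditions=conditions,
            lead_sponsor=_SPONSORS[int(rng.integers(len(_SPONSORS)))],
            collaborator_sponsors=[],
            site_countries=countries,
            references=[],
            has_deposited_results=bool(ended and rng.random() < spec.deposit_rate),
            why_stopped=why_stopped,
        )
        studies.append(study)
        gt.registration_timing[nct] = timing
        if i in hit_idx:
            if status in _ELIGIBLE:
                gt.cohort_ncts.add(nct)
            if study_type is StudyType.INTERVENTIONAL:
                vaccine_candidates.append(len(studies) - 1)
        if i in us_idx:
            gt.us_ncts.add(nct)

    # vaccine titles planted among condition-hit interventional studies
    if study_type is StudyType.INTERVENTIONAL and vaccine_candidates:
        chosen = _plant(rng, vaccine_candidates, spec.vaccine_title_rate)
        for j in sorted(chosen):
            s = studies[j]
            studies[j] = s.model_copy(
                update={
                    "brief_title": f"Study {s.nct_id[-5:]} of a {s.conditions[0]} Vaccine Candidate"
                }
            )
            gt.vaccine_ncts.add(s.nct_id)
    return studies


def _truncnorm_days(rng: np.random.Generator, mean: float, sd: float) -> int:
    """Positive lag draw: normal truncated below at one day."""
    while True:
        v = rng.normal(mean, sd)
        if v >= 1.0:
            return int(round(v))


def generate_corpus(
    spec: CorpusSpec, out_dir: Optional[Path] = None
) -> GeneratedCorpus:
    """Generate a corpus; optionally emit it in both registry dialects.

    Deterministic for a given spec: the same spec (including seed) yields
    byte-identical output files.  When ``out_dir`` is given, writes an API
    v2 JSON bundle, one legacy XML file per study, an EFetch article set
    and ground-truth CSV sidecars.
    """
    seq = np.random.SeedSequence(spec.seed)
    rng_int, rng_obs, rng_reg, rng_links, rng_articles = (
        np.random.default_rng(s) for s in seq.spawn(5)
    )
    gt = GroundTruth()

    studies: list[StudyRecord] = []
    studies += _gen_study_category(
        spec, rng_int, StudyType.INTERVENTIONAL, spec.n_interventional, 4_000_000, gt
    )
    studies += _gen_study_category(
        spec, rng_obs, StudyType.OBSERVATIONAL, spec.n_observational, 4_500_000, gt
    )
    studies += _gen_study_category(
        spec, rng_reg, StudyType.PATIENT_REGISTRY, spec.n_registry, 4_800_000, gt
    )
    by_nct = {s.nct_id: s for s in studies}

    # ---- route assignment over the cohort -------------------------------
    cohort = sorted(gt.cohort_ncts)
    n = len(cohort)
    n_both = round(spec.p_both * n)
    n_reg_only = round((spec.p_registry_link - spec.p_both) * n)
    n_abs_only = round((spec.p_abstract_link - spec.p_both) * n)
    if n_both + n_reg_only + n_abs_only > n:
        raise ValueError("link route probabilities exceed cohort size")
    perm = [cohort[i] for i in rng_links.permutation(n)]
    both_ncts = perm[:n_both]
    reg_only_ncts = perm[n_both : n_both + n_reg_only]
    abs_only_ncts = perm[n_both + n_reg_only : n_both + n_reg_only + n_abs_only]

    n_back = round(spec.p_misclassified_backdate * (n_reg_only + n_both))
    if n_back > len(reg_only_ncts):
        raise ValueError(
            "backdate rate implies more misclassified references than "
            "registry-only links"
        )
    backdated: set[str] = set()
    if n_back:
        idx = rng_links.choice(len(reg_only_ncts), size=n_back, replace=False)
        backdated = {reg_only_ncts[i] for i in idx}

    # shared abstract articles: pairs of abstract-only studies citing one pmid
    n_shared_pairs = round(spec.p_shared_article * len(abs_only_ncts) / 2)
    shared_pairs = [
        (abs_only_ncts[2 * i], abs_only_ncts[2 * i + 1])
        for i in range(n_shared_pairs)
    ]
    shared_members = {nct for pair in shared_pairs for nct in pair}

    # ---- articles -------------------------------------------------------
    articles: list[ArticleRecord] = []
    pmid_counter = 32_000_000
    link_pmids: dict[str, str] = {}

    def next_pmid() -> str:
        nonlocal pmid_counter
        pmid_counter += 1
        return str(pmid_counter)

    def make_article(
        pmid: str,
        ncts_cited: list[str],
        anchor_nct: str,
        backdate: bool,
    ) -> ArticleRecord:
        study = by_nct[anchor_nct]
        start = study.start_date.value
        if backdate:
            pub = start - dt.timedelta(days=int(rng_articles.integers(45, 400)))
            pub_pd = _partial(pub, False)
        else:
            lag = _truncnorm_days(rng_articles, spec.lag_mean_days, spec.lag_sd_days)
            pub = start + dt.timedelta(days=lag)
            month_prec = rng_articles.random() < spec.p_month_precision_pubdate
            pub_pd = _partial(pub, month_prec)
            # an imputed month-start must not fall before the (imputed) trial
            # start, or a true link would look backdated
            if month_prec and any(
                pub_pd.value < by_nct[x].start_date.value
                for x in set(ncts_cited) | {anchor_nct}
            ):
                pub_pd = _partial(pub, False)
        return ArticleRecord(
            pmid=pmid,
            title=f"Outcomes of {study.interventions[0].name if study.interventions else 'observation'} in {study.conditions[0]}: trial {anchor_nct}",
            journal=_JOURNALS[int(rng_articles.integers(len(_JOURNALS)))],
            publication_date=pub_pd,
            publication_types=["Journal Article"],
            secondary_ids=[
                SecondaryId(databank="ClinicalTrials.gov", accession=x)
                for x in ncts_cited
            ],
            mesh_terms=["COVID-19", "SARS-CoV-2"],
        )

    def add_registry_reference(nct: str, pmid: str) -> None:
        s = by_nct[nct]
        by_nct[nct] = s.model_copy(
            update={
                "references": s.references
                + [Reference(pmid=pmid, reference_type=ReferenceType.RESULT_REFERENCE)]
            }
        )

    # both-route links
    for nct in both_ncts:
        pmid = next_pmid()
        articles.append(make_article(pmid, [nct], nct, backdate=False))
        add_registry_reference(nct, pmid)
        link_pmids[nct] = pmid
        gt.true_links[(nct, pmid)] = frozenset({"registry", "abstract"})

    # registry-only links (some backdated → misclassified, not true links)
    for nct in reg_only_ncts:
        pmid = next_pmid()
        is_back = nct in backdated
        articles.append(make_article(pmid, [], nct, backdate=is_back))
        add_registry_reference(nct, pmid)
        link_pmids[nct] = pmid
        if is_back:
            gt.planted_misclassified.add((nct, pmid))
        else:
            gt.true_links[(nct, pmid)] = frozenset({"registry"})

    # abstract-only links, including shared articles citing two trials
    for nct_a, nct_b in shared_pairs:
        pmid = next_pmid()
        anchor = max(nct_a, nct_b, key=lambda x: by_nct[x].start_date.value)
        articles.append(make_article(pmid, [nct_a, nct_b], anchor, backdate=False))
        for nct in (nct_a, nct_b):
            link_pmids[nct] = pmid
            gt.true_links[(nct, pmid)] = frozenset({"abstract"})
    for nct in abs_only_ncts:
        if nct in shared_members:
            continue
        pmid = next_pmid()
        articles.append(make_article(pmid, [nct], nct, backdate=False))
        link_pmids[nct] = pmid
        gt.true_links[(nct, pmid)] = frozenset({"abstract"})

    # plant article classes among non-backdated link articles
    linkable_pmids = sorted({p for (_, p) in gt.true_links})
    protocol_pmids = _plant(rng_articles, linkable_pmids, spec.p_protocol_article)
    other_pool = sorted(set(linkable_pmids) - protocol_pmids)
    n_other = round(spec.p_other_article * len(linkable_pmids))
    other_pmids = (
        _plant(rng_articles, other_pool, n_other / len(other_pool))
        if other_pool and n_other
        else set()
    )
    art_index = {a.pmid: i for i, a in enumerate(articles)}
    for pmid in linkable_pmids:
        a = articles[art_index[pmid]]
        if pmid in protocol_pmids:
            if rng_articles.random() < 0.5:
                update = {"publication_types": ["Journal Article", "Clinical Trial Protocol"]}
            else:
                update = {"title": a.title + ": a randomized study protocol"}
            cls = ArticleClass.PROTOCOL
        elif pmid in other_pmids:
            update = {"publication_types": ["Editorial"]}
            cls = ArticleClass.OTHER
        else:
            update = {"publication_types": ["Journal Article", "Randomized Controlled Trial"]}
            cls = ArticleClass.RESULT
        articles[art_index[pmid]] = a.model_copy(update=update)
        gt.article_classes[pmid] = cls
    for nct, pmid in gt.planted_misclassified:
        gt.article_classes.setdefault(pmid, ArticleClass.RESULT)

    # non-cohort citations appended to some abstract articles (no link)
    noncohort = sorted(set(by_nct) - gt.cohort_ncts)
    if noncohort:
        abstract_pmids = sorted(
            {p for (nct, p), src in gt.true_links.items() if "abstract" in src}
        )
        for pmid in sorted(_plant(rng_articles, abstract_pmids, spec.p_noncohort_citation)):
            a = articles[art_index[pmid]]
            extra = noncohort[int(rng_articles.integers(len(noncohort)))]
            articles[art_index[pmid]] = a.model_copy(
                update={
                    "secondary_ids": a.secondary_ids
                    + [SecondaryId(databank="ClinicalTrials.gov", accession=extra)]
                }
            )

    # unlinked background articles; some studies cite them as background
    unlinked_pmids = []
    for _ in range(spec.n_unlinked_articles):
        pmid = next_pmid()
        unlinked_pmids.append(pmid)
        pub = spec.as_of - dt.timedelta(days=int(rng_articles.integers(30, 700)))
        articles.append(
            ArticleRecord(
                pmid=pmid,
                title="Background perspective on respiratory infection research",
                journal=_JOURNALS[int(rng_articles.integers(len(_JOURNALS)))],
                publication_date=_partial(pub, False),
                publication_types=["Journal Article", "Review"],
                secondary_ids=[],
                mesh_terms=["Pandemics"],
            )
        )
        gt.article_classes[pmid] = ArticleClass.OTHER
    if unlinked_pmids:
        for nct in sorted(_plant(rng_articles, sorted(gt.cohort_ncts), 0.1)):
            s = by_nct[nct]
            by_nct[nct] = s.model_copy(
                update={
                    "references": s.references
                    + [
                        Reference(
                            pmid=unlinked_pmids[
                                int(rng_articles.integers(len(unlinked_pmids)))
                            ],
                            reference_type=ReferenceType.BACKGROUND,
                        )
                    ]
                }
            )

    # ground-truth lags and pre-completion annotations
    for (nct, pmid), sources in gt.true_links.items():
        study = by_nct[nct]
        article = articles[art_index[pmid]]
        gt.lags[(nct, pmid)] = (
            article.publication_date.value - study.start_date.value
        ).days
        if gt.article_classes[pmid] is ArticleClass.RESULT:
            completion = study.primary_completion_date or study.completion_date
            if completion is None or completion.value > spec.as_of:
                gt.pre_completion_links.add((nct, pmid))

    studies = [by_nct[s.nct_id] for s in studies]
    corpus = GeneratedCorpus(studies=studies, articles=articles, ground_truth=gt)
    if out_dir is not None:
        corpus.paths = _write_corpus(corpus, Path(out_dir))
    return corpus


def _write_corpus(corpus: GeneratedCorpus, out_dir: Path) -> dict[str, Path]:
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    api_path = out_dir / "studies_api.json"
    api_path.write_text(
        json.dumps(
            {"studies": [study_to_api_json(s) for s in corpus.studies]}, indent=1
        )
    )
    paths["studies_api_json"] = api_path

    xml_dir = out_dir / "studies_xml"
    xml_dir.mkdir(exist_ok=True)
    for s in corpus.studies:
        (xml_dir / f"{s.nct_id}.xml").write_bytes(study_to_legacy_xml_bytes(s))
    paths["studies_xml_dir"] = xml_dir

    art_path = out_dir / "articles.xml"
    art_path.write_bytes(articles_to_efetch_xml(corpus.articles))
    paths["articles_xml"] = art_path

    gt_dir = out_dir / "ground_truth"
    gt_dir.mkdir(exist_ok=True)
    gt = corpus.ground_truth
    lines = ["nct_id,pmid,sources,misclassified,lag_days"]
    for (nct, pmid), sources in sorted(gt.true_links.items()):
        lines.append(f"{nct},{pmid},{'+'.join(sorted(sources))},False,{gt.lags[(nct, pmid)]}")
    for nct, pmid in sorted(gt.planted_misclassified):
        lines.append(f"{nct},{pmid},registry,True,")
    (gt_dir / "links.csv").write_text("\n".join(lines) + "\n")
    lines = ["nct_id,in_cohort,is_vaccine,us_site,registration_timing,termination_category"]
    for s in corpus.studies:
        nct = s.nct_id
        lines.append(
            ",".join(
                [
                    nct,
                    str(nct in gt.cohort_ncts),
                    str(nct in gt.vaccine_ncts),
                    str(nct in gt.us_ncts),
                    gt.registration_timing.get(nct, RegistrationTiming.UNDETERMINED).value,
                    gt.termination_categories[nct].value
                    if nct in gt.termination_categories
                    else "",
                ]
            )
        )
    (gt_dir / "studies.csv").write_text("\n".join(lines) + "\n")
    lines = ["pmid,article_class"]
    for pmid in sorted(gt.article_classes):
        lines.append(f"{pmid},{gt.article_classes[pmid].value}")
    (gt_dir / "article_classes.csv").write_text("\n".join(lines) + "\n")
    paths["ground_truth_dir"] = gt_dir
    return paths


# ---------------------------------------------------------------------------
# fixed worked-example fixture


_FIXTURE_PROFILES: dict[str, tuple[list[str], dict[int, int]]] = {
    # canonical -> (free-text variants cycled across trials, phase counts)
    "hydroxychloroquine": (
        ["Hydroxychloroquine", "Hydroxychloroquine 200mg", "HCQ"],
        {1: 3, 2: 36, 3: 54, 4: 16, 0: 11},
    ),
    "remdesivir": (["Remdesivir", "Remdesivir 100 mg"], {1: 1, 2: 10, 3: 26, 4: 3, 0: 3}),
    "dexamethasone": (["Dexamethasone"], {2: 2, 3: 13, 4: 7, 0: 2}),
    "mrna 1273": (["mRNA-1273"], {1: 3, 2: 2, 3: 4}),
    "tocilizumab": (["Tocilizumab", "Tocilizumab 8mg"], {1: 1, 2: 18, 3: 12, 4: 3, 0: 6}),
}

_LEVEL_TO_PHASE = {0: Phase.NA, 1: Phase.PHASE_1, 2: Phase.PHASE_2, 4: Phase.PHASE_4}


def make_paper_fixture() -> list[StudyRecord]:
    """A fixed interventional corpus realizing published per-phase profiles.

    The per-intervention phase-count rows (e.g. hydroxychloroquine
    3/36/54/16/11) are materialized as individual completed trials so the
    normalization → aggregation → scoring path can be exercised end to
    end, not just the score formula.  A third of each phase-3 block is
    entered as combined phase 2/3 to exercise phase promotion.
    """
    studies: list[StudyRecord] = []
    accession = 9_000_000
    for canonical, (variants, phase_counts) in _FIXTURE_PROFILES.items():
        trial_idx = 0
        for level, count in phase_counts.items():
            for k in range(count):
                if level == 3:
                    phase = Phase.PHASE_2_3 if k % 3 == 0 else Phase.PHASE_3
                else:
                    phase = _LEVEL_TO_PHASE[level]
                accession += 1
                studies.append(
                    StudyRecord(
                        nct_id=f"NCT{accession:08d}",
                        brief_title=f"Trial of {canonical} in COVID-19 (#{trial_idx})",
                        study_type=StudyType.INTERVENTIONAL,
                        overall_status=OverallStatus.COMPLETED,
                        phase=phase,
                        start_date=PartialDate.from_parts(2020, 4, 1),
                        first_posted_date=PartialDate.from_parts(2020, 3, 15),
                        version_count=3,
                        interventions=[
                            Intervention(
                                name=variants[trial_idx % len(variants)],
                                intervention_type="drug",
                            )
                        ],
                        conditions=["COVID-19"],
                        lead_sponsor=_SPONSORS[trial_idx % len(_SPONSORS)],
                    )
                )
                trial_idx += 1
    return studies
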