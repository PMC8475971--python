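"""Condition cohort selection and study-level classification.

A cohort is the set of registered studies that (a) mention any configured
condition keyword in their conditions list or titles and (b) are in an
eligible status — by default recruiting, active (including not-recruiting
and enrolling-by-invitation) or ended (completed or terminated).  On top of
the cohort this module derives per-study labels: the vaccine-trial flag,
when the study registered relative to its own start and completion
(prior / during / after), why a terminated study stopped, and the effective
numeric phase where a combined phase 2/3 trial counts as phase 3.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

from .models import (
    CohortConfig,
    OverallStatus,
    Phase,
    RegistrationTiming,
    StudyClassification,
    StudyRecord,
    TerminationCategory,
)

#: Numeric phase with combined phases promoted to their higher phase.
_EFFECTIVE_PHASE: dict[Phase, int] = {
    Phase.NA: 0,
    Phase.EARLY_PHASE_1: 1,
    Phase.PHASE_1: 1,
    Phase.PHASE_1_2: 2,
    Phase.PHASE_2: 2,
    Phase.PHASE_2_3: 3,
    Phase.PHASE_3: 3,
    Phase.PHASE_4: 4,
}

#: Keyword lexicon for termination-reason categorization; matching is
#: lowercase substring, categories checked in this order, first hit wins.
DEFAULT_TERMINATION_LEXICON: dict[TerminationCategory, list[str]] = {
    TerminationCategory.RECRUITMENT: [
        "recruit", "enroll", "enrol", "accrual",
    ],
    TerminationCategory.SAFETY: [
        "safety", "adverse", "toxicity", "harm",
    ],
    TerminationCategory.FUTILITY: [
        "futility", "lack of efficacy", "no efficacy", "ineffective",
        "no benefit",
    ],
    TerminationCategory.EXTERNAL_RESULTS: [
        "other trial", "other studies", "results from other",
        "another study", "external evidence", "landscape",
        "no longer needed", "approval of",
    ],
}


def effective_phase(phase: Phase) -> int:
    """Map a registry phase to a single integer level, 0 for not-applicable.

    Combined phases are promoted to the higher phase (2/3 counts as 3,
    1/2 as 2); early phase 1 is grouped with phase 1.
    """
    return _EFFECTIVE_PHASE[phase]


def _keyword_hit(study: StudyRecord, keywords: Sequence[str]) -> bool:
    haystacks = [c.lower() for c in study.conditions]
    haystacks.append(study.brief_title.lower())
    if study.official_title:
        haystacks.append(study.official_title.lower())
    return any(kw in h for kw in keywords for h in haystacks)


def select_cohort(
    studies: Sequence[StudyRecord], config: CohortConfig
) -> list[StudyRecord]:
    """Retain studies with a condition-keyword hit and an eligible status.

    Deterministic and idempotent; input order is preserved.
    """
    return [
        s
        for s in studies
        if s.overall_status in config.eligible_statuses
        and _keyword_hit(s, config.condition_keywords)
    ]


def flag_vaccine_trials(
    studies: Sequence[StudyRecord], config: CohortConfig
) -> dict[str, bool]:
    """Flag studies whose brief title mentions the vaccine keyword."""
    kw = config.vaccine_title_keyword.lower()
    return {s.nct_id: kw in s.brief_title.lower() for s in studies}


def registration_timing(study: StudyRecord) -> RegistrationTiming:
    """Classify when the study registered relative to its own lifecycle.

    ``prior`` if first posted on or before the start date, ``after`` if a
    completion date (primary preferred, else overall) precedes first
    posting, ``during`` otherwise.  Missing anchor dates route to
    ``undetermined``; comparisons use imputed values of partial dates.
    """
    fp = study.first_posted_date
    if fp is None:
        return RegistrationTiming.UNDETERMINED
    start = study.start_date
    if start is not None and fp.value <= start.value:
        return RegistrationTiming.PRIOR
    completion = study.primary_completion_date or study.completion_date
    if completion is not None and completion.value < fp.value:
        return RegistrationTiming.AFTER
    if start is not None:
        return RegistrationTiming.DURING
    return RegistrationTiming.UNDETERMINED


def categorize_termination(
    why_stopped: Optional[str],
    lexicon: Mapping[TerminationCategory, Sequence[str]] = DEFAULT_TERMINATION_LEXICON,
) -> TerminationCategory:
    """Map a free-text termination reason to a coarse category.

    Absent text yields ``unspecified``; text that matches no lexicon term
    yields ``other``.
    """
    if why_stopped is None or not why_stopped.strip():
        return TerminationCategory.UNSPECIFIED
    text = why_stopped.lower()
    for category, terms in lexicon.items():
        if any(t in text for t in terms):
            return category
    return TerminationCategory.OTHER


def classify_studies(
    studies: Sequence[StudyRecord],
    config: CohortConfig,
    cohort_ncts: Optional[set[str]] = None,
    lexicon: Mapping[TerminationCategory, Sequence[str]] = DEFAULT_TERMINATION_LEXICON,
) -> dict[str, StudyClassification]:
    """Derive the full per-study classification table."""
    if cohort_ncts is None:
        cohort_ncts = {s.nct_id for s in select_cohort(studies, config)}
    vaccine = flag_vaccine_trials(studies, config)
    out: dict[str, StudyClassification] = {}
    for s in studies:
        out[s.nct_id] = StudyClassification(
            nct_id=s.nct_id,
            in_cohort=s.nct_id in cohort_ncts,
            is_vaccine_trial=vaccine[s.nct_id],
            registration_timing=registration_timing(s),
            termination_category=(
                categorize_termination(s.why_stopped, lexicon)
                if s.overall_status is OverallStatus.TERMINATED
                else None
            ),
            effective_phase=effective_phase(s.phase),
        )
    return out
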