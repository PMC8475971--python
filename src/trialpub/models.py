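"""Domain model for registry studies, bibliographic articles and their links.

Two record families flow through the pipeline:

* :class:`StudyRecord` — one registered study from a clinical-trial registry
  (ClinicalTrials.gov dialects), carrying identity, design, status, dates,
  interventions, sponsors, sites, literature references and record-activity
  metadata.
* :class:`ArticleRecord` — one bibliographic record (PubMed dialect) with
  publication types, dates and the secondary-identifier (DataBank) list that
  carries trial accessions cited in the abstract.

Downstream stages annotate :class:`TrialArticleLink` pairs and aggregate them
into :class:`InterventionProfile` and :class:`ScoredPublication` objects.

Dates from both sources can be partial (month- or year-precision); they are
carried as :class:`PartialDate` so that interval arithmetic never silently
consumes an imputed day.
"""

from __future__ import annotations

import datetime as dt
import enum
import re
from typing import Optional

from pydantic import BaseModel, Field, field_validator, model_validator

NCT_PATTERN = re.compile(r"^NCT\d{8}$")
PMID_PATTERN = re.compile(r"^\d{1,9}$")

#: Registry accessions earlier than this are treated as data errors.
DEFAULT_ERA_FLOOR = dt.date(1999, 1, 1)


class StudyType(str, enum.Enum):
    INTERVENTIONAL = "interventional"
    OBSERVATIONAL = "observational"
    PATIENT_REGISTRY = "patient_registry"


class OverallStatus(str, enum.Enum):
    RECRUITING = "recruiting"
    ACTIVE_NOT_RECRUITING = "active_not_recruiting"
    ENROLLING_BY_INVITATION = "enrolling_by_invitation"
    COMPLETED = "completed"
    TERMINATED = "terminated"
    SUSPENDED = "suspended"
    WITHDRAWN = "withdrawn"
    NOT_YET_RECRUITING = "not_yet_recruiting"
    UNKNOWN = "unknown"


class Phase(str, enum.Enum):
    NA = "na"
    EARLY_PHASE_1 = "early_phase_1"
    PHASE_1 = "phase_1"
    PHASE_1_2 = "phase_1_2"
    PHASE_2 = "phase_2"
    PHASE_2_3 = "phase_2_3"
    PHASE_3 = "phase_3"
    PHASE_4 = "phase_4"


class DatePrecision(str, enum.Enum):
    DAY = "day"
    MONTH = "month"
    YEAR = "year"


class PartialDate(BaseModel):
    """A calendar date with an explicit precision flag.

    Month-precision dates are imputed to the first day of the month and
    year-precision dates to January 1; the flag is retained so reports can
    footnote comparisons that rest on imputed days.
    """

    model_config = {"frozen": True}

    value: dt.date
    precision: DatePrecision = DatePrecision.DAY

    @classmethod
    def from_parts(
        cls, year: int, month: Optional[int] = None, day: Optional[int] = None
    ) -> "PartialDate":
        if month is None:
            return cls(value=dt.date(year, 1, 1), precision=DatePrecision.YEAR)
        if day is None:
            return cls(value=dt.date(year, month, 1), precision=DatePrecision.MONTH)
        return cls(value=dt.date(year, month, day), precision=DatePrecision.DAY)

    def iso(self) -> str:
        if self.precision is DatePrecision.YEAR:
            return f"{self.value.year:04d}"
        if self.precision is DatePrecision.MONTH:
            return f"{self.value.year:04d}-{self.value.month:02d}"
        return self.value.isoformat()

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.iso()


class ReferenceType(str, enum.Enum):
    RESULT_REFERENCE = "result_reference"
    BACKGROUND = "background"
    DERIVED = "derived"


class Reference(BaseModel):
    """A literature citation inside a registry study record."""

    pmid: Optional[str] = None
    reference_type: ReferenceType = ReferenceType.BACKGROUND
    citation: Optional[str] = None


class Intervention(BaseModel):
    name: str
    intervention_type: str = "other"


class StudyRecord(BaseModel):
    """One registered study, normalized across registry dialects."""

    nct_id: str
    brief_title: str = ""
    official_title: Optional[str] = None
    study_type: StudyType = StudyType.INTERVENTIONAL
    overall_status: OverallStatus = OverallStatus.UNKNOWN
    phase: Phase = Phase.NA
    start_date: Optional[PartialDate] = None
    primary_completion_date: Optional[PartialDate] = None
    completion_date: Optional[PartialDate] = None
    first_posted_date: Optional[PartialDate] = None
    last_update_date: Optional[PartialDate] = None
    version_count: int = Field(default=1, ge=1)
    interventions: list[Intervention] = Field(default_factory=list)
    conditions: list[str] = Field(default_factory=list)
    lead_sponsor: Optional[str] = None
    collaborator_sponsors: list[str] = Field(default_factory=list)
    site_countries: list[str] = Field(default_factory=list)
    references: list[Reference] = Field(default_factory=list)
    has_deposited_results: bool = False
    why_stopped: Optional[str] = None

    @field_validator("nct_id")
    @classmethod
    def _check_nct(cls, v: str) -> str:
        if not NCT_PATTERN.match(v):
            raise ValueError(f"invalid registry accession: {v!r}")
        return v


class SecondaryId(BaseModel):
    """One DataBank entry: (databank name, accession)."""

    databank: str
    accession: str

    @model_validator(mode="after")
    def _check_nct_accession(self) -> "SecondaryId":
        if self.databank == "ClinicalTrials.gov" and not NCT_PATTERN.match(
            self.accession
        ):
            raise ValueError(
                f"ClinicalTrials.gov accession {self.accession!r} is not an NCT id"
            )
        return self


class ArticleRecord(BaseModel):
    """One bibliographic record with trial-accession secondary identifiers."""

    pmid: str
    title: str = ""
    journal: str = ""
    publication_date: Optional[PartialDate] = None
    publication_types: list[str] = Field(default_factory=list)
    secondary_ids: list[SecondaryId] = Field(default_factory=list)
    mesh_terms: list[str] = Field(default_factory=list)

    @field_validator("pmid")
    @classmethod
    def _check_pmid(cls, v: str) -> str:
        if not PMID_PATTERN.match(v):
            raise ValueError(f"invalid PMID: {v!r}")
        return v

    def nct_accessions(self) -> list[str]:
        """Trial accessions cited via the ClinicalTrials.gov DataBank."""
        return [
            s.accession for s in self.secondary_ids if s.databank == "ClinicalTrials.gov"
        ]


class LinkSource(str, enum.Enum):
    REGISTRY = "registry"
    ABSTRACT = "abstract"


class ArticleClass(str, enum.Enum):
    RESULT = "result"
    PROTOCOL = "protocol"
    OTHER = "other"


class TrialArticleLink(BaseModel):
    """One (study, article) pair with its discovery route(s) and class."""

    nct_id: str
    pmid: str
    sources: frozenset[LinkSource]
    article_class: ArticleClass = ArticleClass.RESULT
    publication_date: Optional[PartialDate] = None
    removed_as_misclassified: bool = False
    undatable: bool = False

    @field_validator("sources")
    @classmethod
    def _nonempty(cls, v: frozenset[LinkSource]) -> frozenset[LinkSource]:
        if not v:
            raise ValueError("a link must have at least one source route")
        return v

    @property
    def key(self) -> tuple[str, str]:
        return (self.nct_id, self.pmid)


class LinkAccounting(BaseModel):
    """Route-level bookkeeping for a merged link set.

    ``n_combinations`` counts (link, route) pairs — the unit in which the
    surveillance tables report link totals — while ``n_distinct_pairs``
    counts deduplicated (trial, article) pairs and ``n_distinct_articles``
    deduplicated articles.
    """

    n_combinations: int
    n_abstract: int
    n_registry: int
    n_both: int
    n_distinct_pairs: int
    n_distinct_articles: int
    n_removed_misclassified: int = 0

    @model_validator(mode="after")
    def _identities(self) -> "LinkAccounting":
        if self.n_abstract + self.n_registry != self.n_combinations:
            raise ValueError("route counts do not sum to combination count")
        if self.n_distinct_pairs != self.n_abstract + self.n_registry - self.n_both:
            raise ValueError("distinct-pair count violates inclusion–exclusion")
        if self.n_distinct_articles > self.n_distinct_pairs:
            raise ValueError("more distinct articles than distinct pairs")
        return self


class RegistrationTiming(str, enum.Enum):
    PRIOR = "prior"
    DURING = "during"
    AFTER = "after"
    UNDETERMINED = "undetermined"


class TerminationCategory(str, enum.Enum):
    RECRUITMENT = "recruitment"
    SAFETY = "safety"
    FUTILITY = "futility"
    EXTERNAL_RESULTS = "external_results"
    OTHER = "other"
    UNSPECIFIED = "unspecified"


class StudyClassification(BaseModel):
    """Derived per-study labels used by the surveillance reports."""

    nct_id: str
    in_cohort: bool
    is_vaccine_trial: bool = False
    registration_timing: RegistrationTiming = RegistrationTiming.UNDETERMINED
    termination_category: Optional[TerminationCategory] = None
    effective_phase: int = Field(default=0, ge=0, le=4)


class CohortConfig(BaseModel):
    """Condition keywords and eligibility rules for cohort selection."""

    condition_keywords: list[str]
    eligible_statuses: set[OverallStatus]
    vaccine_title_keyword: str = "vaccine"
    focus_country: Optional[str] = "United States"

    @field_validator("condition_keywords")
    @classmethod
    def _keywords(cls, v: list[str]) -> list[str]:
        if not v:
            raise ValueError("condition_keywords must be non-empty")
        bad = [k for k in v if k != k.lower()]
        if bad:
            raise ValueError(f"condition keywords must be lowercase: {bad}")
        return v

    @field_validator("eligible_statuses")
    @classmethod
    def _statuses(cls, v: set[OverallStatus]) -> set[OverallStatus]:
        if not v:
            raise ValueError("eligible_statuses must be non-empty")
        return v


class InterventionProfile(BaseModel):
    """A normalized intervention with per-phase trial counts and its score."""

    canonical_name: str
    trial_count: int = 0
    phase_counts: dict[int, int] = Field(default_factory=dict)
    sponsor_count: int = 0
    publication_count: int = 0
    significance_score: float = 0.0

    @model_validator(mode="after")
    def _consistent(self) -> "InterventionProfile":
        if self.phase_counts and self.trial_count != sum(self.phase_counts.values()):
            raise ValueError("trial_count must equal the sum of phase_counts")
        return self


class AttentionWeights(BaseModel):
    """Weights of the publication attention score.

    The score multiplies an article-type weight into a sum of trial-side
    terms: effective phase, a US-site bonus, a capped per-update term, an
    exponentially decaying recency term and the normalized intervention
    significance.  All weights are configuration, not constants.
    """

    type_weight: dict[ArticleClass, float] = Field(
        default_factory=lambda: {
            ArticleClass.RESULT: 1.0,
            ArticleClass.PROTOCOL: 0.5,
            ArticleClass.OTHER: 0.25,
        }
    )
    us_bonus: float = 0.5
    update_unit: float = 0.01
    update_cap: float = 0.25
    recency_scale_days: float = 180.0
    recency_weight: float = 0.25
    intervention_weight: float = 0.1

    @model_validator(mode="after")
    def _ordered(self) -> "AttentionWeights":
        tw = self.type_weight
        for v in (
            *tw.values(),
            self.us_bonus,
            self.update_unit,
            self.update_cap,
            self.recency_scale_days,
            self.recency_weight,
            self.intervention_weight,
        ):
            if v < 0:
                raise ValueError("attention weights must be non-negative")
        if not (
            tw[ArticleClass.RESULT]
            >= tw[ArticleClass.PROTOCOL]
            >= tw[ArticleClass.OTHER]
        ):
            raise ValueError(
                "type weights must satisfy result >= protocol >= other"
            )
        return self


class ScoredPublication(BaseModel):
    """A link plus its attention score, component breakdown and rank."""

    link: TrialArticleLink
    attention_score: float
    components: dict[str, float] = Field(default_factory=dict)
    effective_phase: int = 0
    has_us_site: bool = False
    version_count: int = 1
    rank: Optional[int] = None
    on_shortlist: bool = False
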