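"""Parsers for registry study records and bibliographic article records.

Two registry dialects are supported: the ClinicalTrials.gov API v2 JSON
shape (``protocolSection`` modules) and the legacy public-XML shape
(``<clinical_study>``).  Article records are parsed from PubMed EFetch XML
(``<PubmedArticleSet>``).  Both parsers map into the shared domain model in
:mod:`trialpub.models`; optional fields that are absent stay ``None`` /
empty rather than being silently defaulted, and partial dates keep an
explicit precision flag.
"""

from __future__ import annotations

import datetime as dt
import enum
import json
import logging
import re
from pathlib import Path
from typing import Iterable, Optional, Union

from lxml import etree

from .errors import DateParseError, MissingIdentifierError, ParseError
from .models import (
    DEFAULT_ERA_FLOOR,
    ArticleRecord,
    DatePrecision,
    Intervention,
    OverallStatus,
    PartialDate,
    Phase,
    Reference,
    ReferenceType,
    SecondaryId,
    StudyRecord,
    StudyType,
)

log = logging.getLogger(__name__)


class Dialect(str, enum.Enum):
    API_V2_JSON = "api_v2_json"
    LEGACY_XML = "legacy_xml"


# ---------------------------------------------------------------------------
# dates

_MONTHS = {
    m.lower(): i
    for i, m in enumerate(
        [
            "January", "February", "March", "April", "May", "June",
            "July", "August", "September", "October", "November", "December",
        ],
        start=1,
    )
}
_MONTHS.update({m[:3]: i for m, i in list(_MONTHS.items())})

_ISO_DAY = re.compile(r"^(\d{4})-(\d{2})-(\d{2})$")
_ISO_MONTH = re.compile(r"^(\d{4})-(\d{2})$")
_ISO_YEAR = re.compile(r"^(\d{4})$")
# "June 2021" / "Jun 2021"
_NAME_MONTH = re.compile(r"^([A-Za-z]+)\s+(\d{4})$")
# "June 15, 2021"
_NAME_DAY = re.compile(r"^([A-Za-z]+)\s+(\d{1,2}),\s*(\d{4})$")
# MedlineDate styles: "2021 Jul", "2021 Jul 15", "2021 Jul-Aug"
_MEDLINE = re.compile(r"^(\d{4})\s+([A-Za-z]+)(?:-[A-Za-z]+)?(?:\s+(\d{1,2}))?$")


def _month_number(name: str, text: str) -> int:
    try:
        return _MONTHS[name.lower()]
    except KeyError:
        raise DateParseError(f"unrecognized month name in date: {text!r}") from None


def resolve_partial_date(text: str) -> PartialDate:
    """Parse a possibly partial date string into a :class:`PartialDate`.

    Accepted forms: ``YYYY``, ``YYYY-MM``, ``YYYY-MM-DD``, ``Month YYYY``,
    ``Month DD, YYYY`` and MedlineDate styles (``YYYY Mon``, ``YYYY Mon DD``,
    ``YYYY Mon-Mon``, where a month range resolves to its first month).
    Month precision imputes day 1; year precision imputes January 1.
    """
    text = text.strip()
    if m := _ISO_DAY.match(text):
        y, mo, d = map(int, m.groups())
        try:
            return PartialDate.from_parts(y, mo, d)
        except ValueError as e:
            raise DateParseError(f"invalid calendar date: {text!r}") from e
    if m := _ISO_MONTH.match(text):
        y, mo = map(int, m.groups())
        if not 1 <= mo <= 12:
            raise DateParseError(f"invalid month in date: {text!r}")
        return PartialDate.from_parts(y, mo)
    if m := _ISO_YEAR.match(text):
        return PartialDate.from_parts(int(m.group(1)))
    if m := _NAME_DAY.match(text):
        name, d, y = m.groups()
        try:
            return PartialDate.from_parts(int(y), _month_number(name, text), int(d))
        except ValueError as e:
            raise DateParseError(f"invalid calendar date: {text!r}") from e
    if m := _NAME_MONTH.match(text):
        name, y = m.groups()
        return PartialDate.from_parts(int(y), _month_number(name, text))
    if m := _MEDLINE.match(text):
        y, name, d = m.groups()
        mo = _month_number(name, text)
        if d is not None:
            return PartialDate.from_parts(int(y), mo, int(d))
        return PartialDate.from_parts(int(y), mo)
    raise DateParseError(f"unrecognized date format: {text!r}")


def _opt_date(text: Optional[str], where: str) -> Optional[PartialDate]:
    if text is None or text == "":
        return None
    try:
        return resolve_partial_date(text)
    except DateParseError as e:
        raise ParseError(str(e), path=where) from e


# ---------------------------------------------------------------------------
# registry: API v2 JSON

_API_STATUS = {
    "RECRUITING": OverallStatus.RECRUITING,
    "ACTIVE_NOT_RECRUITING": OverallStatus.ACTIVE_NOT_RECRUITING,
    "ENROLLING_BY_INVITATION": OverallStatus.ENROLLING_BY_INVITATION,
    "COMPLETED": OverallStatus.COMPLETED,
    "TERMINATED": OverallStatus.TERMINATED,
    "SUSPENDED": OverallStatus.SUSPENDED,
    "WITHDRAWN": OverallStatus.WITHDRAWN,
    "NOT_YET_RECRUITING": OverallStatus.NOT_YET_RECRUITING,
    "UNKNOWN": OverallStatus.UNKNOWN,
}

_API_PHASE_SINGLE = {
    "NA": Phase.NA,
    "EARLY_PHASE1": Phase.EARLY_PHASE_1,
    "PHASE1": Phase.PHASE_1,
    "PHASE2": Phase.PHASE_2,
    "PHASE3": Phase.PHASE_3,
    "PHASE4": Phase.PHASE_4,
}

_API_REF_TYPE = {
    "RESULT": ReferenceType.RESULT_REFERENCE,
    "BACKGROUND": ReferenceType.BACKGROUND,
    "DERIVED": ReferenceType.DERIVED,
}


def _phase_from_api(phases: list[str], where: str) -> Phase:
    if not phases:
        return Phase.NA
    key = tuple(sorted(phases))
    if key == ("PHASE1", "PHASE2"):
        return Phase.PHASE_1_2
    if key == ("PHASE2", "PHASE3"):
        return Phase.PHASE_2_3
    if len(phases) == 1 and phases[0] in _API_PHASE_SINGLE:
        return _API_PHASE_SINGLE[phases[0]]
    raise ParseError(f"unrecognized phase list {phases!r}", path=where)


def _parse_api_v2(doc: dict, where: str, era_floor: dt.date) -> StudyRecord:
    proto = doc.get("protocolSection")
    if not isinstance(proto, dict):
        raise ParseError("missing protocolSection", path=where)
    ident = proto.get("identificationModule", {})
    nct = ident.get("nctId")
    if not nct:
        raise MissingIdentifierError("study record has no NCT id", path=where)

    status_mod = proto.get("statusModule", {})
    design = proto.get("designModule", {})
    sponsor_mod = proto.get("sponsorCollaboratorsModule", {})
    arms = proto.get("armsInterventionsModule", {})
    conditions = proto.get("conditionsModule", {}).get("conditions", [])
    locations = proto.get("contactsLocationsModule", {}).get("locations", [])
    refs = proto.get("referencesModule", {}).get("references", [])

    raw_status = status_mod.get("overallStatus", "UNKNOWN")
    status = _API_STATUS.get(raw_status)
    if status is None:
        raise ParseError(
            f"unrecognized overall status {raw_status!r}",
            path=f"{where}/statusModule/overallStatus",
        )

    study_type_raw = design.get("studyType", "INTERVENTIONAL")
    if study_type_raw == "INTERVENTIONAL":
        study_type = StudyType.INTERVENTIONAL
    elif study_type_raw == "OBSERVATIONAL":
        study_type = (
            StudyType.PATIENT_REGISTRY
            if design.get("patientRegistry")
            else StudyType.OBSERVATIONAL
        )
    else:
        raise ParseError(
            f"unrecognized study type {study_type_raw!r}",
            path=f"{where}/designModule/studyType",
        )

    def date_of(mod_key: str) -> Optional[PartialDate]:
        struct = status_mod.get(mod_key)
        if not struct:
            return None
        return _opt_date(struct.get("date"), f"{where}/statusModule/{mod_key}")

    references = []
    for i, r in enumerate(refs):
        rtype = _API_REF_TYPE.get(r.get("type", "BACKGROUND"))
        if rtype is None:
            raise ParseError(
                f"unrecognized reference type {r.get('type')!r}",
                path=f"{where}/referencesModule/references[{i}]",
            )
        references.append(
            Reference(pmid=r.get("pmid"), reference_type=rtype, citation=r.get("citation"))
        )

    countries: list[str] = []
    for loc in locations:
        c = loc.get("country")
        if c and c not in countries:
            countries.append(c)

    first_posted = date_of("studyFirstPostDateStruct")
    if (
        first_posted is not None
        and first_posted.precision is DatePrecision.DAY
        and first_posted.value < era_floor
    ):
        raise ParseError(
            f"first-posted date {first_posted.iso()} precedes era floor {era_floor}",
            path=f"{where}/statusModule/studyFirstPostDateStruct",
        )

    return StudyRecord(
        nct_id=nct,
        brief_title=ident.get("briefTitle", ""),
        official_title=ident.get("officialTitle"),
        study_type=study_type,
        overall_status=status,
        phase=_phase_from_api(design.get("phases", []), f"{where}/designModule/phases"),
        start_date=date_of("startDateStruct"),
        primary_completion_date=date_of("primaryCompletionDateStruct"),
        completion_date=date_of("completionDateStruct"),
        first_posted_date=first_posted,
        last_update_date=date_of("lastUpdatePostDateStruct"),
        version_count=int(doc.get("versionCount", 1)),
        interventions=[
            Intervention(
                name=iv.get("name", ""),
                intervention_type=str(iv.get("type", "other")).lower(),
            )
            for iv in arms.get("interventions", [])
        ],
        conditions=list(conditions),
        lead_sponsor=(sponsor_mod.get("leadSponsor") or {}).get("name"),
        collaborator_sponsors=[
            c.get("name", "") for c in sponsor_mod.get("collaborators", [])
        ],
        site_countries=countries,
        references=references,
        has_deposited_results=bool(doc.get("hasResults", False)),
        why_stopped=status_mod.get("whyStopped"),
    )


# ---------------------------------------------------------------------------
# registry: legacy XML

_LEGACY_STATUS = {
    "Recruiting": OverallStatus.RECRUITING,
    "Active, not recruiting": OverallStatus.ACTIVE_NOT_RECRUITING,
    "Enrolling by invitation": OverallStatus.ENROLLING_BY_INVITATION,
    "Completed": OverallStatus.COMPLETED,
    "Terminated": OverallStatus.TERMINATED,
    "Suspended": OverallStatus.SUSPENDED,
    "Withdrawn": OverallStatus.WITHDRAWN,
    "Not yet recruiting": OverallStatus.NOT_YET_RECRUITING,
    "Unknown status": OverallStatus.UNKNOWN,
}

_LEGACY_PHASE = {
    "N/A": Phase.NA,
    "Early Phase 1": Phase.EARLY_PHASE_1,
    "Phase 1": Phase.PHASE_1,
    "Phase 1/Phase 2": Phase.PHASE_1_2,
    "Phase 2": Phase.PHASE_2,
    "Phase 2/Phase 3": Phase.PHASE_2_3,
    "Phase 3": Phase.PHASE_3,
    "Phase 4": Phase.PHASE_4,
}

_LEGACY_TYPE = {
    "Interventional": StudyType.INTERVENTIONAL,
    "Observational": StudyType.OBSERVATIONAL,
    "Observational [Patient Registry]": StudyType.PATIENT_REGISTRY,
}


def _text(el: etree._Element, tag: str) -> Optional[str]:
    child = el.find(tag)
    if child is None or child.text is None:
        return None
    return child.text.strip()


def _as_element(raw: Union[str, bytes, etree._Element], where: str) -> etree._Element:
    if isinstance(raw, etree._Element):
        return raw
    try:
        return etree.fromstring(raw if isinstance(raw, bytes) else raw.encode())
    except etree.XMLSyntaxError as e:
        raise ParseError(f"malformed XML: {e}", path=where) from e


def _parse_legacy_xml(
    raw: Union[str, bytes, etree._Element], where: str, era_floor: dt.date
) -> StudyRecord:
    el = _as_element(raw, where)
    if el.tag != "clinical_study":
        raise ParseError(f"expected <clinical_study>, found <{el.tag}>", path=where)
    nct = _text(el, "id_info/nct_id")
    if not nct:
        raise MissingIdentifierError("study record has no NCT id", path=where)

    status_raw = _text(el, "overall_status")
    status = _LEGACY_STATUS.get(status_raw or "Unknown status")
    if status is None:
        raise ParseError(
            f"unrecognized overall status {status_raw!r}", path=f"{where}/overall_status"
        )
    phase_raw = _text(el, "phase")
    phase = _LEGACY_PHASE.get(phase_raw) if phase_raw else Phase.NA
    if phase is None:
        raise ParseError(f"unrecognized phase {phase_raw!r}", path=f"{where}/phase")
    type_raw = _text(el, "study_type") or "Interventional"
    study_type = _LEGACY_TYPE.get(type_raw)
    if study_type is None:
        raise ParseError(
            f"unrecognized study type {type_raw!r}", path=f"{where}/study_type"
        )

    references: list[Reference] = []
    for ref_el in el.iterchildren("reference", "results_reference"):
        if ref_el.tag == "results_reference":
            rtype = ReferenceType.RESULT_REFERENCE
        elif ref_el.get("derived") == "true":
            rtype = ReferenceType.DERIVED
        else:
            rtype = ReferenceType.BACKGROUND
        references.append(
            Reference(
                pmid=_text(ref_el, "PMID"),
                reference_type=rtype,
                citation=_text(ref_el, "citation"),
            )
        )

    first_posted = _opt_date(_text(el, "study_first_posted"), f"{where}/study_first_posted")
    if (
        first_posted is not None
        and first_posted.precision is DatePrecision.DAY
        and first_posted.value < era_floor
    ):
        raise ParseError(
            f"first-posted date {first_posted.iso()} precedes era floor {era_floor}",
            path=f"{where}/study_first_posted",
        )

    version_raw = _text(el, "version_count")
    return StudyRecord(
        nct_id=nct,
        brief_title=_text(el, "brief_title") or "",
        official_title=_text(el, "official_title"),
        study_type=study_type,
        overall_status=status,
        phase=phase,
        start_date=_opt_date(_text(el, "start_date"), f"{where}/start_date"),
        primary_completion_date=_opt_date(
            _text(el, "primary_completion_date"), f"{where}/primary_completion_date"
        ),
        completion_date=_opt_date(
            _text(el, "completion_date"), f"{where}/completion_date"
        ),
        first_posted_date=first_posted,
        last_update_date=_opt_date(
            _text(el, "last_update_posted"), f"{where}/last_update_posted"
        ),
        version_count=int(version_raw) if version_raw else 1,
        interventions=[
            Intervention(
                name=_text(iv, "intervention_name") or "",
                intervention_type=(_text(iv, "intervention_type") or "other").lower(),
            )
            for iv in el.findall("intervention")
        ],
        conditions=[c.text.strip() for c in el.findall("condition") if c.text],
        lead_sponsor=_text(el, "sponsors/lead_sponsor/agency"),
        collaborator_sponsors=[
            _text(c, "agency") or "" for c in el.findall("sponsors/collaborator")
        ],
        site_countries=[
            c.text.strip() for c in el.findall("location_countries/country") if c.text
        ],
        references=references,
        has_deposited_results=(_text(el, "has_results") == "true"),
        why_stopped=_text(el, "why_stopped"),
    )


def parse_study_record(
    raw_record: Union[dict, str, bytes, etree._Element],
    dialect: Union[Dialect, str],
    *,
    where: str = "<record>",
    era_floor: dt.date = DEFAULT_ERA_FLOOR,
) -> StudyRecord:
    """Parse one registry study record in the declared dialect.

    Parameters
    ----------
    raw_record
        A decoded JSON object (API v2) or an XML string/element (legacy).
    dialect
        ``api_v2_json`` or ``legacy_xml``.
    where
        Context label used in error messages.
    era_floor
        Day-precision first-posted dates before this date are rejected.
    """
    dialect = Dialect(dialect)
    if dialect is Dialect.API_V2_JSON:
        if isinstance(raw_record, (str, bytes)):
            try:
                raw_record = json.loads(raw_record)
            except json.JSONDecodeError as e:
                raise ParseError(f"malformed JSON: {e}", path=where) from e
        if not isinstance(raw_record, dict):
            raise ParseError("API v2 record must be a JSON object", path=where)
        return _parse_api_v2(raw_record, where, era_floor)
    return _parse_legacy_xml(raw_record, where, era_floor)


# ---------------------------------------------------------------------------
# articles: PubMed EFetch XML


def parse_article_record(
    raw_record: Union[str, bytes, etree._Element], *, where: str = "<article>"
) -> ArticleRecord:
    """Parse one ``<PubmedArticle>`` element into an :class:`ArticleRecord`.

    Publication types and secondary identifiers are preserved verbatim.  An
    unparseable publication date keeps the record but leaves the date
    missing (with a logged warning); a missing PMID rejects the record.
    """
    el = _as_element(raw_record, where)
    if el.tag == "PubmedArticleSet":
        children = el.findall("PubmedArticle")
        if len(children) != 1:
            raise ParseError(
                "expected a single PubmedArticle; use parse_article_set", path=where
            )
        el = children[0]
    if el.tag != "PubmedArticle":
        raise ParseError(f"expected <PubmedArticle>, found <{el.tag}>", path=where)

    cit = el.find("MedlineCitation")
    if cit is None:
        raise ParseError("missing MedlineCitation", path=where)
    pmid = _text(cit, "PMID")
    if not pmid:
        raise MissingIdentifierError("article record has no PMID", path=where)
    art = cit.find("Article")
    if art is None:
        raise ParseError("missing Article element", path=f"{where}/MedlineCitation")

    pub_date = None
    pd_el = art.find("Journal/JournalIssue/PubDate")
    if pd_el is not None:
        year = _text(pd_el, "Year")
        month = _text(pd_el, "Month")
        day = _text(pd_el, "Day")
        medline = _text(pd_el, "MedlineDate")
        try:
            if year:
                if month is None:
                    mo = None
                elif month.isdigit():
                    mo = int(month)
                else:
                    mo = _month_number(month, month)
                pub_date = PartialDate.from_parts(
                    int(year), mo, int(day) if (day and mo) else None
                )
            elif medline:
                pub_date = resolve_partial_date(medline)
        except (DateParseError, ValueError):
            log.warning("PMID %s: unparseable publication date; kept without date", pmid)
            pub_date = None

    secondary_ids = []
    for bank in art.findall("DataBankList/DataBank"):
        name = _text(bank, "DataBankName") or ""
        for acc in bank.findall("AccessionNumberList/AccessionNumber"):
            if acc.text:
                secondary_ids.append(
                    SecondaryId(databank=name, accession=acc.text.strip())
                )

    return ArticleRecord(
        pmid=pmid,
        title=_text(art, "ArticleTitle") or "",
        journal=_text(art, "Journal/Title") or "",
        publication_date=pub_date,
        publication_types=[
            t.text.strip()
            for t in art.findall("PublicationTypeList/PublicationType")
            if t.text
        ],
        secondary_ids=secondary_ids,
        mesh_terms=[
            _text(h, "DescriptorName") or ""
            for h in cit.findall("MeshHeadingList/MeshHeading")
        ],
    )


def parse_article_set(
    raw: Union[str, bytes, etree._Element], *, where: str = "<article set>"
) -> list[ArticleRecord]:
    """Parse a full ``<PubmedArticleSet>`` document."""
    el = _as_element(raw, where)
    if el.tag != "PubmedArticleSet":
        raise ParseError(f"expected <PubmedArticleSet>, found <{el.tag}>", path=where)
    return [
        parse_article_record(child, where=f"{where}/PubmedArticle[{i}]")
        for i, child in enumerate(el.findall("PubmedArticle"))
    ]


# ---------------------------------------------------------------------------
# file loaders


def load_studies(path: Union[str, Path]) -> list[StudyRecord]:
    """Load study records from a file or directory.

    Accepts an API v2 JSON file (single study or a paged bundle with a
    ``studies`` array), a legacy XML file (one ``<clinical_study>``), or a
    directory containing any mix of ``*.json`` / ``*.xml`` study files.
    """
    path = Path(path)
    if path.is_dir():
        out: list[StudyRecord] = []
        for p in sorted(path.iterdir()):
            if p.suffix in (".json", ".xml"):
                out.extend(load_studies(p))
        return out
    if path.suffix == ".json":
        try:
            doc = json.loads(path.read_text())
        except json.JSONDecodeError as e:
            raise ParseError(f"malformed JSON: {e}", path=str(path)) from e
        if isinstance(doc, dict) and "studies" in doc:
            return [
                parse_study_record(
                    s, Dialect.API_V2_JSON, where=f"{path}#studies[{i}]"
                )
                for i, s in enumerate(doc["studies"])
            ]
        return [parse_study_record(doc, Dialect.API_V2_JSON, where=str(path))]
    if path.suffix == ".xml":
        return [
            parse_study_record(path.read_bytes(), Dialect.LEGACY_XML, where=str(path))
        ]
    raise ParseError(f"unrecognized study file type: {path.suffix}", path=str(path))


def load_articles(path: Union[str, Path]) -> list[ArticleRecord]:
    """Load an EFetch XML article set from a file."""
    path = Path(path)
    return parse_article_set(path.read_bytes(), where=str(path))


def index_studies(studies: Iterable[StudyRecord]) -> dict[str, StudyRecord]:
    out: dict[str, StudyRecord] = {}
    for s in studies:
        if s.nct_id in out:
            raise ParseError(f"duplicate NCT id in corpus: {s.nct_id}")
        out[s.nct_id] = s
    return out


def index_articles(articles: Iterable[ArticleRecord]) -> dict[str, ArticleRecord]:
    out: dict[str, ArticleRecord] = {}
    for a in articles:
        if a.pmid in out:
            raise ParseError(f"duplicate PMID in corpus: {a.pmid}")
        out[a.pmid] = a
    return out
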