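"""Serialize domain records back into their standard dialects.

These writers are the exact inverses of the parsers in
:mod:`trialpub.ingest` — the synthetic-corpus generator emits through them,
and the round-trip property ``parse(serialize(r)) == r`` is enforced by the
test suite for every field including date precision.
"""

from __future__ import annotations

from lxml import etree

from .models import (
    ArticleRecord,
    DatePrecision,
    OverallStatus,
    PartialDate,
    Phase,
    ReferenceType,
    StudyRecord,
    StudyType,
)

_MONTH_NAMES = [
    "January", "February", "March", "April", "May", "June",
    "July", "August", "September", "October", "November", "December",
]

_STATUS_TO_API = {
    OverallStatus.RECRUITING: "RECRUITING",
    OverallStatus.ACTIVE_NOT_RECRUITING: "ACTIVE_NOT_RECRUITING",
    OverallStatus.ENROLLING_BY_INVITATION: "ENROLLING_BY_INVITATION",
    OverallStatus.COMPLETED: "COMPLETED",
    OverallStatus.TERMINATED: "TERMINATED",
    OverallStatus.SUSPENDED: "SUSPENDED",
    OverallStatus.WITHDRAWN: "WITHDRAWN",
    OverallStatus.NOT_YET_RECRUITING: "NOT_YET_RECRUITING",
    OverallStatus.UNKNOWN: "UNKNOWN",
}

_STATUS_TO_LEGACY = {
    OverallStatus.RECRUITING: "Recruiting",
    OverallStatus.ACTIVE_NOT_RECRUITING: "Active, not recruiting",
    OverallStatus.ENROLLING_BY_INVITATION: "Enrolling by invitation",
    OverallStatus.COMPLETED: "Completed",
    OverallStatus.TERMINATED: "Terminated",
    OverallStatus.SUSPENDED: "Suspended",
    OverallStatus.WITHDRAWN: "Withdrawn",
    OverallStatus.NOT_YET_RECRUITING: "Not yet recruiting",
    OverallStatus.UNKNOWN: "Unknown status",
}

_PHASE_TO_API = {
    Phase.NA: ["NA"],
    Phase.EARLY_PHASE_1: ["EARLY_PHASE1"],
    Phase.PHASE_1: ["PHASE1"],
    Phase.PHASE_1_2: ["PHASE1", "PHASE2"],
    Phase.PHASE_2: ["PHASE2"],
    Phase.PHASE_2_3: ["PHASE2", "PHASE3"],
    Phase.PHASE_3: ["PHASE3"],
    Phase.PHASE_4: ["PHASE4"],
}

_PHASE_TO_LEGACY = {
    Phase.NA: "N/A",
    Phase.EARLY_PHASE_1: "Early Phase 1",
    Phase.PHASE_1: "Phase 1",
    Phase.PHASE_1_2: "Phase 1/Phase 2",
    Phase.PHASE_2: "Phase 2",
    Phase.PHASE_2_3: "Phase 2/Phase 3",
    Phase.PHASE_3: "Phase 3",
    Phase.PHASE_4: "Phase 4",
}

_TYPE_TO_LEGACY = {
    StudyType.INTERVENTIONAL: "Interventional",
    StudyType.OBSERVATIONAL: "Observational",
    StudyType.PATIENT_REGISTRY: "Observational [Patient Registry]",
}

_REF_TYPE_TO_API = {
    ReferenceType.RESULT_REFERENCE: "RESULT",
    ReferenceType.BACKGROUND: "BACKGROUND",
    ReferenceType.DERIVED: "DERIVED",
}


def _legacy_date(d: PartialDate) -> str:
    if d.precision is DatePrecision.YEAR:
        return str(d.value.year)
    if d.precision is DatePrecision.MONTH:
        return f"{_MONTH_NAMES[d.value.month - 1]} {d.value.year}"
    return f"{_MONTH_NAMES[d.value.month - 1]} {d.value.day}, {d.value.year}"


def study_to_api_json(study: StudyRecord) -> dict:
    """Render a study as an API v2 JSON object (``protocolSection`` shape).

    ``versionCount`` is emitted as a top-level extension key: the public
    record does not carry its own history length, but the pipeline consumes
    it as provided metadata.
    """
    status_mod: dict = {"overallStatus": _STATUS_TO_API[study.overall_status]}
    for key, d in (
        ("startDateStruct", study.start_date),
        ("primaryCompletionDateStruct", study.primary_completion_date),
        ("completionDateStruct", study.completion_date),
        ("studyFirstPostDateStruct", study.first_posted_date),
        ("lastUpdatePostDateStruct", study.last_update_date),
    ):
        if d is not None:
            status_mod[key] = {"date": d.iso()}
    if study.why_stopped is not None:
        status_mod["whyStopped"] = study.why_stopped

    design: dict = {
        "studyType": (
            "INTERVENTIONAL"
            if study.study_type is StudyType.INTERVENTIONAL
            else "OBSERVATIONAL"
        ),
    }
    if study.study_type is StudyType.PATIENT_REGISTRY:
        design["patientRegistry"] = True
    if study.study_type is StudyType.INTERVENTIONAL:
        design["phases"] = _PHASE_TO_API[study.phase]

    ident: dict = {"nctId": study.nct_id, "briefTitle": study.brief_title}
    if study.official_title is not None:
        ident["officialTitle"] = study.official_title

    sponsor_mod: dict = {}
    if study.lead_sponsor is not None:
        sponsor_mod["leadSponsor"] = {"name": study.lead_sponsor}
    if study.collaborator_sponsors:
        sponsor_mod["collaborators"] = [
            {"name": c} for c in study.collaborator_sponsors
        ]

    proto: dict = {
        "identificationModule": ident,
        "statusModule": status_mod,
        "designModule": design,
    }
    if sponsor_mod:
        proto["sponsorCollaboratorsModule"] = sponsor_mod
    if study.conditions:
        proto["conditionsModule"] = {"conditions": list(study.conditions)}
    if study.interventions:
        proto["armsInterventionsModule"] = {
            "interventions": [
                {"type": iv.intervention_type.upper(), "name": iv.name}
                for iv in study.interventions
            ]
        }
    if study.site_countries:
        proto["contactsLocationsModule"] = {
            "locations": [{"country": c} for c in study.site_countries]
        }
    if study.references:
        refs = []
        for r in study.references:
            entry: dict = {"type": _REF_TYPE_TO_API[r.reference_type]}
            if r.pmid is not None:
                entry["pmid"] = r.pmid
            if r.citation is not None:
                entry["citation"] = r.citation
            refs.append(entry)
        proto["referencesModule"] = {"references": refs}

    return {
        "protocolSection": proto,
        "hasResults": study.has_deposited_results,
        "versionCount": study.version_count,
    }


def _sub(parent: etree._Element, tag: str, text: str | None = None) -> etree._Element:
    el = etree.SubElement(parent, tag)
    if text is not None:
        el.text = text
    return el


def study_to_legacy_xml(study: StudyRecord) -> etree._Element:
    """Render a study as a legacy ``<clinical_study>`` XML element."""
    root = etree.Element("clinical_study")
    id_info = _sub(root, "id_info")
    _sub(id_info, "nct_id", study.nct_id)
    _sub(root, "brief_title", study.brief_title)
    if study.official_title is not None:
        _sub(root, "official_title", study.official_title)

    sponsors = _sub(root, "sponsors")
    if study.lead_sponsor is not None:
        _sub(_sub(sponsors, "lead_sponsor"), "agency", study.lead_sponsor)
    for c in study.collaborator_sponsors:
        _sub(_sub(sponsors, "collaborator"), "agency", c)

    _sub(root, "overall_status", _STATUS_TO_LEGACY[study.overall_status])
    if study.why_stopped is not None:
        _sub(root, "why_stopped", study.why_stopped)
    for tag, d in (
        ("start_date", study.start_date),
        ("primary_completion_date", study.primary_completion_date),
        ("completion_date", study.completion_date),
        ("study_first_posted", study.first_posted_date),
        ("last_update_posted", study.last_update_date),
    ):
        if d is not None:
            _sub(root, tag, _legacy_date(d))
    if study.study_type is StudyType.INTERVENTIONAL:
        _sub(root, "phase", _PHASE_TO_LEGACY[study.phase])
    _sub(root, "study_type", _TYPE_TO_LEGACY[study.study_type])
    for iv in study.interventions:
        iv_el = _sub(root, "intervention")
        _sub(iv_el, "intervention_type", iv.intervention_type)
        _sub(iv_el, "intervention_name", iv.name)
    for c in study.conditions:
        _sub(root, "condition", c)
    if study.site_countries:
        lc = _sub(root, "location_countries")
        for c in study.site_countries:
            _sub(lc, "country", c)
    for r in study.references:
        tag = (
            "results_reference"
            if r.reference_type is ReferenceType.RESULT_REFERENCE
            else "reference"
        )
        ref_el = _sub(root, tag)
        if r.reference_type is ReferenceType.DERIVED:
            ref_el.set("derived", "true")
        if r.pmid is not None:
            _sub(ref_el, "PMID", r.pmid)
        if r.citation is not None:
            _sub(ref_el, "citation", r.citation)
    _sub(root, "version_count", str(study.version_count))
    _sub(root, "has_results", "true" if study.has_deposited_results else "false")
    return root


def study_to_legacy_xml_bytes(study: StudyRecord) -> bytes:
    return etree.tostring(
        study_to_legacy_xml(study), pretty_print=True, xml_declaration=True,
        encoding="UTF-8",
    )


def article_to_element(article: ArticleRecord) -> etree._Element:
    """Render an article as a ``<PubmedArticle>`` EFetch XML element."""
    root = etree.Element("PubmedArticle")
    cit = _sub(root, "MedlineCitation")
    _sub(cit, "PMID", article.pmid)
    art = _sub(cit, "Article")
    journal = _sub(art, "Journal")
    _sub(journal, "Title", article.journal)
    pub_date_el = _sub(_sub(journal, "JournalIssue"), "PubDate")
    d = article.publication_date
    if d is not None:
        _sub(pub_date_el, "Year", str(d.value.year))
        if d.precision is not DatePrecision.YEAR:
            _sub(pub_date_el, "Month", _MONTH_NAMES[d.value.month - 1][:3])
        if d.precision is DatePrecision.DAY:
            _sub(pub_date_el, "Day", str(d.value.day))
    _sub(art, "ArticleTitle", article.title)
    if article.secondary_ids:
        bank_list = _sub(art, "DataBankList")
        by_bank: dict[str, list[str]] = {}
        for sid in article.secondary_ids:
            by_bank.setdefault(sid.databank, []).append(sid.accession)
        for bank, accessions in by_bank.items():
            bank_el = _sub(bank_list, "DataBank")
            _sub(bank_el, "DataBankName", bank)
            acc_list = _sub(bank_el, "AccessionNumberList")
            for a in accessions:
                _sub(acc_list, "AccessionNumber", a)
    types_el = _sub(art, "PublicationTypeList")
    for t in article.publication_types:
        _sub(types_el, "PublicationType", t)
    if article.mesh_terms:
        mesh_el = _sub(cit, "MeshHeadingList")
        for term in article.mesh_terms:
            _sub(_sub(mesh_el, "MeshHeading"), "DescriptorName", term)
    return root


def articles_to_efetch_xml(articles: list[ArticleRecord]) -> bytes:
    """Render an article list as a full ``<PubmedArticleSet>`` document."""
    root = etree.Element("PubmedArticleSet")
    for a in articles:
        root.append(article_to_element(a))
    return etree.tostring(
        root, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )
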