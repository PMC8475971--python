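"""Intervention significance scoring and publication attention ranking.

The **intervention significance score** summarizes how far and how broadly
an intervention has been pushed through the trial phases: for every phase
level with at least one trial it adds the phase value plus 0.01 per trial
in that phase.  An intervention with 12 phase-3 trials therefore gains
3.12 from phase 3 alone.  Unphased (not-applicable) trials contribute at a
base value of 1; this weight is derived from published per-phase count
tables rather than stated anywhere, and is configurable in principle.

The **attention score** ranks individual trial–article links.  It scales an
article-type weight (results count fully, protocols half, editorials and
similar a quarter by default) into a sum of trial-side terms:

``type_weight × (phase + us_bonus·1[US site] + min(unit·(versions−1), cap)
+ recency_weight·exp(−age/scale) + intervention_weight·norm_score)``

All weights live in :class:`~trialpub.models.AttentionWeights` and the
per-term breakdown is returned with every score so users can re-weight.
"""

from __future__ import annotations

import datetime as dt
import math
import re
from typing import Iterable, Mapping, Optional, Sequence

from .cohort import effective_phase
from .models import (
    ArticleRecord,
    AttentionWeights,
    InterventionProfile,
    ScoredPublication,
    StudyRecord,
    StudyType,
    TrialArticleLink,
)

_PUNCT = re.compile(r"[^\w\s]")
_WS = re.compile(r"\s+")
_UNITS = {"mg", "ml", "iu", "mcg", "ug", "g", "units", "unit", "dose", "doses"}
_NUM = re.compile(r"^\d+(\.\d+)?$")
_NUM_UNIT = re.compile(r"^\d+(\.\d+)?(mg|ml|iu|mcg|ug|g)$")

#: Fallback synonym map for free-text intervention strings; applied after
#: normalization.  Shipped as config in real deployments.
DEFAULT_SYNONYMS: dict[str, str] = {
    "hcq": "hydroxychloroquine",
    "anti sars cov 2 convalescent plasma": "convalescent plasma",
    "convalescent covid 19 plasma": "convalescent plasma",
}


def _strip_dose_tokens(tokens: list[str]) -> list[str]:
    def strip_end(toks: list[str]) -> list[str]:
        stripped_unit = False
        while toks:
            t = toks[-1]
            if t in _UNITS or _NUM_UNIT.match(t):
                toks = toks[:-1]
                stripped_unit = True
            elif stripped_unit and _NUM.match(t):
                toks = toks[:-1]
                stripped_unit = False
            else:
                break
        return toks

    tokens = strip_end(tokens)
    tokens = strip_end(tokens[::-1])[::-1]
    return tokens


def normalize_intervention(
    name: str, synonyms: Optional[Mapping[str, str]] = None
) -> str:
    """Normalize a free-text intervention name to a canonical form.

    Lowercases, maps punctuation to spaces, collapses whitespace, strips
    leading/trailing dose tokens (numbers with mg/ml/iu-style units) and
    finally applies the synonym map.  Raises ``ValueError`` if nothing is
    left after normalization.
    """
    if synonyms is None:
        synonyms = DEFAULT_SYNONYMS
    text = _WS.sub(" ", _PUNCT.sub(" ", name.lower())).strip()
    tokens = _strip_dose_tokens(text.split())
    text = " ".join(tokens)
    text = synonyms.get(text, text)
    if not text:
        raise ValueError(f"intervention name empty after normalization: {name!r}")
    return text


def intervention_significance_score(phase_counts: Mapping[int, int]) -> float:
    """Score an intervention from its per-phase trial counts.

    For each phase level with at least one trial, add the phase value
    (1–4; unphased level 0 counts at value 1) plus 0.01 per trial in that
    phase.  Computed in integer hundredths so printed two-decimal values
    reproduce exactly.
    """
    hundredths = 0
    for level, count in phase_counts.items():
        if not 0 <= level <= 4:
            raise ValueError(f"phase level must be in 0..4, got {level}")
        if count < 0:
            raise ValueError(f"negative trial count for phase {level}: {count}")
        if count == 0:
            continue
        value = 1 if level == 0 else level
        hundredths += 100 * value + count
    return hundredths / 100.0


def build_intervention_profiles(
    studies: Sequence[StudyRecord],
    links: Sequence[TrialArticleLink] = (),
    synonyms: Optional[Mapping[str, str]] = None,
) -> list[InterventionProfile]:
    """Aggregate interventional studies into per-intervention profiles.

    Each profile carries per-phase trial counts (effective phase, combined
    phases promoted), the distinct lead-sponsor count, the number of
    linked publications across the intervention's trials and the
    significance score.
    """
    links_by_nct: dict[str, set[str]] = {}
    for link in links:
        links_by_nct.setdefault(link.nct_id, set()).add(link.pmid)

    trials: dict[str, set[str]] = {}
    sponsors: dict[str, set[str]] = {}
    phases: dict[str, dict[int, int]] = {}
    pubs: dict[str, int] = {}
    for study in studies:
        if study.study_type is not StudyType.INTERVENTIONAL:
            continue
        names = set()
        for iv in study.interventions:
            try:
                names.add(normalize_intervention(iv.name, synonyms))
            except ValueError:
                continue
        level = effective_phase(study.phase)
        for name in names:
            trials.setdefault(name, set()).add(study.nct_id)
            phases.setdefault(name, {})[level] = phases.setdefault(name, {}).get(level, 0) + 1
            if study.lead_sponsor:
                sponsors.setdefault(name, set()).add(study.lead_sponsor)
            pubs[name] = pubs.get(name, 0) + len(links_by_nct.get(study.nct_id, ()))

    return [
        InterventionProfile(
            canonical_name=name,
            trial_count=len(ncts),
            phase_counts=phases[name],
            sponsor_count=len(sponsors.get(name, ())),
            publication_count=pubs.get(name, 0),
            significance_score=intervention_significance_score(phases[name]),
        )
        for name, ncts in sorted(trials.items())
    ]


def intervention_norms(
    profiles: Sequence[InterventionProfile],
) -> dict[str, float]:
    """Significance scores rescaled to [0, 1] by the corpus maximum."""
    if not profiles:
        return {}
    top = max(p.significance_score for p in profiles)
    if top == 0:
        return {p.canonical_name: 0.0 for p in profiles}
    return {p.canonical_name: p.significance_score / top for p in profiles}


def attention_score(
    link: TrialArticleLink,
    study: StudyRecord,
    article: Optional[ArticleRecord],
    intervention_norm: float,
    weights: AttentionWeights,
    as_of: dt.date,
    focus_country: str = "United States",
) -> ScoredPublication:
    """Score one link; returns the total with its component breakdown.

    The phase term is the effective trial phase (0 by construction for
    observational studies and registries).  Recency decays exponentially
    with article age at ``as_of``; a missing publication date zeroes the
    recency term and flags the link.  Links removed as misclassified must
    not be scored.
    """
    if link.removed_as_misclassified:
        raise ValueError(f"refusing to score removed link {link.key}")
    if not 0.0 <= intervention_norm <= 1.0:
        raise ValueError("intervention_norm must lie in [0, 1]")

    phase_term = float(effective_phase(study.phase))
    has_us = focus_country in study.site_countries
    us_term = weights.us_bonus * (1.0 if has_us else 0.0)
    update_term = min(weights.update_unit * (study.version_count - 1), weights.update_cap)
    pub = link.publication_date or (article.publication_date if article else None)
    if pub is None:
        recency_term = 0.0
    else:
        age_days = max((as_of - pub.value).days, 0)
        recency_term = weights.recency_weight * math.exp(
            -age_days / weights.recency_scale_days
        )
    intervention_term = weights.intervention_weight * intervention_norm

    type_w = weights.type_weight[link.article_class]
    inner = phase_term + us_term + update_term + recency_term + intervention_term
    components = {
        "type_weight": type_w,
        "phase": phase_term,
        "us_site": us_term,
        "updates": update_term,
        "recency": recency_term,
        "intervention": intervention_term,
    }
    return ScoredPublication(
        link=link,
        attention_score=type_w * inner,
        components=components,
        effective_phase=effective_phase(study.phase),
        has_us_site=has_us,
        version_count=study.version_count,
    )


def rank_publications(scored: Iterable[ScoredPublication]) -> list[ScoredPublication]:
    """Sort by score descending and assign ranks 1..N.

    Ties break by publication date descending (undated articles sort
    last within a tie), then PMID ascending, making the ranking fully
    deterministic.
    """
    def sort_key(sp: ScoredPublication):
        pub = sp.link.publication_date
        pub_ord = pub.value.toordinal() if pub is not None else 0
        return (-sp.attention_score, -pub_ord, int(sp.link.pmid))

    ranked = sorted(scored, key=sort_key)
    return [sp.model_copy(update={"rank": i}) for i, sp in enumerate(ranked, start=1)]


def shortlist(
    ranked: Sequence[ScoredPublication], min_updates: int = 2
) -> list[ScoredPublication]:
    """Prioritized sublist: result articles from phase-3 trials with a US
    site and at least ``min_updates`` record updates beyond registration.

    Rank order is preserved; retained entries are flagged ``on_shortlist``.
    """
    out = []
    for sp in ranked:
        if (
            sp.link.article_class.value == "result"
            and sp.effective_phase == 3
            and sp.has_us_site
            and sp.version_count - 1 >= min_updates
        ):
            out.append(sp.model_copy(update={"on_shortlist": True}))
    return out
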