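"""Run configuration: condition keywords, lexicons, weights, thresholds.

Everything the pipeline treats as a tunable — the condition keyword list,
status eligibility, the termination lexicon, intervention synonyms, the
attention-score weights and the shortlist thresholds — is config, not
code.  A single YAML file can override any subset of the defaults.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import yaml
from pydantic import BaseModel, Field, ValidationError

from .cohort import DEFAULT_TERMINATION_LEXICON
from .errors import ConfigError
from .models import (
    ArticleClass,
    AttentionWeights,
    CohortConfig,
    OverallStatus,
    TerminationCategory,
)
from .scoring import DEFAULT_SYNONYMS

#: Representative condition keywords for the COVID-19 use case.
DEFAULT_CONDITION_KEYWORDS = [
    "covid",
    "covid-19",
    "sars-cov-2",
    "sars-cov2",
    "2019-ncov",
    "novel coronavirus",
]

#: Recruiting, active (not-recruiting / by-invitation) or ended.
DEFAULT_ELIGIBLE_STATUSES = {
    OverallStatus.RECRUITING,
    OverallStatus.ACTIVE_NOT_RECRUITING,
    OverallStatus.ENROLLING_BY_INVITATION,
    OverallStatus.COMPLETED,
    OverallStatus.TERMINATED,
}


class AppConfig(BaseModel):
    """Full pipeline configuration."""

    project: str = "trialpub"
    cohort: CohortConfig = Field(
        default_factory=lambda: CohortConfig(
            condition_keywords=list(DEFAULT_CONDITION_KEYWORDS),
            eligible_statuses=set(DEFAULT_ELIGIBLE_STATUSES),
        )
    )
    weights: AttentionWeights = Field(default_factory=AttentionWeights)
    termination_lexicon: dict[TerminationCategory, list[str]] = Field(
        default_factory=lambda: {
            k: list(v) for k, v in DEFAULT_TERMINATION_LEXICON.items()
        }
    )
    synonyms: dict[str, str] = Field(default_factory=lambda: dict(DEFAULT_SYNONYMS))
    shortlist_min_updates: int = 2
    minutes_per_abstract: float = 2.0
    top_n_interventions: int = 10


def _coerce_weights(raw: dict) -> dict:
    if "type_weight" in raw:
        raw = dict(raw)
        raw["type_weight"] = {
            ArticleClass(k): v for k, v in raw["type_weight"].items()
        }
    return raw


def load_config(path: Optional[Union[str, Path]] = None) -> AppConfig:
    """Load configuration from a YAML file; defaults when ``path`` is None.

    Raises :class:`~trialpub.errors.ConfigError` on unreadable files or
    schema violations.
    """
    if path is None:
        return AppConfig()
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except (OSError, yaml.YAMLError) as e:
        raise ConfigError(f"cannot read config {path}: {e}") from e
    if raw is None:
        return AppConfig()
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} must be a mapping")
    if "weights" in raw and isinstance(raw["weights"], dict):
        raw["weights"] = _coerce_weights(raw["weights"])
    try:
        return AppConfig.model_validate(raw)
    except ValidationError as e:
        raise ConfigError(f"invalid config {path}: {e}") from e
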