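"""Exception hierarchy shared across the package."""


class TrialPubError(Exception):
    """Base class for package errors."""


class ConfigError(TrialPubError):
    """Invalid or unreadable configuration."""


class ParseError(TrialPubError):
    """A document could not be parsed in its declared dialect.

    ``path`` names the offending document location (file path, record
    index or element path) so the failure is actionable.
    """

    def __init__(self, message: str, path: str | None = None):
        self.path = path
        super().__init__(f"{message}" + (f" (at {path})" if path else ""))


class MissingIdentifierError(ParseError):
    """A record lacks its mandatory accession (NCT id or PMID)."""


class DateParseError(ParseError):
    """A date string is in no recognized format."""
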