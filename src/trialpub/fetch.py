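"""Optional online fetchers for registry and bibliographic records.

Thin wrappers over the public query endpoints, kept behind an explicit
``offline`` switch so that no code path can touch the network unless the
caller opts in.  All analysis and tests run on local files or synthetic
corpora; these helpers exist for live surveillance use only.
"""

from __future__ import annotations

import json
import urllib.parse
import urllib.request

from .errors import TrialPubError

CTG_API = "https://clinicaltrials.gov/api/v2/studies"
EFETCH = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"


class OfflineError(TrialPubError):
    """Raised when a network fetch is attempted in offline mode."""


def fetch_studies_by_condition(
    condition: str, *, offline: bool = True, page_size: int = 100, timeout: float = 30.0
) -> list[dict]:
    """Fetch API v2 study records matching a condition query term."""
    if offline:
        raise OfflineError("online registry fetch disabled (offline mode)")
    out: list[dict] = []
    token = None
    while True:
        params = {"query.cond": condition, "pageSize": str(page_size)}
        if token:
            params["pageToken"] = token
        url = f"{CTG_API}?{urllib.parse.urlencode(params)}"
        with urllib.request.urlopen(url, timeout=timeout) as resp:
            page = json.load(resp)
        out.extend(page.get("studies", []))
        token = page.get("nextPageToken")
        if not token:
            return out


def fetch_articles_by_pmids(
    pmids: list[str], *, offline: bool = True, timeout: float = 30.0
) -> bytes:
    """Fetch an EFetch XML article set for a list of PMIDs."""
    if offline:
        raise OfflineError("online article fetch disabled (offline mode)")
    params = {"db": "pubmed", "retmode": "xml", "id": ",".join(pmids)}
    url = f"{EFETCH}?{urllib.parse.urlencode(params)}"
    with urllib.request.urlopen(url, timeout=timeout) as resp:
        return resp.read()
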