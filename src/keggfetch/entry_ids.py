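"""Clean lists of KEGG entry IDs.

The raw bodies of the ``list`` and ``find`` operations are tab-separated
tables — one line per entry, the ID first, metadata after.  The helpers
here strip the metadata and return only the IDs, or load IDs from a
local one-per-line text file.
"""
from __future__ import annotations

from pathlib import Path
from typing import List, Optional, Sequence, Union

from . import rest as rest_module
from .rest import KEGGresponse, KEGGrest, Status
from .urls import MolecularAttributeQuery


class EntryRetrievalError(RuntimeError):
    """A list/find request did not succeed; carries the response status."""

    def __init__(self, message: str, status: Status) -> None:
        super().__init__(message)
        self.status = status


def parse_entry_id_table(text: str) -> List[str]:
    """Extract entry IDs from a raw ``list``/``find`` response body.

    Each line contributes the substring before its first tab (the whole
    line if there is no tab); blank lines are dropped, surrounding
    whitespace stripped, order and duplicates preserved.
    """
    ids: List[str] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        entry_id = line.split("\t", 1)[0].strip()
        if entry_id:
            ids.append(entry_id)
    return ids


def _ids_from_response(response: KEGGresponse) -> List[str]:
    if response.status is not Status.SUCCESS:
        raise EntryRetrievalError(
            f"request for entry IDs did not succeed (status "
            f"{response.status.value}, URL {response.kegg_url.rendered})",
            response.status,
        )
    return parse_entry_id_table(response.text_body or "")


def from_database(database_name: str,
                  client: Optional[KEGGrest] = None) -> List[str]:
    """All entry IDs of one database, via the ``list`` operation."""
    client = client if client is not None else rest_module.KEGGrest()
    return _ids_from_response(client.list(database_name))


def from_file(file_path: Union[str, Path]) -> List[str]:
    """Entry IDs from a local text file, one per line.

    Lines are stripped and blank lines dropped; a missing file raises
    :class:`FileNotFoundError`.
    """
    text = Path(file_path).read_text()
    return [line.strip() for line in text.splitlines() if line.strip()]


def from_keywords(database_name: str, keywords: Sequence[str],
                  client: Optional[KEGGrest] = None) -> List[str]:
    """Entry IDs matching keywords, via the ``find`` operation."""
    client = client if client is not None else rest_module.KEGGrest()
    return _ids_from_response(client.find_keywords(database_name, keywords))


def from_molecular_attribute(database_name: str,
                             query: MolecularAttributeQuery,
                             client: Optional[KEGGrest] = None) -> List[str]:
    """Entry IDs matching a molecular-attribute query (formula/mass/weight)."""
    client = client if client is not None else rest_module.KEGGrest()
    return _ids_from_response(client.find_molecular(database_name, query))
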