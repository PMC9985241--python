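"""Builders for KEGG REST request URLs.

The KEGG web API is driven entirely by GET URLs of the form
``https://rest.kegg.jp/<operation>/<arg>[/<arg>...]`` where multi-valued
path segments (entry IDs, keywords) are joined with ``+``.  Seven
operations exist: ``info``, ``list``, ``get``, ``find``, ``conv``,
``link`` and ``ddi``.

Every constructor in this module validates its arguments and the fully
rendered URL *before* any network activity can take place, so a caller
gets specific feedback about a malformed request instead of an opaque
server error.  Two server-side limits are enforced here:

* the ``get`` operation accepts at most :data:`MAX_ENTRIES_PER_GET`
  (10) entry IDs per request, and only one ID when the requested entry
  field does not support multi-entry responses;
* the whole rendered URL may be at most :data:`MAX_URL_LENGTH` (4000)
  characters — KEGG's web server rejects longer request lines with a
  non-200 status, so over-long URLs are refused at construction time
  with advice to split the request.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

#: Default KEGG REST endpoint.  Configurable per call (and per client)
#: so the whole stack can be pointed at a local test service.
BASE_URL = "https://rest.kegg.jp"

#: Hard cap on the rendered URL length, scheme and host included.  The
#: KEGG server's request-line limit makes longer URLs fail with a
#: non-200 status, so they are refused client-side.
MAX_URL_LENGTH = 4000

#: Maximum number of entry IDs accepted by one ``get`` request.
MAX_ENTRIES_PER_GET = 10


class KEGGurlError(ValueError):
    """A URL could not be constructed from the given arguments."""


class URLLengthError(KEGGurlError):
    """The rendered URL would exceed :data:`MAX_URL_LENGTH` characters."""


class UnknownDatabaseWarning(UserWarning):
    """A database name outside the known registry was used.

    KEGG adds organism codes continuously, so unknown names are allowed
    (with this warning) rather than rejected; malformed names are still
    errors.
    """


# --------------------------------------------------------------------------
# Entry fields
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EntryFieldSpec:
    """Metadata for one entry field (an alternative rendition of an entry).

    ``supports_multiple`` records whether the KEGG server returns all
    requested entries for this field or silently only the first one;
    ``is_binary`` whether the payload is bytes (PNG images) rather than
    text; ``file_extension`` the extension used when the entry is saved.
    """

    name: str
    supports_multiple: bool
    is_binary: bool
    file_extension: str


#: The default rendition: the KEGG flat file, saved with a ``.txt``
#: extension, multiple entries per request allowed.
FLAT_FILE = EntryFieldSpec(name="", supports_multiple=True, is_binary=False,
                           file_extension="txt")

#: Registry of entry fields.  Multiplicity support is an empirical
#: property of the KEGG server, not documented by KEGG itself: sequence
#: and structure renditions (aaseq/ntseq/mol/kcf) come back one record
#: per requested ID, while image/conf/kgml/json requests silently return
#: only the first entry.
ENTRY_FIELDS = {
    "aaseq": EntryFieldSpec("aaseq", True, False, "aaseq"),
    "ntseq": EntryFieldSpec("ntseq", True, False, "ntseq"),
    "mol": EntryFieldSpec("mol", True, False, "mol"),
    "kcf": EntryFieldSpec("kcf", True, False, "kcf"),
    "image": EntryFieldSpec("image", False, True, "image"),
    "conf": EntryFieldSpec("conf", False, False, "conf"),
    "kgml": EntryFieldSpec("kgml", False, False, "kgml"),
    "json": EntryFieldSpec("json", False, False, "json"),
}


def resolve_entry_field(name: Optional[str]) -> EntryFieldSpec:
    """Map a field name (or ``None`` for the flat file) to its spec."""
    if name is None or name == "":
        return FLAT_FILE
    try:
        return ENTRY_FIELDS[name]
    except KeyError:
        known = ", ".join(sorted(ENTRY_FIELDS))
        raise KEGGurlError(
            f"unknown entry field {name!r}; expected one of: {known}"
        ) from None


# --------------------------------------------------------------------------
# Database registry
# --------------------------------------------------------------------------

#: Names recognised without a warning.  Extensible via
#: :func:`register_database` because KEGG's organism list is unbounded.
KNOWN_DATABASES = {
    # core databases
    "pathway", "brite", "module", "ko", "genome", "genes", "vg", "vp", "ag",
    "compound", "glycan", "reaction", "rclass", "enzyme", "network",
    "variant", "disease", "drug", "dgroup", "organism", "kegg",
    # outside databases usable with conv
    "ncbi-geneid", "ncbi-proteinid", "uniprot", "pubchem", "chebi",
    # a few common organism codes
    "hsa", "mmu", "rno", "dme", "cel", "eco", "sce", "ath",
}


def register_database(name: str) -> None:
    """Add ``name`` to the known-database registry (silences the warning)."""
    _check_token(name, "database name")
    KNOWN_DATABASES.add(name)


def _check_token(value: str, what: str) -> str:
    """Validate one path component: non-empty, no whitespace or slashes."""
    if not isinstance(value, str) or value == "":
        raise KEGGurlError(f"{what} must be a non-empty string, got {value!r}")
    if any(ch.isspace() for ch in value):
        raise KEGGurlError(f"{what} {value!r} contains whitespace")
    if "/" in value or "+" in value:
        raise KEGGurlError(f"{what} {value!r} contains a reserved character")
    return value


def _check_database(name: str) -> str:
    _check_token(name, "database name")
    if name not in KNOWN_DATABASES:
        warnings.warn(
            f"database name {name!r} is not in the known-database registry; "
            "passing it through unchanged (KEGG adds organisms continuously)",
            UnknownDatabaseWarning,
            stacklevel=3,
        )
    return name


# --------------------------------------------------------------------------
# The URL object
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class KEGGurl:
    """A validated, fully rendered KEGG REST request URL.

    ``operation`` identifies which of the REST verbs (with conv/link
    split into their database and entry-ID forms) the URL performs;
    ``arguments`` is the normalised argument tuple it was rendered from.
    """

    operation: str
    rendered: str
    arguments: tuple

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.rendered


def _render(base_url: str, operation: str, segments: Sequence[str],
            arguments: tuple) -> KEGGurl:
    rendered = "/".join([base_url.rstrip("/"), *segments])
    if len(rendered) > MAX_URL_LENGTH:
        raise URLLengthError(
            f"rendered URL is {len(rendered)} characters, above the "
            f"{MAX_URL_LENGTH}-character limit enforced by the KEGG server; "
            "break up the overly long URL into multiple smaller requests"
        )
    return KEGGurl(operation=operation, rendered=rendered, arguments=arguments)


# --------------------------------------------------------------------------
# Constructors, one per REST operation
# --------------------------------------------------------------------------

def make_info_url(database_name: str, base_url: str = BASE_URL) -> KEGGurl:
    """``<base>/info/<database>`` — database release metadata."""
    _check_database(database_name)
    return _render(base_url, "info", ["info", database_name], (database_name,))


def make_list_url(database_name: str, base_url: str = BASE_URL) -> KEGGurl:
    """``<base>/list/<database>`` — every entry ID in a database, with metadata."""
    _check_database(database_name)
    return _render(base_url, "list", ["list", database_name], (database_name,))


def make_get_url(entry_ids: Sequence[str], entry_field: Optional[str] = None,
                 base_url: str = BASE_URL) -> KEGGurl:
    """``<base>/get/<id1>+<id2>+...[/<field>]`` — retrieve entries themselves.

    At most :data:`MAX_ENTRIES_PER_GET` IDs per request; exactly one ID
    when ``entry_field`` does not support multi-entry responses.
    """
    ids = [_check_token(i, "entry ID") for i in entry_ids]
    if not ids:
        raise KEGGurlError("at least one entry ID is required")
    if len(ids) > MAX_ENTRIES_PER_GET:
        raise KEGGurlError(
            f"{len(ids)} entry IDs requested but KEGG accepts at most "
            f"{MAX_ENTRIES_PER_GET} per get request"
        )
    spec = resolve_entry_field(entry_field)
    if len(ids) > 1 and not spec.supports_multiple:
        raise KEGGurlError(
            f"entry field {spec.name!r} only supports one entry per request, "
            f"but {len(ids)} entry IDs were given"
        )
    segments = ["get", "+".join(ids)]
    if spec.name:
        segments.append(spec.name)
    return _render(base_url, "get", segments, (tuple(ids), spec.name or None))


def make_find_keywords_url(database_name: str, keywords: Sequence[str],
                           base_url: str = BASE_URL) -> KEGGurl:
    """``<base>/find/<database>/<kw1>+<kw2>+...`` — keyword search."""
    _check_database(database_name)
    kws = [_check_token(k, "keyword") for k in keywords]
    if not kws:
        raise KEGGurlError("at least one keyword is required")
    return _render(base_url, "find_keywords",
                   ["find", database_name, "+".join(kws)],
                   (database_name, tuple(kws)))


#: Databases whose entries carry molecular attributes searchable by find.
MOLECULAR_DATABASES = {"compound", "drug"}

_MOLECULAR_ATTRIBUTES = ("formula", "exact_mass", "mol_weight")


@dataclass(frozen=True)
class MolecularAttributeQuery:
    """A find query over a molecular attribute.

    ``attribute`` is one of ``formula``, ``exact_mass`` or ``mol_weight``.
    ``value`` is a chemical formula string for ``formula`` queries, and
    either a single positive number or a closed ``(low, high)`` range
    for the mass/weight attributes.
    """

    attribute: str
    value: Union[str, float, int, tuple]

    def __post_init__(self) -> None:
        if self.attribute not in _MOLECULAR_ATTRIBUTES:
            raise KEGGurlError(
                f"unknown molecular attribute {self.attribute!r}; expected "
                f"one of: {', '.join(_MOLECULAR_ATTRIBUTES)}"
            )
        if self.attribute == "formula":
            _check_token(self.value, "chemical formula")
            return
        if isinstance(self.value, tuple):
            if len(self.value) != 2:
                raise KEGGurlError("a range must be a (low, high) pair")
            low, high = self.value
            for bound in (low, high):
                _check_positive_number(bound, self.attribute)
            if low > high:
                raise KEGGurlError(
                    f"inverted {self.attribute} range: low {low!r} is greater "
                    f"than high {high!r}"
                )
        else:
            _check_positive_number(self.value, self.attribute)

    def rendered_value(self) -> str:
        if self.attribute == "formula":
            return self.value
        if isinstance(self.value, tuple):
            low, high = self.value
            return f"{_format_number(low)}-{_format_number(high)}"
        return _format_number(self.value)


def _check_positive_number(value, what: str) -> None:
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise KEGGurlError(f"{what} value must be a number, got {value!r}")
    if value <= 0:
        raise KEGGurlError(f"{what} value must be positive, got {value!r}")


def _format_number(value) -> str:
    """Render a number the way KEGG's find grammar expects.

    Integral values print without a decimal point (``200``, not ``200.0``).
    """
    if isinstance(value, float) and value.is_integer():
        return str(int(value))
    return str(value)


def make_find_molecular_url(database_name: str, query: MolecularAttributeQuery,
                            base_url: str = BASE_URL) -> KEGGurl:
    """``<base>/find/<database>/<value>/<attribute>`` — molecular-attribute search."""
    _check_database(database_name)
    if database_name not in MOLECULAR_DATABASES:
        raise KEGGurlError(
            f"database {database_name!r} does not support molecular-attribute "
            f"searches (expected one of: {', '.join(sorted(MOLECULAR_DATABASES))})"
        )
    if not isinstance(query, MolecularAttributeQuery):
        raise KEGGurlError(
            "query must be a MolecularAttributeQuery, got "
            f"{type(query).__name__}"
        )
    return _render(base_url, "find_molecular",
                   ["find", database_name, query.rendered_value(),
                    query.attribute],
                   (database_name, query.attribute, query.rendered_value()))


def _make_mapping_url(verb: str, target: str,
                      source: Union[str, Sequence[str]],
                      base_url: str) -> KEGGurl:
    _check_database(target)
    if isinstance(source, str):
        _check_database(source)
        return _render(base_url, f"{verb}_database", [verb, target, source],
                       (target, source))
    ids = [_check_token(i, "entry ID") for i in source]
    if not ids:
        raise KEGGurlError("at least one entry ID is required")
    return _render(base_url, f"{verb}_entries", [verb, target, "+".join(ids)],
                   (target, tuple(ids)))


def make_conv_url(target: str, source: Union[str, Sequence[str]],
                  base_url: str = BASE_URL) -> KEGGurl:
    """``<base>/conv/<target>/<source>`` — convert IDs between KEGG and
    outside databases.

    ``source`` is either a database name (database form) or a sequence
    of entry IDs (entries form, joined with ``+``).
    """
    return _make_mapping_url("conv", target, source, base_url)


def make_link_url(target_database: str, source: Union[str, Sequence[str]],
                  base_url: str = BASE_URL) -> KEGGurl:
    """``<base>/link/<target>/<source>`` — cross-references between databases."""
    return _make_mapping_url("link", target_database, source, base_url)


def make_ddi_url(drug_entry_ids: Sequence[str],
                 base_url: str = BASE_URL) -> KEGGurl:
    """``<base>/ddi/<id1>+<id2>+...`` — drug-drug interactions."""
    ids = [_check_token(i, "drug entry ID") for i in drug_entry_ids]
    if not ids:
        raise KEGGurlError("at least one drug entry ID is required")
    return _render(base_url, "ddi", ["ddi", "+".join(ids)], (tuple(ids),))
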