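"""Seeded synthetic KEGG content.

:func:`generate_dataset` builds a deterministic, in-memory stand-in for
a set of KEGG databases: every entry gets an ID in the database's usual
dialect, a searchable name, molecular attributes, sequences, and
renditions in each entry-field format (flat file, FASTA, MOL, KCF,
KGML, JSON, conf, PNG image).  The content is structurally faithful —
flat files end with a ``///`` line, FASTA records start with ``>``,
the image is a valid PNG — but makes no attempt at biological realism.

Generation is a pure function of the seed and the size parameters:
identical inputs produce byte-identical datasets, which lets tests use
the dataset as a byte-exact oracle for everything the mock server
serves.  A configurable number of trailing entries per database can be
marked unavailable: they appear in ``list`` output but cannot be
retrieved, mimicking KEGG entries that are listed yet permanently
absent (as observed for part of the Brite database).
"""
from __future__ import annotations

import json
import random
import struct
import textwrap
import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional

_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_NUCLEOTIDES = "ACGT"

_NAME_WORDS = [
    "glucose", "kinase", "oxidase", "transporter", "hydrolase", "reductase",
    "synthase", "phosphatase", "dehydrogenase", "isomerase", "ligase",
    "mutase", "carrier", "receptor", "channel", "permease",
]

#: ID dialects per database; anything else uses the gene-style
#: ``<db>:<number>`` form.
_ID_PATTERNS = {
    "compound": "cpd:C{:05d}",
    "drug": "dr:D{:05d}",
    "glycan": "gl:G{:05d}",
    "brite": "br:br{:05d}",
    "pathway": "path:map{:05d}",
    "module": "md:M{:05d}",
    "ko": "ko:K{:05d}",
    "reaction": "rn:R{:05d}",
}

_TEXT_FIELDS = ("aaseq", "ntseq", "mol", "kcf", "conf", "kgml", "json")


@dataclass
class MockEntry:
    """One synthetic KEGG entry with its attributes."""

    entry_id: str
    name: str
    formula: str
    exact_mass: float
    mol_weight: float
    aaseq: str
    ntseq: str
    available: bool = True

    @property
    def accession(self) -> str:
        return self.entry_id.split(":", 1)[-1]


@dataclass
class MockDataset:
    """A seeded collection of synthetic KEGG databases."""

    seed: int
    databases: Dict[str, List[MockEntry]]
    index: Dict[str, MockEntry] = field(init=False)

    def __post_init__(self) -> None:
        self.index = {}
        for entries in self.databases.values():
            for entry in entries:
                if entry.entry_id in self.index:
                    raise ValueError(f"duplicate entry ID {entry.entry_id!r}")
                self.index[entry.entry_id] = entry

    # -- bodies served by the mock endpoint -------------------------------

    def list_body(self, database: str) -> str:
        """The ``list`` response: ``<id>\\t<name>`` lines, unavailable
        entries included (they are listed, just not retrievable)."""
        entries = self.databases[database]
        if not entries:
            return "\n"
        return "".join(f"{e.entry_id}\t{e.name}\n" for e in entries)

    def rendition(self, entry: MockEntry, field_name: Optional[str]) -> bytes:
        """The bytes of one entry in one entry-field format."""
        if field_name in (None, ""):
            return self._flat(entry).encode("utf-8")
        if field_name == "aaseq":
            return _fasta(entry.entry_id, entry.name, entry.aaseq).encode("utf-8")
        if field_name == "ntseq":
            return _fasta(entry.entry_id, entry.name, entry.ntseq).encode("utf-8")
        if field_name == "mol":
            return self._mol(entry).encode("utf-8")
        if field_name == "kcf":
            return self._kcf(entry).encode("utf-8")
        if field_name == "kgml":
            return (f'<?xml version="1.0"?>\n'
                    f'<pathway name="{entry.entry_id}" title="{entry.name}">'
                    f'</pathway>\n').encode("utf-8")
        if field_name == "json":
            payload = {"name": entry.accession,
                       "children": [{"name": entry.name}]}
            return (json.dumps(payload, indent=2) + "\n").encode("utf-8")
        if field_name == "conf":
            return (f"rect (1,2) (30,40) {entry.entry_id}\t{entry.name}\n"
                    ).encode("utf-8")
        if field_name == "image":
            return _png_for(entry.entry_id)
        raise KeyError(f"unknown entry field {field_name!r}")

    def _flat(self, entry: MockEntry) -> str:
        return (
            f"ENTRY       {entry.accession:<12}Mock Entry\n"
            f"NAME        {entry.name}\n"
            f"FORMULA     {entry.formula}\n"
            f"EXACT_MASS  {entry.exact_mass}\n"
            f"MOL_WEIGHT  {entry.mol_weight}\n"
            "///\n"
        )

    def _mol(self, entry: MockEntry) -> str:
        return (
            f"{entry.accession}\n"
            "  MockKEGG\n"
            "\n"
            "  0  0  0  0  0  0  0  0  0  0999 V2000\n"
            "M  END\n"
            f"> <ENTRY>\n{entry.entry_id}\n"
            "///\n"
        )

    def _kcf(self, entry: MockEntry) -> str:
        return (
            f"ENTRY       {entry.accession:<12}Compound\n"
            f"ATOM        1\n"
            f"            1   C1a C    10.0  20.0\n"
            "///\n"
        )

    # -- searches ----------------------------------------------------------

    def find_by_keywords(self, database: str,
                         keywords: List[str]) -> List[MockEntry]:
        """Entries whose name contains every keyword (case-insensitive)."""
        hits = []
        for entry in self.databases[database]:
            name = entry.name.lower()
            if all(kw.lower() in name for kw in keywords):
                hits.append(entry)
        return hits

    def find_by_attribute(self, database: str, attribute: str,
                          low: float, high: float) -> List[MockEntry]:
        """Entries whose numeric attribute falls in the closed range."""
        hits = []
        for entry in self.databases[database]:
            value = getattr(entry, attribute)
            if low <= value <= high:
                hits.append(entry)
        return hits

    def find_by_formula(self, database: str, formula: str) -> List[MockEntry]:
        return [e for e in self.databases[database] if e.formula == formula]


def _fasta(entry_id: str, name: str, sequence: str) -> str:
    wrapped = "\n".join(textwrap.wrap(sequence, 60))
    return f">{entry_id} {name}\n{wrapped}\n"


def _png_for(entry_id: str) -> bytes:
    """A small valid PNG whose pixel colour is a pure function of the ID."""
    checksum = zlib.crc32(entry_id.encode("utf-8"))
    rgba = (checksum & 0xFF, (checksum >> 8) & 0xFF, (checksum >> 16) & 0xFF, 255)

    def chunk(tag: bytes, data: bytes) -> bytes:
        return (struct.pack(">I", len(data)) + tag + data
                + struct.pack(">I", zlib.crc32(tag + data)))

    header = struct.pack(">IIBBBBB", 2, 2, 8, 6, 0, 0, 0)
    raw = b"".join(b"\x00" + bytes(rgba) * 2 for _ in range(2))
    return (b"\x89PNG\r\n\x1a\n" + chunk(b"IHDR", header)
            + chunk(b"IDAT", zlib.compress(raw)) + chunk(b"IEND", b""))


def _make_entry_id(database: str, index: int) -> str:
    pattern = _ID_PATTERNS.get(database)
    if pattern is not None:
        return pattern.format(index + 1)
    return f"{database}:{10000 + index}"


def generate_dataset(seed: int, sizes: Dict[str, int],
                     unavailable: Optional[Dict[str, int]] = None,
                     ) -> MockDataset:
    """Build a :class:`MockDataset`.

    Parameters
    ----------
    seed:
        RNG seed; the dataset is a pure function of ``(seed, sizes,
        unavailable)``.
    sizes:
        Number of entries per database name.
    unavailable:
        Per database, how many trailing entries are listed but not
        retrievable (default none).
    """
    unavailable = unavailable or {}
    databases: Dict[str, List[MockEntry]] = {}
    for database in sorted(sizes):
        size = sizes[database]
        n_unavailable = unavailable.get(database, 0)
        if n_unavailable > size:
            raise ValueError(
                f"database {database!r}: {n_unavailable} unavailable entries "
                f"exceed its size {size}"
            )
        rng = random.Random(f"{seed}:{database}")
        entries = []
        for i in range(size):
            name = (f"{rng.choice(_NAME_WORDS)} "
                    f"{rng.choice(_NAME_WORDS)} {i + 1}")
            exact_mass = round(rng.uniform(100.0, 500.0), 4)
            entries.append(MockEntry(
                entry_id=_make_entry_id(database, i),
                name=name,
                formula=(f"C{rng.randint(1, 30)}H{rng.randint(2, 60)}"
                         f"O{rng.randint(1, 20)}"),
                exact_mass=exact_mass,
                mol_weight=round(exact_mass + rng.uniform(0.0, 2.0), 4),
                aaseq="".join(rng.choice(_AMINO_ACIDS)
                              for _ in range(rng.randint(30, 80))),
                ntseq="".join(rng.choice(_NUCLEOTIDES)
                              for _ in range(rng.randint(90, 240))),
                available=i < size - n_unavailable,
            ))
        databases[database] = entries
    return MockDataset(seed=seed, databases=databases)
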