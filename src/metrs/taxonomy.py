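"""Canonical taxonomic ranks and SILVA-style taxonomy databases.

Reference databases such as SILVA describe each rRNA entry by a
semicolon-delimited lineage of variable depth.  Consensus assignment needs a
fixed, ordered rank ladder to escalate through, so lineages are canonicalized
positionally onto the seven classical ranks domain..species: the first seven
segments fill the ladder top-down, segments beyond the seventh are collapsed
into the species slot, and missing deep ranks are left absent (never padded,
so a placeholder can never win a consensus).
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .errors import FormatError


class Rank(enum.IntEnum):
    """The seven canonical ranks, totally ordered domain < ... < species."""

    DOMAIN = 0
    PHYLUM = 1
    CLASS = 2
    ORDER = 3
    FAMILY = 4
    GENUS = 5
    SPECIES = 6

    @property
    def label(self) -> str:
        return self.name.lower()

    @classmethod
    def from_label(cls, label: str) -> "Rank":
        try:
            return cls[label.strip().upper()]
        except KeyError:
            raise ValueError(f"unknown rank {label!r}") from None


#: Ranks in shallow-to-deep order.
RANKS: tuple[Rank, ...] = tuple(Rank)


class _AbsentType:
    """Singleton marker for a rank a truncated lineage does not reach."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "ABSENT"

    def __bool__(self) -> bool:
        return False


#: Distinguished marker returned by :func:`term_at` for missing deep ranks.
ABSENT = _AbsentType()


@dataclass(frozen=True)
class TaxonomyPath:
    """An ordered lineage over the canonical ranks, possibly truncated.

    ``terms[i]`` is the taxonomic term at ``RANKS[i]``.  A valid path always
    carries a domain term and is never gapped internally: if a term exists at
    some rank, terms exist at every shallower rank.
    """

    terms: tuple[str, ...]

    def __post_init__(self):
        if not 1 <= len(self.terms) <= len(RANKS):
            raise ValueError(f"path depth must be 1..7, got {len(self.terms)}")
        for t in self.terms:
            if not t or t != t.strip() or ";" in t:
                raise ValueError(f"invalid taxonomic term {t!r}")

    @property
    def depth(self) -> int:
        return len(self.terms)

    @property
    def deepest_rank(self) -> Rank:
        return Rank(len(self.terms) - 1)

    @property
    def deepest_term(self) -> str:
        return self.terms[-1]

    def truncate(self, rank: Rank) -> "TaxonomyPath":
        """The lineage down to and including ``rank`` (which must be present)."""
        if rank >= len(self.terms):
            raise ValueError(f"path has no term at {rank.label}")
        return TaxonomyPath(self.terms[: rank + 1])

    def __str__(self) -> str:
        return ";".join(self.terms)

    def __iter__(self) -> Iterator[str]:
        return iter(self.terms)


def term_at(path: TaxonomyPath, rank: Rank):
    """The term of ``path`` at ``rank``, or :data:`ABSENT` if truncated above it."""
    if rank < len(path.terms):
        return path.terms[rank]
    return ABSENT


def canonicalize_path(raw: Iterable[str]) -> TaxonomyPath:
    """Map a variable-depth lineage onto the canonical 7-rank ladder.

    Segments are whitespace-trimmed and empty segments dropped; the first
    seven fill domain..species positionally and any overflow is joined into
    the species slot with single spaces.

    Raises :class:`FormatError` if nothing remains after stripping.
    """
    segments = [s.strip() for s in raw]
    segments = [s for s in segments if s]
    if not segments:
        raise FormatError("empty lineage")
    if len(segments) > len(RANKS):
        head = segments[: len(RANKS) - 1]
        tail = " ".join(segments[len(RANKS) - 1 :])
        segments = head + [tail]
    return TaxonomyPath(tuple(segments))


@dataclass
class ReferenceDB:
    """A taxonomy reference: entry id -> canonical lineage.

    Stands in for a full-length curated rDNA database.  ``sequences`` is an
    optional companion map (entry id -> DNA string) used by the synthetic
    read-length specificity analysis; real workflows align externally and
    never need it.
    """

    entries: dict[str, TaxonomyPath]
    name: str = "reference"
    sequences: dict[str, str] | None = None

    def __post_init__(self):
        if not self.entries:
            raise FormatError(f"reference DB {self.name!r} has no entries")

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, entry_id: str) -> bool:
        return entry_id in self.entries

    def path(self, entry_id: str) -> TaxonomyPath:
        return self.entries[entry_id]

    def domain_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for p in self.entries.values():
            counts[p.terms[0]] = counts.get(p.terms[0], 0) + 1
        return counts


def _insert_entry(entries: dict[str, TaxonomyPath], entry_id: str,
                  lineage: str, lineno: int) -> None:
    if entry_id in entries:
        raise FormatError(f"duplicate entry id {entry_id!r}", line=lineno)
    raw = lineage.split(";")
    try:
        entries[entry_id] = canonicalize_path(raw)
    except FormatError as exc:
        raise FormatError(f"entry {entry_id!r}: {exc}", line=lineno) from None


def parse_taxonomy_tsv(stream: Iterable[str], name: str = "reference") -> ReferenceDB:
    """Parse ``entry_id<TAB>lineage`` lines into a :class:`ReferenceDB`.

    Lineages are ';'-delimited, shallowest first.  Lines starting with '#'
    are comments; blank lines are ignored.  Duplicate ids, missing tabs and
    empty lineages raise :class:`FormatError` naming the line.
    """
    entries: dict[str, TaxonomyPath] = {}
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        if "\t" not in line:
            raise FormatError("expected 'entry_id<TAB>lineage'", line=lineno)
        entry_id, _, lineage = line.partition("\t")
        entry_id = entry_id.strip()
        if not entry_id:
            raise FormatError("empty entry id", line=lineno)
        _insert_entry(entries, entry_id, lineage, lineno)
    return ReferenceDB(entries=entries, name=name)


def parse_taxonomy_fasta(stream: Iterable[str], name: str = "reference") -> ReferenceDB:
    """Parse a SILVA-style FASTA export where headers are ``>entry_id lineage``.

    The lineage is everything after the first space on the header line.
    Sequence lines are retained so the DB can drive in-silico fragment
    analyses; they are not required for assignment.
    """
    entries: dict[str, TaxonomyPath] = {}
    sequences: dict[str, list[str]] = {}
    current: str | None = None
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith(">"):
            header = line[1:].strip()
            entry_id, _, lineage = header.partition(" ")
            if not entry_id or not lineage:
                raise FormatError("expected '>entry_id lineage'", line=lineno)
            _insert_entry(entries, entry_id, lineage, lineno)
            current = entry_id
            sequences[current] = []
        else:
            if current is None:
                raise FormatError("sequence before first header", line=lineno)
            sequences[current].append(line.strip())
    seqs = {k: "".join(v) for k, v in sequences.items() if v}
    return ReferenceDB(entries=entries, name=name, sequences=seqs or None)


def load_taxonomy(path: str, name: str | None = None) -> ReferenceDB:
    """Load a taxonomy DB from a file, sniffing TSV vs FASTA from content."""
    dbname = name or path
    with open(path, encoding="utf-8") as fh:
        first = fh.read(1)
        fh.seek(0)
        if first == ">":
            return parse_taxonomy_fasta(fh, name=dbname)
        return parse_taxonomy_tsv(fh, name=dbname)
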