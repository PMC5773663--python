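"""Readers and writers for the toolkit's tabular formats.

Alignment hits arrive either as text SAM (the aligner is run by the user
with multi-hit reporting enabled, e.g. bowtie ``-a -v1 --best --strata``)
or as a plain two-column TSV.  Both are reduced to the same structure: the
set of distinct reference entries each read matched.  Only QNAME, FLAG and
RNAME matter — alignment detail (CIGAR, MAPQ, position) carries no taxonomy
and is ignored, and secondary/supplementary records are kept because
multi-hit reporting is the whole point.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

from .contxt import Assignment, ConsensusParams, HitSet, Status
from .diversity import RarefactionCurve
from .errors import FormatError
from .profile import AbundanceRow, AbundanceTable, CVRecord, FilterParams
from .taxonomy import Rank, ReferenceDB, TaxonomyPath


@dataclass
class HitsTable:
    """Distinct (read_id, entry_id) pairs, insertion-ordered by read."""

    rows: list[tuple[str, str]] = field(default_factory=list)
    _seen: set[tuple[str, str]] = field(default_factory=set, repr=False)

    def add(self, read_id: str, entry_id: str) -> None:
        pair = (read_id, entry_id)
        if pair not in self._seen:
            self._seen.add(pair)
            self.rows.append(pair)

    def hitsets(self) -> list[HitSet]:
        """One HitSet per read, in first-seen read order."""
        grouped: dict[str, set[str]] = {}
        for read_id, entry_id in self.rows:
            grouped.setdefault(read_id, set()).add(entry_id)
        return [HitSet(read_id=r, entry_ids=frozenset(e)) for r, e in grouped.items()]

    def __len__(self) -> int:
        return len(self.rows)


_FLAG_UNMAPPED = 0x4


def read_sam_hits(stream: Iterable[str]) -> HitsTable:
    """Ingest mapped records of a text SAM into a :class:`HitsTable`.

    The header is optional.  Records with the unmapped FLAG bit (0x4) or a
    '*' RNAME contribute nothing; secondary and supplementary records are
    included; duplicate (read, entry) pairs collapse.  RNAME is taken
    verbatim as the taxonomy entry id.
    """
    table = HitsTable()
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("@"):
            continue
        fields = line.split("\t")
        if len(fields) < 11:
            raise FormatError(
                f"SAM record has {len(fields)} fields, expected >= 11", line=lineno
            )
        qname, flag_str, rname = fields[0], fields[1], fields[2]
        try:
            flag = int(flag_str)
        except ValueError:
            raise FormatError(f"non-integer FLAG {flag_str!r}", line=lineno) from None
        if flag & _FLAG_UNMAPPED or rname == "*":
            continue
        table.add(qname, rname)
    return table


def read_hits_tsv(stream: Iterable[str]) -> HitsTable:
    """Ingest ``read_id<TAB>entry_id`` lines ('#' comments) into a HitsTable."""
    table = HitsTable()
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2 or not fields[0] or not fields[1]:
            raise FormatError("expected 'read_id<TAB>entry_id'", line=lineno)
        table.add(fields[0], fields[1])
    return table


def load_hits(path: str) -> HitsTable:
    """Load hits from a file, treating ``.sam`` as SAM and anything else as TSV."""
    with open(path, encoding="utf-8") as fh:
        if path.endswith(".sam"):
            return read_sam_hits(fh)
        return read_hits_tsv(fh)


def write_hits_tsv(table: HitsTable, out: TextIO) -> None:
    out.write("# read_id\tentry_id\n")
    for read_id, entry_id in table.rows:
        out.write(f"{read_id}\t{entry_id}\n")


def write_taxonomy_tsv(db: ReferenceDB, out: TextIO) -> None:
    """Write a ReferenceDB in the canonical taxonomy TSV format."""
    out.write(f"# taxonomy db: {db.name}\n")
    for entry_id, path in db.entries.items():
        out.write(f"{entry_id}\t{path}\n")


def write_assignments_tsv(assignments: Iterable[Assignment], out: TextIO,
                          params: ConsensusParams = ConsensusParams(),
                          db_name: str = "reference") -> None:
    """Write per-read assignments; unknown reads get empty rank/term/lineage."""
    out.write(f"# consensus assignments: threshold={params.threshold} "
              f"strict={params.strict} db={db_name}\n")
    out.write("# read_id\tstatus\trank\tterm\tlineage\tn_hits\n")
    for a in assignments:
        if a.is_assigned:
            out.write(f"{a.read_id}\tassigned\t{a.rank.label}\t{a.term}\t"
                      f"{a.lineage}\t{a.n_hits}\n")
        else:
            out.write(f"{a.read_id}\tunknown\t\t\t\t{a.n_hits}\n")


def read_assignments_tsv(stream: Iterable[str]) -> list[Assignment]:
    """Read back an assignment TSV written by :func:`write_assignments_tsv`."""
    assignments = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 6:
            raise FormatError("expected 6 tab-separated fields", line=lineno)
        read_id, status, rank, term, lineage, n_hits = fields
        try:
            n = int(n_hits)
        except ValueError:
            raise FormatError(f"non-integer n_hits {n_hits!r}", line=lineno) from None
        if status == "assigned":
            assignments.append(Assignment(
                read_id=read_id, status=Status.ASSIGNED, n_hits=n,
                rank=Rank.from_label(rank), term=term,
                lineage=TaxonomyPath(tuple(lineage.split(";"))),
            ))
        elif status == "unknown":
            assignments.append(Assignment(read_id=read_id, status=Status.UNKNOWN,
                                          n_hits=n))
        else:
            raise FormatError(f"unknown status {status!r}", line=lineno)
    return assignments


def write_abundance_tsv(table: AbundanceTable, out: TextIO) -> None:
    """Write an abundance table, rows sorted by descending count then taxon."""
    out.write(f"# sample={table.sample_id}\trank={table.rank.label}\t"
              f"denominator={table.denominator}\n")
    out.write("# rank\tlineage\ttaxon\tread_count\trel_abundance\n")
    rows = sorted(table.rows.values(), key=lambda r: (-r.read_count, r.taxon))
    for r in rows:
        out.write(f"{table.rank.label}\t{r.lineage}\t{r.taxon}\t"
                  f"{r.read_count}\t{r.rel_abundance:.10g}\n")


def read_abundance_tsv(stream: Iterable[str]) -> AbundanceTable:
    """Read back an abundance TSV; counts are exact, fractions re-read as written."""
    sample_id = rank = None
    denominator = None
    rows: dict[str, AbundanceRow] = {}
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("# sample="):
            for part in line[2:].split("\t"):
                key, _, value = part.partition("=")
                if key == "sample":
                    sample_id = value
                elif key == "rank":
                    rank = Rank.from_label(value)
                elif key == "denominator":
                    denominator = int(value)
            continue
        if line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 5:
            raise FormatError("expected 5 tab-separated fields", line=lineno)
        _, lineage, taxon, count, rel = fields
        rows[taxon] = AbundanceRow(
            taxon=taxon, lineage=TaxonomyPath(tuple(lineage.split(";"))),
            read_count=int(count), rel_abundance=float(rel),
        )
    if sample_id is None or rank is None or denominator is None:
        raise FormatError("missing '# sample=...' header")
    return AbundanceTable(sample_id=sample_id, rank=rank, rows=rows,
                          denominator=denominator)


def write_cv_tsv(records: Sequence[CVRecord], out: TextIO) -> None:
    out.write("# taxon\tmean_abundance\tcv\tn_samples\n")
    for r in records:
        out.write(f"{r.taxon}\t{r.mean_abundance:.10g}\t{r.cv:.10g}\t{r.n_samples}\n")


def write_rarefaction_tsv(curve: RarefactionCurve, out: TextIO) -> None:
    out.write(f"# rarefaction: rank={curve.rank.label}\tk={curve.k}\t"
              f"seed={curve.seed}\trng=numpy-PCG64\n")
    out.write("# depth\tmetric\tmean\tsd\n")
    for p in curve.points:
        out.write(f"{p.depth}\tshannon\t{p.mean_shannon:.10g}\t{p.sd_shannon:.10g}\n")
        out.write(f"{p.depth}\trichness\t{p.mean_richness:.10g}\t{p.sd_richness:.10g}\n")
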