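"""Consensus taxonomy assignment of multi-mapped rRNA pseudoreads (ConTxT).

rRNA reads commonly align to many database entries because large stretches of
the molecule are conserved across taxa.  Rather than discarding such reads or
picking an arbitrary best hit, each read is assigned by bottom-up rank
escalation: starting at species, if more than a threshold fraction (default
60%) of the read's hits agree on one taxonomic term, that term is assigned;
otherwise the next shallower rank is interrogated, up to domain.  A read with
no consensus even at domain goes to the reserved "unknown" domain.  Reads
hitting a single entry are assigned that entry's taxonomy directly.

Hits are distinct (read, entry) pairs — repeated placements within one entry
count once, since entry identity is what carries taxonomy.  At every rank the
denominator is the read's full hit count; hits whose lineage is truncated
above that rank dilute the consensus but can never win it.
"""
from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import ContractViolation, UnknownEntryError
from .taxonomy import ABSENT, RANKS, Rank, ReferenceDB, TaxonomyPath, term_at

#: Reserved domain string reported for reads with no consensus at any rank.
UNKNOWN_DOMAIN = "unknown"


@dataclass(frozen=True)
class HitSet:
    """The distinct database entries matched by one mapped pseudoread."""

    read_id: str
    entry_ids: frozenset[str]

    def __post_init__(self):
        if not self.entry_ids:
            raise ContractViolation(f"read {self.read_id!r}: empty hit set")
        object.__setattr__(self, "entry_ids", frozenset(self.entry_ids))

    @property
    def n_hits(self) -> int:
        return len(self.entry_ids)


@dataclass(frozen=True)
class ConsensusParams:
    """Consensus threshold settings.

    threshold
        Fraction of hits that must agree on a term, in (0, 1].
    strict
        If true (default), a term must be *strictly* above the threshold —
        exactly 60% of hits agreeing escalates to the next rank.
    """

    threshold: float = 0.60
    strict: bool = True

    def __post_init__(self):
        if not 0.0 < self.threshold <= 1.0:
            raise ContractViolation(f"threshold must be in (0,1], got {self.threshold}")

    def passes(self, frequency: float) -> bool:
        if self.strict:
            return frequency > self.threshold
        return frequency >= self.threshold


class Status(enum.Enum):
    ASSIGNED = "assigned"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class Assignment:
    """The taxonomy given to one read, or the unknown-domain sentinel."""

    read_id: str
    status: Status
    n_hits: int
    rank: Rank | None = None
    term: str | None = None
    lineage: TaxonomyPath | None = None

    def __post_init__(self):
        if self.status is Status.ASSIGNED:
            if self.rank is None or self.term is None or self.lineage is None:
                raise ContractViolation("assigned read needs rank, term and lineage")
            if self.lineage.deepest_rank != self.rank or self.lineage.deepest_term != self.term:
                raise ContractViolation("lineage must be truncated at the assigned term")
        else:
            if self.rank is not None or self.term is not None or self.lineage is not None:
                raise ContractViolation("unknown read carries no rank/term/lineage")

    @property
    def is_assigned(self) -> bool:
        return self.status is Status.ASSIGNED


def _paths(hits: HitSet, db: ReferenceDB) -> list[TaxonomyPath]:
    paths = []
    for entry_id in sorted(hits.entry_ids):
        try:
            paths.append(db.entries[entry_id])
        except KeyError:
            raise UnknownEntryError(hits.read_id, entry_id) from None
    return paths


def reconstruct_lineage(hits: HitSet, db: ReferenceDB, rank: Rank, term: str) -> TaxonomyPath:
    """Ancestry reported above a winning term.

    Among the supporting hits (those whose term at ``rank`` equals ``term``),
    the most frequent full ancestor tuple wins; ties break on the
    lexicographic order of the ';'-joined ancestor string.  The result is
    truncated at ``rank``.
    """
    ancestors = Counter()
    for path in _paths(hits, db):
        if term_at(path, rank) == term:
            ancestors[path.terms[:rank]] += 1
    if not ancestors:
        raise ContractViolation(
            f"term {term!r} has no supporters at {rank.label} for read {hits.read_id!r}"
        )
    best, _ = min(ancestors.items(), key=lambda kv: (-kv[1], ";".join(kv[0])))
    return TaxonomyPath(best + (term,))


def assign_read(hits: HitSet, db: ReferenceDB,
                params: ConsensusParams = ConsensusParams()) -> Assignment:
    """Assign one read by bottom-up rank escalation.

    Scans species up to domain and returns the first (deepest) rank where a
    term's frequency over *all* hits passes the threshold.  When the
    threshold permits several winning terms (only possible below 50%), the
    most frequent term wins, ties broken lexicographically.  Single-hit reads
    are assigned their entry's deepest present rank directly.
    """
    paths = _paths(hits, db)
    n = len(paths)
    if n == 1:
        path = paths[0]
        return Assignment(
            read_id=hits.read_id, status=Status.ASSIGNED, n_hits=1,
            rank=path.deepest_rank, term=path.deepest_term, lineage=path,
        )
    for rank in reversed(RANKS):
        counts = Counter()
        for path in paths:
            term = term_at(path, rank)
            if term is not ABSENT:
                counts[term] += 1
        if not counts:
            continue
        term, count = min(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        if params.passes(count / n):
            lineage = reconstruct_lineage(hits, db, rank, term)
            return Assignment(
                read_id=hits.read_id, status=Status.ASSIGNED, n_hits=n,
                rank=rank, term=term, lineage=lineage,
            )
    return Assignment(read_id=hits.read_id, status=Status.UNKNOWN, n_hits=n)


@dataclass
class AssignmentSummary:
    """Counts of assignment outcomes over a batch of reads."""

    n_total: int = 0
    n_assigned: int = 0
    n_unknown: int = 0
    per_rank: Counter = field(default_factory=Counter)  # Rank -> exactly-at-rank count

    def add(self, assignment: Assignment) -> None:
        self.n_total += 1
        if assignment.is_assigned:
            self.n_assigned += 1
            self.per_rank[assignment.rank] += 1
        else:
            self.n_unknown += 1


def assign_all(hitsets: Iterable[HitSet], db: ReferenceDB,
               params: ConsensusParams = ConsensusParams(),
               fail_fast: bool = True) -> tuple[list[Assignment], AssignmentSummary]:
    """Assign every read, order-preserving, with a per-rank summary.

    With ``fail_fast`` false, reads whose hits reference missing DB entries
    are collected and reported in one aggregated error after the batch.
    """
    assignments: list[Assignment] = []
    summary = AssignmentSummary()
    failures: list[UnknownEntryError] = []
    for hits in hitsets:
        try:
            a = assign_read(hits, db, params)
        except UnknownEntryError as exc:
            if fail_fast:
                raise
            failures.append(exc)
            continue
        assignments.append(a)
        summary.add(a)
    if failures:
        detail = "; ".join(str(f.args[0]) for f in failures[:5])
        raise UnknownEntryError(
            failures[0].read_id, failures[0].entry_id
        ) from ValueError(f"{len(failures)} reads with unresolvable hits: {detail}")
    return assignments, summary


@dataclass(frozen=True)
class RankSummary:
    """Fraction of mapped reads assigned at each rank or deeper."""

    at_or_deeper: dict[Rank, float]
    unknown_fraction: float


def rank_summary(assignments: Sequence[Assignment]) -> RankSummary:
    """Cumulative assignment-depth profile of a batch.

    ``at_or_deeper[r]`` is the fraction of reads assigned at rank ``r`` or any
    deeper rank; the domain entry plus the unknown fraction is 1, and the
    profile is monotone non-increasing from domain to species.
    """
    if not assignments:
        raise ContractViolation("rank_summary needs at least one assignment")
    n = len(assignments)
    at_or_deeper = {
        rank: sum(1 for a in assignments if a.is_assigned and a.rank >= rank) / n
        for rank in RANKS
    }
    unknown = sum(1 for a in assignments if not a.is_assigned) / n
    return RankSummary(at_or_deeper=at_or_deeper, unknown_fraction=unknown)
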