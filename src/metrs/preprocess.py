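"""Read pre-processing: pair merging, quality trimming, length filtering.

A 2x250 bp partially-overlapping paired-end run is turned into longer
"pseudoreads" by merging each pair across its 3' overlap, then quality
trimming (Q30 from both ends) and discarding anything under 50 bp.  These are
deliberately simple, deterministic contracts with the pipeline's parameter
values (max overlap 250 bp, Q30, min length 50); they do not replicate any
external trimmer bit-for-bit, and downstream assignment does not depend on
tool-exact trimming.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence, TextIO

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ContractViolation

#: Quality cap on merged bases, matching common FASTQ encodings.
MAX_MERGED_QUAL = 41


@dataclass(frozen=True)
class Read:
    """A sequencing read: bases over {A,C,G,T,N} with per-base Phred scores."""

    id: str
    bases: str
    quals: tuple[int, ...]

    def __post_init__(self):
        object.__setattr__(self, "quals", tuple(self.quals))
        if len(self.bases) != len(self.quals):
            raise ContractViolation(
                f"read {self.id!r}: {len(self.bases)} bases vs {len(self.quals)} quals"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class MergeParams:
    """Overlap-merging settings (defaults per a 2x250 bp overlapping run)."""

    min_overlap: int = 10
    max_overlap: int = 250
    max_mismatch_ratio: float = 0.25

    def __post_init__(self):
        if self.min_overlap < 1 or self.min_overlap > self.max_overlap:
            raise ContractViolation("need 1 <= min_overlap <= max_overlap")


@dataclass(frozen=True)
class TrimParams:
    """End-trimming and length-filter settings (Q30, 50 bp minimum)."""

    qual_threshold: int = 30
    min_length: int = 50

    def __post_init__(self):
        if self.min_length < 1:
            raise ContractViolation("min_length must be >= 1")


class _Unmerged:
    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover
        return "UNMERGED"

    def __bool__(self) -> bool:
        return False


#: Sentinel returned by :func:`merge_pair` when no acceptable overlap exists.
UNMERGED = _Unmerged()


def reverse_complement(read: Read) -> Read:
    return Read(read.id, str(Seq(read.bases).reverse_complement()),
                tuple(reversed(read.quals)))


def merge_pair(r1: Read, r2: Read, p: MergeParams = MergeParams()):
    """Merge an overlapping pair into one pseudoread, or return UNMERGED.

    r2 is reverse-complemented, then every candidate overlap between the 3'
    end of r1 and the 5' end of rc(r2) from ``min_overlap`` up to
    ``min(max_overlap, len(r1), len(r2))`` is scored by mismatch fraction
    (positions where either base is N are not counted as mismatches; the
    denominator is the full overlap length).  The lowest-ratio overlap wins,
    ties going to the longest; ratios above ``max_mismatch_ratio`` are
    rejected.  In the merged overlap, agreements take the max quality (capped
    at 41) and disagreements take the higher-quality base with its own
    quality, r1 winning quality ties.
    """
    if len(r1) == 0 or len(r2) == 0:
        raise ContractViolation("cannot merge an empty read")
    rc2 = reverse_complement(r2)
    max_len = min(p.max_overlap, len(r1), len(r2))
    best: tuple[float, int] | None = None  # (ratio, overlap)
    for overlap in range(p.min_overlap, max_len + 1):
        tail = r1.bases[len(r1) - overlap:]
        head = rc2.bases[:overlap]
        mism = sum(
            1 for a, b in zip(tail, head) if a != b and a != "N" and b != "N"
        )
        ratio = mism / overlap
        if ratio > p.max_mismatch_ratio:
            continue
        if best is None or ratio < best[0] or (ratio == best[0] and overlap > best[1]):
            best = (ratio, overlap)
    if best is None:
        return UNMERGED
    overlap = best[1]
    left_bases = r1.bases[: len(r1) - overlap]
    left_quals = r1.quals[: len(r1) - overlap]
    mid_bases: list[str] = []
    mid_quals: list[int] = []
    for i in range(overlap):
        a, qa = r1.bases[len(r1) - overlap + i], r1.quals[len(r1) - overlap + i]
        b, qb = rc2.bases[i], rc2.quals[i]
        if a == b:
            mid_bases.append(a)
            mid_quals.append(min(max(qa, qb), MAX_MERGED_QUAL))
        elif qb > qa:
            mid_bases.append(b)
            mid_quals.append(qb)
        else:
            mid_bases.append(a)
            mid_quals.append(qa)
    right_bases = rc2.bases[overlap:]
    right_quals = rc2.quals[overlap:]
    return Read(
        r1.id,
        left_bases + "".join(mid_bases) + right_bases,
        tuple(left_quals) + tuple(mid_quals) + tuple(right_quals),
    )


def quality_trim(read: Read, p: TrimParams = TrimParams()) -> Read:
    """Strip sub-threshold bases from both ends; interior bases untouched.

    May return an empty read.  Idempotent.
    """
    lo, hi = 0, len(read)
    while lo < hi and read.quals[lo] < p.qual_threshold:
        lo += 1
    while hi > lo and read.quals[hi - 1] < p.qual_threshold:
        hi -= 1
    return Read(read.id, read.bases[lo:hi], read.quals[lo:hi])


def length_filter(reads: Iterable[Read], p: TrimParams = TrimParams()) -> list[Read]:
    """Keep exactly the reads of length >= ``p.min_length``, order preserved."""
    return [r for r in reads if len(r) >= p.min_length]


def read_fastq(handle: TextIO | str) -> Iterator[Read]:
    """Iterate Sanger/Phred+33 FASTQ records as :class:`Read` objects."""
    for rec in SeqIO.parse(handle, "fastq"):
        yield Read(rec.id, str(rec.seq), tuple(rec.letter_annotations["phred_quality"]))


def write_fastq(reads: Iterable[Read], handle: TextIO | str) -> int:
    """Write reads as Sanger FASTQ; returns the number written."""
    records = (
        SeqRecord(Seq(r.bases), id=r.id, description="",
                  letter_annotations={"phred_quality": list(r.quals)})
        for r in reads
    )
    return SeqIO.write(records, handle, "fastq")


def preprocess_pairs(pairs: Iterable[tuple[Read, Read]],
                     merge: MergeParams = MergeParams(),
                     trim: TrimParams = TrimParams(),
                     keep_unmerged: bool = False) -> tuple[list[Read], dict[str, int]]:
    """Full pre-processing stage: merge, trim, length-filter.

    Unmerged pairs are dropped by default; with ``keep_unmerged`` both mates
    are carried forward as single reads.  Returns the surviving pseudoreads
    and stage counts (pairs in, merged, passing trim+length).
    """
    merged: list[Read] = []
    n_pairs = 0
    n_merged = 0
    for r1, r2 in pairs:
        n_pairs += 1
        m = merge_pair(r1, r2, merge)
        if m is UNMERGED:
            if keep_unmerged:
                merged.extend([r1, r2])
            continue
        n_merged += 1
        merged.append(m)
    trimmed = [quality_trim(r, trim) for r in merged]
    kept = length_filter(trimmed, trim)
    counts = {"pairs_in": n_pairs, "merged": n_merged, "passed": len(kept)}
    return kept, counts
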