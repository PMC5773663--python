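"""Abundance tables, detection filters, background subtraction and CV analysis.

The relative-abundance denominator is the total number of mapped reads in the
sample (assigned at any rank plus unknown), constant across ranks, so
abundances stay comparable across ranks and across profiling methods.
Background subtraction operates on relative abundances (sequencing depths
differ between samples) and floors at zero by default.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .contxt import Assignment
from .errors import ContractViolation
from .taxonomy import Rank, TaxonomyPath, term_at


@dataclass(frozen=True)
class AbundanceRow:
    taxon: str
    lineage: TaxonomyPath
    read_count: int
    rel_abundance: float


@dataclass
class AbundanceTable:
    """Per-sample taxon abundances at one rank.

    ``rows`` maps the taxon term to its row; ``denominator`` is the total
    mapped read count of the sample.  After background subtraction,
    ``rel_abundance`` is the adjusted fraction and ``read_count`` only
    bookkeeping (the fraction re-scaled to the sample's depth).
    """

    sample_id: str
    rank: Rank
    rows: dict[str, AbundanceRow]
    denominator: int

    def __post_init__(self):
        if self.denominator <= 0:
            raise ContractViolation("denominator must be positive")

    def rel(self, taxon: str) -> float:
        row = self.rows.get(taxon)
        return row.rel_abundance if row is not None else 0.0


def build_abundance_table(assignments: Sequence[Assignment], rank: Rank,
                          sample_id: str) -> AbundanceTable:
    """Tabulate reads per taxon at ``rank``.

    A read counts toward taxon t iff it was assigned at ``rank`` or deeper
    and its lineage term at ``rank`` is t.  Reads assigned shallower than
    ``rank`` (and unknown reads) stay in the denominator but in no row.
    """
    if not assignments:
        raise ContractViolation("cannot build a table from zero assignments")
    denominator = len(assignments)
    counts: dict[str, int] = {}
    lineages: dict[str, TaxonomyPath] = {}
    for a in assignments:
        if not a.is_assigned or a.rank < rank:
            continue
        term = term_at(a.lineage, rank)
        counts[term] = counts.get(term, 0) + 1
        lineages.setdefault(term, a.lineage.truncate(rank))
    rows = {
        t: AbundanceRow(t, lineages[t], c, c / denominator)
        for t, c in counts.items()
    }
    return AbundanceTable(sample_id=sample_id, rank=rank, rows=rows,
                          denominator=denominator)


@dataclass(frozen=True)
class FilterParams:
    """Detection filter: at least 2 reads and at least 0.01% relative abundance."""

    min_reads: int = 2
    min_rel_abundance: float = 1e-4

    def __post_init__(self):
        if self.min_reads < 0 or not 0.0 <= self.min_rel_abundance <= 1.0:
            raise ContractViolation("invalid filter parameters")

    def keeps(self, row: AbundanceRow) -> bool:
        return (row.read_count >= self.min_reads
                and row.rel_abundance >= self.min_rel_abundance)


def filter_taxa(table: AbundanceTable, p: FilterParams = FilterParams()) -> AbundanceTable:
    """Keep rows passing both detection predicates (inclusive bounds)."""
    rows = {t: r for t, r in table.rows.items() if p.keeps(r)}
    return AbundanceTable(sample_id=table.sample_id, rank=table.rank,
                          rows=rows, denominator=table.denominator)


def subtract_background(sample: AbundanceTable, background: AbundanceTable,
                        allow_negative: bool = False) -> AbundanceTable:
    """Subtract the background sample's relative abundances per taxon.

    Taxa present only in the background are dropped; sample taxa whose
    background abundance exceeds them are floored at zero (they remain in the
    table as detected-but-explained-by-background) unless ``allow_negative``.
    Read counts are replaced by the adjusted fraction times the sample
    denominator, rounded half-up — bookkeeping only.
    """
    if sample.rank != background.rank:
        raise ContractViolation(
            f"rank mismatch: {sample.rank.label} vs {background.rank.label}"
        )
    rows: dict[str, AbundanceRow] = {}
    for taxon, row in sample.rows.items():
        adj = row.rel_abundance - background.rel(taxon)
        if not allow_negative:
            adj = max(0.0, adj)
        count = int(math.floor(adj * sample.denominator + 0.5))
        rows[taxon] = AbundanceRow(taxon, row.lineage, count, adj)
    return AbundanceTable(sample_id=sample.sample_id, rank=sample.rank,
                          rows=rows, denominator=sample.denominator)


@dataclass(frozen=True)
class CVRecord:
    """Reproducibility of one taxon across replicate samples."""

    taxon: str
    mean_abundance: float
    cv: float
    n_samples: int


def cv_analysis(tables: Sequence[AbundanceTable],
                p: FilterParams = FilterParams()) -> list[CVRecord]:
    """Coefficient of variation for every taxon detected in all samples.

    Each table is filtered first; only taxa surviving the filter in every
    table are scored.  CV = sample standard deviation (n-1) of the relative
    abundances across tables, divided by their mean.  Sorted by descending
    mean abundance.
    """
    if len(tables) < 2:
        raise ContractViolation("cv_analysis needs at least 2 tables")
    rank = tables[0].rank
    if any(t.rank != rank for t in tables):
        raise ContractViolation("all tables must share a rank")
    filtered = [filter_taxa(t, p) for t in tables]
    common = set(filtered[0].rows)
    for t in filtered[1:]:
        common &= set(t.rows)
    records = []
    for taxon in common:
        values = np.array([t.rows[taxon].rel_abundance for t in filtered])
        mean = float(values.mean())
        # identical values must give exactly zero, not accumulation noise
        sd = 0.0 if np.ptp(values) == 0.0 else float(values.std(ddof=1))
        records.append(CVRecord(taxon=taxon, mean_abundance=mean,
                                cv=sd / mean, n_samples=len(tables)))
    records.sort(key=lambda r: (-r.mean_abundance, r.taxon))
    return records


def welch_t_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Unpaired t-test with Welch's correction; returns (t, df, two-sided p).

    With zero variance in both groups the statistic degenerates: p = 1 when
    the means agree, otherwise t diverges and p -> 0 (reported as +/-inf, 0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2 or not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ContractViolation("each group needs >= 2 finite values")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        df = float(len(a) + len(b) - 2)
        if a.mean() == b.mean():
            return 0.0, df, 1.0
        return math.copysign(math.inf, a.mean() - b.mean()), df, 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)
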