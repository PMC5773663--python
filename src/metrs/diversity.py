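"""Shannon diversity, rarefaction and sequencing-cost estimation.

Rarefaction subsamples the *mapped reads* (assignment records) without
replacement at increasing depths, recomputing diversity and genus richness
on each subsample; repeated draws (default five) give a mean and standard
deviation per depth.  Dividing a rarefaction depth by a method's mapping
rate (mapped reads / sequenced reads) converts it into the raw sequencing
depth that method would need, which is how methods with very different
mapping rates are compared on cost.
"""
from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .contxt import Assignment
from .errors import ContractViolation
from .profile import AbundanceTable, FilterParams
from .taxonomy import Rank, term_at


def shannon_from_counts(counts: Sequence[int], base: float = 2.0) -> float:
    """Shannon-Wiener index over positive counts (default bits, log base 2)."""
    # sorting makes the summation order-invariant: the same count multiset
    # always yields the bit-identical index
    positive = np.asarray(sorted(c for c in counts if c > 0), dtype=float)
    if positive.size == 0:
        raise ContractViolation("Shannon index needs at least one positive count")
    p = positive / positive.sum()
    return float(-(p * np.log(p)).sum() / math.log(base))


def shannon(table: AbundanceTable, base: float = 2.0) -> float:
    """Shannon-Wiener index of an abundance table, normalized over its rows."""
    return shannon_from_counts([r.read_count for r in table.rows.values()], base=base)


@dataclass(frozen=True)
class RarefactionPoint:
    depth: int
    mean_shannon: float
    sd_shannon: float
    mean_richness: float
    sd_richness: float


@dataclass(frozen=True)
class RarefactionCurve:
    """Mean/SD of Shannon index and richness at increasing subsample depths."""

    points: tuple[RarefactionPoint, ...]
    rank: Rank
    k: int
    seed: int

    @property
    def depths(self) -> tuple[int, ...]:
        return tuple(p.depth for p in self.points)


def _taxon_counts(assignments: Sequence[Assignment], rank: Rank) -> Counter:
    counts: Counter = Counter()
    for a in assignments:
        if a.is_assigned and a.rank >= rank:
            counts[term_at(a.lineage, rank)] += 1
    return counts


def rarefy(assignments: Sequence[Assignment], depths: Sequence[int],
           rank: Rank = Rank.GENUS, k: int = 5, seed: int = 0,
           filter_params: FilterParams | None = None) -> RarefactionCurve:
    """Rarefaction curve over the mapped reads.

    For each depth, draws ``k`` independent subsamples of the assignment list
    without replacement; on each, tabulates taxa at ``rank`` (reads assigned
    shallower, or unknown, contribute no taxon but do occupy subsample
    slots), optionally applies the detection filter at the rarefied depth,
    and records Shannon index (0 when no taxon survives) and richness.
    Reproducible given ``seed``.
    """
    assignments = list(assignments)
    n = len(assignments)
    depths = sorted(set(int(d) for d in depths))
    if not depths or depths[0] < 1:
        raise ContractViolation("depths must be positive")
    if depths[-1] > n:
        raise ContractViolation(f"depth {depths[-1]} exceeds {n} mapped reads")
    rng = np.random.default_rng(seed)
    points = []
    for depth in depths:
        shannons = np.empty(k)
        richnesses = np.empty(k)
        for i in range(k):
            idx = rng.choice(n, size=depth, replace=False)
            counts = _taxon_counts([assignments[j] for j in idx], rank)
            if filter_params is not None:
                counts = Counter({
                    t: c for t, c in counts.items()
                    if c >= filter_params.min_reads
                    and c / depth >= filter_params.min_rel_abundance
                })
            richnesses[i] = len(counts)
            shannons[i] = (shannon_from_counts(list(counts.values()))
                           if counts else 0.0)
        ddof = 1 if k > 1 else 0

        def _sd(values: np.ndarray) -> float:
            # iterations that agree exactly must report SD 0, not noise
            return 0.0 if np.ptp(values) == 0.0 else float(values.std(ddof=ddof))

        points.append(RarefactionPoint(
            depth=depth,
            mean_shannon=float(shannons.mean()),
            sd_shannon=_sd(shannons),
            mean_richness=float(richnesses.mean()),
            sd_richness=_sd(richnesses),
        ))
    return RarefactionCurve(points=tuple(points), rank=rank, k=k, seed=seed)


def round_down_2sig(x: int) -> int:
    """Round a positive integer down to two significant digits."""
    if x < 100:
        return x
    magnitude = 10 ** (len(str(x)) - 2)
    return (x // magnitude) * magnitude


def depth_grid(total_mapped: int) -> list[int]:
    """Log-spaced rarefaction depths, 10 per decade from 10 upward.

    The final depth is the total mapped read count rounded down to two
    significant digits.
    """
    if total_mapped < 1:
        raise ContractViolation("total_mapped must be >= 1")
    last = round_down_2sig(total_mapped)
    depths: list[int] = []
    i = 0
    while True:
        d = int(round(10 ** (1 + i / 10)))
        if d >= last:
            break
        if not depths or d > depths[-1]:
            depths.append(d)
        i += 1
    depths.append(last)
    return depths


@dataclass(frozen=True)
class DepthEstimate:
    """Raw sequencing depth implied by a mapped depth and a mapping rate."""

    mapped_depth: int
    mapping_rate: float
    estimated_sequenced: float


def estimate_sequenced_depth(mapped_depth: int, mapping_rate: float) -> DepthEstimate:
    """Sequenced reads needed for ``mapped_depth`` at the method's mapping rate."""
    if not 0.0 < mapping_rate <= 1.0:
        raise ContractViolation(f"mapping rate must be in (0,1], got {mapping_rate}")
    if mapped_depth < 0:
        raise ContractViolation("mapped_depth must be >= 0")
    return DepthEstimate(mapped_depth=mapped_depth, mapping_rate=mapping_rate,
                         estimated_sequenced=mapped_depth / mapping_rate)


class _NotReached:
    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover
        return "NOT_REACHED"

    def __bool__(self) -> bool:
        return False


#: Sentinel for a saturation fraction no tabulated depth attains.
NOT_REACHED = _NotReached()


def saturation_depth(curve: RarefactionCurve, fraction: float = 0.95):
    """Smallest tabulated depth reaching ``fraction`` of the final richness.

    Saturation is normalized to the curve's own deepest point, so for any
    fraction <= 1 the final depth qualifies and NOT_REACHED can only occur
    for fractions above 1.
    """
    if fraction <= 0:
        raise ContractViolation("fraction must be positive")
    if not curve.points:
        raise ContractViolation("empty rarefaction curve")
    target = fraction * curve.points[-1].mean_richness
    for point in curve.points:
        if point.mean_richness >= target:
            return point.depth
    return NOT_REACHED
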