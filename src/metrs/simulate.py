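"""Synthetic data emulating a Latin-square stool spike-in experiment.

This module makes every pipeline stage testable without the real reference
database or raw sequencing data.  It provides

* fixture taxonomies with full 7-rank lineages over two domains (and
  optional genus-truncated entries),
* 6x6 Latin-square spike-in designs — each spiked species appears exactly
  once at each concentration across the sample set (defaults: six species,
  decade-spaced 1e4..1e9 cells per gram, plus an un-spiked background
  sample),
* an alignment-level read simulator: each read's source species is drawn
  with probability proportional to cells x rRNA copy factor (fungal cells
  carry more rRNA per cell than bacteria, so fungi are over-represented in
  reads relative to cell counts), and its hit set is the true entry plus
  extra same-genus/same-family entries to mimic the multi-mapping that rRNA
  conservation causes.  The true per-species read fractions are recorded so
  recovery can be checked against ground truth.

Hits are simulated at the alignment level; no sequence-level error model is
attempted, and no real dataset's abundances are reproduced.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

import numpy as np
import yaml

from .contxt import ConsensusParams, HitSet, Rank, assign_read
from .errors import ContractViolation
from .iolib import HitsTable
from .taxonomy import RANKS, ReferenceDB, TaxonomyPath

_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def make_fixture_db(n_genera: int, species_per_genus: int,
                    domains_mix: Sequence[str] = ("Bacteria", "Eukaryota"),
                    seed: int = 0, truncated_fraction: float = 0.0,
                    with_sequences: bool = False) -> ReferenceDB:
    """Deterministic synthetic taxonomy standing in for a curated rRNA DB.

    Genera are split across the requested domains in contiguous blocks and
    nest two-per-family, two families per order, and so on, so clades never
    straddle domains.  ``truncated_fraction`` of the entries (chosen
    reproducibly) lose their species term, exercising absent deep ranks.
    With ``with_sequences`` each entry also gets a mosaic sequence of
    universally conserved blocks interleaved with genus- and species-
    specific blocks, supporting in-silico fragment-length analyses.
    """
    if n_genera < 1 or species_per_genus < 1 or not domains_mix:
        raise ContractViolation("sizes must be positive and domains non-empty")
    rng = np.random.default_rng(seed)
    domains = list(domains_mix)
    per_domain = [n_genera // len(domains)] * len(domains)
    for i in range(n_genera % len(domains)):
        per_domain[i] += 1
    entries: dict[str, TaxonomyPath] = {}
    genus_of_entry: dict[str, str] = {}
    entry_index = 0
    genus_names: list[str] = []
    for dom, count in zip(domains, per_domain):
        for g in range(count):
            genus = f"{dom}_gen{g}"
            genus_names.append(genus)
            lineage = (
                dom,
                f"{dom}_phy{g // 16}",
                f"{dom}_cls{g // 8}",
                f"{dom}_ord{g // 4}",
                f"{dom}_fam{g // 2}",
                genus,
            )
            for s in range(species_per_genus):
                entry_id = f"E{entry_index:04d}"
                entry_index += 1
                entries[entry_id] = TaxonomyPath(lineage + (f"{genus} sp{s}",))
                genus_of_entry[entry_id] = genus
    if truncated_fraction > 0.0:
        ids = list(entries)
        n_trunc = int(round(truncated_fraction * len(ids)))
        for entry_id in rng.choice(ids, size=n_trunc, replace=False):
            entries[entry_id] = entries[entry_id].truncate(Rank.GENUS)
    sequences = None
    if with_sequences:
        conserved = [_random_seq(rng, 120) for _ in range(3)]
        genus_blocks = {g: _random_seq(rng, 60) for g in genus_names}
        sequences = {}
        for entry_id in entries:
            species_block = _random_seq(rng, 60)
            g = genus_of_entry[entry_id]
            sequences[entry_id] = (conserved[0] + genus_blocks[g] + conserved[1]
                                   + species_block + conserved[2])
    return ReferenceDB(entries=entries, name=f"fixture(seed={seed})",
                       sequences=sequences)


def default_concentrations(n: int = 6) -> tuple[float, ...]:
    """Decade-spaced spike-in concentrations from 1e4 cells/g upward."""
    return tuple(10.0 ** (4 + i) for i in range(n))


@dataclass(frozen=True)
class SpikeInDesign:
    """A Latin square of (species, concentration) plus a background sample.

    ``square[i][j]`` is the concentration index of species ``j`` in spiked
    sample ``i``; every row and column is a permutation of 0..n-1, so each
    species is observed exactly once at each dose.
    """

    species: tuple[str, ...]
    concentrations: tuple[float, ...]
    square: tuple[tuple[int, ...], ...]
    includes_background: bool = True
    seed: int = 0

    def __post_init__(self):
        n = len(self.species)
        if len(self.concentrations) != n or len(self.square) != n:
            raise ContractViolation("species/concentrations/square sizes differ")
        ref = tuple(range(n))
        for row in self.square:
            if tuple(sorted(row)) != ref:
                raise ContractViolation("square rows must be permutations of 0..n-1")
        for j in range(n):
            if tuple(sorted(row[j] for row in self.square)) != ref:
                raise ContractViolation("square columns must be permutations of 0..n-1")

    @property
    def n(self) -> int:
        return len(self.species)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        ids = tuple(f"S{i + 1}" for i in range(self.n))
        return ids + ("background",) if self.includes_background else ids

    def cells(self, sample_index: int, species: str) -> float:
        j = self.species.index(species)
        return self.concentrations[self.square[sample_index][j]]


def latin_square(species: Sequence[str],
                 concentrations: Sequence[float] | None = None,
                 seed: int = 0, includes_background: bool = True) -> SpikeInDesign:
    """A uniformly seeded Latin-square spike-in design.

    Built from the cyclic base square with random row, column and symbol
    permutations; the Latin property is validated before returning.
    """
    species = tuple(species)
    n = len(species)
    if n < 1:
        raise ContractViolation("need at least one species")
    if len(set(species)) != n:
        raise ContractViolation("species labels must be unique")
    if concentrations is None:
        concentrations = default_concentrations(n)
    concentrations = tuple(float(c) for c in concentrations)
    if len(concentrations) != n:
        raise ContractViolation("need as many concentrations as species")
    rng = np.random.default_rng(seed)
    rowp = rng.permutation(n)
    colp = rng.permutation(n)
    symp = rng.permutation(n)
    square = tuple(
        tuple(int(symp[(rowp[i] + colp[j]) % n]) for j in range(n))
        for i in range(n)
    )
    return SpikeInDesign(species=species, concentrations=concentrations,
                         square=square, includes_background=includes_background,
                         seed=seed)


@dataclass
class CommunityProfile:
    """Cell counts and per-cell rRNA content of one sample's community.

    ``taxa`` holds the spiked species (cells per gram); ``background`` the
    resident community, always present; ``copy_factor`` scales each
    species' read-emission rate per cell (default 1; fungi conventionally
    larger).
    """

    taxa: dict[str, float] = field(default_factory=dict)
    copy_factor: dict[str, float] = field(default_factory=dict)
    background: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for m in (self.taxa, self.background):
            if any(v < 0 for v in m.values()):
                raise ContractViolation("cell counts must be >= 0")
        if any(v <= 0 for v in self.copy_factor.values()):
            raise ContractViolation("copy factors must be > 0")

    def total_cells(self) -> dict[str, float]:
        cells = dict(self.background)
        for s, c in self.taxa.items():
            cells[s] = cells.get(s, 0.0) + c
        return cells


@dataclass(frozen=True)
class MultimapModel:
    """How many spurious same-clade hits accompany each read's true entry.

    Up to ``max_extra`` candidate entries — drawn from the true entry's
    genus, falling back to its family when the genus is exhausted — each
    join the hit set with probability ``p_extra``; with probability
    ``cross_domain_rate`` one entry from a different domain is added,
    modelling hits inside universally conserved rRNA stretches.
    """

    p_extra: float = 0.0
    max_extra: int = 3
    cross_domain_rate: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.p_extra <= 1.0 or not 0.0 <= self.cross_domain_rate <= 1.0:
            raise ContractViolation("probabilities must be in [0,1]")
        if self.max_extra < 0:
            raise ContractViolation("max_extra must be >= 0")


@dataclass
class SimulatedSample:
    """Simulated hit sets plus the ground-truth read fractions behind them."""

    sample_id: str
    hits: HitsTable
    truth: dict[str, float]
    seed: int
    params: dict

    def __post_init__(self):
        if self.truth and abs(sum(self.truth.values()) - 1.0) > 1e-9:
            raise ContractViolation("truth fractions must sum to 1")


def _species_index(db: ReferenceDB) -> dict[str, list[str]]:
    index: dict[str, list[str]] = {}
    for entry_id, path in db.entries.items():
        if path.depth == len(RANKS):
            index.setdefault(path.deepest_term, []).append(entry_id)
    return index


def simulate_sample(db: ReferenceDB, community: CommunityProfile, n_reads: int,
                    multimap: MultimapModel = MultimapModel(), seed: int = 0,
                    sample_id: str = "sim") -> SimulatedSample:
    """Draw ``n_reads`` alignment-level reads from a community.

    Each read's species is drawn with probability proportional to
    cells x copy_factor; its true entry is uniform among the species'
    database entries; extra hits follow the multimap model.  Deterministic
    given ``seed`` and invariant to database entry order.
    """
    if n_reads < 1:
        raise ContractViolation("n_reads must be >= 1")
    species_index = _species_index(db)
    cells = community.total_cells()
    species_list = sorted(s for s, c in cells.items() if c > 0)
    if not species_list:
        raise ContractViolation("community emits no reads (all cell counts zero)")
    for s in species_list:
        if s not in species_index:
            raise LookupError(f"community species {s!r} has no entry in DB {db.name!r}")
    weights = np.array(
        [cells[s] * community.copy_factor.get(s, 1.0) for s in species_list]
    )
    probs = weights / weights.sum()
    truth = {s: float(p) for s, p in zip(species_list, probs)}

    # clade lookup tables, sorted for order-invariance
    genus_members: dict[str, list[str]] = {}
    family_members: dict[str, list[str]] = {}
    domain_members: dict[str, list[str]] = {}
    for entry_id in sorted(db.entries):
        path = db.entries[entry_id]
        genus_members.setdefault(path.terms[Rank.GENUS] if path.depth > Rank.GENUS
                                 else None, []).append(entry_id)
        family_members.setdefault(path.terms[Rank.FAMILY] if path.depth > Rank.FAMILY
                                  else None, []).append(entry_id)
        domain_members.setdefault(path.terms[0], []).append(entry_id)
    all_domains = sorted(domain_members)

    rng = np.random.default_rng(seed)
    draws = rng.choice(len(species_list), size=n_reads, p=probs)
    hits = HitsTable()
    for i, sp_idx in enumerate(draws):
        read_id = f"R{i + 1:06d}"
        pool = sorted(species_index[species_list[sp_idx]])
        true_entry = pool[rng.integers(len(pool))]
        hits.add(read_id, true_entry)
        if multimap.max_extra > 0 and multimap.p_extra > 0.0:
            path = db.entries[true_entry]
            genus = path.terms[Rank.GENUS] if path.depth > Rank.GENUS else None
            family = path.terms[Rank.FAMILY] if path.depth > Rank.FAMILY else None
            candidates = [e for e in genus_members.get(genus, []) if e != true_entry]
            if len(candidates) < multimap.max_extra and family is not None:
                genus_set = set(candidates)
                candidates += [
                    e for e in family_members.get(family, [])
                    if e != true_entry and e not in genus_set
                ]
            if candidates:
                order = rng.permutation(len(candidates))[: multimap.max_extra]
                accept = rng.random(len(order)) < multimap.p_extra
                for j, ok in zip(order, accept):
                    if ok:
                        hits.add(read_id, candidates[j])
        if multimap.cross_domain_rate > 0.0 and rng.random() < multimap.cross_domain_rate:
            others = [d for d in all_domains if d != db.entries[true_entry].terms[0]]
            if others:
                dom = others[rng.integers(len(others))]
                members = domain_members[dom]
                hits.add(read_id, members[rng.integers(len(members))])
    params = {
        "n_reads": n_reads,
        "p_extra": multimap.p_extra,
        "max_extra": multimap.max_extra,
        "cross_domain_rate": multimap.cross_domain_rate,
        "db": db.name,
    }
    return SimulatedSample(sample_id=sample_id, hits=hits, truth=truth,
                           seed=seed, params=params)


def pick_spike_species(db: ReferenceDB, per_domain: int = 3) -> list[str]:
    """One species per genus, ``per_domain`` genera from each domain.

    Mirrors a spike-in panel of distinct organisms (e.g. three bacteria and
    three fungi) drawn from a two-domain reference.
    """
    by_genus: dict[tuple[str, str], str] = {}
    for entry_id in sorted(db.entries):
        path = db.entries[entry_id]
        if path.depth == len(RANKS):
            key = (path.terms[0], path.terms[Rank.GENUS])
            by_genus.setdefault(key, path.deepest_term)
    chosen: list[str] = []
    per_dom_count: dict[str, int] = {}
    for (dom, _), species in sorted(by_genus.items()):
        if per_dom_count.get(dom, 0) < per_domain:
            chosen.append(species)
            per_dom_count[dom] = per_dom_count.get(dom, 0) + 1
    return chosen


def background_community(db: ReferenceDB, exclude: Iterable[str] = (),
                         cells: float = 1e7) -> dict[str, float]:
    """A resident community: one species per genus not in ``exclude``."""
    exclude = set(exclude)
    by_genus: dict[tuple[str, str], str] = {}
    for entry_id in sorted(db.entries):
        path = db.entries[entry_id]
        if path.depth == len(RANKS) and path.deepest_term not in exclude:
            key = (path.terms[0], path.terms[Rank.GENUS])
            by_genus.setdefault(key, path.deepest_term)
    return {species: cells for species in by_genus.values()}


def copy_factors_by_domain(db: ReferenceDB, factors: dict[str, float],
                           ) -> dict[str, float]:
    """Per-species copy factors assigned by domain (e.g. Eukaryota -> 5.0)."""
    out: dict[str, float] = {}
    for path in db.entries.values():
        if path.depth == len(RANKS) and path.terms[0] in factors:
            out[path.deepest_term] = factors[path.terms[0]]
    return out


def spikein_communities(design: SpikeInDesign, background: dict[str, float],
                        copy_factor: dict[str, float] | None = None,
                        ) -> dict[str, CommunityProfile]:
    """One community per design sample: spiked cells per the square, shared
    background, shared copy factors.  The background sample spikes nothing."""
    copy_factor = dict(copy_factor or {})
    communities = {}
    for i, sample_id in enumerate(design.sample_ids):
        if sample_id == "background":
            taxa: dict[str, float] = {}
        else:
            taxa = {sp: design.cells(i, sp) for sp in design.species}
        communities[sample_id] = CommunityProfile(
            taxa=taxa, copy_factor=copy_factor, background=dict(background)
        )
    return communities


def length_specificity_curve(db: ReferenceDB, read_lengths: Sequence[int],
                             seed: int = 0, n_fragments: int = 100,
                             params: ConsensusParams = ConsensusParams(),
                             ) -> dict[int, float]:
    """Fraction of simulated fragments assignable at genus level, by length.

    Fragments are drawn uniformly from the fixture sequences and "mapped" by
    exact substring containment; short fragments falling inside conserved
    blocks hit many entries and cannot reach a genus consensus, so the curve
    rises with length.  A property-level analogue of read-length selection;
    no real-database number is reproduced.
    """
    if db.sequences is None:
        raise ContractViolation("DB carries no sequences; build with with_sequences=True")
    entry_ids = sorted(db.sequences)
    min_len = min(len(db.sequences[e]) for e in entry_ids)
    lengths = sorted(set(int(l) for l in read_lengths))
    if lengths[0] < 1 or lengths[-1] > min_len:
        raise ContractViolation(f"lengths must be within 1..{min_len}")
    rng = np.random.default_rng(seed)
    curve: dict[int, float] = {}
    for length in lengths:
        n_genus = 0
        for f in range(n_fragments):
            source = entry_ids[rng.integers(len(entry_ids))]
            seq = db.sequences[source]
            start = rng.integers(len(seq) - length + 1)
            frag = seq[start:start + length]
            matched = frozenset(e for e in entry_ids if frag in db.sequences[e])
            a = assign_read(HitSet(read_id=f"F{length}_{f}", entry_ids=matched),
                            db, params)
            if a.is_assigned and a.rank >= Rank.GENUS:
                n_genus += 1
        curve[length] = n_genus / n_fragments
    return curve


def write_design_yaml(design: SpikeInDesign, out: TextIO) -> None:
    yaml.safe_dump(
        {
            "species": list(design.species),
            "concentrations": list(design.concentrations),
            "square": [list(row) for row in design.square],
            "includes_background": design.includes_background,
            "seed": design.seed,
        },
        out, sort_keys=False,
    )


def read_design_yaml(stream) -> SpikeInDesign:
    data = yaml.safe_load(stream)
    return SpikeInDesign(
        species=tuple(data["species"]),
        concentrations=tuple(float(c) for c in data["concentrations"]),
        square=tuple(tuple(int(v) for v in row) for row in data["square"]),
        includes_background=bool(data.get("includes_background", True)),
        seed=int(data.get("seed", 0)),
    )


def write_truth_tsv(sample: SimulatedSample, out: TextIO) -> None:
    out.write(f"# truth: sample={sample.sample_id}\tseed={sample.seed}\n")
    for species in sorted(sample.truth):
        out.write(f"{species}\t{sample.truth[species]:.10g}\n")
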