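"""Fixture taxonomies, Latin squares and the alignment-level read simulator."""
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metrs.contxt import assign_all, rank_summary
from metrs.errors import ContractViolation
from metrs.profile import build_abundance_table
from metrs.simulate import (
    CommunityProfile,
    MultimapModel,
    SpikeInDesign,
    background_community,
    copy_factors_by_domain,
    default_concentrations,
    latin_square,
    length_specificity_curve,
    make_fixture_db,
    pick_spike_species,
    read_design_yaml,
    simulate_sample,
    spikein_communities,
    write_design_yaml,
)
from metrs.taxonomy import ABSENT, Rank, ReferenceDB, term_at


class TestMakeFixtureDb:
    def test_entry_and_genus_counts(self):
        db = make_fixture_db(2, 3, seed=1)
        assert len(db) == 6
        genera = {p.terms[Rank.GENUS] for p in db.entries.values()}
        assert len(genera) == 2

    def test_deterministic(self):
        a = make_fixture_db(4, 2, seed=11, with_sequences=True)
        b = make_fixture_db(4, 2, seed=11, with_sequences=True)
        assert a.entries == b.entries and a.sequences == b.sequences

    def test_truncated_fraction(self):
        db = make_fixture_db(5, 4, seed=2, truncated_fraction=0.5)
        absent = sum(
            1 for p in db.entries.values() if term_at(p, Rank.SPECIES) is ABSENT
        )
        assert absent == 10  # half of 20 entries

    def test_both_domains_present(self):
        db = make_fixture_db(6, 2, seed=3)
        assert set(db.domain_counts()) == {"Bacteria", "Eukaryota"}

    def test_zero_sizes_rejected(self):
        with pytest.raises(ContractViolation):
            make_fixture_db(0, 3, seed=1)


def _is_latin(square):
    n = len(square)
    ref = tuple(range(n))
    rows_ok = all(tuple(sorted(r)) == ref for r in square)
    cols_ok = all(tuple(sorted(r[j] for r in square)) == ref for j in range(n))
    return rows_ok and cols_ok


class TestLatinSquare:
    def test_default_design_has_seven_samples(self):
        design = latin_square([f"sp{i}" for i in range(6)], seed=0)
        assert len(design.sample_ids) == 7
        assert design.sample_ids[-1] == "background"
        assert design.concentrations == default_concentrations(6)
        assert _is_latin(design.square)

    def test_single_cell(self):
        design = latin_square(["only"], seed=0)
        assert design.square == ((0,),)
        assert len(design.sample_ids) == 2

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ContractViolation):
            latin_square(["a", "a", "b"])

    def test_invalid_square_rejected(self):
        with pytest.raises(ContractViolation):
            SpikeInDesign(species=("a", "b"), concentrations=(1.0, 2.0),
                          square=((0, 0), (1, 1)))

    @given(st.integers(min_value=0, max_value=500), st.integers(min_value=1, max_value=8))
    @settings(derandomize=True, max_examples=60)
    def test_latin_property_over_seeds_and_sizes(self, seed, n):
        design = latin_square([f"s{i}" for i in range(n)], seed=seed)
        assert _is_latin(design.square)

    def test_each_species_once_per_concentration(self):
        design = latin_square([f"sp{i}" for i in range(6)], seed=42)
        for j in range(6):
            doses = [design.square[i][j] for i in range(6)]
            assert sorted(doses) == list(range(6))

    def test_yaml_roundtrip(self, tmp_path):
        design = latin_square([f"sp{i}" for i in range(4)], seed=9)
        path = tmp_path / "d.yaml"
        with open(path, "w") as fh:
            write_design_yaml(design, fh)
        with open(path) as fh:
            assert read_design_yaml(fh) == design


class TestSimulateSample:
    def test_no_noise_recovers_truth_exactly(self):
        """With copy factor 1 and no multimapping, every read is single-hit
        and species assignments reproduce the drawn community exactly."""
        db = make_fixture_db(4, 2, seed=5)
        species = sorted({p.deepest_term for p in db.entries.values()})[:4]
        community = CommunityProfile(background={s: 10.0 for s in species})
        sample = simulate_sample(db, community, 2000, MultimapModel(), seed=6)
        hitsets = sample.hits.hitsets()
        assert all(h.n_hits == 1 for h in hitsets)
        assignments, summary = assign_all(hitsets, db)
        assert summary.per_rank[Rank.SPECIES] == 2000
        table = build_abundance_table(assignments, Rank.SPECIES, "s")
        drawn = Counter()
        for h in hitsets:
            (entry,) = h.entry_ids
            drawn[db.path(entry).deepest_term] += 1
        assert {t: r.read_count for t, r in table.rows.items()} == dict(drawn)

    def test_cell_ratio_sets_truth_fractions(self):
        db = make_fixture_db(2, 1, seed=7)
        s1, s2 = sorted(p.deepest_term for p in db.entries.values())
        community = CommunityProfile(taxa={s1: 90.0, s2: 10.0})
        sample = simulate_sample(db, community, 10, seed=1)
        assert sample.truth == {s1: pytest.approx(0.9), s2: pytest.approx(0.1)}

    def test_copy_factor_scales_truth(self):
        db = make_fixture_db(2, 1, seed=7)
        s1, s2 = sorted(p.deepest_term for p in db.entries.values())
        community = CommunityProfile(taxa={s1: 50.0, s2: 50.0},
                                     copy_factor={s2: 3.0})
        sample = simulate_sample(db, community, 10, seed=1)
        assert sample.truth[s2] == pytest.approx(0.75)

    def test_truth_sums_to_one(self):
        db = make_fixture_db(6, 3, seed=8)
        species = sorted({p.deepest_term for p in db.entries.values()})
        community = CommunityProfile(background={s: float(i + 1)
                                                 for i, s in enumerate(species)})
        sample = simulate_sample(db, community, 10, seed=2)
        assert sum(sample.truth.values()) == pytest.approx(1.0)

    def test_invariant_to_db_entry_order(self):
        db = make_fixture_db(4, 2, seed=5)
        reordered = ReferenceDB(
            entries=dict(sorted(db.entries.items(), reverse=True)), name=db.name)
        species = sorted({p.deepest_term for p in db.entries.values()})
        community = CommunityProfile(background={s: 5.0 for s in species})
        a = simulate_sample(db, community, 500, MultimapModel(p_extra=0.4), seed=3)
        b = simulate_sample(reordered, community, 500, MultimapModel(p_extra=0.4), seed=3)
        assert a.truth == b.truth
        assert set(a.hits.rows) == set(b.hits.rows)

    def test_unknown_species_is_lookup_error(self):
        db = make_fixture_db(2, 2, seed=5)
        community = CommunityProfile(taxa={"Vibrio cholerae": 10.0})
        with pytest.raises(LookupError, match="Vibrio"):
            simulate_sample(db, community, 10)

    def test_cross_domain_rate_raises_unknown_fraction(self):
        db = make_fixture_db(6, 2, seed=9)
        species = sorted({p.deepest_term for p in db.entries.values()})
        community = CommunityProfile(background={s: 10.0 for s in species})
        unknowns = []
        for rate in (0.0, 0.5, 1.0):
            model = MultimapModel(p_extra=0.0, cross_domain_rate=rate)
            sample = simulate_sample(db, community, 2000, model, seed=4)
            assignments, _ = assign_all(sample.hits.hitsets(), db)
            unknowns.append(rank_summary(assignments).unknown_fraction)
        assert unknowns[0] == 0.0
        assert unknowns[0] < unknowns[1] < unknowns[2]


class TestCommunityHelpers:
    def test_spikein_communities_follow_the_square(self):
        db = make_fixture_db(8, 2, seed=1)
        spiked = pick_spike_species(db)
        assert len(spiked) == 6
        design = latin_square(spiked, seed=1)
        background = background_community(db, exclude=spiked)
        comms = spikein_communities(design, background,
                                    copy_factors_by_domain(db, {"Eukaryota": 5.0}))
        assert set(comms) == set(design.sample_ids)
        assert comms["background"].taxa == {}
        for i, sid in enumerate(design.sample_ids[:-1]):
            for j, sp in enumerate(design.species):
                expected = design.concentrations[design.square[i][j]]
                assert comms[sid].taxa[sp] == expected

    def test_copy_factor_validation(self):
        with pytest.raises(ContractViolation):
            CommunityProfile(taxa={"a": 1.0}, copy_factor={"a": 0.0})


class TestLengthSpecificity:
    db = make_fixture_db(6, 2, seed=12, with_sequences=True)

    def test_full_length_fragments_fully_assignable(self):
        full = len(next(iter(self.db.sequences.values())))
        curve = length_specificity_curve(self.db, [full], seed=1, n_fragments=40)
        assert curve[full] == 1.0

    def test_short_fragments_rarely_genus_assignable(self):
        curve = length_specificity_curve(self.db, [25, 300], seed=1, n_fragments=80)
        assert curve[25] < curve[300]
        assert curve[25] < 0.7

    def test_overlong_fragment_rejected(self):
        with pytest.raises(ContractViolation):
            length_specificity_curve(self.db, [10_000], seed=1)

    def test_requires_sequences(self):
        db = make_fixture_db(2, 2, seed=1)
        with pytest.raises(ContractViolation):
            length_specificity_curve(db, [50], seed=1)
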