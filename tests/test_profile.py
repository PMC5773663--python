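"""Abundance tables, detection filters, background subtraction, CV, Welch test."""
import math

import numpy as np
import pytest

from metrs.contxt import assign_all
from metrs.errors import ContractViolation
from metrs.profile import (
    AbundanceRow,
    AbundanceTable,
    FilterParams,
    build_abundance_table,
    cv_analysis,
    filter_taxa,
    subtract_background,
    welch_t_test,
)
from metrs.taxonomy import RANKS, Rank, TaxonomyPath


def _table(counts: dict[str, int], denominator: int, rank=Rank.GENUS,
           sample_id="s") -> AbundanceTable:
    rows = {}
    for taxon, count in counts.items():
        lin = TaxonomyPath(("Bacteria", "P", "C", "O", "F", taxon)[: rank + 1])
        rows[taxon] = AbundanceRow(taxon, lin, count, count / denominator)
    return AbundanceTable(sample_id=sample_id, rank=rank, rows=rows,
                          denominator=denominator)


class TestBuildAbundanceTable:
    def test_genus_counts_pool_deeper_assignments(self, toy_db, four_read_hitsets):
        # species, species, genus, unknown -> Lactobacillus: 3 of 4 reads
        assignments, _ = assign_all(four_read_hitsets, toy_db)
        table = build_abundance_table(assignments, Rank.GENUS, "s")
        assert table.denominator == 4
        assert table.rows["Lactobacillus"].read_count == 3
        assert table.rows["Lactobacillus"].rel_abundance == 0.75

    def test_all_unknown_gives_empty_rows(self, toy_db):
        from metrs.contxt import HitSet
        hitsets = [HitSet(f"r{i}", frozenset({"E1", "E7"})) for i in range(3)]
        assignments, _ = assign_all(hitsets, toy_db)
        table = build_abundance_table(assignments, Rank.GENUS, "s")
        assert table.rows == {} and table.denominator == 3

    def test_single_species_read(self, toy_db):
        from metrs.contxt import HitSet
        assignments, _ = assign_all([HitSet("r", frozenset({"E1"}))], toy_db)
        table = build_abundance_table(assignments, Rank.SPECIES, "s")
        (row,) = table.rows.values()
        assert row.rel_abundance == 1.0

    def test_conservation_at_every_rank(self, toy_db, four_read_hitsets):
        assignments, _ = assign_all(four_read_hitsets, toy_db)
        for rank in RANKS:
            table = build_abundance_table(assignments, rank, "s")
            counted = sum(r.read_count for r in table.rows.values())
            uncounted = sum(
                1 for a in assignments if not a.is_assigned or a.rank < rank
            )
            assert counted + uncounted == table.denominator

    def test_empty_is_contract_violation(self):
        with pytest.raises(ContractViolation):
            build_abundance_table([], Rank.GENUS, "s")


class TestFilterTaxa:
    def test_single_read_row_dropped(self):
        table = _table({"A": 1, "B": 2}, denominator=10)
        assert set(filter_taxa(table).rows) == {"B"}

    def test_boundary_rel_abundance_kept(self):
        table = _table({"A": 2}, denominator=20000)  # exactly 0.01%
        assert set(filter_taxa(table).rows) == {"A"}
        below = _table({"A": 2}, denominator=20001)
        assert set(filter_taxa(below).rows) == set()

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(13)
        p = FilterParams()
        for _ in range(20):
            denom = int(rng.integers(1000, 50000))
            counts = {f"T{i}": int(c)
                      for i, c in enumerate(rng.integers(0, 8, size=30)) if c > 0}
            table = _table(counts, denominator=denom)
            survivors = set(filter_taxa(table, p).rows)
            expected = {
                t for t, c in counts.items()
                if c >= 2 and c / denom >= 1e-4
            }
            assert survivors == expected

    def test_idempotent_and_monotone(self):
        table = _table({"A": 1, "B": 2, "C": 50}, denominator=100)
        once = filter_taxa(table)
        assert filter_taxa(once).rows == once.rows
        stricter = filter_taxa(table, FilterParams(min_reads=10))
        assert set(stricter.rows) <= set(once.rows)
        assert stricter.denominator == table.denominator


class TestSubtractBackground:
    def test_simple_subtraction(self):
        s = _table({"A": 50}, denominator=10000)   # 0.5%
        b = _table({"A": 20}, denominator=10000)   # 0.2%
        out = subtract_background(s, b)
        assert out.rows["A"].rel_abundance == pytest.approx(0.003)
        assert out.rows["A"].read_count == 30

    def test_floored_at_zero(self):
        s = _table({"A": 10}, denominator=10000)   # 0.1%
        b = _table({"A": 20}, denominator=10000)   # 0.2%
        out = subtract_background(s, b)
        assert out.rows["A"].rel_abundance == 0.0
        assert subtract_background(s, b, allow_negative=True).rows["A"].rel_abundance \
            == pytest.approx(-0.001)

    def test_empty_background_is_identity_on_rel(self):
        s = _table({"A": 10, "B": 3}, denominator=100)
        b = _table({}, denominator=50)
        out = subtract_background(s, b)
        assert {t: r.rel_abundance for t, r in out.rows.items()} == \
               {t: r.rel_abundance for t, r in s.rows.items()}

    def test_background_only_taxa_dropped(self):
        s = _table({"A": 10}, denominator=100)
        b = _table({"A": 1, "Z": 40}, denominator=100)
        assert set(subtract_background(s, b).rows) == {"A"}

    def test_self_subtraction_zeroes(self):
        s = _table({"A": 10, "B": 3}, denominator=100)
        out = subtract_background(s, s)
        assert all(r.rel_abundance == 0.0 for r in out.rows.values())

    def test_rank_mismatch_rejected(self):
        s = _table({"A": 10}, denominator=100, rank=Rank.GENUS)
        b = _table({"A": 10}, denominator=100, rank=Rank.FAMILY)
        with pytest.raises(ContractViolation):
            subtract_background(s, b)


class TestCvAnalysis:
    def test_identical_abundances_give_zero_cv(self):
        tables = [_table({"A": 100}, 1000, sample_id=f"s{i}") for i in range(3)]
        (rec,) = cv_analysis(tables)
        assert rec.cv == 0.0 and rec.n_samples == 3

    def test_two_point_closed_form(self):
        # abundances 1% and 3%: sd = sqrt(2)%, mean = 2% -> cv = sqrt(2)/2
        tables = [_table({"A": 10}, 1000), _table({"A": 30}, 1000)]
        (rec,) = cv_analysis(tables)
        assert rec.cv == pytest.approx(math.sqrt(2) / 2)
        assert rec.mean_abundance == pytest.approx(0.02)

    def test_taxon_missing_from_one_table_excluded(self):
        tables = [_table({"A": 100, "B": 50}, 1000),
                  _table({"A": 100}, 1000),
                  _table({"A": 100, "B": 50}, 1000)]
        assert [r.taxon for r in cv_analysis(tables)] == ["A"]

    def test_detection_is_evaluated_after_filtering(self):
        # B has 1 read in the middle table: detected nowhere near the filter
        tables = [_table({"A": 100, "B": 50}, 1000),
                  _table({"A": 100, "B": 1}, 1000),
                  _table({"A": 100, "B": 50}, 1000)]
        assert [r.taxon for r in cv_analysis(tables)] == ["A"]

    def test_order_invariant(self):
        tables = [_table({"A": 10, "B": 40}, 1000),
                  _table({"A": 30, "B": 20}, 1000),
                  _table({"A": 20, "B": 30}, 1000)]
        fwd = cv_analysis(tables)
        rev = cv_analysis(list(reversed(tables)))
        assert fwd == rev

    def test_fewer_than_two_tables_rejected(self):
        with pytest.raises(ContractViolation):
            cv_analysis([_table({"A": 10}, 100)])


class TestWelchTTest:
    def test_identical_groups(self):
        t, _, p = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_hand_derived_case(self):
        # a=[0]*4, b=[1,1,1,2]: se = sqrt(0 + 0.25/4) = 0.25, t = -1.25/0.25 = -5,
        # Welch-Satterthwaite df collapses to n_b - 1 = 3;
        # p = 2*(1 - T3(5)) via the closed-form t CDF = 0.015394
        t, df, p = welch_t_test([0, 0, 0, 0], [1, 1, 1, 2])
        assert t == pytest.approx(-5.0)
        assert df == pytest.approx(3.0)
        assert p == pytest.approx(0.015394, abs=1e-5)

    def test_antisymmetry(self):
        a, b = [0.1, 0.4, 0.2], [0.5, 0.9, 0.3, 0.8]
        t1, df1, p1 = welch_t_test(a, b)
        t2, df2, p2 = welch_t_test(b, a)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)
        assert df1 == pytest.approx(df2)

    def test_degenerate_zero_variance(self):
        t, _, p = welch_t_test([1, 1, 1], [1, 1])
        assert (t, p) == (0.0, 1.0)
        t, _, p = welch_t_test([2, 2, 2], [1, 1])
        assert math.isinf(t) and t > 0 and p == 0.0

    def test_too_small_group_rejected(self):
        with pytest.raises(ContractViolation):
            welch_t_test([1.0], [1.0, 2.0])
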