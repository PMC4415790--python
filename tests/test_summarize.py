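"""Size distributions, extents, tail composition, matrices, and the proportion test."""

import math

import pytest
from scipy import stats as sps

from mirtail.anchor_profile import ModificationRecord, ModificationTable, profile_library
from mirtail.read_ingest import CollapsedRead
from mirtail.summarize import (
    chi_square_2x2,
    compare_proportions,
    coordinate_matrix,
    long_species_fraction,
    size_distribution,
    tail_composition,
    tail_trim_extent,
)

from conftest import REF_R


def record(trim=0, tail="", count=1, weight=1.0, ref_len=21):
    gmc = ref_len - trim
    return ModificationRecord(
        ref_ids=("miR-R",),
        read_sequence=REF_R[:gmc] + tail,
        count=count,
        weight=weight,
        gmc_len=gmc,
        trim_len=trim,
        tail_seq=tail,
    )


def table_of(*records):
    return ModificationTable(records=list(records))


class TestSizeDistribution:
    def test_weighted_percentages(self):
        # masses: 21 nt -> 84, 20 nt -> 10, 19 nt -> 6
        t = table_of(record(count=84), record(trim=1, count=10), record(trim=2, count=6))
        dist = size_distribution(t, axis="read-length")
        assert dist.percent_by_length == {21: 84.0, 20: 10.0, 19: 6.0}

    def test_single_record_is_one_full_bin(self):
        dist = size_distribution(table_of(record()), axis="read-length")
        assert dist.percent_by_length == {21: 100.0}

    def test_cutoff_flags_display_only(self):
        t = table_of(record(count=996), record(trim=1, count=4))  # 0.4% bin
        dist = size_distribution(t, axis="read-length", display_cutoff=0.5)
        assert dist.below_cutoff(20)
        assert math.isclose(sum(dist.percent_by_length.values()), 100.0)
        assert math.isclose(dist.percent_by_length[20], 0.4)

    def test_gmc_axis_ignores_tails(self):
        t = table_of(record(trim=2, tail="UUUU", count=10))
        dist = size_distribution(t, axis="gmc-length")
        assert dist.percent_by_length == {19: 100.0}

    def test_empty_table_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            size_distribution(table_of(), axis="read-length")

    def test_read_length_mass_matches_matrix_antidiagonals(self):
        # cross-consistency: mass at read length L equals matrix mass on
        # {(t, l): ref_len - t + l == L} for a single-reference table
        t = table_of(
            record(count=40),
            record(trim=1, count=25),
            record(trim=1, tail="U", count=20),
            record(tail="UU", count=10),
            record(trim=3, tail="A", count=5),
        )
        dist = size_distribution(t, axis="read-length")
        matrix = coordinate_matrix(t)
        for length, pct in dist.percent_by_length.items():
            anti = sum(
                p for (tr, tl), p in matrix.mass.items() if 21 - tr + tl == length
            )
            assert math.isclose(anti, pct, abs_tol=1e-9)


class TestTailTrimExtent:
    def test_single_length_extent_and_composition(self):
        t = table_of(record(count=90), record(tail="U", count=10))
        tails, trims = tail_trim_extent(t)
        by_len = {int(s.scope.rsplit("-", 1)[1]): s for s in tails}
        assert math.isclose(by_len[1].extent_percent, 10.0)
        assert by_len[1].fraction_by_nucleotide["U"] == 1.0
        assert math.isclose(by_len[0].extent_percent, 90.0)

    def test_no_tailing_reports_unmodified_mass(self):
        tails, trims = tail_trim_extent(table_of(record(count=5)))
        assert len(tails) == 1 and tails[0].scope == "tail-length-0"
        assert math.isclose(tails[0].extent_percent, 100.0)

    def test_pooled_nucleotide_fraction_hand_count(self):
        # tails UU x3 and UA x1: 8 tail nt, 7 U -> U fraction 0.875
        t = table_of(record(tail="UU", count=3), record(tail="UA", count=1))
        tails, _ = tail_trim_extent(t)
        by_len = {int(s.scope.rsplit("-", 1)[1]): s for s in tails}
        assert math.isclose(by_len[2].fraction_by_nucleotide["U"], 0.875)


class TestTailComposition:
    def test_all_u_tails(self):
        comp = tail_composition(table_of(record(tail="U", count=3)))
        assert comp.fraction_by_nucleotide == {"A": 0.0, "C": 0.0, "G": 0.0, "U": 1.0}

    def test_mixed_tails_quarter_each(self):
        comp = tail_composition(table_of(record(tail="AC"), record(tail="GU")))
        assert all(math.isclose(f, 0.25) for f in comp.fraction_by_nucleotide.values())

    def test_coordinate_1_1_subset(self):
        t = table_of(
            record(trim=1, tail="U", count=10),     # in subset
            record(trim=2, tail="AA", count=50),    # out
            record(tail="G", count=50),             # out (no trim)
        )
        comp = tail_composition(t, subset=lambda c: c == (1, 1), scope="coordinate-1-1")
        assert comp.fraction_by_nucleotide["U"] == 1.0
        assert comp.raw_nucleotide_counts == {"U": 10.0}

    def test_empty_subset_is_flagged(self):
        comp = tail_composition(table_of(record(count=5)))
        assert comp.empty
        assert math.isnan(comp.fraction_by_nucleotide["U"])

    def test_raw_counts_additive_over_disjoint_subsets(self):
        t = table_of(
            record(trim=1, tail="U", count=10),
            record(trim=2, tail="UA", count=5),
            record(tail="G", count=2),
        )
        whole = tail_composition(t)
        part_a = tail_composition(t, subset=lambda c: c[0] <= 1)
        part_b = tail_composition(t, subset=lambda c: c[0] > 1)
        for nt in "ACGU":
            assert math.isclose(
                part_a.raw_nucleotide_counts.get(nt, 0.0)
                + part_b.raw_nucleotide_counts.get(nt, 0.0),
                whole.raw_nucleotide_counts.get(nt, 0.0),
            )


class TestCoordinateMatrix:
    def test_renormalization_after_origin_removal(self):
        t = table_of(record(count=50), record(trim=1, count=30), record(tail="U", count=20))
        matrix = coordinate_matrix(t, renormalize_without_origin=True)
        assert matrix.mass == {(1, 0): 60.0, (0, 1): 40.0}
        assert (0, 0) not in matrix.mass

    def test_single_coordinate_is_total(self):
        matrix = coordinate_matrix(table_of(record(trim=2, tail="UU", count=9)))
        assert matrix.mass == {(2, 2): 100.0}

    @pytest.mark.parametrize("renorm", [False, True])
    def test_total_is_100_within_tolerance(self, renorm):
        t = table_of(
            record(count=13), record(trim=1, count=7), record(tail="U", count=29),
            record(trim=3, tail="AAG", count=17),
        )
        matrix = coordinate_matrix(t, renormalize_without_origin=renorm)
        assert abs(matrix.total - 100.0) <= 1e-9

    def test_renormalization_with_only_origin_mass_is_error(self):
        with pytest.raises(ValueError, match="no variants"):
            coordinate_matrix(table_of(record(count=10)), renormalize_without_origin=True)

    def test_modes_agree_up_to_scalar_on_non_origin_cells(self):
        t = table_of(record(count=50), record(trim=1, count=30), record(tail="U", count=20))
        plain = coordinate_matrix(t)
        renorm = coordinate_matrix(t, renormalize_without_origin=True)
        ratios = {c: renorm.mass[c] / plain.mass[c] for c in renorm.mass}
        assert len(set(round(r, 12) for r in ratios.values())) == 1

    def test_scope_restriction_by_reference_id(self, random_refs):
        reads = [CollapsedRead(e.sequence, 10) for e in random_refs]
        table = profile_library(reads, random_refs)
        one = coordinate_matrix(table, ref_id=random_refs.entries[0].ids[0])
        assert one.mass == {(0, 0): 100.0}


class TestLongSpeciesFraction:
    @pytest.mark.parametrize(
        "records,expected",
        [
            ([record(count=10)], 0.0),                                   # all 21 nt
            ([record(tail="U", count=5), record(trim=1, count=5)], 50.0),  # 22 vs 20
            (
                [record(count=90), record(tail="U", count=6), record(tail="UU", count=4)],
                10.0,
            ),
        ],
    )
    def test_threshold_fraction(self, records, expected):
        assert math.isclose(long_species_fraction(table_of(*records), threshold=22), expected)


class TestCompareProportions:
    def test_chi_square_matches_textbook_closed_form(self):
        # pooled counts: 910/10,000 vs 250/10,000
        res = compare_proportions((910, 10_000), (250, 10_000), method="chi-square")
        a, b, c, d = 910, 9090, 250, 9750
        n = a + b + c + d
        expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert abs(res.statistic - expected) < 1e-10
        assert res.pvalue < 0.0001
        # independent library cross-check
        chi2, p, _, _ = sps.chi2_contingency([[a, b], [c, d]], correction=False)
        assert abs(res.statistic - chi2) < 1e-8 and abs(res.pvalue - p) < 1e-12

    def test_identical_pooled_counts_give_p_of_1(self):
        res = compare_proportions((250, 10_000), (250, 10_000), method="chi-square")
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_anova_degenerate_separation_reports_floor_p(self):
        res = compare_proportions([9.1, 9.1], [2.5, 2.5], method="anova-f")
        assert res.pvalue == 0.0 and math.isinf(res.statistic)

    def test_anova_identical_constant_groups_give_p_of_1(self):
        res = compare_proportions([5.0, 5.0], [5.0, 5.0], method="anova-f")
        assert res.pvalue == 1.0

    def test_anova_ordinary_case_matches_scipy(self):
        a, b = [9.0, 9.3], [2.4, 2.6]
        res = compare_proportions(a, b, method="anova-f")
        stat, p = sps.f_oneway(a, b)
        assert math.isclose(res.statistic, stat) and math.isclose(res.pvalue, p)

    def test_single_replicate_rejected_for_anova(self):
        with pytest.raises(ValueError, match="replicates"):
            compare_proportions([9.1], [2.5], method="anova-f")

    def test_chi_square_helper_validates_counts(self):
        with pytest.raises(ValueError):
            chi_square_2x2(11, 10, 5, 10)


def test_percentages_invariant_to_uniform_count_scaling():
    base = [record(count=5), record(trim=1, tail="U", count=3), record(tail="GG", count=2)]
    scaled = [
        ModificationRecord(
            ref_ids=r.ref_ids, read_sequence=r.read_sequence, count=r.count * 97,
            weight=r.weight, gmc_len=r.gmc_len, trim_len=r.trim_len, tail_seq=r.tail_seq,
        )
        for r in base
    ]
    t1, t2 = table_of(*base), table_of(*scaled)
    assert size_distribution(t1).percent_by_length == size_distribution(t2).percent_by_length
    assert coordinate_matrix(t1).mass == coordinate_matrix(t2).mass
    assert math.isclose(long_species_fraction(t1), long_species_fraction(t2))
    c1, c2 = tail_composition(t1), tail_composition(t2)
    for nt in "ACGU":
        assert math.isclose(c1.fraction_by_nucleotide[nt], c2.fraction_by_nucleotide[nt])
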