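"""Family assignment, subfamily naming, summary tables and probes."""

from __future__ import annotations

import pytest

from tandemsat.classify import (FamilyAssignment, assign_family,
                                design_probe, name_subfamilies,
                                summary_table, total_large_arrays)
from tandemsat.cluster import (LibraryEntry, LibraryMatch,
                               SubfamilyPartition)
from tandemsat.config import DEFAULT_CONFIG
from tandemsat.mapping import LocusClass
from tandemsat.simulate import make_monomer

from conftest import build_array

_SAT = lambda fam: LibraryMatch(
    LibraryEntry(f"{fam}_cons", "ACGT" * 30, "satellite", fam), 0.95)
_TE = LibraryMatch(LibraryEntry("MTA_cons", "ACGT" * 30, "TE", "MTA"), 0.92)


class TestAssignFamily:
    def _array(self):
        return build_array("ACGT" * 800, 4)

    def test_misat_library_match_wins(self):
        a = assign_family(self._array(), _SAT("MiSat"),
                          LocusClass("unplaced"), 5)
        assert (a.superfamily, a.family) == ("A_centromeric", "MiSat")

    def test_masat_library_match(self):
        a = assign_family(self._array(), _SAT("MaSat"),
                          LocusClass("multi_locus"), 0)
        assert (a.superfamily, a.family) == ("B_pericentromeric", "MaSat")

    def test_te_library_match_names_element(self):
        a = assign_family(self._array(), _TE, LocusClass("multi_locus"), 3)
        assert (a.superfamily, a.family) == ("D_TE_related", "MTA_related")

    def test_pericentromeric_subfamily_becomes_trpc(self):
        a = assign_family(self._array(), None, LocusClass("multi_locus"), 2)
        assert (a.superfamily, a.family) == ("C_heterogeneous", "TRPC")

    @pytest.mark.parametrize("locus_class,family", [
        ("unplaced", "unplaced"), ("single_locus", "single_locus"),
        ("multi_locus", "multi_locus")])
    def test_locus_class_fallback(self, locus_class, family):
        a = assign_family(self._array(), None, LocusClass(locus_class), 1)
        assert (a.superfamily, a.family) == ("C_heterogeneous", family)

    def test_assignment_always_total(self):
        # every combination of evidence yields exactly one family
        for match in (None, _SAT("MiSat"), _SAT("MaSat"), _TE):
            for lc in ("unplaced", "single_locus", "multi_locus"):
                for peri in (0, 2):
                    a = assign_family(self._array(), match,
                                      LocusClass(lc), peri)
                    assert a.superfamily and a.family and a.evidence


def _partition_of(units_and_lengths):
    """Build arrays + partition with one subfamily per spec tuple."""
    arrays, assignment = [], {}
    for i, (unit, total_len, fam) in enumerate(units_and_lengths):
        a = build_array("A" * total_len, unit, source=f"s{i:02d}")
        arrays.append(a)
        assignment[a.array_id] = a.array_id
    part = SubfamilyPartition(assignment=assignment)
    fams = {
        a.array_id: FamilyAssignment(a.array_id, "C_heterogeneous", f,
                                     ("test",), subfamily=a.array_id)
        for a, (_, _, f) in zip(arrays, units_and_lengths)
    }
    return arrays, part, fams


class TestNameSubfamilies:
    def test_single_subfamily_name(self):
        arrays, part, fams = _partition_of([(22, 4400, "multi_locus")])
        names = name_subfamilies(part, arrays, fams)
        assert list(names.values()) == ["TR-22A-MM"]

    def test_letters_by_decreasing_total_length(self):
        arrays, part, fams = _partition_of([
            (54, 3000, "single_locus"), (54, 9000, "single_locus")])
        names = name_subfamilies(part, arrays, fams)
        assert names[arrays[1].array_id] == "TR-54A-MM"
        assert names[arrays[0].array_id] == "TR-54B-MM"

    def test_trpc_family_gets_pc_infix(self):
        arrays, part, fams = _partition_of([(21, 4200, "TRPC")])
        names = name_subfamilies(part, arrays, fams)
        assert list(names.values()) == ["TRPC-21A-MM"]

    def test_adding_new_unit_size_keeps_existing_names(self):
        arrays, part, fams = _partition_of([
            (54, 3000, "single_locus"), (54, 9000, "single_locus")])
        before = name_subfamilies(part, arrays, fams)
        arrays2, part2, fams2 = _partition_of([
            (54, 3000, "single_locus"), (54, 9000, "single_locus"),
            (100, 5000, "multi_locus")])
        after = name_subfamilies(part2, arrays2, fams2)
        for aid, name in before.items():
            assert after[aid] == name


def _fake_assignments(counts: dict[str, int]) -> list[FamilyAssignment]:
    sup = {"MiSat": "A_centromeric", "MaSat": "B_pericentromeric",
           "TRPC": "C_heterogeneous", "multi_locus": "C_heterogeneous",
           "single_locus": "C_heterogeneous", "unplaced": "C_heterogeneous",
           "MTA_related": "D_TE_related", "L1_related": "D_TE_related"}
    out = []
    i = 0
    for fam, n in counts.items():
        for _ in range(n):
            out.append(FamilyAssignment(f"a{i}", sup[fam], fam, ("x",),
                                        subfamily=f"sub{fam}"))
            i += 1
    return out


class TestSummaryTable:
    def test_empty_input_empty_table(self):
        assert summary_table([]).empty

    def test_percent_half_up_one_decimal(self):
        rows = summary_table(_fake_assignments({"MaSat": 3, "MiSat": 5}))
        by_fam = rows.set_index("family")
        assert by_fam.loc["MaSat", "percent_of_total"] == 37.5
        assert by_fam.loc["MiSat", "percent_of_total"] == 62.5

    def test_percents_sum_to_about_100(self):
        rows = summary_table(_fake_assignments(
            {"MaSat": 715, "MiSat": 21, "TRPC": 50, "multi_locus": 57,
             "single_locus": 56, "unplaced": 11, "MTA_related": 15,
             "L1_related": 16}))
        assert abs(rows["percent_of_total"].sum() - 100.0) <= 0.1

    def test_assembly_totals(self):
        assert total_large_arrays({"MGSC": 157, "Celera": 784}) == 941
        with pytest.raises(ValueError):
            total_large_arrays({"x": -1})


class TestDesignProbe:
    def test_long_fragment_prefers_divergent_hotspot(self):
        mono = make_monomer(50, 0.5, 60)
        copies = [mono] * 40
        # corrupt copies 20-23 heavily: the most variable region
        bad = make_monomer(50, 0.5, 61)
        for i in range(20, 24):
            copies[i] = bad
        seq = "".join(copies)
        array = build_array(seq, 50)
        probe = design_probe(array, "long_fragment")
        core = probe.seq[20:-20]
        hot_lo, hot_hi = 20 * 50, 24 * 50
        start = seq.find(core)
        assert start != -1
        assert start < hot_hi and start + 150 > hot_lo   # overlaps hotspot
        assert probe.adapters == DEFAULT_CONFIG.probe_adapters
        for adapter in probe.adapters:
            assert adapter not in seq

    def test_perfect_array_takes_leftmost_window(self):
        mono = make_monomer(50, 0.5, 62)
        probe = design_probe(build_array(mono * 10, 50), "long_fragment")
        assert probe.seq[20:-20] == (mono * 3)[:150]

    def test_short_unit_oligo_is_a_dimer(self):
        mono = make_monomer(21, 0.5, 63)
        probe = design_probe(build_array(mono * 200, 21), "oligo")
        assert probe.seq == mono * 2
        assert len(probe.seq) == 42

    def test_long_unit_oligo_is_a_monomer(self):
        mono = make_monomer(120, 0.4, 64)
        probe = design_probe(build_array(mono * 30, 120), "oligo")
        assert probe.seq == mono

    def test_array_shorter_than_window_rejected(self):
        with pytest.raises(ValueError):
            design_probe(build_array("ACGT" * 10, 4), "long_fragment")
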