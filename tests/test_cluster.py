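"""Pairwise scoring, subfamily clustering and library annotation."""

from __future__ import annotations

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tandemsat.align import local_align_score, reverse_complement
from tandemsat.cluster import (AnnotationTieError, LibraryEntry, PairScore,
                               annotate_catalog, annotate_known,
                               borderline_pairs, cluster_subfamilies,
                               pairwise_scores, read_library)
from tandemsat.simulate import make_monomer, make_variants, mutate, _rng

from conftest import build_array

dna = st.text(alphabet="ACGT", min_size=5, max_size=80)


class TestLocalAlignScore:
    def test_identical_sequences_score_two_per_base(self):
        seq = "ACGTGGCTAA" * 5
        assert local_align_score(seq, seq).raw_score == 2 * len(seq)

    def test_reverse_complement_scores_like_forward(self):
        a = make_monomer(60, 0.5, 1)
        b = make_monomer(60, 0.5, 2)
        fwd = local_align_score(a, b).raw_score
        assert local_align_score(a, reverse_complement(b)).raw_score == fwd

    @given(dna, dna)
    @settings(max_examples=60)
    def test_matches_brute_force_dp(self, a, b):
        from _oracles import sw_local_score
        expected = max(sw_local_score(a, b),
                       sw_local_score(a, reverse_complement(b)))
        assert local_align_score(a, b).raw_score == expected

    @given(dna, dna)
    @settings(max_examples=30)
    def test_symmetric(self, a, b):
        assert local_align_score(a, b).raw_score == \
            local_align_score(b, a).raw_score

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            local_align_score("", "ACGT")


def _family_catalog(seed: int, n_families: int = 3, per_family: int = 4):
    """Small catalog of diverged copies of a few unrelated monomers."""
    arrays = []
    rng = _rng(seed)
    for f in range(n_families):
        mono = make_monomer(40, 0.5, seed * 100 + f)
        for i in range(per_family):
            seq = mutate(mono * 6, 0.05, rng)
            arrays.append(build_array(seq, 40,
                                      source=f"f{f}a{i}"))
    return arrays


class TestClusterSubfamilies:
    def test_all_singletons_below_threshold(self):
        arrays = [build_array(make_monomer(50, 0.5, s) * 2, 50,
                              source=f"s{s}") for s in range(4)]
        part = cluster_subfamilies(arrays, threshold=90)
        assert part.n_subfamilies() == len(arrays)

    def test_single_linkage_chains(self):
        # a-b and b-c above threshold, a-c below: one subfamily
        ids = ["a", "b", "c"]
        arrays = [build_array("ACGT" * 30, 4, source=i) for i in ids]
        scores = [
            PairScore("a:1-120", "b:1-120", 120.0),
            PairScore("b:1-120", "c:1-120", 120.0),
            PairScore("a:1-120", "c:1-120", 10.0),
        ]
        part = cluster_subfamilies(arrays, 90, scores=scores)
        assert part.n_subfamilies() == 1
        assert set(part.assignment.values()) == {"a:1-120"}

    def test_planted_families_recovered(self):
        arrays = _family_catalog(7)
        part = cluster_subfamilies(arrays, threshold=90)
        groups = part.members()
        assert len(groups) == 3
        for members in groups.values():
            prefixes = {m[:2] for m in members}
            assert len(prefixes) == 1    # no cross-family merges

    def test_order_invariance(self):
        arrays = _family_catalog(3)
        part1 = cluster_subfamilies(arrays, threshold=90)
        shuffled = arrays[::-1]
        random.Random(5).shuffle(shuffled)
        part2 = cluster_subfamilies(shuffled, threshold=90)
        assert part1.assignment == part2.assignment

    def test_raising_threshold_refines(self):
        arrays = _family_catalog(11)
        scores = pairwise_scores(arrays)
        low = cluster_subfamilies(arrays, 90, scores=scores)
        high = cluster_subfamilies(arrays, 300, scores=scores)
        # every high-threshold subfamily sits inside one low-threshold one
        for sub_members in high.members().values():
            parents = {low.assignment[m] for m in sub_members}
            assert len(parents) == 1

    def test_borderline_pairs_flagged_not_merged(self):
        scores = [PairScore("x", "y", 95.0), PairScore("x", "z", 200.0),
                  PairScore("y", "z", 50.0)]
        flagged = borderline_pairs(scores, threshold=90, frac=0.10)
        assert [(s.id_a, s.id_b) for s in flagged] == [("x", "y")]


class TestAnnotateKnown:
    def test_tandem_of_library_entry_fully_covered(self):
        mono = make_monomer(150, 0.4, 21)
        lib = [LibraryEntry("GSAT_like", mono, "satellite", "MaSat")]
        match = annotate_known(build_array(mono * 20, 150), lib)
        assert match is not None
        assert match.entry.known_family == "MaSat"
        assert match.coverage == pytest.approx(1.0, abs=0.01)

    def test_half_match_is_below_coverage_floor(self):
        mono = make_monomer(150, 0.4, 22)
        other = make_monomer(150, 0.4, 23)
        lib = [LibraryEntry("ENT", mono, "satellite", "MaSat")]
        half = build_array(mono * 10 + other * 10, 150)
        assert annotate_known(half, lib) is None

    def test_diverged_array_still_assigned(self):
        mono = make_monomer(120, 0.35, 24)
        seq = mutate(mono * 28, 0.15, _rng(1))
        lib = [LibraryEntry("SATMIN_like", mono, "satellite", "MiSat"),
               LibraryEntry("OTHER", make_monomer(120, 0.35, 99),
                            "satellite", "MaSat")]
        match = annotate_known(build_array(seq, 120), lib)
        assert match is not None and match.entry.known_family == "MiSat"

    def test_equal_coverage_tie_is_an_error(self):
        mono = make_monomer(100, 0.5, 30)
        lib = [LibraryEntry("E1", mono, "satellite", "MaSat"),
               LibraryEntry("E2", mono, "satellite", "MiSat")]
        with pytest.raises(AnnotationTieError):
            annotate_known(build_array(mono * 31, 100), lib)

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            annotate_known(build_array("ACGT" * 800, 4), [])


def test_read_library_parses_class_tags(tmp_path):
    fa = tmp_path / "lib.fa"
    fa.write_text(">SATMIN class_tag=satellite known_family=MiSat\n"
                  "ACGTACGTAAAA\n"
                  ">MTA class_tag=TE known_family=MTA\nGGGGCCCCAAAA\n"
                  ">ANON\nACACACACACAC\n")
    entries = read_library(fa)
    assert [e.name for e in entries] == ["SATMIN", "MTA", "ANON"]
    assert entries[0].class_tag == "satellite"
    assert entries[1].known_family == "MTA"
    assert entries[2].class_tag == "other"


def test_blast_and_exact_scoring_agree_on_threshold_decisions():
    arrays = _family_catalog(17, n_families=2, per_family=3)
    exact = {frozenset((s.id_a, s.id_b)): s.raw_score
             for s in pairwise_scores(arrays, method="exact")}
    blast = {frozenset((s.id_a, s.id_b)): s.raw_score
             for s in pairwise_scores(arrays, method="blast")}
    for key, s_exact in exact.items():
        assert (blast[key] > 90) == (s_exact > 90)
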