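"""Cleavage geometry, junction enumeration and seam-context extraction."""

import itertools
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from csmkit import (
    ChemistryError,
    CutSite,
    Junction,
    JunctionLibrary,
    ParameterError,
    TargetSite,
    enumerate_macro_junctions,
    enumerate_micro_junctions,
    innermost_cut,
    junction_reference,
    predict_cut_sites,
    predict_trans_junction,
    reverse_complement,
)
from csmkit.design import DonorDesign
from csmkit.simulate import random_sequence


def make_site(start=100, *, length=32, n_cuts=5, spacing=6, cut_offset=4,
              transcript="t"):
    return TargetSite(transcript, start, start + length, "N" * length,
                      n_cuts=n_cuts, spacing=spacing, cut_offset=cut_offset)


class TestPredictCutSites:
    @pytest.mark.parametrize(
        "kwargs, expected",
        [
            (dict(start=100, n_cuts=5, spacing=6, cut_offset=4),
             [104, 110, 116, 122, 128]),
            (dict(start=50, n_cuts=1, cut_offset=0), [50]),
            (dict(start=0, n_cuts=3, spacing=7, cut_offset=2), [2, 9, 16]),
        ],
    )
    def test_positions(self, kwargs, expected):
        cuts = predict_cut_sites(make_site(**kwargs))
        assert [c.position for c in cuts] == expected
        assert [c.rank for c in cuts] == list(range(len(expected)))

    def test_default_increment_is_six(self):
        positions = [c.position for c in predict_cut_sites(make_site())]
        assert all(b - a == 6 for a, b in zip(positions, positions[1:]))

    def test_end_chemistries_are_csm_constants(self):
        cut = predict_cut_sites(make_site())[0]
        assert cut.upstream_end == "2',3'-cyclic phosphate"
        assert cut.downstream_end == "5'-hydroxyl"

    @pytest.mark.parametrize(
        "kwargs, message",
        [
            (dict(n_cuts=0), "n_cuts"),
            (dict(spacing=0), "spacing"),
            (dict(cut_offset=-1), "cut_offset"),
            (dict(cut_offset=10, n_cuts=5, spacing=6), "cut span"),
        ],
    )
    def test_invariant_violations_name_the_constraint(self, kwargs, message):
        with pytest.raises(ParameterError, match=message):
            make_site(**kwargs)

    def test_spacer_length_mismatch_rejected(self):
        with pytest.raises(ParameterError, match="spacer length"):
            TargetSite("t", 0, 32, "ACGT")

    @given(delta=st.integers(min_value=0, max_value=5000))
    @settings(max_examples=50, deadline=None)
    def test_shift_equivariance(self, delta):
        base = [c.position for c in predict_cut_sites(make_site(100))]
        shifted = [c.position for c in predict_cut_sites(make_site(100 + delta))]
        assert shifted == [p + delta for p in base]

    def test_innermost_cut_minimizes_midpoint_distance(self):
        site = make_site(100)
        # midpoint 116 coincides with the rank-2 cut
        assert innermost_cut(site).rank == 2
        # even n_cuts: two cuts tie around the midpoint; 5'-ward one wins
        site4 = make_site(100, length=32, n_cuts=4, cut_offset=7)
        cuts = predict_cut_sites(site4)
        inner = innermost_cut(site4)
        tied = min(c.innermost_distance for c in cuts)
        assert inner.innermost_distance == tied
        assert inner.position == min(
            c.position for c in cuts if c.innermost_distance == tied
        )


def brute_force_micro(site):
    """Independent oracle: all unordered pairs of cut positions."""
    positions = [
        site.start + site.cut_offset + i * site.spacing
        for i in range(site.n_cuts)
    ]
    return sorted(
        (a, b, b - a) for a, b in itertools.combinations(positions, 2)
    )


class TestMicroEnumeration:
    def test_default_deletion_spectrum(self):
        lib = enumerate_micro_junctions(make_site())
        spectrum = Counter(j.deletion_length for j in lib)
        assert spectrum == {6: 4, 12: 3, 18: 2, 24: 1}
        assert max(spectrum) == 24
        assert len(lib) == 10

    def test_two_cuts_single_junction(self):
        lib = enumerate_micro_junctions(make_site(n_cuts=2))
        assert len(lib) == 1
        assert lib.junctions[0].deletion_length == 6

    def test_single_cut_returns_empty_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            lib = enumerate_micro_junctions(make_site(n_cuts=1, cut_offset=0))
        assert len(lib) == 0
        assert "n_cuts" in caplog.text

    def test_sorted_by_deletion_then_position(self):
        lib = enumerate_micro_junctions(make_site())
        keys = [(j.deletion_length, j.left_pos) for j in lib]
        assert keys == sorted(keys)

    def test_frame_preserved_when_spacing_multiple_of_three(self):
        for spacing in (3, 6, 9):
            lib = enumerate_micro_junctions(
                make_site(length=40, spacing=spacing, n_cuts=4, cut_offset=2)
            )
            assert all(j.frame_delta == 0 for j in lib)
            assert all(j.deletion_length % spacing == 0 for j in lib)

    def test_matches_brute_force_over_parameter_grid(self):
        rng = np.random.default_rng(42)
        for n_cuts in range(2, 9):
            for _ in range(15):
                start = int(rng.integers(0, 5000))
                spacing = int(rng.integers(1, 12))
                cut_offset = int(rng.integers(0, 8))
                length = cut_offset + (n_cuts - 1) * spacing + int(rng.integers(1, 10))
                site = make_site(start, length=length, n_cuts=n_cuts,
                                 spacing=spacing, cut_offset=cut_offset)
                got = sorted(
                    (j.left_pos, j.right_pos, j.deletion_length)
                    for j in enumerate_micro_junctions(site)
                )
                assert got == brute_force_micro(site)


class TestMacroEnumeration:
    def test_default_pair_of_sites(self):
        a, b = make_site(100), make_site(400)
        lib = enumerate_macro_junctions(a, b)
        assert len(lib) == 25
        deletions = sorted({j.deletion_length for j in lib})
        assert deletions == list(range(276, 325, 6))

    def test_sites_300_apart_give_central_deletion_near_300(self):
        a, b = make_site(100), make_site(400)
        lib = enumerate_macro_junctions(a, b)
        central = min(lib, key=lambda j: abs(j.deletion_length - 300))
        assert central.deletion_length == 300

    def test_two_single_cut_sites_one_junction(self):
        a = make_site(100, n_cuts=1, cut_offset=0)
        b = make_site(200, n_cuts=1, cut_offset=0)
        lib = enumerate_macro_junctions(a, b)
        assert len(lib) == 1
        assert lib.junctions[0].deletion_length == 100

    def test_overlapping_sites_rejected(self):
        with pytest.raises(ParameterError, match="5' of"):
            enumerate_macro_junctions(make_site(100), make_site(110))

    def test_different_transcripts_direct_to_trans(self):
        a = make_site(100, transcript="x")
        b = make_site(400, transcript="y")
        with pytest.raises(ParameterError, match="predict_trans_junction"):
            enumerate_macro_junctions(a, b)

    def test_matches_brute_force_pairs(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            na, nb = int(rng.integers(1, 6)), int(rng.integers(1, 6))
            a = make_site(int(rng.integers(0, 200)), n_cuts=na, cut_offset=0)
            b = make_site(int(rng.integers(300, 600)), n_cuts=nb, cut_offset=0)
            lib = enumerate_macro_junctions(a, b)
            pa = [a.start + a.cut_offset + i * a.spacing for i in range(na)]
            pb = [b.start + b.cut_offset + i * b.spacing for i in range(nb)]
            expected = sorted((x, y, y - x) for x in pa for y in pb)
            got = sorted(
                (j.left_pos, j.right_pos, j.deletion_length) for j in lib
            )
            assert got == expected


class TestJunctionReference:
    def test_trivial_flank_concatenation(self):
        ref = "AAACGTTCCCCCGGAAA"
        #      AAACGTT|.....|GGAAA : left_pos=7, right_pos=12
        j = Junction("j", "cis_micro", "r", 7, "r", 12, deletion_length=5)
        lib = JunctionLibrary([j], flank_k=3, references={"r": ref})
        assert junction_reference(j, lib) == "GTT" + "GGA"

    def test_matches_string_surgery_oracle(self):
        rng = np.random.default_rng(9)
        ref = random_sequence(600, rng)
        k = 12
        for _ in range(200):
            left = int(rng.integers(k, 500))
            right = left + int(rng.integers(1, 60))
            j = Junction("j", "cis_micro", "r", left, "r", right,
                         deletion_length=right - left)
            lib = JunctionLibrary([j], flank_k=k, references={"r": ref})
            excised = ref[:left] + ref[right:]
            assert junction_reference(j, lib) == excised[left - k : left + k]

    def test_insufficient_flank_names_junction(self):
        ref = "ACGTACGTACGT"
        j = Junction("jshort", "cis_micro", "r", 2, "r", 8, deletion_length=6)
        with pytest.raises(ParameterError, match="jshort"):
            JunctionLibrary([j], flank_k=5, references={"r": ref})

    def test_duplicate_contexts_flagged_ambiguous(self):
        # a 6-periodic reference makes all deletion-6 contexts identical
        ref = "ACGTAG" * 40
        site = TargetSite.from_reference("r", ref, 100, 132)
        lib = enumerate_micro_junctions(site, {"r": ref}, flank_k=8)
        lib = lib.annotate_ambiguous()
        by_len = {}
        for j in lib:
            by_len.setdefault(j.deletion_length, []).append(j)
        assert all(j.ambiguous for j in by_len[6])
        assert len(by_len[6]) == 4  # all retained
        assert all(j.ambiguous for j in by_len[12])

    def test_duplicate_ids_rejected(self):
        j = Junction("dup", "cis_micro", "r", 10, "r", 16, deletion_length=6)
        with pytest.raises(ParameterError, match="dup"):
            JunctionLibrary([j, j], flank_k=1, references={})


class TestTransJunction:
    def make_cut(self, position, transcript="acceptor"):
        return CutSite(transcript, position, rank=2, innermost_distance=0.0)

    def test_chimera_is_prefix_plus_donor(self):
        donor = DonorDesign("rzb_hammerhead", 0, body="GGATCCATG", name="d")
        j = predict_trans_junction(self.make_cut(300), donor)
        assert j.kind == "trans"
        assert (j.left_pos, j.right_pos) == (300, 0)
        acceptor = random_sequence(400, np.random.default_rng(0))
        chimera = acceptor[: j.left_pos] + donor.transcript[j.right_pos :]
        assert chimera == acceptor[:300] + "GGATCCATG"

    def test_leftover_shifts_donor_contribution(self):
        donor = DonorDesign("cas6_hairpin", 8, body="ATGGTT",
                            leftover_seq="G" * 8)
        j = predict_trans_junction(self.make_cut(120), donor)
        assert donor.transcript[j.right_pos :] == "G" * 8 + "ATGGTT"

    def test_frame_delta_zero_at_stop_codon_cut(self):
        # ORF starts at 90; stop codon begins at 300; (300-90) % 3 == 0
        donor = DonorDesign("rzb_hammerhead", 0, body="ATG")
        j = predict_trans_junction(self.make_cut(300), donor, orf_start=90)
        assert j.frame_delta == 0

    def test_non_hydroxyl_donor_rejected(self):
        capped = DonorDesign("capped", 0, body="ATG")
        with pytest.raises(ChemistryError, match="5'-hydroxyl"):
            predict_trans_junction(self.make_cut(10), capped)


def test_reverse_complement_involution():
    rng = np.random.default_rng(3)
    seq = random_sequence(100, rng)
    assert reverse_complement(reverse_complement(seq)) == seq
    assert reverse_complement("ACGT") == "ACGT"
    assert reverse_complement("AAGC") == "GCTT"
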