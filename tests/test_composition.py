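from __future__ import annotations

import pytest

from clonoscope.composition import (
    AA_ALPHABET,
    UndefinedCompositionError,
    hydrophobic_summary,
    imgt_positions,
    middle_aa_frequencies,
)
from clonoscope.io import Repertoire
from clonoscope.simulate import SimParams, simulate_repertoire

from conftest import make_record

_NT = {"A": "GCT", "C": "TGT", "F": "TTT", "Y": "TAT", "S": "AGC", "L": "CTG", "G": "GGT", "W": "TGG"}


def rep_from_cdr3s(seqs, sample_id="s"):
    records = [
        make_record(cdr3_nt="".join(_NT[ch] for ch in seq), cdr3_aa=seq, count=1)
        for seq in seqs
    ]
    return Repertoire(sample_id=sample_id, records=records)


class TestImgtPositions:
    def test_anchors_are_104_and_118(self):
        pa = imgt_positions("CAAAF")
        assert pa.assignments[0] == ("C", "104")
        assert pa.assignments[-1] == ("F", "118")

    def test_full_length_loop_is_contiguous_105_117(self):
        # 15-mer: inner length 13 fills every integer slot
        pa = imgt_positions("C" + "A" * 13 + "F")
        labels = [lab for _, lab in pa.assignments]
        assert labels == [str(p) for p in range(104, 119)]

    def test_inner_index_4_sits_at_108_in_full_length_loop(self):
        seq = "C" + "AAA" + "Y" + "A" * 9 + "F"  # 4th inner residue is Y
        assert imgt_positions(seq).integer_positions()[108] == "Y"

    def test_short_loop_example_cassl_gf(self):
        pa = imgt_positions("CASSLGF")
        assert pa.assignments == (
            ("C", "104"), ("A", "105"), ("S", "106"), ("S", "107"),
            ("L", "116"), ("G", "117"), ("F", "118"),
        )

    def test_long_loop_gets_insertion_codes(self):
        # 17-mer: inner 15 -> left arm 105-111 + 111.1, right arm 117-112 + 112.1
        pa = imgt_positions("C" + "A" * 15 + "F")
        labels = [lab for _, lab in pa.assignments]
        assert "111.1" in labels and "112.1" in labels
        assert labels.index("111.1") == 8  # right after 105..111
        assert labels[labels.index("111.1") + 1] == "112.1"

    @pytest.mark.parametrize("l", range(1, 31))
    def test_integer_position_count_and_uniqueness(self, l):
        pa = imgt_positions("C" + "A" * l + "F")
        inner = pa.assignments[1:-1]
        assert len(inner) == l  # every residue assigned
        integer_labels = [lab for _, lab in inner if "." not in lab]
        assert len(integer_labels) == min(l, 13)
        assert len(set(integer_labels)) == len(integer_labels)
        assert all(105 <= int(lab) <= 117 for lab in integer_labels)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            imgt_positions("CF")

    def test_non_standard_character_rejected(self):
        with pytest.raises(ValueError):
            imgt_positions("CAX*F")

    def test_anchor_free_mode_numbers_whole_string(self):
        pa = imgt_positions("AAAAA", anchors=False)
        labels = [lab for _, lab in pa.assignments]
        assert labels == ["105", "106", "107", "116", "117"]


class TestMiddleFrequencies:
    def test_single_full_length_clonotype_all_middle_A(self):
        comp = middle_aa_frequencies(rep_from_cdr3s(["C" + "A" * 13 + "F"]))
        assert comp.freq["A"] == 1.0
        assert comp.n_observations == 5
        assert comp.n_clonotypes_used == 1

    def test_two_clonotypes_pool_equally(self):
        # middle residues all-A in one clonotype, all-Y in the other
        a = "C" + "AAA" + "AAAAA" + "AAAAA" + "F"
        y = "C" + "AAA" + "YYYYY" + "AAAAA" + "F"
        comp = middle_aa_frequencies(rep_from_cdr3s([a, y]))
        assert comp.freq["A"] == pytest.approx(0.5)
        assert comp.freq["Y"] == pytest.approx(0.5)
        assert comp.n_observations == 10

    def test_unique_clonotype_weighting_ignores_counts(self):
        rep = rep_from_cdr3s(["C" + "A" * 13 + "F", "C" + "Y" * 13 + "F"])
        rep.records[0] = make_record(cdr3_nt=rep.records[0].cdr3_nt, cdr3_aa=rep.records[0].cdr3_aa, count=1000)
        comp = middle_aa_frequencies(rep)
        assert comp.freq["A"] == pytest.approx(comp.freq["Y"]) == pytest.approx(0.5)

    def test_all_short_cdr3s_flagged_undefined(self):
        comp = middle_aa_frequencies(rep_from_cdr3s(["CASSLGF", "CAAAAGF"]))
        assert not comp.defined
        assert comp.n_observations == 0
        with pytest.raises(UndefinedCompositionError):
            hydrophobic_summary(comp)

    def test_frequencies_sum_to_one_on_simulated_repertoire(self):
        rep, _ = simulate_repertoire(SimParams(n_clonotypes=500, depth=5000, seed=3))
        comp = middle_aa_frequencies(rep)
        assert sum(comp.freq.values()) == pytest.approx(1.0, abs=1e-12)
        assert set(comp.freq) == set(AA_ALPHABET)
        assert all(f >= 0 for f in comp.freq.values())

    def test_per_position_average_equals_pooling_when_all_positions_filled(self):
        rep, _ = simulate_repertoire(
            SimParams(n_clonotypes=200, depth=2000,
                      length_dist={15: 0.5, 16: 0.25, 17: 0.25}, seed=4))
        pooled = middle_aa_frequencies(rep)
        averaged = middle_aa_frequencies(rep, per_position_average=True)
        # all CDR3s reach every middle position, so each position has equal n
        for aa in AA_ALPHABET:
            assert pooled.freq[aa] == pytest.approx(averaged.freq[aa], abs=1e-12)


class TestHydrophobicSummary:
    def test_projection_passthrough(self):
        comp = middle_aa_frequencies(rep_from_cdr3s(["C" + "AAA" + "FLWYA" + "AAAAA" + "F"]))
        summary = hydrophobic_summary(comp)
        assert set(summary) == {"F", "L", "W", "Y"}
        assert summary["F"] == comp.freq["F"] == pytest.approx(0.2)

    def test_absent_residue_reports_zero(self):
        comp = middle_aa_frequencies(rep_from_cdr3s(["C" + "A" * 13 + "F"]))
        assert hydrophobic_summary(comp, frozenset("W"))["W"] == 0.0

    def test_summary_bounded_by_total(self):
        rep, _ = simulate_repertoire(SimParams(n_clonotypes=300, depth=3000, seed=5))
        comp = middle_aa_frequencies(rep)
        assert sum(hydrophobic_summary(comp).values()) <= sum(comp.freq.values()) + 1e-12
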