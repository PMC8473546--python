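"""Descriptor correctness: worked example, block invariants, oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from afpkit import features as F
from conftest import WORKED_EXAMPLE

POLARIZABILITY = next(g for g in F.DEFAULT_GROUPINGS
                      if g.property_name == "polarizability")

valid_sequences = st.text(alphabet=F.AMINO_ACIDS, min_size=3, max_size=80)


def idx(a: str, b: str | None = None) -> int:
    if b is None:
        return F.AMINO_ACIDS.index(a)
    return 20 * F.AMINO_ACIDS.index(a) + F.AMINO_ACIDS.index(b)


class TestWorkedExample:
    """The polarizability CTD walk-through on MAGGDLVYAGSIAEHRKL."""

    def test_encoding(self):
        assert F.encode_property_string(WORKED_EXAMPLE, POLARIZABILITY) == \
            "311112231112123332"

    def test_composition(self):
        comp = F.ctd_composition("311112231112123332")
        assert comp.tolist() == pytest.approx([8 / 18, 5 / 18, 5 / 18], abs=0)

    def test_transition(self):
        trans = F.ctd_transition("311112231112123332")
        assert trans.tolist() == pytest.approx([4 / 17, 2 / 17, 3 / 17], abs=0)

    def test_group1_distribution(self):
        dist = F.ctd_distribution("311112231112123332")
        assert dist[:5].tolist() == pytest.approx(
            [2 / 18, 3 / 18, 5 / 18, 10 / 18, 13 / 18], abs=0)

    def test_group2_group3_distribution_by_enumeration(self):
        # group 2 occurs at positions 6,7,12,14,18: anchors k=1,1,3,4,5
        # group 3 occurs at positions 1,8,15,16,17: anchors k=1,1,3,4,5
        dist = F.ctd_distribution("311112231112123332")
        assert dist[5:10].tolist() == pytest.approx(
            [p / 18 for p in (6, 6, 12, 14, 18)], abs=0)
        assert dist[10:15].tolist() == pytest.approx(
            [p / 18 for p in (1, 1, 15, 16, 17)], abs=0)

    def test_aac_counts(self):
        aac = F.compute_aac(WORKED_EXAMPLE)
        assert aac[idx("G")] == pytest.approx(3 / 18, abs=0)
        assert aac[idx("A")] == pytest.approx(3 / 18, abs=0)

    def test_dc_counts(self):
        dc = F.compute_dc(WORKED_EXAMPLE)
        assert dc[idx("G", "G")] == pytest.approx(1 / 17, abs=0)
        assert dc[idx("A", "G")] == pytest.approx(2 / 17, abs=0)

    def test_gapped_counts(self):
        gp = F.compute_gapped(WORKED_EXAMPLE)
        assert gp[idx("A", "G")] == pytest.approx(1 / 16, abs=0)

    def test_full_ctd_polarizability_block(self):
        """All 21 polarizability values inside the assembled 988-d vector."""
        fv = F.assemble_feature_vector(WORKED_EXAMPLE)
        s = fv.as_series()
        expected = {
            "Polarizability Composition; Group 1": 8 / 18,
            "Polarizability Composition; Group 2": 5 / 18,
            "Polarizability Composition; Group 3": 5 / 18,
            "Polarizability Transition; Group 1/2": 4 / 17,
            "Polarizability Transition; Group 1/3": 2 / 17,
            "Polarizability Transition; Group 2/3": 3 / 17,
        }
        for g, positions in ((1, (2, 3, 5, 10, 13)),
                             (2, (6, 6, 12, 14, 18)),
                             (3, (1, 1, 15, 16, 17))):
            for label, p in zip(("first", "25%", "50%", "75%", "100%"), positions):
                expected[f"Polarizability Distribution; Group {g} ({label})"] = p / 18
        for name, value in expected.items():
            assert s[name] == value, name


class TestSimpleExamples:
    @pytest.mark.parametrize("seq,component,value", [
        ("AAAAA", ("A",), 1.0),
        ("ACDEFGHIKLMNPQRSTVWY", ("W",), 0.05),
        ("AAT", ("A", "A"), 0.5),
        ("AA", ("A", "A"), 1.0),
    ])
    def test_composition_examples(self, seq, component, value):
        if len(component) == 1:
            assert F.compute_aac(seq)[idx(*component)] == value
        else:
            assert F.compute_dc(seq)[idx(*component)] == value

    def test_gapped_single_window(self):
        assert F.compute_gapped("ACA")[idx("A", "A")] == 1.0

    def test_gapped_homopolymer(self):
        assert F.compute_gapped("AAAA")[idx("A", "A")] == 1.0

    def test_preconditions(self):
        with pytest.raises(ValueError):
            F.compute_aac("")
        with pytest.raises(ValueError):
            F.compute_dc("A")
        with pytest.raises(ValueError):
            F.compute_gapped("AA")
        with pytest.raises(ValueError):
            F.assemble_feature_vector("AA")

    def test_ctd_degenerate_strings(self):
        assert F.ctd_composition("1111").tolist() == [1, 0, 0]
        assert F.ctd_composition("123").tolist() == pytest.approx([1/3] * 3)
        assert F.ctd_transition("1111").tolist() == [0, 0, 0]
        assert F.ctd_transition("12").tolist() == [1, 0, 0]
        # n=4, k = round(f*4) -> occurrences 1,2,3,4
        assert F.ctd_distribution("1111")[:5].tolist() == \
            pytest.approx([1/4, 1/4, 2/4, 3/4, 4/4])
        assert F.ctd_distribution("111")[5:].tolist() == [0.0] * 10

    def test_single_residue_encoding(self):
        assert F.encode_property_string("G", POLARIZABILITY) == "1"

    def test_degenerate_all_in_one_group(self):
        grouping = F.PropertyGrouping("all", "All", (F.AMINO_ACIDS, "", ""))
        assert F.encode_property_string("WYACK", grouping) == "11111"


class TestGroupings:
    def test_defaults_are_partitions_of_20(self):
        assert len(F.DEFAULT_GROUPINGS) == 8
        for g in F.DEFAULT_GROUPINGS:
            assert sorted("".join(g.groups)) == sorted(F.AMINO_ACIDS)

    def test_overlap_rejected(self):
        with pytest.raises(F.GroupingError):
            F.PropertyGrouping("bad", "Bad", ("AC", "CD", "EFGHIKLMNPQRSTVWY"))

    def test_missing_residue_rejected(self):
        with pytest.raises(F.GroupingError):
            F.PropertyGrouping("bad", "Bad", ("AC", "DE", "FGHIKLMNPQRSTVW"))

    def test_config_round_trip(self, tmp_path):
        path = tmp_path / "groupings.json"
        F.save_groupings(F.DEFAULT_GROUPINGS, path)
        loaded = F.load_groupings(path)
        assert loaded == F.DEFAULT_GROUPINGS


class TestVectorLayout:
    def test_dimensions_and_unique_names(self):
        fv = F.assemble_feature_vector("MKVACDEFGHIKLMNPQRSTVWY")
        assert len(fv.values) == 988
        assert len(fv.names) == 988
        assert len(set(fv.names)) == 988
        assert len(fv.block("AAC")) == 20
        assert len(fv.block("DC")) == 400
        assert len(fv.block("AA-x-AA")) == 400
        assert len(fv.block("CTD")) == 168

    def test_table6_naming_conventions(self):
        names = F.feature_names()
        for expected in ("Cys", "Ala-Ala", "Ala-x-Ala", "Trp-Gly",
                         "Polarity Composition; Group 2",
                         "Disorder Propensity Distribution; Group 1 (50%)",
                         "Normalized VDWV Composition; Group 1",
                         "Hydrophobicity Composition; Group 2",
                         "Polarizability Transition; Group 2/3"):
            assert expected in names


class TestInvariants:
    @given(valid_sequences)
    def test_block_sums(self, seq):
        fv = F.assemble_feature_vector(seq)
        assert fv.block("AAC").sum() == pytest.approx(1, abs=1e-9)
        assert fv.block("DC").sum() == pytest.approx(1, abs=1e-9)
        assert fv.block("AA-x-AA").sum() == pytest.approx(1, abs=1e-9)
        assert np.all(fv.values >= 0) and np.all(fv.values <= 1 + 1e-12)
        ctd = fv.block("CTD")
        for p in range(8):
            block = ctd[21 * p:21 * (p + 1)]
            assert block[:3].sum() == pytest.approx(1, abs=1e-9)
            assert block[3:6].sum() <= 1 + 1e-9

    @given(valid_sequences)
    def test_distribution_monotone_and_last_occurrence(self, seq):
        for grouping in F.DEFAULT_GROUPINGS:
            enc = F.encode_property_string(seq, grouping)
            dist = F.ctd_distribution(enc)
            for gi, digit in enumerate("123"):
                five = dist[5 * gi:5 * gi + 5]
                positions = [i + 1 for i, d in enumerate(enc) if d == digit]
                if positions:
                    assert np.all(np.diff(five) >= -1e-12)
                    assert five[-1] == positions[-1] / len(enc)
                else:
                    assert np.all(five == 0)

    @given(valid_sequences, st.randoms(use_true_random=False))
    def test_aac_permutation_invariance(self, seq, rnd):
        shuffled = list(seq)
        rnd.shuffle(shuffled)
        assert np.array_equal(F.compute_aac(seq), F.compute_aac("".join(shuffled)))

    def test_many_random_sequences_satisfy_sums(self, random_sequences):
        for seq in random_sequences:
            assert F.compute_aac(seq).sum() == pytest.approx(1, abs=1e-9)
            assert F.compute_dc(seq).sum() == pytest.approx(1, abs=1e-9)
            assert F.compute_gapped(seq).sum() == pytest.approx(1, abs=1e-9)


def brute_force_pairs(seq: str, gap: int) -> np.ndarray:
    """Independent window enumerator for DC (gap=0) and AA-x-AA (gap=1)."""
    vec = np.zeros(400)
    windows = 0
    for i in range(len(seq) - gap - 1):
        a, b = seq[i], seq[i + gap + 1]
        vec[20 * F.AMINO_ACIDS.index(a) + F.AMINO_ACIDS.index(b)] += 1
        windows += 1
    return vec / windows


class TestBruteForceOracle:
    """DC and AA-x-AA match window enumeration on an exhaustive small space."""

    ALPHABET_3 = "ACD"

    def test_exhaustive_three_letter_space(self):
        for L in range(3, 9):
            for tup in itertools.product(self.ALPHABET_3, repeat=L):
                seq = "".join(tup)
                assert np.array_equal(F.compute_dc(seq), brute_force_pairs(seq, 0))
                assert np.array_equal(F.compute_gapped(seq), brute_force_pairs(seq, 1))

    def test_length_two_dc_only(self):
        for tup in itertools.product(self.ALPHABET_3, repeat=2):
            seq = "".join(tup)
            assert np.array_equal(F.compute_dc(seq), brute_force_pairs(seq, 0))


class TestAnchorRounding:
    def test_round_half_away_from_zero(self):
        # n=8: anchors at occurrences 1, 2, 4, 6, 8
        assert [F._anchor_index(f, 8) for f in (None, 0.25, 0.5, 0.75, 1.0)] == \
            [1, 2, 4, 6, 8]
        # n=2: 0.25*2 = 0.5 rounds away from zero to 1
        assert F._anchor_index(0.25, 2) == 1
        assert F._anchor_index(0.5, 2) == 1
        assert F._anchor_index(0.75, 2) == 2

    def test_extract_features_table(self, random_sequences):
        from afpkit.seqio import SequenceRecord
        recs = [SequenceRecord(id=f"R{i}", sequence=s)
                for i, s in enumerate(random_sequences[:5])]
        table = F.extract_features(recs)
        assert table.shape == (5, 988)
        assert list(table.index) == [r.id for r in recs]
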