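"""seq_core: FASTA I/O, translation, ORF finding, masses."""

import pytest
from Bio.SeqUtils import molecular_weight
from hypothesis import given, settings, strategies as st

from prfkit.sequences import (
    FastaParseError,
    MassTable,
    NucSequence,
    average_mass,
    find_orfs,
    read_sequences,
    reverse_complement,
    translate,
    write_sequences,
)

from conftest import random_dna
from oracles import brute_orfs

dna = st.text(alphabet="ACGT", min_size=0, max_size=120)


class TestFastaIO:
    def test_rna_input_is_normalized(self, tmp_path):
        f = tmp_path / "x.fa"
        f.write_text(">x\nGCUU\n")
        (seq,) = read_sequences(f)
        assert seq.seq == "GCTT" and seq.was_rna

    def test_empty_file_gives_empty_list(self, tmp_path):
        f = tmp_path / "empty.fa"
        f.write_text("")
        assert read_sequences(f) == []

    def test_reporter_insert_lengths(self, inserts):
        lengths = {name: len(s) for name, s in inserts.items()}
        assert lengths == {
            "Podo-1": 59, "Podo0": 60, "IBV-Podo-1_sp6": 62,
            "IBV-Podo-1_sp2": 59, "IBV-Podo0": 65,
        }

    def test_duplicate_ids_rejected(self, tmp_path):
        f = tmp_path / "dup.fa"
        f.write_text(">a\nACGT\n>a\nACGT\n")
        with pytest.raises(FastaParseError, match="duplicate"):
            read_sequences(f)

    def test_malformed_record_names_line(self, tmp_path):
        f = tmp_path / "bad.fa"
        f.write_text("ACGT\n>a\nACGT\n")
        with pytest.raises(FastaParseError, match="line 1"):
            read_sequences(f)

    def test_non_iupac_letter_is_named(self, tmp_path):
        f = tmp_path / "n.fa"
        f.write_text(">a\nACGNT\n")
        with pytest.raises(ValueError, match="'N'"):
            read_sequences(f)

    @given(st.lists(dna.filter(lambda s: len(s) > 0), min_size=1, max_size=5))
    @settings(max_examples=25, deadline=None)
    def test_round_trip_preserves_content(self, tmp_path_factory, seqs):
        path = tmp_path_factory.mktemp("fa") / "rt.fa"
        records = [NucSequence(f"s{i}", s) for i, s in enumerate(seqs)]
        write_sequences(records, path)
        back = read_sequences(path)
        assert [(r.id, r.seq) for r in back] == [(r.id, r.seq) for r in records]


class TestTranslate:
    def test_atg_is_methionine(self):
        assert translate("ATG") == "M"

    def test_podo1_zero_frame_stops_at_codon_seven(self, podo1):
        aa = translate(podo1, 0, "read_through")
        assert aa[7] == "*" and "*" not in aa[:7]

    def test_podo1_minus_one_register_has_no_stop(self, podo1):
        assert "*" not in translate(podo1, 1, "read_through")

    def test_truncate_policy_cuts_before_stop(self):
        assert translate("ATGTAAATG", 0, "truncate_at_stop") == "M"

    @given(dna, st.integers(0, 3))
    @settings(max_examples=50, deadline=None)
    def test_double_reverse_complement_is_involution(self, s, start):
        start = min(start, len(s))
        rc2 = reverse_complement(reverse_complement(s))
        assert translate(rc2, start) == translate(s, start)


class TestFindOrfs:
    def test_simple_atg_orf(self):
        (orf,) = find_orfs("ATGAAATAA", min_aa=2, require_atg=True)
        assert orf.aa_seq == "MK" and orf.has_terminal_stop

    def test_all_a_with_require_atg_is_empty(self):
        assert find_orfs("A" * 30, min_aa=1, require_atg=True) == []

    @pytest.mark.parametrize("require_atg", [False, True])
    def test_agrees_with_brute_force_on_random_sequences(self, rng, require_atg):
        for _ in range(100):
            n = int(rng.integers(3, 500))
            s = random_dna(rng, n)
            min_aa = int(rng.integers(1, 5))
            got = {
                (o.start, o.end, o.frame, len(o.aa_seq), o.has_terminal_stop)
                for o in find_orfs(s, min_aa=min_aa, require_atg=require_atg)
            }
            assert got == brute_orfs(s, min_aa=min_aa, require_atg=require_atg)


class TestMass:
    def test_empty_peptide_is_water(self):
        assert average_mass("") == pytest.approx(18.02, abs=0.01)

    def test_diglycine(self):
        assert average_mass("GG") == pytest.approx(132.12, abs=0.01)

    def test_unknown_letter_is_named(self):
        with pytest.raises(ValueError, match="'B'"):
            average_mass("AB")

    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", max_size=40),
           st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_additivity(self, a, b):
        w = MassTable.average().water_mass
        assert average_mass(a + b) == pytest.approx(
            average_mass(a) + average_mass(b) - w, abs=1e-6)

    def test_matches_biopython_reference(self):
        pep = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
        ours = average_mass(pep)
        ref = molecular_weight(pep, seq_type="protein")
        assert ours == pytest.approx(ref, abs=0.05)
        mono = average_mass(pep, MassTable.monoisotopic())
        ref_mono = molecular_weight(pep, seq_type="protein", monoisotopic=True)
        assert mono == pytest.approx(ref_mono, abs=0.05)
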