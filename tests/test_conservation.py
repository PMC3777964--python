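"""Alignment, column-pair statistics and compensatory classification."""

import pytest

from prfkit.conservation import (
    AlignParams,
    CassetteAlignment,
    align_cassettes,
    classify_extension_frame,
    column_pair_stats,
    find_compensatory,
)
from prfkit.sequences import NucSequence, find_orfs
from prfkit.simulate import CassetteSpec, FamilySpec, make_family

from oracles import best_affine_alignment_score


def _aln(rows, ids=None, **kw):
    return CassetteAlignment(ids=ids or [f"s{i}" for i in range(len(rows))],
                             rows=rows, **kw)


class TestAlign:
    def test_identical_pair_aligns_without_gaps(self):
        aln = align_cassettes([NucSequence("a", "ACGT"), NucSequence("b", "ACGT")])
        assert aln.rows == ["ACGT", "ACGT"]

    def test_single_gap_matches_exhaustive_score(self):
        params = AlignParams()
        aln = align_cassettes([NucSequence("a", "ACGT"), NucSequence("b", "AGT")], params)
        assert sorted(len(r.replace("-", "")) for r in aln.rows) == [3, 4]
        score = 0.0
        in_gap = False
        for x, y in zip(*aln.rows):
            if x == "-" or y == "-":
                score += params.gap_extend if in_gap else params.gap_open
                in_gap = True
            else:
                score += params.match if x == y else params.mismatch
                in_gap = False
        assert score == best_affine_alignment_score("ACGT", "AGT")

    def test_star_alignment_rows_stay_consistent(self):
        seqs = [NucSequence("a", "ACGTACGT"), NucSequence("b", "ACGACGT"),
                NucSequence("c", "ACGTACG")]
        aln = align_cassettes(seqs)
        assert len({len(r) for r in aln.rows}) == 1
        for seq, row in zip(seqs, aln.rows):
            assert row.replace("-", "") == seq.seq

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            align_cassettes([])


class TestColumnPairStats:
    def test_all_six_pair_types(self):
        rows = ["C" + "G", "G" + "C", "A" + "T", "T" + "A", "G" + "T", "T" + "G"]
        st = column_pair_stats(_aln(rows), 0, 1)
        assert st.n_pair_types == 6 and st.n_incompatible == 0

    def test_uniform_cg_column(self):
        st = column_pair_stats(_aln(["CG"] * 4), 0, 1)
        assert st.n_pair_types == 1 and st.n_incompatible == 0

    def test_mixed_column_with_gap(self):
        rows = ["CG", "CG", "GC", "AA", "A-"]
        st = column_pair_stats(_aln(rows), 0, 1)
        assert (st.n_pair_types, st.n_incompatible, st.n_gapped) == (2, 1, 1)
        assert st.n_compatible + st.n_incompatible + st.n_gapped == 5

    def test_row_permutation_invariance(self):
        rows = ["CG", "GC", "AT", "A-", "AA"]
        a = column_pair_stats(_aln(rows), 0, 1)
        b = column_pair_stats(_aln(rows[::-1]), 0, 1)
        assert a == b


class TestCompensatory:
    def _ref_aln(self, rows, ids=None):
        aln = _aln(rows, ids)
        aln.ref_id = aln.ids[0]
        aln.ref_structure = [(0, 1)]
        return aln

    @pytest.mark.parametrize("species_pair,klass", [
        ("GC", "compensatory"),   # ref C-G, both bases changed, pairing kept
        ("TG", "wobble_shift"),   # one base changed, kept via wobble
        ("AG", "disruptive"),     # pairing lost
        ("-G", "disruptive"),     # gap
    ])
    def test_classification_against_cg_reference(self, species_pair, klass):
        aln = self._ref_aln(["CG", species_pair])
        (event,) = find_compensatory(aln)
        assert event.klass == klass

    def test_identity_produces_no_events(self):
        aln = self._ref_aln(["CG", "CG", "CG"])
        assert find_compensatory(aln) == []

    def test_family_with_full_compensation_recall(self):
        nwk = "((A,B),(C,D),(E,(F,(G,H))));"
        seqs, _, states, truth = make_family(
            FamilySpec(newick=nwk, rate=0.08, compensatory_fraction=1.0, seed=21),
            CassetteSpec(seed=22))
        assert truth["compensatory"], "expected planted compensatory events"
        base = truth["base"]
        rows = [s.seq for s in seqs]  # no indels: already aligned
        aln = CassetteAlignment(ids=[s.id for s in seqs], rows=rows,
                                ref_id=None, ref_structure=[])
        # reference = first present leaf carrying the ancestral pairs
        aln.ref_id = seqs[0].id
        aln.ref_structure = sorted(base["stem1_pairs"] + base["stem2_pairs"])
        events = find_compensatory(aln)
        assert not [e for e in events if e.klass == "disruptive"]
        found = {(e.species, e.columns) for e in events if e.klass == "compensatory"}
        for ev in truth["compensatory"]:
            if ev["leaf"] == aln.ref_id:
                continue  # the reference row cannot flag itself
            pair_cols = tuple(ev["pair"])
            ref_row = aln.row(aln.ref_id)
            leaf_row = aln.row(ev["leaf"])
            if (ref_row[pair_cols[0]] + ref_row[pair_cols[1]]) == ev["from"] \
                    and (leaf_row[pair_cols[0]] + leaf_row[pair_cols[1]]) == ev["to"]:
                assert (ev["leaf"], pair_cols) in found


class TestExtensionFrame:
    def test_planted_shift_classification(self):
        for shift, label in [(-1, "-1"), (+1, "+1")]:
            from prfkit.simulate import make_cassette
            from prfkit.frameshift import find_orf_pairs
            seq, truth = make_cassette(CassetteSpec(shift=shift, seed=23))
            pair = next(op for op in find_orf_pairs(seq)
                        if op.shift == shift and op.orf5.start == 0)
            got = classify_extension_frame(seq, pair.orf5, pair.orf3)
            assert got == label

    def test_same_frame_is_in_frame(self):
        s = "ATGAAATAAATGCCCTAA"
        orfs = [o for o in find_orfs(s) if o.frame == 0]
        assert classify_extension_frame(s, orfs[0], orfs[-1]) == "in_frame"
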