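"""ORF pairs, insert-frame classification and fusion construction."""

import pytest

from prfkit.frameshift import (
    analyze_cds,
    build_fusion,
    classify_insert_frame,
    find_orf_pairs,
)
from prfkit.sequences import NucSequence, translate
from prfkit.simulate import CassetteSpec, make_cassette
from prfkit.slippery import evaluate_site

from conftest import random_dna
from oracles import brute_orfs


class TestClassifyInsertFrame:
    @pytest.mark.parametrize("length,shift", [(60, 0), (59, -1), (62, -1),
                                              (65, -1), (1, 1), (0, 0)])
    def test_reporter_insert_lengths(self, length, shift):
        assert classify_insert_frame(length) == shift

    def test_shift_compensates_length_residue(self):
        for L in range(0, 200):
            assert (L - classify_insert_frame(L)) % 3 == 0


class TestFindOrfPairs:
    def test_planted_minus_one_cassette_yields_its_pair(self):
        seq, truth = make_cassette(CassetteSpec(seed=11))
        p = truth["heptamer_offset"]
        pairs = [op for op in find_orf_pairs(seq)
                 if op.shift == -1 and op.orf5.start == 0]
        assert len(pairs) == 1
        lo, hi = pairs[0].overlap_window
        assert lo <= p and p + 7 <= hi

    def test_plus_one_cassette_yields_plus_one_pair(self):
        seq, truth = make_cassette(CassetteSpec(shift=+1, seed=12))
        pairs = [op for op in find_orf_pairs(seq)
                 if op.shift == +1 and op.orf5.start == 0]
        assert pairs and pairs[0].orf3.end > pairs[0].orf5.end

    def test_single_long_orf_has_no_pair(self):
        s = "ATG" + "GCT" * 30 + "TAA"
        assert [op for op in find_orf_pairs(s) if op.orf5.start == 0] == []

    def test_agrees_with_brute_force_all_pairs_scan(self, rng):
        for _ in range(10):
            s = random_dna(rng, 1000)
            got = {(op.orf5.start, op.orf5.end, op.orf3.start, op.orf3.end, op.shift)
                   for op in find_orf_pairs(s, min_aa5=2, min_aa3=2)}
            orfs = brute_orfs(s, min_aa=2, require_atg=False)
            expect = set()
            for o5 in orfs:
                for o3 in orfs:
                    if o3[2] == o5[2] or not o5[4]:
                        continue
                    if o3[1] <= o5[1] or o3[0] >= o5[1]:
                        continue
                    shift = {1: 1, 2: -1}[(o3[2] - o5[2]) % 3]
                    expect.add((o5[0], o5[1], o3[0], o3[1], shift))
            assert got == expect


class TestBuildFusion:
    def test_fusion_matches_generator_truth(self):
        seq, truth = make_cassette(CassetteSpec(seed=13))
        p = truth["heptamer_offset"]
        pair = next(op for op in find_orf_pairs(seq)
                    if op.shift == -1 and op.orf5.start == 0)
        site = evaluate_site(seq, p, -1)
        fusion = build_fusion(seq, pair, site)
        assert fusion.aa_seq == truth["fusion_aa"]
        assert "*" not in fusion.aa_seq

    def test_fusion_prefix_equals_orf5_translation(self):
        seq, truth = make_cassette(CassetteSpec(seed=14))
        pair = next(op for op in find_orf_pairs(seq)
                    if op.shift == -1 and op.orf5.start == 0)
        site = evaluate_site(seq, truth["heptamer_offset"], -1)
        fusion = build_fusion(seq, pair, site)
        n5 = fusion.parts[0]
        assert fusion.aa_seq[:n5] == pair.orf5.aa_seq[:n5]

    def test_corrective_insertion_reproduces_fusion_suffix(self):
        # adding one nucleotide 5' of the heptamer puts the 3' ORF in frame:
        # plain 0-frame translation then ends with the fusion's 3' segment
        seq, truth = make_cassette(CassetteSpec(seed=15))
        p = truth["heptamer_offset"]
        pair = next(op for op in find_orf_pairs(seq)
                    if op.shift == -1 and op.orf5.start == 0)
        site = evaluate_site(seq, p, -1)
        fusion = build_fusion(seq, pair, site)
        for base in "GACT":
            if seq.seq[p - 2 : p] + base not in ("TAA", "TAG", "TGA"):
                corrected = seq.seq[:p] + base + seq.seq[p:]
                break
        aa = translate(corrected, 0, "truncate_at_stop")
        suffix = fusion.aa_seq[fusion.parts[0]:]
        assert aa.endswith(suffix)

    def test_site_outside_overlap_window_is_rejected(self):
        from dataclasses import replace

        seq, truth = make_cassette(CassetteSpec(seed=16))
        pair = next(op for op in find_orf_pairs(seq)
                    if op.shift == -1 and op.orf5.start == 0)
        site = evaluate_site(seq, truth["heptamer_offset"], -1)
        far = replace(site, start=pair.overlap_window[1])
        with pytest.raises(ValueError, match="outside"):
            build_fusion(seq, pair, far)

    def test_shift_mismatch_is_rejected(self):
        seq, truth = make_cassette(CassetteSpec(seed=16))
        pair = next(op for op in find_orf_pairs(seq)
                    if op.shift == -1 and op.orf5.start == 0)
        plus = evaluate_site(seq, truth["heptamer_offset"], +1)
        with pytest.raises(ValueError, match="match"):
            build_fusion(seq, pair, plus)


class TestAnalyzeCds:
    def test_synthetic_cds_reports_slip_codon_and_masses(self):
        seq, truth = make_cassette(CassetteSpec(orf5_aa=20, orf3_aa=25, seed=17))
        report = analyze_cds(seq, min_aa5=5, min_aa3=5)
        assert report is not None
        p = truth["heptamer_offset"]
        assert report["site"].start == p
        assert report["slip_codon_number"] == (p + 1) // 3 + 1
        assert report["fusion_mass_da"] > report["mass5_da"]
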