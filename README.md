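# prfkit

Tools for finding and characterizing programmed −1 ribosomal frameshift
(−1 PRF) cassettes in nucleotide sequences, built around the frameshift
signal of the fungal *YIP3* gene (*Podospora anserina* `Pa_1_8470`), the
first cellular, non-retroviral eukaryotic gene known to extend a protein by
−1 frameshifting.

A −1 PRF cassette is

```
[5' ORF] … X XXY YYZ … [spacer] … [stimulatory structure] … [out-of-frame 3' ORF]
```

where `X XXY YYZ` is the slippery heptamer on which the P- and A-site tRNAs
re-pair one base upstream, and the stimulatory element (a hairpin or an
H-type pseudoknot) pauses the ribosome over it.  The *PaYIP3* site is
noncanonical on both counts — its heptamer U UUU UCC works only because the
A-site tRNA-Ser(IGA) re-pairs onto UUC through a G·U wobble and an
inosine pair, and its pseudoknot starts almost immediately after the
heptamer — which is exactly what this package quantifies.

`prfkit` is for sequence analysts and molecular biologists who want to

* scan sequences for canonical and relaxed slippery sites and score
  codon–anticodon re-pairing (`WC` / `wobble` / `inosine` / `mismatch`
  per position, tandem vs single-P-site slippage models),
* predict the downstream stimulatory element by exhaustive search
  (best hairpin, best H-type pseudoknot with bulges; scoring
  G·C = 3, A·U = 2, G·U = 1, bulge penalty 2 + 0.5/nt — a transparent
  scheme whose argmax is certifiable, not a thermodynamic folder),
* derive cassette geometry (spacer, stem-1 bulge, basal G·C run) and the
  predicted frameshift fusion protein with its average mass,
* analyze cassette conservation across species: per-column base-pair
  compatibility, compensatory vs disruptive substitutions, frame of the
  3′ extension, and Fitch parsimony mapping of 3′-ORF presence on a
  species tree,
* quantify frameshifting efficiency from dual-reporter
  (β-galactosidase / firefly luciferase) assays,

  efficiency % = 100 · mean(luc/βgal)₍test₎ / mean(luc/βgal)₍in-frame control₎,

  with exact Mann–Whitney tests (full enumeration, mid-ranks),
* and generate synthetic cassettes, ortholog families and reporter
  datasets with known ground truth for validation.

## Worked example

Scan the packaged reporter-insert fixtures (the five printed dual-reporter
cassette inserts, including the natural Podo-1 sequence):

```sh
$ prfkit scan src/prfkit/fixtures/reporter_inserts.fasta -o demo
$ head -2 demo.sites.tsv
seq_id  start  heptamer  shift  model   canonical  structure   score  spacer_nt  stem1_bulge_nt  stem1_base_gc_run  fusion_aa_len  fusion_mass_da
Podo-1  2      TTTTTCC   -1     tandem  0          pseudoknot  36.5   1          3               3                  20             2052.3
```

Reading the Podo-1 row: the scanner finds the U UUU UCC heptamer at offset
2 (0-based), compatible with tandem tRNA slippage; the exhaustive search
folds the downstream window into a pseudoknot (score 36.5) whose stem 1
carries a 3-nt bulge and a G·C stretch at its base; joining the two ORFs
at this site yields a 20-residue fusion peptide of 2052.3 Da.  The
structure, in dot-bracket form (stem 2 in square brackets):

```
GCTTTTTCCGGGGAGGTGGTCTAGGTGGTCGGCCACGAGCTCCCAAATTTTCGCCCCAT
..........(((((((((((..[[[[[..))))))...)))))......]]]]]....
```

Simulate a six-replicate dual-reporter experiment at a true efficiency of
1% and quantify it:

```sh
$ prfkit simulate reporter --seed 11 --efficiency 1.0 -o rep11
$ prfkit quant rep11.reporter.tsv --control control -o rep11
test     1.004%   +/-0.033  p=0.002165
control  100.000% +/-3.496  p=1
```

The estimator recovers the planted 1% (±1 SE) and the exact Mann–Whitney
test separates the construct from its in-frame control at p ≈ 0.002 —
the smallest two-sided p attainable at 6+6 replicates is 2/C(12,6) ≈ 0.0022.

Parsimony mapping of the 3′-ORF character on the packaged Eumycota tree:

```sh
$ prfkit conserve --tree src/prfkit/fixtures/yip3_tree.nwk \
                  --states src/prfkit/fixtures/yip3_states.tsv -o yip3
2 change(s): gain@Pezizomycotina_core, loss@Ascosphaera_apis
```

i.e. a single appearance of the 3′ ORF after the Orbiliomycetes split and
a single secondary loss in *Ascosphaera apis*.

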