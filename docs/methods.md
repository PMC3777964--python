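# Methods

This note documents the models behind `prfkit`, the defaults that matter,
what the synthetic-data generators do and do not emulate, and the numerical
conventions.  Coordinates are 0-based, half-open throughout; DNA is the
internal alphabet (RNA input is normalized, U→T) and all rules below are
stated on DNA letters with U≡T.

## Slippery sites and tRNA re-pairing

A candidate site is a heptamer `h[0..6]` read in the frame of the upstream
ORF: the P-site codon is `h[1:4]`, the A-site codon `h[4:7]`, and `h[0]`
is the last base of the preceding codon (the `X` of `X XXY YYZ`).  After a
shift of −1 the P/A tRNAs face `h[0:3]` / `h[3:6]`; after +1 they face
`h[2:5]` / `h[5:8]` (one base of context beyond the heptamer).

Re-pairing is scored per codon position against the anticodon that decodes
the original codon, aligned antiparallel (codon position *i* against
anticodon position *3−i*).  Productive appositions are Watson–Crick pairs,
G·U wobble pairs (at any position — the argument for U UUU UCC hinges on a
G·U at A-site position 2), and inosine against U/C/A.  Everything else is
a mismatch.  A tRNA "re-pairs" when all three positions are productive;
**tandem** sites re-pair both tRNAs, **single_P** sites only the P-site
tRNA, and the rest are **incompatible**.  How many wobble/inosine pairs a
ribosome really tolerates is not known; mismatch-free is this package's
deliberately conservative rule, and a scored ranking (WC > wobble >
inosine per position) is available for exploratory use.

The default anticodon table is generative: every sense codon gets its
Watson–Crick anticodon, except that the wobble base (anticodon position 1)
is **I** for the eight codon boxes read by inosine-34 tRNAs in yeast (Ala,
Pro, Thr, Val, Ser, Leu-CUN, Ile, Arg-CGN; codons ending U/C/A), and **G**
for U/C-ending codons of the remaining boxes (the G34 sparing rule, e.g.
Phe-GAA).  This reproduces the worked case Ser-UCC→IGA, and makes the
UUUCU-type +1 site a single-P slipper (Phe re-pairs UUU→UUC via G34·C; the
Leu A-site tRNA cannot follow).  Organism-specific tables can be supplied
as TSV.

Scanning modes: `canonical` returns X XXY YYZ pattern matches; `relaxed`
returns the canonical matches **plus** every tandem-re-pairing-compatible
heptamer.  Relaxed is therefore a strict superset of canonical — a
canonical heptamer whose re-pairing fails under the table (e.g.
G GGC CCA, or the IBV U UUA AAC, whose in-vivo slippage involves a
modified U34 outside this model) is still reported, annotated
`incompatible`; pattern and mechanism are kept as independent judgments.

## Stimulatory structures

The search enumerates every legal stem — 3–12 pairs from {G·C, A·U, G·U},
up to two one-sided bulges of ≤5 nt — and every crossing pair of stems
(`stem1.left < stem2.left < stem1.right < stem2.right`, loops L1/L2/L3 ≤
30 nt), scoring

    score = Σ pairs (G·C 3, A·U 2, G·U 1) − Σ bulges (2 + 0.5·nt)

with no loop-length term.  The argmax is returned under a deterministic
tie-break (higher score → longer stem 1 → 5′-most stem 1 → 5′-most
stem 2); structures scoring < 12 are suppressed.  Hairpin prediction is
the same enumeration restricted to a single stem with a ≥3-nt terminal
loop.  This is *not* a free-energy model: the design goal is a small,
fully enumerable search whose optimum can be certified against brute
force (the test suite does exactly that on windows ≤ 40 nt), at the cost
of thermodynamic realism.  Windows are capped at 120 nt (default scan
window: 80 nt downstream of the heptamer); the empty window folds to
nothing, and scores are invariant under RNA/DNA spelling and under
sequence reversal (reverse *complement* does not preserve G·U pairs, so
no such symmetry is claimed).

On the natural Podo-1 cassette the optimum is a pseudoknot with an
11-pair stem 1 interrupted by the 3-nt GAG bulge and a 5-pair stem 2.
One honest discrepancy with the hand-drawn published structure: the
search also pairs one additional G·C at the base of stem 1 (insert
positions 10·43), which shortens the computed spacer to 1 nt where the
drawn structure leaves that pair open and counts 2 nt.  Every additive
scoring scheme in this family keeps that Watson–Crick pair — removing it
always costs score — so the package reports the 1-nt spacer rather than
tuning the search into agreement; the bulge (3 nt) and the basal G·C
stretch are reproduced exactly.

## ORF pairs and fusion products

ORFs are stop-to-stop segments per frame (optionally ATG-anchored).  A
joinable pair needs a terminated 5′ ORF, a 3′ ORF in a different frame
that begins before the 5′ ORF's stop (plus a configurable gap) and ends
beyond it; the required shift is the frame residue (1 → +1, 2 → −1).
Fusion semantics: under tandem slippage the A-site residue is taken from
the 0-frame codon (the same tRNA carries it across the slip) and reading
resumes at `p+7+shift`; under single-P slippage the peptide runs through
the P-site residue and resumes at `p+4+shift`.  Both resumption points
are the unique choices consistent with the shifted register.  Internal
stops anywhere in the implied reading are errors that identify the codon,
signalling an invalid site/pair combination.  Masses are average residue
masses (gel-calibrated kDa convention); monoisotopic tables are available.

## Conservation and parsimony

Column-pair statistics count, across alignment rows, the distinct members
of {C-G, G-C, A-U, U-A, G-U, U-G} (compatible), the rows whose bases
cannot pair, and the gapped rows.  Compensatory classification compares
each species' bases at a reference-paired column pair with the reference:
pairing kept with both bases changed → `compensatory`; kept with one base
changed (necessarily via a wobble alternative) → `wobble_shift`; pairing
lost, including gaps → `disruptive`.  Species are compared against the
reference structure only — no per-species refolding — matching how
comparative figures are drawn.

The bundled aligner is a convenience (Biopython global affine alignment;
star-progressive against the first sequence for >2 rows; match 2,
mismatch −1, gap open −5, extend −1, deterministic); structural aligners'
output can be supplied pre-aligned instead.

Parsimony mapping is unit-cost Sankoff dynamic programming on the rooted
tree (exact for multifurcations), with deterministic resolution: the root
prefers `absent` on ties (the outgroup condition) and every other node
prefers its parent's state, which for a binary character reproduces the
Fitch up-pass.  Gains/losses are emitted on the edge above the node whose
state flips; the event count always equals the DP minimum, and the test
suite certifies it against exhaustive ancestral enumeration and against
dendropy's Fitch down-pass.  The packaged Eumycota tree encodes the
class-level topology with Orbiliomycetes as the earliest-diverging
Pezizomycotina class; see `src/prfkit/fixtures/README.md` for the two
placements the source figure leaves ambiguous (neither affects the
single-gain, single-loss reconstruction).

## Reporter efficiency

Efficiency is the ratio of construct-level ratio means (test and control
are unpaired extracts, so per-replicate pairing would be meaningless),
expressed in percent; its SE combines the two relative standard errors of
the ratio means in quadrature (first-order propagation).  No background
subtraction or normalization is applied.  The Mann–Whitney test
enumerates all C(n_x+n_y, n_x) labelings when n_x+n_y ≤ 20 (mid-ranks for
ties; a labeling is at least as extreme when min(U′, n·m−U′) ≤ min(U,
n·m−U)), and falls back to the tie-corrected normal approximation beyond
that.  Multi-construct summaries report unadjusted exact p-values (one
planned comparison per construct against the control) plus a Holm column
for transparency.

## Synthetic data

`make_cassette` plants a cassette with exact ground truth: 5′ ORF (ATG +
random non-stop codons), heptamer on the reading frame, spacer, stem 1
left arm, L1, stem 2 left arm, L2, stem 1 right arm (Watson–Crick
complement with the requested bulge inserted mid-helix), L3, stem 2 right
arm, then a 3′-ORF tail written on the shifted register with a planted
0-frame stop (so the 5′ ORF terminates) and a terminal shifted-frame
stop.  Stem arms are random with 70% G/C; junction filler (spacer, loops,
register pad, first tail codon) is drawn from {A, C}, a pairing-inert
alphabet, so random filler cannot seed helices that displace the planted
optimum — under fully uniform filler the planted structure essentially
never survives as the argmax.  Every candidate is verified with the
package's own detectors (frame checks, a fast displacing-extension
prefilter, then full scan/fold/fusion) and redrawn on any collision, so a
returned cassette is certified exactly recoverable; unsatisfiable
geometries raise with the violated constraint.  Generation is
deterministic given the seed (numpy `SeedSequence` spawning, one child
per attempt).

`make_family` evolves the cassette on a tree: per-edge Poisson
substitutions confined to the structure region, compensatory at stem
positions with probability `compensatory_fraction` (both partners
replaced by a different WC pair) and one-sided otherwise; substitutions
that would create a stop in either relevant reading are redrawn.  Leaves
below designated loss edges are truncated at the 5′ ORF's stop — they
retain the 5′ gene but no reachable 3′ ORF.  `make_reporter` draws β-gal
levels and luc/β-gal ratios log-normally with mean-exact parameterization
(cv = 0 reproduces the truth exactly); defaults are six replicates and
cv = 0.1, matching the assay design, and the packaged calibration file
sets the true efficiencies of the Podo-1-like (1%) and out-of-frame IBV
control (0.3%) constructs to their published measurements.

What the generators do **not** emulate: indels (family alignments are
column-exact), codon-usage or dN/dS realism, sequencing error,
between-day assay batch effects, and thermodynamically realistic
structure ensembles.  Green round-trip tests therefore certify the
detectors' correctness on cassettes whose signal is cleanly planted, not
their sensitivity on diverged natural sequences.

## Problem sizes and tolerances

The validation suite uses, as the package's own choices: 100 random
windows (≤ 40 nt) for the pseudoknot-vs-brute-force equivalence, all 4⁷
heptamers for the canonical ⊂ relaxed property, 100 random cassette specs
for round-trip recovery, every sample-size combination up to 6+6 for the
exact Mann–Whitney enumeration, and 1000 seeded trials for estimator
recovery (within 3 SEs propagated from the generator's noise model,
e·√(2·cv²/n) — with per-trial *estimated* SEs the small-sample t-tails
put 3-SE coverage near 98.3%, so the estimated-SE calibration is checked
separately).  `scripts/acceptance.py` averages 1000 seeded trials per
reporter construct and reruns the Podo-1 cassette pipeline from the
packaged fixture; all numbers it emits are computed at run time.

## Known limitations

Unmodified anticodons only (sites that depend on modified wobble
nucleosides classify as non-tandem; the canonical branch still reports
them); H-type pseudoknots only (no kissing loops or triples); no
free-energy model; the convenience aligner is not structure-aware; the
fixture tree is class-level, not the full published species sample; and
the 19.5/61.6-kDa full-gene mass checks require the `Pa_1_8470` CDS,
which is not redistributable here (see `tests/test_acceptance.py` for the
expected drop-in location, `data/pa_yip3_cds.fasta`).
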