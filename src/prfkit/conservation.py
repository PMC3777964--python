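"""Structure-aware conservation analysis of aligned frameshift cassettes.

Given an alignment of orthologous cassettes and the stimulatory structure of
a reference species projected onto alignment columns, this module counts
base-pair compatibility per paired column (the six pair types C-G, G-C, A-U,
U-A, G-U, U-G are "compatible"), classifies per-species deviations from the
reference pair as compensatory / wobble-shift / disruptive, and classifies
the frame of each species' 3' extension.

``align_cassettes`` is a convenience global aligner (pairwise-optimal for
two sequences, star-progressive for more); pre-computed alignments from a
dedicated structural aligner can be supplied instead as gapped FASTA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import Align

from .sequences import NucSequence, OpenReadingFrame

__all__ = [
    "AlignParams",
    "CassetteAlignment",
    "ColumnPairStats",
    "CompensatoryEvent",
    "align_cassettes",
    "column_pair_stats",
    "find_compensatory",
    "classify_extension_frame",
]

COMPATIBLE_PAIRS = (("C", "G"), ("G", "C"), ("A", "T"), ("T", "A"), ("G", "T"), ("T", "G"))
_COMPAT = frozenset(COMPATIBLE_PAIRS)
_WOBBLE = {("G", "T"), ("T", "G")}


@dataclass(frozen=True)
class AlignParams:
    """Affine global-alignment parameters for the convenience aligner."""

    match: float = 2.0
    mismatch: float = -1.0
    gap_open: float = -5.0
    gap_extend: float = -1.0


@dataclass
class CassetteAlignment:
    """Equal-length gapped rows plus an optional reference pairing.

    ``ref_structure`` is a list of (col_i, col_j) pairs of alignment columns
    paired in the reference species' structure; ``ref_id`` names that row.
    """

    ids: list[str]
    rows: list[str]
    ref_id: str | None = None
    ref_structure: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows must have equal length")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, id: str) -> str:
        return self.rows[self.ids.index(id)]

    def project_structure(self, structure, ref_id: str) -> None:
        """Attach a structure given in reference *sequence* coordinates by
        mapping its pairs through the reference row's gaps."""
        row = self.row(ref_id)
        seq_to_col = [i for i, c in enumerate(row) if c != "-"]
        stems = [structure.stem1, structure.stem2] if hasattr(structure, "stem2") else [structure]
        pairs = []
        for stem in stems:
            for l, r in stem.pairs:
                pairs.append((seq_to_col[l], seq_to_col[r]))
        self.ref_id = ref_id
        self.ref_structure = sorted(pairs)


@dataclass(frozen=True)
class ColumnPairStats:
    """Base-pair compatibility census for one pair of alignment columns."""

    n_pair_types: int
    n_incompatible: int
    n_gapped: int
    n_compatible: int
    pair_types: tuple


@dataclass(frozen=True)
class CompensatoryEvent:
    columns: tuple[int, int]
    species: str
    from_pair: tuple[str, str]
    to_pair: tuple[str, str]
    klass: str  # compensatory | wobble_shift | disruptive


def _aligner(params: AlignParams) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = params.match
    a.mismatch_score = params.mismatch
    a.open_gap_score = params.gap_open
    a.extend_gap_score = params.gap_extend
    return a


def _pairwise(a: Align.PairwiseAligner, s1: str, s2: str) -> tuple[str, str]:
    aln = a.align(s1, s2)[0]  # first traceback: deterministic
    t1, t2 = str(aln[0]), str(aln[1])
    return t1, t2


def align_cassettes(seqs: Sequence[NucSequence], params: AlignParams | None = None) -> CassetteAlignment:
    """Global alignment of >= 2 cassettes.

    Two sequences get the optimal affine alignment; more are merged
    star-progressively against the first sequence (the center), propagating
    center gaps so all rows stay consistent.  Deterministic.
    """
    if not seqs:
        raise ValueError("no sequences to align")
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences to align")
    params = params or AlignParams()
    a = _aligner(params)
    ids = [s.id for s in seqs]
    if len(seqs) == 2:
        t1, t2 = _pairwise(a, seqs[0].seq, seqs[1].seq)
        return CassetteAlignment(ids=ids, rows=[t1, t2])
    center = seqs[0].seq
    # per-sequence alignment to the center, then merge center gap patterns
    alns = [_pairwise(a, center, s.seq) for s in seqs[1:]]
    # merged center: at each center residue, the max gap run each pairwise
    # alignment inserts before it (and at the end)
    n = len(center)
    gaps_before = [0] * (n + 1)
    for tc, _ in alns:
        pos = 0
        run = 0
        for c in tc:
            if c == "-":
                run += 1
            else:
                gaps_before[pos] = max(gaps_before[pos], run)
                run = 0
                pos += 1
        gaps_before[n] = max(gaps_before[n], run)
    merged_center = ""
    for i, res in enumerate(center):
        merged_center += "-" * gaps_before[i] + res
    merged_center += "-" * gaps_before[n]
    rows = [merged_center]
    for tc, ts in alns:
        out = []
        pos = 0
        i = 0
        pending = []
        for c, srow in zip(tc, ts):
            if c == "-":
                pending.append(srow)
            else:
                out.append("".join(pending).ljust(gaps_before[pos], "-") if pending
                           else "-" * gaps_before[pos])
                out.append(srow)
                pending = []
                pos += 1
        out.append("".join(pending).ljust(gaps_before[n], "-") if pending else "-" * gaps_before[n])
        rows.append("".join(out))
    return CassetteAlignment(ids=ids, rows=rows)


def column_pair_stats(aln: CassetteAlignment, col_i: int, col_j: int) -> ColumnPairStats:
    """Census of the (col_i, col_j) base combinations across rows."""
    if not (0 <= col_i < aln.n_cols and 0 <= col_j < aln.n_cols):
        raise IndexError("column outside alignment")
    types = set()
    n_inc = n_gap = n_comp = 0
    for row in aln.rows:
        x, y = row[col_i], row[col_j]
        if x == "-" or y == "-":
            n_gap += 1
        elif (x, y) in _COMPAT:
            n_comp += 1
            types.add((x, y))
        else:
            n_inc += 1
    return ColumnPairStats(
        n_pair_types=len(types), n_incompatible=n_inc, n_gapped=n_gap,
        n_compatible=n_comp, pair_types=tuple(sorted(types)),
    )


def find_compensatory(aln: CassetteAlignment, ref_row: str | None = None) -> list[CompensatoryEvent]:
    """Per-species deviations from the reference base pairs.

    For each paired column and non-reference row: identical to the reference
    pair -> no event; pairing retained with both bases changed ->
    compensatory; retained with one base changed (necessarily via a wobble
    alternative) -> wobble_shift; pairing lost (or a gap) -> disruptive.
    """
    ref_row = ref_row or aln.ref_id
    if not aln.ref_structure or ref_row is None:
        raise ValueError("alignment has no reference structure")
    ref = aln.row(ref_row)
    events = []
    for (ci, cj) in aln.ref_structure:
        a, b = ref[ci], ref[cj]
        for sp, row in zip(aln.ids, aln.rows):
            if sp == ref_row:
                continue
            x, y = row[ci], row[cj]
            if (x, y) == (a, b):
                continue
            if x == "-" or y == "-" or (x, y) not in _COMPAT:
                klass = "disruptive"
            elif x != a and y != b:
                klass = "compensatory"
            else:
                klass = "wobble_shift"
            events.append(CompensatoryEvent((ci, cj), sp, (a, b), (x, y), klass))
    return events


def classify_extension_frame(seq: NucSequence | str, orf5: OpenReadingFrame,
                             orf3: OpenReadingFrame) -> str:
    """Frame of the 3' extension relative to the 5' ORF: '-1', '+1' or 'in_frame'."""
    residue = (orf3.frame - orf5.frame) % 3
    return {0: "in_frame", 1: "+1", 2: "-1"}[residue]
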