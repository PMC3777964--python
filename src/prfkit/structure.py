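"""Stimulatory-structure prediction downstream of a slippery site.

The stimulatory element of a -1 PRF cassette is usually a hairpin or an
H-type pseudoknot starting a few nucleotides after the heptamer.  This module
performs an exhaustive, deterministic search for the best-scoring single stem
(``predict_hairpin``) and the best pair of crossing stems
(``predict_pseudoknot``) under a transparent additive scoring scheme:

    G.C = 3, A.U = 2, G.U = 1, per-bulge penalty 2 + 0.5 per bulged nt.

Full nearest-neighbor thermodynamics is deliberately out of scope; the point
of the integer-ish scheme is that the search space is small enough to
enumerate completely, so every reported structure is a certified argmax and
oracle-checkable.  Stems may carry up to two one-sided bulges; only H-type
(two crossing stems) pseudoknots are considered.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

from .sequences import NucSequence
from .slippery import SlipperySite

__all__ = [
    "FoldParams",
    "Stem",
    "PseudoknotStructure",
    "CassetteFeatures",
    "predict_hairpin",
    "predict_pseudoknot",
    "cassette_features",
    "dot_bracket",
]

PAIR_SCORES = {
    ("G", "C"): 3.0, ("C", "G"): 3.0,
    ("A", "T"): 2.0, ("T", "A"): 2.0,
    ("G", "T"): 1.0, ("T", "G"): 1.0,
}
GC_PAIRS = {("G", "C"), ("C", "G")}


@dataclass(frozen=True)
class FoldParams:
    """Search bounds and scoring knobs for the exhaustive structure search."""

    min_stem: int = 3            # pairs per stem
    max_stem: int = 12
    max_bulges: int = 2          # one-sided bulges per stem
    max_bulge_len: int = 5       # nt per bulge
    max_loop: int = 30           # nt per loop (L1/L2/L3, and hairpin loop)
    min_hairpin_loop: int = 3    # physical minimum for a closed hairpin
    min_score: float = 12.0      # below this, report nothing
    max_window: int = 120        # guard: the search is exhaustive
    bulge_open: float = 2.0
    bulge_per_nt: float = 0.5


@dataclass(frozen=True)
class Stem:
    """A helix: paired positions plus any one-sided bulges.

    ``pairs`` run outside-in: pairs[0] is the outermost (left-most left arm
    base, right-most right arm base).  ``left``/``right`` are the half-open
    spans of the two arms; ``bulges`` are (side, start, length) with side
    'left' or 'right'.
    """

    pairs: tuple
    score: float
    bulges: tuple = ()

    @property
    def left(self) -> tuple[int, int]:
        return (self.pairs[0][0], self.pairs[-1][0] + 1)

    @property
    def right(self) -> tuple[int, int]:
        return (self.pairs[-1][1], self.pairs[0][1] + 1)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def total_bulge_nt(self) -> int:
        return sum(b[2] for b in self.bulges)


@dataclass(frozen=True)
class PseudoknotStructure:
    """Two crossing stems: stem1.left < stem2.left < stem1.right < stem2.right."""

    stem1: Stem
    stem2: Stem
    loops: tuple[int, int, int]
    score: float
    is_pseudoknot: bool = True


@dataclass(frozen=True)
class CassetteFeatures:
    """Derived cassette geometry relative to a slippery site."""

    spacer_nt: int
    stem1_bulge_nt: int
    stem1_base_gc_run: int


def _stem_bulges(pairs) -> tuple:
    bulges = []
    for (l1, r1), (l2, r2) in zip(pairs, pairs[1:]):
        if l2 - l1 > 1:
            bulges.append(("left", l1 + 1, l2 - l1 - 1))
        if r1 - r2 > 1:
            bulges.append(("right", r2 + 1, r1 - r2 - 1))
    return tuple(bulges)


def _enumerate_stems(seq: str, p: FoldParams, min_inner_gap: int):
    """Yield every legal stem as (score, pairs-tuple), outside-in.

    ``min_inner_gap`` is the minimum number of unpaired nt that must remain
    between the innermost pair's arms (>=3 for a hairpin closing on itself,
    0 for pseudoknot stems whose arms embrace other elements).
    """
    n = len(seq)
    out = []
    steps = [(1, 1, 0)]
    steps += [(1 + b, 1, b) for b in range(1, p.max_bulge_len + 1)]
    steps += [(1, 1 + b, b) for b in range(1, p.max_bulge_len + 1)]

    def extend(pairs, score, n_bulges):
        if p.min_stem <= len(pairs):
            out.append((score, tuple(pairs)))
        if len(pairs) == p.max_stem:
            return
        l, r = pairs[-1]
        for dl, dr, blen in steps:
            if blen and n_bulges == p.max_bulges:
                continue
            l2, r2 = l + dl, r - dr
            if r2 - l2 - 1 < min_inner_gap:
                continue
            sc = PAIR_SCORES.get((seq[l2], seq[r2]))
            if sc is None:
                continue
            pen = (p.bulge_open + p.bulge_per_nt * blen) if blen else 0.0
            pairs.append((l2, r2))
            extend(pairs, score + sc - pen, n_bulges + (1 if blen else 0))
            pairs.pop()

    for l in range(n):
        for r in range(n - 1, l + min_inner_gap, -1):
            sc = PAIR_SCORES.get((seq[l], seq[r]))
            if sc is not None:
                extend([(l, r)], sc, 0)
    return out


def _seq_str(window) -> str:
    return window.seq if isinstance(window, NucSequence) else str(window).upper().replace("U", "T")


def _check_window(s: str, p: FoldParams):
    if len(s) > p.max_window:
        raise ValueError(
            f"window of {len(s)} nt exceeds the exhaustive-search limit "
            f"({p.max_window} nt); fold a smaller window"
        )


def predict_hairpin(window, params: FoldParams | None = None) -> Optional[Stem]:
    """Best single stem in the window, or None below threshold.

    Ties break deterministically: higher score, then more pairs, then
    5'-most left arm, then 5'-most right arm.
    """
    p = params or FoldParams()
    s = _seq_str(window)
    _check_window(s, p)
    best = None
    best_key = None
    for score, pairs in _enumerate_stems(s, p, p.min_hairpin_loop):
        loop = pairs[-1][1] - pairs[-1][0] - 1
        if loop > p.max_loop:
            continue
        key = (-score, -len(pairs), pairs[0][0], pairs[-1][1])
        if best_key is None or key < best_key:
            best_key, best = key, (score, pairs)
    if best is None or best[0] < p.min_score:
        return None
    return Stem(pairs=best[1], score=best[0], bulges=_stem_bulges(best[1]))


def _crossing_geometry(s1_pairs, s2_pairs, p: FoldParams):
    """Loop lengths (L1, L2, L3) if the two stems cross legally, else None."""
    l1 = s2_pairs[0][0] - s1_pairs[-1][0] - 1
    l2 = s1_pairs[-1][1] - s2_pairs[-1][0] - 1
    l3 = s2_pairs[-1][1] - s1_pairs[0][1] - 1
    if l1 < 0 or l2 < 0 or l3 < 0:
        return None
    if l1 > p.max_loop or l2 > p.max_loop or l3 > p.max_loop:
        return None
    # s2 right arm must clear s1's right arm entirely
    if s2_pairs[-1][1] <= s1_pairs[0][1]:
        return None
    return (l1, l2, l3)


def predict_pseudoknot(window, params: FoldParams | None = None) -> Optional[PseudoknotStructure]:
    """Best H-type pseudoknot (two crossing stems) in the window, or None.

    Exhaustive over all legal stem pairs within the bounds; the argmax is
    returned under the deterministic tie-break: higher score, longer stem1,
    5'-most stem1, 5'-most stem2.
    """
    p = params or FoldParams()
    s = _seq_str(window)
    _check_window(s, p)
    stems = _enumerate_stems(s, p, 0)
    if not stems:
        return None
    stems.sort(key=lambda t: -t[0])
    top = stems[0][0]
    occupied = []
    for score, pairs in stems:
        occ = 0
        for l, r in pairs:
            occ |= (1 << l) | (1 << r)
        occupied.append(occ)
    best = None
    best_key = None
    best_score = -1e18
    for i, (sc1, s1) in enumerate(stems):
        if sc1 + top < best_score:
            break
        for j, (sc2, s2) in enumerate(stems):
            total = sc1 + sc2
            if total < best_score:
                break
            if occupied[i] & occupied[j]:
                continue
            if not (s1[0][0] < s2[0][0] < s1[0][1] < s2[0][1]):
                continue
            loops = _crossing_geometry(s1, s2, p)
            if loops is None:
                continue
            key = (-total, -len(s1), s1[0][0], s2[0][0])
            if best_key is None or key < best_key:
                best_key = key
                best_score = total
                best = (sc1, s1, sc2, s2, loops)
    if best is None or best[0] + best[2] < p.min_score:
        return None
    sc1, s1, sc2, s2, loops = best
    return PseudoknotStructure(
        stem1=Stem(pairs=s1, score=sc1, bulges=_stem_bulges(s1)),
        stem2=Stem(pairs=s2, score=sc2, bulges=_stem_bulges(s2)),
        loops=loops,
        score=sc1 + sc2,
    )


def shift_structure(structure, offset: int):
    """Translate all structure coordinates by ``offset`` (window -> sequence)."""
    def mv(stem: Stem) -> Stem:
        return Stem(
            pairs=tuple((l + offset, r + offset) for l, r in stem.pairs),
            score=stem.score,
            bulges=tuple((side, start + offset, ln) for side, start, ln in stem.bulges),
        )
    if isinstance(structure, Stem):
        return mv(structure)
    return replace(structure, stem1=mv(structure.stem1), stem2=mv(structure.stem2))


def cassette_features(seq: NucSequence | str, site: SlipperySite, structure) -> CassetteFeatures:
    """Spacer, stem-1 bulge total and basal G-C run for a site + structure.

    ``structure`` coordinates must be in the same frame as ``site`` (use
    ``shift_structure`` if it was predicted on a downstream window).
    """
    stem1 = structure.stem1 if isinstance(structure, PseudoknotStructure) else structure
    first_paired = stem1.pairs[0][0]
    spacer = first_paired - (site.start + 7)
    if spacer < 0:
        raise ValueError(
            f"structure (first pair at {first_paired}) lies upstream of the "
            f"slippery site ending at {site.start + 7}"
        )
    s = seq.seq if isinstance(seq, NucSequence) else str(seq).upper().replace("U", "T")
    gc_run = 0
    for l, r in stem1.pairs:
        if (s[l], s[r]) in GC_PAIRS:
            gc_run += 1
        else:
            break
    return CassetteFeatures(
        spacer_nt=spacer,
        stem1_bulge_nt=stem1.total_bulge_nt,
        stem1_base_gc_run=gc_run,
    )


def dot_bracket(length: int, structure) -> str:
    """Dot-bracket string; stem1 in '()', stem2 (if any) in '[]'."""
    chars = ["."] * length
    def mark(stem: Stem, open_c: str, close_c: str):
        for l, r in stem.pairs:
            chars[l], chars[r] = open_c, close_c
    if isinstance(structure, PseudoknotStructure):
        mark(structure.stem1, "(", ")")
        mark(structure.stem2, "[", "]")
    elif structure is not None:
        mark(structure, "(", ")")
    return "".join(chars)
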