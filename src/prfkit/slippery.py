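"""Slippery-site scanning and tRNA re-pairing analysis.

A -1 (or +1) programmed frameshift begins at a slippery heptamer, canonically
X XXY YYZ, where the P- and A-site tRNAs detach from their 0-frame codons and
re-pair with the overlapping codons of the shifted frame.  This module scores
that re-pairing position by position against an anticodon table: Watson-Crick
pairs, G.U wobble pairs, and inosine (I, pairing U/C/A) are productive; any
other apposition is a mismatch.

Two slippage models are distinguished: *tandem* (both tRNAs re-pair
mismatch-free, the classic viral mechanism) and *single_P* (only the P-site
tRNA re-pairs, as proposed for sites like the UUUCU of Mycosphaerella
graminicola).  The model uses unmodified anticodons; heptamers whose in-vivo
slippage relies on modified wobble nucleosides (e.g. the IBV U UUA AAC) are
still reported through the canonical-pattern branch of the scanner.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

from .sequences import NucSequence, STOP_CODONS, _normalize

__all__ = [
    "AnticodonTable",
    "SlipperySite",
    "repair_pairs",
    "scan_slippery",
    "classify_site",
    "is_canonical_heptamer",
    "PairClass",
]

PairClass = Literal["WC", "wobble", "inosine", "mismatch"]

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "T"), ("T", "G")}
_INOSINE_OK = {"T", "C", "A"}
_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}

# Codon-box prefixes decoded by inosine-34 anticodons in yeast (Ala, Pro,
# Thr, Val, Ser, Leu CUN, Ile, Arg CGN); codons of these boxes ending U/C/A
# are read with I at the anticodon wobble position.
_INOSINE_BOXES = frozenset({"GC", "CC", "AC", "GT", "TC", "CT", "AT", "CG"})


def _norm_codon(codon: str) -> str:
    dna, _ = _normalize(codon, context=f"codon {codon!r}")
    if len(dna) != 3:
        raise ValueError(f"codon must be 3 nt, got {codon!r}")
    return dna


class AnticodonTable:
    """Codon -> anticodon (5'->3', alphabet A/C/G/T/I).

    The default table pairs every sense codon with its Watson-Crick
    anticodon, substituting inosine at the wobble position (anticodon
    position 1, which reads codon position 3) for the eight yeast codon
    boxes decoded by I-containing tRNAs.  This guarantees the worked case
    Ser-UCC -> IGA.
    """

    def __init__(self, mapping: dict[str, str]):
        self._map = {_norm_codon(c): a.upper().replace("U", "T") if "I" not in a else a.upper()
                     for c, a in mapping.items()}
        for codon, anti in self._map.items():
            if len(anti) != 3 or any(b not in "ACGTI" for b in anti):
                raise ValueError(f"bad anticodon {anti!r} for codon {codon}")

    @classmethod
    def default(cls) -> "AnticodonTable":
        mapping = {}
        for b1 in "ACGT":
            for b2 in "ACGT":
                for b3 in "ACGT":
                    codon = b1 + b2 + b3
                    if codon in STOP_CODONS:
                        continue
                    if codon[:2] in _INOSINE_BOXES and b3 in "TCA":
                        wobble = "I"
                    elif b3 in "TC":
                        # U/C-ending codons outside the inosine boxes are read
                        # by G34 anticodons (e.g. Phe-GAA), the yeast sparing
                        # rule: G pairs C (WC) and U (wobble)
                        wobble = "G"
                    else:
                        wobble = _COMP[b3]
                    mapping[codon] = wobble + _COMP[b2] + _COMP[b1]
        return cls(mapping)

    @classmethod
    def from_tsv(cls, path) -> "AnticodonTable":
        mapping = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                codon, anti = line.split("\t")[:2]
                mapping[codon] = anti
        return cls(mapping)

    def __getitem__(self, codon: str) -> str:
        codon = _norm_codon(codon)
        try:
            return self._map[codon]
        except KeyError:
            raise KeyError(f"codon {codon} absent from anticodon table") from None

    def __contains__(self, codon: str) -> bool:
        try:
            return _norm_codon(codon) in self._map
        except ValueError:
            return False


def _pair_class(codon_base: str, anticodon_base: str) -> PairClass:
    if anticodon_base == "I":
        return "inosine" if codon_base in _INOSINE_OK else "mismatch"
    if (codon_base, anticodon_base) in _WC:
        return "WC"
    if (codon_base, anticodon_base) in _WOBBLE:
        return "wobble"
    return "mismatch"


def repair_pairs(codon_from: str, codon_to: str, table: AnticodonTable | None = None) -> list[PairClass]:
    """Classes of the three codon/anticodon appositions after re-pairing.

    The anticodon cognate to ``codon_from`` is aligned antiparallel to
    ``codon_to``; classes are reported in codon 5'->3' order (codon position
    i pairs anticodon position 3-i).
    """
    table = table or AnticodonTable.default()
    codon_to = _norm_codon(codon_to)
    anti = table[codon_from]
    return [_pair_class(codon_to[i], anti[2 - i]) for i in range(3)]


def is_canonical_heptamer(heptamer: str) -> bool:
    """True for the X XXY YYZ pattern (positions 0-2 equal, 3-5 equal)."""
    h = heptamer
    return len(h) == 7 and h[0] == h[1] == h[2] and h[3] == h[4] == h[5]


@dataclass(frozen=True)
class SlipperySite:
    """A candidate slippage heptamer with its re-pairing analysis.

    ``pair_classes`` holds one per-position class list per tRNA considered:
    two entries (P then A) under the tandem model, one (P) under single_P.
    """

    start: int
    heptamer: str
    shift: int
    model: str  # tandem | single_P | incompatible
    p_codon0: str
    a_codon0: str
    p_codon_shift: str
    a_codon_shift: str | None
    pair_classes: tuple
    canonical: bool

    @property
    def end(self) -> int:
        return self.start + 7


def _mismatch_free(classes) -> bool:
    return classes is not None and "mismatch" not in classes


def evaluate_site(seq: NucSequence | str, start: int, shift: int = -1,
                  table: AnticodonTable | None = None) -> SlipperySite | None:
    """Build the re-pairing record for the heptamer at ``start``.

    Returns None when the 0-frame P or A codon is a stop (no tRNA to slip)
    or the window is incomplete.  For shift +1 the A-site target codon needs
    one base of context beyond the heptamer; if the sequence ends first the
    A-site analysis is unavailable and the site can at most be single_P.
    """
    if shift not in (-1, 1):
        raise ValueError("shift must be -1 or +1")
    table = table or AnticodonTable.default()
    s = seq.seq if isinstance(seq, NucSequence) else seq.upper().replace("U", "T")
    if start < 0 or start + 7 > len(s):
        return None
    h = s[start : start + 7]
    p0, a0 = h[1:4], h[4:7]
    if p0 in STOP_CODONS or a0 in STOP_CODONS:
        return None
    if shift == -1:
        p_shift, a_shift = h[0:3], h[3:6]
    else:
        p_shift = h[2:5]
        a_shift = s[start + 5 : start + 8] if start + 8 <= len(s) else None
    p_classes = tuple(repair_pairs(p0, p_shift, table))
    a_classes = tuple(repair_pairs(a0, a_shift, table)) if a_shift else None
    if _mismatch_free(p_classes) and _mismatch_free(a_classes):
        model = "tandem"
        classes = (p_classes, a_classes)
    elif _mismatch_free(p_classes):
        model = "single_P"
        classes = (p_classes,)
    else:
        model = "incompatible"
        classes = (p_classes,) if a_classes is None else (p_classes, a_classes)
    return SlipperySite(
        start=start, heptamer=h, shift=shift, model=model,
        p_codon0=p0, a_codon0=a0, p_codon_shift=p_shift, a_codon_shift=a_shift,
        pair_classes=classes, canonical=is_canonical_heptamer(h),
    )


def scan_slippery(seq: NucSequence | str, mode: str = "relaxed", shift: int = -1,
                  table: AnticodonTable | None = None) -> list[SlipperySite]:
    """Scan every heptamer register of ``seq`` for slippery sites.

    ``canonical`` mode returns only X XXY YYZ pattern matches.  ``relaxed``
    mode returns the canonical matches plus every heptamer whose P- and
    A-site tRNAs re-pair mismatch-free in the shifted frame under the tandem
    model (wobble and inosine pairs allowed) -- a proper relaxation, so the
    canonical set is always contained in it.  Sites are sorted by start.
    """
    if mode not in ("canonical", "relaxed"):
        raise ValueError(f"unknown mode {mode!r}")
    table = table or AnticodonTable.default()
    s = seq.seq if isinstance(seq, NucSequence) else seq.upper().replace("U", "T")
    out = []
    for p in range(len(s) - 6):
        site = evaluate_site(s, p, shift, table)
        if site is None:
            # stop-codon P/A codon: cannot be canonical (no stop has its
            # first two bases equal), so nothing to report in either mode
            continue
        if mode == "canonical":
            if site.canonical:
                out.append(site)
        else:
            if site.canonical or site.model == "tandem":
                out.append(site)
    return out


def classify_site(site: SlipperySite) -> str:
    """Model assignment for a populated site: tandem, single_P or incompatible."""
    return site.model
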