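"""Overlapping-ORF pair detection and frameshift fusion-product construction.

A -1 PRF gene carries a 5' ORF and an overlapping out-of-frame 3' ORF; the
full-length protein exists only if the ribosome shifts frame inside the
overlap.  ``find_orf_pairs`` enumerates candidate ORF pairs, ``build_fusion``
assembles the fusion peptide implied by a slippery site under the tandem or
single-P slippage mechanics, and ``classify_insert_frame`` gives the net
shift a reporter insert of a given length demands.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .sequences import (
    NucSequence,
    OpenReadingFrame,
    MassTable,
    average_mass,
    find_orfs,
    translate,
)
from .slippery import SlipperySite, scan_slippery

__all__ = [
    "OrfPair",
    "FusionProduct",
    "find_orf_pairs",
    "classify_insert_frame",
    "build_fusion",
    "analyze_cds",
]

_RESIDUE_TO_SHIFT = {0: 0, 1: 1, 2: -1}


@dataclass(frozen=True)
class OrfPair:
    """Two ORFs joinable by a single frameshift inside their overlap."""

    orf5: OpenReadingFrame
    orf3: OpenReadingFrame
    shift: int
    overlap_window: tuple[int, int]


@dataclass(frozen=True)
class FusionProduct:
    aa_seq: str
    shift_site: SlipperySite
    mass_da: float
    parts: tuple[int, int]  # residues encoded 5' / 3' of the slip


def classify_insert_frame(insert_len: int) -> int:
    """Shift the ribosome must make inside an insert of this length for the
    downstream reporter to return to frame (in-frame flanks assumed)."""
    if insert_len < 0:
        raise ValueError("insert length must be >= 0")
    return _RESIDUE_TO_SHIFT[insert_len % 3]


def find_orf_pairs(seq: NucSequence | str, min_aa5: int = 1, min_aa3: int = 1,
                   max_gap: int = 0) -> list[OrfPair]:
    """All same-strand ORF pairs joinable by a single -1/+1 shift.

    The 5' ORF must terminate (have a stop); the 3' ORF must be in a
    different frame, extend beyond the 5' ORF's end, and begin before the 5'
    ORF's stop codon ends (plus ``max_gap`` slop).  Stop-to-stop ORFs are
    used so unannotated genomic windows work.  Pairs are sorted by
    (orf5.start, orf3.start).
    """
    if min_aa5 < 1 or min_aa3 < 1:
        raise ValueError("min_aa thresholds must be >= 1")
    orfs = find_orfs(seq, min_aa=1, require_atg=False)
    pairs = []
    for orf5 in orfs:
        if not orf5.has_terminal_stop or len(orf5.aa_seq) < min_aa5:
            continue
        for orf3 in orfs:
            if orf3.frame == orf5.frame or len(orf3.aa_seq) < min_aa3:
                continue
            if orf3.end <= orf5.end:
                continue
            if orf3.start >= orf5.end + max_gap:
                continue
            shift = _RESIDUE_TO_SHIFT[(orf3.frame - orf5.frame) % 3]
            window = (max(orf5.start, orf3.start), min(orf5.end, orf3.end))
            pairs.append(OrfPair(orf5=orf5, orf3=orf3, shift=shift, overlap_window=window))
    return sorted(pairs, key=lambda p: (p.orf5.start, p.orf3.start))


def build_fusion(seq: NucSequence | str, orf_pair: OrfPair, site: SlipperySite,
                 mass_table: MassTable | None = None) -> FusionProduct:
    """Fusion peptide produced by slipping at ``site`` inside ``orf_pair``.

    Tandem slippage keeps the 0-frame A-site residue (the same tRNA carries
    it across the slip) and resumes reading one heptamer later in the
    shifted register; single-P slippage keeps only through the P-site
    residue.  Raises if the site lies outside the overlap window, disagrees
    with the pair's shift, or the implied reading hits an internal stop.
    """
    s = seq.seq if isinstance(seq, NucSequence) else seq
    if site.shift != orf_pair.shift:
        raise ValueError(
            f"site shift {site.shift:+d} does not match ORF pair shift {orf_pair.shift:+d}"
        )
    lo, hi = orf_pair.overlap_window
    if not (lo <= site.start and site.end <= hi):
        raise ValueError(
            f"slippery site [{site.start}, {site.end}) outside the overlap "
            f"window [{lo}, {hi}) of the ORF pair"
        )
    p = site.start
    if site.model == "single_P":
        prefix_end = p + 4       # through the P-site codon
        resume = p + 4 + site.shift
    else:                        # tandem (default for canonical/tandem sites)
        prefix_end = p + 7       # through the A-site codon
        resume = p + 7 + site.shift
    if (prefix_end - orf_pair.orf5.start) % 3:
        raise ValueError("slippery site is not in the 5' ORF's reading frame")
    if (resume - orf_pair.orf3.start) % 3:
        raise ValueError("resumed register does not match the 3' ORF's frame")
    prefix = translate(s[orf_pair.orf5.start : prefix_end], 0, "read_through")
    if "*" in prefix:
        at = prefix.index("*")
        codon_start = orf_pair.orf5.start + 3 * at
        raise ValueError(
            f"internal stop {s[codon_start:codon_start + 3]} at {codon_start} "
            "upstream of the slippery site: invalid site/pair combination"
        )
    suffix_full = translate(s[resume:], 0, "read_through")
    stop_at = suffix_full.find("*")
    suffix = suffix_full if stop_at == -1 else suffix_full[:stop_at]
    coding_end3 = orf_pair.orf3.end - (3 if orf_pair.orf3.has_terminal_stop else 0)
    if stop_at != -1 and resume + 3 * stop_at < coding_end3:
        codon_start = resume + 3 * stop_at
        raise ValueError(
            f"internal stop {s[codon_start:codon_start + 3]} at {codon_start} "
            "before the 3' ORF's end: invalid site/pair combination"
        )
    aa = prefix + suffix
    return FusionProduct(
        aa_seq=aa,
        shift_site=site,
        mass_da=average_mass(aa, mass_table),
        parts=(len(prefix), len(suffix)),
    )


def analyze_cds(seq: NucSequence, min_aa5: int = 30, min_aa3: int = 30) -> Optional[dict]:
    """One-stop analysis of a CDS/genomic window: best -1 ORF pair, slippery
    site, fusion product and masses.

    Returns None when no -1 pair with a tandem/single-P site exists.  The
    reported ``slip_codon_number`` is 1-based (codon 1 = the 5' ORF's first
    codon), the convention used in human-facing gene reports.
    """
    for pair in find_orf_pairs(seq, min_aa5=min_aa5, min_aa3=min_aa3):
        if pair.shift != -1:
            continue
        lo, hi = pair.overlap_window
        for site in scan_slippery(seq, mode="relaxed", shift=-1):
            if not (lo <= site.start and site.end <= hi):
                continue
            if (site.start + 1 - pair.orf5.start) % 3:
                continue  # heptamer not registered on the 5' ORF's codons
            try:
                fusion = build_fusion(seq, pair, site)
            except ValueError:
                continue
            aa5 = pair.orf5.aa_seq
            return {
                "orf_pair": pair,
                "site": site,
                "fusion": fusion,
                "slip_codon_number": (site.start + 1 - pair.orf5.start) // 3 + 1,
                "mass5_da": average_mass(aa5),
                "fusion_mass_da": fusion.mass_da,
            }
    return None
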