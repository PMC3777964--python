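"""Nucleotide sequence containers, FASTA I/O, translation, ORF finding and
protein mass computation.

All coordinates in this package are 0-based, half-open.  DNA is the internal
alphabet: RNA input is accepted everywhere and normalized to DNA (U -> T),
with the original spelling remembered on the container so reports can echo
it back.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "NucSequence",
    "OpenReadingFrame",
    "MassTable",
    "FastaParseError",
    "read_sequences",
    "write_sequences",
    "translate",
    "find_orfs",
    "average_mass",
    "reverse_complement",
]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class FastaParseError(ValueError):
    """Raised for malformed FASTA input; names the offending line."""


def _normalize(residues: str, *, context: str = "sequence") -> tuple[str, bool]:
    """Uppercase, normalize U->T; reject anything outside A/C/G/T/U.

    Returns (dna, was_rna).
    """
    up = residues.upper()
    was_rna = "U" in up
    dna = up.replace("U", "T")
    bad = sorted(set(dna) - set("ACGT"))
    if bad:
        raise ValueError(
            f"non-IUPAC nucleotide letter(s) {bad!r} in {context} "
            "(only A/C/G/T/U are supported; ambiguity codes are not)"
        )
    return dna, was_rna


@dataclass(frozen=True)
class NucSequence:
    """A named nucleotide sequence over {A,C,G,T}.

    ``was_rna`` records whether the input spelling used U; coordinates into
    the sequence are 0-based half-open everywhere in this package.
    """

    id: str
    seq: str
    was_rna: bool = False

    @classmethod
    def from_string(cls, id: str, residues: str) -> "NucSequence":
        dna, was_rna = _normalize(residues, context=f"sequence {id!r}")
        return cls(id=id, seq=dna, was_rna=was_rna)

    def __len__(self) -> int:
        return len(self.seq)

    def __getitem__(self, item) -> str:
        return self.seq[item]

    def reverse_complement(self) -> "NucSequence":
        return NucSequence(self.id, reverse_complement(self.seq), self.was_rna)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def read_sequences(path: str | Path) -> list[NucSequence]:
    """Read a (multi-)FASTA file into NucSequence records.

    RNA spelling is accepted and normalized; record order is preserved;
    duplicate ids are rejected.  A record body appearing before any header
    is reported with its line number.
    """
    path = Path(path)
    # Cheap pre-scan so parse errors can name the line; Biopython silently
    # skips leading junk, which would hide malformed input.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: sequence data before the first "
                    f"'>' header: {stripped[:30]!r}"
                )
            break
    out: list[NucSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaParseError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        out.append(NucSequence.from_string(rec.id, str(rec.seq)))
    return out


def write_sequences(seqs: Iterable[NucSequence], path: str | Path, width: int = 60) -> None:
    records = [SeqRecord(Seq(s.seq), id=s.id, description="") for s in seqs]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def translate(seq: NucSequence | str, start: int = 0, stop_policy: str = "truncate_at_stop") -> str:
    """Translate from ``start`` with the standard genetic code.

    ``truncate_at_stop`` ends the peptide before the first stop codon;
    ``read_through`` renders every codon, stops included, as '*'.  A trailing
    partial codon is dropped.
    """
    s = seq.seq if isinstance(seq, NucSequence) else seq
    if not 0 <= start <= len(s):
        raise ValueError(f"start {start} outside sequence of length {len(s)}")
    if stop_policy not in ("truncate_at_stop", "read_through"):
        raise ValueError(f"unknown stop_policy {stop_policy!r}")
    trimmed = s[start : start + 3 * ((len(s) - start) // 3)]
    aa = str(Seq(trimmed).translate())
    if stop_policy == "truncate_at_stop":
        cut = aa.find("*")
        if cut != -1:
            aa = aa[:cut]
    return aa


@dataclass(frozen=True)
class OpenReadingFrame:
    """A reading frame segment: [start, end) with end - start % 3 == 0.

    ``frame`` is relative to the window start (position mod 3); ``aa_seq``
    excludes the terminal stop when ``has_terminal_stop`` is set.
    """

    start: int
    end: int
    frame: int
    aa_seq: str
    has_terminal_stop: bool

    def __post_init__(self):
        if (self.end - self.start) % 3:
            raise ValueError("ORF length must be a multiple of 3")
        expect = (self.end - self.start) // 3 - (1 if self.has_terminal_stop else 0)
        if len(self.aa_seq) != expect:
            raise ValueError("aa_seq length inconsistent with coordinates")


def find_orfs(seq: NucSequence | str, min_aa: int = 1, require_atg: bool = False) -> list[OpenReadingFrame]:
    """Report ORFs in all three frames of the given strand, sorted by start.

    Without ``require_atg`` ORFs are stop-to-stop segments (clipped at the
    window edges); with it each segment starts at its first ATG.  Segments
    shorter than ``min_aa`` amino acids are dropped.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    s = seq.seq if isinstance(seq, NucSequence) else seq
    orfs: list[OpenReadingFrame] = []
    for frame in range(3):
        seg_start = frame
        pos = frame
        while pos + 3 <= len(s):
            codon = s[pos : pos + 3]
            if codon in STOP_CODONS:
                orfs.extend(_segment_orf(s, seg_start, pos + 3, frame, True, min_aa, require_atg))
                seg_start = pos + 3
            pos += 3
        orfs.extend(_segment_orf(s, seg_start, pos, frame, False, min_aa, require_atg))
    return sorted(orfs, key=lambda o: (o.start, o.end))


def _segment_orf(s, seg_start, seg_end, frame, has_stop, min_aa, require_atg):
    if require_atg:
        coding_end = seg_end - 3 if has_stop else seg_end
        atg = -1
        for p in range(seg_start, coding_end, 3):
            if s[p : p + 3] == "ATG":
                atg = p
                break
        if atg == -1:
            return []
        seg_start = atg
    if seg_end - seg_start < 3:
        return []
    aa = translate(s[seg_start:seg_end], 0, "truncate_at_stop")
    if len(aa) < min_aa:
        return []
    return [OpenReadingFrame(seg_start, seg_end, frame, aa, has_stop)]


# Standard average and monoisotopic residue masses (Da); chain mass is the
# residue sum plus one water.
_AVERAGE_RESIDUE = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
_MONO_RESIDUE = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276, "V": 99.06841,
    "T": 101.04768, "C": 103.00919, "L": 113.08406, "I": 113.08406,
    "N": 114.04293, "D": 115.02694, "Q": 128.05858, "K": 128.09496,
    "E": 129.04259, "M": 131.04049, "H": 137.05891, "F": 147.06841,
    "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}


@dataclass(frozen=True)
class MassTable:
    """Amino-acid residue masses plus the mass of one water."""

    residue: dict = field(default_factory=lambda: dict(_AVERAGE_RESIDUE))
    water_mass: float = 18.0153

    @classmethod
    def average(cls) -> "MassTable":
        return cls()

    @classmethod
    def monoisotopic(cls) -> "MassTable":
        return cls(residue=dict(_MONO_RESIDUE), water_mass=18.010565)


def average_mass(aa_seq: str, table: MassTable | None = None) -> float:
    """Mass in Da of a peptide: sum of residue masses plus one water.

    Average masses by default (gel-style kDa figures); pass
    ``MassTable.monoisotopic()`` for monoisotopic values.
    """
    table = table or MassTable.average()
    total = table.water_mass
    for aa in aa_seq:
        try:
            total += table.residue[aa]
        except KeyError:
            raise ValueError(f"unknown amino-acid letter {aa!r}") from None
    return total
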