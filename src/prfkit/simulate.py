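"""Synthetic inputs with known ground truth.

Three generators cover everything the pipeline consumes:

* ``make_cassette`` -- a frameshift cassette [5' ORF][slippery heptamer]
  [spacer][H-type pseudoknot][out-of-frame 3' ORF] with a truth record
  (heptamer offset, stem coordinates, intended fusion protein).  Random
  filler is re-checked against the detectors; if an accidental structure
  would outscore the planted one, or a stray stop breaks a reading, the
  filler is redrawn, so round-trip recovery is exact by construction.
* ``make_family`` -- an ortholog family evolved on a tree with compensatory
  stem substitutions and optional 3'-ORF loss on designated edges.
* ``make_reporter`` -- six-replicate dual-reporter measurements with
  multiplicative log-normal noise around a true efficiency.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Optional

import dendropy
import numpy as np

from .frameshift import build_fusion, find_orf_pairs
from .reporter import ReporterDataset
from .sequences import NucSequence, STOP_CODONS, find_orfs
from .slippery import evaluate_site, scan_slippery
from .structure import FoldParams, predict_pseudoknot, shift_structure

__all__ = [
    "CassetteSpec",
    "FamilySpec",
    "ReporterSpec",
    "make_cassette",
    "make_family",
    "make_reporter",
]

_WC = {"G": "C", "C": "G", "A": "T", "T": "A"}


class UnsatisfiableSpec(ValueError):
    """The requested geometry cannot be realized."""


@dataclass(frozen=True)
class CassetteSpec:
    """Blueprint for one planted cassette.

    Stem lengths are base-pair counts; ``loop_lens`` are the L1/L2/L3 loop
    lengths of the pseudoknot (L1 between the stem-1 and stem-2 left arms,
    L2 between the stem-2 left arm and the stem-1 right arm, L3 before the
    stem-2 right arm).  The 3'-ORF length counts codons translated after
    the slip.
    """

    heptamer: str = "TTTTTCC"
    spacer_nt: int = 2
    stem1_len: int = 7
    stem2_len: int = 5
    stem1_bulge_nt: int = 3
    loop_lens: tuple[int, int, int] = (2, 2, 6)
    orf5_aa: int = 12
    orf3_aa: int = 14
    shift: int = -1
    seed: int = 0
    gc_stem_fraction: float = 0.7


@dataclass(frozen=True)
class FamilySpec:
    """Blueprint for an ortholog family evolved on a tree."""

    newick: str
    rate: float = 0.02            # expected substitutions per structure site per edge
    compensatory_fraction: float = 1.0
    loss_edges: tuple = ()        # child-node names whose subtrees lose the 3' ORF
    seed: int = 0


@dataclass(frozen=True)
class ReporterSpec:
    """Blueprint for a dual-reporter measurement pair (test vs control)."""

    true_efficiency_percent: float = 1.0
    n_replicates: int = 6
    cv: float = 0.1
    seed: int = 0
    base_ratio: float = 30.0      # control-construct luciferase / beta-gal
    bgal_level: float = 1000.0


def _random_codon(rng, forbid_stops=True) -> str:
    while True:
        c = "".join(rng.choice(list("ACGT"), size=3))
        if not (forbid_stops and c in STOP_CODONS):
            return c


def _stem_bases(rng, n, gc_fraction) -> str:
    bases = []
    for _ in range(n):
        if rng.random() < gc_fraction:
            bases.append(rng.choice(["G", "C"]))
        else:
            bases.append(rng.choice(["A", "T"]))
    return "".join(bases)


def _frame_has_stop(s: str, start: int, end: int) -> bool:
    for q in range(start, end - 2, 3):
        if s[q : q + 3] in STOP_CODONS:
            return True
    return False


def _build_attempt(spec: CassetteSpec, rng) -> tuple[str, dict]:
    h = spec.heptamer.upper().replace("U", "T")
    if len(h) != 7 or any(b not in "ACGT" for b in h):
        raise UnsatisfiableSpec(f"heptamer must be 7 nt over ACGT/U, got {spec.heptamer!r}")
    if h[1:4] in STOP_CODONS or h[4:7] in STOP_CODONS:
        raise UnsatisfiableSpec("heptamer's 0-frame P/A codons may not be stops")
    if spec.stem1_len < 3 or spec.stem2_len < 3:
        raise UnsatisfiableSpec("stems need at least 3 pairs to be detectable")
    if spec.stem1_bulge_nt and spec.stem1_len < 4:
        raise UnsatisfiableSpec("a bulged stem 1 needs at least 4 pairs")
    if spec.orf5_aa < 3:
        raise UnsatisfiableSpec("5' ORF must have at least 3 codons")

    # --- 5' ORF prefix: ATG + codons, ending 2 nt before the heptamer so the
    # heptamer's P codon sits on the reading frame (heptamer start = 2 mod 3)
    n_pre_codons = max(spec.orf5_aa - 2, 1)
    prefix = "ATG" + "".join(_random_codon(rng) for _ in range(n_pre_codons - 1))
    link = "".join(rng.choice(list("ACGT"), size=2))
    while link + h[0] in STOP_CODONS:
        link = "".join(rng.choice(list("ACGT"), size=2))
    p = len(prefix) + 2  # heptamer offset

    # --- structure
    s1l = _stem_bases(rng, spec.stem1_len, spec.gc_stem_fraction)
    s2l = _stem_bases(rng, spec.stem2_len, spec.gc_stem_fraction)
    s1r = "".join(_WC[b] for b in reversed(s1l))
    if spec.stem1_bulge_nt:
        cut = spec.stem1_len // 2
        bulge = "".join(rng.choice(list("ACGT"), size=spec.stem1_bulge_nt))
        s1r = s1r[:cut] + bulge + s1r[cut:]
    s2r = "".join(_WC[b] for b in reversed(s2l))
    l1, l2, l3 = spec.loop_lens
    # Junction filler (spacer and loops) is drawn from {A, C}: these bases
    # cannot pair with each other, so random filler cannot seed alternative
    # helices that outscore the planted stems (stems themselves stay random).
    spacer = "".join(rng.choice(list("AC"), size=spec.spacer_nt))
    loop1 = "".join(rng.choice(list("AC"), size=l1))
    loop2 = "".join(rng.choice(list("AC"), size=l2))
    loop3 = "".join(rng.choice(list("AC"), size=l3))

    core = spacer + s1l + loop1 + s2l + loop2 + s1r + loop3 + s2r
    seq = prefix + link + h + core
    tail_start = len(seq)

    # --- 3' ORF tail, written on the shifted register (tandem resumption)
    resume = p + 7 + spec.shift
    pad = (resume - len(seq)) % 3
    if pad:
        seq += "".join(rng.choice(list("AC"), size=pad))
    codons_so_far = (len(seq) - resume) // 3
    n_more = max(spec.orf3_aa - codons_so_far, 2)
    # first tail codon also pairing-inert: it abuts the stem-2 right arm
    seq += "".join(rng.choice(list("AC"), size=3))
    seq += "".join(_random_codon(rng) for _ in range(n_more - 1))
    # Plant a 0-frame stop in the tail so the 5' ORF terminates.  The tail's
    # shifted register starts at resume % 3 != 0, so a TAA on a 0-frame
    # boundary can never spell a stop in the shifted reading.
    q = next(q for q in range(tail_start, len(seq) - 2) if q % 3 == 0)
    seq = seq[:q] + "TAA" + seq[q + 3 :]
    seq += "TAA"  # terminal stop of the 3' ORF (shifted register)

    meta = {
        "p": p,
        "resume": resume,
        "s1l_start": p + 7 + spec.spacer_nt,
        "lens": dict(cut=spec.stem1_len // 2),
    }
    return seq, meta


def _planted_pairs(spec: CassetteSpec, meta) -> tuple[tuple, tuple]:
    """Absolute (left, right) pair lists, outside-in, for both stems."""
    a = meta["s1l_start"]
    n1, n2 = spec.stem1_len, spec.stem2_len
    l1, l2, l3 = spec.loop_lens
    s1l = list(range(a, a + n1))
    s2l_start = a + n1 + l1
    s2l = list(range(s2l_start, s2l_start + n2))
    s1r_start = s2l_start + n2 + l2
    s1r_len = n1 + spec.stem1_bulge_nt
    s1r_end = s1r_start + s1r_len          # half-open
    s2r_start = s1r_end + l3
    s2r = list(range(s2r_start, s2r_start + n2))
    # right-arm paired positions: written 5'->3' as revcomp(s1l) with the
    # bulge inserted after `cut` bases
    cut = meta["lens"]["cut"]
    right_positions = list(range(s1r_start, s1r_end))
    if spec.stem1_bulge_nt:
        del right_positions[cut : cut + spec.stem1_bulge_nt]
    # right_positions[i] pairs s1l[n1 - 1 - i]
    stem1 = tuple((s1l[n1 - 1 - i], pos) for i, pos in enumerate(right_positions))[::-1]
    stem1 = tuple(sorted(stem1))  # outside-in: ascending left
    stem2 = tuple((s2l[n2 - 1 - i], pos) for i, pos in enumerate(s2r))[::-1]
    stem2 = tuple(sorted(stem2))
    return stem1, stem2


_PAIRABLE = {("G", "C"), ("C", "G"), ("A", "T"), ("T", "A"), ("G", "T"), ("T", "G")}


def _has_displacing_extension(seq: str, stems, occupied) -> bool:
    """True if any planted helix end could grow by a pair that would raise
    (or tie, which the tie-break also loses) the planted structure's score:
    a direct extension by any legal pair, or a 1-2 nt bulged extension by a
    G.C pair."""
    n = len(seq)
    for pairs in stems:
        ends = [
            (pairs[0][0], pairs[0][1], -1, +1),   # outward from the outer pair
            (pairs[-1][0], pairs[-1][1], +1, -1),  # inward from the inner pair
        ]
        for l0, r0, dl, dr in ends:
            for bl in range(0, 3):
                for br in range(0, 3):
                    if bl and br:
                        continue  # bulges are one-sided
                    lp = l0 + dl * (1 + bl)
                    rp = r0 + dr * (1 + br)
                    if not (0 <= lp < rp < n):
                        continue
                    if lp in occupied or rp in occupied:
                        continue
                    duo = (seq[lp], seq[rp])
                    if (bl or br) and duo not in (("G", "C"), ("C", "G")):
                        continue
                    if duo in _PAIRABLE:
                        return True
    return False


def make_cassette(spec: CassetteSpec, fold_params: FoldParams | None = None,
                  max_attempts: int = 200) -> tuple[NucSequence, dict]:
    """Generate a cassette and its truth record; deterministic given seed.

    The truth record carries the heptamer offset, planted stem pairs (absolute
    coordinates), spacer/bulge geometry, the ORF pair and the intended fusion
    peptide.  Each attempt is validated with the package's own detectors and
    redrawn on collision (a stray stop codon or an accidental structure that
    would outscore the planted one), so acceptance of a returned cassette
    certifies exact round-trip recovery.
    """
    if spec.shift not in (-1, 1):
        raise UnsatisfiableSpec("shift must be -1 or +1")
    fold_params = fold_params or FoldParams()
    if spec.stem1_bulge_nt > fold_params.max_bulge_len:
        raise UnsatisfiableSpec("stem-1 bulge exceeds the fold search's bulge cap")
    if max(spec.stem1_len, spec.stem2_len) > fold_params.max_stem:
        raise UnsatisfiableSpec("stem length exceeds the fold search's stem cap")
    if max(spec.loop_lens) > fold_params.max_loop:
        raise UnsatisfiableSpec("loop length exceeds the fold search's loop cap")
    ss = np.random.SeedSequence(entropy=spec.seed, spawn_key=(0xCA55,))
    for attempt, child in enumerate(ss.spawn(max_attempts)):
        rng = np.random.default_rng(child)
        seq, meta = _build_attempt(spec, rng)
        p, resume = meta["p"], meta["resume"]
        # reading-frame checks (cheap, so they run before any folding)
        if _frame_has_stop(seq, 0, p + 1):
            continue
        if _frame_has_stop(seq, resume, len(seq) - 3):
            continue
        if not _frame_has_stop(seq, p + 7, len(seq)):
            continue
        stem1, stem2 = _planted_pairs(spec, meta)
        occupied = {q for pair in stem1 + stem2 for q in pair}
        if _has_displacing_extension(seq, (stem1, stem2), occupied):
            continue
        site = evaluate_site(seq, p, spec.shift)
        if site is None:
            continue
        found = [s for s in scan_slippery(seq, "relaxed", spec.shift) if s.start == p]
        if site.model == "tandem" and not found:
            continue
        # the planted structure must be the certified argmax on the window
        window = seq[p + 7 :]
        pk = predict_pseudoknot(window, fold_params)
        if pk is None:
            continue
        pk_abs = shift_structure(pk, p + 7)
        if tuple(pk_abs.stem1.pairs) != stem1 or tuple(pk_abs.stem2.pairs) != stem2:
            continue
        nuc = NucSequence(f"cassette_seed{spec.seed}", seq)
        pairs = [op for op in find_orf_pairs(nuc) if op.shift == spec.shift
                 and op.overlap_window[0] <= p and p + 7 <= op.overlap_window[1]]
        fusion = None
        if pairs and site.model in ("tandem", "single_P"):
            try:
                fusion = build_fusion(nuc, pairs[0], site)
            except ValueError:
                continue
        if fusion is None:
            continue
        truth = {
            "heptamer_offset": p,
            "heptamer": site.heptamer,
            "shift": spec.shift,
            "model": site.model,
            "spacer_nt": spec.spacer_nt,
            "stem1_pairs": stem1,
            "stem2_pairs": stem2,
            "stem1_bulge_nt": spec.stem1_bulge_nt,
            "loops": spec.loop_lens,
            "orf5": (pairs[0].orf5.start, pairs[0].orf5.end),
            "orf3": (pairs[0].orf3.start, pairs[0].orf3.end),
            "fusion_aa": fusion.aa_seq,
            "attempt": attempt,
        }
        return nuc, truth
    raise UnsatisfiableSpec(
        f"no satisfying cassette in {max_attempts} attempts; the requested "
        "geometry is likely too constrained (very short stems or loops)"
    )


# ---------------------------------------------------------------------------
# ortholog families


def _structure_sites(truth) -> dict:
    """Paired and loop positions of the planted structure, absolute coords."""
    paired = {}
    for l, r in truth["stem1_pairs"] + truth["stem2_pairs"]:
        paired[l] = r
        paired[r] = l
    lo = min(paired)
    hi = max(paired)
    loops = [q for q in range(lo, hi + 1) if q not in paired]
    return {"paired": paired, "loops": loops}


def make_family(spec: FamilySpec, base: CassetteSpec):
    """Evolve a cassette family on a tree.

    Returns (sequences, tree_newick, states, truth).  Substitutions hit the
    structure region only: a stem position mutates compensatorily (both
    partners replaced by a different Watson-Crick pair) with probability
    ``compensatory_fraction``, otherwise one-sidedly (disruptive); loop
    positions mutate freely.  A substitution that would create a stop in
    either reading of the overlap is redrawn.  Leaves below ``loss_edges``
    are truncated at the 5' ORF's stop -- they have no reachable 3' ORF.
    """
    tree = dendropy.Tree.get(data=spec.newick, schema="newick", preserve_underscores=True)
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(leaves) < 3:
        raise ValueError("family tree needs at least 3 leaves")
    base_seq, truth0 = make_cassette(base)
    sites = _structure_sites(truth0)
    p = truth0["heptamer_offset"]
    resume = p + 7 + base.shift
    rng = np.random.default_rng(np.random.SeedSequence(entropy=spec.seed, spawn_key=(0xFA81,)))

    node_seq = {}
    lost = set()
    comp_events = []  # (leaf-agnostic) per-edge events; leaf truth derived below

    def ok(seq_list) -> bool:
        s = "".join(seq_list)
        return not (_frame_has_stop(s, 0, p + 1) or _frame_has_stop(s, resume, len(s) - 3))

    for node in tree.preorder_node_iter():
        name = node.taxon.label if node.is_leaf() else (node.label or "")
        if node.parent_node is None:
            node_seq[node] = list(base_seq.seq)
            continue
        seq = list(node_seq[node.parent_node])
        is_lost = node.parent_node in lost or name in spec.loss_edges
        if is_lost:
            lost.add(node)
        n_sub = rng.poisson(spec.rate * (len(sites["paired"]) + len(sites["loops"])))
        candidates = sorted(sites["paired"]) + sites["loops"]
        for _ in range(n_sub):
            for _try in range(20):
                pos = int(rng.choice(candidates))
                old = seq[pos]
                if pos in sites["paired"]:
                    partner = sites["paired"][pos]
                    if rng.random() < spec.compensatory_fraction:
                        choices = [(a, _WC[a]) for a in "ACGT"
                                   if a != old and _WC[a] != seq[partner]]
                        a, b = choices[int(rng.integers(len(choices)))]
                        trial = list(seq)
                        trial[pos], trial[partner] = a, b
                    else:
                        a = rng.choice([x for x in "ACGT" if x != old])
                        trial = list(seq)
                        trial[pos] = a
                else:
                    a = rng.choice([x for x in "ACGT" if x != old])
                    trial = list(seq)
                    trial[pos] = a
                if ok(trial):
                    seq = trial
                    break
        node_seq[node] = seq

    sequences = []
    states = {}
    for lf in tree.leaf_node_iter():
        name = lf.taxon.label
        s = "".join(node_seq[lf])
        if lf in lost or any(a in lost for a in lf.ancestor_iter()):
            # truncate at the 5' ORF's stop: no joinable 3' ORF remains
            orf5 = next(o for o in find_orfs(s) if o.start == 0 and o.has_terminal_stop)
            s = s[: orf5.end]
            states[name] = "absent"
        else:
            states[name] = "present"
        sequences.append(NucSequence(name, s))

    ref = sequences[0] if states[sequences[0].id] == "present" else None
    # leaf-level compensatory truth vs the base cassette
    base_s = base_seq.seq
    for nuc in sequences:
        if states[nuc.id] != "present":
            continue
        for l, r in truth0["stem1_pairs"] + truth0["stem2_pairs"]:
            a, b = base_s[l], base_s[r]
            x, y = nuc.seq[l], nuc.seq[r]
            if (x, y) != (a, b) and x != a and y != b and _WC[x] == y:
                comp_events.append({"leaf": nuc.id, "pair": (l, r),
                                    "from": a + b, "to": x + y})
    truth = {
        "base": truth0,
        "states": states,
        "loss_edges": list(spec.loss_edges),
        "compensatory": comp_events,
    }
    return sequences, spec.newick, states, truth


# ---------------------------------------------------------------------------
# dual-reporter measurements


def _lognormal_around(rng, mean: float, cv: float, size: int) -> np.ndarray:
    if cv <= 0:
        return np.full(size, mean)
    sigma = float(np.sqrt(np.log1p(cv * cv)))
    z = rng.standard_normal(size)
    return mean * np.exp(sigma * z - sigma * sigma / 2.0)


def make_reporter(spec: ReporterSpec, names: tuple[str, str] = ("test", "control")
                  ) -> tuple[ReporterDataset, ReporterDataset]:
    """Simulate (test, control) datasets around a true efficiency.

    Beta-gal levels and luciferase/beta-gal ratios are drawn log-normally
    (multiplicative noise, mean-exact) with coefficient of variation ``cv``;
    the test construct's true ratio is base_ratio * efficiency/100.
    """
    if spec.n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=spec.seed, spawn_key=(0x4E9,)))
    out = []
    for name, ratio in [(names[0], spec.base_ratio * spec.true_efficiency_percent / 100.0),
                        (names[1], spec.base_ratio)]:
        bgal = _lognormal_around(rng, spec.bgal_level, spec.cv, spec.n_replicates)
        ratios = _lognormal_around(rng, ratio, spec.cv, spec.n_replicates)
        reps = tuple((float(b), float(b * r)) for b, r in zip(bgal, ratios))
        out.append(ReporterDataset(construct=name, replicates=reps))
    return out[0], out[1]
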