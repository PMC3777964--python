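"""Independent brute-force oracles used by the test suite.

Each oracle re-derives a result by direct enumeration, structured
differently from the package's implementation, so agreement is meaningful.
"""

from __future__ import annotations

import itertools

STOPS = {"TAA", "TAG", "TGA"}
PAIR_SCORES = {
    ("G", "C"): 3.0, ("C", "G"): 3.0,
    ("A", "T"): 2.0, ("T", "A"): 2.0,
    ("G", "T"): 1.0, ("T", "G"): 1.0,
}


# --- ORFs -----------------------------------------------------------------

def brute_orfs(seq: str, min_aa: int = 1, require_atg: bool = False):
    """Every ORF as (start, end, frame, aa_len, has_stop), by scanning every
    (start, frame) pair directly."""
    out = set()
    n = len(seq)
    for frame in range(3):
        boundaries = [frame]
        for q in range(frame, n - 2, 3):
            if seq[q : q + 3] in STOPS:
                boundaries.append(q + 3)
        # segment ends
        segs = []
        prev = frame
        for b in boundaries[1:]:
            segs.append((prev, b, True))
            prev = b
        tail_end = frame + 3 * ((n - frame) // 3)
        segs.append((prev, tail_end, False))
        for start, end, has_stop in segs:
            if require_atg:
                found = None
                search_end = end - 3 if has_stop else end
                for q in range(start, search_end, 3):
                    if seq[q : q + 3] == "ATG":
                        found = q
                        break
                if found is None:
                    continue
                start = found
            aa_len = (end - start) // 3 - (1 if has_stop else 0)
            if aa_len >= min_aa and end > start:
                out.add((start, end, frame, aa_len, has_stop))
    return out


# --- structure ------------------------------------------------------------

def enumerate_stems_naive(seq: str, min_stem=3, max_stem=12, max_bulges=2,
                          max_bulge_len=5, min_inner_gap=0,
                          bulge_open=2.0, bulge_per_nt=0.5):
    """All stems as (score, pairs), by breadth-first growth from every
    outermost pair; includes every inward truncation explicitly."""
    n = len(seq)
    results = []
    frontier = []
    for l in range(n):
        for r in range(n - 1, l + min_inner_gap, -1):
            if (seq[l], seq[r]) in PAIR_SCORES:
                frontier.append(((l, r),))
    while frontier:
        nxt = []
        for pairs in frontier:
            score = stem_score(seq, pairs, bulge_open, bulge_per_nt)
            if len(pairs) >= min_stem:
                results.append((score, pairs))
            if len(pairs) >= max_stem:
                continue
            l, r = pairs[-1]
            n_bulges = sum(
                1 for (a, b), (c, d) in zip(pairs, pairs[1:])
                if c - a > 1 or b - d > 1
            )
            for dl in range(1, max_bulge_len + 2):
                for dr in range(1, max_bulge_len + 2):
                    if dl > 1 and dr > 1:
                        continue
                    bulged = dl > 1 or dr > 1
                    if bulged and n_bulges >= max_bulges:
                        continue
                    l2, r2 = l + dl, r - dr
                    if r2 - l2 - 1 < min_inner_gap or r2 <= l2:
                        continue
                    if (seq[l2], seq[r2]) in PAIR_SCORES:
                        nxt.append(pairs + ((l2, r2),))
        frontier = nxt
    return results


def stem_score(seq, pairs, bulge_open=2.0, bulge_per_nt=0.5):
    s = sum(PAIR_SCORES[(seq[l], seq[r])] for l, r in pairs)
    for (a, b), (c, d) in zip(pairs, pairs[1:]):
        if c - a > 1:
            s -= bulge_open + bulge_per_nt * (c - a - 1)
        if b - d > 1:
            s -= bulge_open + bulge_per_nt * (b - d - 1)
    return s


def best_pseudoknot_score_naive(seq: str, max_loop=30, min_score=12.0, **kw):
    """Max total score over all legal crossing stem pairs, or None."""
    stems = enumerate_stems_naive(seq, min_inner_gap=0, **kw)
    best = None
    for sc1, s1 in stems:
        for sc2, s2 in stems:
            if best is not None and sc1 + sc2 <= best:
                continue
            pos1 = {q for pr in s1 for q in pr}
            pos2 = {q for pr in s2 for q in pr}
            if pos1 & pos2:
                continue
            l1 = s2[0][0] - s1[-1][0] - 1
            l2 = s1[-1][1] - s2[-1][0] - 1
            l3 = s2[-1][1] - s1[0][1] - 1
            if min(l1, l2, l3) < 0 or max(l1, l2, l3) > max_loop:
                continue
            if s2[-1][1] <= s1[0][1]:
                continue
            best = sc1 + sc2
    if best is None or best < min_score:
        return None
    return best


def best_hairpin_score_naive(seq: str, min_hairpin_loop=3, max_loop=30,
                             min_score=12.0, **kw):
    stems = enumerate_stems_naive(seq, min_inner_gap=min_hairpin_loop, **kw)
    best = None
    for sc, pairs in stems:
        loop = pairs[-1][1] - pairs[-1][0] - 1
        if loop > max_loop:
            continue
        if best is None or sc > best:
            best = sc
    if best is None or best < min_score:
        return None
    return best


# --- parsimony ------------------------------------------------------------

def min_changes_exhaustive(tree, states):
    """Minimum state changes over all ancestral assignments, by enumeration.

    ``tree`` is a dendropy.Tree; leaves take their fixed state.
    """
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    leaves = [n for n in tree.leaf_node_iter()]
    best = None
    for combo in itertools.product(["present", "absent"], repeat=len(internals)):
        assign = dict(zip(internals, combo))
        for lf in leaves:
            assign[lf] = states[lf.taxon.label]
        changes = sum(
            1
            for node in tree.preorder_node_iter()
            if node.parent_node is not None and assign[node] != assign[node.parent_node]
        )
        if best is None or changes < best:
            best = changes
    return best


# --- alignment ------------------------------------------------------------

def best_affine_alignment_score(s1: str, s2: str, match=2.0, mismatch=-1.0,
                                gap_open=-5.0, gap_extend=-1.0):
    """Optimal global affine-gap score by enumerating all alignments
    recursively (tiny inputs only)."""
    best = [float("-inf")]

    def rec(i, j, score, state):
        if i == len(s1) and j == len(s2):
            best[0] = max(best[0], score)
            return
        if i < len(s1) and j < len(s2):
            rec(i + 1, j + 1, score + (match if s1[i] == s2[j] else mismatch), "m")
        if i < len(s1):
            pen = gap_extend if state == "g1" else gap_open
            rec(i + 1, j, score + pen, "g1")
        if j < len(s2):
            pen = gap_extend if state == "g2" else gap_open
            rec(i, j + 1, score + pen, "g2")

    rec(0, 0, 0.0, "start")
    return best[0]


# --- Mann-Whitney ---------------------------------------------------------

def mw_exact_p_naive(x, y):
    """Two-sided exact p by enumerating labelings; U from rank sums."""
    from scipy.stats import rankdata

    nx, ny = len(x), len(y)
    pooled = list(x) + list(y)

    def u_of(idx_x):
        ranks = rankdata(pooled)
        rx = sum(ranks[i] for i in idx_x)
        return rx - nx * (nx + 1) / 2

    # relabelings permute which indices are "x"
    obs = u_of(range(nx))
    obs_m = min(obs, nx * ny - obs)
    hits = total = 0
    for comb in itertools.combinations(range(nx + ny), nx):
        u = u_of(comb)
        if min(u, nx * ny - u) <= obs_m + 1e-9:
            hits += 1
        total += 1
    return hits / total
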