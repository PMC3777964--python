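"""Minimum-change mapping of a binary character (3'-ORF presence) on a tree.

Fitch-style parsimony, implemented as unit-cost Sankoff dynamic programming
so multifurcating nodes are handled exactly.  The reconstruction resolves
ties deterministically: the root prefers "absent" (the outgroup condition),
and every other node prefers its parent's state (no change) when both states
tie -- which for a binary character reproduces the classic Fitch up-pass.
State changes are reported as gain (absent -> present) or loss events on the
edge above the node where the state flips.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy

__all__ = ["CharacterTree", "FitchEvent", "fitch_map", "read_states_tsv"]

PRESENT, ABSENT = "present", "absent"
_STATES = (ABSENT, PRESENT)  # order encodes the root tie preference
_INF = float("inf")


@dataclass(frozen=True)
class FitchEvent:
    """A state change on the edge above ``node`` (a leaf name or inner label)."""

    node: str
    kind: str  # gain | loss


@dataclass
class CharacterTree:
    """A rooted tree with binary leaf states and (after mapping) the
    reconstruction and its gain/loss events."""

    tree: dendropy.Tree
    states: dict[str, str]
    reconstruction: dict = field(default_factory=dict)
    events: list[FitchEvent] = field(default_factory=list)
    n_changes: int | None = None

    @classmethod
    def from_files(cls, newick_path: str | Path, states_path: str | Path) -> "CharacterTree":
        tree = dendropy.Tree.get(path=str(newick_path), schema="newick",
                                 preserve_underscores=True)
        return cls(tree=tree, states=read_states_tsv(states_path))


def read_states_tsv(path: str | Path) -> dict[str, str]:
    """Two-column TSV: leaf name, state in {present, absent} (or 1/0)."""
    out = {}
    alias = {"1": PRESENT, "0": ABSENT, PRESENT: PRESENT, ABSENT: ABSENT}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, raw = line.split("\t")[:2]
            try:
                out[name] = alias[raw.strip().lower()]
            except KeyError:
                raise ValueError(f"unrecognized state {raw!r} for leaf {name!r}") from None
    return out


def _node_name(node: dendropy.Node) -> str:
    if node.taxon is not None and node.taxon.label:
        return node.taxon.label
    if node.label:
        return node.label
    # stable fallback for unlabeled internal nodes
    first = next(node.leaf_iter())
    return f"clade_of_{_node_name(first)}"


def fitch_map(tree: CharacterTree) -> CharacterTree:
    """Fill in the minimum-change reconstruction and its events.

    Bottom-up pass: cost[node][state] = sum over children of
    min(cost[child][s'] + [s != s']).  Top-down pass resolves states with
    the deterministic tie rules and emits gain/loss events where a child's
    state differs from its parent's.  Raises on a leaf without a state,
    naming it.
    """
    t = tree.tree
    cost: dict[dendropy.Node, dict[str, float]] = {}
    for node in t.postorder_node_iter():
        if node.is_leaf():
            name = _node_name(node)
            if name not in tree.states:
                raise ValueError(f"leaf {name!r} has no character state")
            obs = tree.states[name]
            cost[node] = {s: (0.0 if s == obs else _INF) for s in _STATES}
        else:
            cost[node] = {
                s: sum(
                    min(cost[ch][s2] + (0 if s2 == s else 1) for s2 in _STATES)
                    for ch in node.child_nodes()
                )
                for s in _STATES
            }
    root = t.seed_node
    best = min(cost[root].values())
    root_state = next(s for s in _STATES if cost[root][s] == best)  # tie -> absent
    assign: dict[dendropy.Node, str] = {root: root_state}
    events: list[FitchEvent] = []
    for node in t.preorder_node_iter():
        if node is root:
            continue
        parent_state = assign[node.parent_node]
        scores = {s: cost[node][s] + (0 if s == parent_state else 1) for s in _STATES}
        m = min(scores.values())
        if scores[parent_state] == m:
            state = parent_state  # tie or win -> no change
        else:
            state = next(s for s in _STATES if scores[s] == m)
        assign[node] = state
        if state != parent_state:
            kind = "gain" if state == PRESENT else "loss"
            events.append(FitchEvent(node=_node_name(node), kind=kind))
    tree.reconstruction = {_node_name(n): s for n, s in assign.items()}
    tree.events = events
    tree.n_changes = int(best)
    if len(events) != tree.n_changes:
        raise AssertionError("event count disagrees with the DP minimum")
    return tree
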