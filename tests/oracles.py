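"""Independent brute-force oracles used by the test suite.

These deliberately re-derive scores by exhaustive enumeration rather than
calling the package's algorithms, so they can certify minimality of the
reconciliation and parsimony reconstructions on small instances.
"""

from __future__ import annotations

import itertools
import random

from intronevo.trees import RootedTree


# ---------------------------------------------------------------- reconcile
def reconciliation_mapping_cost(gtree, stree, mapping, gene_to_species) -> int:
    """Duplication + loss cost of one ancestor-consistent mapping."""

    def species_below(v):
        if v.is_leaf:
            return {gene_to_species[v.id]}
        out = set()
        for c in v.children:
            out |= species_below(c)
        return out

    dups = losses = 0
    for v in gtree.preorder():
        if v.is_leaf:
            continue
        mv = stree[mapping[v.id]]
        spans = []
        for c in v.children:
            sp = species_below(c)
            spans.append(frozenset(
                x.id for x in mv.children if stree.leaf_set_below(x) & sp))
        dup = mv.is_leaf or any(spans[i] & spans[j]
                                for i in range(len(spans))
                                for j in range(i + 1, len(spans)))
        if dup:
            dups += 1
        for c in v.children:
            mc = stree[mapping[c.id]]
            if mc is mv:
                continue
            path = stree.path_down(mv.id, mc.id)
            losses += len(path) - 2
            if dup:
                losses += 1
    return dups + losses


def min_reconciliation_cost(gtree, stree, gene_to_species) -> int:
    """Exhaustive minimum over all ancestor-consistent mappings."""
    internal = [v for v in gtree.postorder() if not v.is_leaf]
    snodes = list(stree.preorder())
    mapping = {l.id: gene_to_species[l.id] for l in gtree.leaves()}
    best = [None]

    def rec(i):
        if i == len(internal):
            c = reconciliation_mapping_cost(gtree, stree, mapping,
                                            gene_to_species)
            best[0] = c if best[0] is None else min(best[0], c)
            return
        v = internal[i]
        for s in snodes:
            if all(stree.is_ancestor_or_equal(s.id, mapping[c.id])
                   for c in v.children):
                mapping[v.id] = s.id
                rec(i + 1)
                del mapping[v.id]

    rec(0)
    return best[0]


def random_tree(leaves, rng: random.Random, allow_polytomy: bool) -> str:
    items = list(leaves)
    rng.shuffle(items)
    while len(items) > 1:
        k = rng.choice([2, 2, 2, 3]) if (allow_polytomy and len(items) >= 3) else 2
        grp = [items.pop() for _ in range(min(k, len(items)))]
        items.append("(" + ",".join(grp) + ")")
        rng.shuffle(items)
    return "[&R] " + items[0] + ";"


# ------------------------------------------------------------- dollo/fitch
def _assignments(stree, leaf_states):
    """Yield full present/absent assignments; missing leaves are free."""
    nodes = list(stree.preorder())
    fixed = {n.id: leaf_states[n.id] for n in nodes
             if n.is_leaf and leaf_states.get(n.id) is not None}
    free = [n.id for n in nodes if n.id not in fixed]
    for bits in itertools.product((False, True), repeat=len(free)):
        assign = dict(fixed)
        assign.update(zip(free, bits))
        yield assign


def _edge_changes(stree, assign, count_root_as_gain=True):
    """Gain/loss edges of an assignment; optionally the root's presence is
    itself counted as the (single) gain, as Dollo requires."""
    gains = losses = 0
    for n in stree.preorder():
        state = assign[n.id]
        if n.parent is None:
            if state and count_root_as_gain:
                gains += 1
            continue
        pstate = assign[n.parent.id]
        if state and not pstate:
            gains += 1
        elif pstate and not state:
            losses += 1
    return gains, losses


def min_dollo_losses(stree: RootedTree, leaf_states) -> int:
    """Min losses over single-gain assignments (root presence counts as the
    gain). Returns None when no possessor exists."""
    if not any(v for v in leaf_states.values() if v):
        return None
    best = None
    for assign in _assignments(stree, leaf_states):
        gains, losses = _edge_changes(stree, assign)
        if gains != 1:
            continue
        best = losses if best is None else min(best, losses)
    return best


def min_fitch_changes(stree: RootedTree, leaf_states) -> int:
    """Min total state changes over all assignments."""
    best = None
    for assign in _assignments(stree, leaf_states):
        gains, losses = _edge_changes(stree, assign, count_root_as_gain=False)
        total = gains + losses
        best = total if best is None else min(best, total)
    return best
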