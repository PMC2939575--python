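"""Ancestral intron complements and per-branch gain/loss events.

Reconstruction runs on a *composite tree*: the species tree replicated per
gene lineage, with the lineages stitched together at the duplication nodes
the reconciliation placed. A duplication copies the gene as-is, so the state
at a daughter lineage's origin node is inherited from the parent lineage
(introns cannot be lost "inside" the instantaneous duplication; they can be
gained between the duplication and the next speciation, which is why gains
may sit on a lineage's origin). Each composite branch corresponds to a
species-tree branch within one lineage, so every inferred event lands on a
(species branch, gene lineage) pair — the currency of the evolutionary
pathway.

Dollo parsimony: each intron site is gained exactly once, at the composite
LCA of the genes possessing it, and lost on the minimal set of branches
below. Missing states (gene lost in that species, or region not covered by
the alignment) are non-informative: they never induce events. A Fitch
(unordered two-state) reconstruction permitting multiple gains is provided
as a sensitivity check.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional

import pandas as pd

from .intron_homology import ABSENT, MISSING, PRESENT, IntronSiteMatrix
from .reconcile import Reconciliation
from .trees import RootedTree, TreeError

log = logging.getLogger(__name__)

__all__ = ["CompositeTree", "CompositeNode", "AncestralStates", "Event",
           "EventHistory", "dollo_reconstruct", "fitch_reconstruct",
           "infer_events", "summarize_pathway", "PathwaySummary"]

Key = tuple[str, str]  # (lineage id, species node id)


@dataclass(eq=False)
class CompositeNode:
    lineage: str
    species_node: str
    parent: Optional["CompositeNode"] = None
    via_duplication: bool = False      # edge from parent crosses a duplication
    children: list["CompositeNode"] = field(default_factory=list)
    gene_id: Optional[str] = None      # attached gene for composite leaves
    depth: int = 0

    @property
    def key(self) -> Key:
        return (self.lineage, self.species_node)

    @property
    def is_leaf(self) -> bool:
        return not self.children


class CompositeTree:
    """Species tree x gene lineages, stitched at duplications.

    Each lineage occupies the part of the species tree spanning its origin
    node, its member genes' species, and the origins of its daughter
    lineages; species branches with no surviving descendant of the lineage
    are pruned (their states would be unobservable).
    """

    def __init__(self, rec: Reconciliation, genes: list[str]):
        self.rec = rec
        stree = rec.species_tree
        gene_set = set(genes)

        # species nodes each lineage must span
        targets: dict[str, set[str]] = {lid: set() for lid in rec.lineages}
        self.gene_at: dict[Key, str] = {}
        for lid, lin in rec.lineages.items():
            for gid in lin.genes:
                if gid not in gene_set:
                    continue
                sp = rec.gene_to_species[gid]
                targets[lid].add(sp)
                key = (lid, sp)
                if key in self.gene_at:
                    raise TreeError(
                        f"two genes of lineage {lid} in species {sp}: "
                        f"{self.gene_at[key]} and {gid}")
                self.gene_at[key] = gid
        # a parent lineage must reach every daughter origin that survives
        order = self._lineage_order(rec)
        for lid in reversed(order):
            lin = rec.lineages[lid]
            if targets[lid] and lin.parent is not None:
                targets[lin.parent].add(lin.origin_species)

        self.nodes: dict[Key, CompositeNode] = {}
        self.root: Optional[CompositeNode] = None
        for lid in order:
            lin = rec.lineages[lid]
            if not targets[lid]:
                continue
            span: set[str] = {lin.origin_species}
            for t in targets[lid]:
                span.update(n.id for n in stree.path_down(lin.origin_species, t))
            # build lineage subtree in species preorder
            for snode in stree.preorder():
                if snode.id not in span:
                    continue
                node = CompositeNode(lineage=lid, species_node=snode.id)
                if snode.id == lin.origin_species:
                    if lin.parent is None:
                        self.root = node
                    else:
                        parent = self.nodes[(lin.parent, lin.origin_species)]
                        node.parent = parent
                        node.via_duplication = True
                        parent.children.append(node)
                else:
                    parent = self.nodes[(lid, snode.parent.id)]
                    node.parent = parent
                    parent.children.append(node)
                self.nodes[node.key] = node
        if self.root is None:
            raise TreeError("empty composite tree: no genes attached")
        for node in self.preorder():
            node.depth = 0 if node.parent is None else node.parent.depth + 1
            key = (node.lineage, node.species_node)
            if key in self.gene_at and node.is_leaf:
                node.gene_id = self.gene_at[key]
        self.leaf_of_gene = {n.gene_id: n for n in self.preorder()
                             if n.gene_id is not None}

    @staticmethod
    def _lineage_order(rec: Reconciliation) -> list[str]:
        order, seen = [], set()
        children: dict[Optional[str], list[str]] = {}
        for lid, lin in rec.lineages.items():
            children.setdefault(lin.parent, []).append(lid)
        stack = sorted(children.get(None, []), reverse=True)
        while stack:
            lid = stack.pop()
            if lid in seen:
                continue
            seen.add(lid)
            order.append(lid)
            stack.extend(sorted(children.get(lid, []), reverse=True))
        return order

    def preorder(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def lca(self, nodes: list[CompositeNode]) -> CompositeNode:
        cur = nodes[0]
        for other in nodes[1:]:
            a, b = cur, other
            while a is not b:
                if a.depth < b.depth:
                    b = b.parent
                elif a.depth > b.depth:
                    a = a.parent
                else:
                    a, b = a.parent, b.parent
            cur = a
        return cur


@dataclass
class AncestralStates:
    """Per (species node, gene lineage, site) presence states."""

    composite: CompositeTree
    site_ids: list[str]
    present: dict[str, set[Key]]          # site -> composite keys reconstructed present
    gain_node: dict[str, Key]             # site -> composite key of the single gain
    method: str = "dollo"
    changes_per_site: dict[str, int] = field(default_factory=dict)
    dropped_sites: list[str] = field(default_factory=list)

    def state(self, species_node: str, lineage: str, site_id: str) -> str:
        return PRESENT if (lineage, species_node) in self.present[site_id] else ABSENT

    def complement(self, species_node: str, lineage: str) -> list[str]:
        """Intron sites reconstructed present for one lineage at one node."""
        key = (lineage, species_node)
        return [s for s in self.site_ids if key in self.present[s]]

    def root_complement(self) -> list[str]:
        root = self.composite.root
        return self.complement(root.species_node, root.lineage)

    def losses_per_site(self) -> dict[str, int]:
        out = {}
        for site in self.site_ids:
            pres = self.present[site]
            n = 0
            for node in self.composite.preorder():
                if node.parent is None:
                    continue
                if node.parent.key in pres and node.key not in pres:
                    n += 1
            out[site] = n
        return out


def _informative(matrix: IntronSiteMatrix, site_id: str,
                 composite: CompositeTree):
    """Leaves with observed present / observed absent state at a site."""
    possessors, absentees = [], []
    for gid in matrix.genes:
        node = composite.leaf_of_gene.get(gid)
        if node is None:
            continue
        s = matrix.state(gid, site_id)
        if s == PRESENT:
            possessors.append(node)
        elif s == ABSENT:
            absentees.append(node)
    return possessors, absentees


def dollo_reconstruct(matrix: IntronSiteMatrix, stree: RootedTree,
                      rec: Reconciliation) -> AncestralStates:
    """Dollo parsimony over the composite tree.

    Per site: the gain sits at the composite LCA of the possessing genes;
    every node on a path from the gain to a possessor is present; elsewhere
    a subtree is dropped to absent as early as possible, except that a
    daughter lineage's origin always inherits the parent lineage's state
    (losses cannot ride on the duplication itself) and subtrees containing
    no informative leaf keep the parental state (no event is charged where
    no gene survives to witness one).
    """
    composite = CompositeTree(rec, matrix.genes)
    present: dict[str, set[Key]] = {}
    gain_node: dict[str, Key] = {}
    dropped: list[str] = []

    # which composite nodes have any informative leaf below (per site this
    # also needs possessor info; precompute descendant leaves per node)
    desc_leaves: dict[Key, list[CompositeNode]] = {}

    def collect(node: CompositeNode) -> list[CompositeNode]:
        if node.is_leaf:
            leaves = [node] if node.gene_id is not None else []
        else:
            leaves = []
            for ch in node.children:
                leaves.extend(collect(ch))
        desc_leaves[node.key] = leaves
        return leaves

    collect(composite.root)

    for site in [s.site_id for s in matrix.sites]:
        possessors, absentees = _informative(matrix, site, composite)
        if not possessors:
            log.warning("site %s present in zero genes; dropped", site)
            dropped.append(site)
            continue
        gain = composite.lca(possessors)
        pres: set[Key] = set()
        forced: set[Key] = set()
        for leaf in possessors:
            node = leaf
            while node is not gain:
                forced.add(node.key)
                node = node.parent
            forced.add(gain.key)
        absent_genes = {n.gene_id for n in absentees}

        def assign(node: CompositeNode, state: bool) -> None:
            if state:
                pres.add(node.key)
            for ch in node.children:
                if not state:
                    assign(ch, False)
                elif ch.key in forced:
                    assign(ch, True)
                elif ch.via_duplication:
                    assign(ch, True)  # inherited across the duplication
                else:
                    informative = any(l.gene_id in absent_genes
                                      for l in desc_leaves[ch.key])
                    # no possessors below (else forced); lose at this edge
                    # if anything below witnesses absence, otherwise keep
                    # the parental state without charging an event
                    assign(ch, not informative)

        assign(gain, True)
        present[site] = pres
        gain_node[site] = gain.key

    site_ids = [s.site_id for s in matrix.sites if s.site_id in present]
    return AncestralStates(composite=composite, site_ids=site_ids,
                           present=present, gain_node=gain_node,
                           method="dollo", dropped_sites=dropped)


def fitch_reconstruct(matrix: IntronSiteMatrix, stree: RootedTree,
                      rec: Reconciliation) -> AncestralStates:
    """Unordered two-state parsimony (multiple gains allowed) per site.

    Unit-cost Sankoff over the composite tree; ties at the root resolve
    toward present, and a child tied between states keeps its parent's.
    ``changes_per_site`` carries the minimal change counts. The gain_node
    map is only filled for sites whose optimal history has a single gain.
    """
    composite = CompositeTree(rec, matrix.genes)
    INF = 10 ** 9
    present: dict[str, set[Key]] = {}
    gains_all: dict[str, Key] = {}
    changes: dict[str, int] = {}
    dropped: list[str] = []

    order = list(composite.preorder())
    for site in [s.site_id for s in matrix.sites]:
        possessors, absentees = _informative(matrix, site, composite)
        if not possessors:
            dropped.append(site)
            continue
        observed = {n.gene_id: True for n in possessors}
        observed.update({n.gene_id: False for n in absentees})
        cost: dict[Key, tuple[int, int]] = {}
        for node in reversed(order):
            if node.is_leaf:
                if node.gene_id in observed:
                    state = observed[node.gene_id]
                    cost[node.key] = (INF, 0) if state else (0, INF)
                else:
                    cost[node.key] = (0, 0)
            else:
                c0 = c1 = 0
                for ch in node.children:
                    k0, k1 = cost[ch.key]
                    c0 += min(k0, k1 + 1)
                    c1 += min(k0 + 1, k1)
                cost[node.key] = (c0, c1)
        r0, r1 = cost[composite.root.key]
        changes[site] = min(r0, r1)
        pres: set[Key] = set()
        state_of: dict[Key, bool] = {}
        for node in order:
            k0, k1 = cost[node.key]
            if node.parent is None:
                state = k1 <= k0  # tie -> present at the root
            else:
                pstate = state_of[node.parent.key]
                a = k0 + (1 if pstate else 0)
                b = k1 + (0 if pstate else 1)
                state = b < a or (b == a and pstate)
            state_of[node.key] = state
            if state:
                pres.add(node.key)
        present[site] = pres
        # single-gain detection for the gain_node map
        gain_edges = [n.key for n in order
                      if state_of[n.key] and (n.parent is None or
                                              not state_of[n.parent.key])]
        if len(gain_edges) == 1:
            gains_all[site] = gain_edges[0]

    site_ids = [s.site_id for s in matrix.sites if s.site_id in present]
    return AncestralStates(composite=composite, site_ids=site_ids,
                           present=present, gain_node=gains_all,
                           method="fitch", changes_per_site=changes,
                           dropped_sites=dropped)


# ---------------------------------------------------------------------------
# events
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Event:
    kind: str                  # "loss" | "gain"
    lineage: str
    branch_child: str          # species node id (branch above it); the
    site_id: str               # lineage origin for gains at a duplication
    at_root: bool = False      # gain that is part of the root state


@dataclass
class EventHistory:
    composite: CompositeTree
    events: list[Event]
    root_complement: list[str]
    site_ancestral_number: dict[str, Optional[int]] = field(default_factory=dict)

    def losses(self) -> list[Event]:
        return [e for e in self.events if e.kind == "loss"]

    def gains(self) -> list[Event]:
        return [e for e in self.events if e.kind == "gain" and not e.at_root]

    def losses_by_branch(self) -> dict[tuple[str, str], list[str]]:
        out: dict[tuple[str, str], list[str]] = {}
        for e in self.losses():
            out.setdefault((e.lineage, e.branch_child), []).append(e.site_id)
        return {k: sorted(v) for k, v in out.items()}

    # ------------------------------------------------------------- replay
    def replay(self) -> dict[str, set[str]]:
        """Replay events from the root state; returns per-gene intron sites."""
        losses = self.losses_by_branch()
        gains: dict[tuple[str, str], list[str]] = {}
        for e in self.gains():
            gains.setdefault((e.lineage, e.branch_child), []).append(e.site_id)
        out: dict[str, set[str]] = {}

        def walk(node: CompositeNode, state: set[str]) -> None:
            key = (node.lineage, node.species_node)
            state = set(state)
            state.update(gains.get(key, ()))
            state.difference_update(losses.get(key, ()))
            if node.gene_id is not None:
                out[node.gene_id] = state
            for ch in node.children:
                walk(ch, state)

        walk(self.composite.root, set(self.root_complement))
        return out

    def to_json(self) -> str:
        by_branch: dict[str, dict] = {}
        for e in self.events:
            if e.at_root:
                continue
            entry = by_branch.setdefault(e.branch_child, {})
            lin = entry.setdefault(e.lineage, {"losses": [], "gains": []})
            lin["losses" if e.kind == "loss" else "gains"].append(e.site_id)
        return json.dumps({
            "root_complement": sorted(self.root_complement),
            "branches": by_branch,
            "site_ancestral_number": self.site_ancestral_number,
        }, indent=2, sort_keys=True)

    def to_annotated_newick(self) -> str:
        """Species tree with per-branch event comments."""
        losses = self.losses_by_branch()
        gains = {(e.lineage, e.branch_child) for e in self.gains()}
        stree = self.composite.rec.species_tree

        def note(node_id: str) -> str:
            parts = []
            for (lid, b), sites in sorted(losses.items()):
                if b == node_id:
                    parts.append(f"{lid}-losses={'/'.join(sites)}")
            for lid, b in sorted(gains):
                if b == node_id:
                    parts.append(f"{lid}-gain")
            return f"[&{','.join(parts)}]" if parts else ""

        def fmt(node) -> str:
            if node.is_leaf:
                return node.id + note(node.id)
            inner = ",".join(fmt(c) for c in node.children)
            return f"({inner}){node.id}{note(node.id)}"

        return f"[&R] {fmt(stree.root)};"


def infer_events(states: AncestralStates,
                 stree: Optional[RootedTree] = None,
                 matrix: Optional[IntronSiteMatrix] = None) -> EventHistory:
    """Read per-branch events off reconstructed states.

    A loss is recorded on a branch for a site iff the site is present at the
    branch's parent and absent at its child; gains analogously (for Dollo
    there is exactly one gain per site, at its gain node).
    """
    composite = states.composite
    events: list[Event] = []
    for site in states.site_ids:
        pres = states.present[site]
        for node in composite.preorder():
            key = node.key
            if node.parent is None:
                if key in pres:
                    events.append(Event("gain", node.lineage, node.species_node,
                                        site, at_root=True))
                continue
            pkey = node.parent.key
            if pkey in pres and key not in pres:
                events.append(Event("loss", node.lineage, node.species_node, site))
            elif pkey not in pres and key in pres:
                events.append(Event("gain", node.lineage, node.species_node, site))
    numbers = {}
    if matrix is not None:
        numbers = {s.site_id: s.ancestral_number for s in matrix.sites}
    return EventHistory(composite=composite, events=events,
                        root_complement=states.root_complement(),
                        site_ancestral_number=numbers)


# ---------------------------------------------------------------------------
# pathway summary
# ---------------------------------------------------------------------------

@dataclass
class PathwaySummary:
    branch_table: pd.DataFrame          # per (lineage, branch): losses/gains
    cumulative: pd.DataFrame            # per gene: losses along its root path
    n_loss_branches: int                # distinct (lineage, branch) with >=1 loss
    total_site_losses: int
    total_gains: int
    max_cumulative_by_lineage: dict[str, int]

    def to_tsv(self) -> str:
        return self.branch_table.to_csv(sep="\t", index=False)


def summarize_pathway(h: EventHistory) -> PathwaySummary:
    """Branch-level and path-cumulative summaries of an event history.

    The branch count follows the convention that one "event" is one
    (species branch x gene lineage) carrying at least one intron loss; the
    per-site loss totals are reported alongside. Cumulative losses for a
    gene sum the losses on every branch of its composite root-to-leaf path
    (crossing duplications), i.e. the number of ancestral-gene introns its
    lineage has shed since the root.
    """
    losses = h.losses_by_branch()
    rows = [{"lineage": lid, "branch_child": b, "n_losses": len(sites),
             "sites": ",".join(sites)}
            for (lid, b), sites in sorted(losses.items())]
    gains = h.gains()
    for e in sorted(gains, key=lambda e: (e.lineage, e.branch_child, e.site_id)):
        rows.append({"lineage": e.lineage, "branch_child": e.branch_child,
                     "n_losses": 0, "sites": f"+{e.site_id}"})
    branch_table = pd.DataFrame(rows, columns=["lineage", "branch_child",
                                               "n_losses", "sites"])

    cum_rows = []
    max_by_lineage: dict[str, int] = {}
    for gene_id, leaf in sorted(h.composite.leaf_of_gene.items()):
        total = 0
        node = leaf
        while node is not None:
            total += len(losses.get((node.lineage, node.species_node), ()))
            node = node.parent
        cum_rows.append({"gene_id": gene_id, "lineage": leaf.lineage,
                         "cumulative_losses": total})
        max_by_lineage[leaf.lineage] = max(max_by_lineage.get(leaf.lineage, 0),
                                           total)
    cumulative = pd.DataFrame(cum_rows, columns=["gene_id", "lineage",
                                                 "cumulative_losses"])
    return PathwaySummary(
        branch_table=branch_table,
        cumulative=cumulative,
        n_loss_branches=len(losses),
        total_site_losses=sum(len(v) for v in losses.values()),
        total_gains=len(gains),
        max_cumulative_by_lineage=max_by_lineage)
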