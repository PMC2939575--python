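"""Gene-tree / species-tree reconciliation by LCA mapping under
duplication-loss parsimony.

Each gene-tree node ``v`` maps to ``M(v)``, the last common ancestor (in the
species tree) of the species of the gene leaves below it. An internal node
is a duplication when its children's lineages cannot be separated by any
(resolution of the) species node it maps to; with a binary species node this
reduces to the classical rule ``M(v) == M(child)``. Species-tree polytomies
are treated as soft: they never force duplications or losses that some
binary resolution would avoid.

Losses are charged per gene-tree edge ``(v, c)``: one loss for every species
node the lineage passes through strictly between ``M(v)`` and ``M(c)``, plus
one at ``M(v)`` itself when ``v`` is a duplication and ``M(c)`` lies strictly
below it. Each charged node places the loss on its off-path child branch
(branches are addressed by their child node id); at a polytomy with several
off-path children a single loss is recorded against the polytomy node itself
and flagged ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import pandas as pd

from .trees import Node, RootedTree, TreeError

__all__ = ["Reconciliation", "GeneLossEvent", "Lineage", "lca_map",
           "report_gene_losses", "MappingError"]

SPECIATION, DUPLICATION, LEAF = "speciation", "duplication", "leaf"


class MappingError(TreeError):
    pass


@dataclass(frozen=True)
class GeneLossEvent:
    """One lost gene lineage, addressed by the species branch it was lost on."""

    branch_child: str          # species node id (the branch above it)
    lineage: str               # lineage of the surviving sister gene copy
    gene_edge: tuple[str, str]  # (parent, child) gene-tree nodes implying it
    ambiguous: bool = False    # True when charged to an unresolved polytomy


@dataclass
class Lineage:
    """A gene lineage: a maximal duplication-free piece of the gene tree."""

    id: str
    parent: Optional[str]
    origin_species: str        # species node where the lineage arose
    origin_gene_node: str
    genes: list[str] = field(default_factory=list)


@dataclass
class Reconciliation:
    gene_tree: RootedTree
    species_tree: RootedTree
    gene_to_species: dict[str, str]
    mapping: dict[str, str]            # gene node id -> species node id
    events: dict[str, str]             # gene node id -> speciation/duplication/leaf
    losses: list[GeneLossEvent]
    lineages: dict[str, Lineage]
    gene_lineage: dict[str, str]       # gene leaf -> lineage id

    @property
    def duplication_nodes(self) -> list[str]:
        return [n for n, e in self.events.items() if e == DUPLICATION]

    def duplications_per_branch(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for n in self.duplication_nodes:
            out[self.mapping[n]] = out.get(self.mapping[n], 0) + 1
        return out

    @property
    def total_losses(self) -> int:
        return len(self.losses)

    @property
    def score(self) -> int:
        """Duplication + loss parsimony score."""
        return len(self.duplication_nodes) + len(self.losses)

    def branch_table(self) -> pd.DataFrame:
        """Per species-tree branch duplication/loss counts."""
        rows = []
        dups = self.duplications_per_branch()
        losses: dict[str, int] = {}
        for ev in self.losses:
            losses[ev.branch_child] = losses.get(ev.branch_child, 0) + 1
        for node_id in sorted(set(dups) | set(losses)):
            rows.append({"branch_child": node_id,
                         "duplications": dups.get(node_id, 0),
                         "gene_losses": losses.get(node_id, 0)})
        return pd.DataFrame(rows, columns=["branch_child", "duplications",
                                           "gene_losses"])

    def to_dict(self) -> dict:
        return {
            "mapping": dict(self.mapping),
            "events": {k: v for k, v in self.events.items() if v != LEAF},
            "losses": [{"branch_child": ev.branch_child, "lineage": ev.lineage,
                        "gene_edge": list(ev.gene_edge),
                        "ambiguous": ev.ambiguous} for ev in self.losses],
            "lineages": {lid: {"parent": l.parent,
                               "origin_species": l.origin_species,
                               "genes": l.genes}
                         for lid, l in self.lineages.items()},
            "score": self.score,
        }


def _entry_span(stree: RootedTree, mv: Node, species_of_child: frozenset[str]) -> frozenset[str]:
    """Children of M(v) through which a gene child's species descend."""
    out = set()
    for ch in mv.children:
        if stree.leaf_set_below(ch) & species_of_child:
            out.add(ch.id)
    return frozenset(out)


def lca_map(gtree: RootedTree, stree: RootedTree,
            gene_to_species: Mapping[str, str]) -> Reconciliation:
    """Reconcile a rooted gene tree with a rooted species tree.

    ``gene_to_species`` maps every gene-tree leaf label to a species-tree
    leaf label. Unmapped gene leaves raise :class:`MappingError` naming the
    leaf.
    """
    mapping: dict[str, str] = {}
    species_sets: dict[str, frozenset[str]] = {}
    events: dict[str, str] = {}

    for node in gtree.postorder():
        if node.is_leaf:
            sp = gene_to_species.get(node.id)
            if sp is None:
                raise MappingError(f"gene leaf {node.id!r} has no species mapping")
            if sp not in stree or not stree[sp].is_leaf:
                raise MappingError(
                    f"gene leaf {node.id!r} maps to {sp!r}, not a species-tree leaf")
            mapping[node.id] = sp
            species_sets[node.id] = frozenset({sp})
            events[node.id] = LEAF
        else:
            child_maps = [mapping[c.id] for c in node.children]
            mv = stree.lca(child_maps)
            mapping[node.id] = mv.id
            species_sets[node.id] = frozenset().union(
                *(species_sets[c.id] for c in node.children))
            if mv.is_leaf:
                # all children within one species: necessarily a duplication
                events[node.id] = DUPLICATION
                continue
            spans = [_entry_span(stree, mv, species_sets[c.id])
                     for c in node.children]
            dup = False
            for i in range(len(spans)):
                for j in range(i + 1, len(spans)):
                    if spans[i] & spans[j]:
                        dup = True
            events[node.id] = DUPLICATION if dup else SPECIATION

    # ---- lineages: cut the gene tree at duplication nodes -----------------
    lineages: dict[str, Lineage] = {}
    gene_lineage: dict[str, str] = {}
    counter = [0]

    def new_lineage(parent: Optional[str], origin_species: str,
                    origin_gene_node: str) -> str:
        counter[0] += 1
        lid = f"L{counter[0]}"
        lineages[lid] = Lineage(id=lid, parent=parent,
                                origin_species=origin_species,
                                origin_gene_node=origin_gene_node)
        return lid

    root_lid = new_lineage(None, mapping[gtree.root.id], gtree.root.id)
    lineage_of_node: dict[str, str] = {}
    stack = [(gtree.root, root_lid)]
    while stack:
        node, lid = stack.pop()
        lineage_of_node[node.id] = lid
        if node.is_leaf:
            lineages[lid].genes.append(node.id)
            gene_lineage[node.id] = lid
            continue
        if events[node.id] == DUPLICATION:
            for child in node.children:
                child_lid = new_lineage(lid, mapping[node.id], child.id)
                stack.append((child, child_lid))
        else:
            for child in node.children:
                stack.append((child, lid))
    for lin in lineages.values():
        lin.genes.sort()

    # ---- implied gene losses ---------------------------------------------
    losses: list[GeneLossEvent] = []
    for node in gtree.preorder():
        if node.is_leaf:
            continue
        mv = stree[mapping[node.id]]
        dup = events[node.id] == DUPLICATION
        for child in node.children:
            mc = stree[mapping[child.id]]
            if mc is mv:
                continue
            path = stree.path_down(mv.id, mc.id)  # mv .. mc inclusive
            charged = path[1:-1]                  # strict intermediates
            if dup:
                charged = [mv] + charged
            for s, nxt in zip(charged, _next_on_path(path, charged, mc)):
                off_path = [c for c in s.children if c is not nxt]
                lid = lineage_of_node[child.id]
                if len(off_path) == 1:
                    losses.append(GeneLossEvent(
                        branch_child=off_path[0].id, lineage=lid,
                        gene_edge=(node.id, child.id)))
                else:
                    losses.append(GeneLossEvent(
                        branch_child=s.id, lineage=lid,
                        gene_edge=(node.id, child.id), ambiguous=True))

    return Reconciliation(gene_tree=gtree, species_tree=stree,
                          gene_to_species=dict(gene_to_species),
                          mapping=mapping, events=events, losses=losses,
                          lineages=lineages, gene_lineage=gene_lineage)


def _next_on_path(path, charged, mc):
    """For each charged node, the path child the gene lineage descends into."""
    nxt = {path[i].id: path[i + 1] for i in range(len(path) - 1)}
    return [nxt[s.id] for s in charged]


def report_gene_losses(rec: Reconciliation, stree: Optional[RootedTree] = None
                       ) -> pd.DataFrame:
    """Per species-tree branch table of lost gene lineages."""
    rows: dict[tuple[str, str], int] = {}
    for ev in rec.losses:
        key = (ev.branch_child, ev.lineage)
        rows[key] = rows.get(key, 0) + 1
    table = pd.DataFrame(
        [{"branch_child": b, "lineage": lid, "n_lost": n}
         for (b, lid), n in sorted(rows.items())],
        columns=["branch_child", "lineage", "n_lost"])
    return table
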