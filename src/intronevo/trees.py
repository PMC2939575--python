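"""Rooted-tree utilities shared by reconciliation and event reconstruction.

Newick I/O is delegated to DendroPy; internally trees are plain parent/child
node records because the reconciliation and parsimony code needs stable node
identifiers (branches are addressed by their child node), cheap LCA queries on
small trees, and polytomy-safe traversal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import dendropy

__all__ = ["Node", "RootedTree", "UnrootedTreeError", "TreeError"]


class TreeError(ValueError):
    pass


class UnrootedTreeError(TreeError):
    """Raised when an input tree cannot be taken as rooted.

    Trees are never silently rooted: a newick tree flagged ``[&U]``, or an
    unflagged tree whose basal node is a trifurcation, must be rooted by the
    caller first.
    """


@dataclass(eq=False)
class Node:
    id: str
    label: Optional[str] = None
    parent: Optional["Node"] = None
    children: list["Node"] = field(default_factory=list)
    depth: int = 0

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.id!r})"


class RootedTree:
    """A rooted tree with uniquely identified nodes; polytomies are allowed.

    Node ids are taken from newick labels where present (leaf labels must be
    unique); unlabeled internal nodes get deterministic ``_n<k>`` ids assigned
    in preorder.
    """

    def __init__(self, root: Node):
        self.root = root
        self.nodes: dict[str, Node] = {}
        for node in self.preorder():
            if node.id in self.nodes:
                raise TreeError(f"duplicate node id {node.id!r}")
            self.nodes[node.id] = node
            node.depth = 0 if node.parent is None else node.parent.depth + 1

    # ------------------------------------------------------------------ I/O
    @classmethod
    def from_newick(cls, source: str, *, assume_rooted: bool = False) -> "RootedTree":
        """Parse a rooted newick tree from a string or a file path."""
        data = source
        if "(" not in source:  # looks like a path
            with open(source) as fh:
                data = fh.read()
        try:
            dtree = dendropy.Tree.get(data=data, schema="newick",
                                      suppress_internal_node_taxa=True)
        except Exception as exc:
            raise TreeError(f"could not parse newick input: {exc}") from exc
        stripped = data.strip().lower()
        explicitly_unrooted = stripped.startswith("[&u]")
        explicitly_rooted = stripped.startswith("[&r]") or dtree.is_rooted
        basal = dtree.seed_node
        if not assume_rooted:
            if explicitly_unrooted:
                raise UnrootedTreeError("tree is flagged [&U]; root it explicitly")
            if not explicitly_rooted and len(basal.child_nodes()) > 2:
                raise UnrootedTreeError(
                    "basal trifurcation without an [&R] flag reads as unrooted; "
                    "root the tree or pass assume_rooted=True")

        counter = [0]

        def build(dnode, parent: Optional[Node]) -> Node:
            if dnode.is_leaf():
                label = dnode.taxon.label if dnode.taxon else dnode.label
                if label is None:
                    raise TreeError("unlabeled leaf in newick input")
                nid = str(label).replace(" ", "_")
            else:
                label = dnode.label
                if label:
                    nid = str(label).replace(" ", "_")
                else:
                    nid = f"_n{counter[0]}"
                    counter[0] += 1
            node = Node(id=nid, label=label, parent=parent)
            for child in dnode.child_nodes():
                node.children.append(build(child, node))
            return node

        return cls(build(basal, None))

    def to_newick(self) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                return node.id
            inner = ",".join(fmt(c) for c in node.children)
            return f"({inner}){node.id}"

        return f"[&R] {fmt(self.root)};"

    # ------------------------------------------------------------ traversal
    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def leaves(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_ids(self) -> list[str]:
        return [n.id for n in self.leaves()]

    def __getitem__(self, node_id: str) -> Node:
        try:
            return self.nodes[node_id]
        except KeyError:
            raise TreeError(f"no node {node_id!r} in tree") from None

    def __contains__(self, node_id: str) -> bool:
        return node_id in self.nodes

    # ------------------------------------------------------------- queries
    def lca(self, node_ids: Iterable[str]) -> Node:
        nodes = [self[i] for i in node_ids]
        if not nodes:
            raise TreeError("lca of empty node set")
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

    def is_ancestor_or_equal(self, anc_id: str, desc_id: str) -> bool:
        node = self[desc_id]
        anc = self[anc_id]
        while node is not None:
            if node is anc:
                return True
            node = node.parent
        return False

    def path_down(self, anc_id: str, desc_id: str) -> list[Node]:
        """Nodes from ``anc`` to ``desc`` inclusive, following parent links."""
        if not self.is_ancestor_or_equal(anc_id, desc_id):
            raise TreeError(f"{anc_id!r} is not an ancestor of {desc_id!r}")
        path = []
        node = self[desc_id]
        anc = self[anc_id]
        while node is not anc:
            path.append(node)
            node = node.parent
        path.append(anc)
        return list(reversed(path))

    def leaf_set_below(self, node: Node) -> frozenset[str]:
        if node.is_leaf:
            return frozenset({node.id})
        out: set[str] = set()
        for child in node.children:
            out |= self.leaf_set_below(child)
        return frozenset(out)

    def n_nodes(self) -> int:
        return len(self.nodes)

    def copy(self) -> "RootedTree":
        return RootedTree.from_newick(self.to_newick(), assume_rooted=True)
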