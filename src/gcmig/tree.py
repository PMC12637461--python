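"""Rooted trees with branch lengths in substitutions/site.

A minimal tree representation used for genealogies, imported phylogenies and
parsimony labelling. Newick parsing/serialisation is delegated to scikit-bio;
this module only adds the fields the analyses need (follicle labels, collapsed
leaf weights, stable branch ids).
"""

from __future__ import annotations

import io
from typing import Iterator, Optional

import skbio


class Node:
    __slots__ = ("name", "length", "children", "parent", "label", "weight")

    def __init__(self, name: Optional[str] = None, length: float = 0.0,
                 label=None, weight: int = 1):
        self.name = name
        self.length = float(length)
        self.children: list[Node] = []
        self.parent: Optional[Node] = None
        self.label = label          # follicle id (leaves: observed; internal: inferred)
        self.weight = weight        # UMIs collapsed into this leaf

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal({len(self.children)})"
        return f"<Node {self.name or ''} {kind} len={self.length:.4g} label={self.label}>"


class LineageTree:
    """Rooted lineage tree; branch lengths are substitutions per site."""

    def __init__(self, root: Node, lineage_id: Optional[int] = None):
        self.root = root
        self.lineage_id = lineage_id

    # -- traversal ---------------------------------------------------------
    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out = list(self.preorder())
        return iter(reversed(out))

    def leaves(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    def branches(self) -> list[Node]:
        """Non-root nodes in preorder; index in this list is the branch id."""
        return [n for n in self.preorder() if n.parent is not None]

    # -- measures ----------------------------------------------------------
    @property
    def total_divergence(self) -> float:
        return float(sum(n.length for n in self.branches()))

    def depths(self) -> dict[Node, float]:
        """Root-to-node divergence for every node."""
        out = {self.root: 0.0}
        for node in self.preorder():
            for child in node.children:
                out[child] = out[node] + child.length
        return out

    def n_leaves(self) -> int:
        return sum(1 for _ in self.leaves())

    def copy(self) -> "LineageTree":
        def clone(node: Node) -> Node:
            new = Node(node.name, node.length, node.label, node.weight)
            for child in node.children:
                new.add(clone(child))
            return new

        return LineageTree(clone(self.root), self.lineage_id)

    # -- newick ------------------------------------------------------------
    def to_newick(self) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                core = node.name or ""
            else:
                core = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if node.name:
                    core += node.name
            if node.parent is not None:
                core += f":{node.length:.10g}"
            return core

        return fmt(self.root) + ";"

    @classmethod
    def from_newick(cls, text: str, lineage_id: Optional[int] = None) -> "LineageTree":
        sk = skbio.TreeNode.read(io.StringIO(text))
        return cls(_from_skbio(sk), lineage_id)

    @classmethod
    def from_skbio(cls, sk, lineage_id: Optional[int] = None) -> "LineageTree":
        return cls(_from_skbio(sk), lineage_id)


def _from_skbio(sk) -> Node:
    node = Node(name=sk.name, length=sk.length or 0.0)
    for child in sk.children:
        node.add(_from_skbio(child))
    return node
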