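"""Lightweight rooted-tree structure shared by the simulator and the
phylogenetics module, with Newick I/O through dendropy."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import dendropy


class TreeError(ValueError):
    pass


@dataclass
class Node:
    """A rooted tree node; ``length`` is the branch above the node
    (substitutions/site), ``support`` a bootstrap percentage for internal
    nodes."""

    name: str = ""
    length: float = 0.0
    children: list["Node"] = field(default_factory=list)
    parent: "Node | None" = None
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def preorder(self) -> Iterator["Node"]:
        yield self
        for c in self.children:
            yield from c.preorder()

    def postorder(self) -> Iterator["Node"]:
        for c in self.children:
            yield from c.postorder()
        yield self

    def leaves(self) -> list["Node"]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def find(self, name: str) -> "Node":
        for n in self.preorder():
            if n.name == name:
                return n
        raise KeyError(name)

    def leafset(self) -> frozenset[str]:
        return frozenset(self.leaf_names())


def parse_newick(text: str, require_lengths: bool = True) -> Node:
    """Parse a rooted Newick string; unnamed internal nodes get deterministic
    ``node<i>`` names (preorder). Raises :class:`TreeError` when branch lengths
    are required but missing."""
    dt = dendropy.Tree.get(
        data=text, schema="newick", suppress_internal_node_taxa=True
    )

    counter = [0]

    def conv(dn) -> Node:
        if dn.taxon is not None:
            name = dn.taxon.label
        elif dn.label:
            name = dn.label
        else:
            name = f"node{counter[0]}"
            counter[0] += 1
        length = dn.edge.length
        if length is None:
            if dn.parent_node is not None and require_lengths:
                raise TreeError("tree lacks branch lengths")
            length = 0.0
        node = Node(name=str(name).replace(" ", "_"), length=float(length))
        for c in dn.child_nodes():
            node.add(conv(c))
        return node

    return conv(dt.seed_node)


def to_newick(root: Node, supports: bool = False) -> str:
    """Serialize; with ``supports`` internal labels carry bootstrap %."""

    def rec(n: Node) -> str:
        if n.is_leaf:
            return f"{n.name}:{n.length:g}"
        inner = ",".join(rec(c) for c in n.children)
        if supports and n.support is not None:
            label = f"{n.support:g}"
        else:
            label = n.name
        return f"({inner}){label}:{n.length:g}"

    return rec(root)[: -len(f":{root.length:g}")] + ";"
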