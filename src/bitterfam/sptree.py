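"""Rooted species tree with stable branch identifiers.

The tree is the scaffold on which gene birth/death events are placed. Every
branch (the edge above a node, including a stem edge above the root) carries a
stable string identifier so that event ledgers can be reported per branch in a
fixed numbering convention. Branch identifiers are read from Newick node
labels; a leaf branch without an explicit label defaults to the leaf name.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import skbio


@dataclass
class Node:
    name: str | None = None
    length: float = 0.0
    branch_id: str | None = None
    children: list["Node"] = field(default_factory=list)
    parent: "Node | None" = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaf_names())
        return out


class SpeciesTree:
    """Rooted (binary or multifurcating) species tree over named leaves.

    Parameters
    ----------
    root
        Root node. The root's ``branch_id`` labels the stem edge above the
        root; events placed there predate the crown radiation.
    """

    def __init__(self, root: Node):
        self.root = root
        names = root.leaf_names()
        if len(names) != len(set(names)):
            raise ValueError("leaf names must be unique")
        ids = [n.branch_id for n in self.preorder() if n.branch_id is not None]
        if len(ids) != len(set(ids)):
            raise ValueError("branch identifiers must be unique")
        for n in self.preorder():
            if n.length < 0:
                raise ValueError(f"negative branch length at {n.name or n.branch_id}")
        self._leaves = {n.name: n for n in self.preorder() if n.is_leaf}
        self._by_branch = {n.branch_id: n for n in self.preorder() if n.branch_id}

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "SpeciesTree":
        """Parse a Newick string; node labels become branch identifiers."""
        sk = skbio.TreeNode.read([text])
        return cls(_convert(sk, parent=None))

    @classmethod
    def read(cls, path) -> "SpeciesTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def to_newick(self) -> str:
        return _unparse(self.root) + ";"

    # -- traversal ---------------------------------------------------------

    def preorder(self, node: Node | None = None) -> Iterator[Node]:
        node = node or self.root
        yield node
        for c in node.children:
            yield from self.preorder(c)

    def leaves(self) -> list[Node]:
        return [self._leaves[n] for n in self.root.leaf_names()]

    @property
    def leaf_names(self) -> list[str]:
        return self.root.leaf_names()

    def node_for_branch(self, branch_id: str) -> Node:
        try:
            return self._by_branch[branch_id]
        except KeyError:
            raise KeyError(f"no branch with id {branch_id!r}") from None

    def branch_ids(self) -> list[str]:
        return [n.branch_id for n in self.preorder() if n.branch_id]

    # -- queries -----------------------------------------------------------

    def mrca(self, names) -> Node:
        names = set(names)
        if not names:
            raise ValueError("mrca of an empty species set")
        unknown = names - set(self._leaves)
        if unknown:
            raise KeyError(f"species not in tree: {sorted(unknown)}")
        node = self.root
        while True:
            below = [c for c in node.children if names <= set(c.leaf_names())]
            if len(below) == 1:
                node = below[0]
            else:
                return node

    def path_branches(self, leaf_name: str) -> list[str]:
        """Branch ids from (and including) the root stem down to the leaf."""
        node = self._leaves[leaf_name]
        out = []
        while node is not None:
            if node.branch_id is not None:
                out.append(node.branch_id)
            node = node.parent
        return out[::-1]

    def depth(self, node: Node) -> int:
        d = 0
        while node.parent is not None:
            d += 1
            node = node.parent
        return d


def _convert(sk: "skbio.TreeNode", parent: Node | None) -> Node:
    name = sk.name
    node = Node(
        name=name if not sk.children else None,
        length=float(sk.length) if sk.length is not None else 0.0,
        branch_id=str(name) if name is not None else None,
        parent=parent,
    )
    if node.is_leaf and node.branch_id is None:
        raise ValueError("unnamed leaf in species tree")
    node.children = [_convert(c, node) for c in sk.children]
    if not node.children and node.branch_id is None:
        node.branch_id = node.name
    return node


def _unparse(node: Node) -> str:
    label = node.branch_id or ""
    if node.is_leaf:
        base = node.name if node.name == node.branch_id else f"{node.name}"
    else:
        base = "(" + ",".join(_unparse(c) for c in node.children) + ")" + label
    return f"{base}:{node.length:.6g}"
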