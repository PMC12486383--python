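"""Minimal phylogenetic tree container used by the paralogon machinery.

A tree is a ``Node``; unrooted trees are represented by a top-level node
with three or more children.  Leaf names are plain strings; internal nodes
carry an optional bootstrap ``support`` in [0, 1].  Newick export writes
supports as internal-node labels, matching the common convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class Node:
    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf:
            return [self]
        out: list[Node] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [leaf.name or "" for leaf in self.leaves()]

    def preorder(self):
        yield self
        for c in self.children:
            yield from c.preorder()

    def copy(self) -> "Node":
        return Node(
            name=self.name,
            length=self.length,
            support=self.support,
            children=[c.copy() for c in self.children],
        )

    # -- newick -------------------------------------------------------------

    def to_newick(self, with_lengths: bool = True, _top: bool = True) -> str:
        if self.is_leaf:
            body = self.name or ""
        else:
            inner = ",".join(c.to_newick(with_lengths, _top=False) for c in self.children)
            label = ""
            if self.support is not None:
                label = format(self.support, "g")
            elif self.name:
                label = self.name
            body = f"({inner}){label}"
        if not _top and with_lengths:
            body += f":{format(self.length, 'g')}"
        return body + (";" if _top else "")


def parse_newick(text: str) -> Node:
    """Parse a Newick string into a Node tree.

    Internal node labels that look numeric are read as supports (the
    convention used by :func:`Node.to_newick`), otherwise kept as names.
    """
    s = text.strip().rstrip(";")
    pos = 0

    def parse_node() -> Node:
        nonlocal pos
        node = Node()
        if s[pos] == "(":
            pos += 1
            node.children.append(parse_node())
            while s[pos] == ",":
                pos += 1
                node.children.append(parse_node())
            if s[pos] != ")":
                raise ValueError(f"newick parse error at {pos}: expected ')'")
            pos += 1
        # label
        start = pos
        while pos < len(s) and s[pos] not in ",():;":
            pos += 1
        label = s[start:pos]
        if label:
            if node.children:
                try:
                    node.support = float(label)
                except ValueError:
                    node.name = label
            else:
                node.name = label
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in ",():;":
                pos += 1
            node.length = float(s[start:pos])
        return node

    root = parse_node()
    if pos != len(s):
        raise ValueError(f"trailing newick text at {pos}: {s[pos:]!r}")
    return root


def bipartitions(tree: Node) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an (un)rooted tree, as the leaf-name set
    on the far side of each internal edge, canonicalized to the side NOT
    containing the lexicographically smallest leaf."""
    all_leaves = frozenset(tree.leaf_names())
    ref = min(all_leaves)
    out: set[frozenset[str]] = set()

    def walk(node: Node) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.name or ""])
        below = frozenset().union(*(walk(c) for c in node.children))
        if node is not tree and 1 < len(below) < len(all_leaves) - 1:
            side = below if ref not in below else all_leaves - below
            out.add(side)
        return below

    for c in tree.children:
        walk(c)
    return out


def support_of_bipartition(tree: Node, side: frozenset[str]) -> float | None:
    """Support of the internal edge inducing ``side`` (either orientation), or
    None if the bipartition is absent."""
    all_leaves = frozenset(tree.leaf_names())
    want = {side, all_leaves - side}
    found: list[float | None] = []

    def walk(node: Node) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.name or ""])
        below = frozenset().union(*(walk(c) for c in node.children))
        if node is not tree and below in want:
            found.append(node.support)
        return below

    for c in tree.children:
        walk(c)
    if not found:
        return None
    return max((f if f is not None else 0.0) for f in found)
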