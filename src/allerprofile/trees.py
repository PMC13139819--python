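"""Minimal rooted-tree container used for dendrograms and simulation trees.

A :class:`Node` carries a *height* (merge distance from the leaf level, in the
units of the clustering distance), so branch lengths are always derived as
``parent.height - child.height``.  Leaves sit at height 0.  The same structure
doubles as the species tree driving the synthetic-data generators, where
heights encode divergence depth.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator


@dataclass(frozen=True)
class Node:
    """A rooted tree node; ``label`` is set on leaves (and optionally internals)."""

    height: float
    label: str | None = None
    children: tuple["Node", ...] = field(default=())

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf:
            return [self]
        out: list[Node] = []
        for child in self.children:
            out.extend(child.leaves())
        return out

    def leaf_labels(self) -> list[str]:
        return [leaf.label or "" for leaf in self.leaves()]

    def iter_nodes(self) -> Iterator["Node"]:
        yield self
        for child in self.children:
            yield from child.iter_nodes()

    def clades(self) -> set[frozenset[str]]:
        """Set of leaf-label sets, one per internal node (topology signature).

        Two rooted trees on the same leaves are topologically identical iff
        their clade sets are equal.
        """
        out: set[frozenset[str]] = set()
        for node in self.iter_nodes():
            if not node.is_leaf:
                out.add(frozenset(node.leaf_labels()))
        return out


def leaf(label: str) -> Node:
    return Node(height=0.0, label=label)


_PLAIN_LABEL = re.compile(r"^[A-Za-z0-9_.|-]+$")


def _format_label(label: str) -> str:
    if _PLAIN_LABEL.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def to_newick(tree: Node) -> str:
    """Serialize the tree to a Newick string with branch lengths."""

    def render(node: Node, parent_height: float) -> str:
        length = parent_height - node.height
        if node.is_leaf:
            return f"{_format_label(node.label or '')}:{length:g}"
        inner = ",".join(render(c, node.height) for c in node.children)
        return f"({inner}):{length:g}"

    if tree.is_leaf:
        return f"{_format_label(tree.label or '')};"
    inner = ",".join(render(c, tree.height) for c in tree.children)
    return f"({inner});"


def write_newick(tree: Node, path) -> None:
    """Write the tree to ``path`` in Newick format (with trailing newline)."""
    with open(path, "w") as fh:
        fh.write(to_newick(tree) + "\n")
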