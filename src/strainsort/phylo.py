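"""A lightweight phylogenetic tree container with Newick I/O.

Trees are unrooted in meaning but stored rooted at an arbitrary
(typically trifurcating) node, the common convention for
neighbor-joining output.  Bootstrap supports are integer percentages
serialized as internal-node labels.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

from Bio import Phylo


class TreeError(ValueError):
    pass


@dataclass
class Node:
    name: str | None = None
    length: float | None = None
    support: int | None = None
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self):
        yield self
        for child in self.children:
            yield from child.walk()


@dataclass
class PhyloTree:
    root: Node

    def leaves(self) -> list[Node]:
        return [n for n in self.root.walk() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def validate(self) -> None:
        names = self.leaf_names()
        if len(names) < 2:
            raise TreeError("tree must have at least 2 leaves")
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise TreeError(f"duplicate leaf names: {dupes}")
        for node in self.root.walk():
            if node is not self.root and node.length is not None and node.length < -1e-12:
                raise TreeError(f"negative branch length {node.length} on {node.name!r}")

    def splits(self, include_trivial: bool = False) -> dict[frozenset, tuple[float | None, int | None]]:
        """Map each edge's bipartition of the leaf set to (length, support).

        A bipartition is a frozenset of the two frozensets of leaf names on
        either side of the edge; this makes comparisons rooting-invariant.
        Trivial (single-leaf) splits are included only on request.
        """
        all_leaves = frozenset(self.leaf_names())
        out: dict[frozenset, tuple[float | None, int | None]] = {}

        def below(node: Node) -> frozenset:
            if node.is_leaf:
                return frozenset([node.name])
            return frozenset().union(*(below(c) for c in node.children))

        for node in self.root.walk():
            if node is self.root:
                continue
            side = below(node)
            if not include_trivial and min(len(side), len(all_leaves - side)) < 2:
                continue
            key = frozenset([side, all_leaves - side])
            # the two edges meeting at a trifurcating root describe the same
            # split; keep the first (lengths there are arbitrary halves anyway)
            if key not in out:
                out[key] = (node.length, node.support)
        return out

    def topology_splits(self) -> set[frozenset]:
        return set(self.splits().keys())

    def newick(self) -> str:
        self.validate()

        def fmt(node: Node) -> str:
            if node.is_leaf:
                label = node.name or ""
            else:
                inner = ",".join(fmt(c) for c in node.children)
                label = f"({inner})"
                if node.support is not None:
                    label += str(int(node.support))
                elif node.name:
                    label += node.name
            if node is not self.root and node.length is not None:
                label += f":{node.length:.6f}"
            return label

        return fmt(self.root) + ";"


def write_newick(tree: PhyloTree, path: str | Path) -> None:
    """Serialize a tree; round-trips topology, names, 6-decimal lengths
    and integer supports through :func:`read_newick`."""
    with open(path, "w") as fh:
        fh.write(tree.newick() + "\n")


def _from_clade(clade) -> Node:
    node = Node(
        name=clade.name,
        length=clade.branch_length,
        children=[_from_clade(c) for c in clade.clades],
    )
    if node.children and clade.confidence is not None:
        node.support = int(round(clade.confidence))
    # numeric internal labels read back as names by some writers
    if node.children and node.support is None and node.name:
        try:
            node.support = int(node.name)
            node.name = None
        except ValueError:
            pass
    return node


def read_newick(source: str | Path | io.TextIOBase) -> PhyloTree:
    """Parse a Newick file (or literal string) into a PhyloTree."""
    if isinstance(source, (str, Path)) and str(source).rstrip().endswith(";"):
        handle: io.TextIOBase | str | Path = io.StringIO(str(source))
    else:
        handle = str(source)
    biotree = Phylo.read(handle, "newick")
    tree = PhyloTree(root=_from_clade(biotree.root))
    tree.validate()
    return tree
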