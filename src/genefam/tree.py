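"""A minimal phylogenetic tree: nodes, branch lengths, bootstrap supports.

The tree is stored rooted (as Newick requires) but represents an
unrooted topology; comparisons therefore go through ``bipartitions()``,
which is invariant to the root position. Newick serialisation is
written directly (6-decimal lengths, integer support labels); parsing is
delegated to Bio.Phylo.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

from Bio import Phylo


@dataclass
class TreeNode:
    name: str | None = None
    branch_length: float = 0.0
    support: int | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Tree:
    root: TreeNode

    def leaves(self) -> list[TreeNode]:
        out = []

        def walk(n):
            if n.is_leaf:
                out.append(n)
            for c in n.children:
                walk(c)

        walk(self.root)
        return out

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def internal_nodes(self) -> list[TreeNode]:
        out = []

        def walk(n):
            if not n.is_leaf:
                out.append(n)
            for c in n.children:
                walk(c)

        walk(self.root)
        return out

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits of the unrooted topology.

        Each split is the leaf set on one side of an internal edge,
        canonicalised to the side *not* containing the lexicographically
        smallest leaf, so the set is root-invariant.
        """
        all_leaves = frozenset(self.leaf_names())
        if len(all_leaves) < 4:
            return set()
        anchor = min(all_leaves)
        splits: set[frozenset[str]] = set()

        def below(n) -> frozenset[str]:
            if n.is_leaf:
                return frozenset([n.name])
            acc = frozenset()
            for c in n.children:
                acc |= below(c)
            return acc

        def walk(n):
            for c in n.children:
                side = below(c)
                if 2 <= len(side) <= len(all_leaves) - 2:
                    if anchor in side:
                        side = all_leaves - side
                    splits.add(side)
                walk(c)

        walk(self.root)
        return splits

    def to_newick(self) -> str:
        def fmt(n: TreeNode, top: bool) -> str:
            if n.is_leaf:
                if not n.name:
                    raise ValueError("unnamed leaf cannot be serialised")
                return f"{n.name}:{n.branch_length:.6f}"
            inner = ",".join(fmt(c, False) for c in n.children)
            label = "" if n.support is None else str(int(n.support))
            if top:
                return f"({inner}){label}"
            return f"({inner}){label}:{n.branch_length:.6f}"

        return fmt(self.root, True) + ";"


def write_newick(tree: Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


def _from_clade(clade) -> TreeNode:
    node = TreeNode(
        name=clade.name,
        branch_length=clade.branch_length or 0.0,
        children=[_from_clade(c) for c in clade.clades],
    )
    if node.children:  # internal label = bootstrap support
        conf = clade.confidence
        if conf is None and clade.name:
            try:
                conf = float(clade.name)
                node.name = None
            except ValueError:
                conf = None
        node.support = None if conf is None else int(round(conf))
    return node


def parse_newick(text: str) -> Tree:
    phylo_tree = Phylo.read(io.StringIO(text), "newick")
    return Tree(root=_from_clade(phylo_tree.root))


def read_newick(path) -> Tree:
    with open(path) as fh:
        return parse_newick(fh.read())
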