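"""Species trees with branch lengths and foreground-branch labels.

Trees arrive as Newick with codeml-style ``#1`` marks on the focal
(foreground) branches.  Parsing goes through dendropy after the marks are
rewritten as bracket comments; internally the tree is a lightweight node
structure convenient for postorder pruning.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import dendropy

_FG_COMMENT = "&hlscan_foreground"


class TreeFormatError(ValueError):
    """Raised on malformed Newick input."""


@dataclass
class TreeNode:
    """One node of a :class:`LabeledTree`; the edge above it carries
    ``length`` and the ``foreground`` flag."""

    name: str | None = None
    length: float = 0.0
    foreground: bool = False
    children: list["TreeNode"] = field(default_factory=list)
    parent: "TreeNode | None" = field(default=None, repr=False)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class LabeledTree:
    """Rooted tree over the alignment taxa with one or more branches
    flagged as the foreground lineage of a branch-site test."""

    root: TreeNode
    missing_lengths: bool = False

    def postorder(self) -> list[TreeNode]:
        out: list[TreeNode] = []

        def walk(node: TreeNode) -> None:
            for ch in node.children:
                walk(ch)
            out.append(node)

        walk(self.root)
        return out

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def branches(self) -> list[TreeNode]:
        """All non-root nodes, i.e. one entry per branch (the edge above)."""
        return [n for n in self.postorder() if n.parent is not None]

    def foreground_branches(self) -> list[TreeNode]:
        return [n for n in self.branches() if n.foreground]

    def branch_lengths(self) -> list[float]:
        return [n.length for n in self.branches()]

    def set_branch_lengths(self, lengths: list[float]) -> None:
        bs = self.branches()
        if len(lengths) != len(bs):
            raise ValueError(f"expected {len(bs)} branch lengths, got {len(lengths)}")
        for node, t in zip(bs, lengths):
            node.length = float(t)

    def copy(self) -> "LabeledTree":
        def clone(node: TreeNode, parent: TreeNode | None) -> TreeNode:
            nn = TreeNode(name=node.name, length=node.length,
                          foreground=node.foreground, parent=parent)
            nn.children = [clone(ch, nn) for ch in node.children]
            return nn

        return LabeledTree(root=clone(self.root, None),
                           missing_lengths=self.missing_lengths)

    def to_newick(self, foreground_token: str = "#1") -> str:
        def fmt(node: TreeNode) -> str:
            mark = f" {foreground_token}" if node.foreground else ""
            if node.is_leaf:
                return f"{node.name}:{node.length:.6g}{mark}"
            inner = ",".join(fmt(ch) for ch in node.children)
            if node.parent is None:
                return f"({inner})"
            return f"({inner}):{node.length:.6g}{mark}"

        return fmt(self.root) + ";"

    def write(self, path: str | Path, foreground_token: str = "#1") -> None:
        Path(path).write_text(self.to_newick(foreground_token) + "\n")


def _from_dendropy(dtree: dendropy.Tree) -> LabeledTree:
    missing = False

    def convert(dnode: dendropy.Node, parent: TreeNode | None) -> TreeNode:
        nonlocal missing
        name = dnode.taxon.label if dnode.taxon else dnode.label
        length = dnode.edge.length
        if length is None:
            length = 0.0
            if parent is not None:
                missing = True
        if length < 0:
            raise TreeFormatError(f"negative branch length {length}")
        fg = any(_FG_COMMENT in c for c in (dnode.comments or []))
        node = TreeNode(name=name, length=float(length), foreground=fg, parent=parent)
        node.children = [convert(ch, node) for ch in dnode.child_nodes()]
        return node

    root = convert(dtree.seed_node, None)
    tree = LabeledTree(root=root, missing_lengths=missing)
    names = tree.leaf_names()
    if len(names) != len(set(names)):
        raise TreeFormatError("duplicate leaf names in tree")
    return tree


def parse_newick(text: str, foreground_token: str = "#1") -> LabeledTree:
    """Parse a Newick string, honoring ``foreground_token`` branch marks.

    The token may follow a leaf name, an internal-node closing parenthesis,
    or a branch length (codeml conventions).  Missing branch lengths become
    0 and set ``missing_lengths`` on the returned tree.
    """
    marked = text.replace(foreground_token, f"[{_FG_COMMENT}]")
    try:
        dtree = dendropy.Tree.get(
            data=marked, schema="newick",
            suppress_internal_node_taxa=True,
            terminating_semicolon_required=False,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeFormatError(f"malformed Newick: {exc}") from exc
    return _from_dendropy(dtree)


def read_tree(path: str | Path, foreground_token: str = "#1") -> LabeledTree:
    """Read a Newick tree file with optional codeml-style foreground marks."""
    return parse_newick(Path(path).read_text(), foreground_token)


def require_matching_taxa(tree: LabeledTree, taxa: list[str]) -> None:
    """Raise unless the tree leaf set equals the alignment taxon set."""
    tl, al = set(tree.leaf_names()), set(taxa)
    if tl != al:
        only_t = sorted(tl - al)
        only_a = sorted(al - tl)
        raise ValueError(
            f"tree/alignment taxon mismatch: only in tree {only_t}, "
            f"only in alignment {only_a}"
        )
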