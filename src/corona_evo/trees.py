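"""Rooted species trees: a light node structure plus Newick round-tripping.

Trees here are always rooted, may contain polytomies, and every node that
participates in an ancestral reconstruction carries a unique name.  Unnamed
internal nodes are assigned stable autogenerated names (``N1``, ``N2``, ... in
postorder) when a tree is parsed or built, so that state maps and event tables
can refer to any node unambiguously.

Parsing is delegated to :mod:`dendropy`; writing uses a small canonical
serializer so that byte-identical round trips are easy to guarantee.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator

import dendropy

__all__ = [
    "TreeNode",
    "Tree",
    "parse_newick",
    "read_newick",
    "write_newick",
    "EUKARYOTE_FIXTURE_NEWICK",
    "eukaryote_fixture_tree",
]

# Ten major eukaryote lineages with labelled Obazoa and SAR ancestors.  The
# topology follows the consensus eukaryote tree: Breviata is sister to
# Opisthokonta+Apusozoa within Obazoa, and Rhizaria is sister to
# Stramenopila+Alveolata (Halvaria) within SAR.  The root (LECA) is a
# polytomy of Amorphea, Diaphoretickes and the Discoba/Metamonada lineages.
EUKARYOTE_FIXTURE_NEWICK = (
    "((((Opisthokonta,Apusozoa)Opisthokonta_Apusozoa,Breviata)Obazoa,"
    "Amoebozoa)Amorphea,"
    "(Archaeplastida,((Stramenopila,Alveolata)Halvaria,Rhizaria)SAR)"
    "Diaphoretickes,"
    "(Discoba,Metamonada)Excavata)LECA;"
)


@dataclass
class TreeNode:
    name: str
    children: list["TreeNode"] = field(default_factory=list)
    parent: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TreeNode({self.name!r}, n_children={len(self.children)})"


class Tree:
    """A rooted tree with uniquely named nodes."""

    def __init__(self, root: TreeNode):
        self.root = root
        self._assign_missing_names()
        names = [n.name for n in self.postorder()]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate node names in tree: {sorted(dupes)}")
        leaf_names = [n.name for n in self.leaves()]
        if len(set(leaf_names)) != len(leaf_names):
            raise ValueError("duplicate leaf names in tree")

    def _assign_missing_names(self) -> None:
        counter = 0
        taken = {n.name for n in self.postorder() if n.name}
        for node in self.postorder():
            if not node.name:
                counter += 1
                candidate = f"N{counter}"
                while candidate in taken:
                    counter += 1
                    candidate = f"N{counter}"
                node.name = candidate
                taken.add(candidate)

    # -- traversal -----------------------------------------------------
    def postorder(self) -> Iterator[TreeNode]:
        def _walk(node: TreeNode) -> Iterator[TreeNode]:
            for child in node.children:
                yield from _walk(child)
            yield node

        yield from _walk(self.root)

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def edges(self) -> list[tuple[TreeNode, TreeNode]]:
        """(parent, child) pairs; excludes the implicit stem above the root."""
        return [(n.parent, n) for n in self.postorder() if n.parent is not None]

    def find(self, name: str) -> TreeNode:
        for node in self.postorder():
            if node.name == name:
                return node
        raise KeyError(f"no node named {name!r} in tree")

    def lca(self, names: list[str]) -> TreeNode:
        if not names:
            raise ValueError("lca of an empty set of nodes is undefined")
        paths = []
        for name in names:
            node = self.find(name)
            path = []
            while node is not None:
                path.append(node)
                node = node.parent
            paths.append(list(reversed(path)))
        ancestor = paths[0][0]
        for depth in range(min(len(p) for p in paths)):
            candidates = {id(p[depth]) for p in paths}
            if len(candidates) == 1:
                ancestor = paths[0][depth]
            else:
                break
        return ancestor

    def subtree_leaves(self, node: TreeNode) -> list[TreeNode]:
        out = []

        def _walk(n: TreeNode) -> None:
            if n.is_leaf:
                out.append(n)
            for c in n.children:
                _walk(c)

        _walk(node)
        return out

    def copy(self) -> "Tree":
        def _clone(node: TreeNode) -> TreeNode:
            new = TreeNode(node.name)
            for child in node.children:
                new.add_child(_clone(child))
            return new

        return Tree(_clone(self.root))

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tree(n_leaves={len(self.leaves())})"


_LABEL_NEEDS_QUOTING = re.compile(r"[\s()\[\]{}:;,'\"]")


def _format_label(label: str) -> str:
    if _LABEL_NEEDS_QUOTING.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _to_newick(node: TreeNode, comments: dict[str, str] | None) -> str:
    comment = ""
    if comments and node.name in comments:
        comment = f"[&&NHX:{comments[node.name]}]"
    if node.is_leaf:
        return _format_label(node.name) + comment
    inner = ",".join(_to_newick(c, comments) for c in node.children)
    return f"({inner})" + _format_label(node.name) + comment


def tree_to_newick(tree: Tree, comments: dict[str, str] | None = None) -> str:
    """Serialize to Newick; ``comments`` maps node name -> NHX payload."""
    return _to_newick(tree.root, comments) + ";"


def parse_newick(text: str) -> Tree:
    """Parse a rooted Newick string (polytomies and quoted labels allowed)."""
    if text.count("(") != text.count(")"):
        raise ValueError(
            "unbalanced parentheses in Newick input "
            f"(({text.count('(')} open vs {text.count(')')} close)"
        )
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises schema-specific errors
        raise ValueError(f"could not parse Newick input: {exc}") from exc

    def _convert(dnode: dendropy.Node) -> TreeNode:
        if dnode.taxon is not None:
            label = dnode.taxon.label or ""
        else:
            label = dnode.label or ""
        node = TreeNode(label)
        for dchild in dnode.child_nodes():
            node.add_child(_convert(dchild))
        return node

    return Tree(_convert(dtree.seed_node))


def read_newick(path) -> Tree:
    with open(path, "r", encoding="utf-8") as fh:
        return parse_newick(fh.read())


def write_newick(tree: Tree, path, comments: dict[str, str] | None = None) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(tree_to_newick(tree, comments) + "\n")


def eukaryote_fixture_tree() -> Tree:
    """The packaged ten-lineage eukaryote tree used throughout the package."""
    return parse_newick(EUKARYOTE_FIXTURE_NEWICK)
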