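"""Unrooted binary phylogenies, stored rooted at a trifurcating basal node.

An unrooted binary tree over n leaves has 2n - 3 edges; here it is held as
a rooted structure whose root has three children (or n children when
n <= 3), so every non-root node owns exactly one edge — the edge to its
parent — carrying a branch length and, for internal edges, an optional
integer bootstrap support.
"""

from __future__ import annotations

from ..errors import InvalidArgumentError


class TreeNode:
    __slots__ = ("name", "length", "support", "children", "parent")

    def __init__(self, name: str | None = None, length: float = 0.0):
        self.name = name
        self.length = length
        self.support: int | None = None
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None

    def add_child(self, child: "TreeNode") -> None:
        child.parent = self
        self.children.append(child)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self):  # pragma: no cover
        kind = "leaf" if self.is_leaf else f"internal[{len(self.children)}]"
        return f"<TreeNode {self.name or ''} {kind} len={self.length:g}>"


class PhyloTree:
    """Unrooted tree with branch lengths and optional bootstrap supports."""

    def __init__(self, root: TreeNode):
        self.root = root
        names = [leaf.name for leaf in self.leaves()]
        if len(names) != len(set(names)):
            raise InvalidArgumentError("leaf labels must be unique")

    # -- traversal -----------------------------------------------------

    def postorder(self):
        stack = [(self.root, False)]
        while stack:
            node, seen = stack.pop()
            if seen or node.is_leaf:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def edges(self) -> list[TreeNode]:
        """Every non-root node owns the edge to its parent."""
        return [n for n in self.postorder() if n.parent is not None]

    def internal_edges(self) -> list[TreeNode]:
        return [n for n in self.edges() if not n.is_leaf]

    @property
    def n_edges(self) -> int:
        return len(self.edges())

    # -- bipartitions --------------------------------------------------

    def leafset_below(self, node: TreeNode) -> frozenset[str]:
        out = []
        stack = [node]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.append(n.name)
            else:
                stack.extend(n.children)
        return frozenset(out)

    def bipartitions(self) -> dict[frozenset[str], TreeNode]:
        """Nontrivial bipartitions keyed by the canonical half.

        The canonical half is the side NOT containing the lexicographically
        smallest leaf label, so equal splits compare equal across trees
        over the same taxa.
        """
        all_leaves = frozenset(self.leaf_names())
        anchor = min(all_leaves)
        out: dict[frozenset[str], TreeNode] = {}
        for node in self.internal_edges():
            below = self.leafset_below(node)
            if len(below) < 2 or len(all_leaves - below) < 2:
                continue
            key = (all_leaves - below) if anchor in below else below
            out[key] = node
        return out

    # -- serialization -------------------------------------------------

    def to_newick(self, *, include_supports: bool = True) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                label = node.name or ""
            else:
                inner = ",".join(fmt(c) for c in node.children)
                sup = ""
                if include_supports and node.support is not None:
                    sup = str(int(node.support))
                label = f"({inner}){sup}"
            if node.parent is None:
                return label
            return f"{label}:{node.length:.10g}"

        return fmt(self.root) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        """Parse Newick via dendropy; internal node labels become supports."""
        import dendropy

        dt = dendropy.Tree.get(data=text, schema="newick",
                               suppress_internal_node_taxa=True)

        def convert(dnode) -> TreeNode:
            node = TreeNode()
            node.length = float(dnode.edge.length or 0.0)
            if dnode.is_leaf():
                node.name = dnode.taxon.label if dnode.taxon else dnode.label
            else:
                if dnode.label is not None:
                    try:
                        node.support = int(float(dnode.label))
                    except ValueError:
                        node.name = dnode.label
                for child in dnode.child_nodes():
                    node.add_child(convert(child))
            return node

        return cls(convert(dt.seed_node))

    def write_newick(self, path, **kwargs) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick(**kwargs) + "\n")
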