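"""A light phylogenetic tree container shared across the package.

Trees are rooted data structures representing (possibly) unrooted topologies:
an unrooted binary tree is stored with a trifurcating root.  Branch lengths
are optional non-negative reals; internal nodes may carry a support value in
[0, 1].  Newick parsing goes through dendropy; writing is done directly.
"""

from __future__ import annotations

import numpy as np

__all__ = ["TreeNode", "Tree"]


class TreeNode:
    __slots__ = ("children", "parent", "length", "label", "support")

    def __init__(self, label=None, length=None):
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None
        self.length = length
        self.label = label
        self.support = None

    def add(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children


class Tree:
    """Rooted container for a (usually unrooted) topology over labelled leaves."""

    def __init__(self, root: TreeNode):
        self.root = root

    # -- traversal -----------------------------------------------------
    def postorder(self):
        stack = [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                yield node
            else:
                stack.append((node, True))
                for c in node.children:
                    stack.append((c, False))

    def preorder(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.label for n in self.leaves()]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def copy(self) -> "Tree":
        def rec(node):
            new = TreeNode(node.label, node.length)
            new.support = node.support
            for c in node.children:
                new.add(rec(c))
            return new

        return Tree(rec(self.root))

    # -- splits --------------------------------------------------------
    def bipartitions(self, include_trivial: bool = False) -> dict[frozenset, float | None]:
        """Map canonical split side -> support for each (internal) edge.

        The canonical side of a split is the one *not* containing the
        lexicographically smallest leaf label, so identical splits compare
        equal regardless of rooting.
        """
        taxa = set(self.leaf_names())
        ref = min(taxa)
        below: dict[int, set] = {}
        out: dict[frozenset, float | None] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = {node.label}
            else:
                s = set()
                for c in node.children:
                    s |= below[id(c)]
                below[id(node)] = s
            if node is self.root:
                continue
            s = below[id(node)]
            side = s if ref not in s else taxa - s
            if not include_trivial and (len(side) < 2 or len(side) > len(taxa) - 2):
                continue
            if len(side) == 0 or len(side) == len(taxa):
                continue
            key = frozenset(side)
            sup = node.support
            if key in out:
                prev = out[key]
                if prev is None or (sup is not None and sup > prev):
                    out[key] = sup
            else:
                out[key] = sup
        return out

    # -- distances -----------------------------------------------------
    def distance_matrix(self, taxa_order: list[str] | None = None):
        """Leaf-to-leaf path-length matrix (requires branch lengths)."""
        from .distances import DistanceMatrix

        leaves = self.leaves()
        order = taxa_order or [n.label for n in leaves]
        index = {t: i for i, t in enumerate(order)}
        n = len(order)
        d = np.zeros((n, n))
        # accumulate pairwise distances by post-order merging of leaf depth maps
        depths: dict[int, dict[int, float]] = {}
        for node in self.postorder():
            if node.is_leaf:
                depths[id(node)] = {index[node.label]: 0.0}
            else:
                merged: dict[int, float] = {}
                child_maps = []
                for c in node.children:
                    bl = c.length or 0.0
                    cm = {k: v + bl for k, v in depths.pop(id(c)).items()}
                    child_maps.append(cm)
                for a in range(len(child_maps)):
                    for b in range(a + 1, len(child_maps)):
                        for i, di in child_maps[a].items():
                            for j, dj in child_maps[b].items():
                                d[i, j] = d[j, i] = di + dj
                for cm in child_maps:
                    merged.update(cm)
                depths[id(node)] = merged
        return DistanceMatrix(list(order), d, "tree-path")

    def total_length(self) -> float:
        return sum(n.length or 0.0 for n in self.postorder() if n is not self.root)

    # -- IO ------------------------------------------------------------
    def to_newick(self, lengths: bool = True, supports: bool = False) -> str:
        def rec(node):
            if node.is_leaf:
                s = node.label
            else:
                s = "(" + ",".join(rec(c) for c in node.children) + ")"
                if supports and node.support is not None:
                    s += f"{node.support:g}"
                elif node.label:
                    s += str(node.label)
            if lengths and node.length is not None and node is not self.root:
                s += f":{node.length:.10g}"
            return s

        return rec(self.root) + ";"

    @classmethod
    def from_newick(cls, newick: str, supports_as_labels: bool = True) -> "Tree":
        import dendropy

        dt = dendropy.Tree.get(data=newick, schema="newick")

        def rec(dnode):
            label = dnode.taxon.label if dnode.taxon else dnode.label
            node = TreeNode(
                label if dnode.is_leaf() else None,
                dnode.edge.length,
            )
            if not dnode.is_leaf() and label is not None:
                try:
                    node.support = float(label)
                except ValueError:
                    node.label = label
            for c in dnode.child_nodes():
                node.add(rec(c))
            return node

        return cls(rec(dt.seed_node))

    @classmethod
    def from_newick_file(cls, path) -> "Tree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def write(self, path, **kw) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick(**kw) + "\n")
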