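"""Light-weight unrooted phylogeny used by the likelihood engine.

Trees are parsed with dendropy and flattened into parent/child index
arrays, which is the layout the pruning recursion and the branch-length
optimiser want.  The tree is stored rooted at an arbitrary internal node
(a basal bifurcation in the input is collapsed), which is harmless for
time-reversible models by the pulley principle.
"""

from __future__ import annotations

from typing import Iterable

import dendropy
import numpy as np

from .errors import DataError


class PhyloTree:
    """Unrooted tree over named leaves with branch lengths.

    Attributes
    ----------
    parent : np.ndarray
        ``parent[i]`` is the parent node index of node i (-1 for the root).
    children : list[list[int]]
        Child indices per node.
    lengths : np.ndarray
        ``lengths[i]`` is the length of the edge above node i (NaN if the
        input carried none); the root entry is unused.
    names : list[str]
        Taxon label per node ('' for internal nodes).
    """

    def __init__(self, parent, children, lengths, names):
        self.parent = np.asarray(parent, dtype=int)
        self.children = [list(c) for c in children]
        self.lengths = np.asarray(lengths, dtype=float)
        self.names = list(names)
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise DataError("tree must have exactly one root node")
        self.root = int(roots[0])
        leaves = self.leaf_indices
        labels = [self.names[i] for i in leaves]
        if len(set(labels)) != len(labels):
            raise DataError("leaf labels must be unique")
        if any(not lab for lab in labels):
            raise DataError("every leaf needs a taxon label")

    # ------------------------------------------------------------------ io

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        try:
            tree = dendropy.Tree.get(data=newick, schema="newick",
                                     preserve_underscores=True)
        except Exception as exc:  # dendropy raises assorted reader errors
            raise DataError(f"failed to parse newick: {exc}") from exc
        return cls.from_dendropy(tree)

    @classmethod
    def from_file(cls, path) -> "PhyloTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "PhyloTree":
        tree = tree.clone(depth=1)
        root = tree.seed_node
        kids = root.child_nodes()
        if len(kids) == 2 and any(not k.is_leaf() for k in kids):
            # collapse a basal bifurcation: unrooted semantics
            # (a two-leaf tree stays rooted; only the length sum matters)
            tree.deroot()
        index: dict = {}
        parent, children, lengths, names = [], [], [], []
        for node in tree.preorder_node_iter():
            i = len(parent)
            index[node] = i
            parent.append(index[node.parent_node] if node.parent_node else -1)
            children.append([])
            if node.parent_node is not None:
                children[index[node.parent_node]].append(i)
            lengths.append(node.edge.length if node.edge.length is not None
                           else np.nan)
            if node.is_leaf():
                names.append(node.taxon.label if node.taxon else "")
            else:
                names.append("")
        return cls(parent, children, lengths, names)

    def to_newick(self, precision: int = 10) -> str:
        def render(i: int) -> str:
            if not self.children[i]:
                label = self.names[i]
            else:
                label = "(" + ",".join(render(c) for c in self.children[i]) + ")"
            if i == self.root:
                return label
            ln = self.lengths[i]
            if np.isnan(ln):
                return label
            return f"{label}:{ln:.{precision}g}"

        return render(self.root) + ";"

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    # ---------------------------------------------------------- structure

    @property
    def n_nodes(self) -> int:
        return len(self.names)

    @property
    def leaf_indices(self) -> list:
        return [i for i in range(self.n_nodes) if not self.children[i]]

    @property
    def leaf_names(self) -> list:
        return [self.names[i] for i in self.leaf_indices]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_indices)

    @property
    def edge_nodes(self) -> list:
        """Indices of nodes that own an edge (everything but the root)."""
        return [i for i in range(self.n_nodes) if i != self.root]

    @property
    def n_edges(self) -> int:
        return self.n_nodes - 1

    def postorder(self) -> list:
        order: list = []

        def walk(i: int) -> None:
            for c in self.children[i]:
                walk(c)
            order.append(i)

        walk(self.root)
        return order

    def preorder(self) -> list:
        order: list = []
        stack = [self.root]
        while stack:
            i = stack.pop()
            order.append(i)
            stack.extend(reversed(self.children[i]))
        return order

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.parent.copy(), [list(c) for c in self.children],
                         self.lengths.copy(), list(self.names))

    def with_lengths(self, lengths: Iterable[float]) -> "PhyloTree":
        t = self.copy()
        t.lengths = np.asarray(list(lengths), dtype=float)
        return t

    def fill_missing_lengths(self, default: float = 0.05) -> "PhyloTree":
        t = self.copy()
        mask = np.isnan(t.lengths)
        t.lengths[mask] = default
        t.lengths[t.root] = 0.0
        return t

    def total_length(self) -> float:
        idx = self.edge_nodes
        return float(np.nansum(self.lengths[idx]))

    def topology_key(self) -> frozenset:
        """Canonical set of non-trivial leaf bipartitions (topology identity)."""
        all_leaves = frozenset(self.leaf_names)
        splits = set()
        below: dict = {}
        for i in self.postorder():
            if not self.children[i]:
                below[i] = frozenset([self.names[i]])
            else:
                s = frozenset().union(*(below[c] for c in self.children[i]))
                below[i] = s
            if i != self.root and 1 < len(below[i]) < len(all_leaves) - 1:
                side = below[i]
                other = all_leaves - side
                splits.add(frozenset([side, other]))
        return frozenset(splits)
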