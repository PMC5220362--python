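"""Rooted bifurcating phylogeny with branch lengths.

A thin array-backed container used by the gain/loss machinery. Nodes are
indexed in preorder (root = 0), so vectorised pruning/posterior passes can
walk plain integer arrays. Newick I/O is delegated to dendropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np


class PhylogenyError(ValueError):
    """Raised when a tree violates the rooted-bifurcating contract."""


@dataclass
class Phylogeny:
    """Rooted, fully bifurcating tree.

    Attributes
    ----------
    parent:
        ``parent[i]`` is the preorder index of node ``i``'s parent
        (``-1`` for the root).
    blen:
        Branch length above each node (``blen[0]`` is ignored).
    labels:
        Node labels; every leaf has a unique genome id, internal nodes
        may be ``None``.
    """

    parent: np.ndarray
    blen: np.ndarray
    labels: list
    children: list = field(init=False)

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.blen = np.asarray(self.blen, dtype=float)
        n = len(self.parent)
        self.children = [[] for _ in range(n)]
        for i in range(1, n):
            p = int(self.parent[i])
            if p < 0 or p >= i:
                raise PhylogenyError("nodes must be in preorder with a single root")
            self.children[p].append(i)
        self._validate()

    def _validate(self) -> None:
        n_child = np.array([len(c) for c in self.children])
        if not np.all((n_child == 0) | (n_child == 2)):
            raise PhylogenyError("tree must be fully bifurcating")
        if np.any(self.blen[1:] <= 0):
            raise PhylogenyError("all branch lengths must be > 0")
        leaves = self.leaf_indices()
        leaf_labels = [self.labels[i] for i in leaves]
        if any(lab is None for lab in leaf_labels):
            raise PhylogenyError("every leaf needs a label")
        if len(set(leaf_labels)) != len(leaf_labels):
            raise PhylogenyError("leaf labels must be unique")

    # ------------------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_indices())

    @property
    def n_branches(self) -> int:
        """Number of branches = 2n - 2 for n leaves (root has none)."""
        return self.n_nodes - 1

    def leaf_indices(self) -> np.ndarray:
        return np.array([i for i, c in enumerate(self.children) if not c], dtype=np.int64)

    def internal_indices(self) -> np.ndarray:
        return np.array([i for i, c in enumerate(self.children) if c], dtype=np.int64)

    def leaf_labels(self) -> list:
        return [self.labels[i] for i in self.leaf_indices()]

    def postorder(self) -> np.ndarray:
        """Children-before-parent node order (reverse preorder works)."""
        return np.arange(self.n_nodes - 1, -1, -1, dtype=np.int64)

    def preorder(self) -> np.ndarray:
        return np.arange(self.n_nodes, dtype=np.int64)

    def branch_child_nodes(self) -> np.ndarray:
        """Branches in the canonical (preorder-of-child) order.

        Branch ``b`` is identified by its child node ``b + 1``; gain
        vectors use this ordering throughout.
        """
        return np.arange(1, self.n_nodes, dtype=np.int64)

    def branch_ids(self) -> list:
        """Stable string ids for branches: child-node label or ``node<k>``."""
        out = []
        for c in self.branch_child_nodes():
            lab = self.labels[c]
            out.append(lab if lab is not None else f"node{c}")
        return out

    # ------------------------------------------------------------------
    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "Phylogeny":
        nodes = list(tree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent = np.full(len(nodes), -1, dtype=np.int64)
        blen = np.zeros(len(nodes))
        labels: list = []
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                blen[i] = nd.edge.length if nd.edge.length is not None else np.nan
            if nd.taxon is not None:
                labels.append(nd.taxon.label)
            else:
                labels.append(nd.label)
        if np.any(np.isnan(blen[1:])):
            raise PhylogenyError("every non-root edge needs a branch length")
        return cls(parent, blen, labels)

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        tree = dendropy.Tree.get(data=newick, schema="newick", rooting="force-rooted")
        return cls.from_dendropy(tree)

    @classmethod
    def read_newick(cls, path) -> "Phylogeny":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def to_newick(self) -> str:
        def rec(i: int) -> str:
            if not self.children[i]:
                name = str(self.labels[i])
            else:
                name = "(" + ",".join(rec(c) for c in self.children[i]) + ")"
                if self.labels[i] is not None:
                    name += str(self.labels[i])
            if self.parent[i] >= 0:
                name += f":{self.blen[i]:.10g}"
            return name

        return rec(0) + ";"

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")
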