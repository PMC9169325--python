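"""Indexed rooted phylogeny used by the simulator and the inference code.

Wraps a dendropy tree into flat arrays (parent pointers, branch lengths,
postorder) so that pruning-style recursions vectorize over sites.  Internal
nodes without labels receive synthetic ``n<i>`` labels; the root's label is
``root`` unless the input names it.
"""

from __future__ import annotations

from pathlib import Path

import dendropy
import numpy as np


class TreeIndex:
    """Flat-array view of a rooted tree with branch lengths."""

    def __init__(self, tree: dendropy.Tree):
        tree = tree.clone(depth=1)
        self._dendropy = tree
        nodes = list(tree.postorder_node_iter())
        if len([lf for lf in tree.leaf_node_iter()]) < 2:
            raise ValueError("tree must have at least 2 leaves")
        self.n_nodes = len(nodes)
        self._node_index: dict[int, int] = {id(nd): i for i, nd in enumerate(nodes)}
        self.postorder = np.arange(self.n_nodes)
        self.parent = np.full(self.n_nodes, -1, dtype=int)
        self.blen = np.zeros(self.n_nodes)
        self.is_leaf = np.zeros(self.n_nodes, dtype=bool)
        self.labels: list[str] = [""] * self.n_nodes
        self.children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        auto = 0
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                p = self._node_index[id(nd.parent_node)]
                self.parent[i] = p
                if nd.edge.length is None or nd.edge.length <= 0:
                    raise ValueError("all branch lengths must be > 0")
                self.blen[i] = float(nd.edge.length)
            if nd.is_leaf():
                self.is_leaf[i] = True
                self.labels[i] = nd.taxon.label.replace(" ", "_")
            else:
                if nd.label:
                    self.labels[i] = nd.label
                elif nd.parent_node is None:
                    self.labels[i] = "root"
                else:
                    self.labels[i] = f"n{auto}"
                    auto += 1
        for i in range(self.n_nodes):
            p = self.parent[i]
            if p >= 0:
                self.children[p].append(i)
        self.root = int(np.flatnonzero(self.parent < 0)[0])
        self.leaf_indices = np.flatnonzero(self.is_leaf)
        self.leaf_labels = [self.labels[i] for i in self.leaf_indices]
        self.index_of = {lab: i for i, lab in enumerate(self.labels)}
        # node -> set of descendant-leaf indices (bitmask per node)
        self._leafsets = [0] * self.n_nodes
        for i in range(self.n_nodes):  # postorder
            if self.is_leaf[i]:
                self._leafsets[i] = 1 << int(np.searchsorted(self.leaf_indices, i))
            else:
                m = 0
                for c in self.children[i]:
                    m |= self._leafsets[c]
                self._leafsets[i] = m

    @classmethod
    def from_newick(cls, newick: str | Path) -> "TreeIndex":
        text = str(newick)
        if "(" not in text:  # a path, not newick data
            text = Path(text).read_text()
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
        return cls(tree)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_indices)

    def preorder(self) -> list[int]:
        order: list[int] = []
        stack = [self.root]
        while stack:
            i = stack.pop()
            order.append(i)
            stack.extend(reversed(self.children[i]))
        return order

    def mrca(self, node_indices) -> int:
        """Most recent common ancestor of a set of node indices."""
        nodes = list(node_indices)
        if not nodes:
            raise ValueError("mrca of empty set")
        mask = 0
        for i in nodes:
            mask |= self._leafsets[i]
        # deepest node whose leaf set covers the mask
        best = self.root
        for i in self.postorder:
            if self._leafsets[i] & mask == mask:
                best = i
                break  # postorder: first cover is the deepest
        return int(best)

    def subtree_leaves(self, node: int) -> list[int]:
        mask = self._leafsets[node]
        return [
            int(self.leaf_indices[b])
            for b in range(self.n_leaves)
            if mask >> b & 1
        ]

    def path_to_root(self, node: int) -> list[int]:
        out = [node]
        while self.parent[out[-1]] >= 0:
            out.append(int(self.parent[out[-1]]))
        return out

    def is_ancestor(self, anc: int, node: int) -> bool:
        """True iff ``anc`` lies on the path from ``node`` to the root (or equals it)."""
        return anc in self.path_to_root(node)

    def patristic_distance(self, a: int, b: int) -> float:
        anc_a = self.path_to_root(a)
        dist_a = {}
        d = 0.0
        for n in anc_a:
            dist_a[n] = d
            d += self.blen[n]
        d = 0.0
        n = b
        while n not in dist_a:
            d += self.blen[n]
            n = int(self.parent[n])
        return d + dist_a[n]

    def to_newick(self) -> str:
        return self._dendropy.as_string(schema="newick").strip()
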