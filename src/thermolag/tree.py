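"""Rooted phylogeny container used throughout the package.

Nodes are integer ids: tips ``0 .. n_tips-1`` (in a fixed label order),
internal nodes follow. Branch lengths are stored on the child node; the
root's length is 0. Newick serialization goes through dendropy so that
trees interoperate with standard tooling.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = ["Phylogeny"]


@dataclass
class Phylogeny:
    """A rooted tree with branch lengths and labelled tips.

    Parameters
    ----------
    parent
        ``parent[i]`` is the parent node id of node ``i`` (-1 for the root).
    lengths
        ``lengths[i]`` is the length of the branch above node ``i``
        (0 for the root).
    tip_labels
        Labels for nodes ``0 .. n_tips-1``.
    """

    parent: np.ndarray
    lengths: np.ndarray
    tip_labels: list[str]
    node_labels: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.lengths = np.asarray(self.lengths, dtype=float)
        n = self.parent.size
        self.n_nodes = n
        self.n_tips = len(self.tip_labels)
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1:
            raise ValueError("tree must have exactly one root")
        self.root = int(roots[0])
        self.children: list[list[int]] = [[] for _ in range(n)]
        for i in range(n):
            p = int(self.parent[i])
            if p >= 0:
                self.children[p].append(i)
        self.postorder = self._postorder()
        self.preorder = self.postorder[::-1]
        self.tip_index = {lab: i for i, lab in enumerate(self.tip_labels)}

    # ------------------------------------------------------------------ #
    def _postorder(self) -> np.ndarray:
        order = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(self.children[node])
        return np.asarray(order[::-1], dtype=np.int64)

    def is_tip(self, node: int) -> bool:
        return node < self.n_tips

    def depths(self) -> np.ndarray:
        """Distance from the root to every node."""
        d = np.zeros(self.n_nodes)
        for node in self.preorder:
            p = self.parent[node]
            if p >= 0:
                d[node] = d[p] + self.lengths[node]
        return d

    def height(self) -> float:
        return float(self.depths()[: self.n_tips].max())

    def total_length(self) -> float:
        return float(self.lengths[np.arange(self.n_nodes) != self.root].sum())

    def subtree_tip_counts(self) -> np.ndarray:
        counts = np.zeros(self.n_nodes, dtype=np.int64)
        counts[: self.n_tips] = 1
        for node in self.postorder:
            p = self.parent[node]
            if p >= 0:
                counts[p] += counts[node]
        return counts

    def subtree_tips(self, node: int) -> list[int]:
        tips = []
        stack = [node]
        while stack:
            v = stack.pop()
            if self.is_tip(v):
                tips.append(v)
            else:
                stack.extend(self.children[v])
        return sorted(tips)

    def mrca(self, tips: list[int]) -> int:
        """Most recent common ancestor of a set of tip ids."""
        if not tips:
            raise ValueError("mrca of an empty tip set is undefined")
        want = set(tips)
        counts = np.zeros(self.n_nodes, dtype=np.int64)
        for t in want:
            counts[t] = 1
        depth = self.depths()
        best, best_depth = self.root, -np.inf
        for node in self.postorder:
            p = self.parent[node]
            if p >= 0:
                counts[p] += counts[node]
            if counts[node] == len(want) and depth[node] > best_depth:
                best, best_depth = node, depth[node]
        return best

    # ------------------------------------------------------------------ #
    def mrca_depth_matrix(self) -> np.ndarray:
        """``C[i, j]`` = depth of the MRCA of tips i and j (the BM vcv)."""
        depth = self.depths()
        n = self.n_tips
        C = np.zeros((n, n))
        np.fill_diagonal(C, depth[:n])
        tipsets: dict[int, np.ndarray] = {
            i: np.array([i], dtype=np.int64) for i in range(n)
        }
        for node in self.postorder:
            if self.is_tip(node):
                continue
            groups = [tipsets.pop(c) for c in self.children[node]]
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    C[np.ix_(groups[a], groups[b])] = depth[node]
                    C[np.ix_(groups[b], groups[a])] = depth[node]
            tipsets[node] = np.concatenate(groups)
        return C

    def patristic_matrix(self) -> np.ndarray:
        C = self.mrca_depth_matrix()
        d = np.diag(C)
        return d[:, None] + d[None, :] - 2.0 * C

    def prune_to(self, keep_labels: list[str]) -> "Phylogeny":
        """Spanning subtree of the given tips, unifurcations collapsed."""
        keep = [self.tip_index[lab] for lab in keep_labels]
        if len(keep) < 2:
            raise ValueError("need at least two tips to prune to")
        marked = np.zeros(self.n_nodes, dtype=bool)
        marked[keep] = True
        for node in self.postorder:
            p = self.parent[node]
            if p >= 0 and marked[node]:
                marked[p] = True
        # collapse chains: effective parent = nearest marked ancestor with
        # >= 2 marked children (or the top-most marked node)
        nkids = np.zeros(self.n_nodes, dtype=np.int64)
        for node in range(self.n_nodes):
            p = self.parent[node]
            if p >= 0 and marked[node]:
                nkids[p] += 1
        is_real = marked & ((nkids >= 2) | (np.arange(self.n_nodes) < self.n_tips))
        new_ids: dict[int, int] = {}
        tips_new = [t for t in range(self.n_tips) if marked[t]]
        for i, t in enumerate(tips_new):
            new_ids[t] = i
        internals = [
            n for n in self.postorder if is_real[n] and n >= self.n_tips
        ]
        for k, n in enumerate(internals):
            new_ids[n] = len(tips_new) + k
        size = len(new_ids)
        parent = np.full(size, -1, dtype=np.int64)
        lengths = np.zeros(size)
        for old, new in new_ids.items():
            ln = 0.0
            p = old
            while True:
                ln += self.lengths[p] if self.parent[p] >= 0 else 0.0
                p = int(self.parent[p])
                if p < 0 or (is_real[p] and p in new_ids):
                    break
            if p >= 0 and p in new_ids:
                parent[new] = new_ids[p]
                lengths[new] = ln
        labels = [self.tip_labels[t] for t in tips_new]
        return Phylogeny(parent, lengths, labels)

    # ------------------------------------------------------------------ #
    #  Newick I/O (via dendropy)
    # ------------------------------------------------------------------ #
    def to_newick(self, node_values: dict[int, str] | None = None) -> str:
        labels = dict(self.node_labels)
        if node_values:
            labels.update({k: str(v) for k, v in node_values.items()})

        def render(node: int) -> str:
            if self.is_tip(node):
                body = self.tip_labels[node]
            else:
                inner = ",".join(render(c) for c in self.children[node])
                body = f"({inner}){labels.get(node, '')}"
            if node == self.root:
                return body
            return f"{body}:{self.lengths[node]:.12g}"

        import sys

        old = sys.getrecursionlimit()
        sys.setrecursionlimit(max(old, 10 * self.n_nodes + 100))
        try:
            return render(self.root) + ";"
        finally:
            sys.setrecursionlimit(old)

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        dt = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        return cls.from_dendropy(dt)

    @classmethod
    def from_dendropy(cls, dt: dendropy.Tree) -> "Phylogeny":
        leaves = list(dt.leaf_node_iter())
        tip_labels = [
            (lf.taxon.label if lf.taxon is not None else lf.label) or f"tip{i}"
            for i, lf in enumerate(leaves)
        ]
        ids: dict[int, int] = {id(lf): i for i, lf in enumerate(leaves)}
        nxt = len(leaves)
        for node in dt.postorder_node_iter():
            if id(node) not in ids:
                ids[id(node)] = nxt
                nxt += 1
        parent = np.full(nxt, -1, dtype=np.int64)
        lengths = np.zeros(nxt)
        node_labels: dict[int, str] = {}
        for node in dt.postorder_node_iter():
            i = ids[id(node)]
            if node.parent_node is not None:
                parent[i] = ids[id(node.parent_node)]
                lengths[i] = node.edge.length or 0.0
            if not node.is_leaf() and node.label:
                node_labels[i] = node.label
        return cls(parent, lengths, tip_labels, node_labels)

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    @classmethod
    def read(cls, path: str) -> "Phylogeny":
        with open(path) as fh:
            return cls.from_newick(fh.read())
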