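"""Array-backed phylogeny container.

dendropy handles newick I/O; the likelihood machinery wants flat arrays.
Nodes are numbered in post-order (tips first within that order), which is
the stable numbering used in all per-node outputs.
"""

from __future__ import annotations

import numpy as np
import dendropy

__all__ = ["Phylogeny"]


class Phylogeny:
    """Rooted tree with branch lengths in Myr, tips labelled uniquely.

    Attributes
    ----------
    n_tips, n_nodes : int
    parent : ndarray (n_nodes,) — parent index, -1 for the root
    children : list[list[int]]
    lengths : ndarray (n_nodes,) — branch length above each node (0 at root)
    postorder : ndarray — node indices, children before parents
    tip_labels : list[str] — label of node i for i < n_tips
    ages : ndarray — node time before present (root = tree height); on
        non-ultrametric trees, measured from the deepest tip
    """

    def __init__(self, parent, children, lengths, tip_labels):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.children = children
        self.lengths = np.asarray(lengths, dtype=float)
        if (self.lengths < 0).any():
            raise ValueError("negative branch lengths")
        self.tip_labels = list(tip_labels)
        if len(set(self.tip_labels)) != len(self.tip_labels):
            raise ValueError("tip labels are not unique")
        self.n_tips = len(tip_labels)
        self.n_nodes = len(parent)
        self.tip_index = {lab: i for i, lab in enumerate(self.tip_labels)}
        self.postorder = self._postorder()
        self.ages = self._ages()

    # -- construction -------------------------------------------------------
    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "Phylogeny":
        nodes = list(tree.postorder_node_iter())
        tips = [nd for nd in nodes if nd.is_leaf()]
        internals = [nd for nd in nodes if not nd.is_leaf()]
        ordered = tips + internals
        index = {id(nd): i for i, nd in enumerate(ordered)}
        parent = np.full(len(ordered), -1, dtype=np.int64)
        lengths = np.zeros(len(ordered))
        children: list[list[int]] = [[] for _ in ordered]
        for nd in ordered:
            i = index[id(nd)]
            lengths[i] = nd.edge.length or 0.0
            if nd.parent_node is not None:
                p = index[id(nd.parent_node)]
                parent[i] = p
                children[p].append(i)
        labels = [nd.taxon.label if nd.taxon is not None else f"tip{i}"
                  for i, nd in enumerate(tips)]
        return cls(parent, children, lengths, labels)

    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        tree = dendropy.Tree.get(data=text, schema="newick")
        return cls.from_dendropy(tree)

    def to_newick(self) -> str:
        def rec(i):
            if i < self.n_tips:
                core = self.tip_labels[i]
            else:
                core = "(" + ",".join(rec(c) for c in self.children[i]) + ")"
            if self.parent[i] >= 0:
                return f"{core}:{self.lengths[i]:.10g}"
            return core

        return rec(int(self.root)) + ";"

    # -- derived structure ---------------------------------------------------
    @property
    def root(self) -> int:
        return int(np.nonzero(self.parent == -1)[0][0])

    def _postorder(self):
        order, stack = [], [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                order.append(node)
            else:
                stack.append((node, True))
                for c in self.children[node]:
                    stack.append((c, False))
        return np.asarray(order, dtype=np.int64)

    def _ages(self):
        depth = np.zeros(self.n_nodes)
        for i in self.postorder[::-1]:
            p = self.parent[i]
            if p >= 0:
                depth[i] = depth[p] + self.lengths[i]
        height = depth[: self.n_tips].max() if self.n_tips else depth.max()
        return height - depth

    @property
    def height(self) -> float:
        return float(self.ages[self.root])

    def is_ultrametric(self, tol=1e-6) -> bool:
        tip_ages = self.ages[: self.n_tips]
        return bool(np.ptp(tip_ages) <= tol * max(self.height, 1.0))

    def is_binary(self) -> bool:
        return all(len(c) in (0, 2) for c in self.children)

    def total_length(self) -> float:
        return float(self.lengths.sum())

    def states_vector(self, tip_states: dict, n_states: int) -> np.ndarray:
        """Tip-state likelihood matrix (n_tips, n_states); ambiguity sets
        become indicator rows over the set."""
        L = np.zeros((self.n_tips, n_states))
        seen = set()
        for label, st in tip_states.items():
            if label not in self.tip_index:
                raise KeyError(f"tip {label!r} not in tree")
            seen.add(label)
            i = self.tip_index[label]
            if np.isscalar(st):
                L[i, int(st)] = 1.0
            else:
                for s in st:
                    L[i, int(s)] = 1.0
        missing = set(self.tip_labels) - seen
        if missing:
            raise KeyError(f"tips without a state: {sorted(missing)[:10]}")
        return L
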