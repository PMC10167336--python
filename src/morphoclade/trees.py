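"""Rooted phylogenies as flat arrays.

Parsing and serialisation go through :mod:`dendropy`; numerical work
(covariance matrices, traversals, Brownian-motion pruning) uses a flat
array representation in which tips occupy indices ``0..n_tips-1`` and
internal nodes follow, with the root last in postorder.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = ["Phylogeny", "TreeSet", "read_trees"]


@dataclass
class Phylogeny:
    """A rooted tree with branch lengths, indexed for vectorised work.

    Attributes
    ----------
    tip_labels : list of str
        Labels of the ``n_tips`` leaves; leaf ``i`` has node index ``i``.
    parent : ndarray of int
        Parent node index per node; the root's parent is ``-1``.
    branch_lengths : ndarray of float
        Length of the branch subtending each node; 0 for the root.
    children : list of list of int
        Child indices per node (empty for tips).
    postorder : ndarray of int
        All node indices, children before parents; root last.
    """

    tip_labels: list
    parent: np.ndarray
    branch_lengths: np.ndarray
    children: list = field(repr=False, default=None)
    postorder: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        self.parent = np.asarray(self.parent, dtype=int)
        self.branch_lengths = np.asarray(self.branch_lengths, dtype=float)
        if np.any(self.branch_lengths < 0):
            raise ValueError("negative branch lengths are not allowed")
        n = len(self.parent)
        if self.children is None:
            self.children = [[] for _ in range(n)]
            for i in range(n):
                if self.parent[i] >= 0:
                    self.children[self.parent[i]].append(i)
        if self.postorder is None:
            self.postorder = self._compute_postorder()

    # ------------------------------------------------------------------ #
    # construction
    # ------------------------------------------------------------------ #
    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "Phylogeny":
        tree = tree.clone(depth=1)
        tree.suppress_unifurcations()
        leaves = [lf for lf in tree.leaf_node_iter()]
        tip_labels = [lf.taxon.label if lf.taxon else str(i)
                      for i, lf in enumerate(leaves)]
        n_tips = len(leaves)
        internals = [nd for nd in tree.postorder_node_iter() if not nd.is_leaf()]
        index = {}
        for i, lf in enumerate(leaves):
            index[id(lf)] = i
        for j, nd in enumerate(internals):
            index[id(nd)] = n_tips + j
        n = n_tips + len(internals)
        parent = np.full(n, -1, dtype=int)
        bl = np.zeros(n)
        for nd in tree.preorder_node_iter():
            i = index[id(nd)]
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                bl[i] = nd.edge.length if nd.edge.length is not None else 0.0
        return cls(tip_labels, parent, bl)

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 rooting="default-rooted")
        return cls.from_dendropy(tree)

    # ------------------------------------------------------------------ #
    # basic structure
    # ------------------------------------------------------------------ #
    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return int(np.where(self.parent < 0)[0][0])

    def _compute_postorder(self) -> np.ndarray:
        order, stack = [], [self.root]
        visited = []
        while stack:
            nd = stack.pop()
            visited.append(nd)
            stack.extend(self.children[nd])
        return np.array(visited[::-1], dtype=int)

    def preorder(self) -> np.ndarray:
        return self.postorder[::-1]

    def node_heights(self) -> np.ndarray:
        """Distance from the root to every node."""
        h = np.zeros(self.n_nodes)
        for nd in self.preorder():
            if self.parent[nd] >= 0:
                h[nd] = h[self.parent[nd]] + self.branch_lengths[nd]
        return h

    @property
    def max_height(self) -> float:
        return float(self.node_heights()[: self.n_tips].max())

    def is_ultrametric(self, tol: float = 1e-6) -> bool:
        th = self.node_heights()[: self.n_tips]
        return bool(th.max() - th.min() <= tol * max(th.max(), 1.0))

    def clade_masks(self) -> np.ndarray:
        """Boolean (n_nodes, n_tips): tips descending from each node."""
        m = np.zeros((self.n_nodes, self.n_tips), dtype=bool)
        for nd in self.postorder:
            if not self.children[nd]:
                m[nd, nd] = True
            else:
                for ch in self.children[nd]:
                    m[nd] |= m[ch]
        return m

    # ------------------------------------------------------------------ #
    # covariance
    # ------------------------------------------------------------------ #
    def vcv(self, branch_lengths: np.ndarray | None = None) -> np.ndarray:
        """Brownian-motion covariance among tips (shared path lengths).

        An alternative set of branch lengths (same indexing) may be
        supplied, e.g. regime- or rate-transformed lengths.
        """
        bl = self.branch_lengths if branch_lengths is None else np.asarray(branch_lengths)
        masks = self.clade_masks()
        C = np.zeros((self.n_tips, self.n_tips))
        for nd in range(self.n_nodes):
            if self.parent[nd] < 0:
                continue
            m = masks[nd]
            C[np.ix_(m, m)] += bl[nd]
        return C

    def full_vcv(self) -> np.ndarray:
        """Shared path length from the root for every pair of nodes."""
        masks = self.clade_masks()
        n = self.n_nodes
        C = np.zeros((n, n))
        heights = self.node_heights()
        # shared path of nodes a,b = height of their MRCA
        anc = [[] for _ in range(n)]
        for nd in range(n):
            cur = nd
            while cur >= 0:
                anc[nd].append(cur)
                cur = self.parent[cur]
            anc[nd] = set(anc[nd])
        for a in range(n):
            for b in range(a, n):
                common = anc[a] & anc[b]
                C[a, b] = C[b, a] = max(heights[c] for c in common)
        return C

    # ------------------------------------------------------------------ #
    # serialisation
    # ------------------------------------------------------------------ #
    def to_newick(self, annotations: dict | None = None, digits: int = 10) -> str:
        """Newick string; ``annotations`` maps node index -> string tag
        inserted as a branch comment ``[&tag]``."""

        def rec(nd: int) -> str:
            if not self.children[nd]:
                s = self.tip_labels[nd].replace(" ", "_")
            else:
                s = "(" + ",".join(rec(c) for c in self.children[nd]) + ")"
            if self.parent[nd] >= 0:
                s += f":{self.branch_lengths[nd]:.{digits}g}"
                if annotations and nd in annotations:
                    s += f"[&{annotations[nd]}]"
            return s

        return rec(self.root) + ";"

    def scale(self, factor: float) -> "Phylogeny":
        return Phylogeny(list(self.tip_labels), self.parent.copy(),
                         self.branch_lengths * factor)

    def rescale_to_height(self, height: float = 1.0) -> "Phylogeny":
        return self.scale(height / self.max_height)

    def tip_index(self, labels) -> np.ndarray:
        lut = {lab: i for i, lab in enumerate(self.tip_labels)}
        try:
            return np.array([lut[l] for l in labels], dtype=int)
        except KeyError as e:
            raise KeyError(f"label {e} not among tree tips") from None


@dataclass
class TreeSet:
    """A collection of rooted trees over a common tip set."""

    trees: list
    summary_tree: Phylogeny | None = None

    def __post_init__(self):
        if not self.trees:
            raise ValueError("empty tree set")
        tips = set(self.trees[0].tip_labels)
        for t in self.trees[1:]:
            if set(t.tip_labels) != tips:
                raise ValueError("trees in a TreeSet must share one tip set")

    def __len__(self):
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    def __getitem__(self, i):
        return self.trees[i]

    @property
    def tip_labels(self):
        return self.trees[0].tip_labels


def read_trees(path, schema: str | None = None) -> TreeSet:
    """Read Newick or NEXUS trees (translate tables supported) from a file."""
    path = str(path)
    if schema is None:
        with open(path) as fh:
            head = fh.read(512).lstrip()
        schema = "nexus" if head.upper().startswith("#NEXUS") else "newick"
    tl = dendropy.TreeList.get(path=path, schema=schema, rooting="default-rooted")
    trees = [Phylogeny.from_dendropy(t) for t in tl]
    return TreeSet(trees, summary_tree=trees[0])


def write_trees(treeset: TreeSet, path) -> None:
    with open(path, "w") as fh:
        for t in treeset:
            fh.write(t.to_newick() + "\n")
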