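"""Rooted binary trees with branch lengths and per-node state annotations.

The container is array-based (parent / child indices, branch lengths) so the
likelihood kernels can walk it without object overhead.  Trees round-trip
through Newick, with node states carried as hot comments (``[&S=0]``) that
dendropy and most phylogenetic viewers understand.  Node *depth* here means
node age: time above the tip level of an ultrametric tree, so tips have
depth 0 and the root's depth is the total tree depth.
"""

from __future__ import annotations

import io
from typing import Mapping

import numpy as np
import dendropy

__all__ = ["Tree", "read_newick", "read_tip_states", "write_tip_states"]

NO_STATE = -1


class Tree:
    """A rooted binary tree stored as index arrays.

    Parameters
    ----------
    parent : (n_nodes,) int array, -1 for the root
    children : (n_nodes, 2) int array, -1 rows for tips
    brlen : (n_nodes,) float array of branch lengths above each node
        (0 for the root)
    labels : sequence of tip labels (or None for internal nodes)
    states : optional (n_nodes,) int array in {0, 1}, -1 where unknown
    """

    def __init__(self, parent, children, brlen, labels, states=None):
        self.parent = np.asarray(parent, dtype=np.int32)
        self.children = np.asarray(children, dtype=np.int32)
        self.brlen = np.asarray(brlen, dtype=np.float64)
        self.labels = list(labels)
        n = self.parent.shape[0]
        if states is None:
            states = np.full(n, NO_STATE, dtype=np.int8)
        self.states = np.asarray(states, dtype=np.int8)
        self._postorder = None
        self._validate()

    # -- basic structure ---------------------------------------------------

    def _validate(self):
        n = self.n_nodes
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}")
        is_tip = self.children[:, 0] < 0
        if np.any((self.children[:, 0] < 0) != (self.children[:, 1] < 0)):
            raise ValueError("nodes must have 0 or 2 children")
        tips = [self.labels[i] for i in np.flatnonzero(is_tip)]
        if any(lbl is None for lbl in tips):
            raise ValueError("every tip must have a label")
        if len(set(tips)) != len(tips):
            dups = sorted({t for t in tips if tips.count(t) > 1})
            raise ValueError(f"duplicate tip labels: {dups}")
        if np.any(self.brlen < 0):
            raise ValueError("negative branch length")

    @property
    def n_nodes(self) -> int:
        return self.parent.shape[0]

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    @property
    def is_tip(self) -> np.ndarray:
        return self.children[:, 0] < 0

    @property
    def tip_indices(self) -> np.ndarray:
        return np.flatnonzero(self.is_tip)

    @property
    def n_tips(self) -> int:
        return int(self.is_tip.sum())

    def postorder(self) -> np.ndarray:
        """Node indices in postorder (children before parents; root last)."""
        if self._postorder is None:
            order = np.empty(self.n_nodes, dtype=np.int32)
            stack = [self.root]
            k = self.n_nodes
            while stack:  # reverse preorder == postorder reversed
                v = stack.pop()
                k -= 1
                order[k] = v
                c0, c1 = self.children[v]
                if c0 >= 0:
                    stack.append(int(c0))
                    stack.append(int(c1))
            self._postorder = order
        return self._postorder

    def tip_states(self) -> dict[str, int]:
        """Mapping tip label -> state for tips with a recorded state."""
        out = {}
        for i in self.tip_indices:
            if self.states[i] != NO_STATE:
                out[self.labels[i]] = int(self.states[i])
        return out

    # -- depths ------------------------------------------------------------

    def distances_from_root(self) -> np.ndarray:
        d = np.zeros(self.n_nodes)
        for v in self.postorder()[::-1]:  # preorder
            p = self.parent[v]
            if p >= 0:
                d[v] = d[p] + self.brlen[v]
        return d

    @property
    def tree_depth(self) -> float:
        d = self.distances_from_root()
        return float(d[self.is_tip].max())

    def node_depths(self, rel_tol: float = 1e-6) -> np.ndarray:
        """Node ages (time above the tip level) for an ultrametric tree.

        Raises
        ------
        ValueError
            If the tree is not ultrametric within ``rel_tol * tree_depth``;
            the message names the worst-offending tip.
        """
        d = self.distances_from_root()
        tips = self.tip_indices
        depth = d[tips].max()
        dev = depth - d[tips]
        worst = int(np.argmax(dev))
        if depth > 0 and dev[worst] > rel_tol * depth:
            raise ValueError(
                "tree is not ultrametric: tip "
                f"{self.labels[tips[worst]]!r} is {dev[worst]:.6g} below the "
                f"deepest tip (tree depth {depth:.6g})"
            )
        ages = depth - d
        ages[tips] = 0.0
        return ages

    # -- newick ------------------------------------------------------------

    def to_newick(self, annotate_states: bool = True, fmt: str = "%.12g") -> str:
        """Serialize to Newick with deterministic child ordering.

        Children are ordered by the lexicographically smallest tip label in
        their subtree.  States (where recorded) are written as ``[&S=x]``
        hot comments after the node label.
        """
        min_label = [None] * self.n_nodes
        for v in self.postorder():
            if self.is_tip[v]:
                min_label[v] = self.labels[v]
            else:
                c0, c1 = self.children[v]
                min_label[v] = min(min_label[c0], min_label[c1])

        def ann(v):
            s = self.states[v]
            return f"[&S={int(s)}]" if (annotate_states and s != NO_STATE) else ""

        # iterative emit to avoid recursion limits on big trees
        out = io.StringIO()
        stack = [("node", self.root, True)]
        while stack:
            kind, v, is_root = stack.pop()
            if kind == "text":
                out.write(v)
                continue
            tail = ann(v) + ("" if is_root else ":" + fmt % self.brlen[v])
            if self.is_tip[v]:
                out.write(self.labels[v] + tail)
            else:
                c0, c1 = self.children[v]
                if min_label[c1] < min_label[c0]:
                    c0, c1 = c1, c0
                out.write("(")
                stack.append(("text", ")" + tail, None))
                stack.append(("node", int(c1), False))
                stack.append(("text", ",", None))
                stack.append(("node", int(c0), False))
        return out.getvalue() + ";"

    @classmethod
    def from_dendropy(cls, dtree: "dendropy.Tree") -> "Tree":
        nodes = list(dtree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        n = len(nodes)
        parent = np.full(n, -1, dtype=np.int32)
        children = np.full((n, 2), -1, dtype=np.int32)
        brlen = np.zeros(n)
        labels: list = [None] * n
        states = np.full(n, NO_STATE, dtype=np.int8)
        for i, nd in enumerate(nodes):
            kids = nd.child_nodes()
            if len(kids) not in (0, 2):
                raise ValueError(
                    f"tree is not binary: node with {len(kids)} children"
                )
            for j, c in enumerate(kids):
                children[i, j] = index[id(c)]
                parent[index[id(c)]] = i
            if nd.edge.length is not None:
                brlen[i] = float(nd.edge.length)
            if nd.taxon is not None:
                labels[i] = nd.taxon.label
            elif nd.label and not kids:
                labels[i] = nd.label
            s = nd.annotations.get_value("S", None)
            if s is not None:
                states[i] = int(s)
        return cls(parent, children, brlen, labels, states)


def read_newick(source: str) -> Tree:
    """Parse a Newick string (``[&S=x]`` comments become node states)."""
    dtree = dendropy.Tree.get(
        data=source,
        schema="newick",
        extract_comment_metadata=True,
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    return Tree.from_dendropy(dtree)


def read_tip_states(text: str) -> dict[str, int]:
    """Parse a two-column tab-separated tip-state table (label, 0/1)."""
    out = {}
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) != 2:
            raise ValueError(f"line {lineno}: expected 2 columns, got {len(fields)}")
        label, state = fields
        if state not in ("0", "1"):
            raise ValueError(f"line {lineno}: state must be 0 or 1, got {state!r}")
        out[label] = int(state)
    return out


def write_tip_states(states: Mapping[str, int]) -> str:
    return "".join(f"{k}\t{v}\n" for k, v in states.items())
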