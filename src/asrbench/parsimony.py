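"""Most-parsimonious reconstruction (MPR) of binary ancestral states.

For each internal node, MPR reports the *set* of states that node takes
across all labelings achieving the global minimum number of state changes
(unit, symmetric change cost; branch lengths ignored).  This differs from a
single-pass Fitch final state: a node's call is "ambiguous" exactly when
both states occur in some minimum-change labeling.

The implementation is the two-pass interval method specialised to two
states: a bottom-up pass computes, for each node and state, the minimal
change count within the node's subtree; a top-down pass computes the
minimal count over the rest of the tree; a state is attainable at a node iff
the two add up to the global minimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._treedata import tree_arrays
from .trees import Tree

__all__ = ["MprResult", "mpr_reconstruct", "AMBIGUOUS"]

#: call code for "both states occur among the most parsimonious labelings"
AMBIGUOUS = 2


@dataclass
class MprResult:
    """Per-node MPR calls (0, 1 or AMBIGUOUS) and the minimum change count.

    ``calls`` is indexed by node id; a tip's call is its observed state.
    """

    calls: np.ndarray
    min_changes: int
    tree: Tree

    def call(self, node: int) -> int:
        return int(self.calls[node])

    def to_table(self) -> str:
        names = {0: "0", 1: "1", AMBIGUOUS: "ambiguous"}
        lines = ["node\tcall"]
        for v in range(self.tree.n_nodes):
            if not self.tree.is_tip[v]:
                lines.append(f"{v}\t{names[int(self.calls[v])]}")
        return "\n".join(lines) + "\n"


def mpr_reconstruct(tree: Tree, tip_states=None) -> MprResult:
    """MPR ancestral-state sets for every internal node.

    Parameters
    ----------
    tree
        Rooted binary tree (branch lengths are ignored).
    tip_states
        Mapping tip label -> {0, 1}; defaults to states on the tree.
    """
    post, children, _, tipstate = tree_arrays(tree, tip_states)
    n = tree.n_nodes
    INF = np.iinfo(np.int32).max // 4

    # subtree cost: minimal changes within v's subtree given state(v) = s
    cost = np.zeros((n, 2), np.int32)
    for v in post:
        c0, c1 = children[v]
        if c0 < 0:
            s = tipstate[v]
            cost[v, 0] = 0 if s == 0 else INF
            cost[v, 1] = 0 if s == 1 else INF
        else:
            for s in (0, 1):
                tot = 0
                for c in (c0, c1):
                    tot += min(cost[c, 0] + (s != 0), cost[c, 1] + (s != 1))
                cost[v, s] = tot

    root = post[-1]
    min_changes = int(min(cost[root, 0], cost[root, 1]))

    # outside cost: minimal changes in the rest of the tree given state(v) = s
    out = np.zeros((n, 2), np.int32)
    for v in post[::-1]:  # preorder
        c0, c1 = children[v]
        if c0 < 0:
            continue
        for c, sib in ((c0, c1), (c1, c0)):
            for s in (0, 1):
                best = INF
                for sv in (0, 1):
                    sib_cost = min(
                        cost[sib, 0] + (sv != 0), cost[sib, 1] + (sv != 1)
                    )
                    tot = (s != sv) + out[v, sv] + sib_cost
                    if tot < best:
                        best = tot
                out[c, s] = best

    calls = np.empty(n, np.int8)
    total = cost + out
    for v in range(n):
        in0 = total[v, 0] == min_changes
        in1 = total[v, 1] == min_changes
        calls[v] = AMBIGUOUS if (in0 and in1) else (0 if in0 else 1)
    return MprResult(calls=calls, min_changes=min_changes, tree=tree)
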