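"""Flat array view of a tree + tip states, shared by the ASR methods."""

from __future__ import annotations

import numpy as np

from .trees import Tree


def tree_arrays(tree: Tree, tip_states=None):
    """Return (postorder, children, brlen, tipstate) arrays.

    ``tip_states`` maps tip label -> {0,1}; defaults to the states recorded
    on the tree.  Raises ``ValueError`` listing tips with no state.
    """
    if tip_states is None:
        tip_states = tree.tip_states()
    tipstate = np.full(tree.n_nodes, -1, np.int8)
    missing = []
    for i in tree.tip_indices:
        lbl = tree.labels[i]
        s = tip_states.get(lbl)
        if s is None:
            missing.append(lbl)
        elif s not in (0, 1):
            raise ValueError(f"tip {lbl!r} has non-binary state {s!r}")
        else:
            tipstate[i] = s
    if missing:
        raise ValueError(f"missing states for tips: {sorted(missing)}")
    return tree.postorder(), tree.children, tree.brlen, tipstate
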