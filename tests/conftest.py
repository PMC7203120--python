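"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive: exhaustive enumeration over
labelings for parsimony and over internal-state assignments for Mk2.  They
are used to validate the production two-pass / pruning implementations on
small trees.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from asrbench.trees import NO_STATE, Tree


# --------------------------------------------------------------------------
# building small trees from nested tuples, e.g. (("A", "B"), "C")
# --------------------------------------------------------------------------

def tuples_to_tree(spec, brlen=1.0, tip_states=None):
    """Build a Tree from nested 2-tuples of tip labels.

    ``brlen`` is a constant branch length or a dict keyed by tip label /
    frozenset of the clade's tip labels for internal nodes.
    """
    parent, children, lengths, labels = [], [], [], []

    def blen(key):
        if isinstance(brlen, dict):
            # the root's entry may be omitted; its length is reset to 0 anyway
            return brlen.get(key, 0.0)
        return brlen

    def build(node):
        idx = len(parent)
        parent.append(-1)
        children.append([-1, -1])
        lengths.append(0.0)
        labels.append(None)
        if isinstance(node, tuple):
            clade = frozenset(_tips_of(node))
            lengths[idx] = blen(clade)
            for k, sub in enumerate(node):
                c = build(sub)
                children[idx][k] = c
                parent[c] = idx
        else:
            labels[idx] = node
            lengths[idx] = blen(node)
        return idx

    build(spec)
    lengths[0] = 0.0
    states = None
    if tip_states is not None:
        states = np.full(len(parent), NO_STATE, np.int8)
        for i, lbl in enumerate(labels):
            if lbl is not None:
                states[i] = tip_states[lbl]
    return Tree(parent, np.array(children), lengths, labels, states)


def _tips_of(node):
    if isinstance(node, tuple):
        for sub in node:
            yield from _tips_of(sub)
    else:
        yield node


def all_topologies(labels):
    """All rooted binary tree shapes on the given labeled tips
    ((2n-3)!! of them), as nested tuples."""
    labels = list(labels)
    if len(labels) == 1:
        return [labels[0]]
    first, rest = labels[0], labels[1:]

    def attach(shape, tip):
        # attach at this position (new root above shape), plus recursively
        yield (shape, tip)
        if isinstance(shape, tuple):
            a, b = shape
            for sub in attach(a, tip):
                yield (sub, b)
            for sub in attach(b, tip):
                yield (a, sub)

    shapes = [first]
    for tip in rest:
        shapes = [s for old in shapes for s in attach(old, tip)]
    return shapes


# --------------------------------------------------------------------------
# oracles
# --------------------------------------------------------------------------

def brute_parsimony(tree: Tree, tip_states):
    """Exhaustive MPR oracle: per-node attainable-state sets and the
    minimum change count, by enumerating all internal labelings."""
    internal = np.flatnonzero(~tree.is_tip)
    tips = {int(i): tip_states[tree.labels[i]] for i in tree.tip_indices}
    best = None
    sets: dict[int, set] = {int(v): set() for v in internal}
    for assign in itertools.product((0, 1), repeat=len(internal)):
        st = dict(tips)
        st.update({int(v): s for v, s in zip(internal, assign)})
        changes = sum(
            st[int(tree.parent[v])] != st[v]
            for v in range(tree.n_nodes)
            if tree.parent[v] >= 0
        )
        if best is None or changes < best:
            best = changes
            sets = {int(v): {st[int(v)]} for v in internal}
        elif changes == best:
            for v in internal:
                sets[int(v)].add(st[int(v)])
    return sets, best


def mk2_pmat(q01, q10, t):
    s = q01 + q10
    pi1, pi0 = q01 / s, q10 / s
    e = np.exp(-s * t)
    return np.array(
        [[pi0 + pi1 * e, pi1 * (1 - e)], [pi0 * (1 - e), pi1 + pi0 * e]]
    )


def brute_mk2(tree: Tree, tip_states, q01, q10, prior=(0.5, 0.5), fix=None):
    """Mk2 likelihood by summing over all internal-state assignments;
    optionally with one node's state fixed."""
    internal = np.flatnonzero(~tree.is_tip)
    tips = {int(i): tip_states[tree.labels[i]] for i in tree.tip_indices}
    root = tree.root
    total = 0.0
    for assign in itertools.product((0, 1), repeat=len(internal)):
        st = dict(tips)
        st.update({int(v): s for v, s in zip(internal, assign)})
        if fix is not None and st[fix[0]] != fix[1]:
            continue
        lik = prior[st[root]]
        for v in range(tree.n_nodes):
            p = tree.parent[v]
            if p >= 0:
                lik *= mk2_pmat(q01, q10, tree.brlen[v])[st[int(p)], st[v]]
        total += lik
    return total


# --------------------------------------------------------------------------
# fixtures
# --------------------------------------------------------------------------

@pytest.fixture(scope="session")
def balanced4():
    """Balanced 4-tip tree ((A,B),(C,D)) with unit branches."""
    return tuples_to_tree((("A", "B"), ("C", "D")))
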