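"""Joint simulation of trees and a binary character under BiSSE.

A single lineage starts in state 0 (the ancestral state).  While a lineage
is in state *s* it speciates at rate ``lambda_s``, goes extinct at rate
``mu_s`` and flips its character at rate ``q_s,1-s``.  Event times are drawn
exactly (Gillespie): the total rate over extant lineages sets an exponential
waiting time, and the lineage/event is chosen proportionally to its rate.

The simulation is *conditioned on survival*: it runs until the extant
lineage count first reaches the target tip number, and attempts in which the
whole clade dies first are discarded (and counted).  Extinct subtrees are
then pruned, unifurcations suppressed (branch lengths summed), and the tree
re-rooted at the earliest bifurcation with surviving descendants on both
sides.  True states are recorded at every node, and character transitions
that lie on branches of the pruned tree are counted.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
from numba import njit

from .scenarios import ScenarioParams
from .trees import NO_STATE, Tree

__all__ = [
    "SimTree",
    "TreeSummary",
    "SimulationError",
    "simulate_conditioned",
    "simulate_summary",
    "prune_extinct",
    "tree_summary",
    "derive_seed",
]


class SimulationError(RuntimeError):
    pass


def derive_seed(global_seed: int, scenario_id: str, replicate: int) -> int:
    """Stable per-tree seed (< 2**31) so any tree is reproducible alone."""
    h = hashlib.blake2b(
        f"{global_seed}:{scenario_id}:{replicate}".encode(), digest_size=4
    ).digest()
    return int.from_bytes(h, "big") & 0x7FFFFFFF


# ---------------------------------------------------------------------------
# Gillespie kernel.  Lineages are edges: each is born at a parent's
# speciation (or at time 0 for the first) and ends by extinction, by
# speciation into two children, or by reaching the stopping time alive.
# status codes: 0 = alive at stop, 1 = extinct, 2 = speciated.
# ---------------------------------------------------------------------------


@njit(cache=True)
def _gillespie(lam0, lam1, mu0, mu1, q01, q10, n_tips, max_attempts, seed):
    np.random.seed(seed)
    r0 = lam0 + mu0 + q01
    r1 = lam1 + mu1 + q10

    cap = 4 * n_tips + 64
    tcap = 4 * n_tips + 64
    parent = np.empty(cap, np.int64)
    child0 = np.empty(cap, np.int64)
    child1 = np.empty(cap, np.int64)
    t_birth = np.empty(cap, np.float64)
    t_end = np.empty(cap, np.float64)
    state_birth = np.empty(cap, np.int8)
    status = np.empty(cap, np.int8)
    trans_lin = np.empty(tcap, np.int64)
    trans_time = np.empty(tcap, np.float64)
    alive0 = np.empty(n_tips + 1, np.int64)
    alive1 = np.empty(n_tips + 1, np.int64)

    n_rejected = 0
    for _attempt in range(max_attempts):
        n_lin = 1
        n_trans = 0
        parent[0] = -1
        child0[0] = -1
        child1[0] = -1
        t_birth[0] = 0.0
        state_birth[0] = 0
        status[0] = 0
        alive0[0] = 0
        n0 = 1
        n1 = 0
        t = 0.0
        alive = True
        while True:
            rate0 = n0 * r0
            total = rate0 + n1 * r1
            t += np.random.exponential(1.0 / total)
            if np.random.random() * total < rate0:
                s = 0
                j = int(np.random.random() * n0)
                if j == n0:
                    j = n0 - 1
                lid = alive0[j]
                u = np.random.random() * r0
                lam, mu = lam0, mu0
            else:
                s = 1
                j = int(np.random.random() * n1)
                if j == n1:
                    j = n1 - 1
                lid = alive1[j]
                u = np.random.random() * r1
                lam, mu = lam1, mu1

            if u < lam:
                # speciation: lineage lid ends, two children born in state s
                if n_lin + 2 > cap:
                    cap *= 2
                    parent = _grow_i8(parent, cap)
                    child0 = _grow_i8(child0, cap)
                    child1 = _grow_i8(child1, cap)
                    t_birth = _grow_f8(t_birth, cap)
                    t_end = _grow_f8(t_end, cap)
                    state_birth = _grow_i1(state_birth, cap)
                    status = _grow_i1(status, cap)
                t_end[lid] = t
                status[lid] = 2
                a = n_lin
                b = n_lin + 1
                n_lin += 2
                for cid in (a, b):
                    parent[cid] = lid
                    child0[cid] = -1
                    child1[cid] = -1
                    t_birth[cid] = t
                    state_birth[cid] = s
                    status[cid] = 0
                child0[lid] = a
                child1[lid] = b
                if s == 0:
                    alive0[j] = a
                    alive0[n0] = b
                    n0 += 1
                else:
                    alive1[j] = a
                    alive1[n1] = b
                    n1 += 1
                if n0 + n1 == n_tips:
                    break
            elif u < lam + mu:
                # extinction
                t_end[lid] = t
                status[lid] = 1
                if s == 0:
                    n0 -= 1
                    alive0[j] = alive0[n0]
                else:
                    n1 -= 1
                    alive1[j] = alive1[n1]
                if n0 + n1 == 0:
                    alive = False
                    break
            else:
                # character transition
                if n_trans + 1 > tcap:
                    tcap *= 2
                    trans_lin = _grow_i8(trans_lin, tcap)
                    trans_time = _grow_f8(trans_time, tcap)
                trans_lin[n_trans] = lid
                trans_time[n_trans] = t
                n_trans += 1
                if s == 0:
                    n0 -= 1
                    alive0[j] = alive0[n0]
                    alive1[n1] = lid
                    n1 += 1
                else:
                    n1 -= 1
                    alive1[j] = alive1[n1]
                    alive0[n0] = lid
                    n0 += 1

        if alive:
            for j in range(n0):
                t_end[alive0[j]] = t
            for j in range(n1):
                t_end[alive1[j]] = t
            return (
                True,
                n_rejected,
                parent[:n_lin].copy(),
                child0[:n_lin].copy(),
                child1[:n_lin].copy(),
                t_birth[:n_lin].copy(),
                t_end[:n_lin].copy(),
                state_birth[:n_lin].copy(),
                status[:n_lin].copy(),
                trans_lin[:n_trans].copy(),
                trans_time[:n_trans].copy(),
                t,
            )
        n_rejected += 1

    return (
        False,
        n_rejected,
        parent[:0].copy(),
        child0[:0].copy(),
        child1[:0].copy(),
        t_birth[:0].copy(),
        t_end[:0].copy(),
        state_birth[:0].copy(),
        status[:0].copy(),
        trans_lin[:0].copy(),
        trans_time[:0].copy(),
        0.0,
    )


@njit(cache=True)
def _grow_i8(a, cap):
    b = np.empty(cap, np.int64)
    b[: a.shape[0]] = a
    return b


@njit(cache=True)
def _grow_f8(a, cap):
    b = np.empty(cap, np.float64)
    b[: a.shape[0]] = a
    return b


@njit(cache=True)
def _grow_i1(a, cap):
    b = np.empty(cap, np.int8)
    b[: a.shape[0]] = a
    return b


@njit(cache=True)
def _kept_and_rep(parent, child0, child1, status):
    """kept = lineage has an extant descendant (or is extant);
    rep[i] = i's chain representative after suppressing unifurcations:
    the first descendant (possibly i itself) that is extant or splits
    into two kept children."""
    n = parent.shape[0]
    kept = status == 0
    for i in range(n - 1, -1, -1):
        if kept[i] and parent[i] >= 0:
            kept[parent[i]] = True
    rep = np.empty(n, np.int64)
    for i in range(n - 1, -1, -1):
        if not kept[i]:
            rep[i] = -1
        elif status[i] != 2:
            rep[i] = i
        else:
            k0 = kept[child0[i]]
            k1 = kept[child1[i]]
            if k0 and k1:
                rep[i] = i
            elif k0:
                rep[i] = rep[child0[i]]
            else:
                rep[i] = rep[child1[i]]
    return kept, rep


@dataclass(frozen=True)
class TreeSummary:
    """Per-tree statistics used for exclusion decisions and reporting."""

    n_tips: int
    tree_depth: float
    n_transitions: int
    n_tips_state0: int
    n_tips_state1: int
    invariant: bool
    n_rejected: int
    seed: int


@dataclass
class SimTree:
    """An accepted, pruned simulation: tree + true states + provenance."""

    tree: Tree
    params: ScenarioParams
    n_transitions: int
    n_rejected: int
    seed: int

    @property
    def tip_states(self) -> dict[str, int]:
        return self.tree.tip_states()

    @property
    def tree_depth(self) -> float:
        return self.tree.tree_depth


def _raw_simulation(params, n_tips, seed, max_attempts):
    ok, n_rej, parent, c0, c1, tb, te, sb, status, tlin, ttime, stop = _gillespie(
        params.lambda0,
        params.lambda1,
        params.mu0,
        params.mu1,
        params.q01,
        params.q10,
        n_tips,
        max_attempts,
        seed,
    )
    if not ok:
        raise SimulationError(
            f"no accepted tree for scenario {params.scenario_id} within "
            f"{max_attempts} attempts (all went extinct before {n_tips} tips)"
        )
    return n_rej, parent, c0, c1, tb, te, sb, status, tlin, ttime, stop


def _end_states(state_birth, trans_lin, n_lin):
    parity = np.bincount(trans_lin, minlength=n_lin).astype(np.int8) & 1
    return state_birth ^ parity


def simulate_summary(
    params: ScenarioParams,
    n_tips: int,
    seed: int,
    max_attempts: int = 100_000,
) -> TreeSummary:
    """Simulate one accepted tree and return its summary only.

    Avoids building the pruned tree object; used for simulator-level
    statistics (depths, invariant-character exclusion and rejection rates)
    at scale.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    n_rej, parent, c0, c1, tb, te, sb, status, tlin, ttime, stop = _raw_simulation(
        params, n_tips, seed, max_attempts
    )
    kept, rep = _kept_and_rep(parent, c0, c1, status)
    root = rep[0]
    root_time = te[root]
    end_state = _end_states(sb, tlin, parent.shape[0])
    tip_states = end_state[status == 0]
    n1 = int(tip_states.sum())
    n_trans = int(np.count_nonzero(kept[tlin] & (ttime > root_time)))
    return TreeSummary(
        n_tips=n_tips,
        tree_depth=float(stop - root_time),
        n_transitions=n_trans,
        n_tips_state0=n_tips - n1,
        n_tips_state1=n1,
        invariant=(n1 == 0 or n1 == n_tips),
        n_rejected=n_rej,
        seed=seed,
    )


def simulate_conditioned(
    params: ScenarioParams,
    n_tips: int,
    seed: int,
    max_attempts: int = 100_000,
    count_transitions: str = "pruned",
) -> SimTree:
    """Simulate one accepted tree under BiSSE, pruned of extinct lineages.

    Parameters
    ----------
    params
        The six BiSSE rates.
    n_tips
        Target number of extant tips (>= 2); the simulation stops at the
        instant the ``n_tips``-th extant lineage is created.
    seed
        Seed for the event stream; identical seed and parameters give a
        bit-identical tree.
    max_attempts
        Cap on rejected (extinct) attempts before raising
        :class:`SimulationError`.
    count_transitions
        ``"pruned"`` (default) counts character changes lying on branches of
        the pruned tree; ``"full"`` counts every change event in the accepted
        simulation, including on extinct lineages.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if count_transitions not in ("pruned", "full"):
        raise ValueError("count_transitions must be 'pruned' or 'full'")
    n_rej, parent, c0, c1, tb, te, sb, status, tlin, ttime, stop = _raw_simulation(
        params, n_tips, seed, max_attempts
    )
    n_lin = parent.shape[0]
    kept, rep = _kept_and_rep(parent, c0, c1, status)
    end_state = _end_states(sb, tlin, n_lin)
    root = int(rep[0])
    root_time = te[root]

    # build pruned tree: nodes are chain representatives
    n_nodes = 2 * n_tips - 1
    p_arr = np.full(n_nodes, -1, np.int32)
    ch_arr = np.full((n_nodes, 2), -1, np.int32)
    bl_arr = np.zeros(n_nodes)
    st_arr = np.full(n_nodes, NO_STATE, np.int8)
    labels: list = [None] * n_nodes

    tip_rank = {}
    for lid in np.flatnonzero(status == 0):
        tip_rank[int(lid)] = len(tip_rank) + 1

    idx_of = {root: 0}
    stack = [root]
    nxt = 1
    while stack:
        lid = stack.pop()
        i = idx_of[lid]
        st_arr[i] = end_state[lid]
        if status[lid] == 0:
            labels[i] = f"t{tip_rank[lid]}"
            continue
        for k, c in enumerate((c0[lid], c1[lid])):
            cr = int(rep[c])
            j = nxt
            nxt += 1
            idx_of[cr] = j
            ch_arr[i, k] = j
            p_arr[j] = i
            bl_arr[j] = te[cr] - te[lid]
            stack.append(cr)

    tree = Tree(p_arr, ch_arr, bl_arr, labels, st_arr)
    if count_transitions == "pruned":
        n_trans = int(np.count_nonzero(kept[tlin] & (ttime > root_time)))
    else:
        n_trans = int(tlin.shape[0])
    return SimTree(tree=tree, params=params, n_transitions=n_trans,
                   n_rejected=n_rej, seed=seed)


def tree_summary(sim: SimTree) -> TreeSummary:
    """Summary record of an accepted tree (invariant flag, depth, counts)."""
    states = np.array(list(sim.tip_states.values()))
    n1 = int(states.sum())
    n = states.shape[0]
    return TreeSummary(
        n_tips=n,
        tree_depth=sim.tree_depth,
        n_transitions=sim.n_transitions,
        n_tips_state0=n - n1,
        n_tips_state1=n1,
        invariant=(n1 == 0 or n1 == n),
        n_rejected=sim.n_rejected,
        seed=sim.seed,
    )


def prune_extinct(tree: Tree, extinct_tips) -> Tree:
    """Remove flagged extinct tips; suppress unifurcations, summing branch
    lengths; re-root at the earliest node with surviving lineages on both
    sides.  States of retained nodes are preserved.

    Parameters
    ----------
    tree
        A rooted binary tree.
    extinct_tips
        Collection of tip labels to remove.
    """
    extinct = set(extinct_tips)
    unknown = extinct - {tree.labels[i] for i in tree.tip_indices}
    if unknown:
        raise ValueError(f"extinct labels not found among tips: {sorted(unknown)}")
    post = tree.postorder()
    kept = np.zeros(tree.n_nodes, bool)
    for v in post:
        if tree.is_tip[v]:
            kept[v] = tree.labels[v] not in extinct
        else:
            c0, c1 = tree.children[v]
            kept[v] = kept[c0] or kept[c1]
    n_extant = int(kept[tree.is_tip].sum())
    if n_extant < 2:
        raise ValueError(
            f"only {n_extant} extant tip(s) remain; cannot root at a bifurcation"
        )

    def resolve(v):
        # follow single-kept-child chains to a tip or a true bifurcation
        while not tree.is_tip[v]:
            c0, c1 = tree.children[v]
            if kept[c0] and kept[c1]:
                return v
            v = c0 if kept[c0] else c1
        return v

    root = resolve(tree.root)
    n_nodes = 2 * n_extant - 1
    p_arr = np.full(n_nodes, -1, np.int32)
    ch_arr = np.full((n_nodes, 2), -1, np.int32)
    bl_arr = np.zeros(n_nodes)
    st_arr = np.full(n_nodes, NO_STATE, np.int8)
    labels: list = [None] * n_nodes

    dist = tree.distances_from_root()
    idx_of = {int(root): 0}
    stack = [int(root)]
    nxt = 1
    while stack:
        v = stack.pop()
        i = idx_of[v]
        st_arr[i] = tree.states[v]
        if tree.is_tip[v]:
            labels[i] = tree.labels[v]
            continue
        for k, c in enumerate(tree.children[v]):
            cr = int(resolve(int(c)))
            j = nxt
            nxt += 1
            idx_of[cr] = j
            ch_arr[i, k] = j
            p_arr[j] = i
            bl_arr[j] = dist[cr] - dist[v]
            stack.append(cr)
    return Tree(p_arr, ch_arr, bl_arr, labels, st_arr)
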