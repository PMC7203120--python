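"""Error scoring of ancestral reconstructions against the true states.

Two metrics are used.  The *raw score* of a node is the probability the
method assigns to the wrong state (1 − p(true state)); maximum parsimony,
which emits calls rather than probabilities, scores 0 (correct), 0.5
(ambiguous) or 1 (wrong).  The *quantised score* maps probabilities to a
call of 1 (p₁ > 0.7), 0 (p₁ < 0.3) or ambiguous, and an *outright error* is
a non-ambiguous call that contradicts the truth.

Nodes are grouped into equal-count depth quantiles per tree (decile 1 =
shallowest, nearest the tips; decile 10 = deepest, containing the root), and
scores are aggregated per tree first, then averaged across the trees of a
scenario.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parsimony import AMBIGUOUS, MprResult
from .trees import Tree

__all__ = [
    "ScoringConfig",
    "quantise",
    "raw_error",
    "depth_deciles",
    "score_tree",
    "aggregate",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScoringConfig:
    """Thresholds for the quantised score and the MP ambiguous raw score."""

    upper_threshold: float = 0.7
    lower_threshold: float = 0.3
    mp_ambiguous_raw: float = 0.5
    n_quantiles: int = 10

    def __post_init__(self):
        if not (0.0 < self.lower_threshold < self.upper_threshold < 1.0):
            raise ValueError(
                "thresholds must satisfy 0 < lower < upper < 1, got "
                f"{self.lower_threshold}, {self.upper_threshold}"
            )


DEFAULT_CONFIG = ScoringConfig()


def quantise(p1, config: ScoringConfig = DEFAULT_CONFIG):
    """Map P(state 1) to a call: 1 above the upper threshold, 0 below the
    lower, ambiguous between (boundary values are ambiguous)."""
    p = np.asarray(p1, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("probabilities must lie in [0, 1]")
    call = np.full(p.shape, AMBIGUOUS, np.int8)
    call[p > config.upper_threshold] = 1
    call[p < config.lower_threshold] = 0
    return call if call.shape else int(call[()])


def raw_error(estimate, true_state, config: ScoringConfig = DEFAULT_CONFIG):
    """Raw error score of an estimate against the true state.

    Probability estimates score ``1 − p(true state)``; parsimony calls score
    0 if correct, ``config.mp_ambiguous_raw`` if ambiguous, 1 if wrong.
    """
    t = np.asarray(true_state)
    est = np.asarray(estimate)
    if np.issubdtype(est.dtype, np.floating):
        return np.where(t == 1, 1.0 - est, est)
    err = np.where(est == t, 0.0, 1.0)
    return np.where(est == AMBIGUOUS, config.mp_ambiguous_raw, err)


def depth_deciles(tree: Tree, n_quantiles: int = 10) -> dict[int, int]:
    """Assign each internal node a depth quantile (1 = shallowest group,
    ``n_quantiles`` = deepest, always containing the root).

    Internal nodes are ranked by age (ties broken by node id) and split into
    groups as equal as possible, any remainder going to the deepest groups.
    With fewer internal nodes than quantiles, the nodes fill the deepest
    groups one each.
    """
    ages = tree.node_depths()
    internal = np.flatnonzero(~tree.is_tip)
    order = internal[np.lexsort((internal, ages[internal]))]
    m = order.shape[0]
    if m <= n_quantiles:
        return {int(v): n_quantiles - m + i + 1 for i, v in enumerate(order)}
    base, rem = divmod(m, n_quantiles)
    sizes = [base + (1 if q > n_quantiles - rem else 0)
             for q in range(1, n_quantiles + 1)]
    res = {}
    k = 0
    for q, sz in enumerate(sizes, start=1):
        for v in order[k:k + sz]:
            res[int(v)] = q
        k += sz
    return res


def depth_decile_bins(tree: Tree, n_quantiles: int = 10) -> dict[int, int]:
    """Alternative grouping by equal-width age intervals (not rank)."""
    ages = tree.node_depths()
    depth = ages.max()
    internal = np.flatnonzero(~tree.is_tip)
    res = {}
    for v in internal:
        q = int(np.floor(ages[v] / depth * n_quantiles)) + 1
        res[int(v)] = min(q, n_quantiles)
    return res


def score_tree(
    tree: Tree,
    method: str,
    estimate,
    config: ScoringConfig = DEFAULT_CONFIG,
    grouping: str = "rank",
) -> pd.DataFrame:
    """Per-internal-node error records for one reconstruction of one tree.

    Parameters
    ----------
    tree
        Tree carrying the true states of every node.
    method
        Label for the reconstruction method (e.g. "MP", "Mk2", "BiSSE").
    estimate
        Either an :class:`MprResult` or an array of P(state 1) per node.
    grouping
        "rank" (equal-count depth deciles, default) or "age" (equal-width
        age bins).

    Returns
    -------
    DataFrame with columns node, depth, decile, true_state, method, p1,
    raw_error, quantised_call, outright_error.
    """
    ages = tree.node_depths()
    internal = np.flatnonzero(~tree.is_tip)
    truth = tree.states[internal].astype(int)
    if np.any(truth < 0):
        raise ValueError("tree is missing true states at internal nodes")
    groups = (depth_deciles if grouping == "rank" else depth_decile_bins)(
        tree, config.n_quantiles
    )
    decile = np.array([groups[int(v)] for v in internal])

    if isinstance(estimate, MprResult):
        calls = estimate.calls[internal]
        p1 = np.full(internal.shape, np.nan)
        raw = raw_error(calls, truth, config)
    else:
        p1 = np.asarray(estimate, dtype=float)[internal]
        calls = quantise(p1, config)
        raw = raw_error(p1, truth, config)
    outright = (calls != AMBIGUOUS) & (calls != truth)
    return pd.DataFrame(
        {
            "node": internal,
            "depth": ages[internal],
            "decile": decile,
            "true_state": truth,
            "method": method,
            "p1": p1,
            "raw_error": raw,
            "quantised_call": calls,
            "outright_error": outright,
        }
    )


def aggregate(
    records: pd.DataFrame,
    group_by: str = "scenario_decile",
    pooled: bool = False,
) -> pd.DataFrame:
    """Aggregate node error records.

    ``records`` must carry ``scenario_id`` and ``replicate`` columns in
    addition to the per-node columns of :func:`score_tree`.

    group_by
        "tree" — one row per (scenario, method, replicate);
        "scenario_decile" — per-tree decile means averaged (unweighted)
        across a scenario's trees, one row per (scenario, method, decile);
        "scenario_method" — per-tree means averaged across trees, one row
        per (scenario, method).
    pooled
        Pool all nodes of a group directly instead of averaging per-tree
        means (alternative averaging order).

    Output columns: mean_raw_error, accuracy (= 1 − mean_raw_error),
    outright_error_rate, ambiguous_rate, n_trees.
    """
    if records.empty:
        raise ValueError("no records to aggregate")
    req = {"scenario_id", "replicate", "method", "decile", "raw_error"}
    missing = req - set(records.columns)
    if missing:
        raise ValueError(f"records lack columns: {sorted(missing)}")

    per_tree_keys = ["scenario_id", "method", "replicate"]
    if group_by == "tree":
        keys, fine = per_tree_keys, per_tree_keys
    elif group_by == "scenario_decile":
        keys, fine = (["scenario_id", "method", "decile"],
                      per_tree_keys + ["decile"])
    elif group_by == "scenario_method":
        keys, fine = ["scenario_id", "method"], per_tree_keys
    else:
        raise ValueError(f"unknown group_by {group_by!r}")

    df = records.assign(
        ambiguous=records["quantised_call"] == AMBIGUOUS,
        outright=records["outright_error"].astype(float),
    )
    if pooled or group_by == "tree":
        grouped = df.groupby(keys, sort=True)
        out = grouped.agg(
            mean_raw_error=("raw_error", "mean"),
            outright_error_rate=("outright", "mean"),
            ambiguous_rate=("ambiguous", "mean"),
        )
        out["n_trees"] = grouped["replicate"].nunique()
    else:
        per_tree = df.groupby(fine, sort=True).agg(
            mean_raw_error=("raw_error", "mean"),
            outright_error_rate=("outright", "mean"),
            ambiguous_rate=("ambiguous", "mean"),
        )
        grouped = per_tree.groupby(keys, sort=True)
        out = grouped.mean()
        out["n_trees"] = per_tree.reset_index().groupby(keys)["replicate"].nunique()
    n_empty = out["mean_raw_error"].isna().sum()
    if n_empty:
        logger.warning("omitting %d empty group(s)", n_empty)
        out = out.dropna(subset=["mean_raw_error"])
    out["accuracy"] = 1.0 - out["mean_raw_error"]
    return out.reset_index()
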