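"""Mk2 ancestral state reconstruction.

The Mk2 model is a two-state continuous-time Markov chain on a fixed tree:
the character flips 0→1 at rate ``q01`` and 1→0 at rate ``q10``, with no
feedback on speciation or extinction.  The likelihood is computed by
Felsenstein pruning with the closed-form 2×2 transition probabilities

    P(t) = [[π0 + π1 e, π1 (1−e)], [π0 (1−e), π1 + π0 e]],
    e = exp(−(q01+q10) t),  π1 = q01/(q01+q10),  π0 = 1 − π1,

and marginal ancestral states are the relative likelihoods of the data with
a node fixed in state 0 versus 1, computed for every node in one
outside-pass.

Usage follows the model/results idiom::

    model = Mk2Asr(tree)                   # states read off the tree, or
    model = Mk2Asr(tree, tip_states={...}) # supplied separately
    res = model.fit(init_center=(0.1, 0.1), seed=1)
    res.marginal_asr()                     # P(state 1) per node
"""

from __future__ import annotations

import numpy as np
from numba import njit

from ._treedata import tree_arrays
from .fit import FitResult, multistart_fit
from .trees import Tree

__all__ = ["Mk2Asr", "Mk2AsrResults", "mk2_loglik", "ROOT_PRIORS"]

ROOT_PRIORS = ("flat", "stationary", "observed")


@njit(cache=True, inline="always")
def _pmat(q01, q10, t):
    s = q01 + q10
    pi1 = q01 / s
    pi0 = q10 / s
    e = np.exp(-s * t)
    return pi0 + pi1 * e, pi1 * (1.0 - e), pi0 * (1.0 - e), pi1 + pi0 * e


@njit(cache=True)
def _mk2_up(post, children, brlen, tipstate, q01, q10):
    n = post.shape[0]
    L = np.empty((n, 2))
    logscale = 0.0
    for k in range(n):
        v = post[k]
        c0 = children[v, 0]
        if c0 < 0:
            s = tipstate[v]
            L[v, 0] = 1.0 if s == 0 else 0.0
            L[v, 1] = 1.0 if s == 1 else 0.0
        else:
            c1 = children[v, 1]
            l0 = 1.0
            l1 = 1.0
            for c in (c0, c1):
                p00, p01, p10, p11 = _pmat(q01, q10, brlen[c])
                l0 *= p00 * L[c, 0] + p01 * L[c, 1]
                l1 *= p10 * L[c, 0] + p11 * L[c, 1]
            m = max(l0, l1)
            if m <= 0.0:
                return L, -np.inf
            L[v, 0] = l0 / m
            L[v, 1] = l1 / m
            logscale += np.log(m)
    return L, logscale


@njit(cache=True)
def _mk2_loglik(post, children, brlen, tipstate, q01, q10, prior0, prior1, obs_prior):
    L, logscale = _mk2_up(post, children, brlen, tipstate, q01, q10)
    if logscale == -np.inf:
        return -np.inf
    root = post[post.shape[0] - 1]
    if obs_prior:
        tot = L[root, 0] + L[root, 1]
        prior0 = L[root, 0] / tot
        prior1 = L[root, 1] / tot
    lik = prior0 * L[root, 0] + prior1 * L[root, 1]
    if lik <= 0.0:
        return -np.inf
    return np.log(lik) + logscale


@njit(cache=True)
def _mk2_marginal(post, children, brlen, tipstate, q01, q10, prior0, prior1,
                  obs_prior):
    n = post.shape[0]
    L, _ = _mk2_up(post, children, brlen, tipstate, q01, q10)
    root = post[n - 1]
    if obs_prior:
        tot = L[root, 0] + L[root, 1]
        prior0 = L[root, 0] / tot
        prior1 = L[root, 1] / tot
    # outside pass: O[v] ∝ likelihood of everything except v's subtree,
    # as a function of v's state (root prior included)
    O = np.empty((n, 2))
    O[root, 0] = prior0
    O[root, 1] = prior1
    for k in range(n - 1, -1, -1):  # preorder
        v = post[k]
        c0 = children[v, 0]
        if c0 < 0:
            continue
        c1 = children[v, 1]
        for c, sib in ((c0, c1), (c1, c0)):
            ps00, ps01, ps10, ps11 = _pmat(q01, q10, brlen[sib])
            s0 = ps00 * L[sib, 0] + ps01 * L[sib, 1]
            s1 = ps10 * L[sib, 0] + ps11 * L[sib, 1]
            p00, p01, p10, p11 = _pmat(q01, q10, brlen[c])
            a0 = O[v, 0] * s0
            a1 = O[v, 1] * s1
            o0 = a0 * p00 + a1 * p10
            o1 = a0 * p01 + a1 * p11
            m = o0 + o1
            O[c, 0] = o0 / m
            O[c, 1] = o1 / m
    p1 = np.empty(n)
    for v in range(n):
        w0 = L[v, 0] * O[v, 0]
        w1 = L[v, 1] * O[v, 1]
        p1[v] = w1 / (w0 + w1)
    return p1


def _prior_tuple(root_prior, q01=None, q10=None):
    if root_prior == "flat":
        return 0.5, 0.5, False
    if root_prior == "stationary":
        s = q01 + q10
        return q10 / s, q01 / s, False
    if root_prior == "observed":
        return 0.5, 0.5, True
    raise ValueError(f"unknown root prior {root_prior!r}; expected {ROOT_PRIORS}")


def mk2_loglik(tree: Tree, tip_states, params, root_prior="flat") -> float:
    """Log-likelihood of tip states under Mk2 rates ``params = (q01, q10)``."""
    return Mk2Asr(tree, tip_states, root_prior=root_prior).loglike(params)


class Mk2Asr:
    """Mk2 model of a binary character on a fixed tree.

    Parameters
    ----------
    tree
        Rooted binary tree with branch lengths.
    tip_states
        Mapping tip label -> {0, 1}; defaults to states recorded on the tree.
    root_prior
        "flat" (default: 1/2, 1/2), "stationary" (the chain's equilibrium
        at the fitted rates) or "observed" (weights proportional to the
        root's conditional likelihoods).
    """

    n_params = 2
    param_names = ("q01", "q10")

    def __init__(self, tree: Tree, tip_states=None, root_prior: str = "flat"):
        _prior_tuple(root_prior)  # validate early
        self.tree = tree
        self.root_prior = root_prior
        self.post, self.children, self.brlen, self.tipstate = tree_arrays(
            tree, tip_states
        )

    def loglike(self, params) -> float:
        q01, q10 = float(params[0]), float(params[1])
        if not (np.isfinite(q01) and np.isfinite(q10) and q01 > 0 and q10 > 0):
            raise ValueError(f"rates must be finite and positive, got {params}")
        p0, p1, obs = _prior_tuple(self.root_prior, q01, q10)
        return float(
            _mk2_loglik(
                self.post, self.children, self.brlen, self.tipstate,
                q01, q10, p0, p1, obs,
            )
        )

    def fit(self, init_center=None, n_starts: int = 3, seed=None,
            **fit_kwargs) -> "Mk2AsrResults":
        """Maximum-likelihood fit with multi-start Nelder–Mead on log rates.

        ``init_center`` is the center of the random starts (the true rates in
        a simulation study); defaults to a parsimony-flavoured guess of one
        expected change per total tree length for both rates.
        """
        if init_center is None:
            total = self.brlen.sum()
            guess = max(1.0 / total, 1e-4) if total > 0 else 0.1
            init_center = (guess, guess)
        result = multistart_fit(
            lambda r: self._loglik_raw(r),
            np.asarray(init_center, float),
            n_starts=n_starts,
            rng=seed,
            **fit_kwargs,
        )
        return Mk2AsrResults(self, result)

    def _loglik_raw(self, rates) -> float:
        p0, p1, obs = _prior_tuple(self.root_prior, rates[0], rates[1])
        return float(
            _mk2_loglik(
                self.post, self.children, self.brlen, self.tipstate,
                rates[0], rates[1], p0, p1, obs,
            )
        )

    def marginal_asr(self, params) -> np.ndarray:
        """Marginal P(state 1) for every node at the given rates.

        Returns an array over all node indices (tips included; a tip's value
        is its observed state).
        """
        q01, q10 = float(params[0]), float(params[1])
        p0, p1, obs = _prior_tuple(self.root_prior, q01, q10)
        p = _mk2_marginal(
            self.post, self.children, self.brlen, self.tipstate,
            q01, q10, p0, p1, obs,
        )
        if not np.all(np.isfinite(p)):
            bad = int(np.flatnonzero(~np.isfinite(p))[0])
            raise ArithmeticError(f"non-finite marginal probability at node {bad}")
        return p


class Mk2AsrResults:
    """Fitted Mk2 model: rates, log-likelihood and reconstructions."""

    def __init__(self, model: Mk2Asr, fit_result: FitResult):
        self.model = model
        self.fit_result = fit_result
        self.params = fit_result.params
        self.loglik = fit_result.loglik
        self.converged = fit_result.converged

    @property
    def q01(self) -> float:
        return float(self.params[0])

    @property
    def q10(self) -> float:
        return float(self.params[1])

    def marginal_asr(self) -> np.ndarray:
        """Marginal P(state 1) per node at the fitted rates."""
        return self.model.marginal_asr(self.params)

    def summary(self) -> str:
        lines = [
            "Mk2 ancestral state reconstruction",
            "==================================",
            f"tips: {self.model.tree.n_tips}    "
            f"root prior: {self.model.root_prior}",
            f"log-likelihood: {self.loglik:.6f}   "
            f"(best of {self.fit_result.n_starts} starts, "
            f"converged: {self.converged})",
            f"  q01 = {self.q01:.6g}",
            f"  q10 = {self.q10:.6g}",
        ]
        return "\n".join(lines)

    def __repr__(self):
        return (
            f"<Mk2AsrResults q01={self.q01:.4g} q10={self.q10:.4g} "
            f"loglik={self.loglik:.4f}>"
        )
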