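"""BiSSE likelihood and marginal ancestral state reconstruction.

Under BiSSE the observed tree and tip characters are modelled jointly:
a lineage in state *i* speciates at rate λ_i, goes extinct at rate µ_i and
flips state at rate q_ij.  Along each branch two quantities are integrated
backwards in time (t = time before present):

    dE_i/dt = µ_i − (λ_i + µ_i + q_ij) E_i + q_ij E_j + λ_i E_i²
    dD_i/dt = −(λ_i + µ_i + q_ij) D_i + q_ij D_j + 2 λ_i E_i D_i

where E_i(t) is the probability that a lineage in state *i* at time t leaves
no sampled descendants, and D_i(t) is the likelihood of the subtended data.
At tips E_i(0) = 0 and D_i(0) = 1{tip state = i}; at internal nodes
D_i ← λ_i D_i^left D_i^right; at the root the states are combined with a
prior, optionally after conditioning on survival of both root lineages
(dividing by λ_i (1 − E_i)² per state).

Marginal reconstruction fixes a node's state (zeroing the other state's D)
and re-propagates only the root-ward path, reusing cached subtree
quantities; the two fixings share every scale factor, so their ratio is the
exact marginal probability.

The integrator is an embedded Cash–Karp Runge–Kutta 4(5) pair with adaptive
step control (relative tolerance 1e-8, absolute 1e-10 by default).
"""

from __future__ import annotations

import numpy as np
from numba import njit

from ._treedata import tree_arrays
from .fit import FitResult, multistart_fit
from .scenarios import ScenarioParams
from .trees import Tree

__all__ = ["BisseAsr", "BisseAsrResults", "bisse_loglik"]

_RTOL = 1e-8
_ATOL = 1e-10
_MAX_STEPS = 100_000


@njit(cache=True)
def _deriv(y, dy, n_d, lam0, lam1, mu0, mu1, q01, q10):
    e0 = y[0]
    e1 = y[1]
    dy[0] = mu0 - (lam0 + mu0 + q01) * e0 + q01 * e1 + lam0 * e0 * e0
    dy[1] = mu1 - (lam1 + mu1 + q10) * e1 + q10 * e0 + lam1 * e1 * e1
    for k in range(n_d):
        d0 = y[2 + 2 * k]
        d1 = y[3 + 2 * k]
        dy[2 + 2 * k] = -(lam0 + mu0 + q01) * d0 + q01 * d1 + 2.0 * lam0 * e0 * d0
        dy[3 + 2 * k] = -(lam1 + mu1 + q10) * d1 + q10 * d0 + 2.0 * lam1 * e1 * d1


@njit(cache=True)
def _integrate(y, n_d, t_len, lam0, lam1, mu0, mu1, q01, q10, rtol, atol):
    """Integrate the E/D system over a branch of length t_len, in place.

    Returns True on success; False if step control failed or E left [0,1].
    """
    m = 2 + 2 * n_d
    if t_len <= 0.0:
        return True
    k1 = np.empty(m)
    k2 = np.empty(m)
    k3 = np.empty(m)
    k4 = np.empty(m)
    k5 = np.empty(m)
    k6 = np.empty(m)
    ytmp = np.empty(m)
    y4 = np.empty(m)
    y5 = np.empty(m)

    t = 0.0
    h = t_len
    for _ in range(_MAX_STEPS):
        if h > t_len - t:
            h = t_len - t
        _deriv(y, k1, n_d, lam0, lam1, mu0, mu1, q01, q10)
        for i in range(m):
            ytmp[i] = y[i] + h * 0.2 * k1[i]
        _deriv(ytmp, k2, n_d, lam0, lam1, mu0, mu1, q01, q10)
        for i in range(m):
            ytmp[i] = y[i] + h * (0.075 * k1[i] + 0.225 * k2[i])
        _deriv(ytmp, k3, n_d, lam0, lam1, mu0, mu1, q01, q10)
        for i in range(m):
            ytmp[i] = y[i] + h * (0.3 * k1[i] - 0.9 * k2[i] + 1.2 * k3[i])
        _deriv(ytmp, k4, n_d, lam0, lam1, mu0, mu1, q01, q10)
        for i in range(m):
            ytmp[i] = y[i] + h * (
                (-11.0 / 54.0) * k1[i]
                + 2.5 * k2[i]
                + (-70.0 / 27.0) * k3[i]
                + (35.0 / 27.0) * k4[i]
            )
        _deriv(ytmp, k5, n_d, lam0, lam1, mu0, mu1, q01, q10)
        for i in range(m):
            ytmp[i] = y[i] + h * (
                (1631.0 / 55296.0) * k1[i]
                + (175.0 / 512.0) * k2[i]
                + (575.0 / 13824.0) * k3[i]
                + (44275.0 / 110592.0) * k4[i]
                + (253.0 / 4096.0) * k5[i]
            )
        _deriv(ytmp, k6, n_d, lam0, lam1, mu0, mu1, q01, q10)
        err = 0.0
        for i in range(m):
            y5[i] = y[i] + h * (
                (37.0 / 378.0) * k1[i]
                + (250.0 / 621.0) * k3[i]
                + (125.0 / 594.0) * k4[i]
                + (512.0 / 1771.0) * k6[i]
            )
            y4[i] = y[i] + h * (
                (2825.0 / 27648.0) * k1[i]
                + (18575.0 / 48384.0) * k3[i]
                + (13525.0 / 55296.0) * k4[i]
                + (277.0 / 14336.0) * k5[i]
                + 0.25 * k6[i]
            )
            sc = atol + rtol * max(abs(y[i]), abs(y5[i]))
            e = abs(y5[i] - y4[i]) / sc
            if e > err:
                err = e
        if err <= 1.0:
            t += h
            for i in range(m):
                y[i] = y5[i]
            if y[0] < -1e-8 or y[0] > 1.0 + 1e-8 or y[1] < -1e-8 or y[1] > 1.0 + 1e-8:
                return False
            if y[0] < 0.0:
                y[0] = 0.0
            if y[1] < 0.0:
                y[1] = 0.0
            if y[0] > 1.0:
                y[0] = 1.0
            if y[1] > 1.0:
                y[1] = 1.0
            if t >= t_len:
                return True
        fac = 0.9 * err ** -0.2 if err > 0.0 else 5.0
        if fac < 0.2:
            fac = 0.2
        elif fac > 5.0:
            fac = 5.0
        h *= fac
        if h <= 1e-14 * t_len:
            return False
    return False


@njit(cache=True)
def _bisse_up(post, children, brlen, tipstate, lam0, lam1, mu0, mu1, q01, q10,
              rtol, atol):
    """Pruning pass.  Returns (E, D, Dup, logscale, fail_node).

    E[v], D[v]: extinction probabilities / normalized data likelihoods at
    node v (post children-combine).  Dup[v]: D after integrating v's branch
    toward its parent (from the normalized D[v]).  fail_node >= 0 flags an
    integration failure on the branch above that node.
    """
    n = post.shape[0]
    E = np.zeros((n, 2))
    D = np.zeros((n, 2))
    Dup = np.zeros((n, 2))
    Eup = np.zeros((n, 2))
    logscale = 0.0
    y = np.empty(4)
    for k in range(n):
        v = post[k]
        c0 = children[v, 0]
        if c0 < 0:
            E[v, 0] = 0.0
            E[v, 1] = 0.0
            D[v, 0] = 1.0 if tipstate[v] == 0 else 0.0
            D[v, 1] = 1.0 if tipstate[v] == 1 else 0.0
        else:
            c1 = children[v, 1]
            for c in (c0, c1):
                y[0] = E[c, 0]
                y[1] = E[c, 1]
                y[2] = D[c, 0]
                y[3] = D[c, 1]
                ok = _integrate(y, 1, brlen[c], lam0, lam1, mu0, mu1, q01, q10,
                                rtol, atol)
                if not ok:
                    return E, D, Dup, logscale, c
                Eup[c, 0] = y[0]
                Eup[c, 1] = y[1]
                Dup[c, 0] = y[2]
                Dup[c, 1] = y[3]
            E[v, 0] = 0.5 * (Eup[c0, 0] + Eup[c1, 0])
            E[v, 1] = 0.5 * (Eup[c0, 1] + Eup[c1, 1])
            d0 = lam0 * Dup[c0, 0] * Dup[c1, 0]
            d1 = lam1 * Dup[c0, 1] * Dup[c1, 1]
            m = max(d0, d1)
            if m <= 0.0 or not np.isfinite(m):
                return E, D, Dup, logscale, v
            D[v, 0] = d0 / m
            D[v, 1] = d1 / m
            logscale += np.log(m)
    return E, D, Dup, logscale, -1


@njit(cache=True)
def _root_weights(D_root, E_root, lam0, lam1, condition):
    w0 = D_root[0]
    w1 = D_root[1]
    if condition:
        w0 /= lam0 * (1.0 - E_root[0]) ** 2
        w1 /= lam1 * (1.0 - E_root[1]) ** 2
    return w0, w1


@njit(cache=True)
def _bisse_loglik_kernel(post, children, brlen, tipstate, lam0, lam1, mu0,
                         mu1, q01, q10, prior0, prior1, obs_prior, condition,
                         rtol, atol):
    E, D, Dup, logscale, fail = _bisse_up(
        post, children, brlen, tipstate, lam0, lam1, mu0, mu1, q01, q10,
        rtol, atol,
    )
    if fail >= 0:
        return -np.inf, fail
    root = post[post.shape[0] - 1]
    w0, w1 = _root_weights(D[root], E[root], lam0, lam1, condition)
    if obs_prior:
        tot = w0 + w1
        prior0 = w0 / tot
        prior1 = w1 / tot
    lik = prior0 * w0 + prior1 * w1
    if lik <= 0.0 or not np.isfinite(lik):
        return -np.inf, root
    return np.log(lik) + logscale, -1


@njit(cache=True)
def _bisse_marginal_kernel(post, children, parent, brlen, tipstate, lam0,
                           lam1, mu0, mu1, q01, q10, prior0, prior1,
                           obs_prior, condition, rtol, atol):
    n = post.shape[0]
    E, D, Dup, logscale, fail = _bisse_up(
        post, children, brlen, tipstate, lam0, lam1, mu0, mu1, q01, q10,
        rtol, atol,
    )
    p1 = np.full(n, np.nan)
    if fail >= 0:
        return p1, fail
    root = post[n - 1]
    w0, w1 = _root_weights(D[root], E[root], lam0, lam1, condition)
    if obs_prior:
        tot = w0 + w1
        prior0 = w0 / tot
        prior1 = w1 / tot

    y = np.empty(6)
    for k in range(n):
        v = post[k]
        if children[v, 0] < 0:
            p1[v] = float(tipstate[v])
            continue
        # two fixings propagated jointly; shared scale factors cancel
        a0 = D[v, 0]
        a1 = 0.0
        b0 = 0.0
        b1 = D[v, 1]
        u = v
        while u != root:
            y[0] = E[u, 0]
            y[1] = E[u, 1]
            y[2] = a0
            y[3] = a1
            y[4] = b0
            y[5] = b1
            ok = _integrate(y, 2, brlen[u], lam0, lam1, mu0, mu1, q01, q10,
                            rtol, atol)
            if not ok:
                return p1, u
            p = parent[u]
            sib = children[p, 1] if children[p, 0] == u else children[p, 0]
            a0 = lam0 * y[2] * Dup[sib, 0]
            a1 = lam1 * y[3] * Dup[sib, 1]
            b0 = lam0 * y[4] * Dup[sib, 0]
            b1 = lam1 * y[5] * Dup[sib, 1]
            m = max(max(a0, a1), max(b0, b1))
            if m <= 0.0 or not np.isfinite(m):
                return p1, u
            a0 /= m
            a1 /= m
            b0 /= m
            b1 /= m
            u = p
        ra0, ra1 = _root_weights(np.array((a0, a1)), E[root], lam0, lam1,
                                 condition)
        rb0, rb1 = _root_weights(np.array((b0, b1)), E[root], lam0, lam1,
                                 condition)
        l_fix0 = prior0 * ra0 + prior1 * ra1
        l_fix1 = prior0 * rb0 + prior1 * rb1
        p1[v] = l_fix1 / (l_fix0 + l_fix1)
    return p1, -1


def _as_rates(params):
    if isinstance(params, ScenarioParams):
        return np.array(params.rates(), float)
    p = np.asarray(params, float)
    if p.shape != (6,):
        raise ValueError(
            "expected 6 rates (lambda0, lambda1, mu0, mu1, q01, q10)"
        )
    return p


def bisse_loglik(tree: Tree, tip_states, params, root_prior="flat",
                 condition_on_survival: bool = True) -> float:
    """BiSSE log-likelihood of an ultrametric tree with all tips extant."""
    return BisseAsr(
        tree, tip_states, root_prior=root_prior,
        condition_on_survival=condition_on_survival,
    ).loglike(params)


class BisseAsr:
    """BiSSE model of a binary character evolving with the tree.

    Parameters
    ----------
    tree
        Ultrametric rooted binary tree, all tips extant.
    tip_states
        Mapping tip label -> {0, 1}; defaults to states on the tree.
    root_prior
        "flat", "stationary" (equilibrium of the transition subprocess,
        q10/(q01+q10) for state 0) or "observed" (weights proportional to the
        root state likelihoods).
    condition_on_survival
        Condition the likelihood on both root lineages surviving (default
        True, matching a simulation protocol that discards extinct clades).
    rtol, atol
        ODE tolerances for the branch integrations.
    """

    n_params = 6
    param_names = ("lambda0", "lambda1", "mu0", "mu1", "q01", "q10")

    def __init__(self, tree: Tree, tip_states=None, root_prior: str = "flat",
                 condition_on_survival: bool = True, rtol: float = _RTOL,
                 atol: float = _ATOL):
        if root_prior not in ("flat", "stationary", "observed"):
            raise ValueError(f"unknown root prior {root_prior!r}")
        tree.node_depths()  # raises if not ultrametric
        self.tree = tree
        self.root_prior = root_prior
        self.condition_on_survival = bool(condition_on_survival)
        self.rtol = rtol
        self.atol = atol
        self.post, self.children, self.brlen, self.tipstate = tree_arrays(
            tree, tip_states
        )

    def _priors(self, rates):
        if self.root_prior == "flat":
            return 0.5, 0.5, False
        if self.root_prior == "stationary":
            s = rates[4] + rates[5]
            return rates[5] / s, rates[4] / s, False
        return 0.5, 0.5, True

    def loglike(self, params) -> float:
        rates = _as_rates(params)
        if np.any(~np.isfinite(rates)) or np.any(rates <= 0):
            raise ValueError(f"rates must be finite and positive, got {rates}")
        p0, p1, obs = self._priors(rates)
        ll, fail = _bisse_loglik_kernel(
            self.post, self.children, self.brlen, self.tipstate,
            rates[0], rates[1], rates[2], rates[3], rates[4], rates[5],
            p0, p1, obs, self.condition_on_survival, self.rtol, self.atol,
        )
        if fail >= 0:
            raise ArithmeticError(
                f"BiSSE branch integration failed above node {fail} "
                f"(rates {rates})"
            )
        return float(ll)

    def _loglik_raw(self, rates) -> float:
        p0, p1, obs = self._priors(rates)
        ll, fail = _bisse_loglik_kernel(
            self.post, self.children, self.brlen, self.tipstate,
            rates[0], rates[1], rates[2], rates[3], rates[4], rates[5],
            p0, p1, obs, self.condition_on_survival, self.rtol, self.atol,
        )
        return -np.inf if fail >= 0 else float(ll)

    def fit(self, init_center=None, n_starts: int = 3, seed=None,
            **fit_kwargs) -> "BisseAsrResults":
        """Multi-start ML fit of all six rates (log scale, Nelder–Mead).

        ``init_center`` — center of the ``U(0.5, 1.5)``-scaled random starts;
        in a simulation study, the true generating rates.
        """
        if init_center is None:
            raise ValueError(
                "init_center is required: supply the generating rates (or a "
                "data-driven guess) as (lambda0, lambda1, mu0, mu1, q01, q10)"
            )
        init_center = _as_rates(init_center)
        result = multistart_fit(
            self._loglik_raw,
            init_center,
            n_starts=n_starts,
            rng=seed,
            **fit_kwargs,
        )
        return BisseAsrResults(self, result)

    def marginal_asr(self, params) -> np.ndarray:
        """Marginal P(state 1) per node at the given rates (tips: observed)."""
        rates = _as_rates(params)
        p0, p1, obs = self._priors(rates)
        probs, fail = _bisse_marginal_kernel(
            self.post, self.children, self.tree.parent, self.brlen,
            self.tipstate,
            rates[0], rates[1], rates[2], rates[3], rates[4], rates[5],
            p0, p1, obs, self.condition_on_survival, self.rtol, self.atol,
        )
        if fail >= 0:
            raise ArithmeticError(
                f"BiSSE marginal reconstruction failed at node {fail}"
            )
        return probs


class BisseAsrResults:
    """Fitted BiSSE model: rates, log-likelihood and reconstructions."""

    def __init__(self, model: BisseAsr, fit_result: FitResult):
        self.model = model
        self.fit_result = fit_result
        self.params = fit_result.params
        self.loglik = fit_result.loglik
        self.converged = fit_result.converged

    def marginal_asr(self) -> np.ndarray:
        return self.model.marginal_asr(self.params)

    def summary(self) -> str:
        lines = [
            "BiSSE ancestral state reconstruction",
            "====================================",
            f"tips: {self.model.tree.n_tips}    "
            f"root prior: {self.model.root_prior}    "
            f"survival conditioning: {self.model.condition_on_survival}",
            f"log-likelihood: {self.loglik:.6f}   "
            f"(best of {self.fit_result.n_starts} starts, "
            f"converged: {self.converged})",
        ]
        for name, val in zip(self.model.param_names, self.params):
            lines.append(f"  {name:8s} = {val:.6g}")
        return "\n".join(lines)

    def __repr__(self):
        pars = ", ".join(f"{n}={v:.3g}" for n, v in
                         zip(self.model.param_names, self.params))
        return f"<BisseAsrResults {pars} loglik={self.loglik:.4f}>"
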