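"""Multi-start maximum-likelihood fitting on log-transformed rates.

Rates are optimized on the log scale with a derivative-free simplex search
(Nelder–Mead, mirroring the "subplex" style of local search used for these
models), restarted from several random initial points.  Following the study
protocol, each start is drawn as ``init_center * Uniform(0.5, 1.5)`` per
parameter, where ``init_center`` is typically the true generating rates in a
simulation study (or a data-driven guess for empirical trees).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

__all__ = ["FitResult", "multistart_fit", "RATE_BOUNDS"]

RATE_BOUNDS = (1e-8, 1e3)


@dataclass
class StartDiagnostics:
    x0: np.ndarray
    loglik_at_start: float
    loglik: float
    n_evals: int
    converged: bool
    message: str


@dataclass
class FitResult:
    params: np.ndarray
    loglik: float
    converged: bool
    starts: list = field(default_factory=list)

    @property
    def n_starts(self) -> int:
        return len(self.starts)


def multistart_fit(
    loglik_fn,
    init_center,
    n_starts: int = 3,
    rng=None,
    bounds=RATE_BOUNDS,
    xtol: float = 1e-6,
    ftol: float = 1e-6,
    maxfev: int | None = None,
) -> FitResult:
    """Maximize ``loglik_fn(rates)`` over positive rates.

    Parameters
    ----------
    loglik_fn
        Callable mapping a rate vector to a log-likelihood (may return -inf).
    init_center
        Center of the random initialisation; each start is
        ``init_center * U(0.5, 1.5)`` elementwise.
    n_starts
        Number of independent restarts (>= 1); the best final
        log-likelihood wins.
    rng
        ``numpy.random.Generator`` or seed for the start draws.

    Returns
    -------
    FitResult
        The result is never worse than the best start's initial point.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    init_center = np.asarray(init_center, dtype=float)
    if np.any(init_center <= 0) or not np.all(np.isfinite(init_center)):
        raise ValueError("init_center must be finite and positive")
    rng = np.random.default_rng(rng)
    lo, hi = np.log(bounds[0]), np.log(bounds[1])
    k = init_center.shape[0]
    if maxfev is None:
        maxfev = 400 * k

    def neg(x):
        if np.any(x < lo) or np.any(x > hi):
            return 1e12
        ll = loglik_fn(np.exp(x))
        if not np.isfinite(ll):
            return 1e12
        return -ll

    starts = []
    best = None
    for _ in range(n_starts):
        x0 = np.log(np.clip(init_center * rng.uniform(0.5, 1.5, size=k),
                            bounds[0], bounds[1]))
        f0 = -neg(x0)
        res = minimize(
            neg,
            x0,
            method="Nelder-Mead",
            options={
                "xatol": xtol,
                "fatol": ftol,
                "maxfev": maxfev,
                "initial_simplex": _initial_simplex(x0, 0.15),
            },
        )
        diag = StartDiagnostics(
            x0=np.exp(x0),
            loglik_at_start=f0,
            loglik=-res.fun,
            n_evals=res.nfev,
            converged=bool(res.success) and np.isfinite(res.fun),
            message=res.message,
        )
        starts.append(diag)
        if np.isfinite(res.fun) and (best is None or -res.fun > best[1]):
            best = (np.exp(res.x), -res.fun, diag.converged)

    if best is None or not np.isfinite(best[1]) or best[1] <= -1e11:
        lines = [
            f"  start {i}: x0={s.x0}, loglik={s.loglik}, evals={s.n_evals}, "
            f"{s.message}"
            for i, s in enumerate(starts)
        ]
        raise RuntimeError(
            "all optimization starts failed to produce a finite "
            "log-likelihood:\n" + "\n".join(lines)
        )
    return FitResult(
        params=best[0],
        loglik=float(best[1]),
        converged=bool(best[2]) or any(s.converged for s in starts),
        starts=starts,
    )


def _initial_simplex(x0, step):
    k = x0.shape[0]
    simplex = np.tile(x0, (k + 1, 1))
    for i in range(k):
        simplex[i + 1, i] += step
    return simplex
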