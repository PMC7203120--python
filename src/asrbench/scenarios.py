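"""Simulation scenario grids for the BiSSE ancestral-state study.

A *scenario* is one setting of the six BiSSE rates: state-dependent
speciation (``lambda0``, ``lambda1``), extinction (``mu0``, ``mu1``) and
character transition (``q01`` forward, ``q10`` reverse).  The study design
constrains the mean speciation rate ``(lambda0 + lambda1)/2`` to 1 so that
time is measured in units of expected speciation waiting time, and keeps
``lambda/q >= 10`` so that ancestral reconstruction is theoretically
recoverable.  The full factorial design crosses 16 extinction pairs,
9 transition pairs and 5 speciation pairs: 720 scenarios.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable

__all__ = [
    "ScenarioParams",
    "GridSpec",
    "enumerate_scenarios",
    "scenario_table",
    "read_grid_config",
    "STUDY_GRID",
    "SUBSETS",
]

SUBSETS = ("full", "symmetric_lambda", "corner", "expanding")

# Corner-case speciation pairs that reproduce the published count of 32
# corner settings (the symmetric pair plus the two extreme asymmetric pairs).
CORNER_LAMBDA_PAIRS = ((0.2, 1.8), (1.0, 1.0), (1.8, 0.2))


@dataclass(frozen=True, order=True)
class ScenarioParams:
    """One BiSSE rate setting (all rates in events per unit time)."""

    lambda0: float
    lambda1: float
    mu0: float
    mu1: float
    q01: float
    q10: float

    def __post_init__(self):
        for name in ("lambda0", "lambda1", "mu0", "mu1", "q01", "q10"):
            v = getattr(self, name)
            if not (v > 0):
                raise ValueError(f"rate {name} must be strictly positive, got {v}")

    @property
    def scenario_id(self) -> str:
        """Stable string ID used for file naming and seed derivation."""
        g = lambda x: f"{x:g}"
        return (
            f"L{g(self.lambda0)}_M{g(self.mu0)}-{g(self.mu1)}"
            f"_Q{g(self.q01)}-{g(self.q10)}"
        )

    @property
    def is_expanding(self) -> bool:
        """True if each state's extinction rate is strictly below its
        speciation rate, so the clade is expected to expand in either state."""
        return self.mu0 < self.lambda0 and self.mu1 < self.lambda1

    def rates(self) -> tuple[float, float, float, float, float, float]:
        return (self.lambda0, self.lambda1, self.mu0, self.mu1, self.q01, self.q10)

    def sort_key(self):
        return (self.lambda0, self.mu0, self.mu1, self.q01, self.q10)


@dataclass(frozen=True)
class GridSpec:
    """Factorial design of a scenario grid.

    The default values reproduce the published design: extinction rates in
    {0.01, 0.25, 0.5, 0.8}, transition rates in {0.01, 0.05, 0.1}, five
    speciation pairs averaging 1, 400-tip trees, 500 replicates/scenario.
    """

    mu_values: tuple[float, ...] = (0.01, 0.25, 0.5, 0.8)
    q_values: tuple[float, ...] = (0.01, 0.05, 0.1)
    lambda_pairs: tuple[tuple[float, float], ...] = (
        (0.2, 1.8),
        (0.5, 1.5),
        (1.0, 1.0),
        (1.5, 0.5),
        (1.8, 0.2),
    )
    n_tips: int = 400
    n_trees: int = 500

    def __post_init__(self):
        if not self.mu_values or not self.q_values or not self.lambda_pairs:
            raise ValueError("GridSpec sets must be non-empty")
        for v in itertools.chain(self.mu_values, self.q_values, *self.lambda_pairs):
            if not (v > 0):
                raise ValueError("all rates must be strictly positive")

    @property
    def size(self) -> int:
        return len(self.mu_values) ** 2 * len(self.q_values) ** 2 * len(self.lambda_pairs)


STUDY_GRID = GridSpec()


def enumerate_scenarios(
    spec: GridSpec = STUDY_GRID,
    subset: str = "full",
    corner_all_lambda_pairs: bool = False,
) -> list[ScenarioParams]:
    """Enumerate scenarios of a grid, optionally filtered to a named subset.

    Parameters
    ----------
    spec
        Factorial design to enumerate.
    subset
        ``"full"`` — the whole factorial grid;
        ``"symmetric_lambda"`` — scenarios with state-independent speciation
        (``lambda0 == lambda1``);
        ``"expanding"`` — scenarios in which each extinction rate is strictly
        below the matching speciation rate;
        ``"corner"`` — the corner-case settings used for the tree-size
        analysis: ``q`` in {min, max} of the transition set, ``mu`` in
        {min, max} of the extinction set, ``mu_i <= lambda_i``, and
        speciation pairs restricted to the symmetric and the two extreme
        asymmetric pairs (pass ``corner_all_lambda_pairs=True`` to keep all
        pairs instead).

    Returns
    -------
    list of :class:`ScenarioParams`, sorted lexicographically by
    ``(lambda0, mu0, mu1, q01, q10)``.  Deterministic for a given input.
    """
    if subset not in SUBSETS:
        raise ValueError(f"unknown subset {subset!r}; expected one of {SUBSETS}")

    scenarios = [
        ScenarioParams(l0, l1, m0, m1, qf, qr)
        for (l0, l1) in spec.lambda_pairs
        for m0 in spec.mu_values
        for m1 in spec.mu_values
        for qf in spec.q_values
        for qr in spec.q_values
    ]

    if subset == "symmetric_lambda":
        scenarios = [s for s in scenarios if s.lambda0 == s.lambda1]
    elif subset == "expanding":
        scenarios = [s for s in scenarios if s.is_expanding]
    elif subset == "corner":
        q_corner = {min(spec.q_values), max(spec.q_values)}
        mu_corner = {min(spec.mu_values), max(spec.mu_values)}
        lam_ok = (
            set(spec.lambda_pairs)
            if corner_all_lambda_pairs
            else {p for p in spec.lambda_pairs if p in CORNER_LAMBDA_PAIRS}
        )
        scenarios = [
            s
            for s in scenarios
            if s.q01 in q_corner
            and s.q10 in q_corner
            and s.mu0 in mu_corner
            and s.mu1 in mu_corner
            and s.mu0 <= s.lambda0
            and s.mu1 <= s.lambda1
            and (s.lambda0, s.lambda1) in lam_ok
        ]

    if not scenarios:
        raise ValueError(f"subset {subset!r} of this grid is empty")
    return sorted(scenarios, key=ScenarioParams.sort_key)


def scenario_table(scenarios: Iterable[ScenarioParams]) -> str:
    """Render scenarios as a tab-separated table (one row per scenario)."""
    header = "scenario_id\tlambda0\tlambda1\tmu0\tmu1\tq01\tq10"
    rows = [header]
    for s in scenarios:
        rows.append(
            "\t".join(
                [s.scenario_id]
                + [f"{v:g}" for v in s.rates()]
            )
        )
    return "\n".join(rows) + "\n"


def read_grid_config(text: str) -> GridSpec:
    """Parse a plain-text grid configuration.

    Format: one ``key = values`` pair per line; ``#`` starts a comment.
    ``mu_values`` and ``q_values`` are space- or comma-separated numbers;
    ``lambda_pairs`` is a list of colon-separated pairs (``0.2:1.8 1:1``);
    ``n_tips`` and ``n_trees`` are integers.  Missing keys keep the
    published defaults.
    """
    kwargs = {}
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"line {lineno}: expected 'key = values', got {raw!r}")
        key, _, val = line.partition("=")
        key, val = key.strip(), val.replace(",", " ").strip()
        if key in ("mu_values", "q_values"):
            kwargs[key] = tuple(float(x) for x in val.split())
        elif key == "lambda_pairs":
            pairs = []
            for tok in val.split():
                a, _, b = tok.partition(":")
                pairs.append((float(a), float(b)))
            kwargs[key] = tuple(pairs)
        elif key in ("n_tips", "n_trees"):
            kwargs[key] = int(val)
        else:
            raise ValueError(f"line {lineno}: unknown key {key!r}")
    return GridSpec(**kwargs)
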