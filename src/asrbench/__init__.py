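"""asrbench: accuracy of ancestral state reconstruction for non-neutral
binary traits.

Trees and a binary character are simulated jointly under the BiSSE model
(state-dependent speciation, extinction and transition rates, root forced to
state 0), ancestral states are re-estimated by maximum parsimony, Mk2 and
BiSSE marginal reconstruction, and the errors are scored by node-depth
decile and analysed with tree-level logistic regressions.
"""

__version__ = "0.1.0"

from .scenarios import (  # noqa: F401
    GridSpec,
    STUDY_GRID,
    ScenarioParams,
    enumerate_scenarios,
    read_grid_config,
    scenario_table,
)
from .trees import Tree, read_newick, read_tip_states, write_tip_states  # noqa: F401
from .simulate import (  # noqa: F401
    SimTree,
    SimulationError,
    TreeSummary,
    derive_seed,
    prune_extinct,
    simulate_conditioned,
    simulate_summary,
    tree_summary,
)
from .parsimony import AMBIGUOUS, MprResult, mpr_reconstruct  # noqa: F401
from .mk2 import Mk2Asr, Mk2AsrResults, mk2_loglik  # noqa: F401
from .bisse import BisseAsr, BisseAsrResults, bisse_loglik  # noqa: F401
from .fit import FitResult, multistart_fit  # noqa: F401
from .scoring import (  # noqa: F401
    ScoringConfig,
    aggregate,
    depth_deciles,
    quantise,
    raw_error,
    score_tree,
)
from .glm import build_tree_table, fit_error_glm, predict_error_probability  # noqa: F401
from .experiment import (  # noqa: F401
    ExperimentConfig,
    ExperimentResult,
    PRESETS,
    run_experiment,
    run_preset,
)


def fit_mle(model, tree, tip_states=None, init_center=None, n_starts=3,
            seed=None, **kwargs):
    """Functional entry point for the likelihood fits.

    ``model`` is ``"mk2"`` or ``"bisse"``; returns the corresponding results
    object (see :class:`Mk2Asr` / :class:`BisseAsr` for the keyword options).
    """
    if model == "mk2":
        return Mk2Asr(tree, tip_states).fit(init_center=init_center,
                                            n_starts=n_starts, seed=seed,
                                            **kwargs)
    if model == "bisse":
        return BisseAsr(tree, tip_states).fit(init_center=init_center,
                                              n_starts=n_starts, seed=seed,
                                              **kwargs)
    raise ValueError(f"unknown model {model!r}; expected 'mk2' or 'bisse'")
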