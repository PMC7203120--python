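"""Logistic-regression analysis of reconstruction errors at the tree level.

Each analysed tree contributes one row per reconstruction method with a
binary response: did the reconstruction contain at least one outright error
(a non-ambiguous call contradicting the true state)?  Covariates are the
scenario's extinction and transition rates, the natural log of the true
number of character transitions in the tree, the method (categorical,
reference BiSSE), and optionally the state-0 speciation rate (categorical,
reference λ0 = 1, since its effect is not linear; λ1 is omitted because the
design determines it from λ0).

Two model formulas are fitted:

    Model 1:  error ~ (mu0 + mu1 + q01 + q10 + log_transitions) * method
    Model 2:  error ~ (mu0 + mu1 + q01 + q10 + lambda0 + log_transitions)
                        * method
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = ["build_tree_table", "fit_error_glm", "predict_error_probability"]

logger = logging.getLogger(__name__)

REQUIRED = ["mu0", "mu1", "q01", "q10", "lambda0", "method",
            "log_transitions", "any_outright_error"]

def _formula(model_id: int, table: pd.DataFrame) -> str:
    """Model formula with deterministic reference levels: method=BiSSE and
    lambda0=1 where present, else the first level."""
    methods = sorted(table["method"].unique())
    m_ref = "BiSSE" if "BiSSE" in methods else methods[0]
    lams = sorted(table["lambda0"].unique())
    l_ref = 1.0 if 1.0 in lams else lams[0]
    covs = "mu0 + mu1 + q01 + q10 + log_transitions"
    if model_id == 2:
        covs = (f"mu0 + mu1 + q01 + q10 + C(lambda0, Treatment({l_ref!r}))"
                " + log_transitions")
    return (f"any_outright_error ~ ({covs})"
            f" * C(method, Treatment({m_ref!r}))")


def build_tree_table(per_tree: pd.DataFrame) -> pd.DataFrame:
    """Regression input from per-tree records.

    ``per_tree`` needs columns: mu0, mu1, q01, q10, lambda0, method,
    n_transitions, any_outright_error.  Trees with zero recorded transitions
    are excluded (their log is undefined); the exclusion count is logged and
    stored in ``df.attrs['n_zero_transitions']``.
    """
    df = per_tree.copy()
    zero = df["n_transitions"] <= 0
    if zero.any():
        logger.info(
            "excluding %d tree-rows with zero transitions from regression",
            int(zero.sum()),
        )
    df = df.loc[~zero].copy()
    df["log_transitions"] = np.log(df["n_transitions"].astype(float))
    df["any_outright_error"] = df["any_outright_error"].astype(int)
    out = df[REQUIRED].reset_index(drop=True)
    out.attrs["n_zero_transitions"] = int(zero.sum())
    return out


def fit_error_glm(table: pd.DataFrame, model_id: int = 1):
    """Fit Model 1 or Model 2 by binomial GLM with logit link.

    Returns the statsmodels results object (coefficients via ``.params``,
    standard errors via ``.bse``, p-values via ``.pvalues``,
    ``.summary()`` for the table).
    """
    if model_id not in (1, 2):
        raise ValueError(f"model_id must be 1 or 2, got {model_id}")
    missing = set(REQUIRED) - set(table.columns)
    if missing:
        raise ValueError(f"table lacks columns: {sorted(missing)}")
    if not np.all(np.isfinite(table["log_transitions"])):
        raise ValueError("log_transitions contains non-finite values")
    if table["method"].nunique() < 2:
        raise ValueError("need at least 2 method levels to fit interactions")
    y = table["any_outright_error"]
    if y.nunique() < 2:
        raise ValueError(
            "response is constant (all trees "
            + ("with" if y.iloc[0] else "without")
            + " outright errors); simulate more or harder scenarios"
        )
    try:
        model = smf.glm(_formula(model_id, table), data=table,
                        family=sm.families.Binomial())
        res = model.fit()
    except PerfectSeparationError as exc:
        raise RuntimeError(
            "perfect separation in the logistic regression; add replicates "
            "or scenarios so both outcomes occur across covariate levels"
        ) from exc
    return res


def predict_error_probability(fit, settings) -> np.ndarray:
    """Predicted probability of at least one outright error.

    ``settings`` is a DataFrame (or dict of columns) with the covariates of
    the fitted model; predictions are the inverse-logit of the linear
    predictor, vectorized over rows (e.g. over a grid of log_transitions).
    """
    df = pd.DataFrame(settings)
    known = set(fit.model.data.frame["method"].unique())
    bad = set(df["method"].unique()) - known
    if bad:
        raise ValueError(f"unknown method level(s): {sorted(bad)}; "
                         f"fitted levels are {sorted(known)}")
    return np.asarray(fit.predict(df))
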