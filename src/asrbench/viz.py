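"""Minimal plotting helpers for experiment summaries."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["plot_error_by_decile"]


def plot_error_by_decile(summary, ax=None, metric="mean_raw_error"):
    """Line plot of a score by depth decile, one line per method.

    ``summary`` is the output of
    :meth:`ExperimentResult.scenario_decile_summary` (or any frame with
    decile / method / metric columns); scenarios are averaged.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    for method, grp in summary.groupby("method"):
        by_dec = grp.groupby("decile")[metric].mean()
        ax.plot(by_dec.index, by_dec.values, marker="o", label=method)
    ax.set_xlabel("node depth decile (1 = shallowest)")
    ax.set_ylabel(metric.replace("_", " "))
    ax.legend(title="method")
    ax.set_ylim(bottom=0)
    return ax
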