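"""Static plotting hooks for fit inspection.

Thin matplotlib wrappers over the tidy outputs of the diagnostics and
mixture modules: the posterior predictive envelope against observed
weekly means, the distribution of per-subject responder probabilities
(typically strongly bimodal when the classes separate), and
probability-of-response curves for single covariates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "plot_ppc_envelope",
    "plot_responder_probabilities",
    "plot_response_curve",
]


def _get_ax(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_ppc_envelope(ppc, stat: str = "mean", ax=None):
    """Observed weekly summary against the replicated 2.5-97.5% envelope."""
    ax = _get_ax(ax)
    sub = ppc.table[ppc.table["stat"] == stat].sort_values("week_bin")
    ax.fill_between(sub["week_bin"], sub["q025"], sub["q975"],
                    alpha=0.3, label="95% replicated envelope")
    ax.plot(sub["week_bin"], sub["q500"], ls="--", label="replicated median")
    ax.plot(sub["week_bin"], sub["observed"], marker="o", label="observed")
    ax.set_xlabel("week")
    ax.set_ylabel(f"BDI-II {stat}")
    ax.legend()
    return ax


def plot_responder_probabilities(p_resp, threshold: float | None = None, ax=None):
    """Histogram of per-subject responder probabilities."""
    ax = _get_ax(ax)
    ax.hist(np.asarray(pd.Series(p_resp)), bins=np.linspace(0, 1, 21),
            edgecolor="white")
    if threshold is not None:
        ax.axvline(threshold, color="k", ls="--", label=f"threshold {threshold}")
        ax.legend()
    ax.set_xlabel("P(responder)")
    ax.set_ylabel("subjects")
    return ax


def plot_response_curve(curve: pd.DataFrame, ax=None):
    """Mean responder probability with its HDI band over one covariate."""
    ax = _get_ax(ax)
    curve = curve.sort_values("value")
    ax.fill_between(curve["value"], curve["hdi_low"], curve["hdi_high"],
                    alpha=0.3, label="95% HDI")
    ax.plot(curve["value"], curve["mean"], color="k", label="posterior mean")
    ax.set_xlabel(str(curve["covariate"].iloc[0]) + " (standardized)")
    ax.set_ylabel("P(responder)")
    ax.set_ylim(0, 1)
    ax.legend()
    return ax
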