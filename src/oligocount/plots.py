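"""Figure helpers: histogram + prediction overlay, K scan, capture curve."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

from .capture import CaptureCurve
from .oligomer import CopyNumberDistribution, DualPoissonFit, ModelSelectionResult

__all__ = ["plot_histogram_fit", "plot_k_scan", "plot_capture_curve"]


def plot_histogram_fit(
    dist: CopyNumberDistribution, fit: DualPoissonFit, ax=None, n_max: int = 20
):
    """Observed copy-number frequencies with the fitted mixture overlaid."""
    if ax is None:
        _, ax = plt.subplots()
    n = np.arange(1, n_max + 1)
    obs = [dist.p_obs(int(i)) for i in n]
    pred = [fit.predicted[i] if i < fit.predicted.size else 0.0 for i in n]
    ax.bar(n, pred, color="tab:orange", alpha=0.6,
           label=f"predicted (K={fit.K}, m={fit.m:.2f}, k={fit.k:.2f})")
    ax.plot(n, obs, "o-", color="tab:blue", label="observed")
    ax.set_xlabel("copies per cluster, N")
    ax.set_ylabel("frequency")
    ax.legend(frameon=False)
    return ax


def plot_k_scan(selection: ModelSelectionResult, ax=None):
    """V and O goodness-of-fit versus assumed oligomer size K."""
    if ax is None:
        _, ax = plt.subplots()
    tbl = selection.table
    finite = tbl.replace([np.inf], np.nan)
    ax.plot(tbl["K"], finite["V"], "s-", label="V")
    ax2 = ax.twinx()
    ax2.plot(tbl["K"], finite["O"], "o--", color="tab:red", label="O")
    ax.set_xlabel("assumed oligomer size K")
    ax.set_ylabel("V")
    ax2.set_ylabel("O")
    ax.axvline(selection.best_K_by_O, color="gray", ls=":", lw=1)
    return ax


def plot_capture_curve(curve: CaptureCurve, ax=None):
    """Empirical per-N vesicle-capture fraction with the model prediction."""
    if ax is None:
        _, ax = plt.subplots()
    tbl = curve.table
    ax.bar(tbl["N"], tbl["fraction_bound"], color="tab:blue", alpha=0.6,
           label="observed")
    if "predicted" in tbl:
        ax.plot(tbl["N"], tbl["predicted"], "o--", color="tab:orange",
                label="model")
    ax.set_xlabel("copies per cluster, N")
    ax.set_ylabel("P(vesicle capture)")
    ax.set_ylim(0, 1.05)
    ax.legend(frameon=False)
    return ax
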