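"""Figure helpers: KM curves, SMD love plot, MCMC trace plots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .reporting import KmCurve
from .weighting import BalanceTable

__all__ = ["plot_km", "plot_love", "plot_traces"]


def plot_km(curves: list[KmCurve], path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    for curve in curves:
        ax.step(curve.times, curve.survival, where="post", label=curve.arm or None)
    ax.set_xlabel("years since surgery")
    ax.set_ylabel("overall survival")
    ax.set_ylim(0, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_love(balance: BalanceTable, path: str | Path) -> None:
    tab = balance.table.sort_values("smd_unweighted")
    y = np.arange(len(tab))
    fig, ax = plt.subplots(figsize=(6, 0.35 * len(tab) + 1.5))
    ax.scatter(tab["smd_unweighted"], y, label="unweighted", marker="o")
    ax.scatter(tab["smd_weighted"], y, label="weighted", marker="s")
    ax.axvline(0.1, color="grey", linestyle="--", linewidth=1)
    ax.set_yticks(y, tab["covariate"])
    ax.set_xlabel("absolute standardized mean difference")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_traces(chains: np.ndarray, param_names: list[str], path: str | Path, max_params: int = 6) -> None:
    """Trace plot of the first ``max_params`` parameters across chains (m, n, p)."""
    p = min(chains.shape[2], max_params)
    fig, axes = plt.subplots(p, 1, figsize=(7, 1.6 * p), sharex=True, squeeze=False)
    for j in range(p):
        for m in range(chains.shape[0]):
            axes[j, 0].plot(chains[m, :, j], linewidth=0.4)
        axes[j, 0].set_ylabel(param_names[j], fontsize=8)
    axes[-1, 0].set_xlabel("iteration")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
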