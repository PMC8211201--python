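"""Minimal per-regime figure exports for experiment results."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def boxplot_by_regime(
    results: pd.DataFrame,
    column: str,
    path: str | Path,
    reference: float | None = None,
    threshold: float | None = None,
) -> None:
    """One panel per number of individuals; boxes over observations per individual."""
    levels = sorted(results["n_individuals"].unique())
    fig, axes = plt.subplots(1, len(levels), figsize=(3 * len(levels), 3.2), sharey=True)
    if len(levels) == 1:
        axes = [axes]
    for ax, n_ind in zip(axes, levels):
        sub = results[results["n_individuals"] == n_ind]
        obs_levels = sorted(sub["n_obs"].unique())
        ax.boxplot(
            [sub.loc[sub["n_obs"] == o, column] for o in obs_levels],
            tick_labels=[str(o) for o in obs_levels],
        )
        if reference is not None:
            ax.axhline(reference, color="red", lw=1)
        if threshold is not None:
            ax.axhline(threshold, color="blue", lw=1)
        ax.set_title(f"{n_ind} individuals", fontsize=9)
        ax.set_xlabel("observations per individual", fontsize=8)
    axes[0].set_ylabel(column)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def detection_curves(results: pd.DataFrame, column: str, path: str | Path) -> None:
    """Proportion of replicates with a binary outcome, by regime."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for n_ind, sub in results.groupby("n_individuals"):
        prop = sub.groupby("n_obs")[column].mean()
        ax.plot(prop.index, prop.values, marker="o", ms=3, label=f"n={n_ind}")
    ax.set_xlabel("observations per individual")
    ax.set_ylabel(f"proportion {column} = 1")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
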