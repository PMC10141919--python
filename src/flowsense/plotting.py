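"""Plots: the person-item (Wright) map and permutation-importance bars."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_wright_map", "plot_importance"]


def plot_wright_map(results, path=None, ax=None):
    """Person measures and item difficulties on the shared logit scale."""
    table = results.wright_map()
    items = table[table["kind"] == "item"]
    persons = table[table["kind"] == "person"]
    if ax is None:
        fig, ax = plt.subplots(figsize=(6, 5))
    else:
        fig = ax.figure
    ax.hist(persons["measure"].to_numpy(), bins=20, orientation="horizontal",
            color="#9ecae1", edgecolor="white", label="task measures")
    for _, row in items.iterrows():
        ax.axhline(row["measure"], color="#de2d26", lw=0.8, alpha=0.6)
        ax.annotate(row["name"], (ax.get_xlim()[1], row["measure"]),
                    fontsize=7, va="bottom", ha="right", color="#de2d26")
    ax.set_ylabel("logit scale")
    ax.set_xlabel("number of tasks")
    ax.set_title("person-item map")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return ax


def plot_importance(imp, path=None, ax=None):
    """Mean AUC reduction per shuffled feature, with SD whiskers."""
    table = imp.importance.sort_values("mean_auc_drop")
    if ax is None:
        fig, ax = plt.subplots(figsize=(6, 0.5 * len(table) + 1.5))
    else:
        fig = ax.figure
    y = np.arange(len(table))
    ax.barh(y, table["mean_auc_drop"], xerr=table["sd_auc_drop"],
            color="#3182bd", ecolor="black", capsize=3)
    ax.set_yticks(y, table.index)
    ax.set_xlabel("mean reduction in AUC")
    ax.set_title(f"permutation importance ({imp.n_shuffles} shuffles)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return ax
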