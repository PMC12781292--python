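"""Report figures: dose-response curve, network, stability, interventions.

These are plain matplotlib renderings for reports; layout aesthetics are not
a contract of the package.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import networkx as nx
import numpy as np

from .bridges import to_graph
from .ising import IsingModel
from .nira import BASELINE, InterventionResult
from .stability import StabilityResult


def plot_dose_response_curve(curve_df, path, exposure="cf_total", title=None):
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve_df[exposure], curve_df["fit"], color="tab:blue")
    ax.fill_between(
        curve_df[exposure], curve_df["ci_low"], curve_df["ci_high"],
        alpha=0.25, color="tab:blue",
    )
    ax.set_xlabel("Compassion fatigue total score")
    ax.set_ylabel("Predicted moral distress")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_network(model: IsingModel, partition, path, seed=0):
    g = to_graph(model)
    pos = nx.spring_layout(g, seed=seed, weight="weight")
    colors = ["tab:orange" if partition[n] == "MD" else "tab:green" for n in g.nodes]
    weights = np.array([abs(g.edges[e]["weight"]) for e in g.edges])
    widths = 3 * weights / weights.max() if len(weights) else []
    fig, ax = plt.subplots(figsize=(8, 8))
    nx.draw_networkx(
        g, pos, ax=ax, node_color=colors, node_size=250, font_size=6,
        width=widths, edge_color="steelblue",
    )
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_stability(result: StabilityResult, path):
    fig, ax = plt.subplots(figsize=(6, 4))
    for index, by_frac in result.correlations.items():
        fracs = sorted(by_frac)
        means = [np.nanmean(by_frac[f]) for f in fracs]
        ax.plot([1 - f for f in fracs], means, marker="o", ms=3, label=index)
    ax.axhline(0.7, ls="--", color="grey", lw=0.8)
    ax.set_xlabel("Proportion of cases retained")
    ax.set_ylabel("Mean correlation with full sample")
    ax.set_ylim(-1, 1)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_interventions(result: InterventionResult, path):
    table = result.table[result.table.scenario != BASELINE]
    base = float(result.table.loc[result.table.scenario == BASELINE, "mean_md"].iloc[0])
    fig, ax = plt.subplots(figsize=(8, 4))
    colors = ["tab:green" if s else "lightgrey" for s in table.significant]
    ax.bar(table.scenario, table.mean_md, color=colors)
    ax.axhline(base, color="black", lw=1, label="baseline mean MD")
    ax.set_ylabel("Mean MD sum score")
    ax.set_title(f"{result.direction} interventions")
    ax.tick_params(axis="x", rotation=90, labelsize=6)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
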