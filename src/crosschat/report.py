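"""Best-effort static figures for pipeline artifacts.

Conventions: hierarchy nodes are sized by the number of cells in the group
and interaction edges are widened by strength; tree diagrams mirror the
nested JSON; frequency rankings become bar charts.
"""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .markov import HierarchicalClustering
from .trees import SignalTree, TreeSet

logger = logging.getLogger(__name__)


def plot_hierarchy(
    hier: HierarchicalClustering,
    interactions=None,
    path: str | Path = "hierarchy.png",
) -> None:
    """Scales as rows, clusters as circles sized by cell count; optional
    interaction edges widened by strength."""
    fig, ax = plt.subplots(figsize=(8, 2 + hier.n_scales))
    positions: dict[str, tuple[float, float]] = {}
    for si in range(hier.n_scales):
        clusters = hier.clusters_at(si)
        k = len(clusters)
        for c, cells in enumerate(clusters):
            x = (c + 0.5) / k
            y = hier.n_scales - si
            positions[f"s{si}c{c}"] = (x, y)
            ax.scatter([x], [y], s=20 + 3 * len(cells), zorder=3, color="tab:blue")
            ax.annotate(f"s{si}c{c}", (x, y), fontsize=7, ha="center", va="bottom")
    if interactions:
        mx = max((i.strength for i in interactions), default=1.0) or 1.0
        for i in interactions:
            if i.sender in positions and i.receiver in positions and i.strength > 0:
                (x0, y0), (x1, y1) = positions[i.sender], positions[i.receiver]
                ax.plot([x0, x1], [y0, y1], lw=2.5 * i.strength / mx, color="gray", alpha=0.5)
    ax.set_axis_off()
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def _layout(tree: SignalTree) -> dict[str, tuple[float, float]]:
    pos: dict[str, tuple[float, float]] = {}
    next_x = [0.0]

    def rec(node, depth):
        if not node.children:
            x = next_x[0]
            next_x[0] += 1.0
        else:
            xs = [rec(c, depth + 1) for c in node.children]
            x = float(np.mean(xs))
        pos[node.entity] = (x, -depth)
        return x

    rec(tree.root, 0)
    return pos


def plot_trees(ts: TreeSet, path: str | Path = "trees.png", max_trees: int = 12) -> None:
    trees = ts.trees[:max_trees]
    if not trees:
        fig, ax = plt.subplots()
        ax.text(0.5, 0.5, "no trees detected", ha="center")
        ax.set_axis_off()
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return
    cols = min(3, len(trees))
    rows = int(np.ceil(len(trees) / cols))
    fig, axes = plt.subplots(rows, cols, figsize=(4 * cols, 3 * rows), squeeze=False)
    for ax in axes.ravel():
        ax.set_axis_off()
    for ti, tree in enumerate(trees):
        ax = axes[ti // cols][ti % cols]
        pos = _layout(tree)
        for node in tree.nodes():
            for ch in node.children:
                (x0, y0), (x1, y1) = pos[node.entity], pos[ch.entity]
                ax.plot([x0, x1], [y0, y1], color="gray", zorder=1)
        for node in tree.nodes():
            x, y = pos[node.entity]
            ax.scatter([x], [y], s=30 + len(node.support) * 0.3, color="tab:green", zorder=2)
            ax.annotate(node.entity, (x, y), fontsize=7, ha="center", va="bottom")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def plot_frequency(freqs: list[tuple[str, int]], path: str | Path, top: int = 30) -> None:
    freqs = freqs[:top]
    fig, ax = plt.subplots(figsize=(8, max(2, 0.25 * len(freqs))))
    if freqs:
        names, counts = zip(*freqs)
        ax.barh(range(len(names)), counts, color="tab:purple")
        ax.set_yticks(range(len(names)), names, fontsize=7)
        ax.invert_yaxis()
        ax.set_xlabel("trees containing the entity")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def plot_similarity_groups(
    ids: list[str], coords: np.ndarray, groups: np.ndarray, path: str | Path
) -> None:
    fig, ax = plt.subplots(figsize=(6, 5))
    for g in np.unique(groups):
        m = groups == g
        ax.scatter(coords[m, 0], coords[m, 1], label=f"group {g}")
    for i, name in enumerate(ids):
        ax.annotate(name, coords[i], fontsize=6)
    ax.legend(fontsize=7)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
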