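"""Interaction-strength scoring between cell groups.

The default backend is a simple mass-action saturation score: with x the
mean ligand-unit expression over sender cells and y the mean receptor-unit
expression over receivers, strength = xy / (Kh + xy) in [0, 1).  Any
callable mapping (em, sender cells, receiver cells, interaction) to a
non-negative real can be plugged in; downstream hierarchy and tree outputs
are structurally independent of the backend.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .io import ExpressionMatrix, LRDatabase, LRInteraction
from .markov import HierarchicalClustering
from .specificity import unit_expression

logger = logging.getLogger(__name__)


@dataclass
class InteractionStrength:
    sender: str
    receiver: str
    interaction: LRInteraction
    strength: float
    proportion: float = 0.0


def interaction_strength(
    em: ExpressionMatrix,
    sender_cells: np.ndarray,
    receiver_cells: np.ndarray,
    pair: LRInteraction,
    kh: float = 0.5,
) -> float:
    """Hill-type saturation of mean ligand x mean receptor expression."""
    if len(sender_cells) == 0 or len(receiver_cells) == 0:
        raise ValueError("sender and receiver groups must be nonempty")
    x = float(unit_expression(em, pair.ligand)[sender_cells].mean())
    y = float(unit_expression(em, pair.receptor)[receiver_cells].mean())
    xy = x * y
    return xy / (kh + xy)


ScoreBackend = Callable[[ExpressionMatrix, np.ndarray, np.ndarray, LRInteraction], float]


def hierarchy_interactions(
    em: ExpressionMatrix,
    groups: dict[str, np.ndarray],
    db: LRDatabase,
    pairs_subset: Sequence[str] | None = None,
    backend: ScoreBackend | None = None,
    kh: float = 0.5,
) -> list[InteractionStrength]:
    """Score all sender x receiver group pairs for each requested LR pair.

    ``groups`` maps group id -> cell indices (hierarchy clusters or tree-node
    supports).  Per LR pair, proportions normalize strengths to sum to 1
    over group pairs (when the total is positive).
    """
    if backend is None:
        backend = lambda e, s, r, it: interaction_strength(e, s, r, it, kh)
    wanted = set(pairs_subset) if pairs_subset is not None else None
    out: list[InteractionStrength] = []
    for it in db.interactions:
        if wanted is not None and it.name not in wanted:
            continue
        try:
            unit_expression(em, it.ligand)
            unit_expression(em, it.receptor)
        except KeyError:
            continue
        rows = []
        for sname, scells in groups.items():
            for rname, rcells in groups.items():
                s = float(backend(em, scells, rcells, it))
                rows.append(InteractionStrength(sname, rname, it, s))
        total = sum(r.strength for r in rows)
        if total > 0:
            for r in rows:
                r.proportion = r.strength / total
        out.extend(rows)
    return out


def hierarchy_groups(hier: HierarchicalClustering) -> dict[str, np.ndarray]:
    """Flatten hierarchy clusters into named groups 's{scale}c{cluster}'."""
    groups: dict[str, np.ndarray] = {}
    for si in range(hier.n_scales):
        for c, cells in enumerate(hier.clusters_at(si)):
            groups[f"s{si}c{c}"] = cells
    return groups


def split_clusters_by_support(
    hier_groups: dict[str, np.ndarray], support: frozenset[int] | set[int]
) -> dict[str, np.ndarray]:
    """Split each group into (group ∩ support) and (group \\ support);
    empty halves are dropped (the "intersected" cluster view)."""
    out: dict[str, np.ndarray] = {}
    sup = np.array(sorted(support), dtype=int)
    for name, cells in hier_groups.items():
        inside = np.intersect1d(cells, sup)
        outside = np.setdiff1d(cells, sup)
        if inside.size and outside.size:
            out[f"{name}+"] = inside
            out[f"{name}-"] = outside
        else:
            out[name] = cells
    return out


def pattern_distance_under_subsampling(
    em: ExpressionMatrix,
    hier: HierarchicalClustering,
    db: LRDatabase,
    scale: int = -1,
    frac: float = 0.8,
    n_reps: int = 20,
    seed: int = 0,
    kh: float = 0.5,
) -> dict[int, np.ndarray]:
    """Cosine distance between each cluster's outgoing-strength vector on the
    full data and on within-cluster subsamples (robustness diagnostic).

    Returns per-cluster arrays of length <= n_reps (replicates that empty a
    cluster are skipped with a warning).
    """
    if not 0 < frac <= 1:
        raise ValueError("frac must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    labels = hier.partitions[scale]
    k = int(labels.max()) + 1
    clusters = [np.where(labels == c)[0] for c in range(k)]

    def outgoing(cluster_cells: list[np.ndarray]) -> np.ndarray:
        vec = []
        for it in db.interactions:
            try:
                lig = unit_expression(em, it.ligand)
                rec = unit_expression(em, it.receptor)
            except KeyError:
                continue
            for c in range(k):
                for c2 in range(k):
                    x = lig[cluster_cells[c]].mean() if len(cluster_cells[c]) else 0.0
                    y = rec[cluster_cells[c2]].mean() if len(cluster_cells[c2]) else 0.0
                    vec.append(x * y / (kh + x * y))
        return np.array(vec).reshape(-1, k, k)

    full = outgoing(clusters)  # (pairs, sender, receiver)
    out: dict[int, list[float]] = {c: [] for c in range(k)}
    for _ in range(n_reps):
        sub = []
        ok = True
        for cells in clusters:
            m = max(1, int(round(frac * len(cells))))
            if len(cells) == 0:
                ok = False
                break
            sub.append(rng.choice(cells, size=m, replace=False))
        if not ok:
            warnings.warn("cluster emptied by subsampling; replicate skipped")
            continue
        rep = outgoing(sub)
        for c in range(k):
            u, v = full[:, c, :].ravel(), rep[:, c, :].ravel()
            nu, nv = np.linalg.norm(u), np.linalg.norm(v)
            d = 1.0 - float(u @ v / (nu * nv)) if nu > 0 and nv > 0 else 0.0
            out[c].append(d)
    return {c: np.array(v) for c, v in out.items()}
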