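"""Spatial variants: coordinate-augmented embeddings, neighborhood-restricted
supports, and a permutation-based neighborhood-enrichment score."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .graph import Embedding
from .io import LRDatabase, SpatialCoords, ValidationError
from .trees import SupportMatrix

logger = logging.getLogger(__name__)


@dataclass
class NeighborhoodIndex:
    """Per-cell neighbor lists within Euclidean radius r (self excluded)."""

    cell_ids: list[str]
    neighbors: list[np.ndarray]
    radius: float

    @property
    def n(self) -> int:
        return len(self.cell_ids)


def default_radius(coords: SpatialCoords, multiplier: float = 2.0) -> float:
    """Twice the 5th percentile of the nearest-neighbor distance distribution."""
    tree = cKDTree(coords.xy)
    d, _ = tree.query(coords.xy, k=2)
    return float(np.percentile(d[:, 1], 5) * multiplier)


def build_neighborhood(coords: SpatialCoords, radius: float | None = None) -> NeighborhoodIndex:
    if radius is None:
        radius = default_radius(coords)
    tree = cKDTree(coords.xy)
    pairs = tree.query_ball_tree(tree, r=radius)
    neighbors = [
        np.array([j for j in lst if j != i], dtype=int) for i, lst in enumerate(pairs)
    ]
    return NeighborhoodIndex(list(coords.cell_ids), neighbors, radius)


def augment_embedding(
    emb: Embedding, coords: SpatialCoords, weight: float = 1.0
) -> Embedding:
    """Append min-max-scaled (then weighted) x/y columns to the embedding."""
    pos = {c: i for i, c in enumerate(coords.cell_ids)}
    missing = [c for c in emb.cell_ids if c not in pos]
    if missing:
        raise ValidationError(f"cells without coordinates: {missing[:5]}")
    xy = coords.xy[[pos[c] for c in emb.cell_ids]]
    lo, hi = xy.min(axis=0), xy.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    scaled = (xy - lo) / span * weight
    return Embedding(
        list(emb.cell_ids),
        np.hstack([emb.vectors, scaled]),
        provenance="pca_plus_spatial",
    )


def restrict_supports(
    sm: SupportMatrix,
    partner_sm: SupportMatrix,
    db: LRDatabase,
    idx: NeighborhoodIndex,
    side: str = "ligand",
) -> SupportMatrix:
    """Keep a spot in a unit's support only if a neighbor (within r) supports
    at least one cognate partner unit in the database.

    ``side`` says whether ``sm`` holds ligand or receptor units; partners
    are looked up accordingly.  Units with no database partner lose their
    entire support (warned).
    """
    if side not in ("ligand", "receptor"):
        raise ValueError(side)
    partner_of: dict[str, set[str]] = {}
    for it in db.interactions:
        a, b = (it.ligand, it.receptor) if side == "ligand" else (it.receptor, it.ligand)
        partner_of.setdefault(a, set()).add(b)
    partner_support = dict(zip(partner_sm.entity_ids, partner_sm.supports))
    new_sups: list[frozenset[int]] = []
    for eid, s in zip(sm.entity_ids, sm.supports):
        partners = partner_of.get(eid, set())
        avail = [partner_support[p] for p in partners if p in partner_support]
        if not avail:
            warnings.warn(f"unit {eid} has no cognate partner in database; support emptied")
            new_sups.append(frozenset())
            continue
        cognate_cells = frozenset().union(*avail)
        kept = frozenset(
            c for c in s if any(j in cognate_cells for j in idx.neighbors[c])
        )
        new_sups.append(kept)
    return SupportMatrix(list(sm.entity_ids), new_sups, sm.n_cells, sm.tau)


def neighborhood_enrichment(
    labels: list[str] | np.ndarray,
    idx: NeighborhoodIndex,
    n_perm: int = 200,
    seed: int = 0,
) -> dict[str, float]:
    """Per-label z-score of same-label neighbor pairs against label permutations.

    Labels with fewer than two cells, or degenerate permutation variance,
    are reported as NaN.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != idx.n:
        raise ValidationError("labels do not cover the indexed cells")
    rng = np.random.default_rng(seed)
    uniq = np.unique(labels)

    def counts_for(lab: np.ndarray) -> dict[str, int]:
        c = {u: 0 for u in uniq}
        for i, nbrs in enumerate(idx.neighbors):
            li = lab[i]
            c[li] += int((lab[nbrs] == li).sum())
        return c  # each unordered pair counted twice, consistently

    obs = counts_for(labels)
    perms = {u: np.zeros(n_perm) for u in uniq}
    for p in range(n_perm):
        shuffled = rng.permutation(labels)
        cp = counts_for(shuffled)
        for u in uniq:
            perms[u][p] = cp[u]
    out: dict[str, float] = {}
    for u in uniq:
        if (labels == u).sum() < 2:
            out[str(u)] = float("nan")
            continue
        mu, sd = perms[u].mean(), perms[u].std()
        out[str(u)] = float((obs[u] - mu) / sd) if sd > 0 else float("nan")
    return out
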