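"""Marker assignment of ligand/receptor units over hierarchical clusters.

Each unit's per-cell expression (geometric mean over subunits for
multi-subunit complexes) is tested one-vs-rest with a one-sided (greater)
Wilcoxon rank-sum test in every cluster at every selected scale.  A unit is
assigned globally to the (scale, cluster) with the smallest p-value; an LR
pair is "specific" when both sides pass p < 1e-3, and pairs are ranked by
the product of the two p-values (ascending, most specific first).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.stats import norm, rankdata

from .io import ExpressionMatrix, LRDatabase
from .markov import HierarchicalClustering

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# unit expression
# ---------------------------------------------------------------------------

def unit_expression(em: ExpressionMatrix, unit: str) -> np.ndarray:
    """Per-cell expression of a (possibly multi-subunit) unit.

    Single subunit: that gene's column.  Multi-subunit: element-wise
    geometric mean of the subunit columns (zero in any subunit annihilates).
    Raises KeyError if any subunit gene is absent.
    """
    subunits = unit.split("_")
    gidx = em.gene_index()
    for s in subunits:
        if s not in gidx:
            raise KeyError(s)
    cols = np.column_stack([em.column(s) for s in subunits])
    if cols.shape[1] == 1:
        return cols[:, 0]
    return np.exp(np.mean(np.log(np.maximum(cols, 1e-300)), axis=1)) * (cols > 0).all(axis=1)


def unit_expression_matrix(
    em: ExpressionMatrix, units: list[str], *, drop_zero: bool = True
) -> tuple[np.ndarray, list[str]]:
    """Stack unit expression vectors; units with missing subunits or
    identically-zero expression are skipped (logged)."""
    kept: list[str] = []
    vecs: list[np.ndarray] = []
    n_missing = n_zero = 0
    for u in units:
        try:
            v = unit_expression(em, u)
        except KeyError:
            n_missing += 1
            continue
        if drop_zero and not np.any(v > 0):
            n_zero += 1
            continue
        kept.append(u)
        vecs.append(v)
    if n_missing or n_zero:
        logger.info(
            "unit_expression_matrix: skipped %d units with missing subunits, %d all-zero",
            n_missing, n_zero,
        )
    if not vecs:
        return np.zeros((em.n_cells, 0)), []
    return np.column_stack(vecs), kept


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum (one-sided, greater)
# ---------------------------------------------------------------------------

def rank_sum_greater(values: np.ndarray, in_group: np.ndarray) -> np.ndarray:
    """Vectorized one-sided Wilcoxon rank-sum p-values, columns of ``values``.

    Normal approximation with tie correction and continuity correction;
    tests whether in-group values are stochastically greater than the rest.
    Ranks are computed over all rows, so repeated calls with different
    groups should go through :func:`rank_sum_greater_from_ranks`.
    """
    ranks, tie_term = _ranks_and_ties(values)
    return rank_sum_greater_from_ranks(ranks, tie_term, in_group)


def _ranks_and_ties(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.ndim == 1:
        values = values[:, None]
    ranks = rankdata(values, axis=0)
    n = values.shape[0]
    tie_term = np.zeros(values.shape[1])
    for j in range(values.shape[1]):
        _, counts = np.unique(values[:, j], return_counts=True)
        tie_term[j] = float((counts.astype(float) ** 3 - counts).sum())
    return ranks, tie_term


def rank_sum_greater_from_ranks(
    ranks: np.ndarray, tie_term: np.ndarray, in_group: np.ndarray
) -> np.ndarray:
    n = ranks.shape[0]
    n1 = int(in_group.sum())
    n2 = n - n1
    r1 = ranks[in_group].sum(axis=0)
    u = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    sigma_sq = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    sigma = np.sqrt(np.maximum(sigma_sq, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (u - mu - 0.5) / sigma
    p = norm.sf(z)
    p[sigma == 0] = 1.0  # constant column: no evidence either way
    return np.minimum(np.maximum(p, np.finfo(float).tiny), 1.0)


def rank_sum_exact_greater(x: np.ndarray, y: np.ndarray) -> float:
    """Exact one-sided rank-sum p-value by DP over the tied-rank multiset.

    Valid for any tie pattern; intended for small groups (both sides <= 12).
    """
    pooled = np.concatenate([x, y])
    ranks2 = np.round(2 * rankdata(pooled)).astype(int)  # doubled -> integers
    n1 = len(x)
    w_obs = int(ranks2[: len(x)].sum())
    # null distribution of the doubled rank-sum over C(n, n1) subsets
    max_s = int(ranks2.sum())
    dist = np.zeros((n1 + 1, max_s + 1))
    dist[0, 0] = 1.0
    for r in ranks2:
        for k in range(min(n1, 1_000_000) - 1, -1, -1):
            row = dist[k]
            nz = np.nonzero(row)[0]
            if nz.size:
                dist[k + 1, nz + r] += row[nz]
    total = dist[n1].sum()
    p = dist[n1, w_obs:].sum() / total
    return float(min(max(p, np.finfo(float).tiny), 1.0))


EXACT_MAX_GROUP = 12


# ---------------------------------------------------------------------------
# marker assignment
# ---------------------------------------------------------------------------

@dataclass
class MarkerAssignment:
    unit: str
    scale: int
    cluster: int
    p_value: float


def assign_markers(
    em: ExpressionMatrix,
    hier: HierarchicalClustering,
    units: list[str],
) -> dict[str, MarkerAssignment]:
    """Assign each unit to the (scale, cluster) with the minimum one-vs-rest
    rank-sum p-value; ties broken toward the coarser scale, then the lower
    cluster id.  Clusters of size < 2 are skipped with a warning."""
    values, kept = unit_expression_matrix(em, units)
    if not kept:
        return {}
    ranks, tie_term = _ranks_and_ties(values)
    n = values.shape[0]
    best_p = np.full(len(kept), np.inf)
    best_scale = np.full(len(kept), -1)
    best_cluster = np.full(len(kept), -1)
    for si in range(hier.n_scales):
        labels = hier.partitions[si]
        for c in range(int(labels.max()) + 1):
            mask = labels == c
            n1 = int(mask.sum())
            if n1 < 2:
                logger.warning("scale %d cluster %d has <2 cells; skipped", si, c)
                continue
            if n1 <= EXACT_MAX_GROUP and n - n1 <= EXACT_MAX_GROUP:
                p = np.array(
                    [rank_sum_exact_greater(values[mask, j], values[~mask, j])
                     for j in range(len(kept))]
                )
            else:
                p = rank_sum_greater_from_ranks(ranks, tie_term, mask)
            better = p < best_p  # strict: earlier (coarser) scale wins ties
            best_p[better] = p[better]
            best_scale[better] = si
            best_cluster[better] = c
    return {
        u: MarkerAssignment(u, int(best_scale[j]), int(best_cluster[j]), float(best_p[j]))
        for j, u in enumerate(kept)
        if best_scale[j] >= 0
    }


# ---------------------------------------------------------------------------
# specific LR pairs
# ---------------------------------------------------------------------------

@dataclass
class SpecificLRPair:
    ligand: MarkerAssignment
    receptor: MarkerAssignment
    pathway: str

    @property
    def score(self) -> float:
        return self.ligand.p_value * self.receptor.p_value

    @property
    def name(self) -> str:
        return f"{self.ligand.unit}-{self.receptor.unit}"


def specific_pairs(
    ligand_assignments: dict[str, MarkerAssignment],
    receptor_assignments: dict[str, MarkerAssignment],
    db: LRDatabase,
    p_threshold: float = 1e-3,
) -> list[SpecificLRPair]:
    """Database pairs whose ligand and receptor both pass the p threshold,
    ordered by ascending specificity score (ties by interaction name)."""
    out: list[SpecificLRPair] = []
    for it in db.interactions:
        la = ligand_assignments.get(it.ligand)
        ra = receptor_assignments.get(it.receptor)
        if la is None or ra is None:
            continue
        if la.p_value < p_threshold and ra.p_value < p_threshold:
            out.append(SpecificLRPair(la, ra, it.pathway))
    out.sort(key=lambda pr: (pr.score, pr.name))
    return out
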