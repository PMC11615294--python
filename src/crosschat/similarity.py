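"""Markov-time-weighted similarity of LR pairs and pathways.

For a unit (or pathway aggregate), its mean expression over the clusters of
each selected scale forms one vector per scale.  Two profiles are compared
by summing, over scales, the cosine similarity of the vectors weighted by
w_i = 1 / (ln(max(T_i, 1)) + 1), so coarser (larger Markov time) scales
contribute less.  LR-pair similarity adds the ligand-side and
receptor-side similarities; pathway profiles sum member-unit expression
before averaging per cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import ExpressionMatrix, LRDatabase, ValidationError
from .markov import HierarchicalClustering
from .specificity import SpecificLRPair, unit_expression

logger = logging.getLogger(__name__)


@dataclass
class MultiscaleProfile:
    """Mean expression per cluster at each selected scale."""

    times: list[float]
    vectors: list[np.ndarray]


def scale_weight(t: float) -> float:
    """1 / (ln(T) + 1) with T clamped below at 1, so weights lie in (0, 1]."""
    return 1.0 / (np.log(max(t, 1.0)) + 1.0)


def multiscale_profile(
    expr: np.ndarray, hier: HierarchicalClustering
) -> MultiscaleProfile:
    vectors = []
    for si in range(hier.n_scales):
        labels = hier.partitions[si]
        k = int(labels.max()) + 1
        means = np.array([expr[labels == c].mean() for c in range(k)])
        vectors.append(means)
    return MultiscaleProfile(list(hier.times), vectors)


def _cos(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    return float(u @ v / (nu * nv))


def weighted_similarity(p1: MultiscaleProfile, p2: MultiscaleProfile) -> float:
    if len(p1.vectors) != len(p2.vectors) or any(
        a.shape != b.shape for a, b in zip(p1.vectors, p2.vectors)
    ):
        raise ValidationError("profiles have mismatched scale structure")
    return float(
        sum(
            scale_weight(t) * _cos(u, v)
            for t, u, v in zip(p1.times, p1.vectors, p2.vectors)
        )
    )


@dataclass
class SimilarityMatrix:
    ids: list[str]
    matrix: np.ndarray


def pair_similarity(
    em: ExpressionMatrix,
    pairs: list[SpecificLRPair],
    ligand_hier: HierarchicalClustering,
    receptor_hier: HierarchicalClustering | None = None,
) -> SimilarityMatrix:
    """LR-pair similarity = ligand-side + receptor-side weighted similarity.

    ``receptor_hier`` defaults to the ligand hierarchy (single-hierarchy
    analyses use the same clusters for both sides)."""
    receptor_hier = receptor_hier or ligand_hier
    lig_profiles = {}
    rec_profiles = {}
    for pr in pairs:
        if pr.ligand.unit not in lig_profiles:
            lig_profiles[pr.ligand.unit] = multiscale_profile(
                unit_expression(em, pr.ligand.unit), ligand_hier
            )
        if pr.receptor.unit not in rec_profiles:
            rec_profiles[pr.receptor.unit] = multiscale_profile(
                unit_expression(em, pr.receptor.unit), receptor_hier
            )
    ids = [pr.name for pr in pairs]
    n = len(pairs)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            s = weighted_similarity(
                lig_profiles[pairs[i].ligand.unit], lig_profiles[pairs[j].ligand.unit]
            ) + weighted_similarity(
                rec_profiles[pairs[i].receptor.unit], rec_profiles[pairs[j].receptor.unit]
            )
            m[i, j] = m[j, i] = s
    return SimilarityMatrix(ids, m)


def pathway_similarity(
    em: ExpressionMatrix,
    db: LRDatabase,
    ligand_hier: HierarchicalClustering,
    receptor_hier: HierarchicalClustering | None = None,
    pathways: list[str] | None = None,
) -> SimilarityMatrix:
    """Pathway similarity from summed member ligand / receptor expression."""
    receptor_hier = receptor_hier or ligand_hier
    pathways = pathways or db.pathways()
    lig_prof: dict[str, MultiscaleProfile] = {}
    rec_prof: dict[str, MultiscaleProfile] = {}
    kept: list[str] = []
    for pw in pathways:
        members = [it for it in db.interactions if it.pathway == pw]
        lig_sum = np.zeros(em.n_cells)
        rec_sum = np.zeros(em.n_cells)
        found = 0
        for it in members:
            try:
                lig_sum = lig_sum + unit_expression(em, it.ligand)
                rec_sum = rec_sum + unit_expression(em, it.receptor)
                found += 1
            except KeyError:
                continue
        if found == 0:
            logger.warning("pathway %s has no detected members; excluded", pw)
            continue
        kept.append(pw)
        lig_prof[pw] = multiscale_profile(lig_sum, ligand_hier)
        rec_prof[pw] = multiscale_profile(rec_sum, receptor_hier)
    n = len(kept)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            s = weighted_similarity(lig_prof[kept[i]], lig_prof[kept[j]]) + \
                weighted_similarity(rec_prof[kept[i]], rec_prof[kept[j]])
            m[i, j] = m[j, i] = s
    return SimilarityMatrix(kept, m)


def embed_and_group(
    sim: SimilarityMatrix, n_groups: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded 2D embedding (UMAP) of the similarity matrix rows + K-means.

    Returns (group labels, 2D coordinates).  Deterministic given seed.
    """
    n = len(sim.ids)
    if n_groups > n:
        raise ValidationError(f"n_groups={n_groups} exceeds {n} items")
    from sklearn.cluster import KMeans

    if n_groups == 1:
        coords = _embed2d(sim.matrix, seed)
        return np.zeros(n, dtype=int), coords
    coords = _embed2d(sim.matrix, seed)
    km = KMeans(n_clusters=n_groups, n_init=10, random_state=seed)
    labels = km.fit_predict(coords)
    return labels, coords


def _embed2d(matrix: np.ndarray, seed: int) -> np.ndarray:
    n = matrix.shape[0]
    if n < 5:
        # too few items for a neighborhood embedding; use classical MDS-style PCA
        from sklearn.decomposition import PCA

        return PCA(n_components=min(2, n), random_state=seed).fit_transform(matrix)
    import umap

    # small item sets need a local neighborhood well below the item count,
    # or the embedding mixes distinct similarity blocks; spectral init is
    # not reliably seeded on such tiny fuzzy graphs, random init is
    nn = min(15, max(2, n // 4))
    init = "random" if n < 30 else "spectral"
    reducer = umap.UMAP(n_components=2, n_neighbors=nn, random_state=seed, init=init)
    return reducer.fit_transform(matrix)
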