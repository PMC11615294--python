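"""Multiscale Markov-stability clustering and scale selection.

A continuous-time random walk on the weighted KNN cell graph has transition
matrix P(t) = exp(-t L) with L = I - D^{-1}A the random-walk Laplacian.
For a partition into communities C_1..C_k, the Markov stability

    MS(t) = sum_{u,v in same community} (P(t)_{uv} - pi_v)

measures the excess probability that the walker is still inside its starting
community after time t, relative to the stationary distribution pi.  Small t
rewards fine partitions, large t coarse ones; scanning t on a log grid and
keeping partitions that are reproducible across neighboring scales (flat
basins of the variation-of-information landscape) yields a hierarchy of
robust clusterings.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from ._louvain import louvain_dense
from .graph import CellGraph
from .io import ValidationError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# random-walk operator
# ---------------------------------------------------------------------------

@dataclass
class RandomWalkOperator:
    """Spectral factorization of the random-walk Laplacian of a connected graph.

    P(t) is evaluated exactly through the symmetric conjugate
    D^{1/2} (D^{-1}A) D^{-1/2}, whose eigendecomposition (U, lam) gives
    P(t) = D^{-1/2} U diag(e^{-t(1-lam)}) U^T D^{1/2}.
    """

    degrees: np.ndarray
    pi: np.ndarray
    eigvals: np.ndarray
    eigvecs: np.ndarray

    @property
    def n(self) -> int:
        return self.degrees.shape[0]

    def transition(self, t: float) -> np.ndarray:
        """Dense P(t); eigencomponents with negligible weight are dropped
        (exact to ~1e-15 relative)."""
        if t < 0:
            raise ValidationError("Markov time must be non-negative")
        g = np.exp(-t * (1.0 - self.eigvals))
        keep = g > g.max() * 1e-16
        d_isqrt = 1.0 / np.sqrt(self.degrees)
        d_sqrt = np.sqrt(self.degrees)
        U = self.eigvecs[:, keep]
        left = (d_isqrt[:, None] * U) * g[keep]
        return left @ (U.T * d_sqrt[None, :])

    def quality_matrix(self, t: float) -> np.ndarray:
        """Symmetric matrix Q with sum_{same community} Q_uv = MS(t)."""
        p = self.transition(t)
        q = 0.5 * (p + p.T)
        q -= 0.5 * (self.pi[None, :] + self.pi[:, None])
        return q


def build_operator(g: CellGraph) -> RandomWalkOperator:
    from scipy.sparse.csgraph import connected_components

    n_comp, _ = connected_components(g.adjacency, directed=False)
    if n_comp > 1:
        raise ValidationError(
            "graph is disconnected; repair connectivity before building the operator"
        )
    deg = g.degrees
    if np.any(deg <= 0):
        raise ValidationError("zero-degree node in graph")
    pi = deg / deg.sum()
    d_isqrt = 1.0 / np.sqrt(deg)
    a = g.adjacency.toarray() if sp.issparse(g.adjacency) else np.asarray(g.adjacency)
    m_sym = d_isqrt[:, None] * a * d_isqrt[None, :]
    m_sym = 0.5 * (m_sym + m_sym.T)  # enforce exact symmetry for eigh
    lam, u = np.linalg.eigh(m_sym)
    return RandomWalkOperator(deg, pi, lam, u)


# ---------------------------------------------------------------------------
# partitions, stability, variation of information
# ---------------------------------------------------------------------------

def _as_labels(partition, n: int) -> np.ndarray:
    labels = np.asarray(partition, dtype=np.int64)
    if labels.shape != (n,):
        raise ValidationError(f"partition must assign all {n} nodes")
    return labels


def markov_stability(op: RandomWalkOperator, partition, t: float) -> float:
    """MS(t) = sum over same-community pairs of (P(t)_{uv} - pi_v)."""
    labels = _as_labels(partition, op.n)
    p = op.transition(t)
    return _stability_from_matrix(p - op.pi[None, :], labels)


def _stability_from_matrix(b: np.ndarray, labels: np.ndarray) -> float:
    k = labels.max() + 1
    h = np.zeros((b.shape[0], k))
    h[np.arange(b.shape[0]), labels] = 1.0
    m = b @ h
    return float(m[np.arange(b.shape[0]), labels].sum())


def variation_of_information(x, y) -> float:
    """VI between two partitions (natural log); a metric, zero iff equal."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValidationError("partitions cover different cell sets")
    n = x.shape[0]
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    cont = sp.coo_matrix(
        (np.ones(n), (xi, yi)), shape=(xi.max() + 1, yi.max() + 1)
    ).toarray()
    r = cont / n
    p = r.sum(axis=1)
    q = r.sum(axis=0)
    nz = r > 0
    rr = r[nz]
    pp = np.broadcast_to(p[:, None], r.shape)[nz]
    qq = np.broadcast_to(q[None, :], r.shape)[nz]
    return float(-(rr * (np.log(rr / pp) + np.log(rr / qq))).sum())


def relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Community ids renumbered by decreasing size (ties by first occurrence)."""
    ids, inv, counts = np.unique(labels, return_inverse=True, return_counts=True)
    order = np.argsort(-counts, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    return rank[inv]


# ---------------------------------------------------------------------------
# scan across Markov times
# ---------------------------------------------------------------------------

@dataclass
class ScaleScan:
    log_times: np.ndarray
    times: np.ndarray
    representatives: list[np.ndarray]
    ms_values: np.ndarray
    vi_g: np.ndarray
    n_communities: np.ndarray
    vi_p: np.ndarray

    @property
    def n_scales(self) -> int:
        return len(self.times)


def louvain_quality(
    op: RandomWalkOperator, t: float, n_runs: int = 100, seed: int = 0
) -> tuple[np.ndarray, list[np.ndarray], float, float]:
    """Louvain ensemble at Markov time t.

    Runs ``n_runs`` seeded Louvain optimizations of the MS quality matrix,
    picks the highest-MS partition as representative (ties: lowest run
    index), and returns (representative, ensemble, VI_g, MS value) where
    VI_g is the mean pairwise VI over the ensemble (diagonal included, per
    the 1/R^2 normalization).
    """
    if t <= 0:
        raise ValidationError("Louvain scan requires t > 0")
    q = op.quality_matrix(t)
    if np.abs(q).max() < 1e-12:
        # fully equilibrated walk: every partition has MS ~ 0; report the
        # t -> infinity limit (one community spanning the graph)
        one = np.zeros(op.n, dtype=np.int64)
        return one, [one.copy() for _ in range(n_runs)], 0.0, 0.0
    run_seeds = np.random.SeedSequence(seed).generate_state(n_runs) >> 1
    ensemble: list[np.ndarray] = []
    for s in run_seeds:
        ensemble.append(louvain_dense(q, int(s)))
    ms = np.array([_stability_from_matrix(q, lab) for lab in ensemble])
    best = int(np.argmax(ms))  # argmax returns first (lowest index) maximum
    vi_g = _mean_pairwise_vi(ensemble)
    return ensemble[best], ensemble, vi_g, float(ms[best])


def _canonical(labels: np.ndarray) -> bytes:
    """Canonical byte form invariant to label permutation."""
    _, inv = np.unique(labels, return_inverse=True)
    first = {}
    out = np.empty_like(inv)
    nxt = 0
    for i, v in enumerate(inv):
        if v not in first:
            first[v] = nxt
            nxt += 1
        out[i] = first[v]
    return out.tobytes()


def _mean_pairwise_vi(ensemble: list[np.ndarray]) -> float:
    # dedupe identical partitions: VI depends only on the pair of partitions
    uniq: dict[bytes, tuple[np.ndarray, int]] = {}
    for lab in ensemble:
        key = _canonical(lab)
        if key in uniq:
            uniq[key] = (uniq[key][0], uniq[key][1] + 1)
        else:
            uniq[key] = (lab, 1)
    items = list(uniq.values())
    r = len(ensemble)
    total = 0.0
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            vi = variation_of_information(items[i][0], items[j][0])
            total += 2 * vi * items[i][1] * items[j][1]
    return total / (r * r)


def run_scan(
    op: RandomWalkOperator,
    grid_min: float = -1.0,
    grid_max: float = 4.0,
    grid_points: int = 100,
    n_runs: int = 100,
    seed: int = 0,
) -> ScaleScan:
    """Louvain/MS scan over ``grid_points`` log10-spaced Markov times."""
    log_times = np.linspace(grid_min, grid_max, grid_points)
    times = 10.0**log_times
    scale_seeds = np.random.SeedSequence([seed, 0x5CA1E]).generate_state(grid_points) >> 1
    reps: list[np.ndarray] = []
    ms_vals = np.zeros(grid_points)
    vi_g = np.zeros(grid_points)
    n_comm = np.zeros(grid_points, dtype=int)
    for i, t in enumerate(times):
        rep, _, vg, ms = louvain_quality(op, float(t), n_runs=n_runs, seed=int(scale_seeds[i]))
        reps.append(relabel_by_size(rep))
        ms_vals[i] = ms
        vi_g[i] = vg
        n_comm[i] = reps[-1].max() + 1
        logger.debug("scale %d t=%.3g: %d communities, MS=%.4f, VI_g=%.4f", i, t, n_comm[i], ms, vg)
    vi_p = np.zeros((grid_points, grid_points))
    for i in range(grid_points):
        for j in range(i + 1, grid_points):
            vi_p[i, j] = vi_p[j, i] = variation_of_information(reps[i], reps[j])
    return ScaleScan(log_times, times, reps, ms_vals, vi_g, n_comm, vi_p)


# ---------------------------------------------------------------------------
# scale selection
# ---------------------------------------------------------------------------

@dataclass
class HierarchicalClustering:
    """Partitions at the selected robust scales, ordered coarse -> fine."""

    scale_indices: list[int]
    times: list[float]
    partitions: list[np.ndarray] = field(default_factory=list)

    @property
    def n_scales(self) -> int:
        return len(self.scale_indices)

    def n_communities(self) -> list[int]:
        return [int(p.max()) + 1 for p in self.partitions]

    def clusters_at(self, i: int) -> list[np.ndarray]:
        labels = self.partitions[i]
        return [np.where(labels == c)[0] for c in range(labels.max() + 1)]

    def to_frame(self, cell_ids: list[str]):
        import pandas as pd

        rows = []
        for si, (gi, t, lab) in enumerate(
            zip(self.scale_indices, self.times, self.partitions)
        ):
            for cid, c in zip(cell_ids, lab):
                rows.append((cid, si, gi, t, int(c)))
        return pd.DataFrame(
            rows, columns=["cell_id", "scale", "grid_index", "markov_time", "cluster"]
        )


def _maximal_basins(vi_p: np.ndarray, theta: float) -> list[tuple[int, int]]:
    """Maximal contiguous index runs whose pairwise VI_P entries are all <= theta."""
    g = vi_p.shape[0]
    runs: list[tuple[int, int]] = []
    b = 0
    for a in range(g):
        if b < a:
            b = a
        # shrinking the left end keeps validity, so b only grows with a
        while b + 1 < g and np.all(vi_p[a : b + 2, b + 1] <= theta):
            b += 1
        if not runs or b > runs[-1][1]:
            runs.append((a, b))
    return runs


def select_scales(
    scan: ScaleScan,
    basin_depth_theta: float = 0.1,
    basin_min_width: int = 3,
) -> HierarchicalClustering:
    """Pick one robust scale per flat VI basin.

    A basin is a maximal contiguous run of scales whose representative
    partitions are pairwise within ``basin_depth_theta`` VI (natural log
    units); runs narrower than ``basin_min_width`` grid points are ignored.
    Within each kept basin the scale minimizing the ensemble dispersion
    VI_g is selected.  If nothing qualifies, the single global VI_g
    minimum is returned with a warning.
    """
    runs = [
        r for r in _maximal_basins(scan.vi_p, basin_depth_theta)
        if r[1] - r[0] + 1 >= basin_min_width
    ]
    if not runs:
        warnings.warn("no VI basin found; falling back to the global VI_g minimum")
        chosen = [int(np.argmin(scan.vi_g))]
    else:
        chosen = []
        for a, b in runs:
            local = int(np.argmin(scan.vi_g[a : b + 1])) + a
            chosen.append(local)
    # deduplicate identical partitions across basins (keep coarser/later ones once)
    chosen = sorted(set(chosen), key=lambda i: -scan.times[i])  # coarse -> fine
    seen: dict[bytes, int] = {}
    final: list[int] = []
    for i in chosen:
        key = _canonical(scan.representatives[i])
        if key not in seen:
            seen[key] = i
            final.append(i)
    n_comms = [int(scan.representatives[i].max()) + 1 for i in final]
    if any(b < a for a, b in zip(n_comms, n_comms[1:])):
        warnings.warn(
            "selected hierarchy is not monotone in community count "
            f"(coarse->fine counts: {n_comms})"
        )
    return HierarchicalClustering(
        scale_indices=final,
        times=[float(scan.times[i]) for i in final],
        partitions=[scan.representatives[i].copy() for i in final],
    )
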