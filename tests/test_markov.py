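import itertools

import numpy as np
import pytest
import scipy.sparse as sp
from scipy.linalg import expm

from crosschat.graph import CellGraph
from crosschat.io import ValidationError
from crosschat.markov import (
    HierarchicalClustering,
    ScaleScan,
    build_operator,
    louvain_quality,
    markov_stability,
    relabel_by_size,
    select_scales,
    variation_of_information,
)
from conftest import random_partition


def _graph(a):
    a = np.asarray(a, float)
    return CellGraph([f"c{i}" for i in range(a.shape[0])], sp.csr_matrix(a))


def _path_graph(n):
    a = np.zeros((n, n))
    for i in range(n - 1):
        a[i, i + 1] = a[i + 1, i] = 1.0
    return _graph(a)


class TestOperator:
    def test_k2_closed_form(self):
        for w in (1.0, 2.5):
            op = build_operator(_graph([[0, w], [w, 0]]))
            np.testing.assert_allclose(op.pi, [0.5, 0.5])
            for t in (0.0, 0.3, 2.0):
                expected = np.array(
                    [
                        [(1 + np.exp(-2 * t)) / 2, (1 - np.exp(-2 * t)) / 2],
                        [(1 - np.exp(-2 * t)) / 2, (1 + np.exp(-2 * t)) / 2],
                    ]
                )
                np.testing.assert_allclose(op.transition(t), expected, atol=1e-12)

    def test_transition_at_zero_is_identity(self, two_clique_graph):
        op = build_operator(two_clique_graph)
        np.testing.assert_allclose(op.transition(0.0), np.eye(op.n), atol=1e-12)

    def test_path_graph_matches_expm_oracle(self):
        g = _path_graph(5)
        op = build_operator(g)
        a = g.adjacency.toarray()
        L = np.eye(5) - np.diag(1 / a.sum(1)) @ a
        np.testing.assert_allclose(op.transition(1.0), expm(-L), atol=1e-8)

    def test_rows_sum_to_one_and_pi_stationary(self, two_clique_graph):
        op = build_operator(two_clique_graph)
        a = two_clique_graph.adjacency.toarray()
        p_step = np.diag(1 / a.sum(1)) @ a
        np.testing.assert_allclose(op.pi @ p_step, op.pi, atol=1e-10)
        for t in (0.1, 1.0, 10.0):
            np.testing.assert_allclose(op.transition(t).sum(1), 1.0, atol=1e-8)

    def test_disconnected_graph_rejected(self):
        a = np.zeros((4, 4))
        a[0, 1] = a[1, 0] = 1
        a[2, 3] = a[3, 2] = 1
        with pytest.raises(ValidationError):
            build_operator(_graph(a))


class TestMarkovStability:
    def test_one_block_is_zero_any_graph(self, rng, two_clique_graph):
        op = build_operator(two_clique_graph)
        for t in (0.0, 0.5, 3.0, 50.0):
            assert markov_stability(op, np.zeros(op.n, int), t) == pytest.approx(0.0, abs=1e-10)

    def test_singletons_at_zero_is_n_minus_one(self, two_clique_graph):
        op = build_operator(two_clique_graph)
        assert markov_stability(op, np.arange(op.n), 0.0) == pytest.approx(op.n - 1, abs=1e-10)

    def test_nonincreasing_in_t_fixed_partition(self, rng, two_clique_graph):
        op = build_operator(two_clique_graph)
        parts = [np.r_[np.zeros(10, int), np.ones(10, int)]]
        for _ in range(3):
            parts.append(random_partition(rng, op.n, 4))
        ts = [0.1, 0.5, 1.0, 3.0, 10.0, 100.0]
        for part in parts:
            vals = [markov_stability(op, part, t) for t in ts]
            assert all(a >= b - 1e-9 for a, b in zip(vals, vals[1:]))


class TestVariationOfInformation:
    def test_identity(self, rng):
        x = random_partition(rng, 20, 5)
        assert variation_of_information(x, x) == 0.0

    def test_one_block_vs_singletons(self):
        assert variation_of_information(np.zeros(4, int), np.arange(4)) == pytest.approx(np.log(4))

    def test_hand_example_vs_entropy_oracle(self):
        # X = {123}{456}, Y = {12}{34}{56}: VI = H(X)+H(Y)-2I = 0.867563...
        x = np.array([0, 0, 0, 1, 1, 1])
        y = np.array([0, 0, 1, 1, 2, 2])
        got = variation_of_information(x, y)
        assert got == pytest.approx(_vi_entropy_oracle(x, y), abs=1e-12)
        assert got == pytest.approx(0.8675632, abs=1e-6)

    def test_metric_axioms_on_random_triples(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 13))
            x, y, z = (random_partition(rng, n, 4) for _ in range(3))
            dxy = variation_of_information(x, y)
            dyx = variation_of_information(y, x)
            assert dxy == pytest.approx(dyx, abs=1e-12)
            assert dxy >= -1e-12
            assert dxy == pytest.approx(_vi_entropy_oracle(x, y), abs=1e-10)
            dxz = variation_of_information(x, z)
            dzy = variation_of_information(z, y)
            assert dxy <= dxz + dzy + 1e-10

    def test_mismatched_sets_error(self):
        with pytest.raises(ValidationError):
            variation_of_information(np.zeros(3, int), np.zeros(4, int))


def _vi_entropy_oracle(x, y):
    def entropy(lab):
        _, c = np.unique(lab, return_counts=True)
        p = c / c.sum()
        return -(p * np.log(p)).sum()

    n = len(x)
    joint = {}
    for a, b in zip(x, y):
        joint[(a, b)] = joint.get((a, b), 0) + 1
    hx, hy = entropy(x), entropy(y)
    px = {a: (x == a).mean() for a in set(x)}
    py = {b: (y == b).mean() for b in set(y)}
    mi = sum(
        (c / n) * np.log((c / n) / (px[a] * py[b])) for (a, b), c in joint.items()
    )
    return hx + hy - 2 * mi


class TestLouvain:
    def test_two_cliques_recovered_mid_t(self, two_clique_graph):
        op = build_operator(two_clique_graph)
        rep, ens, vi_g, ms = louvain_quality(op, 2.0, n_runs=10, seed=0)
        expected = np.r_[np.zeros(10, int), np.ones(10, int)]
        assert variation_of_information(rep, expected) == pytest.approx(0.0, abs=1e-12)
        assert vi_g == pytest.approx(0.0, abs=1e-9)
        # exhaustive check: 2-block MS beats the merge and the singletons
        ms_two = markov_stability(op, expected, 2.0)
        assert ms_two >= markov_stability(op, np.zeros(20, int), 2.0)
        assert ms_two >= markov_stability(op, np.arange(20), 2.0)

    def test_huge_t_single_community(self, two_clique_graph):
        op = build_operator(two_clique_graph)
        rep, *_ = louvain_quality(op, 1e4, n_runs=5, seed=1)
        assert rep.max() == 0

    def test_same_seed_identical_ensemble(self, two_clique_graph):
        op = build_operator(two_clique_graph)
        _, e1, *_ = louvain_quality(op, 1.0, n_runs=8, seed=7)
        _, e2, *_ = louvain_quality(op, 1.0, n_runs=8, seed=7)
        assert all((a == b).all() for a, b in zip(e1, e2))

    def test_never_worse_than_trivial_partitions(self, rng):
        # random sparse-ish graphs
        for trial in range(3):
            n = 12
            a = np.triu(rng.random((n, n)) < 0.4, 1).astype(float)
            a = a + a.T
            a[a.sum(1) == 0, 0] = 1
            a[0, a.sum(1) == 0] = 1
            g = _graph(np.maximum(a, a.T) - np.diag(np.diag(a)))
            op = build_operator(g)
            for t in (0.2, 2.0):
                rep, *_ , ms = louvain_quality(op, t, n_runs=5, seed=trial)
                assert ms >= markov_stability(op, np.zeros(n, int), t) - 1e-9
                assert ms >= markov_stability(op, np.arange(n), t) - 1e-9


class TestSelectScales:
    def _scan_from_vip(self, vi_p, vi_g, reps, times=None):
        g = vi_p.shape[0]
        times = times if times is not None else np.logspace(-1, 4, g)
        return ScaleScan(
            log_times=np.log10(times),
            times=times,
            representatives=reps,
            ms_values=np.zeros(g),
            vi_g=np.asarray(vi_g, float),
            n_communities=np.array([r.max() + 1 for r in reps]),
            vi_p=vi_p,
        )

    def test_three_zero_blocks_give_three_scales(self, rng):
        widths = [40, 30, 30]
        g = 100
        vi_p = np.ones((g, g))
        reps = []
        start = 0
        protos = [np.repeat([0, 1], 5), np.repeat([0, 1, 2, 3], [3, 3, 2, 2]), np.arange(10) % 5]
        for w, proto in zip(widths, protos):
            vi_p[start : start + w, start : start + w] = 0.0
            reps += [proto.copy() for _ in range(w)]
            start += w
        np.fill_diagonal(vi_p, 0.0)
        scan = self._scan_from_vip(vi_p, rng.random(g) * 0.01, reps)
        hier = select_scales(scan, basin_depth_theta=0.1, basin_min_width=5)
        assert hier.n_scales == 3

    def test_fallback_when_no_basin(self, rng):
        g = 10
        vi_p = np.ones((g, g)) * 0.5
        np.fill_diagonal(vi_p, 0.0)
        reps = [random_partition(rng, 8, 4) for _ in range(g)]
        vi_g = rng.random(g)
        scan = self._scan_from_vip(vi_p, vi_g, reps)
        with pytest.warns(UserWarning):
            hier = select_scales(scan, basin_depth_theta=0.1, basin_min_width=3)
        assert hier.n_scales == 1
        assert hier.scale_indices == [int(np.argmin(vi_g))]

    def test_scales_ordered_coarse_to_fine(self, rng):
        g = 20
        vi_p = np.ones((g, g))
        vi_p[:10, :10] = 0.0
        vi_p[10:, 10:] = 0.0
        coarse = np.repeat([0, 1], 4)
        fine = np.arange(8) % 4
        reps = [fine.copy() for _ in range(10)] + [coarse.copy() for _ in range(10)]
        scan = self._scan_from_vip(vi_p, np.ones(g), reps)
        hier = select_scales(scan, 0.1, 3)
        assert hier.n_communities() == [2, 4]
        assert hier.times[0] > hier.times[1]


def test_relabel_by_size():
    lab = np.array([5, 5, 2, 2, 2, 9])
    out = relabel_by_size(lab)
    np.testing.assert_array_equal(out, [1, 1, 0, 0, 0, 2])
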