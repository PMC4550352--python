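import numpy as np
import pandas as pd
import pytest

from dendropart.eigenmaps import (
    EigenfunctionSet,
    aem_edge_weights,
    aem_eigenfunctions,
    mem_eigenfunctions,
    morans_i,
    positive_eigenfunction_filter,
)
from dendropart.network import DistanceMatrix

from conftest import make_network, random_tree_network


def collinear_distance(n=10, spacing=1.0):
    x = np.arange(n) * spacing
    return DistanceMatrix(
        np.abs(x[:, None] - x[None, :]), list(range(n)), "overland_geo"
    )


class TestMem:
    def test_collinear_points_give_cosine_like_axes(self):
        n = 10
        es = mem_eigenfunctions(collinear_distance(n))
        x = np.arange(n, dtype=float)
        for k in range(es.k):
            tmpl = np.cos((k + 1) * np.pi * (x + 0.5) / n)
            tmpl -= tmpl.mean()
            tmpl /= np.linalg.norm(tmpl)
            # sign-free cosine similarity, bound computed from this construction
            assert abs(float(es.basis[:, k] @ tmpl)) > 0.85

    def test_columns_orthonormal_and_centred(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 100, (15, 2))
        d = np.hypot(*(pts[:, None, :] - pts[None, :, :]).transpose(2, 0, 1))
        es = mem_eigenfunctions(DistanceMatrix(d, list(range(15)), "overland_geo"))
        gram = es.basis.T @ es.basis
        assert np.allclose(gram, np.eye(es.k), atol=1e-8)
        assert np.allclose(es.basis.sum(axis=0), 0.0, atol=1e-8)

    def test_retained_count_matches_dense_eigendecomposition_oracle(self):
        rng = np.random.default_rng(4)
        pts = rng.uniform(0, 100, (12, 2))
        d = np.hypot(*(pts[:, None, :] - pts[None, :, :]).transpose(2, 0, 1))
        es = mem_eigenfunctions(DistanceMatrix(d, list(range(12)), "overland_geo"))
        # oracle: explicit double-centring with loops + scipy eigh
        from scipy.linalg import eigh

        t = es.meta["truncation"]
        n = 12
        dstar = d.copy()
        dstar[d > t] = 4 * t
        np.fill_diagonal(dstar, 0.0)
        a = -0.5 * dstar**2
        b = np.empty_like(a)
        for i in range(n):
            for j in range(n):
                b[i, j] = a[i, j] - a[i, :].mean() - a[:, j].mean() + a.mean()
        vals = eigh(b, eigvals_only=True)
        n_pos = int(np.sum(vals > 1e-10 * vals.max()))
        assert es.k == n_pos
        assert np.allclose(np.sort(vals)[::-1][: es.k], es.eigenvalues, atol=1e-8)

    def test_relabelling_invariance_up_to_sign(self):
        rng = np.random.default_rng(9)
        pts = rng.uniform(0, 100, (12, 2))
        d = np.hypot(*(pts[:, None, :] - pts[None, :, :]).transpose(2, 0, 1))
        es = mem_eigenfunctions(DistanceMatrix(d, list(range(12)), "overland_geo"))
        perm = rng.permutation(12)
        es_p = mem_eigenfunctions(
            DistanceMatrix(d[np.ix_(perm, perm)], list(perm), "overland_geo")
        )
        assert np.allclose(es_p.eigenvalues, es.eigenvalues, atol=1e-8)
        for k in range(es.k):
            a, b = es.basis[perm, k], es_p.basis[:, k]
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-6

    def test_disconnected_threshold_raises(self):
        d = collinear_distance(6)
        with pytest.raises(ValueError, match="truncation"):
            mem_eigenfunctions(d, truncation=0.5)


class TestAemWeights:
    def test_equal_distances_equal_weights(self):
        w = aem_edge_weights(np.array([5.0, 5.0, 5.0]))
        assert np.allclose(w, w[0])

    def test_zero_distance_full_weight(self):
        w = aem_edge_weights(np.array([0.0, 100.0]))
        assert w[0] == pytest.approx(1.0)

    def test_linear_formula(self):
        w = aem_edge_weights(np.array([25.0, 100.0]), alpha=1.0)
        assert w[0] == pytest.approx(0.75)
        assert w[1] == pytest.approx(1e-6)  # floor keeps the edge attached

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            aem_edge_weights(np.array([-1.0, 2.0]))


class TestAem:
    def _chain(self, n=4):
        nodes = [(i, float(i), 0.0, 4400.0 - 100 * i) for i in range(n)]
        segs = [(i - 1, i, 100.0) for i in range(1, n)]
        return make_network(nodes, segs)

    def test_chain_incidence_is_nested(self):
        # 4-site downstream chain: site i's directed path covers all edges
        # above it, so eigenfunction 1 is monotone along the chain
        net = self._chain(4)
        es = aem_eigenfunctions(net)
        v = es.basis[:, 0]
        assert np.all(np.diff(v) > 0) or np.all(np.diff(v) < 0)
        assert es.k <= min(4 - 1, len(net.segments) + 1)

    def test_chain_first_axis_matches_explicit_svd(self):
        # oracle: SVD of the explicitly written incidence matrix of a
        # 4-site chain with a virtual origin (lower-triangular of ones)
        net = self._chain(4)
        es = aem_eigenfunctions(net)
        e = np.tril(np.ones((4, 4)))  # col 0 = origin edge, cols 1-3 = segments
        ec = e - e.mean(axis=0)
        u, s, _ = np.linalg.svd(ec, full_matrices=False)
        keep = s > 1e-10 * s[0]
        assert es.k == int(keep.sum())
        for k in range(es.k):
            a, b = u[:, k], es.basis[:, k]
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-8

    def test_sibling_branches_disjoint_edge_support(self, y_network):
        # sites on different tributaries share no branch edges above the
        # confluence, so their rows differ on the branch columns
        es = aem_eigenfunctions(y_network)
        assert es.k >= 2

    def test_edge_order_invariance_of_column_space(self):
        net = random_tree_network(3, n=12)
        es1 = aem_eigenfunctions(net)
        shuffled = net.segments.sample(frac=1.0, random_state=0)
        from dendropart.network import StreamNetwork

        net2 = StreamNetwork(nodes=net.nodes.copy(), segments=shuffled.reset_index(drop=True))
        es2 = aem_eigenfunctions(net2)
        q = es1.basis
        resid = es2.basis - q @ (q.T @ es2.basis)
        assert np.abs(resid).max() < 1e-8

    def test_site_subset_rows(self):
        net = random_tree_network(5, n=12)
        subset = net.site_ids[:5]
        es = aem_eigenfunctions(net, site_subset=subset)
        assert es.basis.shape[0] == 5
        assert es.labels == subset


class TestMoransI:
    def test_checkerboard_negative(self):
        v = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        w = np.diag(np.ones(5), 1) + np.diag(np.ones(5), -1)
        assert morans_i(v, w) < 0

    def test_smooth_gradient_positive(self):
        v = np.linspace(0, 1, 8)
        w = np.diag(np.ones(7), 1) + np.diag(np.ones(7), -1)
        assert morans_i(v, w) > 0

    def test_matches_naive_double_sum_oracle(self):
        rng = np.random.default_rng(12)
        n = 15
        v = rng.normal(size=n)
        w = rng.uniform(0, 1, (n, n))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        vc = v - v.mean()
        num = sum(
            w[i, j] * vc[i] * vc[j] for i in range(n) for j in range(n)
        )
        expect = n / w.sum() * num / float(vc @ vc)
        assert morans_i(v, w) == pytest.approx(expect, rel=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            morans_i(np.ones(5), np.ones((5, 5)) - np.eye(5))


class TestPositiveFilter:
    def test_mem_filter_idempotent(self):
        es = mem_eigenfunctions(collinear_distance(8))
        f = positive_eigenfunction_filter(es)
        assert f.k == es.k

    def test_aem_chain_retains_monotone_axis(self):
        nodes = [(i, float(i), 0.0, 4400.0 - 100 * i) for i in range(6)]
        segs = [(i - 1, i, 100.0) for i in range(1, 6)]
        net = make_network(nodes, segs)
        es = aem_eigenfunctions(net)
        f = positive_eigenfunction_filter(es)
        assert f.k >= 1
        assert f.morans_i[0] > 0  # the smooth axis survives

    def test_all_nonpositive_gives_empty_flag(self):
        es = EigenfunctionSet(
            basis=np.zeros((5, 0)),
            eigenvalues=np.array([]),
            morans_i=np.array([]),
            construction="MEM",
            dist_type="overland_geo",
            labels=list(range(5)),
        )
        f = positive_eigenfunction_filter(es)
        assert f.is_empty


def test_straight_line_overland_equals_watercourse_mem():
    # a perfectly straight channel (sinuosity 1): the two distances agree,
    # so the eigenfunction sets must coincide
    from dendropart.network import (
        overland_distance_matrix,
        watercourse_distance_matrix,
    )

    n = 9
    nodes = [(i, 100.0 * i, 0.0, 4400.0 - 10 * i) for i in range(n)]
    segs = [(i - 1, i, 100.0) for i in range(1, n)]
    net = make_network(nodes, segs)
    m_ov = mem_eigenfunctions(overland_distance_matrix(net))
    m_wc = mem_eigenfunctions(watercourse_distance_matrix(net))
    assert np.allclose(m_ov.eigenvalues, m_wc.eigenvalues, atol=1e-6)
    for k in range(m_ov.k):
        a, b = m_ov.basis[:, k], m_wc.basis[:, k]
        assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-6
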