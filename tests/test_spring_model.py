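import warnings

import numpy as np
import pytest

from springgeo.network_io import (
    network_from_edges,
    node_masses,
    oriented_incidence,
)
from springgeo.spring_model import (
    DissimilarityMatrix,
    rescale_stiffness,
    stiffness_equilibrium,
    stiffness_nonequilibrium,
    stiffness_to_dissimilarity,
    vibrational_centrality,
    weighted_incidence,
)


def _weighted(g):
    return weighted_incidence(oriented_incidence(g), node_masses(g))


def _random_connected(seed: int, n_max: int = 30):
    import networkx as nx

    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, n_max + 1))
    gx = nx.gnp_random_graph(n, 0.35, seed=seed)
    if not nx.is_connected(gx):
        comps = [list(c) for c in nx.connected_components(gx)]
        for a, b in zip(comps[:-1], comps[1:]):
            gx.add_edge(a[0], b[0])
    return network_from_edges(
        [(f"v{u:03d}", f"v{v:03d}") for u, v in gx.edges]
    )


class TestVibrationalCentrality:
    def test_single_edge(self, fixtures):
        # L = [[1,-1],[-1,1]], pinv diagonal = 1/4 -> displacement 0.5
        vib = vibrational_centrality(fixtures["p2"].network)
        assert np.allclose(vib.displacement, 0.5, atol=1e-12)

    def test_triangle(self, fixtures):
        # Lplus = (1/3)(I - J/3): diagonal 2/9 -> displacement sqrt(2/9)
        vib = vibrational_centrality(fixtures["triangle"].network)
        assert np.allclose(vib.displacement, np.sqrt(2.0 / 9.0), atol=1e-12)

    def test_vertex_transitive_equal(self, fixtures):
        # cliques are vertex-transitive
        vib = vibrational_centrality(fixtures["two_cliques"].network)
        assert np.allclose(vib.displacement, vib.displacement[0])

    def test_temperature_scaling(self, fixtures):
        g = fixtures["path5"].network
        v1 = vibrational_centrality(g, temperature=1.0).displacement
        v4 = vibrational_centrality(g, temperature=4.0).displacement
        assert np.allclose(v4, 2.0 * v1)

    def test_invalid_params(self, fixtures):
        with pytest.raises(ValueError):
            vibrational_centrality(fixtures["p2"].network, temperature=-1.0)


class TestWeightedIncidence:
    def test_unit_masses(self, fixtures):
        g = fixtures["p2"].network
        c = _weighted(g)
        assert list(c[:, 0]) == [1.0, -1.0]

    def test_star_rows(self, fixtures):
        g = fixtures["star3"].network
        c = _weighted(g)
        hub = g.index("hub")
        assert set(np.abs(c[hub][c[hub] != 0])) == {3.0}
        for i in range(4):
            if i != hub:
                nz = c[i][c[i] != 0]
                assert set(np.abs(nz)) == {1.0}

    def test_column_structure(self, fixtures):
        g = fixtures["path5"].network
        c = _weighted(g)
        m = node_masses(g)
        for e, (i, j) in enumerate(g.edges):
            col = c[:, e]
            assert col[i] == m[i]
            assert col[j] == -m[j]
            assert np.count_nonzero(col) == 2

    def test_mass_scaling_preserves_kernel_direction(self, fixtures):
        g = fixtures["star3"].network
        a = oriented_incidence(g)
        m = node_masses(g)
        c1 = weighted_incidence(a, m)
        c2 = weighted_incidence(a, 5.0 * m)
        assert np.allclose(c2, 5.0 * c1)
        k1 = stiffness_equilibrium(c1).raw
        k2 = stiffness_equilibrium(c2).raw
        assert np.allclose(k1, k2, atol=1e-12)

    def test_zero_mass_incident_errors(self, fixtures):
        a = oriented_incidence(fixtures["p2"].network)
        with pytest.raises(ValueError, match="mass"):
            weighted_incidence(a, np.array([0.0, 1.0]))


class TestStiffnessEquilibrium:
    def test_single_edge(self, fixtures):
        k = stiffness_equilibrium(_weighted(fixtures["p2"].network))
        assert np.allclose(k.raw, 0.5)
        assert k.kernel_dim == 1

    def test_triangle(self, fixtures):
        k = stiffness_equilibrium(_weighted(fixtures["triangle"].network))
        assert np.allclose(k.raw, 1.0 / 3.0, atol=1e-12)

    def test_star_closed_form(self, fixtures):
        g = fixtures["star3"].network
        k = stiffness_equilibrium(_weighted(g))
        hub = g.index("hub")
        leaves = [i for i in range(4) if i != hub]
        assert np.allclose(k.raw[hub, leaves], 3.0 / 28.0, atol=1e-12)
        assert np.allclose(
            k.raw[leaves[0], leaves[1]], 9.0 / 28.0, atol=1e-12
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_kernel_certificate_and_closed_form(self, seed):
        g = _random_connected(seed)
        m = node_masses(g)
        c = _weighted(g)
        k = stiffness_equilibrium(c)
        assert k.kernel_dim == 1
        # kernel certificate: m_i v_i = m_j v_j on every edge
        for v in k.kernel_basis.T:
            resid = max(
                abs(m[i] * v[i] - m[j] * v[j]) for i, j in g.edges
            )
            assert resid <= 1e-10 * m.max()
        # closed form: k_ij = (1/(m_i m_j)) / sum_l 1/m_l^2
        inv2 = np.sum(1.0 / m**2)
        expected = np.outer(1.0 / m, 1.0 / m) / inv2
        assert np.max(np.abs(k.raw - expected)) < 1e-12

    def test_orientation_invariance(self, fixtures):
        g = fixtures["path5"].network
        a = oriented_incidence(g)
        m = node_masses(g)
        k_ref = stiffness_equilibrium(weighted_incidence(a, m)).raw
        rng = np.random.default_rng(4)
        for _ in range(5):
            flip = rng.random(a.shape[1]) < 0.5
            a2 = a.copy()
            a2[:, flip] *= -1.0
            k2 = stiffness_equilibrium(weighted_incidence(a2, m)).raw
            assert np.allclose(k2, k_ref, atol=1e-12)

    def test_component_additivity(self, fixtures):
        f = fixtures["two_cliques"]
        k = stiffness_equilibrium(_weighted(f.network))
        assert k.kernel_dim == 2
        assert np.allclose(k.raw, f.expected_stiffness, atol=1e-12)
        # block diagonal: zero across components
        assert np.allclose(k.raw[:10, 10:], 0.0, atol=1e-12)

    def test_psd_with_trace_kernel_dim(self, fixtures):
        for name in ("p2", "star3", "two_cliques"):
            k = stiffness_equilibrium(_weighted(fixtures[name].network))
            eigvals = np.linalg.eigvalsh(k.raw)
            assert eigvals.min() > -1e-12
            assert np.isclose(np.trace(k.raw), k.kernel_dim)

    def test_zero_matrix_errors(self):
        with pytest.raises(ValueError):
            stiffness_equilibrium(np.zeros((3, 2)))


class TestStiffnessNonEquilibrium:
    def test_zero_forces_zero_stiffness(self, fixtures):
        g = fixtures["p2"].network
        c = _weighted(g)
        with pytest.warns(RuntimeWarning, match="pseudoinverse"):
            k = stiffness_nonequilibrium(c, np.zeros(2), np.ones(2))
        assert np.allclose(k.raw, 0.0)

    def test_zero_displacement_errors(self, fixtures):
        c = _weighted(fixtures["p2"].network)
        with pytest.raises(ValueError, match="invertible"):
            stiffness_nonequilibrium(c, np.ones(2), np.array([1.0, 0.0]))

    def test_single_edge_least_squares_oracle(self, fixtures):
        c = _weighted(fixtures["p2"].network)
        f = np.array([1.0, -1.0])
        with pytest.warns(RuntimeWarning):
            k = stiffness_nonequilibrium(c, f, np.ones(2))
        # oracle: minimum-norm least-squares solve of the 1x2 system
        expected, *_ = np.linalg.lstsq(c.T, f.reshape(1, 2), rcond=None)
        expected = 0.5 * (expected + expected.T)
        assert np.allclose(k.raw, expected, atol=1e-12)
        assert np.allclose(k.raw, k.raw.T)


class TestRescaleAndDissimilarity:
    def test_star_rescale(self, fixtures):
        g = fixtures["star3"].network
        k = rescale_stiffness(stiffness_equilibrium(_weighted(g)))
        hub = g.index("hub")
        leaves = [i for i in range(4) if i != hub]
        assert np.allclose(k.rescaled[hub, leaves], 0.0)
        assert np.allclose(k.rescaled[leaves[0], leaves[1]], 1.0)

    def test_degenerate_rescale_warns(self, fixtures):
        k = stiffness_equilibrium(_weighted(fixtures["triangle"].network))
        with pytest.warns(RuntimeWarning, match="degenerate"):
            k = rescale_stiffness(k)
        off = k.rescaled[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 1.0)

    def test_scale_invariance(self, fixtures):
        k = stiffness_equilibrium(_weighted(fixtures["star3"].network))
        k1 = rescale_stiffness(k)
        import dataclasses

        k_scaled = dataclasses.replace(k, raw=7.5 * k.raw)
        k2 = rescale_stiffness(k_scaled)
        assert np.allclose(k1.rescaled, k2.rescaled, atol=1e-12)

    def test_dissimilarity_endpoints(self, fixtures):
        g = fixtures["star3"].network
        k = rescale_stiffness(stiffness_equilibrium(_weighted(g)))
        d = stiffness_to_dissimilarity(k)
        hub = g.index("hub")
        leaves = [i for i in range(4) if i != hub]
        assert np.allclose(d.values[hub, leaves], 1.0)  # k~ = 0 -> d = 1
        assert np.allclose(d.values[leaves[0], leaves[1]], 0.5)  # k~=1 -> 0.5
        assert np.allclose(np.diag(d.values), 0.0)

    def test_dissimilarity_range_and_monotonicity(self, fixtures):
        g = fixtures["path5"].network
        k = rescale_stiffness(stiffness_equilibrium(_weighted(g)))
        d = stiffness_to_dissimilarity(k)
        off = ~np.eye(d.n, dtype=bool)
        assert np.all(d.values[off] >= 0.5 - 1e-12)
        assert np.all(d.values[off] <= 1.0 + 1e-12)
        # monotone: larger rescaled stiffness -> smaller dissimilarity
        flat_k = k.rescaled[off]
        flat_d = d.values[off]
        order = np.argsort(flat_k)
        assert np.all(np.diff(flat_d[order]) <= 1e-12)

    def test_requires_rescale(self, fixtures):
        k = stiffness_equilibrium(_weighted(fixtures["p2"].network))
        with pytest.raises(ValueError, match="rescale"):
            stiffness_to_dissimilarity(k)


class TestDissimilarityMatrix:
    def test_validation(self):
        with pytest.raises(ValueError, match="symmetric"):
            DissimilarityMatrix(np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValueError, match="diagonal"):
            DissimilarityMatrix(np.array([[1.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValueError, match="square"):
            DissimilarityMatrix(np.zeros((2, 3)))

    def test_csv_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        a = rng.random((5, 5))
        a = 0.5 * (a + a.T)
        np.fill_diagonal(a, 0.0)
        d = DissimilarityMatrix(a, node_ids=tuple("abcde"))
        path = tmp_path / "d.csv"
        d.to_csv(path)
        d2 = DissimilarityMatrix.from_csv(path)
        assert d2.node_ids == d.node_ids
        assert np.allclose(d2.values, d.values, atol=1e-15)
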