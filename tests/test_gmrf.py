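import numpy as np
import pytest

from qintreg.gmrf import (LatentSpec, build_latent_precision,
                          build_pcar_precision, export_structure,
                          sample_constrained_gmrf)
from qintreg.graphs import RegionGraph, build_region_graph


def path_graph(n):
    names = [f"P{i}" for i in range(n)]
    return RegionGraph.from_edges(list(zip(names[:-1], names[1:])), names)


class TestStructures:
    def test_rw1_is_first_difference_crossproduct(self):
        q = build_latent_precision(LatentSpec("RW1", dimension=3))
        expected = np.array([[1, -1, 0], [-1, 2, -1], [0, -1, 1]], dtype=float)
        assert np.array_equal(q.matrix.toarray(), expected)
        assert q.rank_deficiency == 1

    def test_rw2_annihilates_affine_sequences(self):
        q = build_latent_precision(LatentSpec("RW2", dimension=4))
        assert np.allclose(q.matrix @ np.array([1.0, 2.0, 3.0, 4.0]), 0)
        for n in (5, 11, 30):
            qn = build_latent_precision(LatentSpec("RW2", dimension=n))
            seq = 2.5 - 0.7 * np.arange(1, n + 1)
            assert np.allclose(qn.matrix @ seq, 0, atol=1e-9)
            assert qn.rank_deficiency == 2

    def test_icar_on_path_graph_equals_rw1(self):
        icar = build_latent_precision(LatentSpec("ICAR", graph=path_graph(3)))
        rw1 = build_latent_precision(LatentSpec("RW1", dimension=3))
        assert np.array_equal(icar.matrix.toarray(), rw1.matrix.toarray())

    def test_icar_row_sums_zero(self, namibia):
        q = build_latent_precision(LatentSpec("ICAR", graph=namibia))
        assert np.allclose(np.asarray(q.matrix.sum(axis=1)).ravel(), 0)

    def test_iid_is_identity(self):
        q = build_latent_precision(LatentSpec("IID", dimension=5))
        assert np.array_equal(q.matrix.toarray(), np.eye(5))
        assert q.rank_deficiency == 0

    def test_rw2_needs_three_points(self):
        with pytest.raises(ValueError, match="RW2"):
            LatentSpec("RW2", dimension=2)

    def test_icar_needs_connected_graph(self):
        with pytest.raises(ValueError, match="connected"):
            RegionGraph.from_edges([("A", "B")], ["A", "B", "C"])

    @pytest.mark.parametrize("kind,dim", [("RW1", 8), ("RW2", 8),
                                          ("RW1", 50), ("RW2", 50)])
    def test_psd_and_null_dimension(self, kind, dim):
        q = build_latent_precision(LatentSpec(kind, dimension=dim))
        w = np.linalg.eigvalsh(q.matrix.toarray())
        assert w.min() > -1e-10
        assert int(np.sum(np.abs(w) < 1e-8)) == q.rank_deficiency


class TestPcar:
    def test_rho_zero_is_degree_diagonal(self, namibia):
        q = build_pcar_precision(namibia, 0.0)
        assert np.array_equal(q.matrix.toarray(), np.diag(namibia.degrees()))
        assert q.rank_deficiency == 0

    def test_two_node_eigenvalues(self):
        g = RegionGraph.from_edges([("A", "B")])
        q = build_pcar_precision(g, 0.5).matrix.toarray()
        assert np.allclose(q, [[1, -0.5], [-0.5, 1]])
        assert np.allclose(sorted(np.linalg.eigvalsh(q)), [0.5, 1.5])

    @pytest.mark.parametrize("rho", [-0.9, -0.3, 0.0, 0.5, 0.99])
    def test_positive_definite_for_any_valid_rho(self, rho, namibia):
        q = build_pcar_precision(namibia, rho).matrix.toarray()
        np.linalg.cholesky(q + 0.0)  # raises if not PD

    def test_positive_definite_on_random_connected_graphs(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            n = int(rng.integers(4, 12))
            names = [f"N{i}" for i in range(n)]
            edges = list(zip(names[:-1], names[1:]))  # spanning path
            for _ in range(n):
                i, j = rng.integers(0, n, 2)
                if i != j:
                    edges.append((names[min(i, j)], names[max(i, j)]))
            g = RegionGraph.from_edges(list(set(edges)), names)
            rho = float(rng.uniform(-0.99, 0.99))
            np.linalg.cholesky(build_pcar_precision(g, rho).matrix.toarray())

    def test_row_sums_equal_degree_times_one_minus_rho(self, namibia):
        rho = 0.7
        q = build_pcar_precision(namibia, rho)
        expected = namibia.degrees() * (1 - rho)
        assert np.allclose(np.asarray(q.matrix.sum(axis=1)).ravel(), expected)

    def test_converges_to_icar_as_rho_to_one(self, namibia):
        icar = build_latent_precision(
            LatentSpec("ICAR", graph=namibia)).matrix.toarray()
        for rho in (0.9, 0.999, 0.999999):
            pc = build_pcar_precision(namibia, rho).matrix.toarray()
            assert np.max(np.abs(pc - icar)) <= (1 - rho) * namibia.degrees().max() + 1e-12

    def test_invalid_rho_rejected(self, namibia):
        with pytest.raises(ValueError):
            build_pcar_precision(namibia, 1.0)
        with pytest.raises(ValueError):
            LatentSpec("PCAR", graph=namibia, rho=-1.5)


class TestSampler:
    def test_sum_to_zero_exact(self):
        q = build_latent_precision(LatentSpec("RW2", dimension=12))
        x = sample_constrained_gmrf(q, 3.0, seed=0, size=200)
        assert np.max(np.abs(x.sum(axis=1))) < 1e-10

    def test_seeded_determinism(self):
        q = build_latent_precision(LatentSpec("RW1", dimension=6))
        a = sample_constrained_gmrf(q, 1.0, seed=42)
        b = sample_constrained_gmrf(q, 1.0, seed=42)
        assert np.array_equal(a, b)

    def test_covariance_matches_pseudo_inverse(self):
        # RW1, n=4, 50k draws: empirical covariance within 3 MC SE of the
        # constrained pseudo-inverse, entrywise
        n, precision, draws = 4, 2.0, 50_000
        q = build_latent_precision(LatentSpec("RW1", dimension=n))
        x = sample_constrained_gmrf(q, precision, seed=7, size=draws)
        emp = np.cov(x, rowvar=False)
        oracle = np.linalg.pinv(precision * q.matrix.toarray())
        se = np.sqrt((np.outer(np.diag(oracle), np.diag(oracle))
                      + oracle**2) / draws)
        assert np.all(np.abs(emp - oracle) < 3 * se)

    def test_proper_structure_constrained_covariance(self, ring4):
        # PCAR is proper; conditioning on sum zero gives S - S1(1'S1)^-1 1'S
        q = build_pcar_precision(ring4, 0.4)
        x = sample_constrained_gmrf(q, 1.0, seed=3, size=50_000)
        s = np.linalg.inv(q.matrix.toarray())
        one = np.ones(4)
        oracle = s - np.outer(s @ one, s @ one) / (one @ s @ one)
        se = np.sqrt((np.outer(np.diag(oracle), np.diag(oracle))
                      + oracle**2) / 50_000) + 1e-12
        assert np.all(np.abs(np.cov(x, rowvar=False) - oracle) < 4 * se)

    def test_invalid_precision_rejected(self):
        q = build_latent_precision(LatentSpec("RW1", dimension=4))
        with pytest.raises(ValueError):
            sample_constrained_gmrf(q, 0.0, seed=0)


def test_structure_export_coordinate_text(tmp_path):
    q = build_latent_precision(LatentSpec("RW1", dimension=3))
    p = export_structure(q, tmp_path / "q.txt")
    rows = [line.split() for line in p.read_text().splitlines()]
    rebuilt = np.zeros((3, 3))
    for i, j, v in rows:
        rebuilt[int(i), int(j)] = float(v)
    assert np.array_equal(rebuilt, q.matrix.toarray())
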