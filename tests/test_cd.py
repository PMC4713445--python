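import numpy as np
import pytest

from cdlink.cd import (
    cd_ld_table,
    cd_score,
    cd_table,
    cd_times_ld_table,
    cdi_table,
    cosine_similarity,
    ld_score,
)
from cdlink.baselines import baseline_table
from cdlink.distances import bfs_apsp, coordinate_matrix, diameter, k_distance_matrix
from cdlink.fixtures import make_er, make_struct_equiv, make_toy

from oracles import naive_cd, naive_cd_ld, naive_cd_times_ld, naive_cdi

TOL = 1e-12


class TestCosineWorkedExamples:
    """The two 3-dimensional coordinate examples that motivate the unit
    diagonal: with c_ii = 1 the shared coordinate 0.2 contributes, with
    c_ii = 0 it becomes irrelevant and the score inflates."""

    def test_unit_diagonal_vectors(self):
        assert round(cosine_similarity([1, 0.2, 0.4], [0.2, 1, 0.5]), 4) == 0.4822

    def test_zero_diagonal_vectors(self):
        assert round(cosine_similarity([0, 0.2, 0.4], [0.2, 0, 0.5]), 4) == 0.8305

    def test_parallel_vectors_score_one(self):
        assert cosine_similarity([1, 0.5, 0.25], [2, 1, 0.5]) == pytest.approx(1.0)


class TestCdScore:
    def test_identical_rows_give_one(self):
        c = np.array([[1.0, 0.5, 0.5], [1.0, 0.5, 0.5], [0.5, 0.5, 1.0]])
        assert cd_score(c, 0, 1) == pytest.approx(1.0)

    def test_self_pair_rejected(self):
        c = np.eye(3)
        with pytest.raises(ValueError):
            cd_score(c, 1, 1)

    def test_structural_equivalence(self):
        """Twin nodes (identical neighbour sets) get identical CD scores
        against every third node."""
        for seed in range(3):
            base = make_er(9, 0.4, seed=seed, connected=True)
            for node in (0, 3):
                g = make_struct_equiv(base, node)
                twin = g.n - 1
                c = coordinate_matrix(bfs_apsp(g))
                for j in range(g.n):
                    if j in (node, twin):
                        continue
                    assert abs(cd_score(c, node, j) - cd_score(c, twin, j)) < TOL


class TestCdTable:
    def test_complete_graph_all_scores_equal(self, toy_graphs):
        t = cd_table(toy_graphs["k4"])
        vals = [s for _, s in t.items()]
        assert np.ptp(vals) < TOL

    def test_threshold_changes_path3_scores(self, toy_graphs):
        # k=1: rows of A+I; k=2 adds the 1/2 entry for the endpoints
        g = toy_graphs["path3"]
        t1 = cd_table(g, 1)
        t2 = cd_table(g, 2)
        # hand cosines: rows (1,1,0),(0.5,1,... ) etc.
        c1 = np.array([[1, 1, 0], [1, 1, 1], [0, 1, 1]], dtype=float)
        c2 = np.array([[1, 1, 0.5], [1, 1, 1], [0.5, 1, 1]])
        exp1 = c1[0] @ c1[2] / (np.linalg.norm(c1[0]) * np.linalg.norm(c1[2]))
        exp2 = c2[0] @ c2[2] / (np.linalg.norm(c2[0]) * np.linalg.norm(c2[2]))
        assert t1.get(0, 2) == pytest.approx(exp1, abs=TOL)
        assert t2.get(0, 2) == pytest.approx(exp2, abs=TOL)
        assert t1.get(0, 2) != pytest.approx(t2.get(0, 2))

    def test_matches_entrywise_cd_score(self, small_random_graphs):
        g = small_random_graphs[0]
        d = bfs_apsp(g)
        c = coordinate_matrix(k_distance_matrix(d, diameter(d)))
        t = cd_table(g)
        for (i, j), s in t.items():
            assert s == pytest.approx(cd_score(c, i, j), abs=TOL)

    def test_index_names(self, toy_graphs):
        g = toy_graphs["path4"]
        assert cd_table(g).index_name == "CD"
        assert cd_table(g, 2).index_name == "CD-2"

    def test_oversized_threshold_clamps(self, toy_graphs):
        g = toy_graphs["path3"]
        t_big = cd_table(g, 99)
        t_diam = cd_table(g, "diameter")
        np.testing.assert_allclose(t_big.matrix(), t_diam.matrix(), atol=TOL)


class TestLdScore:
    def test_no_common_neighbors_gives_zero(self, toy_graphs):
        g = toy_graphs["path4"]
        base = cd_table(g)
        assert ld_score(g, base, 0, 3) == 0.0

    def test_single_common_neighbor_gives_zero(self, toy_graphs):
        g = toy_graphs["star5"]  # leaves share only the centre
        base = cd_table(g)
        assert ld_score(g, base, 1, 2) == 0.0

    def test_k4_pair_is_single_base_term(self, toy_graphs):
        g = toy_graphs["k4"]
        base = cd_table(g)
        # common neighbours of (0,1) are {2,3}; one unordered pair
        assert ld_score(g, base, 0, 1) == pytest.approx(base.get(2, 3), abs=TOL)

    def test_include_self_adds_community_size(self, toy_graphs):
        g = toy_graphs["k4"]
        base = cd_table(g)
        assert ld_score(g, base, 0, 1, include_self=True) == pytest.approx(
            base.get(2, 3) + 2.0, abs=TOL
        )


class TestTableOracles:
    """Brute-force equivalence of the whole CD family on small fixtures."""

    @pytest.mark.parametrize("k", [1, 2, "diameter"])
    def test_cd_family_matches_naive(self, oracle_suite_graphs, k):
        for g in oracle_suite_graphs:
            d = bfs_apsp(g)
            kk = diameter(d) if k == "diameter" else min(k, diameter(d))
            pairs = {
                "cd": (cd_table(g, k), naive_cd(g, kk)),
                "cd_ld": (cd_ld_table(g, k), naive_cd_ld(g, kk)),
                "cd_x_ld": (cd_times_ld_table(g, k), naive_cd_times_ld(g, kk)),
                "cdi": (cdi_table(g, k), naive_cdi(g, kk)),
            }
            for label, (table, expected) in pairs.items():
                for (i, j), want in expected.items():
                    assert table.get(i, j) == pytest.approx(want, abs=1e-9), (
                        label,
                        g,
                        (i, j),
                    )


class TestInvariants:
    def test_cd_scores_in_unit_interval(self, oracle_suite_graphs):
        for g in oracle_suite_graphs:
            vals = [s for _, s in cd_table(g).items()]
            assert all(0.0 <= v <= 1.0 for v in vals)

    def test_family_scores_nonnegative(self, small_random_graphs):
        g = small_random_graphs[1]
        for maker in (cd_ld_table, cd_times_ld_table, cdi_table):
            assert all(s >= 0.0 for _, s in maker(g).items())

    def test_symmetric_queries(self, small_random_graphs):
        g = small_random_graphs[0]
        t = cd_table(g)
        for i in range(g.n):
            for j in range(i + 1, g.n):
                assert t.get(i, j) == t.get(j, i)

    def test_star_cd_ld_all_zero(self, toy_graphs):
        t = cd_ld_table(toy_graphs["star5"])
        assert all(s == 0.0 for _, s in t.items())

    def test_cd_times_ld_zero_where_ld_zero(self, small_random_graphs):
        g = small_random_graphs[2]
        ld = cd_ld_table(g)
        prod = cd_times_ld_table(g)
        for (i, j), s in ld.items():
            if s == 0.0:
                assert prod.get(i, j) == 0.0


class TestCdi:
    def test_degree_product_scaling(self):
        # CD = 0.5 with degrees 3 and 4 must yield 6.0; build directly
        from cdlink.graph import Graph
        from cdlink.scores import ScoreTable

        g = make_er(8, 0.5, seed=1, connected=True)
        cd = cd_table(g)
        cdi = cdi_table(g)
        for (i, j), s in cd.items():
            assert cdi.get(i, j) == pytest.approx(
                s * g.degree(i) * g.degree(j), abs=1e-12
            )

    def test_degree_one_endpoints_reduce_to_cd(self, toy_graphs):
        g = make_toy("path", 2)  # both endpoints degree 1
        assert cdi_table(g).get(0, 1) == pytest.approx(cd_table(g).get(0, 1))

    def test_ranking_matches_cd_times_pa(self):
        g = make_er(10, 0.35, seed=5, connected=True)
        cdi = cdi_table(g)
        cd = cd_table(g)
        pa = baseline_table(g, "PA")
        pairs = [(i, j) for i in range(g.n) for j in range(i + 1, g.n)]
        by_cdi = sorted(pairs, key=lambda p: cdi.get(*p))
        by_prod = sorted(pairs, key=lambda p: cd.get(*p) * pa.get(*p))
        assert by_cdi == by_prod
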