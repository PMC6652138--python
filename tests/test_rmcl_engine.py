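"""Flow-iteration kernels: expand/regularize/inflate/prune, balanced
regularizer, convergence, and cluster extraction."""

import numpy as np
import pytest

from psmcl.graph_io import add_self_loops, initial_flow_matrix, read_edge_list
from psmcl.rmcl_engine import (
    FlowState,
    RmclParams,
    balanced_regularizer,
    expand,
    extract_clusters,
    inflate_column,
    mcl,
    prune_column,
    r_mcl,
    regularize,
    rmcl_step,
    run_to_convergence,
)
from psmcl.sparse_core import SparseColumn, csc_from_entries

from conftest import (
    csc_from_dense,
    dense_balanced_regularizer,
    dense_inflate,
    dense_prune,
)


def random_stochastic(rng, n):
    dense = rng.random((n, n)) * (rng.random((n, n)) < 0.6)
    dense[rng.integers(n), :] += 0.2  # no zero column
    return dense / dense.sum(axis=0)


def path_graph_flow():
    gl = add_self_loops(read_edge_list("a b\nb c\n"))
    return initial_flow_matrix(gl)


class TestParams:
    @pytest.mark.parametrize(
        "kwargs", [dict(r=1.0), dict(r=0.5), dict(b=-0.1),
                   dict(prune_threshold=1.0), dict(conv_tol=0.0)]
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            RmclParams(**kwargs)


class TestExpandRegularize:
    def test_expand_identity(self):
        I = csc_from_dense(np.eye(4))
        np.testing.assert_array_equal(expand(I).to_dense(), np.eye(4))

    def test_expand_uniform_idempotent(self):
        U = csc_from_dense(np.full((4, 4), 0.25))
        np.testing.assert_allclose(expand(U).to_dense(), 0.25, atol=1e-15)

    def test_expand_non_square_rejected(self):
        M = csc_from_entries([(0, 0, 1.0)], 2, 3)
        with pytest.raises(ValueError):
            expand(M)

    def test_regularize_identity_either_side(self, rng):
        M = csc_from_dense(random_stochastic(rng, 5))
        I = csc_from_dense(np.eye(5))
        np.testing.assert_allclose(regularize(I, M).to_dense(), M.to_dense(), atol=1e-15)
        np.testing.assert_allclose(regularize(M, I).to_dense(), M.to_dense(), atol=1e-15)

    def test_regularize_path_graph_square(self):
        M_G = path_graph_flow()
        got = regularize(M_G, M_G).to_dense()
        np.testing.assert_allclose(got, M_G.to_dense() @ M_G.to_dense(), rtol=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_dense_products(self, seed):
        rng = np.random.default_rng(seed)
        A = random_stochastic(rng, 6)
        B = random_stochastic(rng, 6)
        np.testing.assert_allclose(expand(csc_from_dense(A)).to_dense(), A @ A, rtol=1e-12, atol=1e-13)
        np.testing.assert_allclose(
            regularize(csc_from_dense(A), csc_from_dense(B)).to_dense(), A @ B,
            rtol=1e-12, atol=1e-13)


class TestBalancedRegularizer:
    def test_b_zero_returns_regularizer_exactly(self, rng):
        M = csc_from_dense(random_stochastic(rng, 5))
        M_G = csc_from_dense(random_stochastic(rng, 5))
        assert balanced_regularizer(M, M_G, 0.0) is M_G

    def test_uniform_flow_leaves_regularizer_unchanged(self):
        n = 4
        M = csc_from_dense(np.full((n, n), 1 / n))
        M_G = path_graph_flow()
        M_G4 = csc_from_dense(random_stochastic(np.random.default_rng(0), n))
        np.testing.assert_allclose(
            balanced_regularizer(M, M_G4, 1.0).to_dense(), M_G4.to_dense(), rtol=1e-12)

    @pytest.mark.parametrize("b", [0.5, 1.0, 1.5, 2.0])
    @pytest.mark.parametrize("seed", range(3))
    def test_matches_dense_formula(self, b, seed):
        rng = np.random.default_rng(seed)
        Md = random_stochastic(rng, 6)
        Gd = random_stochastic(rng, 6)
        got = balanced_regularizer(csc_from_dense(Md), csc_from_dense(Gd), b).to_dense()
        np.testing.assert_allclose(got, dense_balanced_regularizer(Md, Gd, b), rtol=1e-12, atol=1e-13)

    def test_path_graph_b1_matches_dense(self):
        M_G = path_graph_flow()
        got = balanced_regularizer(M_G, M_G, 1.0).to_dense()
        expected = dense_balanced_regularizer(M_G.to_dense(), M_G.to_dense(), 1.0)
        np.testing.assert_allclose(got, expected, rtol=1e-12)


class TestInflatePrune:
    def test_inflate_symmetric_unchanged(self):
        c = SparseColumn(2, np.array([0, 1]), np.array([0.5, 0.5]))
        np.testing.assert_allclose(inflate_column(c, 2.0).values, [0.5, 0.5])

    def test_inflate_point_mass_fixed(self):
        c = SparseColumn(2, np.array([0]), np.array([1.0]))
        np.testing.assert_allclose(inflate_column(c, 3.7).values, [1.0])

    def test_inflate_concentrates(self):
        c = SparseColumn(2, np.array([0, 1]), np.array([0.6, 0.4]))
        out = inflate_column(c, 2.0)
        np.testing.assert_allclose(out.values, [9 / 13, 4 / 13])

    def test_inflate_never_decreases_max(self, rng):
        for _ in range(20):
            vals = rng.random(5) + 0.01
            vals /= vals.sum()
            c = SparseColumn(5, np.arange(5), vals)
            assert inflate_column(c, 2.0).values.max() >= vals.max() - 1e-15

    def test_prune_drops_and_renormalizes(self):
        c = SparseColumn(2, np.array([0, 1]), np.array([0.05, 0.95]))
        out = prune_column(c, 0.1)
        assert out.entries() == [(1, 1.0)]

    def test_prune_noop_above_threshold(self):
        c = SparseColumn(3, np.arange(3), np.array([0.3, 0.3, 0.4]))
        np.testing.assert_allclose(prune_column(c, 0.1).values, [0.3, 0.3, 0.4])

    def test_prune_rescues_largest(self):
        c = SparseColumn(3, np.arange(3), np.array([0.04, 0.03, 0.93]))
        out = prune_column(c, 0.95)
        assert out.entries() == [(2, 1.0)]


class TestRmclStep:
    def make_state(self, rng, n=6, b=0.0):
        Gd = random_stochastic(rng, n)
        M_G = csc_from_dense(Gd)
        return FlowState(M_G, M_G)

    @pytest.mark.parametrize("workers", [2, 4, 8])
    def test_worker_count_never_changes_result(self, rng, workers):
        state = self.make_state(rng, n=50)
        params = RmclParams(b=1.0)
        a = rmcl_step(state, params, n_workers=1)
        b = rmcl_step(state, params, n_workers=workers)
        np.testing.assert_array_equal(a.M.val, b.M.val)
        np.testing.assert_array_equal(a.M.row_ind, b.M.row_ind)
        np.testing.assert_array_equal(a.M.col_ptr, b.M.col_ptr)

    @pytest.mark.parametrize("seed", range(10))
    def test_step_matches_dense_oracle(self, seed):
        rng = np.random.default_rng(seed)
        Gd = random_stochastic(rng, 7)
        params = RmclParams(r=2.0, b=0.0, prune_threshold=1e-3)
        state = FlowState(csc_from_dense(Gd), csc_from_dense(Gd))
        got = rmcl_step(state, params).M.to_dense()
        expected = dense_prune(dense_inflate(Gd @ Gd, 2.0), 1e-3)
        np.testing.assert_allclose(got, expected, rtol=1e-12, atol=1e-13)

    def test_converged_state_is_fixed_point(self):
        # two disconnected edges, flow fully attracted
        gl = add_self_loops(read_edge_list("a b\nc d\n"))
        M_G = initial_flow_matrix(gl)
        state = run_to_convergence(FlowState(M_G, M_G), RmclParams())
        again = rmcl_step(state, RmclParams())
        np.testing.assert_allclose(again.M.to_dense(), state.M.to_dense(), atol=1e-9)

    def test_column_stochastic_preserved(self, rng):
        state = self.make_state(rng, n=20)
        for _ in range(5):
            state = rmcl_step(state, RmclParams(b=1.5))
            np.testing.assert_allclose(state.M.column_sums(), 1.0, atol=1e-9)


class TestConvergenceAndExtraction:
    def test_two_components_two_clusters(self):
        g = read_edge_list("a b\nc d\n")
        assert r_mcl(g).canonical() == [["a", "b"], ["c", "d"]]

    def test_single_node(self):
        g = read_edge_list("# empty\n")
        g.add_node("x")
        assert r_mcl(g).canonical() == [["x"]]

    def test_flow_never_crosses_components(self):
        gl = add_self_loops(read_edge_list("a b\nb c\nx y\ny z\n"))
        M_G = initial_flow_matrix(gl)
        state = run_to_convergence(FlowState(M_G, M_G), RmclParams(b=1.0))
        comp1 = {gl.node_id(l) for l in "abc"}
        for i, j, _ in state.M.entries():
            assert (i in comp1) == (j in comp1)

    def test_b_zero_balanced_equals_plain_trajectory(self):
        gl = add_self_loops(read_edge_list("a b\nb c\na c\nc d\nd e\ne f\nd f\n"))
        M_G = initial_flow_matrix(gl)
        s_plain = FlowState(M_G, M_G)
        s_bal = FlowState(M_G, M_G)
        for _ in range(6):
            s_plain = rmcl_step(s_plain, RmclParams(b=0.0))
            s_bal = rmcl_step(s_bal, RmclParams(b=0.0))
            np.testing.assert_array_equal(s_plain.M.val, s_bal.M.val)
            np.testing.assert_array_equal(s_plain.M.row_ind, s_bal.M.row_ind)

    def test_extract_identity_all_singletons(self):
        I = csc_from_dense(np.eye(3))
        c = extract_clusters(I, ["a", "b", "c"])
        assert c.n_clusters == 3

    def test_extract_shared_attractor(self):
        cols = np.zeros((3, 3))
        cols[0, 0] = cols[0, 1] = 1.0
        cols[2, 2] = 1.0
        c = extract_clusters(csc_from_dense(cols), ["a", "b", "c"])
        assert c.canonical() == [["a", "b"], ["c"]]

    def test_extract_tie_goes_to_smallest_row(self):
        # column b holds 0.5 at rows 0 and 1; the tie resolves to row 0,
        # so b joins a's cluster and c stays alone
        M = csc_from_entries(
            [(0, 0, 1.0), (0, 1, 0.5), (1, 1, 0.5), (2, 2, 1.0)], 3, 3)
        c = extract_clusters(M, ["a", "b", "c"])
        assert {frozenset(s) for s in c.clusters} == {frozenset("ab"), frozenset("c")}

    def test_extract_empty_column_rejected(self):
        M = csc_from_entries([(0, 0, 1.0)], 2, 2)
        with pytest.raises(ValueError):
            extract_clusters(M, ["a", "b"])


class TestMclBaseline:
    def test_two_triangles(self):
        g = read_edge_list("a b\nb c\na c\nd e\ne f\nd f\n")
        c = mcl(g)
        assert {frozenset(s) for s in c.clusters} == {frozenset("abc"), frozenset("def")}

    def test_singleton_graph(self):
        g = read_edge_list("#\n")
        g.add_node("only")
        assert mcl(g).n_clusters == 1

    def test_mcl_fragments_at_least_as_much_as_psmcl(self):
        from psmcl.fixtures import ring_of_cliques
        from psmcl.multilevel import DriverConfig, ps_mcl

        g, _ = ring_of_cliques(4, 5)
        k_mcl = mcl(g).n_clusters
        k_ps = ps_mcl(g, DriverConfig(depth=1, params=RmclParams(b=1.0), seed=0)).n_clusters
        assert k_mcl >= k_ps
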