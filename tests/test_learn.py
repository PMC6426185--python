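import numpy as np
import pytest

from surewalk.graph_io import row_normalize
from surewalk.learn import (
    LearnConfig,
    TrainingInstance,
    build_p_tilde,
    cost_F,
    grad_score_dense,
    gradient_F,
    learn_restart,
    loss_h,
    loss_h_prime,
    read_restart_vector,
    solve_r_tilde,
    write_restart_vector,
)
from surewalk.rwer import dense_resolvent, rwer_closed_form, seed_vector
from surewalk.synthetic import generate_sbm, make_ranking_instance

from conftest import random_digraph


def random_instance(rng, g, n_pos=2, n_neg=2):
    nodes = rng.permutation(g.n)
    return TrainingInstance(
        seed=int(nodes[0]),
        positives=tuple(int(x) for x in nodes[1:1 + n_pos]),
        negatives=tuple(int(x) for x in nodes[1 + n_pos:1 + n_pos + n_neg]),
    )


class TestLoss:
    def test_midpoint_is_half(self):
        for b in (1e-3, 1e-2, 1.0):
            assert loss_h(0.0, b) == 0.5

    def test_derivative_at_zero(self):
        for b in (1e-2, 0.5):
            assert np.isclose(loss_h_prime(0.0, b), 1 / (4 * b))

    def test_saturation_value(self):
        b = 0.01
        assert np.isclose(loss_h(10 * b, b), 0.9999546, atol=1e-7)

    def test_symmetry_and_monotonicity(self):
        x = np.linspace(-5, 5, 101)
        h = loss_h(x, 0.3)
        assert np.allclose(loss_h(-x, 0.3), 1 - h)
        assert np.all(np.diff(h) > 0)

    def test_overflow_safe(self):
        assert loss_h(1e6, 1e-3) == 1.0
        assert loss_h(-1e6, 1e-3) == 0.0
        assert loss_h_prime(1e6, 1e-3) == 0.0


class TestInstance:
    def test_overlap_rejected(self):
        with pytest.raises(ValueError):
            TrainingInstance(seed=0, positives=(1,), negatives=(1,))

    def test_labeled_seed_rejected(self):
        with pytest.raises(ValueError):
            TrainingInstance(seed=1, positives=(1,), negatives=(2,))


class TestCost:
    def test_no_pairs_reduces_to_regularizer(self, two_node_cycle):
        _, At = two_node_cycle
        inst = TrainingInstance(seed=0, positives=(), negatives=())
        cfg = LearnConfig(lam=2.0, origin=0.15)
        c = np.array([0.4, 0.6])
        assert np.isclose(cost_F(c, inst, cfg, At),
                          2.0 * np.sum((c - 0.15) ** 2))

    def test_tied_pair_costs_half(self, rng):
        # symmetric graph, symmetric labels around the seed -> r_y == r_x
        import scipy.sparse as sp

        from surewalk.graph_io import Graph

        a = np.zeros((3, 3))
        a[0, 1] = a[1, 0] = a[0, 2] = a[2, 0] = 1.0
        At = row_normalize(Graph(adjacency=sp.csr_matrix(a), directed=False))
        inst = TrainingInstance(seed=0, positives=(1,), negatives=(2,))
        cfg = LearnConfig(lam=0.0)
        assert np.isclose(cost_F(np.full(3, 0.2), inst, cfg, At), 0.5, atol=1e-9)

    def test_cost_matches_direct_recomputation(self, path4, rng):
        _, At = path4
        inst = TrainingInstance(seed=0, positives=(1,), negatives=(3,))
        cfg = LearnConfig(lam=1.0, b=0.05, origin=0.2)
        c = rng.uniform(0.05, 0.9, 4)
        r = rwer_closed_form(At, seed_vector(4, 0), c).r
        direct = np.sum((c - 0.2) ** 2) + 1 / (1 + np.exp(-(r[3] - r[1]) / 0.05))
        assert np.isclose(cost_F(c, inst, cfg, At), direct, atol=1e-8)

    def test_pairwise_cost_bounded(self, rng):
        g = random_digraph(rng, n_max=20, n_min=10)
        At = row_normalize(g)
        inst = random_instance(rng, g, 2, 3)
        cfg = LearnConfig(lam=0.0)
        val = cost_F(rng.uniform(0.05, 0.9, g.n), inst, cfg, At)
        assert 0.0 < val < len(inst.positives) * len(inst.negatives)


class TestPTilde:
    def test_single_tied_pair(self):
        r = np.zeros(4)
        inst = TrainingInstance(seed=0, positives=(1,), negatives=(2,))
        p = build_p_tilde(inst, r, b=0.25)
        expected = np.zeros(4)
        expected[2] = 1 / (4 * 0.25)
        expected[1] = -1 / (4 * 0.25)
        assert np.allclose(p, expected)

    def test_shared_negative_sums_weights(self):
        r = np.array([0.0, 0.1, 0.2, 0.05])
        inst = TrainingInstance(seed=0, positives=(1, 2), negatives=(3,))
        p = build_p_tilde(inst, r, b=0.1)
        w1 = loss_h_prime(r[3] - r[1], 0.1)
        w2 = loss_h_prime(r[3] - r[2], 0.1)
        assert np.isclose(p[3], w1 + w2)

    def test_longhand_over_all_pairs(self, rng):
        r = rng.random(8)
        inst = TrainingInstance(seed=0, positives=(1, 2), negatives=(3, 4))
        b = 0.07
        expected = np.zeros(8)
        for x in inst.positives:
            for y in inst.negatives:
                w = loss_h_prime(r[y] - r[x], b)
                expected[y] += w
                expected[x] -= w
        assert np.allclose(build_p_tilde(inst, r, b), expected)

    def test_mass_balance_exact(self, rng):
        r = rng.random(30)
        inst = TrainingInstance(seed=0, positives=(1, 5, 9), negatives=(2, 7))
        assert build_p_tilde(inst, r, 0.01).sum() == 0.0


class TestAdjointSolve:
    def test_zero_rhs_gives_zero(self, two_node_cycle):
        _, At = two_node_cycle
        x = solve_r_tilde(At, np.full(2, 0.2), seed_vector(2, 0), np.zeros(2))
        assert np.allclose(x, 0.0)

    def test_matches_dense_resolvent(self, rng):
        for _ in range(10):
            g = random_digraph(rng, n_max=15)
            At = row_normalize(g)
            q = seed_vector(g.n, int(rng.integers(g.n)))
            c = rng.uniform(0.05, 0.9, g.n)
            p = rng.normal(size=g.n)
            p -= p.mean()
            x = solve_r_tilde(At, c, q, p, solver_eps=1e-9)
            M = dense_resolvent(At, q, c)
            assert np.abs(x - M.T @ p).max() < 1e-7

    def test_residual_contract(self, rng):
        from surewalk.rwer import build_b_dense

        for _ in range(10):
            g = random_digraph(rng, n_max=40)
            At = row_normalize(g)
            q = seed_vector(g.n, 0)
            c = rng.uniform(0.05, 0.9, g.n)
            p = rng.normal(size=g.n)
            p -= p.mean()
            x = solve_r_tilde(At, c, q, p, solver_eps=1e-8)
            A = np.eye(g.n) - build_b_dense(At, q, c)
            assert np.linalg.norm(A.T @ x - p) < 1e-8


class TestGradient:
    def test_no_pairs_is_pure_regularizer(self, two_node_cycle):
        _, At = two_node_cycle
        inst = TrainingInstance(seed=0, positives=(), negatives=())
        cfg = LearnConfig(lam=3.0, origin=0.5)
        c = np.array([0.2, 0.8])
        assert np.allclose(gradient_F(c, inst, cfg, At), 2 * 3.0 * (c - 0.5))
        assert np.allclose(gradient_F(np.full(2, 0.5), inst, cfg, At), 0.0)

    def test_matches_finite_differences(self, rng):
        worst = 0.0
        for _ in range(8):
            g = random_digraph(rng, n_max=25, n_min=10)
            At = row_normalize(g)
            inst = random_instance(rng, g, 2, 2)
            cfg = LearnConfig(lam=1.0, b=0.05, inner_eps=1e-13,
                              inner_max_iter=100000, solver_eps=1e-11)
            c = rng.uniform(0.05, 0.9, g.n)
            g_an = gradient_F(c, inst, cfg, At)
            h = 1e-6
            g_fd = np.empty(g.n)
            for i in range(g.n):
                cp, cm = c.copy(), c.copy()
                cp[i] += h
                cm[i] -= h
                g_fd[i] = (cost_F(cp, inst, cfg, At)
                           - cost_F(cm, inst, cfg, At)) / (2 * h)
            worst = max(worst, np.abs(g_an - g_fd).max()
                        / max(1e-8, np.abs(g_an).max()))
        assert worst < 1e-4

    def test_per_score_derivative_matches_finite_differences(self, rng):
        g = random_digraph(rng, n_max=10, n_min=8)
        At = row_normalize(g)
        q = seed_vector(g.n, 0)
        c = rng.uniform(0.1, 0.8, g.n)
        M = dense_resolvent(At, q, c)
        x = 3
        grad = grad_score_dense(M, x, 0, At, q)
        h = 1e-6
        fd = np.empty(g.n)
        for i in range(g.n):
            cp, cm = c.copy(), c.copy()
            cp[i] += h
            cm[i] -= h
            fd[i] = (rwer_closed_form(At, q, cp).r[x]
                     - rwer_closed_form(At, q, cm).r[x]) / (2 * h)
        assert np.abs(grad - fd).max() < 1e-6

    def test_pairwise_assembly_identity(self, rng):
        # summing per-score derivatives with loss weights over all pairs
        # reproduces the assembled (non-regularizer) gradient term
        g = random_digraph(rng, n_max=15, n_min=10)
        At = row_normalize(g)
        inst = random_instance(rng, g, 2, 2)
        cfg = LearnConfig(lam=0.0, b=0.05, inner_eps=1e-13,
                          inner_max_iter=100000, solver_eps=1e-12)
        c = rng.uniform(0.1, 0.8, g.n)
        q = seed_vector(g.n, inst.seed)
        M = dense_resolvent(At, q, c)
        r = M[:, inst.seed]
        assembled = gradient_F(c, inst, cfg, At)
        longhand = np.zeros(g.n)
        for x in inst.positives:
            for y in inst.negatives:
                w = loss_h_prime(r[y] - r[x], cfg.b)
                longhand += w * (grad_score_dense(M, y, inst.seed, At, q)
                                 - grad_score_dense(M, x, inst.seed, At, q))
        assert np.abs(assembled - longhand).max() < 1e-8

    def test_unreachable_node_has_zero_score_derivative(self):
        import scipy.sparse as sp

        from surewalk.graph_io import Graph

        # node 4 is isolated from the component of the seed and of x
        a = np.zeros((5, 5))
        for u, v in ((0, 1), (1, 2), (2, 3)):
            a[u, v] = a[v, u] = 1.0
        a[4, 4] = 1.0
        At = row_normalize(Graph(adjacency=sp.csr_matrix(a)))
        q = seed_vector(5, 0)
        M = dense_resolvent(At, q, np.full(5, 0.2))
        grad = grad_score_dense(M, 3, 0, At, q)
        assert abs(grad[4]) < 1e-12


class TestLearnRestart:
    @pytest.fixture
    def sbm_setup(self):
        scn = generate_sbm(30, 30, 0.2, 0.05, rng_seed=5)
        for query in range(60):
            try:
                ri = make_ranking_instance(scn, query, min_degree=5)
                return scn, ri
            except Exception:
                continue
        raise RuntimeError("no valid query in fixture scenario")

    def test_huge_lambda_pins_c_to_origin(self, sbm_setup):
        scn, ri = sbm_setup
        cfg = LearnConfig(lam=1e6, origin=0.3, eta=1e-7, max_outer=300,
                          rng_seed=0)
        res = learn_restart(scn.graph, ri.instance, cfg)
        assert np.abs(res.c - 0.3).max() < 1e-3

    def test_cost_decreases(self, sbm_setup):
        scn, ri = sbm_setup
        res = learn_restart(scn.graph, ri.instance,
                            LearnConfig(rng_seed=1, max_outer=40))
        assert res.cost_trace[-1] < res.cost_trace[0]

    def test_trace_deterministic_per_seed(self, sbm_setup):
        scn, ri = sbm_setup
        cfg = LearnConfig(rng_seed=7, max_outer=15)
        t1 = learn_restart(scn.graph, ri.instance, cfg).cost_trace
        t2 = learn_restart(scn.graph, ri.instance, cfg).cost_trace
        assert t1 == t2

    def test_c_stays_in_clamp_range(self, sbm_setup):
        scn, ri = sbm_setup
        cfg = LearnConfig(rng_seed=2, max_outer=30, c_min=0.01, c_max=0.9)
        res = learn_restart(scn.graph, ri.instance, cfg)
        assert res.c.min() >= 0.01 and res.c.max() <= 0.9

    def test_empty_labels_rejected(self, two_node_cycle):
        g, _ = two_node_cycle
        inst = TrainingInstance(seed=0, positives=(), negatives=(1,))
        with pytest.raises(ValueError):
            learn_restart(g, inst)

    def test_restart_vector_roundtrip(self, tmp_path, rng):
        c = rng.uniform(0.05, 0.9, 12)
        path = tmp_path / "c.tsv"
        write_restart_vector(c, path)
        assert np.allclose(read_restart_vector(path, 12), c)

    def test_missing_node_in_restart_file(self, tmp_path):
        path = tmp_path / "c.tsv"
        path.write_text("0\t0.1\n")
        from surewalk.graph_io import GraphFormatError

        with pytest.raises(GraphFormatError, match="node 1"):
            read_restart_vector(path, 2)
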