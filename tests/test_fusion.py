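import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from lncfuse import (
    FitConfig,
    RankConfig,
    SyntheticConfig,
    fit,
    generate,
    init_factors,
    objective,
    reconstruct,
    residual,
    save_model,
    update_factors,
    update_weights,
)
from lncfuse.fusion import all_residuals
from lncfuse.relations import EntityCatalog, RelationMatrix, build_graph

from conftest import random_tiny_graph

ALPHA = 1e5


def brute_force_residual(R, Gi, S, Gj):
    total = 0.0
    for a in range(R.shape[0]):
        for b in range(R.shape[1]):
            pred = 0.0
            for p in range(Gi.shape[1]):
                for q in range(Gj.shape[1]):
                    pred += Gi[a, p] * S[p, q] * Gj[b, q]
            total += (R[a, b] - pred) ** 2
    return total


class TestResidual:
    def test_perfect_reconstruction_is_zero(self):
        rng = np.random.default_rng(0)
        Gi, S, Gj = rng.random((4, 2)), rng.random((2, 3)), rng.random((5, 3))
        assert residual(Gi @ S @ Gj.T, Gi, S, Gj) == pytest.approx(0.0, abs=1e-20)

    def test_all_ones_against_zero_core_counts_cells(self):
        R = np.ones((4, 4))
        assert residual(R, np.eye(4), np.zeros((4, 4)), np.eye(4)) == 16.0

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(3)
        R = rng.random((6, 5))
        Gi, S, Gj = rng.random((6, 2)), rng.standard_normal((2, 3)), rng.random((5, 3))
        assert residual(R, Gi, S, Gj) == pytest.approx(
            brute_force_residual(R, Gi, S, Gj), rel=1e-10
        )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="conformable"):
            residual(np.ones((3, 3)), np.ones((3, 2)), np.ones((2, 2)), np.ones((4, 2)))


class TestObjective:
    def test_zero_residuals_uniform_weights_closed_form(self):
        # seven perfectly reconstructed blocks at weight 1/7 leave only the
        # complexity penalty: alpha * 7 * (1/7)^2
        rng = np.random.default_rng(1)
        types = [f"t{i}" for i in range(8)]
        cats, rels, G, S = {}, {}, {}, {}
        cats["t0"] = EntityCatalog("t0", ("x0", "x1"))
        G["t0"] = rng.random((2, 2))
        for i in range(1, 8):
            cats[types[i]] = EntityCatalog(types[i], (f"y{i}0", f"y{i}1", f"y{i}2"))
            G[types[i]] = rng.random((3, 2))
            core = rng.random((2, 2))
            prod = G["t0"] @ core @ G[types[i]].T  # strictly positive
            scale = prod.max()
            S[("t0", types[i])] = core / scale
            rels[("t0", types[i])] = RelationMatrix("t0", types[i], prod / scale)
        graph = build_graph(cats, rels, ("t0", "t1"))
        from lncfuse.fusion import FactorSet

        factors = FactorSet(G, S)
        w = {k: 1.0 / 7 for k in rels}
        assert objective(graph, factors, w, ALPHA) == pytest.approx(ALPHA / 7, rel=1e-8)

    def test_matches_term_by_term_summation(self):
        graph = random_tiny_graph(5)
        ranks = RankConfig({t: 2 for t in graph.catalogs})
        factors = init_factors(graph, ranks)
        rng = np.random.default_rng(5)
        raw = rng.random(len(graph.relations))
        w = {k: v / raw.sum() for k, v in zip(sorted(graph.relations), raw)}
        expected = ALPHA * sum(v * v for v in w.values())
        for key, rel in graph.relations.items():
            expected += w[key] * brute_force_residual(
                rel.values, factors.G[key[0]], factors.S[key], factors.G[key[1]]
            )
        assert objective(graph, factors, w, ALPHA) == pytest.approx(expected, rel=1e-10)


def waterfill_oracle(h, alpha):
    """Scalar root-finder solution of sum(max(gamma - H, 0)) = 2*alpha."""
    f = lambda g: np.sum(np.maximum(g - h, 0.0)) - 2.0 * alpha
    gamma = brentq(f, np.min(h), np.max(h) + 2.0 * alpha + 1.0, xtol=1e-12)
    return np.maximum(gamma - h, 0.0) / (2.0 * alpha)


class TestUpdateWeights:
    def test_equal_residuals_give_uniform_weights(self):
        H = {("a", str(i)): 3.7 for i in range(5)}
        wv = update_weights(H, ALPHA)
        for v in wv.w.values():
            assert v == pytest.approx(0.2, abs=1e-12)

    def test_distant_residual_dropped_entirely(self):
        # H = (0, 4*alpha): the multiplier 2*alpha leaves the far block inactive
        wv = update_weights({("a", "b"): 0.0, ("a", "c"): 4.0 * ALPHA}, ALPHA)
        assert wv.w[("a", "b")] == pytest.approx(1.0, abs=1e-12)
        assert wv.w[("a", "c")] == 0.0
        assert wv.gamma == pytest.approx(2.0 * ALPHA)

    def test_empty_relation_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            update_weights({}, ALPHA)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0.0, 1e7, allow_nan=False), min_size=1, max_size=12),
        st.sampled_from([1.0, 10.0, 1e3, 1e5]),
    )
    def test_simplex_and_oracle_agreement(self, h_list, alpha):
        H = {("a", str(i)): h for i, h in enumerate(h_list)}
        wv = update_weights(H, alpha)
        w = np.array([wv.w[("a", str(i))] for i in range(len(h_list))])
        assert w.min() >= 0.0
        assert abs(w.sum() - 1.0) <= 1e-12
        expected = waterfill_oracle(np.array(h_list), alpha)
        np.testing.assert_allclose(w, expected, atol=1e-9)


class TestInitFactors:
    def test_rank_one_block_reconstructed_exactly(self):
        cats = {
            "a": EntityCatalog("a", tuple(f"a{i}" for i in range(4))),
            "b": EntityCatalog("b", tuple(f"b{i}" for i in range(3))),
        }
        rel = RelationMatrix("a", "b", np.ones((4, 3)))
        graph = build_graph(cats, [rel], ("a", "b"))
        factors = init_factors(graph, RankConfig({"a": 1, "b": 1}))
        assert residual(
            rel.values, factors.G["a"], factors.S[("a", "b")], factors.G["b"]
        ) == pytest.approx(0.0, abs=1e-20)

    def test_same_seed_bit_identical(self, default_graph, default_ranks):
        graph, _ = default_graph
        f1 = init_factors(graph, default_ranks, seed=7)
        f2 = init_factors(graph, default_ranks, seed=7)
        for typ in f1.G:
            np.testing.assert_array_equal(f1.G[typ], f2.G[typ])
        for key in f1.S:
            np.testing.assert_array_equal(f1.S[key], f2.S[key])

    def test_planted_rank_three_block_recovered_at_true_rank(self):
        # the abs-SVD start cannot itself be exact (absolute values of
        # mixed-sign singular vectors leave the data column space) but must
        # put the solver close enough that the fit at the true rank reaches
        # the noiseless optimum
        rng = np.random.default_rng(2)
        U, V = rng.random((12, 3)), rng.random((9, 3))
        R = U @ V.T
        R = R / R.max()
        cats = {
            "a": EntityCatalog("a", tuple(f"a{i}" for i in range(12))),
            "b": EntityCatalog("b", tuple(f"b{i}" for i in range(9))),
        }
        graph = build_graph(cats, [RelationMatrix("a", "b", R)], ("a", "b"))
        ranks = RankConfig({"a": 3, "b": 3})
        factors = init_factors(graph, ranks)
        norm = np.sum(R * R)
        init_res = residual(R, factors.G["a"], factors.S[("a", "b")], factors.G["b"])
        assert init_res <= 0.05 * norm
        model = fit(graph, ranks, FitConfig(tol=1e-12, max_iter=500))
        fitted = residual(
            R, model.factors.G["a"], model.factors.S[("a", "b")], model.factors.G["b"]
        )
        assert fitted <= 1e-6 * norm

    def test_rank_above_axis_size_clamped_with_warning(self, small_graph):
        graph, _ = small_graph
        ranks = RankConfig({t: 3 for t in graph.catalogs}).with_rank("cancer", 50)
        with pytest.warns(UserWarning, match="clamped"):
            resolved = ranks.resolved(graph)
        assert resolved["cancer"] == 3

    def test_nonpositive_rank_rejected(self, small_graph):
        graph, _ = small_graph
        ranks = RankConfig({t: 3 for t in graph.catalogs}).with_rank("gene", 0)
        with pytest.raises(ValueError, match=">= 1"):
            ranks.resolved(graph)


class TestUpdateFactors:
    def test_zero_graph_reaches_penalty_floor(self):
        cats = {
            "a": EntityCatalog("a", tuple(f"a{i}" for i in range(5))),
            "b": EntityCatalog("b", tuple(f"b{i}" for i in range(4))),
            "c": EntityCatalog("c", tuple(f"c{i}" for i in range(3))),
        }
        rels = [
            RelationMatrix("a", "b", np.zeros((5, 4))),
            RelationMatrix("a", "c", np.zeros((5, 3))),
        ]
        graph = build_graph(cats, rels, ("a", "b"))
        ranks = RankConfig({"a": 2, "b": 2, "c": 2})
        model = fit(graph, ranks, FitConfig(max_iter=5))
        for S in model.factors.S.values():
            np.testing.assert_allclose(S, 0.0, atol=1e-8)
        w2 = sum(v * v for v in model.weights.w.values())
        assert model.objective_trace[-1] == pytest.approx(ALPHA * w2, rel=1e-10)

    def test_objective_never_increases_over_fifty_sweeps(self):
        graph = random_tiny_graph(9, sizes=(8, 7, 6))
        ranks = RankConfig({t: 2 for t in graph.catalogs})
        cfg = FitConfig(max_iter=1)
        factors = init_factors(graph, ranks)
        w = {k: 1.0 / len(graph.relations) for k in graph.relations}
        prev = objective(graph, factors, w, cfg.alpha)
        for _ in range(50):
            factors = update_factors(factors, graph, w, cfg)
            cur = objective(graph, factors, w, cfg.alpha)
            assert cur <= prev * (1 + 1e-12) + 1e-12
            prev = cur

    def test_factors_stay_nonnegative(self):
        graph = random_tiny_graph(4)
        ranks = RankConfig({t: 2 for t in graph.catalogs})
        cfg = FitConfig()
        factors = init_factors(graph, ranks)
        w = {k: 1.0 / len(graph.relations) for k in graph.relations}
        for _ in range(5):
            factors = update_factors(factors, graph, w, cfg)
            for G in factors.G.values():
                assert G.min() > 0.0


class TestFit:
    def test_same_seed_identical_trace(self, small_graph):
        graph, _ = small_graph
        ranks = RankConfig({t: 3 for t in graph.catalogs})
        t1 = fit(graph, ranks, FitConfig(seed=3, max_iter=20)).objective_trace
        t2 = fit(graph, ranks, FitConfig(seed=3, max_iter=20)).objective_trace
        assert t1 == t2

    def test_trace_monotone_within_slack(self, small_graph):
        graph, _ = small_graph
        ranks = RankConfig({t: 3 for t in graph.catalogs})
        trace = np.array(fit(graph, ranks, FitConfig(max_iter=60, tol=1e-14)).objective_trace)
        rel_inc = (trace[1:] - trace[:-1]) / np.maximum(np.abs(trace[:-1]), 1e-300)
        assert rel_inc.max() <= 1e-8

    def test_weights_on_simplex_after_fit(self, small_graph):
        graph, _ = small_graph
        ranks = RankConfig({t: 3 for t in graph.catalogs})
        model = fit(graph, ranks, FitConfig(max_iter=15))
        w = np.array(list(model.weights.w.values()))
        assert abs(w.sum() - 1.0) <= 1e-12 and w.min() >= 0.0

    def test_noiseless_planted_graph_recovered_at_true_ranks(self):
        cfg = SyntheticConfig(seed=7, binarize=False, holdout_fraction=0.0)
        graph, _ = generate(cfg)
        ranks = RankConfig(dict(cfg.ranks))
        factors0 = init_factors(graph, ranks)
        H0 = all_residuals(graph, factors0)
        m = len(graph.relations)
        initial = sum(H0[k] / m for k in H0)
        model = fit(graph, ranks, FitConfig(seed=7, tol=1e-9, max_iter=200))
        final = sum(model.weights.w[k] * model.weights.H[k] for k in model.weights.H)
        assert final <= 1e-4 * initial


class TestReconstruct:
    def test_identity_factors_return_core(self):
        cats = {
            "a": EntityCatalog("a", ("a0", "a1")),
            "b": EntityCatalog("b", ("b0", "b1")),
        }
        rel = RelationMatrix("a", "b", np.eye(2))
        graph = build_graph(cats, [rel], ("a", "b"))
        model = fit(graph, RankConfig({"a": 2, "b": 2}), FitConfig(max_iter=1))
        model.factors.G["a"] = np.eye(2)
        model.factors.G["b"] = np.eye(2)
        S = np.array([[0.3, 0.1], [0.2, 0.9]])
        model.factors.S[("a", "b")] = S
        np.testing.assert_array_equal(reconstruct(model, ("a", "b")), S)

    def test_matches_naive_triple_product(self, small_graph):
        graph, _ = small_graph
        ranks = RankConfig({t: 3 for t in graph.catalogs})
        model = fit(graph, ranks, FitConfig(max_iter=3))
        key = ("lncRNA", "cancer")
        Gi, S, Gj = model.factors.G["lncRNA"], model.factors.S[key], model.factors.G["cancer"]
        naive = np.zeros((Gi.shape[0], Gj.shape[0]))
        for a in range(Gi.shape[0]):
            for b in range(Gj.shape[0]):
                naive[a, b] = Gi[a] @ S @ Gj[b]
        np.testing.assert_allclose(reconstruct(model, key), naive, atol=1e-10)
        assert reconstruct(model, key).shape == (Gi.shape[0], Gj.shape[0])

    def test_unknown_key_rejected(self, small_graph):
        graph, _ = small_graph
        ranks = RankConfig({t: 3 for t in graph.catalogs})
        model = fit(graph, ranks, FitConfig(max_iter=1))
        with pytest.raises(KeyError):
            reconstruct(model, ("lncRNA", "nosuch"))


def test_save_model_writes_plain_text_archive(tmp_path, small_graph):
    graph, _ = small_graph
    ranks = RankConfig({t: 3 for t in graph.catalogs})
    model = fit(graph, ranks, FitConfig(max_iter=5))
    save_model(model, tmp_path)
    assert (tmp_path / "G_lncRNA.tsv").exists()
    assert (tmp_path / "S_lncRNA__cancer.tsv").exists()
    assert (tmp_path / "objective_trace.tsv").exists()
    import pandas as pd

    weights = pd.read_csv(tmp_path / "weights.tsv", sep="\t")
    assert weights.w.sum() == pytest.approx(1.0, abs=1e-9)
    G = np.loadtxt(tmp_path / "G_lncRNA.tsv")
    np.testing.assert_allclose(G, model.factors.G["lncRNA"])
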