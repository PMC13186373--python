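import numpy as np
import pytest

from hgdti import autodiff as ad
from hgdti.autodiff import Tensor
from hgdti.model import (
    INDIRECT_BRANCHES,
    RGCN_RELATIONS,
    ModelConfig,
    build_graph,
    fc_embed,
    feature_dims,
    forward,
    forward_network,
    hetero_gcn,
    homo_gcn,
    init_features,
    init_params,
    interaction_scores,
    load_checkpoint,
    mlp_aggregate,
    parameter_census,
    rgcn_input,
    rgcn_layer,
    rgcn_relation_outputs,
    save_checkpoint,
)
from hgdti.network import AssociationMatrix, EntityCatalog, HeteroNetwork, normalize_adjacency
import scipy.sparse as sp

from conftest import random_network

RTOL = 1e-5


def small_config(**kw):
    defaults = dict(embed_dim=6, mlp_dims=(6, 5, 4), gcn_layers=2, rgcn_layers=2)
    defaults.update(kw)
    return ModelConfig(**defaults)


class TestInitFeatures:
    def test_one_hot_identity(self, tiny_network):
        cfg = small_config(feature_scheme="one_hot")
        feats = init_features(tiny_network, cfg)
        np.testing.assert_array_equal(feats["drug"], np.eye(4))

    def test_assoc_rows_width(self, tiny_network):
        cfg = small_config()
        feats = init_features(tiny_network, cfg)
        total = sum(tiny_network.n(t) for t in ("drug", "disease", "gene", "protein"))
        assert feats["drug"].shape == (4, total)
        assert feats["gene"].shape == (5, 4 + 3 + 5)
        assert feature_dims(tiny_network, cfg)["drug"] == total

    def test_isolated_drug_has_zero_vector(self):
        net = random_network(3, 2, 2, 2, seed=0, density=0.0)
        feats = init_features(net, small_config())
        np.testing.assert_array_equal(feats["drug"], np.zeros_like(feats["drug"]))

    def test_variant_drops_columns(self, tiny_network):
        cfg = small_config(variant="no_gene")
        feats = init_features(tiny_network, cfg)
        total = sum(tiny_network.n(t) for t in ("drug", "disease", "protein"))
        assert feats["drug"].shape[1] == total
        assert "gene" not in feats


class TestHomoGcn:
    def test_zero_weights_zero_output(self, tiny_network):
        adj = normalize_adjacency(tiny_network.relations["drdr"]).values
        v = Tensor(np.random.default_rng(0).random((4, 3)))
        ws = [Tensor(np.zeros((3, 2))), Tensor(np.zeros((2, 2)))]
        out = homo_gcn(v, adj, ws)
        np.testing.assert_array_equal(out.value, np.zeros((4, 2)))

    def test_isolated_node_identity_weights(self):
        # single node, no edges: normalized adjacency is [[1]], ReLU no-op on
        # non-negative input, identity weights -> output equals input
        adj = sp.csr_matrix(np.array([[1.0]]))
        v = Tensor(np.array([[0.3, 0.7]]))
        out = homo_gcn(v, adj, [Tensor(np.eye(2))])
        np.testing.assert_allclose(out.value, v.value)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_per_node_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, f, d = 6, 4, 3
        upper = np.triu(rng.random((n, n)) < 0.4, k=1)
        a = (upper + upper.T).astype(float)
        m = AssociationMatrix("drug", "drug", sp.csr_matrix(a))
        adj = normalize_adjacency(m).values
        v = rng.normal(size=(n, f))
        w1, w2 = rng.normal(size=(f, d)), rng.normal(size=(d, d))
        out = homo_gcn(Tensor(v), adj, [Tensor(w1), Tensor(w2)]).value

        # oracle: explicit message passing per node, no sparse algebra
        a_tilde = a + np.eye(n)
        deg = a_tilde.sum(axis=1)
        x = v
        for w in (w1, w2):
            nxt = np.zeros((n, w.shape[1]))
            for i in range(n):
                msg = np.zeros(x.shape[1])
                for j in range(n):
                    if a_tilde[i, j]:
                        msg += x[j] / np.sqrt(deg[i] * deg[j])
                nxt[i] = np.maximum(msg @ w, 0)
            x = nxt
        np.testing.assert_allclose(out, x, rtol=RTOL, atol=1e-10)


class TestFcEmbed:
    def test_zero_params(self):
        out = fc_embed(Tensor(np.ones((2, 3))), Tensor(np.zeros((3, 2))), Tensor(np.zeros(2)))
        np.testing.assert_array_equal(out.value, np.zeros((2, 2)))

    def test_identity(self):
        v = np.array([[0.5, 1.5]])
        out = fc_embed(Tensor(v), Tensor(np.eye(2)), Tensor(np.zeros(2)))
        np.testing.assert_allclose(out.value, v)

    def test_hand_case(self):
        # column-convention W = [[1, -1], [0, 1]] applied to (3, 1):
        # (3*1 + 1*(-1), 3*0 + 1*1) = (2, 1); row convention uses W^T
        w_col = np.array([[1.0, -1.0], [0.0, 1.0]])
        out = fc_embed(Tensor(np.array([[3.0, 1.0]])), Tensor(w_col.T), Tensor(np.zeros(2)))
        np.testing.assert_allclose(out.value, [[2.0, 1.0]])


class TestHeteroGcn:
    def test_empty_association_reduces_to_self_propagation(self):
        m = AssociationMatrix("drug", "disease", sp.csr_matrix((2, 2)))
        from hgdti.network import bipartite_block

        block = bipartite_block(m).values
        rng = np.random.default_rng(0)
        x, y = rng.random((2, 3)), rng.random((2, 3))
        w = rng.normal(size=(3, 3))
        xo, yo = hetero_gcn(Tensor(x), Tensor(y), block, [Tensor(w)])
        np.testing.assert_allclose(xo.value, np.maximum(x @ w, 0), rtol=RTOL)
        np.testing.assert_allclose(yo.value, np.maximum(y @ w, 0), rtol=RTOL)

    def test_single_link_mixes_symmetrically(self):
        m = AssociationMatrix("drug", "disease", sp.csr_matrix(np.array([[1.0]])))
        from hgdti.network import bipartite_block

        block = bipartite_block(m).values
        x, y = np.array([[1.0, 2.0]]), np.array([[3.0, 4.0]])
        w = np.eye(2)
        xo, yo = hetero_gcn(Tensor(x), Tensor(y), block, [Tensor(w)])
        np.testing.assert_allclose(xo.value, yo.value)
        np.testing.assert_allclose(xo.value, 0.5 * (x + y))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_stacked_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_x, n_y, d = 4, 3, 3
        a = (rng.random((n_x, n_y)) < 0.5).astype(float)
        m = AssociationMatrix("drug", "disease", sp.csr_matrix(a))
        from hgdti.network import bipartite_block

        block = bipartite_block(m).values
        x, y = rng.normal(size=(n_x, d)), rng.normal(size=(n_y, d))
        w1, w2 = rng.normal(size=(d, d)), rng.normal(size=(d, d))
        xo, yo = hetero_gcn(Tensor(x), Tensor(y), block, [Tensor(w1), Tensor(w2)])

        # oracle: dense assembly of the stacked system
        square = np.zeros((n_x + n_y, n_x + n_y))
        square[:n_x, n_x:] = a
        square[n_x:, :n_x] = a.T
        a_tilde = square + np.eye(n_x + n_y)
        dinv = np.diag(1 / np.sqrt(a_tilde.sum(axis=1)))
        norm = dinv @ a_tilde @ dinv
        h = np.vstack([x, y])
        for w in (w1, w2):
            h = np.maximum(norm @ h @ w, 0)
        np.testing.assert_allclose(xo.value, h[:n_x], rtol=RTOL, atol=1e-10)
        np.testing.assert_allclose(yo.value, h[n_x:], rtol=RTOL, atol=1e-10)


class TestRgcn:
    def make_graph(self, seed=0):
        net = random_network(4, 3, 5, 2, seed=seed)
        cfg = small_config()
        return net, cfg, build_graph(net, cfg)

    def test_isolated_node_keeps_self_term_only(self):
        net = random_network(3, 2, 2, 2, seed=0, density=0.0)
        cfg = small_config()
        graph = build_graph(net, cfg)
        rng = np.random.default_rng(1)
        d = 3
        h = {t: Tensor(rng.random((net.n(t), d))) for t in cfg.active_types()}
        ws = {r: Tensor(rng.normal(size=(d, d))) for r in cfg.active_rgcn_relations()}
        w_self = Tensor(rng.normal(size=(d, d)))
        out = rgcn_layer(h, graph, ws, w_self, cfg.active_rgcn_relations())
        for t in h:
            np.testing.assert_allclose(
                out[t].value, np.maximum(h[t].value @ w_self.value, 0), rtol=RTOL
            )

    def test_single_neighbor_single_relation(self):
        # drug 0 - disease 0 is the only edge; zero self weight ->
        # sigma(W_r h_j) with a single-message mean
        catalogs = {
            "drug": EntityCatalog("drug", ("dr0", "dr1")),
            "disease": EntityCatalog("disease", ("di0",)),
            "gene": EntityCatalog("gene", ("g0", "g1")),
            "protein": EntityCatalog("protein", ("p0", "p1")),
        }
        from hgdti.network import RELATION_TYPES, empty_relation

        relations = {name: empty_relation(name, catalogs) for name in RELATION_TYPES}
        relations["drdi"] = AssociationMatrix(
            "drug", "disease", sp.csr_matrix(np.array([[1.0], [0.0]]))
        )
        net = HeteroNetwork(catalogs, relations)
        cfg = small_config()
        graph = build_graph(net, cfg)
        rng = np.random.default_rng(2)
        d = 3
        h = {t: Tensor(rng.random((net.n(t), d))) for t in cfg.active_types()}
        ws = {r: Tensor(rng.normal(size=(d, d))) for r in cfg.active_rgcn_relations()}
        zero_self = Tensor(np.zeros((d, d)))
        out = rgcn_layer(h, graph, ws, zero_self, cfg.active_rgcn_relations())
        expected = np.maximum(h["disease"].value[0] @ ws["drdi"].value, 0)
        np.testing.assert_allclose(out["drug"].value[0], expected, rtol=RTOL)
        np.testing.assert_allclose(out["drug"].value[1], 0)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_double_loop_oracle(self, seed):
        net, cfg, graph = self.make_graph(seed)
        rng = np.random.default_rng(seed + 10)
        d = 3
        h = {t: Tensor(rng.normal(size=(net.n(t), d))) for t in cfg.active_types()}
        ws = {r: Tensor(rng.normal(size=(d, d))) for r in cfg.active_rgcn_relations()}
        w_self = Tensor(rng.normal(size=(d, d)))
        out = rgcn_layer(h, graph, ws, w_self, cfg.active_rgcn_relations())

        # oracle: per node, per relation, explicit neighbor enumeration
        for t in cfg.active_types():
            n_t = net.n(t)
            expected = np.zeros((n_t, d))
            for i in range(n_t):
                acc = h[t].value[i] @ w_self.value
                for rel in cfg.active_rgcn_relations():
                    tgt, src, base, transposed = RGCN_RELATIONS[rel]
                    if tgt != t:
                        continue
                    a = net.relations[base].toarray()
                    if transposed:
                        a = a.T
                    nbrs = np.flatnonzero(a[i])
                    if nbrs.size == 0:
                        continue
                    mean_msg = h[src].value[nbrs].mean(axis=0)
                    acc = acc + mean_msg @ ws[rel].value
                expected[i] = np.maximum(acc, 0)
            np.testing.assert_allclose(out[t].value, expected, rtol=RTOL, atol=1e-10)

    def test_relation_outputs_match_oracle(self):
        net, cfg, graph = self.make_graph(1)
        rng = np.random.default_rng(3)
        d = 3
        h = {t: Tensor(rng.normal(size=(net.n(t), d))) for t in cfg.active_types()}
        outputs = cfg.active_relation_outputs()
        hetero_rels = {r for rels in outputs.values() for r in rels}
        ws = {r: Tensor(rng.normal(size=(d, d))) for r in hetero_rels}
        w_self = Tensor(rng.normal(size=(d, d)))
        out = rgcn_relation_outputs(h, graph, ws, w_self, outputs)
        assert set(out) == {
            "drdi", "drg", "drp", "didr", "dig", "dip", "gdr", "gdi", "pdr", "pdi",
        }
        for rel in out:
            tgt, src, base, transposed = RGCN_RELATIONS[rel]
            a = net.relations[base].toarray()
            if transposed:
                a = a.T
            n_t = net.n(tgt)
            expected = np.zeros((n_t, d))
            for i in range(n_t):
                nbrs = np.flatnonzero(a[i])
                msg = h[src].value[nbrs].mean(axis=0) @ ws[rel].value if nbrs.size else 0
                expected[i] = np.maximum(msg + h[tgt].value[i] @ w_self.value, 0)
            np.testing.assert_allclose(out[rel].value, expected, rtol=RTOL, atol=1e-10)


class TestRgcnInput:
    def branches(self, values):
        b = {k: None for k in (
            "dr1", "dr2", "dr3", "dr4", "dr5", "di1", "di2", "di3", "di4", "di5",
            "g1", "g2", "g3", "p1", "p2", "p3")}
        b.update({k: Tensor(np.asarray(v, dtype=float)) for k, v in values.items()})
        return b

    def filled(self, rows=(1, 2)):
        arr = np.array([rows], dtype=float)
        return self.branches({
            "dr1": arr, "dr2": arr, "dr3": arr,
            "di1": arr, "di2": arr, "di3": arr,
            "g2": arr, "g3": arr, "p2": arr, "p3": arr,
        })

    def test_all_zero(self):
        z = np.zeros((2, 3))
        b = self.branches({k: z for k in (
            "dr1", "dr2", "dr3", "di1", "di2", "di3", "g2", "g3", "p2", "p3")})
        out = rgcn_input(b, small_config())
        for t in out:
            np.testing.assert_array_equal(out[t].value, z)

    def test_elementwise_sum(self):
        b = self.filled()
        b["dr1"] = Tensor(np.array([[1.0, 2.0]]))
        b["dr2"] = Tensor(np.array([[3.0, -1.0]]))
        b["dr3"] = Tensor(np.array([[0.0, 0.0]]))
        out = rgcn_input(b, small_config())
        np.testing.assert_allclose(out["drug"].value, [[4.0, 1.0]])

    def test_no_indirect_uses_g1(self):
        b = self.filled()
        b["g2"] = b["g3"] = None
        b["g1"] = Tensor(np.array([[9.0, 9.0]]))
        b["p2"] = b["p3"] = None
        b["p1"] = Tensor(np.array([[7.0, 7.0]]))
        out = rgcn_input(b, small_config(variant="no_indirect"))
        np.testing.assert_allclose(out["gene"].value, [[9.0, 9.0]])
        np.testing.assert_allclose(out["protein"].value, [[7.0, 7.0]])

    def test_indirect_in_rgcn_flag(self):
        b = self.filled()
        b["dr4"] = Tensor(np.array([[10.0, 0.0]]))
        b["dr5"] = Tensor(np.array([[0.0, 10.0]]))
        base = rgcn_input(b, small_config())["drug"].value
        with_flag = rgcn_input(b, small_config(indirect_in_rgcn=True))["drug"].value
        np.testing.assert_allclose(with_flag - base, [[10.0, 10.0]])


class TestMlpAggregate:
    def test_identity_layers_clip_at_zero(self):
        cfg = ModelConfig(embed_dim=2, mlp_dims=(2, 2, 2), gcn_layers=1, rgcn_layers=1)
        rel = {
            "drdi": Tensor(np.array([[1.0, -3.0]])),
            "drg": Tensor(np.array([[2.0, 1.0]])),
            "drp": Tensor(np.array([[0.5, 0.0]])),
            "didr": Tensor(np.array([[1.0, 1.0]])),
            "dig": Tensor(np.array([[0.0, 0.0]])),
            "dip": Tensor(np.array([[0.0, 0.0]])),
            "gdr": Tensor(np.array([[1.0, -1.0]])),
            "gdi": Tensor(np.array([[1.0, 1.0]])),
            "pdr": Tensor(np.array([[2.0, 2.0]])),
            "pdi": Tensor(np.array([[0.0, -1.0]])),
        }
        params = {}
        for t in ("drug", "disease", "gene", "protein"):
            for i in range(3):
                params[f"mlp.{t}.{i}.W"] = Tensor(np.eye(2))
                params[f"mlp.{t}.{i}.b"] = Tensor(np.zeros(2))
        out = mlp_aggregate(rel, params, cfg)
        # identity weights + ReLU at every layer = raw sum clipped at zero
        np.testing.assert_allclose(out["drug"].value, [[3.5, 0.0]])
        np.testing.assert_allclose(out["gene"].value, [[2.0, 0.0]])

    def test_zero_everything(self):
        cfg = ModelConfig(embed_dim=2, mlp_dims=(2, 2, 2), gcn_layers=1, rgcn_layers=1)
        rel = {r: Tensor(np.zeros((2, 2))) for r in (
            "drdi", "drg", "drp", "didr", "dig", "dip", "gdr", "gdi", "pdr", "pdi")}
        params = {}
        for t in ("drug", "disease", "gene", "protein"):
            for i in range(3):
                params[f"mlp.{t}.{i}.W"] = Tensor(np.zeros((2, 2)))
                params[f"mlp.{t}.{i}.b"] = Tensor(np.zeros(2))
        out = mlp_aggregate(rel, params, cfg)
        for t in out:
            np.testing.assert_array_equal(out[t].value, np.zeros((2, 2)))


class TestInteractionScores:
    def test_orthogonal_rows(self):
        a = Tensor(np.array([[1.0, 0.0]]))
        b = Tensor(np.array([[0.0, 1.0]]))
        assert interaction_scores(a, b, "dot").value[0, 0] == 0.0

    def test_identical_unit_rows(self):
        a = Tensor(np.array([[1.0, 0.0]]))
        assert interaction_scores(a, a, "dot").value[0, 0] == 1.0
        assert interaction_scores(a, a, "cosine").value[0, 0] == pytest.approx(1.0)

    def test_dot_hand_case(self):
        a = Tensor(np.array([[1.0, 2.0]]))
        b = Tensor(np.array([[3.0, 4.0]]))
        assert interaction_scores(a, b, "dot").value[0, 0] == 11.0

    def test_cosine_zero_vector_scores_zero(self):
        a = Tensor(np.array([[0.0, 0.0]]))
        b = Tensor(np.array([[3.0, 4.0]]))
        assert interaction_scores(a, b, "cosine").value[0, 0] == 0.0

    def test_cosine_is_normalized_dot(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=(3, 4)), rng.normal(size=(2, 4))
        got = interaction_scores(Tensor(a), Tensor(b), "cosine").value
        an = a / np.linalg.norm(a, axis=1, keepdims=True)
        bn = b / np.linalg.norm(b, axis=1, keepdims=True)
        np.testing.assert_allclose(got, an @ bn.T, rtol=RTOL)


def dense_forward_oracle(network, params, config):
    """Monolithic end-to-end re-computation: dense numpy only, no module
    boundaries, no autodiff.  Mirrors the layer wiring from first principles."""

    def norm_adj(a):
        a_tilde = a + np.eye(a.shape[0])
        d = np.diag(1 / np.sqrt(a_tilde.sum(axis=1)))
        return d @ a_tilde @ d

    def block(a):
        n_x, n_y = a.shape
        sq = np.zeros((n_x + n_y, n_x + n_y))
        sq[:n_x, n_x:] = a
        sq[n_x:, :n_x] = a.T
        return norm_adj(sq)

    rel = {k: network.relations[k].toarray() for k in network.relations}
    feats = init_features(network, config)
    active = config.active_types()

    # homogeneous GCN branches
    def gcn(v, adj, prefix):
        x = v
        for l in range(config.gcn_layers):
            x = np.maximum(adj @ x @ params[f"{prefix}.gcn{l}.W"], 0)
        return x

    br = {}
    br["dr1"] = gcn(feats["drug"], norm_adj(rel["drdr"]), "dr1")
    br["di1"] = gcn(feats["disease"], norm_adj(rel["didi"]), "di1")
    for name, t in (("dr2", "drug"), ("di2", "disease"), ("g1", "gene"), ("p1", "protein")):
        if t in active:
            br[name] = np.maximum(feats[t] @ params[f"{name}.fc.W"] + params[f"{name}.fc.b"], 0)

    def hetero(x, y, a, prefix):
        h = np.vstack([x, y])
        nb = block(a)
        for l in range(config.gcn_layers):
            h = np.maximum(nb @ h @ params[f"{prefix}.gcn{l}.W"], 0)
        return h[: x.shape[0]], h[x.shape[0]:]

    br["dr3"], br["di3"] = hetero(br["dr2"], br["di2"], rel["drdi"], "drdi")
    if config.variant != "no_indirect":
        if "gene" in active:
            br["dr4"], br["g2"] = hetero(br["dr2"], br["g1"], rel["drg"], "drg")
            br["di4"], br["g3"] = hetero(br["di2"], br["g1"], rel["dig"], "dig")
        if "protein" in active:
            br["dr5"], br["p2"] = hetero(br["dr2"], br["p1"], rel["drp"], "drp")
            br["di5"], br["p3"] = hetero(br["di2"], br["p1"], rel["dip"], "dip")

    h = {}
    h["drug"] = br["dr1"] + br["dr2"] + br["dr3"]
    h["disease"] = br["di1"] + br["di2"] + br["di3"]
    if config.indirect_in_rgcn and config.variant != "no_indirect":
        for k in ("dr4", "dr5"):
            if k in br:
                h["drug"] = h["drug"] + br[k]
        for k in ("di4", "di5"):
            if k in br:
                h["disease"] = h["disease"] + br[k]
    if "gene" in active:
        h["gene"] = br["g1"] if config.variant == "no_indirect" else br["g2"] + br["g3"]
    if "protein" in active:
        h["protein"] = br["p1"] if config.variant == "no_indirect" else br["p2"] + br["p3"]

    def mean_agg(a):
        deg = a.sum(axis=1, keepdims=True)
        return np.divide(a, deg, out=np.zeros_like(a), where=deg > 0)

    rel_mats = {}
    for name in config.active_rgcn_relations():
        tgt, src, base, transposed = RGCN_RELATIONS[name]
        a = rel[base].T if transposed else rel[base]
        rel_mats[name] = (tgt, src, mean_agg(a))

    for l in range(config.rgcn_layers - 1):
        nxt = {}
        for t in h:
            acc = h[t] @ params[f"rgcn{l}.self.W"]
            for name, (tgt, src, m) in rel_mats.items():
                if tgt == t:
                    acc = acc + m @ h[src] @ params[f"rgcn{l}.{name}.W"]
            nxt[t] = np.maximum(acc, 0)
        h = nxt
    last = config.rgcn_layers - 1
    outputs = config.active_relation_outputs()
    rel_out = {}
    for t, names in outputs.items():
        for name in names:
            tgt, src, m = rel_mats[name]
            rel_out[name] = np.maximum(
                m @ h[src] @ params[f"rgcn{last}.{name}.W"] + h[t] @ params[f"rgcn{last}.self.W"], 0
            )

    final = {}
    for t, names in outputs.items():
        x = sum(rel_out[n] for n in names)
        for i in range(3):
            x = np.maximum(x @ params[f"mlp.{t}.{i}.W"] + params[f"mlp.{t}.{i}.b"], 0)
        final[t] = x

    scores = {}
    for name in config.active_score_relations():
        tgt, src, _, _ = RGCN_RELATIONS[name]
        scores[name] = final[tgt] @ final[src].T
    return scores


class TestForward:
    def test_zero_params_zero_scores(self, tiny_network):
        cfg = small_config()
        params = init_params(tiny_network, cfg, seed=0)
        zeros = {k: np.zeros_like(v) for k, v in params.items()}
        scores = forward_network(tiny_network, zeros, cfg)
        for s in scores.values():
            np.testing.assert_array_equal(s, np.zeros_like(s))

    def test_deterministic(self, tiny_network):
        cfg = small_config()
        params = init_params(tiny_network, cfg, seed=1)
        s1 = forward_network(tiny_network, params, cfg)
        s2 = forward_network(tiny_network, params, cfg)
        for k in s1:
            np.testing.assert_array_equal(s1[k], s2[k])

    @pytest.mark.parametrize("variant", ["full", "no_protein", "no_gene", "no_indirect"])
    def test_matches_monolithic_oracle(self, variant):
        net = random_network(4, 3, 5, 2, seed=7)
        cfg = small_config(variant=variant)
        params = init_params(net, cfg, seed=5)
        got = forward_network(net, params, cfg)
        expected = dense_forward_oracle(net, params, cfg)
        assert set(got) == set(expected)
        for k in got:
            np.testing.assert_allclose(got[k], expected[k], rtol=RTOL, atol=1e-9)

    def test_score_relations_per_variant(self, tiny_network):
        assert small_config().active_score_relations() == ("drdi", "drg", "drp", "dig", "dip")
        assert small_config(variant="no_gene").active_score_relations() == ("drdi", "drp", "dip")
        assert small_config(variant="no_protein").active_score_relations() == ("drdi", "drg", "dig")
        assert small_config(variant="no_indirect").active_score_relations() == (
            "drdi", "drg", "drp", "dig", "dip")

    def test_ablation_containment_no_indirect(self, tiny_network):
        cfg = small_config(variant="no_indirect")
        params = {k: Tensor(v) for k, v in init_params(tiny_network, cfg, seed=0).items()}
        graph = build_graph(tiny_network, cfg)
        feats = init_features(tiny_network, cfg)
        _, inter = forward(graph, feats, params, cfg)
        for b in ("dr4", "dr5", "di4", "di5", "g2", "g3", "p2", "p3"):
            assert inter[b] is None
        assert inter["g1"] is not None and inter["p1"] is not None
        assert not any(k.startswith("drg.gcn") for k in init_params(tiny_network, cfg, 0))

    def test_ablation_containment_no_gene(self, tiny_network):
        cfg = small_config(variant="no_gene")
        params = {k: Tensor(v) for k, v in init_params(tiny_network, cfg, seed=0).items()}
        graph = build_graph(tiny_network, cfg)
        feats = init_features(tiny_network, cfg)
        _, inter = forward(graph, feats, params, cfg)
        for b in ("g1", "g2", "g3", "dr4", "di4"):
            assert inter[b] is None
        assert inter["dr5"] is not None and inter["p2"] is not None

    def test_permutation_equivariance(self):
        net = random_network(5, 4, 3, 2, seed=9)
        cfg = small_config(feature_scheme="one_hot")
        params = init_params(net, cfg, seed=2)
        scores = forward_network(net, params, cfg)

        rng = np.random.default_rng(0)
        p_dr = rng.permutation(5)
        p_di = rng.permutation(4)
        perm_net = _permute_network(net, p_dr, p_di)
        perm_params = dict(params)
        # one-hot features: relabelling entities permutes the rows of every
        # first-layer weight matrix indexed by those entities
        perm_params["dr1.gcn0.W"] = params["dr1.gcn0.W"][p_dr]
        perm_params["dr2.fc.W"] = params["dr2.fc.W"][p_dr]
        perm_params["di1.gcn0.W"] = params["di1.gcn0.W"][p_di]
        perm_params["di2.fc.W"] = params["di2.fc.W"][p_di]
        perm_scores = forward_network(perm_net, perm_params, cfg)
        np.testing.assert_allclose(
            perm_scores["drdi"], scores["drdi"][np.ix_(p_dr, p_di)], rtol=RTOL, atol=1e-9
        )
        np.testing.assert_allclose(
            perm_scores["drg"], scores["drg"][p_dr], rtol=RTOL, atol=1e-9
        )

    def test_parameter_census_matches_init(self, tiny_network):
        for variant in ("full", "no_protein", "no_gene", "no_indirect"):
            cfg = small_config(variant=variant)
            params = init_params(tiny_network, cfg, seed=0)
            total = sum(v.size for v in params.values())
            assert total == parameter_census(tiny_network, cfg), variant

    def test_checkpoint_roundtrip_bit_exact(self, tiny_network, tmp_path):
        cfg = small_config()
        params = init_params(tiny_network, cfg, seed=3)
        path = str(tmp_path / "ckpt.npz")
        save_checkpoint(path, params, cfg, seed=3)
        loaded, cfg2, seed = load_checkpoint(path)
        assert cfg2 == cfg and seed == 3
        s1 = forward_network(tiny_network, params, cfg)
        s2 = forward_network(tiny_network, loaded, cfg2)
        for k in s1:
            np.testing.assert_array_equal(s1[k], s2[k])


def _permute_network(net, p_dr, p_di):
    import scipy.sparse as sp

    catalogs = dict(net.catalogs)
    catalogs["drug"] = EntityCatalog("drug", tuple(net.catalogs["drug"].ids[i] for i in p_dr))
    catalogs["disease"] = EntityCatalog(
        "disease", tuple(net.catalogs["disease"].ids[i] for i in p_di)
    )
    relations = {}
    for name, m in net.relations.items():
        arr = m.toarray()
        if m.type_a == "drug":
            arr = arr[p_dr]
        elif m.type_a == "disease":
            arr = arr[p_di]
        if m.type_b == "drug":
            arr = arr[:, p_dr]
        elif m.type_b == "disease":
            arr = arr[:, p_di]
        relations[name] = AssociationMatrix(m.type_a, m.type_b, sp.csr_matrix(arr))
    return HeteroNetwork(catalogs, relations)


class TestConfigValidation:
    def test_bad_variant(self):
        with pytest.raises(ValueError):
            ModelConfig(variant="bogus")

    def test_bad_mlp_dims(self):
        with pytest.raises(ValueError):
            ModelConfig(mlp_dims=(4, 4))

    def test_bad_scheme(self):
        with pytest.raises(ValueError):
            ModelConfig(feature_scheme="embeddings")
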