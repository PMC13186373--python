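"""Hierarchical heterogeneous graph convolutional model.

The forward pass composes, in order:

1. homogeneous GCN branches on the drug-drug and disease-disease graphs
   (``dr1``, ``di1``);
2. per-entity fully-connected embedding layers (``dr2``, ``di2``, ``g1``,
   ``p1``);
3. a direct heterogeneous GCN on the drug-disease bipartite block
   (``dr3``, ``di3``);
4. four indirect heterogeneous GCNs on the drug-gene, drug-protein,
   disease-gene and disease-protein blocks (``dr4``/``g2``, ``dr5``/``p2``,
   ``di4``/``g3``, ``di5``/``p3``);
5. a relational GCN over the full typed node set whose last layer keeps
   per-relation aggregates (``drdi``, ``drg``, ... ``pdi``);
6. a per-entity three-layer MLP over the summed relation-scoped embeddings;
7. inner-product interaction scores between final embeddings.

Ablation variants (``no_protein``, ``no_gene``, ``no_indirect``) are pure
configuration: they remove entity types or branches from the same code path.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Mapping

import numpy as np
import scipy.sparse as sp

from . import autodiff as ad
from .autodiff import Tensor
from .network import HeteroNetwork, bipartite_block, normalize_adjacency

VARIANTS = ("full", "no_protein", "no_gene", "no_indirect")

#: RGCN directed relation -> (target type, source type, base relation, transposed)
RGCN_RELATIONS: dict[str, tuple[str, str, str, bool]] = {
    "drdr": ("drug", "drug", "drdr", False),
    "didi": ("disease", "disease", "didi", False),
    "gg": ("gene", "gene", "gg", False),
    "pp": ("protein", "protein", "pp", False),
    "drdi": ("drug", "disease", "drdi", False),
    "didr": ("disease", "drug", "drdi", True),
    "drg": ("drug", "gene", "drg", False),
    "gdr": ("gene", "drug", "drg", True),
    "drp": ("drug", "protein", "drp", False),
    "pdr": ("protein", "drug", "drp", True),
    "dig": ("disease", "gene", "dig", False),
    "gdi": ("gene", "disease", "dig", True),
    "dip": ("disease", "protein", "dip", False),
    "pdi": ("protein", "disease", "dip", True),
}

#: the relation-scoped outputs retained by the last RGCN layer, per entity type
RELATION_OUTPUTS: dict[str, tuple[str, ...]] = {
    "drug": ("drdi", "drg", "drp"),
    "disease": ("didr", "dig", "dip"),
    "gene": ("gdr", "gdi"),
    "protein": ("pdr", "pdi"),
}

#: indirect branch name -> (x branch, y branch, base relation)
INDIRECT_BRANCHES: dict[str, tuple[str, str, str]] = {
    "drg": ("dr4", "g2", "drg"),
    "drp": ("dr5", "p2", "drp"),
    "dig": ("di4", "g3", "dig"),
    "dip": ("di5", "p3", "dip"),
}

#: relations whose interaction scores enter the composite loss
SCORE_RELATIONS = ("drdi", "drg", "drp", "dig", "dip")


@dataclass(frozen=True)
class ModelConfig:
    embed_dim: int = 256
    mlp_dims: tuple[int, int, int] = (256, 128, 64)
    gcn_layers: int = 2
    rgcn_layers: int = 2
    feature_scheme: str = "assoc_rows"
    score_mode: str = "dot"
    variant: str = "full"
    indirect_in_rgcn: bool = False

    def __post_init__(self):
        if self.embed_dim <= 0 or self.gcn_layers < 1 or self.rgcn_layers < 1:
            raise ValueError("dimensions and layer counts must be positive")
        if len(self.mlp_dims) != 3 or any(d <= 0 for d in self.mlp_dims):
            raise ValueError("mlp_dims must be three positive widths")
        if self.feature_scheme not in ("assoc_rows", "one_hot"):
            raise ValueError(f"unknown feature scheme {self.feature_scheme!r}")
        if self.score_mode not in ("dot", "cosine"):
            raise ValueError(f"unknown score mode {self.score_mode!r}")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")

    def active_types(self) -> tuple[str, ...]:
        types = ["drug", "disease", "gene", "protein"]
        if self.variant == "no_gene":
            types.remove("gene")
        if self.variant == "no_protein":
            types.remove("protein")
        return tuple(types)

    def active_score_relations(self) -> tuple[str, ...]:
        active = set(self.active_types())
        out = []
        for rel in SCORE_RELATIONS:
            tgt, src, _, _ = RGCN_RELATIONS[rel]
            if tgt in active and src in active:
                out.append(rel)
        return tuple(out)

    def active_rgcn_relations(self) -> tuple[str, ...]:
        active = set(self.active_types())
        return tuple(
            name
            for name, (tgt, src, _, _) in RGCN_RELATIONS.items()
            if tgt in active and src in active
        )

    def active_relation_outputs(self) -> dict[str, tuple[str, ...]]:
        active = set(self.active_types())
        out: dict[str, tuple[str, ...]] = {}
        for t in self.active_types():
            rels = tuple(
                r for r in RELATION_OUTPUTS[t] if RGCN_RELATIONS[r][1] in active
            )
            out[t] = rels
        return out

    def active_indirect_branches(self) -> tuple[str, ...]:
        if self.variant == "no_indirect":
            return ()
        active = set(self.active_types())
        return tuple(
            name
            for name, (_, _, rel) in INDIRECT_BRANCHES.items()
            if all(t in active for t in _branch_types(rel))
        )


def _branch_types(rel: str) -> tuple[str, str]:
    tgt, src, _, _ = RGCN_RELATIONS[rel]
    return tgt, src


@dataclass
class GraphOps:
    """Constant (non-trainable) sparse operators derived from the network."""

    dims: dict[str, int]
    homo: dict[str, sp.csr_matrix]  # normalized drug-drug / disease-disease
    direct_block: sp.csr_matrix  # normalized [[I, A_drdi], [A^T, I]]
    indirect_blocks: dict[str, sp.csr_matrix]
    rgcn: dict[str, tuple[str, str, sp.csr_matrix]]  # name -> (tgt, src, mean matrix)


def _mean_aggregation(a: sp.spmatrix) -> sp.csr_matrix:
    """Row-normalize: each row averages its neighbors; zero rows stay zero."""
    a = sp.csr_matrix(a, dtype=np.float64)
    deg = np.asarray(a.sum(axis=1)).ravel()
    inv = np.divide(1.0, deg, out=np.zeros_like(deg), where=deg > 0)
    return (sp.diags(inv) @ a).tocsr()


def build_graph(network: HeteroNetwork, config: ModelConfig) -> GraphOps:
    dims = {t: network.n(t) for t in ("drug", "disease", "gene", "protein")}
    homo = {
        name: normalize_adjacency(network.relations[name]).values
        for name in ("drdr", "didi")
    }
    direct_block = bipartite_block(network.relations["drdi"]).values
    indirect_blocks = {
        name: bipartite_block(network.relations[INDIRECT_BRANCHES[name][2]]).values
        for name in config.active_indirect_branches()
    }
    rgcn: dict[str, tuple[str, str, sp.csr_matrix]] = {}
    for name in config.active_rgcn_relations():
        tgt, src, base, transposed = RGCN_RELATIONS[name]
        a = network.relations[base].values
        if transposed:
            a = a.T
        rgcn[name] = (tgt, src, _mean_aggregation(a))
    return GraphOps(dims, homo, direct_block, indirect_blocks, rgcn)


# ---------------------------------------------------------------------------
# initial features


def init_features(network: HeteroNetwork, config: ModelConfig) -> dict[str, np.ndarray]:
    """Per-type feature matrices.

    ``assoc_rows``: each entity's feature vector concatenates its rows of the
    relations it participates in (restricted to the active entity types);
    ``one_hot``: identity features.
    """
    active = config.active_types()
    feats: dict[str, np.ndarray] = {}
    if config.feature_scheme == "one_hot":
        for t in active:
            feats[t] = np.eye(network.n(t))
        return feats
    rel = network.relations
    blocks: dict[str, list] = {
        "drug": [rel["drdr"].values, rel["drdi"].values, rel["drg"].values, rel["drp"].values],
        "disease": [rel["drdi"].values.T, rel["didi"].values, rel["dig"].values, rel["dip"].values],
        "gene": [rel["drg"].values.T, rel["dig"].values.T, rel["gg"].values],
        "protein": [rel["drp"].values.T, rel["dip"].values.T, rel["pp"].values],
    }
    col_types: dict[str, list] = {
        "drug": ["drug", "disease", "gene", "protein"],
        "disease": ["drug", "disease", "gene", "protein"],
        "gene": ["drug", "disease", "gene"],
        "protein": ["drug", "disease", "protein"],
    }
    for t in active:
        kept = [b for b, ct in zip(blocks[t], col_types[t]) if ct in active]
        feats[t] = sp.hstack(kept).toarray()
    return feats


def feature_dims(network: HeteroNetwork, config: ModelConfig) -> dict[str, int]:
    if config.feature_scheme == "one_hot":
        return {t: network.n(t) for t in config.active_types()}
    active = config.active_types()
    sizes = {t: network.n(t) for t in active}
    total = sum(sizes.values())
    out = {}
    for t in active:
        if t == "drug" or t == "disease":
            out[t] = total
        elif t == "gene":
            out[t] = sizes.get("drug", 0) + sizes.get("disease", 0) + sizes["gene"]
        else:
            out[t] = sizes.get("drug", 0) + sizes.get("disease", 0) + sizes["protein"]
    return out


# ---------------------------------------------------------------------------
# parameters

FC_BRANCH_TYPE = {"dr2": "drug", "di2": "disease", "g1": "gene", "p1": "protein"}


def init_params(
    network: HeteroNetwork, config: ModelConfig, seed: int = 0
) -> dict[str, np.ndarray]:
    """Symmetric-uniform (Glorot) weight init, zero biases, keyed by branch."""
    rng = np.random.default_rng(seed)
    fd = feature_dims(network, config)
    d = config.embed_dim
    params: dict[str, np.ndarray] = {}

    def glorot(name: str, fan_in: int, fan_out: int) -> None:
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        params[name] = rng.uniform(-limit, limit, size=(fan_in, fan_out))

    # homogeneous GCN branches (drugs and diseases only)
    for branch, t in (("dr1", "drug"), ("di1", "disease")):
        for layer in range(config.gcn_layers):
            fan_in = fd[t] if layer == 0 else d
            glorot(f"{branch}.gcn{layer}.W", fan_in, d)
    # per-entity FC embeddings
    for branch, t in FC_BRANCH_TYPE.items():
        if t not in config.active_types():
            continue
        glorot(f"{branch}.fc.W", fd[t], d)
        params[f"{branch}.fc.b"] = np.zeros(d)
    # direct heterogeneous GCN
    for layer in range(config.gcn_layers):
        glorot(f"drdi.gcn{layer}.W", d, d)
    # indirect heterogeneous GCNs
    for name in config.active_indirect_branches():
        for layer in range(config.gcn_layers):
            glorot(f"{name}.gcn{layer}.W", d, d)
    # RGCN
    hetero_outputs = {r for rels in config.active_relation_outputs().values() for r in rels}
    for layer in range(config.rgcn_layers):
        last = layer == config.rgcn_layers - 1
        rels = sorted(hetero_outputs) if last else sorted(config.active_rgcn_relations())
        for rel in rels:
            glorot(f"rgcn{layer}.{rel}.W", d, d)
        glorot(f"rgcn{layer}.self.W", d, d)
    # per-type aggregation MLP
    m1, m2, m3 = config.mlp_dims
    for t in config.active_types():
        widths = [d, m1, m2, m3]
        for i in range(3):
            glorot(f"mlp.{t}.{i}.W", widths[i], widths[i + 1])
            params[f"mlp.{t}.{i}.b"] = np.zeros(widths[i + 1])
    return params


def parameter_census(network: HeteroNetwork, config: ModelConfig) -> int:
    """Closed-form trainable parameter count implied by the configuration."""
    fd = feature_dims(network, config)
    d = config.embed_dim
    n = 0
    for t in ("drug", "disease"):  # homogeneous GCN stacks
        n += fd[t] * d + (config.gcn_layers - 1) * d * d
    for t in config.active_types():  # FC embeddings
        n += fd[t] * d + d
    n += config.gcn_layers * d * d  # direct hetero GCN
    n += len(config.active_indirect_branches()) * config.gcn_layers * d * d
    hetero_outputs = {r for rels in config.active_relation_outputs().values() for r in rels}
    if config.rgcn_layers > 1:
        n += (config.rgcn_layers - 1) * (len(config.active_rgcn_relations()) + 1) * d * d
    n += (len(hetero_outputs) + 1) * d * d  # last RGCN layer
    m1, m2, m3 = config.mlp_dims
    for t in config.active_types():
        n += d * m1 + m1 + m1 * m2 + m2 + m2 * m3 + m3
    return n


# ---------------------------------------------------------------------------
# layer operations (each consumes/produces autodiff Tensors)


def homo_gcn(v: Tensor, adj: sp.csr_matrix, weights: list[Tensor]) -> Tensor:
    """Stack of ``ReLU(normalized_adjacency @ x @ W)`` layers."""
    x = v
    for w in weights:
        x = ad.relu(ad.matmul(ad.spmm(adj, x), w))
    return x


def fc_embed(v: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Single affine map plus ReLU."""
    return ad.relu(ad.add_bias(ad.matmul(v, w), b))


def hetero_gcn(
    x_in: Tensor, y_in: Tensor, block_adj: sp.csr_matrix, weights: list[Tensor]
) -> tuple[Tensor, Tensor]:
    """Propagate the stacked (x, y) embeddings through a bipartite block."""
    n_x = x_in.shape[0]
    n_y = y_in.shape[0]
    h = ad.vstack([x_in, y_in])
    for w in weights:
        h = ad.relu(ad.matmul(ad.spmm(block_adj, h), w))
    return ad.rows(h, 0, n_x), ad.rows(h, n_x, n_x + n_y)


def rgcn_layer(
    h: Mapping[str, Tensor],
    graph: GraphOps,
    weights: Mapping[str, Tensor],
    self_weight: Tensor,
    relation_names: tuple[str, ...],
) -> dict[str, Tensor]:
    """One intermediate RGCN update: per-type sum of relation means + self."""
    out: dict[str, Tensor] = {}
    for t in h:
        terms = [ad.matmul(h[t], self_weight)]
        for rel in relation_names:
            tgt, src, m = graph.rgcn[rel]
            if tgt != t:
                continue
            terms.append(ad.matmul(ad.spmm(m, h[src]), weights[rel]))
        out[t] = ad.relu(ad.add(*terms))
    return out


def rgcn_relation_outputs(
    h: Mapping[str, Tensor],
    graph: GraphOps,
    weights: Mapping[str, Tensor],
    self_weight: Tensor,
    outputs: Mapping[str, tuple[str, ...]],
) -> dict[str, Tensor]:
    """Final RGCN layer: keep each node's per-relation aggregate."""
    out: dict[str, Tensor] = {}
    for t, rels in outputs.items():
        for rel in rels:
            tgt, src, m = graph.rgcn[rel]
            msg = ad.matmul(ad.spmm(m, h[src]), weights[rel])
            out[rel] = ad.relu(ad.add(msg, ad.matmul(h[t], self_weight)))
    return out


def rgcn_input(branches: Mapping[str, Tensor | None], config: ModelConfig) -> dict[str, Tensor]:
    """Element-wise sum of each entity type's branch embeddings."""
    groups: dict[str, list[str]] = {
        "drug": ["dr1", "dr2", "dr3"],
        "disease": ["di1", "di2", "di3"],
        "gene": ["g2", "g3"],
        "protein": ["p2", "p3"],
    }
    if config.indirect_in_rgcn:
        groups["drug"] += ["dr4", "dr5"]
        groups["disease"] += ["di4", "di5"]
    if config.variant == "no_indirect":
        groups["gene"] = ["g1"]
        groups["protein"] = ["p1"]
        groups["drug"] = ["dr1", "dr2", "dr3"]
        groups["disease"] = ["di1", "di2", "di3"]
    out: dict[str, Tensor] = {}
    for t in config.active_types():
        present = [branches[b] for b in groups[t] if branches.get(b) is not None]
        if not present:
            raise ValueError(f"no branch embeddings available for type {t!r}")
        out[t] = present[0] if len(present) == 1 else ad.add(*present)
    return out


def mlp_aggregate(
    rel_embeddings: Mapping[str, Tensor],
    params: Mapping[str, Tensor],
    config: ModelConfig,
) -> dict[str, Tensor]:
    """Sum each type's relation-scoped embeddings and apply its 3-layer MLP."""
    out: dict[str, Tensor] = {}
    for t, rels in config.active_relation_outputs().items():
        present = [rel_embeddings[r] for r in rels if r in rel_embeddings]
        if not present:
            raise ValueError(f"no relation-scoped embeddings for type {t!r}")
        x = present[0] if len(present) == 1 else ad.add(*present)
        for i in range(3):
            x = ad.relu(ad.add_bias(ad.matmul(x, params[f"mlp.{t}.{i}.W"]), params[f"mlp.{t}.{i}.b"]))
        out[t] = x
    return out


def interaction_scores(a: Tensor, b: Tensor, mode: str = "dot") -> Tensor:
    """Inner-product score matrix; cosine mode L2-normalizes rows first."""
    if mode == "dot":
        return ad.matmul_t(a, b)
    norm_a = np.linalg.norm(a.value, axis=1, keepdims=True)
    norm_b = np.linalg.norm(b.value, axis=1, keepdims=True)
    inv_a = np.divide(1.0, norm_a, out=np.zeros_like(norm_a), where=norm_a > 0)
    inv_b = np.divide(1.0, norm_b, out=np.zeros_like(norm_b), where=norm_b > 0)
    # row scaling by constants keeps the graph differentiable w.r.t. a and b
    a_scaled = ad.Tensor(a.value * inv_a, (a,), lambda g, a=a, s=inv_a: ad._acc(a, g * s))
    b_scaled = ad.Tensor(b.value * inv_b, (b,), lambda g, b=b, s=inv_b: ad._acc(b, g * s))
    return ad.matmul_t(a_scaled, b_scaled)


# ---------------------------------------------------------------------------
# forward pass


def forward(
    graph: GraphOps,
    features: Mapping[str, np.ndarray],
    params: Mapping[str, Tensor],
    config: ModelConfig,
) -> tuple[dict[str, Tensor], dict[str, Tensor | None]]:
    """Run the full hierarchy; returns (score matrices, branch intermediates).

    Deterministic given parameters; raises on any shape mismatch.
    """
    active = config.active_types()
    v = {t: ad.constant(features[t]) for t in active}
    branches: dict[str, Tensor | None] = {k: None for k in (
        "dr1", "dr2", "dr3", "dr4", "dr5", "di1", "di2", "di3", "di4", "di5",
        "g1", "g2", "g3", "p1", "p2", "p3",
    )}

    # 1. homogeneous GCNs
    for branch, t, adj_name in (("dr1", "drug", "drdr"), ("di1", "disease", "didi")):
        ws = [params[f"{branch}.gcn{l}.W"] for l in range(config.gcn_layers)]
        branches[branch] = homo_gcn(v[t], graph.homo[adj_name], ws)

    # 2. FC embeddings
    for branch, t in FC_BRANCH_TYPE.items():
        if t in active:
            branches[branch] = fc_embed(v[t], params[f"{branch}.fc.W"], params[f"{branch}.fc.b"])

    # 3. direct heterogeneous GCN
    ws = [params[f"drdi.gcn{l}.W"] for l in range(config.gcn_layers)]
    branches["dr3"], branches["di3"] = hetero_gcn(
        branches["dr2"], branches["di2"], graph.direct_block, ws
    )

    # 4. indirect heterogeneous GCNs
    x_inputs = {"drg": "dr2", "drp": "dr2", "dig": "di2", "dip": "di2"}
    y_inputs = {"drg": "g1", "drp": "p1", "dig": "g1", "dip": "p1"}
    for name in config.active_indirect_branches():
        x_branch, y_branch, _ = INDIRECT_BRANCHES[name]
        ws = [params[f"{name}.gcn{l}.W"] for l in range(config.gcn_layers)]
        branches[x_branch], branches[y_branch] = hetero_gcn(
            branches[x_inputs[name]], branches[y_inputs[name]], graph.indirect_blocks[name], ws
        )

    # 5. RGCN
    h = rgcn_input(branches, config)
    for layer in range(config.rgcn_layers - 1):
        rel_ws = {r: params[f"rgcn{layer}.{r}.W"] for r in config.active_rgcn_relations()}
        h = rgcn_layer(h, graph, rel_ws, params[f"rgcn{layer}.self.W"], config.active_rgcn_relations())
    last = config.rgcn_layers - 1
    outputs = config.active_relation_outputs()
    hetero_rels = {r for rels in outputs.values() for r in rels}
    rel_ws = {r: params[f"rgcn{last}.{r}.W"] for r in hetero_rels}
    rel_embed = rgcn_relation_outputs(h, graph, rel_ws, params[f"rgcn{last}.self.W"], outputs)

    # 6. MLP aggregation
    final = mlp_aggregate(rel_embed, params, config)

    # 7. interaction scores
    scores: dict[str, Tensor] = {}
    for rel in config.active_score_relations():
        tgt, src, _, _ = RGCN_RELATIONS[rel]
        scores[rel] = interaction_scores(final[tgt], final[src], config.score_mode)

    intermediates = dict(branches)
    intermediates.update({f"rel.{k}": v_ for k, v_ in rel_embed.items()})
    intermediates.update({f"final.{k}": v_ for k, v_ in final.items()})
    return scores, intermediates


def forward_network(
    network: HeteroNetwork, params: Mapping[str, np.ndarray], config: ModelConfig
) -> dict[str, np.ndarray]:
    """Convenience wrapper: raw arrays in, raw score arrays out."""
    graph = build_graph(network, config)
    feats = init_features(network, config)
    tensors = {k: Tensor(v) for k, v in params.items()}
    scores, _ = forward(graph, feats, tensors, config)
    return {k: s.value for k, s in scores.items()}


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(path: str, params: Mapping[str, np.ndarray], config: ModelConfig, seed: int) -> None:
    meta = json.dumps({"config": asdict(config), "seed": seed})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **params)


def load_checkpoint(path: str) -> tuple[dict[str, np.ndarray], ModelConfig, int]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        params = {k: data[k].copy() for k in data.files if k != "__meta__"}
    cfg = meta["config"]
    cfg["mlp_dims"] = tuple(cfg["mlp_dims"])
    return params, ModelConfig(**cfg), meta["seed"]
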