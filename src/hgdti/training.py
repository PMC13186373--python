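"""Composite multi-relation loss and the full-batch training loop.

The loss is the direct drug-disease reconstruction term plus ``beta`` times
the sum of the four indirect terms; each term is half the mean squared
difference over entries not excluded by the mask.  Optimization is plain
Adam over the full graph (no mini-batching), deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import autodiff as ad
from .autodiff import Tensor
from .model import (
    ModelConfig,
    build_graph,
    forward,
    init_features,
    init_params,
)
from .network import HeteroNetwork


@dataclass
class TrainConfig:
    epochs: int = 2000
    lr: float = 1e-4
    beta: float = 0.05
    seed: int = 0
    mask: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    log_every: int = 0  # 0 disables per-epoch stderr logging

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if self.beta < 0:
            raise ValueError("beta must be non-negative")


class TrainingDivergedError(RuntimeError):
    pass


def _keep_masks(
    targets: Mapping[str, np.ndarray],
    mask: Mapping[str, Sequence[tuple[int, int]]],
) -> dict[str, np.ndarray | None]:
    keeps: dict[str, np.ndarray | None] = {}
    for rel, a in targets.items():
        pairs = mask.get(rel)
        if not pairs:
            keeps[rel] = None
            continue
        keep = np.ones(a.shape, dtype=bool)
        for i, j in pairs:
            keep[i, j] = False
        keeps[rel] = keep
    return keeps


def composite_loss(
    scores: Mapping[str, Tensor | np.ndarray],
    targets: Mapping[str, np.ndarray],
    beta: float,
    mask: Mapping[str, Sequence[tuple[int, int]]] | None = None,
) -> tuple[Tensor, dict[str, float]]:
    """Direct term + beta * (sum of indirect terms), each a masked half-MSE.

    ``scores`` may be autodiff Tensors (training path) or plain arrays;
    returns the total as a Tensor plus the per-component float values.
    """
    mask = mask or {}
    tensors = {
        rel: s if isinstance(s, Tensor) else ad.constant(s) for rel, s in scores.items()
    }
    keeps = _keep_masks({r: np.asarray(targets[r]) for r in tensors}, mask)
    components: dict[str, float] = {}
    direct = ad.half_mse(tensors["drdi"], np.asarray(targets["drdi"]), keeps["drdi"])
    components["drdi"] = float(direct.value)
    indirect_terms = []
    for rel in ("drg", "drp", "dig", "dip"):
        if rel not in tensors:
            continue
        term = ad.half_mse(tensors[rel], np.asarray(targets[rel]), keeps[rel])
        components[rel] = float(term.value)
        indirect_terms.append(term)
    if indirect_terms and beta != 0:
        total = ad.add(direct, ad.scale(ad.add(*indirect_terms) if len(indirect_terms) > 1
                                        else indirect_terms[0], beta))
    else:
        total = direct
    return total, components


@dataclass
class TrainResult:
    params: dict[str, np.ndarray]
    history: pd.DataFrame
    config: ModelConfig
    train_config: TrainConfig


def train(
    network: HeteroNetwork,
    model_config: ModelConfig,
    train_config: TrainConfig,
    log=None,
) -> TrainResult:
    """Algorithm: mask -> build operators -> E epochs of forward/backprop/Adam.

    Masked positives are removed from both the supervision targets and every
    adjacency operator before training starts, so held-out interactions leak
    into neither the loss nor message passing.
    """
    net = network.masked(train_config.mask) if train_config.mask else network
    graph = build_graph(net, model_config)
    feats = init_features(net, model_config)
    params = init_params(net, model_config, seed=train_config.seed)
    targets = {
        rel: net.relations[rel].toarray() for rel in model_config.active_score_relations()
    }

    m = {k: np.zeros_like(v) for k, v in params.items()}
    v2 = {k: np.zeros_like(v) for k, v in params.items()}
    b1, b2, eps = train_config.adam_beta1, train_config.adam_beta2, train_config.adam_eps

    rows = []
    for epoch in range(1, train_config.epochs + 1):
        tensors = {k: Tensor(val) for k, val in params.items()}
        scores, _ = forward(graph, feats, tensors, model_config)
        loss, components = composite_loss(scores, targets, train_config.beta, train_config.mask)
        total = float(loss.value)
        if not np.isfinite(total):
            bad = [r for r, c in components.items() if not np.isfinite(c)]
            raise TrainingDivergedError(
                f"non-finite loss at epoch {epoch} (components: {bad or 'total'})"
            )
        ad.backward(loss)
        for k in params:
            g = tensors[k].grad
            if g is None:
                continue
            m[k] = b1 * m[k] + (1 - b1) * g
            v2[k] = b2 * v2[k] + (1 - b2) * g * g
            m_hat = m[k] / (1 - b1**epoch)
            v_hat = v2[k] / (1 - b2**epoch)
            params[k] = params[k] - train_config.lr * m_hat / (np.sqrt(v_hat) + eps)
        row = {"epoch": epoch, "loss": total}
        for rel in ("drdi", "drg", "drp", "dig", "dip"):
            row[f"loss_{rel}"] = components.get(rel, np.nan)
        rows.append(row)
        if log is not None and train_config.log_every and epoch % train_config.log_every == 0:
            log(f"epoch {epoch} loss {total:.6f} " +
                " ".join(f"{r}={c:.6f}" for r, c in components.items()))

    history = pd.DataFrame(rows)
    return TrainResult(params=params, history=history, config=model_config,
                       train_config=train_config)
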