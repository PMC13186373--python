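"""Cross-validation, ranking metrics, repositioning, and ablation runs."""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .model import ModelConfig, forward_network
from .network import AssociationMatrix, HeteroNetwork
from .training import TrainConfig, TrainResult, train

METRICS = ("auc", "aupr", "f1", "precision", "recall")


@dataclass(frozen=True)
class Fold:
    test_positives: tuple[tuple[int, int], ...]
    test_negatives: tuple[tuple[int, int], ...]


@dataclass(frozen=True)
class FoldSplit:
    folds: tuple[Fold, ...]
    seed: int

    @property
    def k(self) -> int:
        return len(self.folds)


@dataclass
class EvalReport:
    per_fold: pd.DataFrame  # one row per fold, columns METRICS (+ fold, threshold)
    seed: int
    threshold_rule: str = "train_f1"

    @property
    def mean(self) -> dict[str, float]:
        return {m: float(self.per_fold[m].mean()) for m in METRICS}

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "threshold_rule": self.threshold_rule,
                "per_fold": self.per_fold.to_dict(orient="records"),
                "mean": self.mean,
            },
            indent=2,
        )


def cv_split(m: AssociationMatrix, k: int, seed: int) -> FoldSplit:
    """Partition positives into k near-equal folds; per fold sample an equal
    number of zero entries (disjoint from all positives and across folds)."""
    rng = np.random.default_rng(seed)
    positives = m.pairs()
    if len(positives) < k:
        raise ValueError(f"need at least {k} positives for {k}-fold CV")
    order = rng.permutation(len(positives))
    pos_folds = [
        [positives[i] for i in chunk] for chunk in np.array_split(order, k)
    ]
    n_a, n_b = m.shape
    n_neg_needed = len(positives)
    n_zero = n_a * n_b - len(positives)
    if n_zero < n_neg_needed:
        raise ValueError("fewer zero entries than required negatives")
    pos_set = set(positives)
    negatives: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()
    # rejection sampling without replacement; dense fallback for tiny matrices
    if n_zero <= 4 * n_neg_needed:
        all_zeros = [
            (i, j) for i in range(n_a) for j in range(n_b) if (i, j) not in pos_set
        ]
        idx = rng.choice(len(all_zeros), size=n_neg_needed, replace=False)
        negatives = [all_zeros[i] for i in idx]
    else:
        while len(negatives) < n_neg_needed:
            i = int(rng.integers(n_a))
            j = int(rng.integers(n_b))
            if (i, j) in pos_set or (i, j) in seen:
                continue
            seen.add((i, j))
            negatives.append((i, j))
    folds = []
    start = 0
    for pf in pos_folds:
        nf = negatives[start : start + len(pf)]
        start += len(pf)
        folds.append(Fold(tuple(pf), tuple(nf)))
    return FoldSplit(tuple(folds), seed)


def best_f1_threshold(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Score threshold maximizing F1 (predict positive when score >= t)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    n_pos = int(y.sum())
    precision = tp / np.maximum(tp + fp, 1)
    recall = tp / max(n_pos, 1)
    f1 = np.divide(
        2 * precision * recall,
        precision + recall,
        out=np.zeros_like(precision),
        where=(precision + recall) > 0,
    )
    best = int(np.argmax(f1))
    return float(s[best])


def compute_metrics(
    scores: Sequence[float], labels: Sequence[int], threshold: float
) -> dict[str, float]:
    """AUC (rank concordance, half-credit ties), AUPR (step integration),
    and F1/precision/recall at the given score threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return {
        "auc": float(roc_auc_score(labels, scores)),
        "aupr": float(average_precision_score(labels, scores)),
        "f1": f1,
        "precision": precision,
        "recall": recall,
    }


def evaluate_cv(
    network: HeteroNetwork,
    model_config: ModelConfig,
    train_config: TrainConfig,
    k: int = 5,
    seed: int = 0,
    relation: str = "drdi",
    return_details: bool = False,
):
    """k-fold CV on one supervised relation.

    Per fold: mask the fold's test positives from the relation (hence from
    every adjacency operator and from the loss), train, score test pairs,
    pick the F1 threshold on train-fold positives vs an equal train-negative
    sample, and compute metrics on the held-out pairs.
    """
    split = cv_split(network.relations[relation], k, seed)
    rng = np.random.default_rng(seed + 1)
    rows = []
    details = []
    full = network.relations[relation]
    for fold_idx, fold in enumerate(split.folds):
        mask = dict(train_config.mask)
        mask[relation] = list(fold.test_positives)
        fold_tc = TrainConfig(
            epochs=train_config.epochs,
            lr=train_config.lr,
            beta=train_config.beta,
            seed=train_config.seed,
            mask=mask,
            log_every=train_config.log_every,
        )
        result = train(network, model_config, fold_tc)
        masked_net = network.masked(mask)
        # invariant: held-out positives are absent from the training relation
        arr = masked_net.relations[relation].toarray()
        assert all(arr[i, j] == 0 for i, j in fold.test_positives)
        scores = forward_network(masked_net, result.params, model_config)[relation]

        train_pos = [p for p in full.pairs() if p not in set(fold.test_positives)]
        excluded = set(fold.test_positives) | set(fold.test_negatives) | set(full.pairs())
        train_neg = _sample_zeros(full.shape, excluded, len(train_pos), rng)
        thr_scores = [scores[i, j] for i, j in train_pos + train_neg]
        thr_labels = [1] * len(train_pos) + [0] * len(train_neg)
        threshold = best_f1_threshold(thr_scores, thr_labels)

        test_pairs = list(fold.test_positives) + list(fold.test_negatives)
        test_scores = [scores[i, j] for i, j in test_pairs]
        test_labels = [1] * len(fold.test_positives) + [0] * len(fold.test_negatives)
        metrics = compute_metrics(test_scores, test_labels, threshold)
        rows.append({"fold": fold_idx, "threshold": threshold, **metrics})
        if return_details:
            details.append(
                {"fold": fold, "scores": scores, "params": result.params,
                 "history": result.history}
            )
    report = EvalReport(per_fold=pd.DataFrame(rows), seed=seed)
    if return_details:
        return report, details
    return report


def _sample_zeros(shape, excluded, count, rng) -> list[tuple[int, int]]:
    n_a, n_b = shape
    available = n_a * n_b - len(excluded)
    count = min(count, available)
    out: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()
    if available <= 4 * count:
        pool = [(i, j) for i in range(n_a) for j in range(n_b) if (i, j) not in excluded]
        idx = rng.choice(len(pool), size=count, replace=False)
        return [pool[i] for i in idx]
    while len(out) < count:
        i = int(rng.integers(n_a))
        j = int(rng.integers(n_b))
        if (i, j) in excluded or (i, j) in seen:
            continue
        seen.add((i, j))
        out.append((i, j))
    return out


def repositioning_mask(network: HeteroNetwork, disease_idx: int) -> dict[str, list[tuple[int, int]]]:
    """Every association touching one disease, across all disease relations."""
    mask: dict[str, list[tuple[int, int]]] = {}
    for rel, axis in (("drdi", 1), ("didi", 0), ("dig", 0), ("dip", 0)):
        m = network.relations[rel]
        pairs = [
            (i, j) for i, j in m.pairs() if (j if axis == 1 else i) == disease_idx
        ]
        if pairs:
            mask[rel] = pairs
    return mask


def repositioning_rank(
    network: HeteroNetwork,
    result: TrainResult,
    disease_id: str,
    top_k: int = 10,
) -> pd.DataFrame:
    """Rank drugs for one disease by descending score, catalog-order ties.

    The caller is responsible for training ``result`` on a network where the
    disease's associations were masked (see :func:`repositioning_mask`).
    Standardized scores are min-max over the full drug list.
    """
    catalog = network.catalogs["disease"]
    if disease_id not in catalog:
        raise KeyError(f"unknown disease {disease_id!r}")
    j = catalog.index(disease_id)
    masked = network.masked(result.train_config.mask) if result.train_config.mask else network
    scores = forward_network(masked, result.params, result.config)["drdi"][:, j]
    lo, hi = float(scores.min()), float(scores.max())
    std = (scores - lo) / (hi - lo) if hi > lo else np.zeros_like(scores)
    order = np.lexsort((np.arange(len(scores)), -scores))  # stable catalog-order ties
    top = order[: min(top_k, len(order))]
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(top) + 1),
            "drug_id": [network.catalogs["drug"].ids[i] for i in top],
            "score": scores[top],
            "standardized_score": std[top],
        }
    )


def run_ablation(
    network: HeteroNetwork,
    base_config: ModelConfig,
    train_config: TrainConfig,
    k: int = 5,
    seed: int = 0,
    variants: Sequence[str] = ("full", "no_protein", "no_gene", "no_indirect"),
) -> pd.DataFrame:
    """Evaluate each architectural variant with identical data and seeds."""
    rows = []
    for variant in variants:
        cfg = ModelConfig(
            embed_dim=base_config.embed_dim,
            mlp_dims=base_config.mlp_dims,
            gcn_layers=base_config.gcn_layers,
            rgcn_layers=base_config.rgcn_layers,
            feature_scheme=base_config.feature_scheme,
            score_mode=base_config.score_mode,
            variant=variant,
            indirect_in_rgcn=base_config.indirect_in_rgcn,
        )
        report = evaluate_cv(network, cfg, train_config, k=k, seed=seed)
        rows.append({"variant": variant, **report.mean})
    return pd.DataFrame(rows)
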