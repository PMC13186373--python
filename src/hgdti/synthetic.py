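"""Seeded synthetic heterogeneous networks with planted low-rank structure.

Every entity gets a latent vector; each relation marks the top pairs by
latent inner product until its target density is met, then a density-
preserving fraction of entries is flipped as noise.  Because all relations
share the same latents, multi-hop branches carry genuine signal and
held-out associations are recoverable — the desk-scale testbed for the
whole pipeline.  A disease hierarchy and drug substructure token sets are
generated alongside so the similarity measures are exercisable end to end.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import scipy.sparse as sp

from .evaluation import EvalReport, evaluate_cv
from .model import ModelConfig
from .network import (
    RELATION_TYPES,
    AssociationMatrix,
    EntityCatalog,
    HeteroNetwork,
    write_bundle,
)
from .similarity import DiseaseDag, SubstructureSet
from .training import TrainConfig

#: per-relation target densities, scaled from the reference dataset's shape
DEFAULT_DENSITIES: dict[str, float] = {
    "drdr": 0.0418,
    "didi": 0.1887,
    "gg": 0.0082,
    "pp": 0.0036,
    "drdi": 0.2185,
    "drg": 0.0011,
    "drp": 0.0018,
    "dig": 0.0339,
    "dip": 0.4953,
}


@dataclass(frozen=True)
class SyntheticSpec:
    n_dr: int = 54
    n_di: int = 39
    n_g: int = 200
    n_p: int = 40
    latent_dim: int = 8
    densities: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_DENSITIES))
    noise_rate: float = 0.05
    dag_depth: int = 3
    dag_branching: int = 3
    tokens_per_drug: int = 20
    shuffle: bool = False  # destroy planted signal while preserving densities
    #: derive gene latents from protein latents (plus jitter) so the gene and
    #: protein modalities carry largely redundant signal
    redundant_gene_latents: bool = False
    gene_latent_jitter: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if min(self.n_dr, self.n_di, self.n_g, self.n_p) < 2:
            raise ValueError("entity counts must be >= 2")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if not (0 <= self.noise_rate < 0.5):
            raise ValueError("noise_rate must lie in [0, 0.5)")
        for rel, rho in self.densities.items():
            if not (0 < rho < 1):
                raise ValueError(f"density for {rel!r} must lie in (0, 1)")

    @property
    def counts(self) -> dict[str, int]:
        return {"drug": self.n_dr, "disease": self.n_di, "gene": self.n_g, "protein": self.n_p}


def high_signal_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """The dense-enough fixture on which planted signal is recoverable."""
    densities = dict(DEFAULT_DENSITIES)
    densities.update(
        {"drg": 0.06, "drp": 0.10, "dig": 0.08, "dip": 0.2, "pp": 0.05,
         "gg": 0.02, "drdi": 0.2, "drdr": 0.08, "didi": 0.15}
    )
    defaults = dict(
        n_dr=50, n_di=30, n_g=200, n_p=40, latent_dim=4, densities=densities,
        noise_rate=0.05, seed=seed,
    )
    defaults.update(overrides)
    return SyntheticSpec(**defaults)


@dataclass
class GroundTruth:
    latents: dict[str, np.ndarray]
    clean: dict[str, np.ndarray]  # noise-free binary indicators per relation
    top_drug: dict[int, int]  # disease index -> planted best drug index


def _top_pairs_hetero(scores: np.ndarray, k: int) -> np.ndarray:
    """Binary matrix marking the k largest entries of ``scores``."""
    out = np.zeros(scores.shape, dtype=np.int8)
    if k <= 0:
        return out
    flat = np.argsort(scores, axis=None, kind="stable")[::-1][:k]
    out.flat[flat] = 1
    return out


def _top_pairs_homo(scores: np.ndarray, k_entries: int) -> np.ndarray:
    """Symmetric zero-diagonal binary matrix with ~k_entries ones (both
    orientations), chosen as the top upper-triangle similarity pairs."""
    n = scores.shape[0]
    sym = (scores + scores.T) / 2.0
    iu = np.triu_indices(n, k=1)
    vals = sym[iu]
    k_pairs = min(max(k_entries // 2, 1), vals.size)
    keep = np.argsort(vals, kind="stable")[::-1][:k_pairs]
    out = np.zeros((n, n), dtype=np.int8)
    out[iu[0][keep], iu[1][keep]] = 1
    return out + out.T


def _flip_noise_hetero(a: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Swap an equal number of ones->zeros and zeros->ones (density kept)."""
    out = a.copy()
    ones = np.flatnonzero(out)
    zeros = np.flatnonzero(out == 0)
    n_flip = int(round(rate * ones.size))
    n_flip = min(n_flip, ones.size, zeros.size)
    if n_flip == 0:
        return out
    off = rng.choice(ones, size=n_flip, replace=False)
    on = rng.choice(zeros, size=n_flip, replace=False)
    out.flat[off] = 0
    out.flat[on] = 1
    return out


def _flip_noise_homo(a: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    n = a.shape[0]
    iu = np.triu_indices(n, k=1)
    upper = a[iu]
    ones = np.flatnonzero(upper)
    zeros = np.flatnonzero(upper == 0)
    n_flip = int(round(rate * ones.size))
    n_flip = min(n_flip, ones.size, zeros.size)
    if n_flip:
        off = rng.choice(ones, size=n_flip, replace=False)
        on = rng.choice(zeros, size=n_flip, replace=False)
        upper[off] = 0
        upper[on] = 1
    out = np.zeros_like(a)
    out[iu] = upper
    return out + out.T


def _shuffle_matrix(a: np.ndarray, rng: np.random.Generator, homo: bool) -> np.ndarray:
    """Random matrix with the same count (destroys any planted structure)."""
    if homo:
        n = a.shape[0]
        iu = np.triu_indices(n, k=1)
        upper = a[iu]
        rng.shuffle(upper)
        out = np.zeros_like(a)
        out[iu] = upper
        return out + out.T
    flat = a.flatten()
    rng.shuffle(flat)
    return flat.reshape(a.shape)


def generate_network(spec: SyntheticSpec) -> tuple[HeteroNetwork, GroundTruth]:
    rng = np.random.default_rng(spec.seed)
    counts = spec.counts
    catalogs = {
        t: EntityCatalog(t, tuple(f"{t[:2]}{i:04d}" for i in range(n)))
        for t, n in counts.items()
    }
    latents = {
        t: rng.normal(size=(n, spec.latent_dim)) / np.sqrt(spec.latent_dim)
        for t, n in counts.items()
    }
    if spec.redundant_gene_latents:
        reps = int(np.ceil(spec.n_g / spec.n_p))
        base = np.tile(latents["protein"], (reps, 1))[: spec.n_g]
        jitter = rng.normal(size=base.shape) / np.sqrt(spec.latent_dim)
        latents["gene"] = base + spec.gene_latent_jitter * jitter
    clean: dict[str, np.ndarray] = {}
    noisy: dict[str, np.ndarray] = {}
    for rel, (ta, tb) in RELATION_TYPES.items():
        rho = spec.densities[rel]
        scores = latents[ta] @ latents[tb].T
        if ta == tb:
            n = counts[ta]
            k_entries = int(round(rho * n * n))
            if k_entries < 2:
                raise ValueError(f"density for {rel!r} unreachable at n={n}")
            c = _top_pairs_homo(scores, k_entries)
            m = _flip_noise_homo(c, spec.noise_rate, rng)
            if spec.shuffle:
                m = _shuffle_matrix(m, rng, homo=True)
        else:
            total = counts[ta] * counts[tb]
            k = int(round(rho * total))
            if k < 1:
                raise ValueError(f"density for {rel!r} unreachable at shape "
                                 f"({counts[ta]}, {counts[tb]})")
            c = _top_pairs_hetero(scores, k)
            m = _flip_noise_hetero(c, spec.noise_rate, rng)
            if spec.shuffle:
                m = _shuffle_matrix(m, rng, homo=False)
        clean[rel] = c
        noisy[rel] = m
    relations = {
        rel: AssociationMatrix(*RELATION_TYPES[rel], sp.csr_matrix(noisy[rel].astype(float)))
        for rel in RELATION_TYPES
    }
    network = HeteroNetwork(catalogs, relations)
    drdi_scores = latents["drug"] @ latents["disease"].T
    top_drug = {j: int(np.argmax(drdi_scores[:, j])) for j in range(counts["disease"])}
    return network, GroundTruth(latents=latents, clean=clean, top_drug=top_drug)


def generate_disease_dag(spec: SyntheticSpec) -> tuple[DiseaseDag, dict[str, str]]:
    """Random tree of the requested depth/branching plus a few cross edges;
    every disease maps to a leaf term."""
    rng = np.random.default_rng(spec.seed + 1)
    terms: list[str] = ["T0"]
    parents: dict[str, set[str]] = {}
    levels: list[list[str]] = [["T0"]]
    counter = 1
    for _ in range(spec.dag_depth):
        level: list[str] = []
        for parent in levels[-1]:
            for _ in range(spec.dag_branching):
                term = f"T{counter}"
                counter += 1
                terms.append(term)
                parents[term] = {parent}
                level.append(term)
        levels.append(level)
    # a small fraction of extra DAG edges: child gains a second parent from a
    # strictly shallower level, which cannot create a cycle
    for depth, level in enumerate(levels[2:], start=2):
        for term in level:
            if rng.random() < 0.15:
                shallow = levels[rng.integers(0, depth - 1)]
                extra = shallow[int(rng.integers(len(shallow)))]
                parents[term].add(extra)
    dag = DiseaseDag(frozenset(terms), {c: frozenset(p) for c, p in parents.items()})
    leaves = levels[-1]
    disease_ids = [f"di{i:04d}" for i in range(spec.n_di)]
    term_map = {
        d: leaves[int(rng.integers(len(leaves)))] for d in disease_ids
    }
    return dag, term_map


def generate_fingerprints(spec: SyntheticSpec, truth: GroundTruth | None = None) -> dict[str, SubstructureSet]:
    """Token sets where latent-similar drugs share more tokens.

    Drugs are clustered by the sign pattern of their first two latent axes;
    each cluster owns a token pool, plus a global pool, so same-cluster
    Jaccard exceeds cross-cluster Jaccard in expectation.
    """
    rng = np.random.default_rng(spec.seed + 2)
    if truth is None:
        truth = generate_network(spec)[1]
    z = truth.latents["drug"]
    cluster = (z[:, 0] > 0).astype(int) * 2 + (z[:, 1 % z.shape[1]] > 0).astype(int)
    t = spec.tokens_per_drug
    n_shared = max(t // 2, 1)
    sets: dict[str, SubstructureSet] = {}
    for i in range(spec.n_dr):
        c = int(cluster[i])
        pool = [f"c{c}_tok{k}" for k in range(t)]
        chosen = rng.choice(len(pool), size=n_shared, replace=False)
        tokens = {pool[k] for k in chosen}
        k = 0
        while len(tokens) < t:
            tokens.add(f"dr{i}_priv{k}")
            k += 1
        drug_id = f"dr{i:04d}"
        sets[drug_id] = SubstructureSet(drug_id, frozenset(tokens))
    return sets


def write_ground_truth(truth: GroundTruth, out_dir: str) -> None:
    gt_dir = os.path.join(out_dir, "ground_truth")
    os.makedirs(gt_dir, exist_ok=True)
    for t, z in truth.latents.items():
        with open(os.path.join(gt_dir, f"latents_{t}.tsv"), "w") as fh:
            for row in z:
                fh.write("\t".join(f"{x:.10g}" for x in row) + "\n")
    for rel, c in truth.clean.items():
        coo = sp.coo_matrix(c)
        with open(os.path.join(gt_dir, f"clean_{rel}.tsv"), "w") as fh:
            fh.write("row\tcol\n")
            for i, j in sorted(zip(coo.row.tolist(), coo.col.tolist())):
                fh.write(f"{i}\t{j}\n")
    with open(os.path.join(gt_dir, "top_drug.tsv"), "w") as fh:
        fh.write("disease_index\tdrug_index\n")
        for j in sorted(truth.top_drug):
            fh.write(f"{j}\t{truth.top_drug[j]}\n")


def generate_bundle(spec: SyntheticSpec, out_dir: str) -> tuple[HeteroNetwork, GroundTruth]:
    """Generate and write the full on-disk bundle (network + ground truth +
    disease DAG + fingerprints), byte-identical for identical specs."""
    network, truth = generate_network(spec)
    manifest_extra = {"synthetic_spec": _spec_dict(spec)}
    write_bundle(network, out_dir, extra_manifest=manifest_extra)
    write_ground_truth(truth, out_dir)
    dag, term_map = generate_disease_dag(spec)
    with open(os.path.join(out_dir, "disease_dag.tsv"), "w") as fh:
        for child in sorted(dag.parents):
            for parent in sorted(dag.parents[child]):
                fh.write(f"{child}\t{parent}\n")
    with open(os.path.join(out_dir, "disease_terms.tsv"), "w") as fh:
        for d in sorted(term_map):
            fh.write(f"{d}\t{term_map[d]}\n")
    fingerprints = generate_fingerprints(spec, truth)
    with open(os.path.join(out_dir, "drug_substructures.tsv"), "w") as fh:
        for drug_id in sorted(fingerprints):
            for tok in sorted(fingerprints[drug_id].features):
                fh.write(f"{drug_id}\t{tok}\n")
    return network, truth


def _spec_dict(spec: SyntheticSpec) -> dict:
    d = asdict(spec)
    d["densities"] = dict(d["densities"])
    return d


@dataclass
class RecoveryReport:
    cv: EvalReport
    ground_truth_auc: float
    ground_truth_aupr: float


def recovery_experiment(
    spec: SyntheticSpec,
    model_config: ModelConfig,
    train_config: TrainConfig,
    k: int = 5,
    seed: int | None = None,
) -> RecoveryReport:
    """Generate a network, run CV, and score held-out pairs against the
    noise-free planted ground truth."""
    seed = spec.seed if seed is None else seed
    network, truth = generate_network(spec)
    report, details = evaluate_cv(
        network, model_config, train_config, k=k, seed=seed, return_details=True
    )
    clean = truth.clean["drdi"]
    gt_scores: list[float] = []
    gt_labels: list[int] = []
    for detail in details:
        fold = detail["fold"]
        for i, j in list(fold.test_positives) + list(fold.test_negatives):
            gt_scores.append(float(detail["scores"][i, j]))
            gt_labels.append(int(clean[i, j]))
    if len(set(gt_labels)) < 2:
        raise ValueError("ground-truth labels are single-class on held-out pairs")
    from sklearn.metrics import average_precision_score, roc_auc_score

    return RecoveryReport(
        cv=report,
        ground_truth_auc=float(roc_auc_score(gt_labels, gt_scores)),
        ground_truth_aupr=float(average_precision_score(gt_labels, gt_scores)),
    )
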