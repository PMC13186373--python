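"""Drug structural similarity, disease semantic similarity, and binarization.

Drug similarity is a Jaccard coefficient over precomputed substructure token
sets (the set-level analogue of maximal-common-substructure counting).
Disease similarity accumulates decayed semantic contributions over a
hierarchy of terms.  ``binarize_similarity`` turns a similarity matrix into
the binary homogeneous edge sets the network layer consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import scipy.sparse as sp

from .network import AssociationMatrix


class UndefinedSimilarityError(ValueError):
    """Similarity is undefined (e.g. both substructure sets empty)."""


@dataclass(frozen=True)
class SubstructureSet:
    """A drug's set of discrete substructure / fingerprint tokens."""

    entity_id: str
    features: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.features)


@dataclass(frozen=True)
class DiseaseDag:
    """Directed acyclic hierarchy of terms, child -> parent(s)."""

    terms: frozenset[str]
    parents: Mapping[str, frozenset[str]]  # child -> set of parents

    def __post_init__(self):
        for child, ps in self.parents.items():
            if child not in self.terms:
                raise ValueError(f"edge from unknown term {child!r}")
            for p in ps:
                if p not in self.terms:
                    raise ValueError(f"edge to unknown term {p!r}")
        if self._has_cycle():
            raise ValueError("disease hierarchy contains a cycle")

    def _has_cycle(self) -> bool:
        WHITE, GREY, BLACK = 0, 1, 2
        color = {t: WHITE for t in self.terms}
        for start in self.terms:
            if color[start] != WHITE:
                continue
            stack: list[tuple[str, Iterable[str]]] = [(start, iter(self.parents.get(start, ())))]
            color[start] = GREY
            while stack:
                node, it = stack[-1]
                advanced = False
                for nxt in it:
                    if color[nxt] == GREY:
                        return True
                    if color[nxt] == WHITE:
                        color[nxt] = GREY
                        stack.append((nxt, iter(self.parents.get(nxt, ()))))
                        advanced = True
                        break
                if not advanced:
                    color[node] = BLACK
                    stack.pop()
        return False

    @property
    def roots(self) -> frozenset[str]:
        return frozenset(t for t in self.terms if not self.parents.get(t))


@dataclass(frozen=True)
class ContributionMap:
    """Decayed semantic contribution of each ancestor term to one disease."""

    disease_id: str
    weights: Mapping[str, float] = field(default_factory=dict)

    @property
    def total(self) -> float:
        return float(sum(self.weights.values()))


@dataclass(frozen=True)
class SimilarityMatrix:
    entity_type: str
    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("similarity matrix shape does not match id list")
        if not np.allclose(v, v.T):
            raise ValueError("similarity matrix must be symmetric")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("similarity values must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return len(self.ids)


def jaccard_mcs_similarity(a: SubstructureSet, b: SubstructureSet) -> float:
    """|common| / (|a| + |b| - |common|); symmetric; errors if both empty."""
    if a.size == 0 and b.size == 0:
        raise UndefinedSimilarityError(
            f"similarity undefined: {a.entity_id!r} and {b.entity_id!r} are both empty"
        )
    common = len(a.features & b.features)
    return common / (a.size + b.size - common)


def semantic_contribution(
    disease_term: str, dag: DiseaseDag, decay: float = 0.5
) -> ContributionMap:
    """Self weight 1; every ancestor gets ``max over paths of decay**length``."""
    if disease_term not in dag.terms:
        raise KeyError(f"unknown term {disease_term!r}")
    if not (0 < decay < 1):
        raise ValueError("decay must be in (0, 1)")
    weights: dict[str, float] = {disease_term: 1.0}
    frontier = [disease_term]
    while frontier:
        nxt: list[str] = []
        for t in frontier:
            w = weights[t] * decay
            for p in dag.parents.get(t, ()):
                if w > weights.get(p, 0.0):
                    weights[p] = w
                    nxt.append(p)
        frontier = nxt
    return ContributionMap(disease_term, weights)


def disease_semantic_similarity(
    d1: str,
    d2: str,
    dag: DiseaseDag,
    decay: float = 0.5,
    mode: str = "literal",
    term_map: Mapping[str, str] | None = None,
) -> float:
    """Shared-ancestor semantic similarity between two diseases.

    The shared mass is ``sum over shared terms of (w1 + w2) / 2``.  In
    ``literal`` mode the result is ``mass / (total1 + total2)`` (identical
    diseases score 0.5); ``reconciled`` mode doubles the numerator so that
    identical diseases score 1.
    """
    if mode not in ("literal", "reconciled"):
        raise ValueError(f"unknown mode {mode!r}")
    t1 = term_map[d1] if term_map is not None else d1
    t2 = term_map[d2] if term_map is not None else d2
    cp1 = semantic_contribution(t1, dag, decay)
    cp2 = semantic_contribution(t2, dag, decay)
    shared = set(cp1.weights) & set(cp2.weights)
    mass = sum((cp1.weights[t] + cp2.weights[t]) / 2.0 for t in shared)
    value = mass / (cp1.total + cp2.total)
    return 2.0 * value if mode == "reconciled" else value


def drug_similarity_matrix(sets: Iterable[SubstructureSet]) -> SimilarityMatrix:
    sets = list(sets)
    ids = tuple(s.entity_id for s in sets)
    n = len(sets)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = jaccard_mcs_similarity(sets[i], sets[j])
    return SimilarityMatrix("drug", ids, values)


def disease_similarity_matrix(
    disease_ids: Iterable[str],
    dag: DiseaseDag,
    term_map: Mapping[str, str] | None = None,
    decay: float = 0.5,
    mode: str = "literal",
) -> SimilarityMatrix:
    ids = tuple(disease_ids)
    n = len(ids)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            values[i, j] = values[j, i] = disease_semantic_similarity(
                ids[i], ids[j], dag, decay=decay, mode=mode, term_map=term_map
            )
    return SimilarityMatrix("disease", ids, values)


def binarize_similarity(
    s: SimilarityMatrix,
    threshold: float | None = None,
    target_density: float | None = None,
) -> AssociationMatrix:
    """Turn a similarity matrix into a symmetric binary edge set (zero diag).

    ``threshold`` keeps off-diagonal entries strictly greater than the value.
    ``target_density`` instead picks the largest cutoff whose resulting
    off-diagonal density reaches the target, keeping every tied entry.
    """
    if (threshold is None) == (target_density is None):
        raise ValueError("provide exactly one of threshold / target_density")
    v = s.values.copy()
    np.fill_diagonal(v, 0.0)
    if target_density is not None:
        if not (0 <= target_density <= 1):
            raise ValueError("target_density must lie in [0, 1]")
        need = target_density * s.n * s.n
        if need <= 0:
            adj = np.zeros_like(v, dtype=bool)
        else:
            off = v[~np.eye(s.n, dtype=bool)]
            order = np.sort(off)[::-1]
            k = min(int(np.ceil(need)), off.size)
            cutoff = order[k - 1]
            adj = (v >= cutoff) & ~np.eye(s.n, dtype=bool)
    else:
        adj = (v > threshold) & ~np.eye(s.n, dtype=bool)
    return AssociationMatrix(s.entity_type, s.entity_type, sp.csr_matrix(adj.astype(float)))


# ---------------------------------------------------------------------------
# I/O for the two-column TSV interfaces


def load_substructure_sets(path: str) -> dict[str, SubstructureSet]:
    """Two-column TSV (entity_id, token), one token per row."""
    tokens: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            entity_id, token = line.split("\t")
            tokens.setdefault(entity_id, set()).add(token)
    return {
        eid: SubstructureSet(eid, frozenset(toks)) for eid, toks in tokens.items()
    }


def load_disease_dag(path: str) -> DiseaseDag:
    """Two-column TSV (child_term, parent_term)."""
    parents: dict[str, set[str]] = {}
    terms: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            child, parent = line.split("\t")
            terms.update((child, parent))
            parents.setdefault(child, set()).add(parent)
    return DiseaseDag(frozenset(terms), {c: frozenset(p) for c, p in parents.items()})


def load_term_map(path: str) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            disease, term = line.split("\t")
            out[disease] = term
    return out


def write_similarity_matrix(path: str, s: SimilarityMatrix) -> None:
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(s.ids) + "\n")
        for i, row_id in enumerate(s.ids):
            fh.write(row_id + "\t" + "\t".join(f"{x:.8f}" for x in s.values[i]) + "\n")


def load_similarity_matrix(path: str, entity_type: str) -> SimilarityMatrix:
    with open(path) as fh:
        ids = tuple(fh.readline().rstrip("\n").split("\t")[1:])
        values = np.array(
            [[float(x) for x in line.rstrip("\n").split("\t")[1:]] for line in fh]
        )
    return SimilarityMatrix(entity_type, ids, values)
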