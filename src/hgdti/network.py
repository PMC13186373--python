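"""Entity catalogs, typed association matrices and the heterogeneous network.

The network bundles four entity types (drug, disease, gene, protein) and nine
binary relations.  Homogeneous relations (drug-drug, disease-disease,
gene-gene, protein-protein) are stored with both orientations so that the
edge count divided by n^2 reproduces the conventional density accounting.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp
import yaml

ENTITY_TYPES = ("drug", "disease", "gene", "protein")

#: canonical relation name -> (row entity type, column entity type)
RELATION_TYPES: dict[str, tuple[str, str]] = {
    "drdr": ("drug", "drug"),
    "didi": ("disease", "disease"),
    "gg": ("gene", "gene"),
    "pp": ("protein", "protein"),
    "drdi": ("drug", "disease"),
    "drg": ("drug", "gene"),
    "drp": ("drug", "protein"),
    "dig": ("disease", "gene"),
    "dip": ("disease", "protein"),
}

#: meta-path schemas as ordered entity-type sequences
METAPATHS: dict[str, tuple[str, ...]] = {
    "drdi": ("drug", "disease"),
    "drgdi": ("drug", "gene", "disease"),
    "drpdi": ("drug", "protein", "disease"),
    "drgpdi": ("drug", "gene", "protein", "disease"),
}


class ValidationError(ValueError):
    """Raised when an input file or matrix violates the network contracts."""


@dataclass(frozen=True)
class EntityCatalog:
    """Ordered identifier list for one entity type; the id<->index authority."""

    entity_type: str
    ids: tuple[str, ...]

    def __post_init__(self):
        if self.entity_type not in ENTITY_TYPES:
            raise ValidationError(f"unknown entity type {self.entity_type!r}")
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError(f"duplicate ids in {self.entity_type} catalog")
        object.__setattr__(self, "_index", {i: k for k, i in enumerate(self.ids)})

    @property
    def n(self) -> int:
        return len(self.ids)

    def index(self, entity_id: str) -> int:
        try:
            return self._index[entity_id]
        except KeyError:
            raise KeyError(f"unknown {self.entity_type} id {entity_id!r}") from None

    def __contains__(self, entity_id: str) -> bool:
        return entity_id in self._index


class AssociationMatrix:
    """Binary relation matrix between two entity types.

    ``symmetric`` defaults to ``type_a == type_b``; symmetric matrices must
    equal their transpose and carry a zero diagonal, and their ``count``
    includes both orientations of every undirected pair.
    """

    def __init__(self, type_a: str, type_b: str, values, symmetric: bool | None = None):
        self.type_a = type_a
        self.type_b = type_b
        v = sp.csr_matrix(values, dtype=np.float64)
        v.data = np.ones_like(v.data)  # binarize defensively
        v.eliminate_zeros()
        self.values = v
        self.symmetric = (type_a == type_b) if symmetric is None else symmetric
        self._validate()

    def _validate(self) -> None:
        if self.symmetric:
            if self.type_a != self.type_b:
                raise ValidationError("symmetric flag requires matching entity types")
            if self.values.diagonal().any():
                raise ValidationError("symmetric relation must have a zero diagonal")
            if (self.values != self.values.T).nnz != 0:
                raise ValidationError("symmetric relation matrix is not symmetric")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def count(self) -> int:
        return int(self.values.nnz)

    def pairs(self) -> list[tuple[int, int]]:
        coo = self.values.tocoo()
        return sorted(zip(coo.row.tolist(), coo.col.tolist()))

    def toarray(self) -> np.ndarray:
        return self.values.toarray()

    def copy(self) -> "AssociationMatrix":
        return AssociationMatrix(self.type_a, self.type_b, self.values.copy(), self.symmetric)


@dataclass
class NormalizedAdjacency:
    """Symmetrically degree-normalized adjacency with self-loops added."""

    values: sp.csr_matrix
    base_shape: tuple[int, int]


@dataclass
class HeteroNetwork:
    """Four catalogs, nine relations and the meta-path registry."""

    catalogs: dict[str, EntityCatalog]
    relations: dict[str, AssociationMatrix]
    metapaths: dict[str, tuple[str, ...]] = field(default_factory=lambda: dict(METAPATHS))

    def __post_init__(self):
        for t in ENTITY_TYPES:
            if t not in self.catalogs:
                raise ValidationError(f"missing catalog for entity type {t!r}")
        for name, (ta, tb) in RELATION_TYPES.items():
            if name not in self.relations:
                raise ValidationError(f"missing relation slot {name!r}")
            m = self.relations[name]
            if m.shape != (self.catalogs[ta].n, self.catalogs[tb].n):
                raise ValidationError(
                    f"relation {name}: shape {m.shape} does not match catalogs "
                    f"({self.catalogs[ta].n}, {self.catalogs[tb].n})"
                )

    def n(self, entity_type: str) -> int:
        return self.catalogs[entity_type].n

    def masked(self, mask: Mapping[str, Sequence[tuple[int, int]]]) -> "HeteroNetwork":
        """Return a copy with the given positives zeroed per relation."""
        relations = {
            name: mask_positives(m, mask[name]) if name in mask else m.copy()
            for name, m in self.relations.items()
        }
        return HeteroNetwork(self.catalogs, relations, dict(self.metapaths))


def empty_relation(name: str, catalogs: Mapping[str, EntityCatalog]) -> AssociationMatrix:
    ta, tb = RELATION_TYPES[name]
    return AssociationMatrix(ta, tb, sp.csr_matrix((catalogs[ta].n, catalogs[tb].n)))


def load_edge_table(
    path: str,
    type_a: str,
    type_b: str,
    catalogs: Mapping[str, EntityCatalog],
    strict: bool = True,
) -> AssociationMatrix:
    """Load a headered two-column TSV of id pairs into a binary matrix.

    For homogeneous relations both orientations are stored.  In strict mode an
    unknown id raises a :class:`ValidationError` naming the id and line; with
    ``strict=False`` such rows are dropped.
    """
    cat_a, cat_b = catalogs[type_a], catalogs[type_b]
    rows_i: list[int] = []
    cols_j: list[int] = []
    with open(path) as fh:
        header = fh.readline()
        if header.strip() and len(header.rstrip("\n").split("\t")) != 2:
            raise ValidationError(f"{path}: expected a two-column TSV header")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValidationError(f"{path}:{lineno}: expected two columns")
            a, b = parts
            if a not in cat_a:
                if strict:
                    raise ValidationError(f"{path}:{lineno}: unknown {type_a} id {a!r}")
                continue
            if b not in cat_b:
                if strict:
                    raise ValidationError(f"{path}:{lineno}: unknown {type_b} id {b!r}")
                continue
            i, j = cat_a.index(a), cat_b.index(b)
            if type_a == type_b and i == j:
                continue  # self-pairs are not edges; self-loops enter at normalization
            rows_i.append(i)
            cols_j.append(j)
            if type_a == type_b:
                rows_i.append(j)
                cols_j.append(i)
    m = sp.csr_matrix(
        (np.ones(len(rows_i)), (rows_i, cols_j)), shape=(cat_a.n, cat_b.n)
    )
    m.data = np.ones_like(m.data)  # collapse duplicates
    return AssociationMatrix(type_a, type_b, m)


def write_edge_table(path: str, m: AssociationMatrix, catalogs: Mapping[str, EntityCatalog]) -> None:
    """Inverse of :func:`load_edge_table`; symmetric pairs written once (i<j)."""
    cat_a, cat_b = catalogs[m.type_a], catalogs[m.type_b]
    with open(path, "w") as fh:
        fh.write(f"{m.type_a}_id\t{m.type_b}_id\n")
        for i, j in m.pairs():
            if m.symmetric and i > j:
                continue
            fh.write(f"{cat_a.ids[i]}\t{cat_b.ids[j]}\n")


def network_density(m: AssociationMatrix) -> float:
    """Fraction of known associations among all possible entity pairs."""
    n_a, n_b = m.shape
    if n_a == 0 or n_b == 0:
        raise ZeroDivisionError("density undefined for an empty catalog")
    return m.count / (n_a * n_b)


def normalize_adjacency(m: AssociationMatrix | sp.spmatrix) -> NormalizedAdjacency:
    """Return ``D^{-1/2} (A + I) D^{-1/2}`` with D the degree of ``A + I``."""
    a = m.values if isinstance(m, AssociationMatrix) else sp.csr_matrix(m)
    n_a, n_b = a.shape
    if n_a != n_b:
        raise ValidationError("normalize_adjacency requires a square matrix")
    a_tilde = (a + sp.identity(n_a, format="csr")).tocsr()
    deg = np.asarray(a_tilde.sum(axis=1)).ravel()
    d_inv_sqrt = 1.0 / np.sqrt(deg)  # self-loop guarantees deg >= 1
    d = sp.diags(d_inv_sqrt)
    return NormalizedAdjacency(values=(d @ a_tilde @ d).tocsr(), base_shape=a.shape)


def bipartite_block(m: AssociationMatrix) -> NormalizedAdjacency:
    """Normalize the stacked block matrix ``[[I, A], [A^T, I]]``.

    The identity blocks double as the self-loops, so normalization
    is applied to the off-diagonal association blocks with the block identity
    kept intact (degree counts the self-loop once, exactly as
    :func:`normalize_adjacency` does for the square case).
    """
    a = m.values
    n_a, n_b = a.shape
    block = sp.bmat([[None, a], [a.T, None]], format="csr")
    na = normalize_adjacency(block)
    na.base_shape = (n_a + n_b, n_a + n_b)
    return na


def mask_positives(
    m: AssociationMatrix, pairs: Iterable[tuple[int, int]]
) -> AssociationMatrix:
    """Copy ``m`` with the listed entries set to zero (both orientations for
    symmetric relations).  Out-of-range pairs raise ``IndexError``."""
    v = m.values.tolil()
    n_a, n_b = m.shape
    for i, j in pairs:
        if not (0 <= i < n_a and 0 <= j < n_b):
            raise IndexError(f"pair ({i}, {j}) out of range for shape {m.shape}")
        v[i, j] = 0
        if m.symmetric:
            v[j, i] = 0
    return AssociationMatrix(m.type_a, m.type_b, v.tocsr(), m.symmetric)


# ---------------------------------------------------------------------------
# bundle I/O


def write_catalog(path: str, catalog: EntityCatalog) -> None:
    with open(path, "w") as fh:
        for i in catalog.ids:
            fh.write(i + "\n")


def load_catalog(path: str, entity_type: str) -> EntityCatalog:
    with open(path) as fh:
        ids = tuple(line.strip() for line in fh if line.strip())
    return EntityCatalog(entity_type, ids)


def write_bundle(network: HeteroNetwork, out_dir: str, extra_manifest: dict | None = None) -> None:
    """Write the on-disk bundle: catalogs, nine relation TSVs, YAML manifest."""
    os.makedirs(os.path.join(out_dir, "catalogs"), exist_ok=True)
    os.makedirs(os.path.join(out_dir, "relations"), exist_ok=True)
    manifest: dict = {"catalogs": {}, "relations": {}}
    for t in ENTITY_TYPES:
        rel = os.path.join("catalogs", f"{t}.txt")
        write_catalog(os.path.join(out_dir, rel), network.catalogs[t])
        manifest["catalogs"][t] = rel
    for name, m in network.relations.items():
        rel = os.path.join("relations", f"{name}.tsv")
        write_edge_table(os.path.join(out_dir, rel), m, network.catalogs)
        manifest["relations"][name] = rel
    if extra_manifest:
        manifest.update(extra_manifest)
    with open(os.path.join(out_dir, "manifest.yaml"), "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)


def load_bundle(bundle_dir: str, strict: bool = True) -> HeteroNetwork:
    with open(os.path.join(bundle_dir, "manifest.yaml")) as fh:
        manifest = yaml.safe_load(fh)
    catalogs = {
        t: load_catalog(os.path.join(bundle_dir, rel), t)
        for t, rel in manifest["catalogs"].items()
    }
    relations = {}
    for name, rel in manifest["relations"].items():
        ta, tb = RELATION_TYPES[name]
        relations[name] = load_edge_table(
            os.path.join(bundle_dir, rel), ta, tb, catalogs, strict=strict
        )
    return HeteroNetwork(catalogs, relations)
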