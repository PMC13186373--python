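import numpy as np
import pytest
import scipy.sparse as sp

from hgdti.network import (
    RELATION_TYPES,
    AssociationMatrix,
    EntityCatalog,
    HeteroNetwork,
)


def make_catalogs(n_dr=4, n_di=3, n_g=5, n_p=2):
    return {
        "drug": EntityCatalog("drug", tuple(f"dr{i}" for i in range(n_dr))),
        "disease": EntityCatalog("disease", tuple(f"di{i}" for i in range(n_di))),
        "gene": EntityCatalog("gene", tuple(f"g{i}" for i in range(n_g))),
        "protein": EntityCatalog("protein", tuple(f"p{i}" for i in range(n_p))),
    }


def random_network(n_dr=4, n_di=3, n_g=5, n_p=2, seed=0, density=0.4):
    """Small random heterogeneous network for oracle tests."""
    rng = np.random.default_rng(seed)
    catalogs = make_catalogs(n_dr, n_di, n_g, n_p)
    relations = {}
    for name, (ta, tb) in RELATION_TYPES.items():
        n_a, n_b = catalogs[ta].n, catalogs[tb].n
        if ta == tb:
            upper = rng.random((n_a, n_a)) < density
            m = np.triu(upper, k=1)
            m = m + m.T
        else:
            m = rng.random((n_a, n_b)) < density
        relations[name] = AssociationMatrix(ta, tb, sp.csr_matrix(m.astype(float)))
    return HeteroNetwork(catalogs, relations)


@pytest.fixture
def tiny_network():
    return random_network(4, 3, 5, 2, seed=42)


@pytest.fixture
def catalogs():
    return make_catalogs()
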