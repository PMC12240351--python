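import numpy as np
import pytest

from entroqspr import datasets, edge_partition, gen_graph, partition_from_counts

#: an explicit 15-vertex, 17-edge realization of the Oxaliplatin
#: degree structure: cyclohexane ring with two amine bridges to a
#: 4-coordinate metal centre closing over an oxalate moiety
OXALIPLATIN_EDGES = """
C1 C2
C2 C3
C3 C4
C4 C5
C5 C6
C6 C1
C1 N1
C2 N2
N1 Pt
N2 Pt
Pt O1
Pt O2
O1 C7
O2 C8
C7 C8
C7 O3
C8 O4
"""

OXALIPLATIN_CELLS = {(1, 3): 2, (2, 3): 6, (2, 2): 3, (2, 4): 4, (3, 3): 2}


@pytest.fixture(scope="session")
def oxaliplatin():
    return datasets.oxaliplatin_partition()


@pytest.fixture(scope="session")
def drug_entropies():
    return datasets.load_drug_entropies()


@pytest.fixture(scope="session")
def drug_properties():
    return datasets.load_drug_properties()


@pytest.fixture(scope="session")
def random_partitions():
    """100 partitions of random chemistry-like graphs, with their graphs."""
    out = []
    for i in range(100):
        rng = np.random.default_rng(1000 + i)
        n = int(rng.integers(4, 30))
        g = gen_graph(n, max_degree=4, ring_prob=0.4, seed=rng, name=f"g{i}")
        out.append((g, edge_partition(g)))
    return out


@pytest.fixture
def path4():
    return partition_from_counts([(1, 2, 2), (2, 2, 1)])
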