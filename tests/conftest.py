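import networkx as nx
import numpy as np
import pytest

from hiertier.connectome import BinaryConnectome, NodeTable


def graph_from_edges(edges, n):
    A = np.zeros((n, n), dtype=np.int8)
    for i, j in edges:
        A[i, j] = A[j, i] = 1
    return BinaryConnectome(A, NodeTable.trivial(n))


def random_connectome(n, p, seed):
    g = nx.gnp_random_graph(n, p, seed=seed)
    A = nx.to_numpy_array(g, nodelist=range(n)).astype(np.int8)
    return BinaryConnectome(A, NodeTable.trivial(n))


def brute_force_hc(G):
    """Literal nested-loop transcription of the hierarchical-complexity sum.

    Independent of the vectorized implementation: plain Python loops over
    degree classes, sequence positions and class members.
    """
    A = np.asarray(G.A)
    n = A.shape[0]
    degrees = [int(A[i].sum()) for i in range(n)]
    distinct = sorted(set(degrees))
    D = len(distinct)
    total = 0.0
    any_class = False
    for p in distinct:
        members = [i for i in range(n) if degrees[i] == p]
        if len(members) <= 1:
            continue
        any_class = True
        if p == 0:
            continue
        seqs = []
        for i in members:
            s = sorted(degrees[j] for j in range(n) if A[i, j])
            seqs.append(s)
        inner = 0.0
        for j in range(p):
            mu = sum(s[j] for s in seqs) / len(seqs)
            for s in seqs:
                inner += (s[j] - mu) ** 2
        total += inner / (p * (len(members) - 1))
    if not any_class:
        return 0.0
    return total / D


@pytest.fixture
def chord_cycle():
    """5-cycle with one chord: degrees (3,2,3,2,2), R = 1/12."""
    return graph_from_edges([(0, 1), (1, 2), (2, 3), (3, 4), (4, 0), (0, 2)], 5)
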