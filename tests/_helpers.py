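"""Shared test utilities: random trees, additive matrices, small simulations."""

import numpy as np

from meplace.seqio import Topology


def random_topology(n, rng, with_lengths=True, lo=0.05, hi=0.3):
    """Random unrooted binary topology via sequential random attachment."""

    def L():
        return float(rng.uniform(lo, hi)) if with_lengths else None

    spec = (None, None, [("t0", L(), []), ("t1", L(), []), ("t2", L(), [])])
    topo = Topology.from_spec(spec)
    for k in range(3, n):
        e = int(rng.integers(topo.n_edges))
        topo = topo.insert_on_edge(e, f"t{k}", pendant_length=L())
        if with_lengths:
            # insert_on_edge halves the split edge; re-draw the pendant length
            pass
    return topo


def additive_matrix(topo):
    """Leaf labels and the exact path-length distance matrix."""
    return topo.leaf_path_distance_matrix()


def random_distance_matrix(n, rng, lo=0.05, hi=1.0):
    D = rng.uniform(lo, hi, (n, n))
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return D


def lstsq_branch_lengths(topo, D, order):
    """Independent OLS oracle: solve the path design matrix by least squares."""
    import itertools

    pos = {lab: k for k, lab in enumerate(order)}
    leaves = topo.leaves
    pairs = list(itertools.combinations(range(len(leaves)), 2))
    X = np.zeros((len(pairs), topo.n_edges))
    y = np.zeros(len(pairs))
    for r, (i, j) in enumerate(pairs):
        vi, vj = leaves[i], leaves[j]
        anc = set()
        v = vi
        while v != -1:
            anc.add(v)
            v = topo.parent[v]
        path = []
        v = vj
        while v not in anc:
            path.append(v - 1)
            v = topo.parent[v]
        top = v
        v = vi
        while v != top:
            path.append(v - 1)
            v = topo.parent[v]
        for e in path:
            X[r, e] = 1.0
        y[r] = D[pos[topo.label[vi]], pos[topo.label[vj]]]
    sol, *_ = np.linalg.lstsq(X, y, rcond=None)
    return sol


def pauplin_length(topo, D, order):
    """Balanced (BME) total tree length by Pauplin's formula: an independent
    oracle for the balanced criterion."""
    pos = {lab: k for k, lab in enumerate(order)}
    leaves = topo.leaves
    total = 0.0
    for i in range(len(leaves)):
        for j in range(i + 1, len(leaves)):
            p = _topo_dist(topo, leaves[i], leaves[j])
            total += 2.0 ** (1 - p) * D[
                pos[topo.label[leaves[i]]], pos[topo.label[leaves[j]]]
            ]
    return total


def _topo_dist(topo, x, y):
    da = {}
    v, d = x, 0
    while v != -1:
        da[v] = d
        v = topo.parent[v]
        d += 1
    v, d = y, 0
    while v != -1:
        if v in da:
            return da[v] + d
        v = topo.parent[v]
        d += 1
    raise AssertionError
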