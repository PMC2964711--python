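"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own graph/tree code paths: the
parsimony oracle works on the full site hypercube with a Dreyfus-Wagner
dynamic program, and the rho/sigma oracle enumerates root-to-tip paths
explicitly.
"""

from __future__ import annotations

import numpy as np


def exhaustive_parsimony(vectors, weights=None) -> float:
    """Exact minimum Steiner-tree length connecting binary state vectors in
    the site hypercube (= the most-parsimonious tree length).

    ``vectors``: iterable of equal-length 0/1 sequences (the terminals).
    ``weights``: per-site weights (default 1).
    """
    terms = sorted({tuple(int(x) for x in v) for v in vectors})
    if not terms:
        return 0.0
    k = len(terms[0])
    if k == 0 or len(terms) == 1:
        return 0.0
    if k > 16:
        raise ValueError("hypercube oracle limited to 16 sites")
    w = np.ones(k) if weights is None else np.asarray(weights, dtype=float)
    V = 1 << k
    t = len(terms)
    term_ids = [sum(b << i for i, b in enumerate(v)) for v in terms]
    INF = np.inf
    dp = np.full((1 << t, V), INF)
    for i, tid in enumerate(term_ids):
        dp[1 << i, tid] = 0.0

    def relax(row):
        # Bellman-Ford over hypercube edges, vectorised per site bit
        while True:
            before = row.copy()
            for b in range(k):
                idx = np.arange(V) ^ (1 << b)
                np.minimum(row, row[idx] + w[b], out=row)
            if np.array_equal(before, row):
                return row

    for mask in range(1, 1 << t):
        sub = (mask - 1) & mask
        while sub:
            other = mask ^ sub
            if sub < other:
                np.minimum(dp[mask], dp[sub] + dp[other], out=dp[mask])
            sub = (sub - 1) & mask
        relax(dp[mask])
    return float(dp[(1 << t) - 1].min())


def brute_rho_sigma(tree, class_filter, root=None):
    """Recompute rho and sigma by explicit path enumeration.

    Collects every node's root path as a flat mutation list, weights by node
    multiplicity, and evaluates sigma by counting, for every edge, the
    individuals whose path passes through it.
    """
    root = root if root is not None else tree.root

    paths = []  # (node, list of edges on root->node path)

    def collect(node, edges):
        paths.append((node, list(edges)))
        for c in node.children:
            collect(c, edges + [c])

    collect(root, [])
    n = sum(node.multiplicity for node, _ in paths)
    count = lambda edge_node: sum(1 for m in edge_node.edge if class_filter(m))
    rho = sum(node.multiplicity * sum(count(e) for e in edges)
              for node, edges in paths) / n
    # sigma: for each edge (represented by its child node), individuals below
    var = 0.0
    all_edges = {id(e): e for _, edges in paths for e in edges}
    for e in all_edges.values():
        below = sum(node.multiplicity for node, edges in paths
                    if any(x is e for x in edges))
        var += (below / n) ** 2 * count(e)
    return rho, var ** 0.5, n
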