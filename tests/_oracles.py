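"""Independent oracles shared by unit and acceptance tests.

These deliberately re-derive results from first principles (brute force,
exhaustive enumeration) and never call the implementation paths they check.
"""

import itertools

import numpy as np


def brute_force_wpgma(names, D):
    """WPGMA linkage with the inter-cluster distance recomputed from scratch
    (stored pairwise table rebuilt) after every merge."""
    clusters = {i: (i,) for i in range(len(names))}
    dist = {(i, j): D[i, j] for i in range(len(names)) for j in range(len(names)) if i < j}
    merges = []
    next_id = len(names)
    while len(clusters) > 1:
        best = None
        for i in sorted(clusters):
            for j in sorted(clusters):
                if j <= i:
                    continue
                d = dist[(i, j)]
                key = (d, min(names[min(clusters[i])], names[min(clusters[j])]),
                       max(names[min(clusters[i])], names[min(clusters[j])]))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, a, b = best
        merges.append((a, b, dist[(a, b)]))
        for k in sorted(clusters):
            if k in (a, b):
                continue
            dist[(min(k, next_id), max(k, next_id))] = (
                dist[(min(a, k), max(a, k))] + dist[(min(b, k), max(b, k))]
            ) / 2.0
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return merges


def mww_exact_p_enumeration(a, b):
    """Exhaustive two-sided Mann-Whitney p-value over all C(n, na) splits."""
    pooled = np.concatenate([a, b])
    na = len(a)
    n = len(pooled)

    def u_stat(idx_a):
        aa = pooled[list(idx_a)]
        bb = pooled[[i for i in range(n) if i not in idx_a]]
        return sum((x > y) + 0.5 * (x == y) for x in aa for y in bb)

    observed = u_stat(tuple(range(na)))
    us = [u_stat(c) for c in itertools.combinations(range(n), na)]
    mean_u = len(a) * len(b) / 2
    dev = abs(observed - mean_u)
    count = sum(abs(u - mean_u) >= dev - 1e-12 for u in us)
    return count / len(us)
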