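"""Shared brute-force Ward.D2 oracle used by the clustering tests."""

import numpy as np

from floodmeadow import community as comm


def ward_d2_oracle(d: np.ndarray):
    """Naive Lance–Williams Ward.D2 agglomeration, scanning all pairs.

    Maintains squared inter-cluster dissimilarities, merges the cheapest
    pair at every step and reports heights on the dissimilarity scale.
    """
    n = d.shape[0]
    clusters = {i: frozenset([i]) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    active = list(range(n))
    dist = {
        frozenset((i, j)): float(d[i, j]) ** 2
        for i in range(n)
        for j in range(i + 1, n)
    }
    heights, merges = [], []
    next_id = n
    while len(active) > 1:
        best = min(
            (frozenset((i, j)) for i in active for j in active if i < j),
            key=lambda pair: dist[pair],
        )
        i, j = sorted(best)
        h2 = dist[best]
        heights.append(np.sqrt(h2))
        merged = clusters[i] | clusters[j]
        merges.append(merged)
        ni, nj = sizes[i], sizes[j]
        for k in active:
            if k in (i, j):
                continue
            nk = sizes[k]
            dik = dist[frozenset((i, k))]
            djk = dist[frozenset((j, k))]
            dist[frozenset((next_id, k))] = (
                (ni + nk) * dik + (nj + nk) * djk - nk * h2
            ) / (ni + nj + nk)
        clusters[next_id] = merged
        sizes[next_id] = ni + nj
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1
    return heights, merges


def oracle_partition(merges, n, k):
    parts = [frozenset([i]) for i in range(n)]
    for merged in merges[: n - k]:
        parts = [p for p in parts if not p <= merged] + [merged]
    return set(parts)


def scipy_partition(result, k):
    assignment = comm.cut_clusters(result, k)
    groups = {}
    for idx, lab in enumerate(result.labels):
        groups.setdefault(assignment.labels[lab], set()).add(idx)
    return {frozenset(g) for g in groups.values()}
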