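"""Independent brute-force reference implementations used only by tests.

These are written directly from the procedure definitions, with no shared
code paths with the package: repeated full scans instead of sorted pair
lists, plain nested loops instead of incremental bookkeeping.
"""

from __future__ import annotations


def naive_chain_probability(seq: str, initial: dict, transitions: dict,
                            order: int) -> float:
    """Plain product over hand-indexed factors of an order-h chain.

    ``transitions`` maps 1-based position -> {context: {base: prob}}.
    """
    p = initial.get(seq[:order], 0.0)
    for j in range(order + 1, len(seq) + 1):
        ctx = seq[j - 1 - order:j - 1]
        base = seq[j - 1]
        p = p * transitions.get(j, {}).get(ctx, {}).get(base, 0.0)
    return p


def naive_mini_clusters(values: list[float]) -> list[set[int]]:
    """O(n^3) realization of the nearest-pair mini-cluster agglomeration.

    Every step rescans all pairs from scratch: find the closest pair of
    both-unassigned elements (ties by smaller, then larger, index); the
    first such pair founds the first cluster; later pairs either join the
    clusters of their nearest assigned elements (when either member is at
    least as close to an assigned element as to its partner) or found a
    new cluster; a final leftover joins its nearest assigned element.
    """
    n = len(values)
    if n == 1:
        return [{0}]
    cluster_of: dict[int, int] = {}
    clusters: list[set[int]] = []

    def dist(i, j):
        return (values[i] - values[j]) ** 2

    while True:
        best = None
        for i in range(n):
            for j in range(i + 1, n):
                if i in cluster_of or j in cluster_of:
                    continue
                cand = (dist(i, j), i, j)
                if best is None or cand < best:
                    best = cand
        if best is None:
            break
        d, i, j = best
        if not clusters:
            clusters.append({i, j})
            cluster_of[i] = cluster_of[j] = 0
            continue
        near = {}
        for m in (i, j):
            options = [(dist(m, k), k) for k in cluster_of]
            options.sort()
            near[m] = options[0]
        if near[i][0] <= d or near[j][0] <= d:
            for m in (i, j):
                cid = cluster_of[near[m][1]]
                clusters[cid].add(m)
                cluster_of[m] = cid
        else:
            clusters.append({i, j})
            cluster_of[i] = cluster_of[j] = len(clusters) - 1

    for m in range(n):
        if m not in cluster_of:
            options = sorted((dist(m, k), k) for k in cluster_of)
            cid = cluster_of[options[0][1]]
            clusters[cid].add(m)
            cluster_of[m] = cid
    return clusters


def naive_best_kmeans_partition(values: list[float], k: int) -> float:
    """Minimum SSE over ALL k-labelings (exponential; tiny n only)."""
    from itertools import product

    n = len(values)
    best = float("inf")
    for labels in product(range(k), repeat=n):
        if len(set(labels)) != k:
            continue
        sse = 0.0
        for c in range(k):
            members = [values[i] for i in range(n) if labels[i] == c]
            mu = sum(members) / len(members)
            sse += sum((x - mu) ** 2 for x in members)
        best = min(best, sse)
    return best
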