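"""Mini-cluster agglomeration on one-dimensional probability features.

Instead of forcing a single effective/ineffective boundary on the relative
mean probability axis, sequences are grouped into many small clusters of
near-identical score ("mini-clusters"), each cluster inherits a label from
its members with known efficacy, and label-free clusters are merged into
the nearest labelled one.

Agglomeration rule (nearest-pair, one pass over all pairs sorted by
squared-difference distance):

1. Sort all unordered index pairs ascending by (distance, smaller index,
   larger index).
2. Take the first pair whose members are BOTH unassigned.  If no cluster
   exists yet they found cluster 1.  Otherwise compute each member's
   minimum distance to any already-assigned element: if for either member
   that distance is <= the pair distance, each member joins the cluster of
   its own nearest assigned element; otherwise the pair founds a new
   cluster.
3. Repeat until no both-unassigned pair remains.
4. A final leftover element (at most one can remain) joins the cluster of
   its nearest assigned element.

The non-strict comparison in step 2 guarantees that tied feature values
always end up in one cluster.  Pairs with exactly one assigned member are
skipped; their unassigned member is captured by step 2's closer-to-cluster
branch or by the leftover rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .records import EFFECTIVE, INEFFECTIVE, UNCERTAIN


class NoDeterminedClusterError(ValueError):
    """Merging was requested but no cluster carries a known efficacy label:
    no training label reached any cluster."""


def pairwise_distance(qa: float, qb: float) -> float:
    """Squared difference of two feature values (symmetric, 0 iff equal)."""
    d = float(qa) - float(qb)
    return d * d


@dataclass
class MiniCluster:
    """A mini-cluster: member indices plus an efficacy label.

    Label semantics: ``effective`` if at least one member has a known
    effective label; ``ineffective`` if all known-labelled members are
    ineffective (and at least one exists); ``uncertain`` if no member has a
    known label.
    """

    members: set[int] = field(default_factory=set)
    label: str = UNCERTAIN


@dataclass
class Clustering:
    """A partition of sequence indices 0..n-1 into mini-clusters."""

    clusters: list[MiniCluster]
    n: int

    def assignments(self) -> list[int]:
        """Cluster id (creation order, 0-based) per sequence index."""
        out = [-1] * self.n
        for cid, c in enumerate(self.clusters):
            for i in c.members:
                out[i] = cid
        return out

    def labels(self) -> list[str]:
        """Cluster label per sequence index."""
        out = [UNCERTAIN] * self.n
        for c in self.clusters:
            for i in c.members:
                out[i] = c.label
        return out

    def check_partition(self) -> None:
        seen: set[int] = set()
        for c in self.clusters:
            if not c.members:
                raise ValueError("empty mini-cluster")
            if seen & c.members:
                raise ValueError("overlapping mini-clusters")
            seen |= c.members
        if seen != set(range(self.n)):
            raise ValueError("clusters do not cover all indices")


def build_mini_clusters(values: Sequence[float]) -> Clustering:
    """Agglomerate 1-D feature values into mini-clusters (rule in module doc).

    ``values`` is the clustering feature per sequence — the relative mean
    probability Q4 by default in the full pipeline, any of Q1..Q3 when
    configured.  Clusters are numbered in creation order; all sequences
    with identical values are guaranteed to share a cluster.
    """
    n = len(values)
    if n == 0:
        raise ValueError("cannot cluster an empty value list")
    v = [float(x) for x in values]
    if n == 1:
        return Clustering([MiniCluster({0})], 1)

    pairs = sorted(((pairwise_distance(v[i], v[j]), i, j)
                    for i in range(n) for j in range(i + 1, n)))
    assigned: dict[int, int] = {}  # index -> cluster id
    clusters: list[set[int]] = []

    def nearest_assigned(i: int) -> tuple[float, int]:
        # (distance, cluster id) of i's nearest already-assigned element;
        # ties resolved toward the element of smallest index
        best = (float("inf"), -1, -1)
        for k, cid in assigned.items():
            best = min(best, (pairwise_distance(v[i], v[k]), k, cid))
        return best[0], best[2]

    for d, i, j in pairs:
        if i in assigned or j in assigned:
            continue
        if not clusters:
            clusters.append({i, j})
            assigned[i] = assigned[j] = 0
            continue
        di, ci = nearest_assigned(i)
        dj, cj = nearest_assigned(j)
        if di <= d or dj <= d:
            clusters[ci].add(i)
            assigned[i] = ci
            clusters[cj].add(j)
            assigned[j] = cj
        else:
            clusters.append({i, j})
            assigned[i] = assigned[j] = len(clusters) - 1

    leftovers = [i for i in range(n) if i not in assigned]
    for i in leftovers:  # at most one when n >= 2
        _, cid = nearest_assigned(i)
        clusters[cid].add(i)
        assigned[i] = cid

    out = Clustering([MiniCluster(set(c)) for c in clusters], n)
    out.check_partition()
    return out


def label_clusters(clustering: Clustering,
                   known: Mapping[int, str]) -> Clustering:
    """Label every cluster from its members' known efficacy.

    ``known`` maps a subset of sequence indices to "effective" or
    "ineffective".  A cluster with at least one known-effective member is
    effective; one whose known members are all ineffective is ineffective;
    one with no known member is uncertain.
    """
    for i, lab in known.items():
        if lab not in (EFFECTIVE, INEFFECTIVE):
            raise ValueError(f"known label for index {i} must be "
                             f"effective/ineffective, got {lab!r}")
    clusters = []
    for c in clustering.clusters:
        labs = {known[i] for i in c.members if i in known}
        if EFFECTIVE in labs:
            label = EFFECTIVE
        elif INEFFECTIVE in labs:
            label = INEFFECTIVE
        else:
            label = UNCERTAIN
        clusters.append(MiniCluster(set(c.members), label))
    return Clustering(clusters, clustering.n)


def merge_uncertain(clustering: Clustering,
                    values: Sequence[float]) -> Clustering:
    """Merge every uncertain cluster into its nearest determined cluster.

    Cluster-to-cluster distance is single linkage: the minimum pairwise
    squared difference over cross members.  The uncertain cluster adopts
    the nearest determined cluster's label and its members join that
    cluster; determined clusters are never relabelled.  A tie between an
    effective and an ineffective cluster at the same distance resolves
    toward the effective one (sensitivity-first behaviour).
    """
    v = [float(x) for x in values]
    determined = [c for c in clustering.clusters if c.label != UNCERTAIN]
    uncertain = [c for c in clustering.clusters if c.label == UNCERTAIN]
    if not uncertain:
        return Clustering([MiniCluster(set(c.members), c.label)
                           for c in clustering.clusters], clustering.n)
    if not determined:
        raise NoDeterminedClusterError(
            "uncertain clusters exist but no cluster has a known label; "
            "provide labelled training sequences so at least one cluster "
            "can be determined")

    # distances use the determined clusters' original members: every
    # uncertain cluster is matched independently, not to earlier merges
    merged = [MiniCluster(set(c.members), c.label) for c in determined]
    for b in uncertain:
        best = None  # (distance, label priority, creation order)
        for idx, a in enumerate(determined):
            d = min(pairwise_distance(v[u], v[w])
                    for u in a.members for w in b.members)
            prio = 0 if a.label == EFFECTIVE else 1
            key = (d, prio, idx)
            if best is None or key < best[0]:
                best = (key, idx)
        merged[best[1]].members |= b.members
    out = Clustering(merged, clustering.n)
    out.check_partition()
    return out
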