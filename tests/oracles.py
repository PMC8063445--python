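"""Independent brute-force reference implementations used only by tests.

These deliberately recompute everything from first principles (no shared
code with the package) so that agreement is a genuine cross-check.
"""

from itertools import combinations

import numpy as np


def brute_force_bh(p):
    """Benjamini-Hochberg step-up by direct evaluation of the definition:

    adj_(i) = min_{j >= i} min(1, m * p_(j) / j) over ascending order stats.
    """
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running_min = min(running_min, m * p[idx] / rank)
        adj[idx] = running_min
    return adj


def brute_force_ward_partition(X, k):
    """Greedy Ward agglomeration recomputing the merge criterion from scratch.

    At each step every candidate pair's increase in within-cluster sum of
    squares is evaluated as |A||B|/(|A|+|B|) * ||centroid_A - centroid_B||^2;
    the minimum is merged (ties: lexicographically smallest member pair).
    Returns the partition at k clusters as a set of frozensets of row indices.
    """
    X = np.asarray(X, dtype=float)
    clusters = [[i] for i in range(len(X))]
    while len(clusters) > k:
        best = None
        for i, j in combinations(range(len(clusters)), 2):
            A, B = X[clusters[i]], X[clusters[j]]
            na, nb = len(A), len(B)
            cost = na * nb / (na + nb) * float(
                np.sum((A.mean(axis=0) - B.mean(axis=0)) ** 2)
            )
            tie = (min(clusters[i] + clusters[j]), max(clusters[i] + clusters[j]))
            if best is None or (cost, tie) < (best[0], best[1]):
                best = (cost, tie, i, j)
        _, _, i, j = best
        clusters[i] = sorted(clusters[i] + clusters[j])
        del clusters[j]
    return {frozenset(c) for c in clusters}


def partition_of(labels):
    """Set-of-frozensets view of a flat labelling (relabelling-invariant)."""
    labels = np.asarray(labels)
    return {
        frozenset(np.flatnonzero(labels == lab).tolist())
        for lab in np.unique(labels)
    }


def brute_force_overlap_counts(member_sets):
    """Exclusive-combination counts by per-gene membership enumeration."""
    union = set().union(*member_sets)
    counts = {}
    for g in union:
        key = tuple(g in s for s in member_sets)
        counts[key] = counts.get(key, 0) + 1
    return counts
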