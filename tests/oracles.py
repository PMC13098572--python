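"""Independent brute-force oracles used to check the package's statistics.

Everything here is deliberately naive: direct definitions, exhaustive
enumeration, and pair counting. None of it shares code with the package.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np


def bh_stepup(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values straight from the definition."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        adjusted[i] = running_min
    return np.clip(adjusted, 0, 1)


def auc_paircount(scores, labels) -> float:
    """AUC as the fraction of concordant case/control pairs (ties = 1/2)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    pos = s[y == 1]
    neg = s[y == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


def u_paircount(cases, controls) -> float:
    """Mann-Whitney U for the case sample, by pair counting."""
    total = 0.0
    for a in cases:
        for b in controls:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total


def spearman_distinct(a, b) -> float:
    """Spearman rho via 1 - 6*sum(d^2)/(n(n^2-1)); distinct values only."""
    a, b = np.asarray(a), np.asarray(b)
    ra = np.argsort(np.argsort(a))
    rb = np.argsort(np.argsort(b))
    n = len(a)
    d2 = np.sum((ra - rb) ** 2)
    return 1 - 6 * d2 / (n * (n**2 - 1))


def complete_linkage_bruteforce(D: np.ndarray, labels: list[str]):
    """Naive complete-linkage agglomeration.

    Returns merges as (frozenset_a, frozenset_b, height) with the same
    lexicographic tie-break as the implementation under test (smallest pair
    of cluster-leading labels).
    """
    clusters = [frozenset([lab]) for lab in labels]
    loc = {lab: i for i, lab in enumerate(labels)}
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters, key=min), 2):
            dist = max(D[loc[x], loc[y]] for x in a for y in b)
            key = (dist, tuple(sorted((min(a), min(b)))))
            if best is None or key < best[0]:
                best = (key, a, b)
        (dist, _), a, b = best
        merges.append((a, b, dist))
        clusters = [c for c in clusters if c not in (a, b)] + [a | b]
    return merges


def cut_bruteforce(merges, leaves, k):
    """Partition after applying the first n-k merges (merge-order cut)."""
    groups = {frozenset([lab]) for lab in leaves}
    for a, b, _ in merges[: len(leaves) - k]:
        groups = {g for g in groups if g not in (a, b)} | {a | b}
    return sorted(groups, key=min)


def ari_paircount(labels_a: dict, labels_b: dict) -> float:
    """ARI from agreements over item pairs (the textbook definition)."""
    items = sorted(labels_a)
    n11 = n00 = n10 = n01 = 0
    for x, y in itertools.combinations(items, 2):
        same_a = labels_a[x] == labels_a[y]
        same_b = labels_b[x] == labels_b[y]
        if same_a and same_b:
            n11 += 1
        elif same_a:
            n10 += 1
        elif same_b:
            n01 += 1
        else:
            n00 += 1
    num = 2.0 * (n11 * n00 - n10 * n01)
    den = (n11 + n10) * (n10 + n00) + (n11 + n01) * (n01 + n00)
    if den == 0:
        return 1.0 if n10 + n01 == 0 else 0.0
    return num / den


def set_partitions(items):
    """All set partitions of a sequence (Bell-number enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partition in set_partitions(rest):
        for i in range(len(partition)):
            yield partition[:i] + [partition[i] + [first]] + partition[i + 1 :]
        yield partition + [[first]]


def partition_to_labels(partition) -> dict:
    return {item: i for i, block in enumerate(partition) for item in block}


def shapley_exhaustive(f, x, baseline: np.ndarray) -> np.ndarray:
    """Interventional Shapley values by averaging over all permutations.

    ``f`` maps a 2-D array to outputs; tractable only for a handful of
    features. Independent of the package's enumeration (permutations, not
    coalition weights).
    """
    d = len(x)
    phi = np.zeros(d)

    def value(subset) -> float:
        data = baseline.copy()
        for j in subset:
            data[:, j] = x[j]
        return float(np.mean(f(data)))

    for perm in itertools.permutations(range(d)):
        prev = value(())
        chosen = []
        for j in perm:
            chosen.append(j)
            cur = value(tuple(chosen))
            phi[j] += cur - prev
            prev = cur
    from math import factorial

    return phi / factorial(d)
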