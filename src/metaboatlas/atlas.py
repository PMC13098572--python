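"""Composite inter-disease similarity, clustering, and robustness checks.

The atlas summarizes how metabolically alike two diseases are with the
composite similarity

    S = omega * J + (1 - omega) * R'

where J is the Jaccard overlap of the two diseases' altered-metabolite sets
(|meanZ| above the profiling threshold) and R' is the Spearman rank
correlation of their meanZ profiles rescaled from [-1, 1] to [0, 1];
omega = 0.5 in the primary analysis. Diseases are organized by complete-
linkage agglomerative clustering of the dissimilarity D = 1 - S with fully
deterministic lexicographic tie-breaking, so atlases are reproducible across
runs and platforms. Medication robustness is probed by re-deriving the atlas
on statin-residualized data and comparing partition cuts with the Adjusted
Rand Index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .profiling import DiseaseProfile


class AtlasError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Pairwise similarity components
# ---------------------------------------------------------------------------

def jaccard(set_a, set_b) -> float:
    """|A∩B| / |A∪B|; two empty sets count as identical (J = 1)."""
    a, b = set(set_a), set(set_b)
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def spearman_rescaled(profile_a, profile_b) -> float:
    """Average-rank Spearman rho mapped to [0, 1] via (rho + 1) / 2.

    A zero-variance profile has no rank ordering; the uninformative midpoint
    0.5 is returned with a warning.
    """
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.shape != b.shape:
        raise AtlasError(f"profile length mismatch: {a.shape} vs {b.shape}")
    if a.size < 3:
        raise AtlasError("profiles must have length >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("zero-variance profile; R' set to 0.5", stacklevel=2)
        return 0.5
    rho = stats.spearmanr(a, b).statistic
    return (rho + 1.0) / 2.0


# ---------------------------------------------------------------------------
# Deterministic complete-linkage agglomeration
# ---------------------------------------------------------------------------

@dataclass
class Dendrogram:
    """Sequence of agglomerative merges over labeled leaves.

    Each merge is ``(left_leaves, right_leaves, height)`` with the two sides
    ordered so the lexicographically smaller leading leaf comes first.
    """

    leaves: list[str]
    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]]

    def __post_init__(self) -> None:
        heights = [h for _, _, h in self.merges]
        if any(h2 < h1 - 1e-12 for h1, h2 in zip(heights, heights[1:])):
            raise AtlasError("dendrogram heights must be non-decreasing")

    def leaf_order(self) -> list[str]:
        """Display order: recursive traversal, smaller-label subtree first."""
        children: dict[tuple[str, ...], tuple] = {}
        for left, right, _ in self.merges:
            children[tuple(sorted(left + right))] = (left, right)

        def walk(cluster: tuple[str, ...]) -> list[str]:
            if cluster not in children:
                return list(cluster)
            left, right = children[cluster]
            first, second = sorted((left, right), key=min)
            return walk(tuple(sorted(first))) + walk(tuple(sorted(second)))

        return walk(tuple(sorted(self.leaves)))

    def to_newick(self) -> str:
        """Newick string with branch lengths = parent height - child height."""
        height_of: dict[tuple[str, ...], float] = {}
        children: dict[tuple[str, ...], tuple] = {}
        for left, right, h in self.merges:
            key = tuple(sorted(left + right))
            children[key] = (tuple(sorted(left)), tuple(sorted(right)))
            height_of[key] = h

        def newick(cluster: tuple[str, ...], parent_h: float) -> str:
            if cluster not in children:
                return f"{cluster[0]}:{parent_h:.6g}"
            h = height_of[cluster]
            left, right = sorted(children[cluster], key=min)
            inner = f"({newick(left, h)},{newick(right, h)})"
            return f"{inner}:{parent_h - h:.6g}" if parent_h > 0 else inner

        if not self.merges:
            return f"({self.leaves[0]});" if self.leaves else "();"
        root = tuple(sorted(self.leaves))
        return newick(root, 0.0) + ";"


def complete_linkage(D: pd.DataFrame) -> Dendrogram:
    """Complete-linkage agglomeration of a labeled dissimilarity matrix.

    Inter-cluster distance is the maximum pairwise dissimilarity. Ties are
    broken by the lexicographically smallest pair of cluster-leading labels,
    making the merge sequence deterministic.
    """
    if list(D.index) != list(D.columns):
        raise AtlasError("dissimilarity matrix must have matching row/col labels")
    arr = D.to_numpy(dtype=float)
    if not np.allclose(arr, arr.T, atol=1e-12):
        raise AtlasError("dissimilarity matrix must be symmetric")
    labels = list(D.index)
    clusters: dict[tuple[str, ...], list[str]] = {
        (lab,): [lab] for lab in labels
    }
    loc = {lab: i for i, lab in enumerate(labels)}
    merges = []
    while len(clusters) > 1:
        best = None
        for ka in clusters:
            for kb in clusters:
                if ka >= kb:
                    continue
                dist = max(
                    arr[loc[x], loc[y]]
                    for x in clusters[ka]
                    for y in clusters[kb]
                )
                key = (dist, tuple(sorted((ka[0], kb[0]))))
                if best is None or key < best[0]:
                    best = (key, ka, kb)
        (dist, _), ka, kb = best
        left, right = sorted((ka, kb), key=min)
        merges.append((left, right, float(dist)))
        merged = tuple(sorted(ka + kb))
        members = clusters.pop(ka) + clusters.pop(kb)
        clusters[merged] = members
    return Dendrogram(leaves=sorted(labels), merges=merges)


@dataclass
class Partition:
    """Phenotype -> cluster label map obtained from a dendrogram cut."""

    labels: dict[str, int]
    k: int
    tied_cut: bool = False

    def as_groups(self) -> list[frozenset[str]]:
        groups: dict[int, set[str]] = {}
        for item, lab in self.labels.items():
            groups.setdefault(lab, set()).add(item)
        return [frozenset(groups[g]) for g in sorted(groups)]


def cut_partition(dendrogram: Dendrogram, k: int) -> Partition:
    """The k clusters obtained by removing the k-1 highest merges.

    Because merge heights are non-decreasing, this applies the first
    ``n - k`` merges. A tie between the last kept and first removed merge is
    resolved by merge order and flagged on the result.
    """
    n = len(dendrogram.leaves)
    if not 1 <= k <= n:
        raise AtlasError(f"k must lie in [1, {n}], got {k}")
    parent = {lab: lab for lab in dendrogram.leaves}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    n_apply = n - k
    for left, right, _ in dendrogram.merges[:n_apply]:
        ra, rb = find(left[0]), find(right[0])
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)
    tied = False
    if 0 < n_apply < len(dendrogram.merges):
        if dendrogram.merges[n_apply][2] == dendrogram.merges[n_apply - 1][2]:
            tied = True
            warnings.warn(
                f"tie at cut height for k={k}; resolved by merge order",
                stacklevel=2,
            )
    roots = sorted({find(lab) for lab in dendrogram.leaves})
    root_id = {r: i for i, r in enumerate(roots)}
    return Partition(
        labels={lab: root_id[find(lab)] for lab in dendrogram.leaves},
        k=k,
        tied_cut=tied,
    )


def adjusted_rand_index(partition_a: Partition | dict, partition_b: Partition | dict) -> float:
    """Permutation-model ARI from the contingency table.

    ARI = (Index - Expected) / (Max - Expected), where Index is the sum of
    within-cell pair counts and Expected is the product of marginal pair
    counts over the total pair count.
    """
    la = partition_a.labels if isinstance(partition_a, Partition) else dict(partition_a)
    lb = partition_b.labels if isinstance(partition_b, Partition) else dict(partition_b)
    if set(la) != set(lb):
        raise AtlasError("partitions must cover the same items")
    items = sorted(la)
    n = len(items)
    if n < 2:
        raise AtlasError("ARI requires at least 2 items")
    table: dict[tuple, int] = {}
    row: dict = {}
    col: dict = {}
    for it in items:
        key = (la[it], lb[it])
        table[key] = table.get(key, 0) + 1
        row[la[it]] = row.get(la[it], 0) + 1
        col[lb[it]] = col.get(lb[it], 0) + 1
    index = sum(comb(v, 2) for v in table.values())
    sum_a = sum(comb(v, 2) for v in row.values())
    sum_b = sum(comb(v, 2) for v in col.values())
    total = comb(n, 2)
    expected = sum_a * sum_b / total
    maximum = (sum_a + sum_b) / 2.0
    if maximum == expected:  # both partitions trivial (all-singletons or one cluster)
        return 1.0 if index == expected else 0.0
    return (index - expected) / (maximum - expected)


# ---------------------------------------------------------------------------
# Atlas assembly
# ---------------------------------------------------------------------------

@dataclass
class SimilarityAtlas:
    """Composite-similarity matrices, derived clustering, and flags."""

    phenotypes: list[str]
    J: pd.DataFrame
    R_rescaled: pd.DataFrame
    S: pd.DataFrame
    D: pd.DataFrame
    omega: float
    tau: float
    dendrogram: Dendrogram
    flags: list[str] = field(default_factory=list)

    def cut(self, k: int) -> Partition:
        return cut_partition(self.dendrogram, k)

    def leaf_order(self) -> list[str]:
        return self.dendrogram.leaf_order()


def composite_similarity(
    profiles: dict[str, DiseaseProfile],
    omega: float = 0.5,
    tau: float | None = None,
) -> SimilarityAtlas:
    """Build the full similarity atlas from disease profiles.

    ``tau`` overrides the altered-set threshold stored on the profiles.
    With omega = 1 the composite reduces to the Jaccard matrix; with
    omega = 0 to the rescaled-Spearman matrix.
    """
    if not 0.0 <= omega <= 1.0:
        raise AtlasError("omega must lie in [0, 1]")
    names = sorted(profiles)
    if len(names) < 2:
        raise AtlasError("need at least 2 profiles")
    feats = list(profiles[names[0]].mean_z.index)
    for p in names:
        if list(profiles[p].mean_z.index) != feats:
            raise AtlasError(f"profile {p} is on a different feature universe")
    if tau is None:
        tau = profiles[names[0]].tau
    altered = {
        p: frozenset(
            profiles[p].mean_z.index[profiles[p].mean_z.abs() > tau]
        )
        for p in names
    }
    m = len(names)
    J = np.eye(m)
    R = np.eye(m)
    flags = []
    for p in names:
        if not altered[p]:
            flags.append(f"empty altered set: {p}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(m):
            for j in range(i + 1, m):
                J[i, j] = J[j, i] = jaccard(altered[names[i]], altered[names[j]])
                R[i, j] = R[j, i] = spearman_rescaled(
                    profiles[names[i]].mean_z.to_numpy(),
                    profiles[names[j]].mean_z.to_numpy(),
                )
    S = omega * J + (1 - omega) * R
    np.fill_diagonal(S, 1.0)
    D = 1.0 - S
    np.fill_diagonal(D, 0.0)
    as_df = lambda a: pd.DataFrame(a, index=names, columns=names)
    dend = complete_linkage(as_df(D))
    return SimilarityAtlas(
        phenotypes=names,
        J=as_df(J),
        R_rescaled=as_df(R),
        S=as_df(S),
        D=as_df(D),
        omega=omega,
        tau=tau,
        dendrogram=dend,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# Statin residualization and robustness
# ---------------------------------------------------------------------------

def statin_residualize(
    matrix: pd.DataFrame,
    statin_flags,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-feature OLS residuals after regressing out the statin indicator.

    With an indicator-only design the residual group means are exactly
    balanced across flag levels. Residuals are returned standardized
    (mean 0, SD 1), ready for re-profiling.
    """
    flags = np.asarray(statin_flags, dtype=float)
    if len(np.unique(flags)) < 2:
        raise AtlasError("statin flag must have both levels present")
    design = [np.ones(len(flags)), flags]
    if covariates is not None:
        for c in covariates.columns:
            design.append(covariates[c].to_numpy(dtype=float))
    X = np.column_stack(design)
    Y = matrix.to_numpy(dtype=float)
    if np.isnan(Y).any():
        raise AtlasError("residualization requires an imputed (complete) matrix")
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    sd = resid.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return pd.DataFrame(resid / sd, index=matrix.index, columns=matrix.columns)


def ari_sweep(
    atlas_a: SimilarityAtlas,
    atlas_b: SimilarityAtlas,
    ks: range | list[int] = range(2, 11),
) -> pd.DataFrame:
    """ARI between the two atlases' partition cuts over a sweep of k."""
    rows = []
    n = len(atlas_a.phenotypes)
    for k in ks:
        if k > n:
            continue
        rows.append(
            (k, adjusted_rand_index(atlas_a.cut(k), atlas_b.cut(k)))
        )
    return pd.DataFrame(rows, columns=["k", "ari"])
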