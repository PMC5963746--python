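"""Inter-operator agreement diagnostics.

Size agreement is summarized by pairwise Pearson correlations of centroid
size between operators; shape agreement by Pearson correlations between the
operators' Procrustes distance matrices (strictly-lower-triangle entries; no
Mantel test by default — the correlation is descriptive and cannot expose
biases).  The replica structure is visualized with a UPGMA phenogram in which
an individual's replicas should cluster together when error is small, and the
relative spread of shape variation is summarized by the (trimmed) ratio of
the largest to smallest distance to the sample mean.

UPGMA is implemented here rather than delegated so that ties between equal
minimum distances break deterministically by lexicographic leaf-label order;
trees are scikit-bio ``TreeNode`` objects and serialize to newick.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio.tree import TreeNode

from .procrustes import ShapeDistanceMatrix


def pairwise_size_correlation(
    cs_by_operator: Mapping[str, pd.Series],
) -> tuple[pd.DataFrame, float]:
    """Pearson correlations of centroid size between operator pairs.

    Each series is indexed by individual id; correlations use the
    individuals shared by each pair (>= 3 required).  Returns the symmetric
    unit-diagonal matrix and the mean of the off-diagonal pairs.
    """
    ops = list(cs_by_operator)
    if len(ops) < 2:
        raise ValueError("need >= 2 operators")
    mat = pd.DataFrame(np.eye(len(ops)), index=ops, columns=ops)
    off = []
    for a, b in itertools.combinations(ops, 2):
        sa, sb = cs_by_operator[a], cs_by_operator[b]
        shared = sa.index.intersection(sb.index)
        if len(shared) < 3:
            raise ValueError(
                f"operators {a!r}/{b!r} share only {len(shared)} individuals"
            )
        r = float(np.corrcoef(sa.loc[shared], sb.loc[shared])[0, 1])
        mat.loc[a, b] = mat.loc[b, a] = r
        off.append(r)
    return mat, float(np.mean(off))


def distance_matrix_correlation(
    dist_a: ShapeDistanceMatrix,
    dist_b: ShapeDistanceMatrix,
    mantel_permutations: int = 0,
    seed: int = 0,
) -> float | tuple[float, float]:
    """Pearson correlation over the strictly-lower triangles of two matrices.

    Labels must match in order.  With ``mantel_permutations`` > 0 a seeded
    Mantel P value is returned alongside.
    """
    if dist_a.labels != dist_b.labels:
        raise ValueError("distance matrices have different labels")
    n = len(dist_a.labels)
    if n < 4:
        raise ValueError("need >= 4 records for a distance-matrix correlation")
    tri = np.tril_indices(n, k=-1)
    a = dist_a.values[tri]
    b = dist_b.values[tri]
    r = float(np.corrcoef(a, b)[0, 1])
    if mantel_permutations <= 0:
        return r
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(mantel_permutations):
        perm = rng.permutation(n)
        bp = dist_b.values[np.ix_(perm, perm)][tri]
        hits += abs(float(np.corrcoef(a, bp)[0, 1])) >= abs(r)
    return r, (1 + hits) / (1 + mantel_permutations)


def upgma_tree(dm: ShapeDistanceMatrix) -> TreeNode:
    """Average-linkage (UPGMA) phenogram of a distance matrix.

    Merge heights are half the average inter-cluster distance (so an exactly
    ultrametric matrix is reconstructed exactly); averages are weighted by
    cluster sizes; ties in the minimum distance break by the lexicographic
    order of the clusters' smallest leaf labels, making the tree
    deterministic across platforms.
    """
    n = len(dm.labels)
    if n < 2:
        raise ValueError("need >= 2 leaves")
    nodes = {i: TreeNode(name=dm.labels[i]) for i in range(n)}
    size = {i: 1 for i in range(n)}
    height = {i: 0.0 for i in range(n)}
    rep = {i: dm.labels[i] for i in range(n)}
    dist = {
        (i, j): float(dm.values[i, j])
        for i in range(n)
        for j in range(i + 1, n)
    }
    active = set(range(n))
    next_id = n
    while len(active) > 1:
        best = min(
            dist.items(), key=lambda kv: (kv[1], *sorted((rep[kv[0][0]], rep[kv[0][1]])))
        )
        (i, j), d = best
        h = d / 2.0
        a, b = sorted((i, j), key=lambda c: rep[c])
        child_a, child_b = nodes[a], nodes[b]
        child_a.length = h - height[a]
        child_b.length = h - height[b]
        new = TreeNode(children=[child_a, child_b])
        nodes[next_id] = new
        size[next_id] = size[i] + size[j]
        height[next_id] = h
        rep[next_id] = min(rep[i], rep[j])
        active -= {i, j}
        for c in active:
            d_ic = dist.pop((min(i, c), max(i, c)))
            d_jc = dist.pop((min(j, c), max(j, c)))
            dist[(min(next_id, c), max(next_id, c))] = (
                size[i] * d_ic + size[j] * d_jc
            ) / (size[i] + size[j])
        del dist[(min(i, j), max(i, j))]
        active.add(next_id)
        next_id += 1
    root = nodes[next_id - 1]
    root.length = None
    return root


@dataclass
class ClusterCountReport:
    """How often an individual's replicas cluster together in a phenogram."""

    n_individuals: int
    n_triplets: int  # all k replicas form an exclusive clade
    n_pairs_or_better: int  # >= 2 replicas form an exclusive 2-clade (or triplet)

    def __post_init__(self) -> None:
        if not 0 <= self.n_triplets <= self.n_pairs_or_better <= self.n_individuals:
            raise ValueError("inconsistent cluster counts")

    def to_dict(self) -> dict:
        return {
            "n_individuals": self.n_individuals,
            "n_triplets": self.n_triplets,
            "n_pairs_or_better": self.n_pairs_or_better,
        }


def replica_cluster_counts(
    tree: TreeNode, individual_of: Mapping[str, str]
) -> ClusterCountReport:
    """Count individuals whose replicas form exclusive clades in the tree.

    ``individual_of`` maps every leaf label to its individual id.  A
    *triplet* means all of the individual's k leaves form an exclusive clade;
    *pair-or-better* means some two of them form an exclusive 2-leaf clade
    (sister leaves), or the triplet condition holds.
    """
    leaves = {t.name for t in tree.tips()}
    unmapped = leaves - set(individual_of)
    if unmapped:
        raise ValueError(f"leaves not mapped to individuals: {sorted(unmapped)}")
    groups: dict[str, list[str]] = {}
    for leaf, ind in individual_of.items():
        if leaf in leaves:
            groups.setdefault(ind, []).append(leaf)
    n_trip = 0
    n_pair = 0
    for ind, names in groups.items():
        k = len(names)
        lca = tree.lca(names) if k > 1 else None
        triplet = k > 1 and lca.count(tips=True) == k
        pair = triplet
        if not pair:
            for x, y in itertools.combinations(names, 2):
                if tree.lca([x, y]).count(tips=True) == 2:
                    pair = True
                    break
        n_trip += triplet
        n_pair += pair
    return ClusterCountReport(
        n_individuals=len(groups), n_triplets=n_trip, n_pairs_or_better=n_pair
    )


@dataclass
class RangeStatistic:
    """Relative range of distances to the mean shape: max/min, raw and trimmed."""

    ratio: float
    trimmed_ratio: float
    trim_fraction: float
    trim_method: str = "symmetric"  # ceil(f/2 * n) dropped from each tail

    def __post_init__(self) -> None:
        if not self.ratio >= self.trimmed_ratio >= 1.0 - 1e-12:
            raise ValueError("expected ratio >= trimmed_ratio >= 1")

    def to_dict(self) -> dict:
        return {
            "ratio": self.ratio,
            "trimmed_ratio": self.trimmed_ratio,
            "trim_fraction": self.trim_fraction,
            "trim_method": self.trim_method,
        }


def relative_range(
    distances_to_mean: Sequence[float] | np.ndarray | pd.Series,
    trim_fraction: float = 0.05,
) -> RangeStatistic:
    """Max/min ratio of shape distances to the mean, raw and outlier-trimmed.

    Trimming is symmetric: the ceil(trim_fraction/2 * n) largest and equally
    many smallest distances are dropped (the statistic uses both extremes, so
    both tails are trimmed).
    """
    d = np.asarray(distances_to_mean, dtype=float)
    if len(d) < 3:
        raise ValueError("need >= 3 distances")
    if (d <= 0).any():
        raise ValueError("zero or negative distance: ratio undefined")
    ratio = float(d.max() / d.min())
    m = int(np.ceil(trim_fraction / 2.0 * len(d)))
    kept = np.sort(d)[m : len(d) - m] if m > 0 else np.sort(d)
    if len(kept) < 2:
        raise ValueError("trimming left fewer than 2 distances")
    trimmed = float(kept.max() / kept.min())
    return RangeStatistic(
        ratio=ratio, trimmed_ratio=trimmed, trim_fraction=trim_fraction
    )


def mean_shape_correlation(r_values: Sequence[float]) -> float:
    """Average of pairwise matrix correlations (the 'averaged' summary row)."""
    return float(np.mean(list(r_values)))
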