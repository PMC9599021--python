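"""Distance matrices, UPGMA dendrograms and the Mantel permutation test.

This module links the two halves of a germplasm study: a Euclidean distance
matrix over (optionally z-scored) biochemical genotype means, a genetic
distance matrix over diploid SSR allele sizes, average-linkage (UPGMA)
clustering with Newick export, and a permutation Mantel test for congruence
between the two matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .ssr import SSRGenotypeTable

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "MantelResult",
    "biochem_distance",
    "genetic_distance",
    "upgma",
    "cut_clusters",
    "mantel_test",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric, zero-diagonal dissimilarity matrix over labelled genotypes."""

    labels: tuple[str, ...]
    values: np.ndarray
    metric_name: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if np.any(np.isnan(v)):
            raise ValueError("distance matrix contains NaN")
        if np.any(v < 0):
            raise ValueError("distances must be non-negative")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix must have a zero diagonal")
        vs = 0.5 * (v + v.T)
        np.fill_diagonal(vs, 0.0)
        object.__setattr__(self, "values", vs)
        object.__setattr__(self, "labels", tuple(map(str, self.labels)))

    def reorder(self, labels: Sequence[str]) -> "DistanceMatrix":
        """Align to a new label order (must be a permutation of the labels)."""
        if set(labels) != set(self.labels) or len(labels) != len(self.labels):
            raise ValueError("labels are not a permutation of this matrix's labels")
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(
            tuple(labels), self.values[np.ix_(idx, idx)], self.metric_name
        )

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


def biochem_distance(
    means: pd.DataFrame,
    variables: Sequence[str] | None = None,
    *,
    standardize: bool = True,
) -> DistanceMatrix:
    """Euclidean distance over biochemical genotype means.

    Variables are z-scored by default: the assays live on wildly different
    scales (total phenolics in the hundreds, anthocyanins in the tens), so an
    unstandardized distance would be dominated by the largest-scale variable.
    """
    cols = list(variables) if variables is not None else list(means.columns)
    sub = means[cols].astype(float)
    if len(sub) < 2:
        raise ValueError("need at least 2 genotypes")
    if sub.isna().any().any():
        bad = sub.isna().stack()
        g, v = bad[bad].index[0]
        raise ValueError(f"missing value for genotype {g!r}, variable {v!r}")
    x = sub.to_numpy()
    if standardize:
        sd = x.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("zero-variance variable cannot be z-scored")
        x = (x - x.mean(axis=0)) / sd
    d = squareform(pdist(x, metric="euclidean"))
    name = "euclidean_z" if standardize else "euclidean"
    return DistanceMatrix(tuple(map(str, sub.index)), d, name)


def genetic_distance(
    table: SSRGenotypeTable,
    method: Literal["allele_size_euclidean", "shared_allele"] = "allele_size_euclidean",
    *,
    locus_mean_size: bool = False,
) -> DistanceMatrix:
    """Pairwise genetic distance from diploid allele sizes.

    ``allele_size_euclidean`` treats each locus as the sorted two-allele-size
    vector (or its mean with ``locus_mean_size=True``) and takes the Euclidean
    distance over the per-pair typed loci, normalized by the number of loci
    used so pairs with missing loci stay comparable. ``shared_allele`` is
    1 minus the mean proportion of shared alleles per locus.
    """
    n = len(table.genotypes)
    if n < 2:
        raise ValueError("need at least 2 genotypes")
    L = len(table.loci)
    calls = np.sort(table.calls, axis=2)  # heterozygote order made deterministic
    typed = ~np.isnan(calls[:, :, 0])
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = typed[i] & typed[j]
            used = int(both.sum())
            if used == 0:
                raise ValueError(
                    f"genotypes {table.genotypes[i]!r} and {table.genotypes[j]!r} "
                    "share no typed locus"
                )
            a, b = calls[i, both], calls[j, both]
            if method == "allele_size_euclidean":
                if locus_mean_size:
                    diff2 = (a.mean(axis=1) - b.mean(axis=1)) ** 2
                else:
                    diff2 = ((a - b) ** 2).sum(axis=1)
                d[i, j] = d[j, i] = float(np.sqrt(diff2.sum() / used))
            elif method == "shared_allele":
                shared = np.zeros(used)
                eq = a == b
                # sorted pairs: multiset intersection of two 2-element multisets
                shared = eq.sum(axis=1).astype(float)
                cross = (a[:, 0] == b[:, 1]) | (a[:, 1] == b[:, 0])
                shared = np.where((shared == 0) & cross, 1.0, shared)
                d[i, j] = d[j, i] = float(1.0 - np.mean(shared / 2.0))
            else:
                raise ValueError(f"unknown method {method!r}")
    return DistanceMatrix(tuple(table.genotypes), d, method)


@dataclass(frozen=True)
class _Node:
    height: float
    label: str | None = None
    children: tuple["_Node", ...] = ()

    def leaves(self) -> list[str]:
        if self.label is not None:
            return [self.label]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass(frozen=True)
class Dendrogram:
    """Rooted ultrametric binary tree with leaves at height 0."""

    root: _Node
    labels: tuple[str, ...]
    merges: tuple[tuple[frozenset, frozenset, float], ...] = field(repr=False, default=())

    def to_newick(self, precision: int = 6) -> str:
        def fmt(node: _Node, parent_height: float) -> str:
            bl = parent_height - node.height
            if node.label is not None:
                return f"{node.label}:{bl:.{precision}f}"
            inner = ",".join(fmt(c, node.height) for c in node.children)
            return f"({inner}):{bl:.{precision}f}"

        inner = ",".join(fmt(c, self.root.height) for c in self.root.children)
        return f"({inner});"

    def cophenetic(self) -> DistanceMatrix:
        """Cophenetic distances: twice the height of the lowest common ancestor."""
        n = len(self.labels)
        idx = {l: i for i, l in enumerate(self.labels)}
        d = np.zeros((n, n))

        def walk(node: _Node) -> list[str]:
            if node.label is not None:
                return [node.label]
            groups = [walk(c) for c in node.children]
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for a in groups[gi]:
                        for b in groups[gj]:
                            d[idx[a], idx[b]] = d[idx[b], idx[a]] = 2.0 * node.height
            return [l for g in groups for l in g]

        walk(self.root)
        return DistanceMatrix(self.labels, d, "cophenetic")


def upgma(dm: DistanceMatrix) -> Dendrogram:
    """Average-linkage agglomeration; merge height is half the merge distance.

    Ties in the minimum distance are broken toward the pair whose clusters
    contain the smallest original leaf indices, so output is reproducible.
    """
    n = len(dm.labels)
    if n < 2:
        raise ValueError("need at least 2 labels")
    d = dm.values.astype(float).copy()
    # active clusters: id -> (node, size, min original index)
    nodes: dict[int, _Node] = {i: _Node(0.0, dm.labels[i]) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    min_idx = {i: i for i in range(n)}
    active = list(range(n))
    dist = {(i, j): d[i, j] for i in range(n) for j in range(i + 1, n)}
    merges: list[tuple[frozenset, frozenset, float]] = []
    next_id = n
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                key = (min(i, j), max(i, j))
                cand = (
                    dist[key],
                    min(min_idx[i], min_idx[j]),
                    max(min_idx[i], min_idx[j]),
                )
                if best is None or cand < best[0]:
                    best = (cand, i, j)
        (dmin, _, _), i, j = best
        h = dmin / 2.0
        merges.append(
            (
                frozenset(nodes[i].leaves()),
                frozenset(nodes[j].leaves()),
                dmin,
            )
        )
        # order children deterministically by smallest original leaf index
        ci, cj = (i, j) if min_idx[i] <= min_idx[j] else (j, i)
        new = _Node(h, None, (nodes[ci], nodes[cj]))
        nid = next_id
        next_id += 1
        for k in active:
            if k in (i, j):
                continue
            key_i = (min(i, k), max(i, k))
            key_j = (min(j, k), max(j, k))
            dk = (sizes[i] * dist[key_i] + sizes[j] * dist[key_j]) / (
                sizes[i] + sizes[j]
            )
            dist[(min(nid, k), max(nid, k))] = dk
        nodes[nid] = new
        sizes[nid] = sizes[i] + sizes[j]
        min_idx[nid] = min(min_idx[i], min_idx[j])
        active = [k for k in active if k not in (i, j)] + [nid]
        for k in (i, j):
            del nodes[k], sizes[k], min_idx[k]
    return Dendrogram(nodes[active[0]], dm.labels, tuple(merges))


def cut_clusters(tree: Dendrogram, k: int) -> dict[str, int]:
    """Cut the dendrogram into ``k`` clusters (undo the k-1 highest merges).

    Returns genotype -> cluster id (1-based, ordered by first appearance in
    the label order).
    """
    n = len(tree.labels)
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}]")
    # merges are recorded in non-decreasing height order (UPGMA is monotone)
    groups: dict[str, frozenset] = {l: frozenset([l]) for l in tree.labels}
    for left, right, _ in tree.merges[: n - k]:
        merged = left | right
        for l in merged:
            groups[l] = merged
    seen: dict[frozenset, int] = {}
    out: dict[str, int] = {}
    for l in tree.labels:
        g = groups[l]
        if g not in seen:
            seen[g] = len(seen) + 1
        out[l] = seen[g]
    return out


@dataclass(frozen=True)
class MantelResult:
    r: float
    p_value: float
    n_permutations: int
    seed: int | None


def mantel_test(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_permutations: int = 9999,
    seed: int | None = None,
) -> MantelResult:
    """Mantel permutation test between two labelled distance matrices.

    The matrices are aligned by label (not position). ``r`` is the Pearson
    correlation over upper-triangle entries; the one-sided upper-tail p-value
    permutes rows and columns of ``d2`` jointly, with the +1 correction:
    p = (1 + #{r* >= r}) / (n_permutations + 1).
    """
    if set(d1.labels) != set(d2.labels):
        raise ValueError("distance matrices have different label sets")
    n = len(d1.labels)
    if n < 4:
        raise ValueError("Mantel test needs at least 4 genotypes")
    d2 = d2.reorder(d1.labels)
    iu = np.triu_indices(n, 1)
    x = d1.values[iu]
    y_full = d2.values
    if np.std(x) == 0 or np.std(y_full[iu]) == 0:
        raise ValueError("zero variance in a distance matrix")
    xc = (x - x.mean()) / x.std()
    y = y_full[iu]
    r_obs = float(np.mean(xc * (y - y.mean()) / y.std()))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        yp = y_full[np.ix_(perm, perm)][iu]
        r_perm = np.mean(xc * (yp - yp.mean()) / yp.std())
        if r_perm >= r_obs - 1e-12:
            count += 1
    p = (1 + count) / (n_permutations + 1)
    return MantelResult(r_obs, float(p), n_permutations, seed)
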