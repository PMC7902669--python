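"""Locus-level haplotype analysis.

SNP-count distance matrices, two-group k-means haplotype assignment,
per-group nucleotide diversity, JC69 distances, and a deterministic
Saitou-Nei neighbor-joining tree builder (Newick-serializable via
dendropy).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from .io import MISSING

__all__ = [
    "LocusHaplotypeSet",
    "DistanceMatrix",
    "snp_distance_matrix",
    "kmeans_haplotype_groups",
    "per_group_diversity",
    "jc69_distance",
    "neighbor_joining",
]


@dataclass
class LocusHaplotypeSet:
    """Per-sample 0/1/missing SNP vectors over one locus.

    ``positions`` are 0-based offsets of the variant sites within the locus
    span ``[start, end)`` on ``chrom``.
    """

    sample_ids: list[str]
    chrom: str
    start: int
    end: int
    positions: np.ndarray
    vectors: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.vectors = np.asarray(self.vectors, dtype=np.int8)
        if self.vectors.shape != (len(self.sample_ids), len(self.positions)):
            raise ValueError("vectors shape must be (samples, variant sites)")
        if self.end <= self.start:
            raise ValueError("locus span inverted")
        if len(self.positions) and (
            (self.positions < 0) | (self.positions >= self.end - self.start)
        ).any():
            raise ValueError("variant positions outside locus span")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def span_bp(self) -> int:
        return self.end - self.start

    def subset(self, rows: Sequence[int]) -> "LocusHaplotypeSet":
        rows = np.asarray(rows, dtype=int)
        return LocusHaplotypeSet(
            sample_ids=[self.sample_ids[i] for i in rows],
            chrom=self.chrom, start=self.start, end=self.end,
            positions=self.positions, vectors=self.vectors[rows],
        )


@dataclass
class DistanceMatrix:
    """Square symmetric distance matrix with sample labels.  Entries may be
    NaN where a pair shares no called site."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(np.nan_to_num(self.values), np.nan_to_num(self.values.T)):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diagonal(self.values), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        defined = ~np.isnan(self.values)
        if (self.values[defined] < 0).any():
            raise ValueError("distances must be non-negative")

    def __len__(self) -> int:
        return len(self.sample_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", na_rep="NA")


def snp_distance_matrix(locus: LocusHaplotypeSet) -> DistanceMatrix:
    """Pairwise count of differing sites over pairwise-complete positions."""
    if locus.n_samples < 2:
        raise ValueError("need >= 2 samples")
    v = locus.vectors
    n = locus.n_samples
    d = np.zeros((n, n), dtype=float)
    if v.shape[1] == 0:  # no variant sites: all samples identical
        return DistanceMatrix(list(locus.sample_ids), d)
    called = v != MISSING
    for i in range(n):
        both = called[i] & called[i + 1:]
        diff = (v[i] != v[i + 1:]) & both
        counts = diff.sum(axis=1).astype(float)
        counts[both.sum(axis=1) == 0] = np.nan
        d[i, i + 1:] = counts
        d[i + 1:, i] = counts
    return DistanceMatrix(list(locus.sample_ids), d)


# ---------------------------------------------------------------------------
# k-means haplotype grouping
# ---------------------------------------------------------------------------

def kmeans_haplotype_groups(locus: LocusHaplotypeSet, k: int = 2,
                            seed: int = 0, n_init: int = 10) -> np.ndarray:
    """Lloyd's k-means on the 0/1 SNP vectors.

    Missing entries are imputed to the site mean for clustering only.  The
    rows are clustered in a canonical (lexicographically sorted) order so
    the partition is invariant to sample order, and labels are renumbered
    by cluster size descending (ties by first member).
    """
    from sklearn.cluster import KMeans

    n = locus.n_samples
    if not 2 <= k <= n:
        raise ValueError("need 2 <= k <= n_samples")
    x = locus.vectors.astype(float)
    miss = locus.vectors == MISSING
    if miss.any():
        col_mean = np.where(
            (~miss).sum(axis=0) > 0,
            np.where(miss, 0, x).sum(axis=0) / np.maximum((~miss).sum(axis=0), 1),
            0.5,
        )
        x = np.where(miss, col_mean[None, :], x)

    order = np.lexsort(x.T[::-1])  # canonical row order
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed, algorithm="lloyd")
    labels_sorted = km.fit_predict(x[order])
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted

    sizes = np.bincount(labels, minlength=k)
    first = np.array([np.argmax(labels == c) if (labels == c).any() else n
                      for c in range(k)])
    rank = np.lexsort((first, -sizes))
    remap = np.empty(k, dtype=int)
    remap[rank] = np.arange(k)
    return remap[labels]


def per_group_diversity(locus: LocusHaplotypeSet, labels: Sequence[int],
                        span_bp: int | None = None) -> dict[int, float]:
    """Nucleotide diversity per haplotype group over ``span_bp`` (defaults
    to the locus span).  Singleton groups get NaN."""
    from .stats import nucleotide_diversity
    from .io import GenotypeMatrix

    labels = np.asarray(labels, dtype=int)
    if len(labels) != locus.n_samples:
        raise ValueError("labels length mismatch")
    span = span_bp if span_bp is not None else locus.span_bp
    out: dict[int, float] = {}
    for g in sorted(set(labels.tolist())):
        rows = np.flatnonzero(labels == g)
        if len(rows) < 2:
            out[g] = float("nan")
            continue
        sub = locus.subset(rows)
        gm = GenotypeMatrix(
            sample_ids=list(sub.sample_ids),
            chrom=np.array([sub.chrom] * len(sub.positions), dtype=object),
            pos=sub.positions + 1,
            ref=np.array(["A"] * len(sub.positions), dtype=object),
            alt=np.array(["T"] * len(sub.positions), dtype=object),
            calls=sub.vectors,
        )
        out[g] = nucleotide_diversity(gm, span_bp=span)
    return out


# ---------------------------------------------------------------------------
# JC69
# ---------------------------------------------------------------------------

def jc69_distance(seq_a: str | Sequence, seq_b: str | Sequence) -> float:
    """Jukes-Cantor distance -(3/4) ln(1 - 4p/3) over pairwise-complete
    sites; NaN at saturation (p >= 3/4)."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal length")
    gaps = set("-Nn?")
    pairs = [(a, b) for a, b in zip(seq_a, seq_b)
             if a not in gaps and b not in gaps and a != MISSING and b != MISSING]
    if not pairs:
        return float("nan")
    p = sum(a != b for a, b in pairs) / len(pairs)
    if p >= 0.75:
        return float("nan")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(dist: DistanceMatrix,
                     outgroup: str | None = None) -> dendropy.Tree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Ties in the Q-criterion are resolved by the lexicographically smallest
    (row, column) index pair.  Negative branch lengths are clamped to zero
    with the deficit moved to the sister branch.  When ``outgroup`` is
    given, the tree is rooted at the midpoint of its pendant edge.
    """
    n = len(dist)
    if n < 3:
        raise ValueError("need >= 3 taxa")
    if np.isnan(dist.values).any():
        raise ValueError("incomplete distance matrix")

    taxa = dendropy.TaxonNamespace(dist.sample_ids)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes: list[dendropy.Node] = []
    for name in dist.sample_ids:
        node = dendropy.Node(taxon=taxa.get_taxon(name))
        nodes.append(node)

    d = dist.values.astype(float).copy()
    active = list(range(n))

    while len(active) > 2:
        r = len(active)
        sub = d[np.ix_(active, active)]
        row_sums = sub.sum(axis=1)
        q = (r - 2.0) * sub - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(q, np.inf)
        best = (np.inf, (r, r))
        for i in range(r):
            for j in range(i + 1, r):
                if q[i, j] < best[0] - 1e-12 or (
                    abs(q[i, j] - best[0]) <= 1e-12 and (i, j) < best[1]
                ):
                    best = (q[i, j], (i, j))
        i, j = best[1]
        ai, aj = active[i], active[j]
        dij = d[ai, aj]
        li = 0.5 * dij + (row_sums[i] - row_sums[j]) / (2.0 * (r - 2.0))
        lj = dij - li
        if li < 0:
            lj -= li
            li = 0.0
        if lj < 0:
            li -= lj
            lj = 0.0

        parent = dendropy.Node()
        parent.add_child(nodes[ai])
        nodes[ai].edge.length = float(li)
        parent.add_child(nodes[aj])
        nodes[aj].edge.length = float(lj)

        new_idx = d.shape[0]
        d = np.pad(d, ((0, 1), (0, 1)))
        for m_local, am in enumerate(active):
            if am in (ai, aj):
                continue
            dm = 0.5 * (d[ai, am] + d[aj, am] - dij)
            d[new_idx, am] = d[am, new_idx] = max(dm, 0.0)
        nodes.append(parent)
        active = [a for a in active if a not in (ai, aj)] + [new_idx]

    a, b = active
    if nodes[a].is_leaf() and nodes[b].is_leaf():  # n == 2 never happens (n >= 3)
        root = dendropy.Node()
        root.add_child(nodes[a])
        root.add_child(nodes[b])
        nodes[a].edge.length = float(d[a, b] / 2.0)
        nodes[b].edge.length = float(d[a, b] / 2.0)
    else:
        if nodes[b].is_leaf():
            a, b = b, a
        root = nodes[b]          # internal node absorbs the final edge
        root.add_child(nodes[a])
        nodes[a].edge.length = float(max(d[a, b], 0.0))
    tree.seed_node = root
    tree.is_rooted = False

    if outgroup is not None:
        taxon = taxa.get_taxon(outgroup)
        if taxon is None:
            raise ValueError(f"outgroup {outgroup!r} not in matrix")
        node = tree.find_node_with_taxon_label(outgroup)
        edge_len = node.edge.length or 0.0
        tree.reroot_at_edge(node.edge, length1=edge_len / 2.0,
                            length2=edge_len / 2.0,
                            update_bipartitions=False)
        tree.is_rooted = True
    return tree
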