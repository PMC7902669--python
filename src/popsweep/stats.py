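"""Diversity and differentiation statistics on haplotype matrices.

All estimators operate on haploid 0/1 calls with -1 marking missing data
and use pairwise-complete site counts (per-site derived count ``k`` over
per-site called count ``n``).  The F_ST estimator is the haploid
Weir-Cockerham variance-component form (no heterozygosity component),
appropriate for haplotype-split inbred-line data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix, PopulationSpec

__all__ = [
    "WindowStatTrack",
    "SiteCounts",
    "FstResult",
    "nucleotide_diversity",
    "wattersons_theta",
    "tajimas_d",
    "tajima_constants",
    "site_counts",
    "fst_weir_cockerham",
    "ld_r2",
    "filter_variants",
    "windowed_stat",
    "tile_windows",
]


# ---------------------------------------------------------------------------
# track / counts containers
# ---------------------------------------------------------------------------

@dataclass
class WindowStatTrack:
    """Per-window (chrom, start, end, n_snps, value) records for one statistic."""

    statistic: str
    window_size: int
    step: int
    chrom: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))
    start: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))
    end: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))
    n_snps: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))
    value: np.ndarray = field(default_factory=lambda: np.array([], dtype=float))

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        self.n_snps = np.asarray(self.n_snps, dtype=np.int64)
        self.value = np.asarray(self.value, dtype=float)
        n = len(self.chrom)
        if not all(len(a) == n for a in (self.start, self.end, self.n_snps, self.value)):
            raise ValueError("track column lengths differ")
        if n and (self.end <= self.start).any():
            raise ValueError("window end <= start")

    def __len__(self) -> int:
        return len(self.chrom)

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.value)

    def midpoints(self) -> np.ndarray:
        return (self.start + self.end) / 2.0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chrom": self.chrom, "start": self.start, "end": self.end,
            "n_snps": self.n_snps, "value": self.value,
        })

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, na_rep="NA")

    @classmethod
    def read_tsv(cls, path: str | Path, statistic: str = "",
                 window_size: int = 0, step: int = 0) -> "WindowStatTrack":
        df = pd.read_csv(path, sep="\t", na_values=["NA"])
        return cls(
            statistic=statistic, window_size=window_size, step=step,
            chrom=df["chrom"].to_numpy(dtype=object), start=df["start"].to_numpy(),
            end=df["end"].to_numpy(), n_snps=df["n_snps"].to_numpy(),
            value=df["value"].to_numpy(dtype=float),
        )


@dataclass
class SiteCounts:
    """Per-site derived-allele count ``k`` and called-haplotype count ``n``
    for two populations, with site coordinates."""

    chrom: np.ndarray
    pos: np.ndarray
    k1: np.ndarray
    n1: np.ndarray
    k2: np.ndarray
    n2: np.ndarray

    def __post_init__(self) -> None:
        for k, n in ((self.k1, self.n1), (self.k2, self.n2)):
            if ((k < 0) | (k > n)).any():
                raise ValueError("need 0 <= k <= n")

    def __len__(self) -> int:
        return len(self.pos)

    def subset(self, idx) -> "SiteCounts":
        idx = np.asarray(idx)
        return SiteCounts(self.chrom[idx], self.pos[idx], self.k1[idx],
                          self.n1[idx], self.k2[idx], self.n2[idx])


def site_counts(matrix: GenotypeMatrix, populations: PopulationSpec,
                pop1: str, pop2: str) -> SiteCounts:
    """Tabulate per-site (k, n) for two populations of a matrix."""
    i1 = populations.haplotype_indices(matrix, pop1)
    i2 = populations.haplotype_indices(matrix, pop2)
    k1, n1 = matrix.site_counts(i1)
    k2, n2 = matrix.site_counts(i2)
    return SiteCounts(matrix.chrom, matrix.pos, k1, n1, k2, n2)


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------

def _k_n(matrix: GenotypeMatrix, rows: Sequence[int] | None):
    k, n = matrix.site_counts(rows)
    return k.astype(float), n.astype(float)


def nucleotide_diversity(matrix: GenotypeMatrix,
                         rows: Sequence[int] | None = None,
                         span_bp: int | None = None) -> float:
    """Mean pairwise difference per site, pairwise-complete over missing calls.

    ``sum_sites 2 k (n - k) / (n (n - 1)) / span_bp``; NaN when no site has
    two called haplotypes.
    """
    if span_bp is None:
        raise ValueError("span_bp is required")
    if span_bp <= 0:
        raise ValueError("span_bp must be positive")
    k, n = _k_n(matrix, rows)
    usable = n >= 2
    if not usable.any() and matrix.n_sites > 0:
        return float("nan")
    k, n = k[usable], n[usable]
    return float(np.sum(2.0 * k * (n - k) / (n * (n - 1.0))) / span_bp)


def tajima_constants(n: int) -> dict[str, float]:
    """Tajima (1989) normalization constants for sample size ``n``."""
    if n < 2:
        raise ValueError("need n >= 2")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def wattersons_theta(matrix: GenotypeMatrix,
                     rows: Sequence[int] | None = None) -> float:
    """Segregating-sites estimator S / a1 (total over sites, not per bp)."""
    k, n = _k_n(matrix, rows)
    seg = (k > 0) & (k < n)
    s = int(seg.sum())
    n_hap = matrix.n_haplotypes if rows is None else len(rows)
    if n_hap < 2:
        return float("nan")
    return s / tajima_constants(n_hap)["a1"]


def tajimas_d(matrix: GenotypeMatrix, rows: Sequence[int] | None = None) -> float:
    """Tajima's D; NaN when there are no segregating sites.

    Uses the subset's haplotype count for the constants and
    pairwise-complete per-site counts for the mean pairwise difference.
    """
    n_hap = matrix.n_haplotypes if rows is None else len(rows)
    if n_hap < 2:
        return float("nan")
    k, n = _k_n(matrix, rows)
    seg = (k > 0) & (k < n)
    s = int(seg.sum())
    if s == 0:
        return float("nan")
    usable = n >= 2
    pi_total = float(np.sum(
        2.0 * k[usable] * (n[usable] - k[usable]) / (n[usable] * (n[usable] - 1.0))
    ))
    c = tajima_constants(n_hap)
    var = c["e1"] * s + c["e2"] * s * (s - 1.0)
    if var <= 0:
        return float("nan")
    return (pi_total - s / c["a1"]) / np.sqrt(var)


# ---------------------------------------------------------------------------
# F_ST (haploid Weir-Cockerham)
# ---------------------------------------------------------------------------

@dataclass
class FstResult:
    a: np.ndarray          # among-population variance component per site
    b: np.ndarray          # within-population component per site
    per_site: np.ndarray   # a / (a + b), NaN where the denominator is 0
    overall: float         # ratio of sums  sum(a) / sum(a + b)
    mean_per_site: float   # plain mean of defined per-site values


def fst_weir_cockerham(counts: SiteCounts) -> FstResult:
    """Haploid Weir-Cockerham variance components for two populations.

    Sites monomorphic across both populations, or with fewer than two
    called haplotypes in either population, are excluded (components 0,
    per-site value NaN).  Estimates are reported as computed — negative
    values are not clamped.
    """
    n1 = counts.n1.astype(float)
    n2 = counts.n2.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = np.where(n1 > 0, counts.k1 / np.maximum(n1, 1), np.nan)
        p2 = np.where(n2 > 0, counts.k2 / np.maximum(n2, 1), np.nan)
    ok = (n1 >= 2) & (n2 >= 2)
    poly = ok & ~((counts.k1 + counts.k2 == 0) | (counts.k1 + counts.k2 == counts.n1 + counts.n2))

    r = 2.0
    nbar = (n1 + n2) / r
    with np.errstate(divide="ignore", invalid="ignore"):
        nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        b = nbar / (nbar - 1.0) * (pbar * (1.0 - pbar) - (r - 1.0) / r * s2)
        a = nbar / nc * (s2 - b / nbar)

    a = np.where(poly, a, 0.0)
    b = np.where(poly, b, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        per_site = np.where(poly & (a + b != 0), a / (a + b), np.nan)
    denom = float(np.sum(a + b))
    overall = float(np.sum(a) / denom) if denom != 0 else float("nan")
    defined = ~np.isnan(per_site)
    mean_ps = float(np.nanmean(per_site)) if defined.any() else float("nan")
    return FstResult(a=a, b=b, per_site=per_site, overall=overall, mean_per_site=mean_ps)


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------

def ld_r2(matrix: GenotypeMatrix, site_i: int, site_j: int,
          rows: Sequence[int] | None = None) -> float:
    """Squared Pearson correlation of two 0/1 haplotype columns over
    pairwise-complete samples; NaN when either site is monomorphic there."""
    c = matrix.calls if rows is None else matrix.calls[np.asarray(rows, dtype=int)]
    x = c[:, site_i].astype(float)
    y = c[:, site_j].astype(float)
    both = (x != MISSING) & (y != MISSING)
    x, y = x[both], y[both]
    if len(x) < 2 or x.std() == 0 or y.std() == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _r2_matrix(calls: np.ndarray) -> np.ndarray:
    """Pairwise r^2 between columns of a complete 0/1 matrix (NaN for
    monomorphic columns)."""
    x = calls.astype(float)
    x = x - x.mean(axis=0)
    sd = x.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (x.T @ x) / (len(x) * np.outer(sd, sd))
    return corr**2


# ---------------------------------------------------------------------------
# variant filtering
# ---------------------------------------------------------------------------

def filter_variants(matrix: GenotypeMatrix, maf_min: float = 0.1,
                    r2_max: float = 0.2, missing_max: float = 0.3,
                    ld_window: int = 50) -> GenotypeMatrix:
    """Missingness, MAF and LD-pruning cascade, in that order.

    * keep sites with missing fraction strictly below ``missing_max``;
    * keep sites with minor allele frequency strictly above ``maf_min``
      (frequency over called haplotypes);
    * greedy left-to-right pruning: a site is dropped when any *kept* site
      within the previous ``ld_window`` original sites has r^2 >= ``r2_max``
      with it.
    """
    for v, name in ((maf_min, "maf_min"), (r2_max, "r2_max"), (missing_max, "missing_max")):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    k, n = matrix.site_counts()
    n_hap = matrix.n_haplotypes
    miss_frac = 1.0 - n / n_hap
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, k / np.maximum(n, 1), 0.0)
    maf = np.minimum(p, 1.0 - p)
    keep = (miss_frac < missing_max) & (maf > maf_min)
    idx = np.flatnonzero(keep)

    kept: list[int] = []
    for j in idx:
        drop = False
        for i in reversed(kept):
            if j - i >= ld_window:
                break
            r2 = ld_r2(matrix, i, j)
            if not np.isnan(r2) and r2 >= r2_max:
                drop = True
                break
        if not drop:
            kept.append(int(j))
    return matrix.subset_sites(kept)


# ---------------------------------------------------------------------------
# windowing
# ---------------------------------------------------------------------------

def tile_windows(chrom_len: int, window_size: int, step: int) -> list[tuple[int, int]]:
    """Tile [0, chrom_len) with windows anchored at 0.

    Full windows start at 0, step, 2*step, ... while they fit; when the end
    of the chromosome is not reached exactly, one terminal (shorter) window
    [last_start + step, chrom_len) is appended.
    """
    if not (window_size >= step > 0):
        raise ValueError("need window_size >= step > 0")
    if chrom_len <= 0:
        return []
    windows: list[tuple[int, int]] = []
    start = 0
    while start + window_size <= chrom_len:
        windows.append((start, start + window_size))
        start += step
    covered_to = windows[-1][1] if windows else 0
    if covered_to < chrom_len:
        windows.append((start, chrom_len))
    return windows


_WINDOW_STATS = ("pi", "tajimas_d", "fst")


def windowed_stat(matrix: GenotypeMatrix, populations: PopulationSpec | None,
                  stat: str, window_size: int, step: int,
                  population: str | None = None,
                  pop_pair: tuple[str, str] | None = None,
                  chrom_lengths: dict[str, int] | None = None) -> WindowStatTrack:
    """Compute a per-window statistic track.

    ``stat`` is one of ``pi``, ``tajimas_d`` (both over one population, or
    all haplotypes when ``population`` is None) or ``fst`` (requires
    ``pop_pair``).  Chromosome lengths default to the last SNP position.
    """
    if stat not in _WINDOW_STATS:
        raise ValueError(f"unknown statistic {stat!r}; choose from {_WINDOW_STATS}")
    if stat == "fst" and (populations is None or pop_pair is None):
        raise ValueError("fst needs populations and pop_pair")

    if population is not None and populations is not None:
        rows = populations.haplotype_indices(matrix, population)
    else:
        rows = None
    if stat == "fst":
        counts_all = site_counts(matrix, populations, pop_pair[0], pop_pair[1])

    chroms, starts, ends, n_snps, values = [], [], [], [], []
    for c in dict.fromkeys(matrix.chrom):
        on_c = np.flatnonzero(matrix.chrom == c)
        pos0 = matrix.pos[on_c] - 1  # 0-based site coordinates
        clen = (chrom_lengths or {}).get(str(c), int(pos0.max()) + 1 if len(pos0) else 0)
        for start, end in tile_windows(clen, window_size, step):
            in_w = on_c[(pos0 >= start) & (pos0 < end)]
            chroms.append(c)
            starts.append(start)
            ends.append(end)
            n_snps.append(len(in_w))
            if len(in_w) == 0:
                values.append(float("nan"))
                continue
            sub = matrix.subset_sites(in_w)
            if stat == "pi":
                values.append(nucleotide_diversity(sub, rows, span_bp=end - start))
            elif stat == "tajimas_d":
                values.append(tajimas_d(sub, rows))
            else:
                res = fst_weir_cockerham(counts_all.subset(in_w))
                values.append(res.overall)
    return WindowStatTrack(
        statistic=stat, window_size=window_size, step=step,
        chrom=np.array(chroms, dtype=object), start=np.array(starts),
        end=np.array(ends), n_snps=np.array(n_snps), value=np.array(values),
    )
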