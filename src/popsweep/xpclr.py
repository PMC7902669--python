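"""Cross-population composite likelihood ratio sweep scan.

The scan contrasts, window by window, a hitchhiking model of query-population
allele frequencies against pure drift, conditional on reference-population
frequencies.

Model
-----
Let ``p1`` be the reference frequency of a SNP, ``d`` its genetic distance
(Morgans) from the putative sweep center, and ``omega`` the genome-wide
drift variance scale.  The modeled density of the (pre-sampling) query
frequency is:

* neutral (s = 0): Normal(p1, omega * p1 (1 - p1)) censored to [0, 1],
  with the censored tail mass placed as point masses at the boundaries;
* sweep (s > 0): a deterministic hitchhiking map with lineage escape
  probability ``c = 1 - (2 Ne s) ** (-d / s)`` (clamped to [0, 1]).
  Escaped lineages keep frequency p1; swept lineages go to 1 with
  probability p1 and to 0 otherwise.  Each mixture component then receives
  the same censored-normal drift noise.

The observed derived count is binomial given the query frequency; the
integral over the density uses fixed 64-point Gauss-Legendre quadrature on
[0, 1] plus the explicit boundary point masses.  The window score is
``2 * (max_s l(s) - l(0))`` over a selection grid containing 0, so scores
are non-negative by construction.  SNPs are down-weighted by ``1 / m``
where ``m`` counts window SNPs whose reference-population r^2 with the SNP
is at or above the correlation threshold (including itself).

This likelihood is self-contained and is not intended to be numerically
identical to any external implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.stats import binom, norm

from .io import GenotypeMatrix, PopulationSpec
from .stats import SiteCounts, WindowStatTrack, _r2_matrix, site_counts, tile_windows

__all__ = ["XpclrConfig", "XpclrResult", "estimate_omega",
           "xpclr_window_score", "xpclr_scan"]

_MIN_OMEGA = 1e-2   # keeps the censored normal resolvable by the quadrature
_TINY = 1e-300

_QUAD_X, _QUAD_W = np.polynomial.legendre.leggauss(64)
_QUAD_X = 0.5 * (_QUAD_X + 1.0)   # map [-1,1] -> [0,1]
_QUAD_W = 0.5 * _QUAD_W


def _default_sel_grid() -> np.ndarray:
    return np.concatenate([[0.0], np.geomspace(1e-4, 0.5, 10)])


@dataclass
class XpclrConfig:
    window_size: int = 50_000
    step: int = 100
    max_snps: int = 50
    r2_weight_threshold: float = 0.7
    sel_grid: np.ndarray = field(default_factory=_default_sel_grid)
    omega: float | None = None
    rec_rate: float = 1e-8          # Morgans per bp (1 cM/Mb)
    ne: float = 1000.0              # effective size in the hitchhiking map
    seed: int = 0

    def __post_init__(self) -> None:
        self.sel_grid = np.sort(np.asarray(self.sel_grid, dtype=float))
        if 0.0 not in self.sel_grid:
            raise ValueError("sel_grid must contain 0")
        if self.window_size < self.step:
            raise ValueError("window_size must be >= step")
        if self.max_snps < 1:
            raise ValueError("max_snps must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "XpclrConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "sel_grid" in raw:
            raw["sel_grid"] = np.asarray(raw["sel_grid"], dtype=float)
        return cls(**raw)


@dataclass
class XpclrResult:
    track: WindowStatTrack
    s_hat: np.ndarray
    omega: float


def estimate_omega(counts: SiteCounts) -> float:
    """Method-of-moments drift scale.

    Mean over sites with 0 < p1 < 1 of
    ``(p2 - p1)^2 / (p1 (1 - p1)) - 1/n2`` (the subtraction corrects for
    query sampling noise), floored at a small positive value.
    """
    n1 = counts.n1.astype(float)
    n2 = counts.n2.astype(float)
    ok = (n1 > 0) & (n2 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = counts.k1 / np.maximum(n1, 1)
        p2 = counts.k2 / np.maximum(n2, 1)
    eligible = ok & (p1 > 0.0) & (p1 < 1.0)
    if not eligible.any():
        raise ValueError("no sites with 0 < p1 < 1 to estimate omega from")
    term = (p2[eligible] - p1[eligible]) ** 2 / (p1[eligible] * (1.0 - p1[eligible]))
    term = term - 1.0 / n2[eligible]
    return float(max(term.mean(), _MIN_OMEGA))


def _censored_normal_parts(mu: np.ndarray, sigma: np.ndarray):
    """Density values at the quadrature nodes plus boundary point masses for
    Normal(mu, sigma^2) censored to [0, 1].  Shapes broadcast over SNPs."""
    x = _QUAD_X[None, :]
    dens = norm.pdf(x, loc=mu[:, None], scale=sigma[:, None])
    mass0 = norm.cdf((0.0 - mu) / sigma)
    mass1 = norm.sf((1.0 - mu) / sigma)
    return dens, mass0, mass1


def _loglik(s: float, p1: np.ndarray, binom_nodes: np.ndarray,
            k: np.ndarray, n: np.ndarray, d: np.ndarray,
            omega: float, ne: float) -> np.ndarray:
    """Per-SNP log composite likelihood under selection coefficient ``s``."""
    sigma = np.sqrt(omega * p1 * (1.0 - p1))
    if s <= 0.0:
        comps = [(np.ones_like(p1), p1)]
    else:
        with np.errstate(over="ignore"):
            base = 2.0 * ne * s
            c = 1.0 - base ** (-d / s) if base > 0 else np.zeros_like(d)
        c = np.clip(np.nan_to_num(c, nan=0.0, posinf=1.0, neginf=0.0), 0.0, 1.0)
        comps = [
            (c, p1),                                  # escaped: stays at p1
            ((1.0 - c) * p1, np.ones_like(p1)),       # swept to fixation
            ((1.0 - c) * (1.0 - p1), np.zeros_like(p1)),  # swept to loss
        ]
    lik = np.zeros(len(p1))
    for weight, mu in comps:
        dens, mass0, mass1 = _censored_normal_parts(mu, sigma)
        integral = (binom_nodes * dens * _QUAD_W[None, :]).sum(axis=1)
        boundary = mass0 * (k == 0) + mass1 * (k == n)
        lik += weight * (integral + boundary)
    return np.log(np.maximum(lik, _TINY))


def xpclr_window_score(counts: SiteCounts, center: float, config: XpclrConfig,
                       omega: float, weights: np.ndarray | None = None
                       ) -> tuple[float, float]:
    """Composite log-likelihood-ratio score and arg-max selection coefficient
    for the SNPs of one window around ``center`` (bp)."""
    m = len(counts)
    if m == 0:
        return float("nan"), float("nan")
    n1 = counts.n1.astype(float)
    usable = (n1 > 0) & (counts.n2 > 0)
    p1 = np.clip(counts.k1[usable] / n1[usable], 1e-6, 1.0 - 1e-6)
    k = counts.k2[usable].astype(int)
    n = counts.n2[usable].astype(int)
    d = config.rec_rate * np.abs(counts.pos[usable].astype(float) - center)
    w = np.ones(len(p1)) if weights is None else np.asarray(weights, float)[usable]
    if len(p1) == 0:
        return float("nan"), float("nan")

    binom_nodes = binom.pmf(k[:, None], n[:, None], _QUAD_X[None, :])
    ells = np.array([
        float(np.sum(w * _loglik(s, p1, binom_nodes, k, n, d, omega, config.ne)))
        for s in config.sel_grid
    ])
    i0 = int(np.flatnonzero(config.sel_grid == 0.0)[0])
    best = int(np.argmax(ells))
    score = max(2.0 * (ells[best] - ells[i0]), 0.0)
    return float(score), float(config.sel_grid[best])


def snp_weights(ref_calls: np.ndarray, threshold: float) -> np.ndarray:
    """LD down-weights 1/m_j, m_j = number of window SNPs whose reference
    r^2 with SNP j is >= threshold (including itself)."""
    calls = ref_calls.astype(float)
    miss = ref_calls < 0
    if miss.any():  # impute missing reference calls to the site mean
        col_n = np.maximum((~miss).sum(axis=0), 1)
        col_mean = np.where(miss, 0.0, calls).sum(axis=0) / col_n
        calls = np.where(miss, col_mean[None, :], calls)
    r2 = _r2_matrix(calls)
    r2 = np.nan_to_num(r2, nan=0.0)
    np.fill_diagonal(r2, 1.0)
    m = (r2 >= threshold).sum(axis=1)
    return 1.0 / m


def xpclr_scan(matrix: GenotypeMatrix, populations: PopulationSpec,
               ref_pop: str, query_pop: str, config: XpclrConfig,
               chrom_lengths: dict[str, int] | None = None) -> XpclrResult:
    """Windowed XP-CLR scan of query against reference.

    Windows are tiled as in :func:`popsweep.stats.tile_windows`; windows
    holding more than ``max_snps`` SNPs are subsampled uniformly with the
    run seed.  Roles are asymmetric: swapping reference and query changes
    the scores.
    """
    counts = site_counts(matrix, populations, ref_pop, query_pop)
    omega = config.omega if config.omega is not None else estimate_omega(counts)
    ref_rows = populations.haplotype_indices(matrix, ref_pop)
    rng = np.random.default_rng(config.seed)

    chroms, starts, ends, n_snps, scores, s_hats = [], [], [], [], [], []
    for c in dict.fromkeys(matrix.chrom):
        on_c = np.flatnonzero(matrix.chrom == c)
        pos0 = matrix.pos[on_c] - 1
        clen = (chrom_lengths or {}).get(str(c), int(pos0.max()) + 1 if len(pos0) else 0)
        for start, end in tile_windows(clen, config.window_size, config.step):
            in_w = on_c[(pos0 >= start) & (pos0 < end)]
            if len(in_w) > config.max_snps:
                in_w = np.sort(rng.choice(in_w, size=config.max_snps, replace=False))
            chroms.append(c)
            starts.append(start)
            ends.append(end)
            n_snps.append(len(in_w))
            if len(in_w) == 0:
                scores.append(float("nan"))
                s_hats.append(float("nan"))
                continue
            w = snp_weights(matrix.calls[np.ix_(ref_rows, in_w)], config.r2_weight_threshold)
            score, s_hat = xpclr_window_score(
                counts.subset(in_w), center=(start + end) / 2.0,
                config=config, omega=omega, weights=w,
            )
            scores.append(score)
            s_hats.append(s_hat)

    track = WindowStatTrack(
        statistic="xpclr", window_size=config.window_size, step=config.step,
        chrom=np.array(chroms, dtype=object), start=np.array(starts),
        end=np.array(ends), n_snps=np.array(n_snps), value=np.array(scores),
    )
    return XpclrResult(track=track, s_hat=np.array(s_hats), omega=omega)
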