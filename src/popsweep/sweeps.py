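"""Turn window statistic tracks into candidate sweep regions and genes.

LOESS smoothing of tracks, empirical top-fraction thresholds
(nearest-rank), interval merging of candidate windows, and CDS-overlap
gene annotation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .io import GeneModel
from .stats import WindowStatTrack

logger = logging.getLogger(__name__)

__all__ = ["SweepRegion", "loess_smooth", "empirical_top_fraction",
           "call_sweep_regions", "annotate_regions"]


@dataclass
class SweepRegion:
    chrom: str
    start: int
    end: int
    peak: float
    threshold: float
    n_windows: int
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("region end <= start")
        if self.peak < self.threshold:
            raise ValueError("region peak below threshold")


def _loess_fit_point(x0: float, x: np.ndarray, y: np.ndarray, r: int) -> float:
    """Degree-1 tricube local regression evaluated at x0 using the r nearest
    points."""
    d = np.abs(x - x0)
    nearest = np.argsort(d, kind="stable")[:r]
    xs, ys, ds = x[nearest], y[nearest], d[nearest]
    h = ds.max()
    if h == 0:
        return float(ys.mean())
    w = (1.0 - np.minimum(ds / h, 1.0) ** 3) ** 3
    sw = w.sum()
    if sw == 0:
        return float(ys.mean())
    xm = np.sum(w * xs) / sw
    ym = np.sum(w * ys) / sw
    sxx = np.sum(w * (xs - xm) ** 2)
    if sxx <= 1e-12 * max(1.0, xm * xm):
        return float(ym)
    beta = np.sum(w * (xs - xm) * (ys - ym)) / sxx
    return float(ym + beta * (x0 - xm))


def loess_smooth(track: WindowStatTrack, span: float = 0.05) -> WindowStatTrack:
    """LOESS (tricube weights, local degree-1 fits) per chromosome, evaluated
    at window midpoints.  Undefined windows are excluded from the fit and
    stay undefined.  Chromosomes with fewer than 3 defined windows are left
    unsmoothed with a warning."""
    if not 0.0 < span <= 1.0:
        raise ValueError("span must be in (0, 1]")
    mid = track.midpoints().astype(float)
    out = track.value.copy()
    for c in dict.fromkeys(track.chrom):
        on_c = np.flatnonzero(track.chrom == c)
        defined = on_c[~np.isnan(track.value[on_c])]
        if len(defined) < 3:
            logger.warning("loess_smooth: %s has < 3 defined windows; left unsmoothed", c)
            continue
        x = mid[defined]
        y = track.value[defined]
        r = max(2, math.ceil(span * len(defined)))
        for i in defined:
            out[i] = _loess_fit_point(mid[i], x, y, r)
    return WindowStatTrack(
        statistic=f"{track.statistic}_loess", window_size=track.window_size,
        step=track.step, chrom=track.chrom, start=track.start, end=track.end,
        n_snps=track.n_snps, value=out,
    )


def empirical_top_fraction(track: WindowStatTrack, fraction: float = 0.01) -> float:
    """Nearest-rank (1 - fraction) quantile of the defined window values.
    Windows with value >= the returned threshold are candidates."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    vals = track.value[track.defined]
    if len(vals) == 0:
        raise ValueError("no defined windows")
    vals = np.sort(vals)
    rank = math.ceil((1.0 - fraction) * len(vals))
    rank = min(max(rank, 1), len(vals))
    return float(vals[rank - 1])


def call_sweep_regions(track: WindowStatTrack, threshold: float,
                       merge_gap: int | None = None) -> list[SweepRegion]:
    """Merge candidate windows (value >= threshold) that overlap or lie
    within ``merge_gap`` bp of each other.  ``merge_gap`` defaults to one
    step."""
    gap = track.step if merge_gap is None else merge_gap
    cand = np.flatnonzero(track.defined & (track.value >= threshold))
    regions: list[SweepRegion] = []
    for i in cand:
        c, s, e, v = (str(track.chrom[i]), int(track.start[i]),
                      int(track.end[i]), float(track.value[i]))
        last = regions[-1] if regions else None
        if last is not None and last.chrom == c and s <= last.end + gap:
            last.end = max(last.end, e)
            last.peak = max(last.peak, v)
            last.n_windows += 1
        else:
            regions.append(SweepRegion(chrom=c, start=s, end=e, peak=v,
                                       threshold=threshold, n_windows=1))
    return regions


def annotate_regions(regions: list[SweepRegion],
                     genes: list[GeneModel]) -> list[SweepRegion]:
    """Attach a gene to a region when any CDS base overlaps it (half-open
    intersection).  Returns the same region objects, genes filled in."""
    chroms = {r.chrom for r in regions}
    gene_chroms = {g.chrom for g in genes}
    if regions and genes and not (chroms & gene_chroms):
        logger.warning("annotate_regions: no shared chromosome names "
                       "(regions: %s, genes: %s)", sorted(chroms), sorted(gene_chroms))
    for r in regions:
        r.gene_ids = [
            g.gene_id for g in genes
            if g.chrom == r.chrom
            and any(s < r.end and r.start < e for s, e in g.cds)
        ]
    return regions
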