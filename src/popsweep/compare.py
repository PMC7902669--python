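"""Pairwise genome comparison: specific sequences and genes, conservation
categories, pan-gene classes, TE-overlap fractions, and k-mer genome size.

The built-in mapper is a minimal exact-k-mer seed + ungapped X-drop
extension aligner.  It only exists to produce the (aligned_fraction,
identity) pair the classification rules consume; externally computed hit
tables in the same schema can be substituted anywhere a list of
:class:`AlignmentHit` is accepted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import GeneModel, IntervalSet
from .sim import GenomePair, KmerHistogram
from .stats import tile_windows

logger = logging.getLogger(__name__)

__all__ = [
    "AlignmentHit",
    "KmerIndex",
    "map_sequence",
    "map_windows",
    "classify_specific_windows",
    "merge_specific_regions",
    "interval_overlap_fraction",
    "gene_specific_by_overlap",
    "categorize_gene_conservation",
    "categorize_genes",
    "final_specific_genes",
    "pangene_classify",
    "estimate_genome_size",
    "CONSERVATION_CATEGORIES",
]

CONSERVATION_CATEGORIES = ("highly_conserved", "mutated", "structural_variant", "specific")


@dataclass
class AlignmentHit:
    """Best-hit summary for one query window or sequence."""

    query_id: str
    aligned_fraction: float
    identity: float
    target_chrom: str | None = None
    target_pos: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.aligned_fraction <= 1.0 and 0.0 <= self.identity <= 1.0):
            raise ValueError("fractions must be in [0, 1]")

    @staticmethod
    def table_to_hits(df: pd.DataFrame) -> list["AlignmentHit"]:
        return [
            AlignmentHit(str(r.query_id), float(r.aligned_fraction), float(r.identity))
            for r in df.itertuples(index=False)
        ]

    @staticmethod
    def hits_to_table(hits: list["AlignmentHit"]) -> pd.DataFrame:
        return pd.DataFrame({
            "query_id": [h.query_id for h in hits],
            "aligned_fraction": [h.aligned_fraction for h in hits],
            "identity": [h.identity for h in hits],
        })


# ---------------------------------------------------------------------------
# minimal mapper
# ---------------------------------------------------------------------------

class KmerIndex:
    """Exact k-mer position index over a set of target sequences."""

    def __init__(self, seqs: dict[str, str], k: int = 31):
        self.k = k
        self.index: dict[str, list[tuple[str, int]]] = {}
        for name, seq in seqs.items():
            for i in range(len(seq) - k + 1):
                self.index.setdefault(seq[i:i + k], []).append((name, i))
        self.seqs = seqs


def _xdrop_extend(q: str, t: str, diag: int, seed_q: int, k: int,
                  mismatch: float = 2.0, xdrop: float = 20.0) -> tuple[int, int, int]:
    """Ungapped two-way X-drop extension on one diagonal.

    Returns (q_start, q_end, matches) of the maximal-scoring segment
    around the seed.  ``diag`` is target_pos - query_pos.
    """
    qlen, tlen = len(q), len(t)
    lo = max(0, -diag)
    hi = min(qlen, tlen - diag)

    def walk(rng) -> int:
        score = best = 0.0
        best_pos = None
        for i in rng:
            score += 1.0 if q[i] == t[i + diag] else -mismatch
            if score > best:
                best, best_pos = score, i
            elif best - score > xdrop:
                break
        return best_pos

    right = walk(range(seed_q, hi))
    left = walk(range(seed_q + k - 1, lo - 1, -1))
    q_end = (right + 1) if right is not None else seed_q + k
    q_start = left if left is not None else seed_q
    matches = sum(1 for i in range(q_start, q_end) if q[i] == t[i + diag])
    return q_start, q_end, matches


def map_sequence(query: str, index: KmerIndex, stride: int = 4,
                 snap_min: float = 0.9) -> AlignmentHit:
    """Map one query sequence against the index; report the best single
    diagonal's covered fraction and identity.

    When the covered fraction reaches ``snap_min`` and the full query fits
    in the target at that diagonal, coverage is snapped to 1 and identity
    recomputed over the whole query (end-trimming rescue, mirroring how
    full-length aligners report near-complete hits).
    """
    k = index.k
    qlen = len(query)
    votes: dict[tuple[str, int], int] = {}
    seed_at: dict[tuple[str, int], list[int]] = {}
    for qpos in range(0, max(qlen - k + 1, 0), stride):
        for name, tpos in index.index.get(query[qpos:qpos + k], ()):
            key = (name, tpos - qpos)
            votes[key] = votes.get(key, 0) + 1
            seed_at.setdefault(key, []).append(qpos)
    if not votes:
        return AlignmentHit("", 0.0, 0.0)
    (tname, diag), _ = max(votes.items(), key=lambda kv: kv[1])
    target = index.seqs[tname]

    covered: list[tuple[int, int]] = []
    matches = 0
    for qpos in seed_at[(tname, diag)]:
        if covered and qpos < covered[-1][1]:
            continue
        s, e, m = _xdrop_extend(query, target, diag, qpos, k)
        if covered and s <= covered[-1][1]:
            if e > covered[-1][1]:
                add = sum(1 for i in range(covered[-1][1], e)
                          if query[i] == target[i + diag])
                matches += add
                covered[-1] = (covered[-1][0], e)
        else:
            covered.append((s, e))
            matches += m
    cov_bases = sum(e - s for s, e in covered)
    if cov_bases == 0:
        return AlignmentHit("", 0.0, 0.0)
    aligned_fraction = cov_bases / qlen
    identity = matches / cov_bases

    if aligned_fraction >= snap_min and 0 <= diag and diag + qlen <= len(target):
        full_matches = sum(1 for i in range(qlen) if query[i] == target[i + diag])
        aligned_fraction = 1.0
        identity = full_matches / qlen
    return AlignmentHit("", float(aligned_fraction), float(identity),
                        target_chrom=tname, target_pos=max(diag, 0))


def map_windows(pair: GenomePair, k_seed: int = 31, to_self: bool = False
                ) -> list[AlignmentHit]:
    """Tile the query genome and map each window against the target (or
    against the query itself with ``to_self``)."""
    targets = pair.query if to_self else pair.target
    index = KmerIndex(targets, k=k_seed)
    hits: list[AlignmentHit] = []
    for chrom, seq in pair.query.items():
        for start, end in tile_windows(len(seq), pair.window_size, pair.step):
            hit = map_sequence(seq[start:end], index)
            hit.query_id = f"{chrom}:{start}-{end}"
            hits.append(hit)
    return hits


# ---------------------------------------------------------------------------
# specific sequence classification
# ---------------------------------------------------------------------------

def _parse_window_id(query_id: str) -> tuple[str, int, int]:
    chrom, span = query_id.rsplit(":", 1)
    s, e = span.split("-")
    return chrom, int(s), int(e)


def classify_specific_windows(hits_to_other: list[AlignmentHit],
                              hits_to_self: list[AlignmentHit],
                              threshold: float = 0.20) -> list[str]:
    """Window ids that align to the other genome over strictly less than
    ``threshold`` of their length while self-aligning perfectly."""
    self_by_id = {h.query_id: h for h in hits_to_self}
    specific: list[str] = []
    n_missing = 0
    for h in hits_to_other:
        sh = self_by_id.get(h.query_id)
        if sh is None:
            n_missing += 1
            continue
        if h.aligned_fraction < threshold and sh.aligned_fraction == 1.0 and sh.identity == 1.0:
            specific.append(h.query_id)
    if n_missing:
        logger.warning("classify_specific_windows: %d windows lacked a self hit", n_missing)
    return specific


def merge_specific_regions(window_ids: list[str]) -> tuple[IntervalSet, int]:
    """Union of the (possibly overlapping) specific windows, plus total bp."""
    ivs = IntervalSet([_parse_window_id(w) for w in window_ids]).merged()
    return ivs, ivs.total_bp


def interval_overlap_fraction(a: IntervalSet, b: IntervalSet) -> float:
    """Fraction of a's bases contained in b; NaN when a is empty."""
    a = a.merged()
    b = b.merged()
    if a.total_bp == 0:
        return float("nan")
    inter = 0
    for ca, sa, ea in a:
        for cb, sb, eb in b:
            if ca != cb:
                continue
            inter += max(0, min(ea, eb) - max(sa, sb))
    return inter / a.total_bp


# ---------------------------------------------------------------------------
# specific / conserved genes
# ---------------------------------------------------------------------------

def gene_specific_by_overlap(genes: list[GeneModel], specific: IntervalSet,
                             min_frac: float = 0.80) -> set[str]:
    """Genes with strictly more than ``min_frac`` of CDS bases inside the
    specific intervals."""
    spec = specific.merged()
    out: set[str] = set()
    for g in genes:
        total = g.cds_length
        if total == 0:
            raise ValueError(f"{g.gene_id}: zero-length CDS")
        inter = 0
        for s, e in g.cds:
            for c, sb, eb in spec:
                if c == g.chrom:
                    inter += max(0, min(e, eb) - max(s, sb))
        if inter / total > min_frac:
            out.add(g.gene_id)
    return out


def categorize_gene_conservation(hit: AlignmentHit) -> str:
    """Map (coverage, identity) to a conservation category.

    highly_conserved: coverage = 1 and identity = 1; mutated: coverage = 1
    and 0.90 <= identity < 1; structural_variant: 0.50 <= coverage < 1 and
    identity >= 0.90; otherwise specific.
    """
    cov, ident = hit.aligned_fraction, hit.identity
    if cov == 1.0 and ident == 1.0:
        return "highly_conserved"
    if cov == 1.0 and ident >= 0.90:
        return "mutated"
    if 0.50 <= cov and ident >= 0.90:
        return "structural_variant"
    return "specific"


def categorize_genes(genes: list[GeneModel], query_genome: dict[str, str],
                     index: KmerIndex) -> dict[str, str]:
    """Extract each gene's CDS sequence from the query genome, map it
    against the target index, and categorize."""
    out: dict[str, str] = {}
    for g in genes:
        seq = "".join(query_genome[g.chrom][s:e] for s, e in g.cds)
        hit = map_sequence(seq, index)
        hit.query_id = g.gene_id
        out[g.gene_id] = categorize_gene_conservation(hit)
    return out


def final_specific_genes(method1: set[str], method2: set[str]) -> set[str]:
    """Genes called specific by both detection routes."""
    return set(method1) & set(method2)


# ---------------------------------------------------------------------------
# pan-genes
# ---------------------------------------------------------------------------

def pangene_classify(families: pd.DataFrame, n_genomes: int) -> pd.Series:
    """Classify each gene family as core / dispensable / singleton.

    ``families`` needs columns ``gene``, ``family`` and ``genome``.  A
    family present in all ``n_genomes`` genomes is core; in exactly one,
    singleton; otherwise dispensable.
    """
    required = {"gene", "family", "genome"}
    if not required.issubset(families.columns):
        raise ValueError(f"families table needs columns {sorted(required)}")
    if families[["gene", "family", "genome"]].isna().any().any():
        raise ValueError("unlabeled gene in families table")
    counts = families.groupby("family")["genome"].nunique()
    if (counts > n_genomes).any():
        raise ValueError("family present in more genomes than n_genomes")
    cls = pd.Series("dispensable", index=counts.index, name="class")
    cls[counts == n_genomes] = "core"
    cls[counts == 1] = "singleton"
    return cls


# ---------------------------------------------------------------------------
# genome size
# ---------------------------------------------------------------------------

def estimate_genome_size(hist: KmerHistogram, min_mult: int = 3) -> float:
    """Total retained k-mers divided by the coverage-peak depth.

    The peak depth is the modal multiplicity above the noise cutoff,
    refined to the count-weighted mean multiplicity within +/-25% of the
    mode (the integer mode alone jitters by a few bins at high coverage).
    """
    eligible = {m: c for m, c in hist.counts.items() if m >= min_mult and c > 0}
    if not eligible:
        raise ValueError(f"no histogram mode at multiplicity >= {min_mult}")
    mode = max(eligible, key=lambda m: (eligible[m], -m))
    lo, hi = 0.75 * mode, 1.25 * mode
    window = {m: c for m, c in eligible.items() if lo <= m <= hi}
    peak = sum(m * c for m, c in window.items()) / sum(window.values())
    total = sum(m * c for m, c in eligible.items())
    return total / peak
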