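"""Synthetic-data generators with planted ground truth.

Everything downstream is tested against data produced here: a forward
haploid Wright-Fisher simulator with an optional completed sweep, a
two-haplotype-group locus generator, a genome pair with planted
genome-specific insertions and annotated genes, and an error-free
k-mer histogram sampler.  All generators are deterministic under their
integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import GenotypeMatrix, GeneModel, IntervalSet, PopulationSpec
from .haplo import LocusHaplotypeSet

__all__ = [
    "SimConfig",
    "SimTruth",
    "GenomePair",
    "KmerHistogram",
    "simulate_two_pop_sweep",
    "simulate_haplotype_groups",
    "simulate_genome_pair",
    "simulate_kmer_histogram",
    "two_pop_spec",
    "SweepFixationError",
]

_NUC = np.frombuffer(b"ACGT", dtype="S1")


class SweepFixationError(RuntimeError):
    """Raised when the beneficial allele fails to reach the target
    frequency within the configured number of retries."""


@dataclass
class SimConfig:
    """Parameters of the two-population Wright-Fisher simulation.

    ``pop_size`` is the haploid population size; ``mu`` and ``rho`` are
    per-site per-generation probabilities; ``sel_coeff`` is the selection
    coefficient of the beneficial allele planted at 1-based ``sweep_pos``
    (0 = neutral).  ``burn_gens`` defaults to ``10 * pop_size``.
    """

    pop_size: int = 200
    split_gens: int = 200
    seq_len: int = 10_000
    mu: float = 1e-5
    rho: float = 1e-5
    sel_coeff: float = 0.0
    sweep_pos: int = 5_000
    n_sample_ref: int = 20
    n_sample_query: int = 20
    seed: int = 0
    burn_gens: int | None = None
    max_retries: int = 1000
    fix_freq: float = 0.99

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        if not 0.0 <= self.sel_coeff <= 1.0:
            raise ValueError("sel_coeff must be in [0, 1]")
        if not 1 <= self.sweep_pos <= self.seq_len:
            raise ValueError("sweep_pos must be in [1, seq_len]")
        for v, name in ((self.mu, "mu"), (self.rho, "rho")):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_sample_ref > self.pop_size or self.n_sample_query > self.pop_size:
            raise ValueError("sample sizes cannot exceed pop_size")
        if self.sel_coeff > 0 and self.split_gens <= 0:
            raise ValueError("a sweep needs split_gens > 0")


@dataclass
class SimTruth:
    """Planted ground truth attached to a generated dataset."""

    sweep_pos: int | None = None
    fixed: bool | None = None
    group_labels: dict[str, int] | None = None
    specific_intervals: IntervalSet | None = None
    gene_categories: dict[str, str] | None = None
    genes: list[GeneModel] | None = None


@dataclass
class GenomePair:
    """Query and target genome sequences plus the query window tiling."""

    query: dict[str, str]
    target: dict[str, str]
    window_size: int = 1000
    step: int = 500

    def __post_init__(self) -> None:
        if not self.query or not self.target:
            raise ValueError("both genomes must be non-empty")
        if self.window_size < self.step:
            raise ValueError("window_size must be >= step")


@dataclass
class KmerHistogram:
    """Histogram of k-mer multiplicity -> number of distinct k-mer
    observations at that multiplicity."""

    k: int
    counts: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.k < 11:
            raise ValueError("k must be >= 11")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("counts must be non-negative")

    @property
    def total_kmers(self) -> int:
        return sum(m * c for m, c in self.counts.items())


# ---------------------------------------------------------------------------
# Wright-Fisher forward simulation
# ---------------------------------------------------------------------------

def _next_generation(pop: np.ndarray, mu: float, rho: float,
                     rng: np.random.Generator,
                     sel_site: int | None = None, s: float = 0.0) -> np.ndarray:
    """One generation: fitness-weighted parent choice, single-crossover
    recombination, finite-sites toggling mutation."""
    n, L = pop.shape
    if sel_site is not None and s > 0.0:
        w = 1.0 + s * pop[:, sel_site].astype(float)
        p = w / w.sum()
        parents = rng.choice(n, size=n, p=p)
    else:
        parents = rng.integers(0, n, size=n)
    children = pop[parents].copy()

    p_rec = min(1.0, rho * (L - 1))
    if p_rec > 0.0:
        rec = np.flatnonzero(rng.random(n) < p_rec)
        if len(rec):
            if sel_site is not None and s > 0.0:
                second = rng.choice(n, size=len(rec), p=p)
            else:
                second = rng.integers(0, n, size=len(rec))
            cuts = rng.integers(1, L, size=len(rec))
            for i, par2, cut in zip(rec, second, cuts):
                children[i, cut:] = pop[par2, cut:]

    n_mut = rng.poisson(n * L * mu)
    if n_mut:
        rows = rng.integers(0, n, size=n_mut)
        cols = rng.integers(0, L, size=n_mut)
        # re-mutation toggles between the two allelic states
        children[rows, cols] = 1 - children[rows, cols]
    return children


def _evolve(pop: np.ndarray, gens: int, mu: float, rho: float,
            rng: np.random.Generator, sel_site: int | None = None,
            s: float = 0.0) -> np.ndarray:
    for _ in range(gens):
        pop = _next_generation(pop, mu, rho, rng, sel_site=sel_site, s=s)
    return pop


def two_pop_spec(n_ref: int, n_query: int) -> PopulationSpec:
    """Population assignment matching :func:`simulate_two_pop_sweep` output."""
    a = {f"ref_{i}": "reference" for i in range(n_ref)}
    a.update({f"qry_{i}": "query" for i in range(n_query)})
    return PopulationSpec(a)


def simulate_two_pop_sweep(config: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Forward-simulate an ancestral population, split it into reference and
    query, and (optionally) drive a beneficial allele planted at
    ``sweep_pos`` to fixation in the query population.

    Sweep conditioning is by rejection: the post-split query trajectory is
    re-run with a retry counter mixed into the seed until the beneficial
    allele reaches frequency ``fix_freq``; after ``max_retries`` failures a
    :class:`SweepFixationError` is raised.
    """
    cfg = config
    N, L = cfg.pop_size, cfg.seq_len
    burn = cfg.burn_gens if cfg.burn_gens is not None else 10 * N
    sweep_idx = cfg.sweep_pos - 1

    rng_burn = np.random.default_rng((cfg.seed, 0))
    pop = np.zeros((N, L), dtype=np.int8)
    pop = _evolve(pop, burn, cfg.mu, cfg.rho, rng_burn)

    ref_pop = _evolve(pop.copy(), cfg.split_gens, cfg.mu, cfg.rho,
                      np.random.default_rng((cfg.seed, 1)))

    fixed: bool | None = None
    if cfg.sel_coeff > 0.0:
        query_pop = None
        for attempt in range(cfg.max_retries):
            rng_q = np.random.default_rng((cfg.seed, 2, attempt))
            trial = pop.copy()
            # plant a single beneficial copy on a random background
            trial[:, sweep_idx] = 0
            trial[rng_q.integers(0, N), sweep_idx] = 1
            trial = _evolve(trial, cfg.split_gens, cfg.mu, cfg.rho, rng_q,
                            sel_site=sweep_idx, s=cfg.sel_coeff)
            freq = trial[:, sweep_idx].mean()
            if freq >= cfg.fix_freq:
                query_pop = trial
                break
        if query_pop is None:
            raise SweepFixationError(
                f"beneficial allele did not reach frequency {cfg.fix_freq} "
                f"within the retry cap of {cfg.max_retries} attempts"
            )
        fixed = True
    else:
        query_pop = _evolve(pop.copy(), cfg.split_gens, cfg.mu, cfg.rho,
                            np.random.default_rng((cfg.seed, 2, 0)))

    rng_s = np.random.default_rng((cfg.seed, 3))
    ref_rows = rng_s.choice(N, size=cfg.n_sample_ref, replace=False)
    qry_rows = rng_s.choice(N, size=cfg.n_sample_query, replace=False)
    sample = np.vstack([ref_pop[ref_rows], query_pop[qry_rows]])

    seg = np.flatnonzero((sample.sum(axis=0) > 0) & (sample.sum(axis=0) < len(sample)))
    calls = sample[:, seg]
    ids = [f"ref_{i}" for i in range(cfg.n_sample_ref)]
    ids += [f"qry_{i}" for i in range(cfg.n_sample_query)]
    matrix = GenotypeMatrix(
        sample_ids=ids,
        chrom=np.array(["sim1"] * len(seg), dtype=object),
        pos=(seg + 1).astype(np.int64),
        ref=np.array(["A"] * len(seg), dtype=object),
        alt=np.array(["T"] * len(seg), dtype=object),
        calls=calls,
    )
    truth = SimTruth(sweep_pos=cfg.sweep_pos, fixed=fixed)
    return matrix, truth


# ---------------------------------------------------------------------------
# haplotype-group locus
# ---------------------------------------------------------------------------

def simulate_haplotype_groups(n1: int, n2: int, n_diff: int,
                              div1: float, div2: float,
                              locus_len: int, seed: int
                              ) -> tuple[LocusHaplotypeSet, SimTruth]:
    """Two haplotype groups whose consensus sequences differ at exactly
    ``n_diff`` uniformly placed sites; individuals mutate off their group
    consensus so that expected within-group per-site diversity is ``div``.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n1, n2 >= 2")
    if n_diff > locus_len:
        raise ValueError("n_diff cannot exceed locus_len")
    rng = np.random.default_rng(seed)
    diff_sites = rng.choice(locus_len, size=n_diff, replace=False)
    consensus = np.zeros((2, locus_len), dtype=np.int8)
    consensus[1, diff_sites] = 1

    # pairwise within-group diversity 2q(1-q) per site ~= div for small div
    seqs = np.empty((n1 + n2, locus_len), dtype=np.int8)
    labels = np.concatenate([np.zeros(n1, dtype=int), np.ones(n2, dtype=int)])
    for g, (div, rows) in enumerate(((div1, range(n1)), (div2, range(n1, n1 + n2)))):
        q = div / 2.0
        for i in rows:
            noise = (rng.random(locus_len) < q).astype(np.int8)
            seqs[i] = consensus[g] ^ noise

    variant = np.flatnonzero(
        (seqs.sum(axis=0) > 0) & (seqs.sum(axis=0) < len(seqs))
    )
    ids = [f"g1_{i}" for i in range(n1)] + [f"g2_{i}" for i in range(n2)]
    locus = LocusHaplotypeSet(
        sample_ids=ids, chrom="locus", start=0, end=locus_len,
        positions=variant.astype(np.int64), vectors=seqs[:, variant],
    )
    truth = SimTruth(group_labels={s: int(l) for s, l in zip(ids, labels)})
    return locus, truth


# ---------------------------------------------------------------------------
# genome pair with planted insertions and genes
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _NUC[rng.integers(0, 4, size=length)].tobytes().decode()


def _mutate_positions(seq: list[str], positions: Sequence[int],
                      rng: np.random.Generator) -> None:
    for p in positions:
        old = seq[p]
        choices = [b for b in "ACGT" if b != old]
        seq[p] = choices[rng.integers(0, 3)]


def simulate_genome_pair(length: int, n_insert: int,
                         insert_len_range: tuple[int, int],
                         snp_rate: float, n_genes: int, seed: int,
                         window_size: int = 1000, step: int = 500
                         ) -> tuple[GenomePair, SimTruth]:
    """Genome B = genome A plus planted novel insertions and background SNPs,
    with ``n_genes`` genes planted per conservation category.

    Categories planted on B (the query genome): ``highly_conserved`` (CDS
    identical in A), ``mutated`` (CDS with ~4% substitutions), then
    ``structural_variant`` (CDS straddling an insertion boundary) and
    ``specific`` (CDS wholly inside an insertion) whenever insertions are
    planted.  The planted insertion intervals (B coordinates, 0-based
    half-open) and the per-gene categories are recorded in the truth.
    """
    rng = np.random.default_rng(seed)
    lo, hi = insert_len_range
    if n_insert > 0 and (lo < 1 or hi < lo):
        raise ValueError("bad insert_len_range")
    gene_len = 600
    margin = 2000
    need = n_insert * (hi + margin) + 4 * n_genes * (gene_len + margin) + margin
    if need > length:
        raise ValueError(
            f"cannot pack {n_insert} insertions and {4 * n_genes} genes into {length} bp"
        )

    a_seq = _random_seq(rng, length)

    ins_lens = [int(rng.integers(lo, hi + 1)) for _ in range(n_insert)]
    # anchor points in A, spaced so insertions and flanking genes never collide
    anchors = np.sort(rng.choice(
        np.arange(margin, length - margin), size=n_insert, replace=False))
    while n_insert > 1 and np.diff(anchors).min() < hi + margin:
        anchors = np.sort(rng.choice(
            np.arange(margin, length - margin), size=n_insert, replace=False))

    b_parts: list[str] = []
    cursor = 0
    offset = 0  # B coordinate minus A coordinate, after processed anchors
    specific: list[tuple[str, int, int]] = []
    sv_zones: list[tuple[int, int]] = []  # (B insertion start, insertion len)
    for anchor, ilen in zip(anchors, ins_lens):
        b_parts.append(a_seq[cursor:anchor])
        ins_start_b = anchor + offset
        b_parts.append(_random_seq(rng, ilen))
        specific.append(("chrB", ins_start_b, ins_start_b + ilen))
        sv_zones.append((ins_start_b, ilen))
        cursor = anchor
        offset += ilen
    b_parts.append(a_seq[cursor:])
    b_list = list("".join(b_parts))
    b_len = len(b_list)

    protected = np.zeros(b_len, dtype=bool)
    for _, s, e in specific:
        protected[s:e] = True

    def b_is_insertion(pos: int) -> bool:
        return any(s <= pos < e for _, s, e in specific)

    genes: list[GeneModel] = []
    categories: dict[str, str] = {}

    def place_conserved_block(glen: int) -> int:
        """Start of a fresh conserved (non-insertion, unprotected) block."""
        for _ in range(10_000):
            s = int(rng.integers(margin // 2, b_len - glen - margin // 2))
            if not protected[s - 50:s + glen + 50].any() and not b_is_insertion(s):
                protected[s - 50:s + glen + 50] = True
                return s
        raise ValueError("infeasible packing of gene models")

    for i in range(n_genes):
        s = place_conserved_block(gene_len)
        gid = f"geneHC_{i}"
        genes.append(GeneModel(gid, "chrB", "+", [(s, s + gene_len)]))
        categories[gid] = "highly_conserved"

    for i in range(n_genes):
        s = place_conserved_block(gene_len)
        n_mut = max(2, int(round(0.04 * gene_len)))
        muts = s + rng.choice(np.arange(20, gene_len - 20), size=n_mut, replace=False)
        _mutate_positions(b_list, sorted(int(m) for m in muts), rng)
        gid = f"geneMUT_{i}"
        genes.append(GeneModel(gid, "chrB", "+", [(s, s + gene_len)]))
        categories[gid] = "mutated"

    if n_insert > 0 and n_genes > 0:
        if len(sv_zones) < 1:
            raise ValueError("structural-variant genes need at least one insertion")
        for i in range(n_genes):
            ins_start, ilen = sv_zones[i % len(sv_zones)]
            inside = int(rng.integers(int(0.2 * gene_len), int(0.45 * gene_len)))
            if inside >= ilen - 50:
                raise ValueError("insertions too short for straddling genes")
            s = ins_start - (gene_len - inside)
            gid = f"geneSV_{i}"
            genes.append(GeneModel(gid, "chrB", "+", [(s, s + gene_len)]))
            categories[gid] = "structural_variant"
            protected[s:ins_start] = True
        for i in range(n_genes):
            ins_start, ilen = sv_zones[i % len(sv_zones)]
            if ilen < gene_len + 400:
                raise ValueError("insertions too short to host specific genes")
            s = ins_start + 200 + (i // len(sv_zones)) * 0  # interior placement
            gid = f"geneSP_{i}"
            genes.append(GeneModel(gid, "chrB", "+", [(s, s + gene_len)]))
            categories[gid] = "specific"

    if snp_rate > 0.0:
        eligible = np.flatnonzero(~protected)
        n_snp = rng.poisson(len(eligible) * snp_rate)
        if n_snp:
            snp_pos = rng.choice(eligible, size=min(n_snp, len(eligible)), replace=False)
            _mutate_positions(b_list, sorted(int(p) for p in snp_pos), rng)

    pair = GenomePair(query={"chrB": "".join(b_list)}, target={"chrA": a_seq},
                      window_size=window_size, step=step)
    truth = SimTruth(
        specific_intervals=IntervalSet(specific) if specific else IntervalSet([]),
        gene_categories=categories,
        genes=genes,
    )
    return pair, truth


# ---------------------------------------------------------------------------
# k-mer histogram
# ---------------------------------------------------------------------------

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def simulate_kmer_histogram(genome: str, depth: float, k: int, seed: int,
                            read_len: int = 1000) -> KmerHistogram:
    """Draw error-free reads uniformly to ``depth`` coverage, count their
    k-mers, and return the multiplicity histogram."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    if k < 11:
        raise ValueError("k must be >= 11")
    G = len(genome)
    if G < k:
        raise ValueError("genome shorter than k")
    read_len = min(read_len, G)
    rng = np.random.default_rng(seed)
    n_reads = max(1, int(round(depth * G / read_len)))
    starts = rng.integers(0, G - read_len + 1, size=n_reads)

    enc = _CODE[np.frombuffer(genome.encode(), dtype=np.uint8)]
    if (enc == 255).any():
        raise ValueError("genome contains non-ACGT characters")
    reads = enc[starts[:, None] + np.arange(read_len)[None, :]].astype(np.uint64)

    n_kmers_per_read = read_len - k + 1
    codes = np.zeros((n_reads, n_kmers_per_read), dtype=np.uint64)
    for j in range(k):
        codes = (codes << np.uint64(2)) | reads[:, j:j + n_kmers_per_read]
    _, mult = np.unique(codes.ravel(), return_counts=True)
    ms, cs = np.unique(mult, return_counts=True)
    return KmerHistogram(k=k, counts={int(m): int(c) for m, c in zip(ms, cs)})
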