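"""Readers and writers for the standard formats the pipeline touches.

All internal coordinates are 0-based half-open.  The only places the
1-based inclusive convention of VCF and GFF3 appears are the read/write
boundaries in this module: positions are converted on the way in and
restored on the way out.

The genotype substrate is :class:`GenotypeMatrix` — haplotypes by biallelic
SNP sites, with entries 0 (ref), 1 (alt) or -1 (missing).  Diploid VCF
calls are split into two haplotypes per sample (``S`` becomes ``S|1`` and
``S|2``); see :func:`read_vcf`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

MISSING = -1

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "PopulationSpec",
    "GeneModel",
    "IntervalSet",
    "read_vcf",
    "write_vcf",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_bed",
    "write_bed",
    "read_newick",
    "write_newick",
    "read_population_tsv",
    "write_population_tsv",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Haplotypes x biallelic SNP sites.

    Parameters
    ----------
    sample_ids
        One identifier per haplotype row.  Haplotypes split from a diploid
        sample ``S`` are named ``S|1`` and ``S|2``.
    chrom, pos, ref, alt
        Per-site contig name, 1-based position, and single-nucleotide
        alleles.  Positions are strictly increasing within each contig.
    calls
        ``(n_haplotypes, n_sites)`` int8 array with entries in
        ``{0, 1, MISSING}``.
    """

    sample_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    calls: np.ndarray
    n_skipped: int = 0

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be 2-D (haplotypes x sites)")
        n_hap, n_sites = self.calls.shape
        if n_hap != len(self.sample_ids):
            raise ValueError("calls rows do not match sample_ids")
        for arr, name in ((self.chrom, "chrom"), (self.pos, "pos"),
                          (self.ref, "ref"), (self.alt, "alt")):
            if len(arr) != n_sites:
                raise ValueError(f"{name} length does not match calls columns")
        bad = ~np.isin(self.calls, (0, 1, MISSING))
        if bad.any():
            raise ValueError("calls entries must be 0, 1 or MISSING (-1)")
        for c in dict.fromkeys(self.chrom):
            p = self.pos[self.chrom == c]
            if len(p) > 1 and not (np.diff(p) > 0).all():
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_haplotypes(self) -> int:
        return self.calls.shape[0]

    @property
    def n_sites(self) -> int:
        return self.calls.shape[1]

    def subset_samples(self, idx: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in idx],
            chrom=self.chrom, pos=self.pos, ref=self.ref, alt=self.alt,
            calls=self.calls[idx],
        )

    def subset_sites(self, idx: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            chrom=self.chrom[idx], pos=self.pos[idx],
            ref=self.ref[idx], alt=self.alt[idx],
            calls=self.calls[:, idx],
        )

    def site_counts(self, rows: Sequence[int] | None = None):
        """Per-site derived-allele count ``k`` and called-haplotype count ``n``."""
        c = self.calls if rows is None else self.calls[np.asarray(rows, dtype=int)]
        called = c != MISSING
        n = called.sum(axis=0)
        k = (c == 1).sum(axis=0)
        return k.astype(np.int64), n.astype(np.int64)

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.sample_ids == other.sample_ids
            and np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.ref, other.ref)
            and np.array_equal(self.alt, other.alt)
            and np.array_equal(self.calls, other.calls)
        )


def _base_id(hap_id: str) -> str:
    return hap_id.rsplit("|", 1)[0]


@dataclass
class PopulationSpec:
    """Mapping from sample id to population label.

    Haplotype ids of the form ``S|1`` / ``S|2`` match the assignment of
    their base sample ``S``.
    """

    assignment: dict[str, str]

    def populations(self) -> list[str]:
        return sorted(set(self.assignment.values()))

    def haplotype_indices(self, matrix: GenotypeMatrix, population: str) -> np.ndarray:
        idx = [
            i for i, s in enumerate(matrix.sample_ids)
            if self.assignment.get(s, self.assignment.get(_base_id(s))) == population
        ]
        return np.asarray(idx, dtype=int)

    def validate(self, matrix: GenotypeMatrix, min_samples: int = 2) -> None:
        known = set(matrix.sample_ids) | {_base_id(s) for s in matrix.sample_ids}
        missing = [s for s in self.assignment if s not in known]
        if missing:
            raise ValueError(f"samples not in matrix: {missing[:5]}")
        for pop in self.populations():
            if len(self.haplotype_indices(matrix, pop)) < min_samples:
                raise ValueError(f"population {pop!r} has < {min_samples} haplotypes")


@dataclass
class GeneModel:
    """A gene with its CDS intervals in internal (0-based half-open) coordinates."""

    gene_id: str
    chrom: str
    strand: str
    cds: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        self.cds = sorted((int(a), int(b)) for a, b in self.cds)
        prev_end = None
        for start, end in self.cds:
            if end <= start:
                raise ValueError(f"{self.gene_id}: inverted CDS [{start},{end})")
            if prev_end is not None and start < prev_end:
                raise ValueError(f"{self.gene_id}: overlapping CDS intervals")
            prev_end = end

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    @property
    def span(self) -> tuple[int, int]:
        return self.cds[0][0], self.cds[-1][1]


@dataclass
class IntervalSet:
    """(chrom, start, end) triples, 0-based half-open."""

    intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for c, s, e in self.intervals:
            if e <= s:
                raise ValueError(f"inverted interval {c}:{s}-{e}")
        self.intervals = sorted((str(c), int(s), int(e)) for c, s, e in self.intervals)

    def merged(self) -> "IntervalSet":
        out: list[tuple[str, int, int]] = []
        for c, s, e in self.intervals:
            if out and out[-1][0] == c and s <= out[-1][2]:
                out[-1] = (c, out[-1][1], max(out[-1][2], e))
            else:
                out.append((c, s, e))
        return IntervalSet(out)

    @property
    def total_bp(self) -> int:
        return sum(e - s for _, s, e in self.merged().intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_NUCS = frozenset("ACGT")


def read_vcf(path: str | Path, assume_haploid: bool = False) -> GenotypeMatrix:
    """Read a VCF 4.x into a :class:`GenotypeMatrix`.

    Diploid GT fields are split into two haplotypes per sample; haploid GT
    fields give one haplotype per sample.  Multiallelic and non-SNP records
    are skipped and counted in ``matrix.n_skipped``.  With
    ``assume_haploid`` a diploid GT raises instead of being split.
    """
    path = Path(path)
    try:
        vf = pysam.VariantFile(str(path))
    except Exception as exc:  # pragma: no cover - pysam error text varies
        raise ValueError(f"malformed VCF {path}: {exc}") from exc

    samples = list(vf.header.samples)
    chrom: list[str] = []
    pos: list[int] = []
    ref: list[str] = []
    alt: list[str] = []
    columns: list[np.ndarray] = []
    n_skipped = 0
    ploidy: int | None = None

    for lineno, rec in enumerate(vf, start=1):
        alts = rec.alts or ()
        if (
            len(alts) != 1
            or rec.ref is None
            or len(rec.ref) != 1
            or len(alts[0]) != 1
            or rec.ref.upper() not in _NUCS
            or alts[0].upper() not in _NUCS
        ):
            n_skipped += 1
            continue
        gts = []
        for s in samples:
            gt = rec.samples[s].get("GT", (None,))
            if gt is None:
                gt = (None,)
            gts.append(gt)
        rec_ploidy = max(len(g) for g in gts) if gts else 1
        if rec_ploidy > 2:
            raise ValueError(f"record {lineno} ({rec.chrom}:{rec.pos}): ploidy > 2")
        if assume_haploid and rec_ploidy == 2:
            raise ValueError(
                f"record {lineno} ({rec.chrom}:{rec.pos}): diploid GT with --assume-haploid"
            )
        if ploidy is None:
            ploidy = rec_ploidy
        elif rec_ploidy != ploidy:
            raise ValueError(f"record {lineno}: mixed ploidy in VCF")

        col = np.full(len(samples) * ploidy, MISSING, dtype=np.int8)
        for i, gt in enumerate(gts):
            for j in range(ploidy):
                a = gt[j] if j < len(gt) else None
                if a is not None:
                    if a not in (0, 1):
                        raise ValueError(f"record {lineno}: allele index {a} out of range")
                    col[i * ploidy + j] = a
        chrom.append(rec.chrom)
        pos.append(rec.pos)
        ref.append(rec.ref.upper())
        alt.append(alts[0].upper())
        columns.append(col)

    vf.close()
    if ploidy is None:
        ploidy = 1
    if ploidy == 2:
        sample_ids = [f"{s}|{h}" for s in samples for h in (1, 2)]
    else:
        sample_ids = samples
    calls = (
        np.stack(columns, axis=1)
        if columns
        else np.zeros((len(sample_ids), 0), dtype=np.int8)
    )
    if n_skipped:
        logger.info("read_vcf: skipped %d multiallelic/non-SNP records", n_skipped)
    return GenotypeMatrix(
        sample_ids=sample_ids,
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        calls=calls,
        n_skipped=n_skipped,
    )


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a haploid-GT VCF 4.2 (one column per haplotype row)."""
    path = Path(path)
    order: dict[str, None] = dict.fromkeys(matrix.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in order:
            fh.write(f"##contig=<ID={c}>\n")
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        header += list(matrix.sample_ids)
        fh.write("\t".join(header) + "\n")
        for j in range(matrix.n_sites):
            gts = ["." if v == MISSING else str(int(v)) for v in matrix.calls[:, j]]
            row = [
                str(matrix.chrom[j]), str(int(matrix.pos[j])), ".",
                str(matrix.ref[j]), str(matrix.alt[j]), ".", "PASS", ".", "GT",
            ] + gts
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an ordered ``{name: sequence}`` dict (uppercased)."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models (gene/mRNA/CDS) from GFF3.

    GFF's 1-based inclusive CDS coordinates become 0-based half-open;
    CDS intervals of all transcripts of a gene are union-merged so the
    per-gene interval list is sorted and non-overlapping.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        raw: list[tuple[int, int]] = []
        for c in db.children(g.id, featuretype="CDS"):
            if c.end < c.start:
                raise ValueError(f"{g.id}: CDS end < start at {c.start}-{c.end}")
            raw.append((c.start - 1, c.end))
        merged: list[tuple[int, int]] = []
        for s, e in sorted(raw):
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        genes.append(GeneModel(gene_id=g.id, chrom=g.seqid, strand=g.strand, cds=merged))
    return genes


def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            start, end = g.span
            fh.write(
                f"{g.chrom}\tpopsweep\tgene\t{start + 1}\t{end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            mrna = f"{g.gene_id}.t1"
            fh.write(
                f"{g.chrom}\tpopsweep\tmRNA\t{start + 1}\t{end}\t.\t{g.strand}\t.\t"
                f"ID={mrna};Parent={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.cds, start=1):
                fh.write(
                    f"{g.chrom}\tpopsweep\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t0\t"
                    f"ID={mrna}.cds{i};Parent={mrna}\n"
                )


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> IntervalSet:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        usecols=[0, 1, 2], names=["chrom", "start", "end"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64},
    )
    bad = df[df.end <= df.start]
    if len(bad):
        row = bad.iloc[0]
        raise ValueError(f"BED interval end <= start: {row.chrom}:{row.start}-{row.end}")
    return IntervalSet(list(df.itertuples(index=False, name=None)))


def write_bed(intervals: IntervalSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for c, s, e in intervals:
            fh.write(f"{c}\t{s}\t{e}\n")


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def read_newick(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


# ---------------------------------------------------------------------------
# population TSV
# ---------------------------------------------------------------------------

def read_population_tsv(path: str | Path) -> PopulationSpec:
    """Two-column TSV: sample id, population label.  A header line
    ``sample<TAB>population`` is accepted and ignored."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "population"],
                     dtype=str)
    if len(df) and df.iloc[0, 0] == "sample":
        df = df.iloc[1:]
    return PopulationSpec(dict(zip(df["sample"], df["population"])))


def write_population_tsv(spec: PopulationSpec, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s, p in spec.assignment.items():
            fh.write(f"{s}\t{p}\n")
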