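"""Domain types and readers/writers for the standard formats the pipeline touches.

All internal coordinates are 1-based inclusive.  VCF positions are kept
as-is; BED intervals are converted on read and write.  Sequences are held
as uppercase strings over the alphabet {A, C, G, T, N}.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import gffutils
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "SequenceSet",
    "GeneModel",
    "VariantRecord",
    "GenomicInterval",
    "QTLHotspot",
    "FormatError",
    "ModelError",
    "read_fasta",
    "write_fasta",
    "read_gff3_genes",
    "write_gff3",
    "read_vcf_variants",
    "write_vcf",
    "read_bed_intervals",
    "read_hotspot_bed",
    "write_bed",
    "write_report_table",
]

_VALID_BASES = frozenset("ACGTN")


class FormatError(ValueError):
    """A file does not conform to the expected text format."""


class ModelError(ValueError):
    """A gene model violates its structural invariants."""


@dataclass
class SequenceSet:
    """A set of named nucleotide sequences (e.g., a reference genome)."""

    entries: dict[str, str] = field(default_factory=dict)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.entries.items()}

    def __getitem__(self, name: str) -> str:
        return self.entries[name]

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return bases ``start..end`` (1-based inclusive, clipped to the chromosome)."""
        seq = self.entries[chrom]
        return seq[max(start - 1, 0) : min(end, len(seq))]


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based inclusive interval on a chromosome."""

    id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"interval {self.id}: start {self.start} > end {self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )


@dataclass(frozen=True)
class QTLHotspot:
    """A QTL hotspot interval plus the parent donating the tolerant allele."""

    interval: GenomicInterval
    hotspot_id: int
    donor_parent: str


@dataclass
class GeneModel:
    """A protein-coding gene locus with one transcript.

    Exons are sorted by genomic coordinate and non-overlapping; CDS segments
    are contained in exons; UTRs are derived as exonic-minus-CDS, split by
    coding orientation.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]]
    cds_segments: list[tuple[int, int]]
    stress_related: bool = False
    description: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ModelError(f"{self.gene_id}: strand must be + or -")
        self.exons = sorted(self.exons)
        self.cds_segments = sorted(self.cds_segments)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ModelError(f"{self.gene_id}: overlapping exons")
        for cs, ce in self.cds_segments:
            if not any(s <= cs and ce <= e for s, e in self.exons):
                raise ModelError(f"{self.gene_id}: CDS segment {cs}-{ce} outside exons")

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.gene_id, self.chrom, self.start, self.end)

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_segments)

    def _utr_intervals(self) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
        """Exonic intervals left/right of the CDS span, in genomic order."""
        if not self.cds_segments:
            return [], []
        cds_lo = self.cds_segments[0][0]
        cds_hi = self.cds_segments[-1][1]
        left, right = [], []
        for s, e in self.exons:
            if s < cds_lo:
                left.append((s, min(e, cds_lo - 1)))
            if e > cds_hi:
                right.append((max(s, cds_hi + 1), e))
        return left, right

    @property
    def five_prime_utr(self) -> list[tuple[int, int]]:
        left, right = self._utr_intervals()
        return left if self.strand == "+" else right

    @property
    def three_prime_utr(self) -> list[tuple[int, int]]:
        left, right = self._utr_intervals()
        return right if self.strand == "+" else left

    def shifted(self, offset: int) -> "GeneModel":
        """A copy of this model translated by ``offset`` bases."""
        return replace(
            self,
            start=self.start + offset,
            end=self.end + offset,
            exons=[(s + offset, e + offset) for s, e in self.exons],
            cds_segments=[(s + offset, e + offset) for s, e in self.cds_segments],
        )


@dataclass(frozen=True)
class VariantRecord:
    """One called variant in VCF convention (anchored-base indels)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float
    zygosity: str  # "hom" | "het"
    sample_id: str
    reference_id: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    @property
    def net_length(self) -> int:
        return len(self.alt) - len(self.ref)

    @property
    def ref_span(self) -> tuple[int, int]:
        """Genomic span of the reference allele, 1-based inclusive."""
        return self.pos, self.pos + len(self.ref) - 1

    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | os.PathLike) -> SequenceSet:
    """Read a FASTA file into a :class:`SequenceSet` (sequences uppercased)."""
    entries: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - _VALID_BASES
        if bad:
            raise FormatError(
                f"{path}: record {rec.id} contains non-IUPAC characters {sorted(bad)}"
            )
        if rec.id in entries:
            raise FormatError(f"{path}: duplicate sequence id {rec.id}")
        entries[rec.id] = seq
    return SequenceSet(entries)


def write_fasta(seqs: SequenceSet, path: str | os.PathLike, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in seqs.entries.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# GFF3


def read_gff3_genes(
    path: str | os.PathLike, stress_gene_ids: set[str] | frozenset[str] = frozenset()
) -> list[GeneModel]:
    """Parse gene models from GFF3 (one transcript per gene).

    If a gene carries several mRNAs the transcript with the longest summed
    CDS is used.  ``stress_related`` is set for genes whose id is in
    ``stress_gene_ids``.  Genes without CDS are retained with empty
    ``cds_segments``.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        transcripts = list(db.children(gene, featuretype="mRNA"))
        best_exons: list[tuple[int, int]] = []
        best_cds: list[tuple[int, int]] = []
        best_len = -1
        parents = transcripts if transcripts else [gene]
        for tx in parents:
            exons = [(f.start, f.end) for f in db.children(tx, featuretype="exon")]
            cds = [(f.start, f.end) for f in db.children(tx, featuretype="CDS")]
            clen = sum(e - s + 1 for s, e in cds)
            if clen > best_len:
                best_len = clen
                best_exons, best_cds = sorted(exons), sorted(cds)
        if not best_exons:
            best_exons = [(gene.start, gene.end)]
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                start=gene.start,
                end=gene.end,
                exons=best_exons,
                cds_segments=best_cds,
                stress_related=gene.id in stress_gene_ids,
                description=gene.attributes.get("description", [""])[0],
            )
        )
    return genes


def write_gff3(genes: list[GeneModel], path: str | os.PathLike) -> None:
    """Emit gene/mRNA/exon/CDS features for each model."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            attrs = f"ID={g.gene_id}"
            if g.description:
                attrs += f";description={g.description}"
            fh.write(
                f"{g.chrom}\tsaltmine\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            mrna = f"{g.gene_id}.1"
            fh.write(
                f"{g.chrom}\tsaltmine\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mrna};Parent={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\tsaltmine\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={mrna}.exon{i};Parent={mrna}\n"
                )
            for i, (s, e) in enumerate(g.cds_segments, 1):
                fh.write(
                    f"{g.chrom}\tsaltmine\tCDS\t{s}\t{e}\t.\t{g.strand}\t0\t"
                    f"ID={mrna}.cds{i};Parent={mrna}\n"
                )


# ---------------------------------------------------------------------------
# VCF


def read_vcf_variants(
    path: str | os.PathLike, sample_id: str, reference_id: str
) -> list[VariantRecord]:
    """Read a single-sample VCF into variant records.

    Multi-allelic sites are split into one record per alternate allele.
    Zygosity derives from GT (missing GT -> "het", conservatively excluded
    by the downstream homozygosity filter); missing QUAL -> 0.
    """
    out: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            qual = float(rec.qual) if rec.qual is not None else 0.0
            gt = None
            if rec.samples:
                sample = rec.samples[0]
                gt = sample.get("GT")
            for i, alt in enumerate(rec.alts or (), start=1):
                if alt is None or alt == "*":
                    continue
                if gt is None or any(a is None for a in gt):
                    zyg = "het"
                else:
                    zyg = "hom" if all(a == i for a in gt) else "het"
                out.append(
                    VariantRecord(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        qual=qual,
                        zygosity=zyg,
                        sample_id=sample_id,
                        reference_id=reference_id,
                    )
                )
    return out


def write_vcf(
    variants: list[VariantRecord],
    path: str | os.PathLike,
    contig_lengths: dict[str, int],
    sample_name: str = "SAMPLE",
) -> None:
    """Write variant records as a minimal single-sample VCF v4.2 text file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=saltmine\n")
        for chrom, length in contig_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample_name + "\n"
        )
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)):
            gt = "1/1" if v.zygosity == "hom" else "0/1"
            qual = f"{v.qual:g}"
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t{qual}\t.\t.\tGT\t{gt}\n"
            )


# ---------------------------------------------------------------------------
# BED


def read_bed_intervals(path: str | os.PathLike) -> list[GenomicInterval]:
    """Read 3+ column BED (0-based half-open) into 1-based inclusive intervals."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise FormatError(f"{path}:{lineno}: BED start {start} >= end {end}")
            name = fields[3] if len(fields) > 3 else f"interval{len(out) + 1}"
            out.append(GenomicInterval(name, chrom, start + 1, end))
    return out


def read_hotspot_bed(path: str | os.PathLike) -> list[QTLHotspot]:
    """Read hotspots from BED with name column ``hotspot<k>:<donor>``."""
    hotspots = []
    for iv in read_bed_intervals(path):
        name, _, donor = iv.id.partition(":")
        if not name.startswith("hotspot") or not donor:
            raise FormatError(f"hotspot BED name {iv.id!r} not of form hotspot<k>:<donor>")
        hotspots.append(QTLHotspot(iv, int(name[len("hotspot") :]), donor))
    return hotspots


def write_bed(intervals: list[GenomicInterval], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{iv.id}\n")


def write_hotspot_bed(hotspots: list[QTLHotspot], path: str | os.PathLike) -> None:
    write_bed(
        [
            GenomicInterval(
                f"hotspot{h.hotspot_id}:{h.donor_parent}",
                h.interval.chrom,
                h.interval.start,
                h.interval.end,
            )
            for h in hotspots
        ],
        path,
    )


# ---------------------------------------------------------------------------
# Report tables


def write_report_table(rows: list[dict], path: str | os.PathLike, columns: list[str] | None = None) -> None:
    """Write homogeneous records as TSV, sorted by (gene_id, pos) when present."""
    if columns is None:
        columns = list(rows[0].keys()) if rows else []

    def sort_key(r: dict):
        return (str(r.get("gene_id", "")), int(r.get("pos", 0)))

    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for r in sorted(rows, key=sort_key):
            fh.write("\t".join(str(r.get(c, "")) for c in columns) + "\n")
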