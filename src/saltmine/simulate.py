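"""Fully labelled synthetic study generator.

Emulates the study design this pipeline targets: two inbred rice parents
called against two coordinate-shifted reference genomes, genes inside and
outside QTL hotspot intervals, planted exon/intron/UTR/promoter variants
with constructively computed consequences, and a cultivar panel
segregating the planted InDels at configurable allele frequencies.

Truth is computed constructively — the generator builds the mutated codons
and frames itself with its own codon table and never calls the annotator
under test.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np

from .io import (
    GeneModel,
    GenomicInterval,
    QTLHotspot,
    SequenceSet,
    VariantRecord,
    write_bed,
    write_fasta,
    write_gff3,
    write_hotspot_bed,
    write_vcf,
)

__all__ = [
    "PlantSpec",
    "SimulationConfig",
    "TruthRecord",
    "SimulatedStudy",
    "SpecError",
    "default_variant_plan",
    "generate_reference_genome",
    "derive_second_reference",
    "plant_parental_variants",
    "generate_panel",
    "emit_truth_table",
    "simulate_study",
    "synthesize_cds_locus",
    "concordance_demo_config",
]

# Generator-private codon table (independent truth oracle; the annotator
# keeps its own).
_BASES = "ACGT"
_T = {}
for _c1 in _BASES:
    for _c2 in _BASES:
        for _c3 in _BASES:
            _T[_c1 + _c2 + _c3] = None
_T.update(
    {
        "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
        "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
        "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
        "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
        "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
        "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
        "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
        "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
        "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
        "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
        "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
        "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
        "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
        "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
        "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
        "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
    }
)
_SENSE_CODONS = sorted(c for c, aa in _T.items() if aa not in (None, "*"))
_STOPS = {"TAA", "TAG", "TGA"}
_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def _translate(seq: str) -> tuple[str, bool]:
    """Generator-private translation: protein up to first stop, no-stop flag."""
    aas = []
    for i in range(0, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if codon in _STOPS:
            return "".join(aas), False
        aas.append(_T.get(codon) or "X")
    return "".join(aas), True


class SpecError(ValueError):
    """A planted-variant spec cannot be realized in the generated genome."""


@dataclass(frozen=True)
class PlantSpec:
    """One variant to plant.

    ``feature`` targets exon/intron/5utr/3utr/promoter/intergenic;
    ``consequence`` is the intended effect for exonic (and start-gain)
    specs, "noncoding" otherwise; ``net`` is the signed indel length.
    """

    feature: str
    vtype: str  # "snp" | "indel"
    consequence: str
    carrier: str = "P1"  # "P1" | "P2" | "both"
    net: int = 0
    quality: float = 150.0
    zygosity: str = "hom"
    ref1_only: bool = False


def default_variant_plan(n_per_class: int = 22) -> list[PlantSpec]:
    """The default planting plan: every consequence class plus noncoding
    variants in each genic feature, carriers cycling P1/P2/both."""
    plan: list[PlantSpec] = []
    carriers = ["P1", "P2", "both"]
    k = 0

    def add(feature, vtype, consequence, net=0):
        nonlocal k
        plan.append(
            PlantSpec(feature, vtype, consequence, carriers[k % 3], net=net)
        )
        k += 1

    for i in range(n_per_class):
        add("exon", "snp", "synonymous")
        add("exon", "snp", "missense")
        add("exon", "indel", "inframe_indel", net=[3, -3, 6, -6][i % 4])
        add("exon", "indel", "frameshift", net=[1, -1, 2, -2][i % 4])
        add("exon", "snp", "stop_gain")
        add("exon", "snp", "stop_loss")
        add("5utr" if i % 5 else "promoter", "snp", "start_gain")
    for i in range(n_per_class):
        for feat in ("intron", "3utr", "promoter", "intergenic"):
            add(feat, "snp" if i % 2 else "indel", "noncoding",
                net=0 if i % 2 else [2, -2, 3][i % 3])
    return plan


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 500_000
    n_genes: int = 40
    n_hotspots: int = 4
    fraction_genes_in_hotspots: float = 0.8
    planted_variants: list[PlantSpec] = field(default_factory=default_variant_plan)
    second_reference_shift: dict[str, int] = field(
        default_factory=lambda: {"chr1": 5000, "chr2": 12000}
    )
    panel_size: int = 50
    panel_allele_frequencies: list[float] = field(
        default_factory=lambda: [0.04, 0.10, 0.25, 0.40, 0.60, 0.75]
    )
    donor_lines: tuple[str, ...] = ("Pokkali", "Nona_bokra", "FL478")
    p1_name: str = "At354"
    p2_name: str = "Bg352"
    ref1_name: str = "ref1"
    ref2_name: str = "ref2"
    promoter_length: int = 1000
    readthrough_limit: int = 3000

    def __post_init__(self) -> None:
        if not 0 <= self.fraction_genes_in_hotspots <= 1:
            raise ValueError("fraction_genes_in_hotspots must be in [0,1]")
        for f in self.panel_allele_frequencies:
            if not 0 <= f <= 1:
                raise ValueError("panel allele frequencies must be in [0,1]")


@dataclass
class TruthRecord:
    gene_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    vtype: str
    feature: str
    consequence: str
    aa_change: str
    protein_length_ref: int
    protein_length_alt: int
    frame_shift_start: int | None
    carriers: tuple[str, ...]
    quality: float
    zygosity: str
    ref1_only: bool
    pos_ref2: int

    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def locus_id(self) -> str:
        return f"{self.gene_id}:{self.pos}"


# ---------------------------------------------------------------------------
# Gene construction


@dataclass
class _GeneBuild:
    """Private construction record pairing a GeneModel with its coding-space view."""

    model: GeneModel
    local: str  # utr5 + exons/introns + utr3, coding orientation
    place_start: int  # genomic 1-based start of the local block
    utr5_len: int
    utr3_len: int
    cds_local: list[tuple[int, int]]  # CDS segments in local coordinates
    intron_local: list[tuple[int, int]]

    def local_to_genomic(self, x: int) -> int:
        if self.model.strand == "+":
            return self.place_start + x - 1
        return self.place_start + len(self.local) - x

    @property
    def spliced_cds(self) -> str:
        return "".join(self.local[s - 1 : e] for s, e in self.cds_local)

    def spliced_to_local(self, i: int) -> int:
        """Map a 1-based spliced-CDS offset to a local coordinate."""
        for s, e in self.cds_local:
            seg = e - s + 1
            if i <= seg:
                return s + i - 1
            i -= seg
        raise IndexError("spliced offset beyond CDS")

    def segment_room(self, i: int, width: int) -> bool:
        """True if spliced offsets i..i+width-1 fall in one CDS segment."""
        a = self.spliced_to_local(i)
        b = self.spliced_to_local(i + width - 1)
        return any(s <= a and b <= e for s, e in self.cds_local) and b - a + 1 == width


def _build_gene(
    rng: np.random.Generator, gene_id: str, chrom: str, place_start: int, strand: str
) -> _GeneBuild:
    n_codons = int(rng.integers(250, 400))
    utr5_len, utr3_len, intron_len = 150, 150, 120
    body = [_SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), n_codons - 1)]
    cds = "ATG" + "".join(body) + "TAA"
    # split CDS into three codon-aligned chunks
    third = (len(cds) // 9) * 3
    chunks = [cds[:third], cds[third : 2 * third], cds[2 * third :]]
    utr5 = "".join(rng.choice(list(_BASES), utr5_len))
    utr3 = "".join(rng.choice(list(_BASES), utr3_len))
    introns = ["".join(rng.choice(list(_BASES), intron_len)) for _ in range(2)]

    local = utr5 + chunks[0] + introns[0] + chunks[1] + introns[1] + chunks[2] + utr3
    o = utr5_len
    cds_local = []
    intron_local = []
    for i, chunk in enumerate(chunks):
        cds_local.append((o + 1, o + len(chunk)))
        o += len(chunk)
        if i < 2:
            intron_local.append((o + 1, o + intron_len))
            o += intron_len

    L = len(local)

    def to_genomic(iv: tuple[int, int]) -> tuple[int, int]:
        s, e = iv
        if strand == "+":
            return (place_start + s - 1, place_start + e - 1)
        return (place_start + L - e, place_start + L - s)

    exon_local = [
        (1, cds_local[0][1]),
        cds_local[1],
        (cds_local[2][0], L),
    ]
    model = GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        start=place_start,
        end=place_start + L - 1,
        exons=sorted(to_genomic(iv) for iv in exon_local),
        cds_segments=sorted(to_genomic(iv) for iv in cds_local),
    )
    return _GeneBuild(model, local, place_start, utr5_len, utr3_len, cds_local, intron_local)


def generate_reference_genome(
    config: SimulationConfig,
) -> tuple[SequenceSet, list[GeneModel], list[QTLHotspot]]:
    genome, genes, hotspots, _ = _generate_with_builds(config)
    return genome, genes, hotspots


def _generate_with_builds(config: SimulationConfig):
    rng = np.random.default_rng(config.seed)
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    per_chrom = [
        config.n_genes // config.n_chromosomes
        + (1 if i < config.n_genes % config.n_chromosomes else 0)
        for i in range(config.n_chromosomes)
    ]
    genome_entries: dict[str, str] = {}
    builds: list[_GeneBuild] = []
    clearance = config.promoter_length + 500
    gene_no = 0
    for chrom, k in zip(chrom_names, per_chrom):
        if k:
            slot = config.chrom_length // k
            if slot < clearance + 6000:
                raise SpecError(
                    f"chromosome {chrom} too short for {k} genes with "
                    f"{config.promoter_length}-bp promoter clearance"
                )
        seq = rng.choice(list(_BASES), config.chrom_length)
        seq = "".join(seq)
        pieces = []
        cursor = 0  # 0-based length written so far
        for j in range(k):
            gene_no += 1
            place = j * slot + clearance + int(rng.integers(0, 500))
            gb = _build_gene(rng, f"G{gene_no:03d}", chrom, place + 1, "+" if gene_no % 2 else "-")
            pieces.append(seq[cursor:place])
            pieces.append(gb.local if gb.model.strand == "+" else _revcomp(gb.local))
            cursor = place + len(gb.local)
            builds.append(gb)
        pieces.append(seq[cursor:])
        genome_entries[chrom] = "".join(pieces)[: config.chrom_length]
    genome = SequenceSet(genome_entries)

    hotspots = _place_hotspots(config, builds)
    hotspot_trees = [(h.interval.chrom, h.interval.start, h.interval.end) for h in hotspots]
    genes = []
    for gb in builds:
        genes.append(gb.model)
    del hotspot_trees
    return genome, genes, hotspots, builds


def _place_hotspots(
    config: SimulationConfig, builds: list[_GeneBuild]
) -> list[QTLHotspot]:
    """Choose hotspot intervals covering the configured fraction of genes.

    Genes are grouped into contiguous runs per chromosome; each run becomes
    one hotspot padded by 200 bp (never reaching a neighbouring gene).
    """
    by_chrom: dict[str, list[_GeneBuild]] = {}
    for gb in builds:
        by_chrom.setdefault(gb.model.chrom, []).append(gb)
    n_in = round(config.fraction_genes_in_hotspots * len(builds))
    chroms = sorted(by_chrom)
    n_hot_per = [
        config.n_hotspots // len(chroms)
        + (1 if i < config.n_hotspots % len(chroms) else 0)
        for i in range(len(chroms))
    ]
    total = len(builds)
    hotspots: list[QTLHotspot] = []
    hid = 0
    remaining_in = n_in
    for chrom, n_hot in zip(chroms, n_hot_per):
        gbs = sorted(by_chrom[chrom], key=lambda g: g.model.start)
        share = round(n_in * len(gbs) / total)
        share = min(share, remaining_in, len(gbs))
        remaining_in -= share
        if n_hot == 0 or share == 0:
            continue
        base = share // n_hot
        sizes = [base + (1 if i < share % n_hot else 0) for i in range(n_hot)]
        cursor = 0
        for size in sizes:
            if size == 0:
                continue
            run = gbs[cursor : cursor + size]
            cursor += size
            hid += 1
            iv = GenomicInterval(
                f"hotspot{hid}",
                chrom,
                max(run[0].model.start - 200, 1),
                run[-1].model.end + 200,
            )
            donor = "P1" if hid % 2 else "P2"
            hotspots.append(QTLHotspot(iv, hid, donor))
    return hotspots


# ---------------------------------------------------------------------------
# Second reference


def derive_second_reference(
    genome: SequenceSet,
    genes: list[GeneModel],
    shifts: dict[str, int],
    seed: int = 0,
) -> tuple[SequenceSet, list[GeneModel], list[tuple[str, GenomicInterval, GenomicInterval]]]:
    """Second reference with padding inserted at chromosome starts.

    Returns the shifted genome, shifted gene models and the anchor map
    pairing each gene's span in both references.
    """
    rng = np.random.default_rng(seed + 104729)
    entries = {}
    for chrom, seq in genome.entries.items():
        shift = shifts.get(chrom, 0)
        if shift < 0:
            raise ValueError("shifts must be >= 0")
        pad = "".join(rng.choice(list(_BASES), shift)) if shift else ""
        entries[chrom] = pad + seq
    genes2 = [g.shifted(shifts.get(g.chrom, 0)) for g in genes]
    anchors = [
        (g.gene_id, g.span, g2.span) for g, g2 in zip(genes, genes2)
    ]
    return SequenceSet(entries), genes2, anchors


# ---------------------------------------------------------------------------
# Variant planting

_SNP_ALTS = {b: [c for c in _BASES if c != b] for b in _BASES}


def _scan_upstream_starts(upstream: str) -> set[int]:
    """Generator-private start-gain scan (offsets in residues)."""
    n = len(upstream)
    out = set()
    for i in range(n - 2):
        if upstream[i : i + 3] == "ATG" and (n - i) % 3 == 0:
            if not any(
                upstream[j : j + 3] in _STOPS for j in range(i, n, 3)
            ):
                out.add((n - i) // 3)
    return out


class _Planter:
    def __init__(self, config: SimulationConfig, genome: SequenceSet, builds: list[_GeneBuild]):
        self.cfg = config
        self.genome = genome
        self.builds = builds
        self.rng = np.random.default_rng(config.seed + 7919)
        self.used: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.entries}
        self.stop_used: set[str] = set()

    # -- bookkeeping

    def _free(self, chrom: str, lo: int, hi: int, pad: int = 10) -> bool:
        return all(hi + pad < s or e + pad < lo for s, e in self.used[chrom])

    def _reserve(self, chrom: str, lo: int, hi: int) -> None:
        self.used[chrom].append((lo, hi))

    # -- sequence context (coding orientation), generator-private

    def _downstream(self, gb: _GeneBuild) -> str:
        """3'UTR plus post-gene genomic sequence, coding orientation."""
        m = gb.model
        chrom_seq = self.genome[m.chrom]
        limit = self.cfg.readthrough_limit
        utr3 = gb.local[len(gb.local) - gb.utr3_len :]
        if m.strand == "+":
            tail = chrom_seq[m.end : m.end + limit]
        else:
            tail = _revcomp(chrom_seq[max(m.start - 1 - limit, 0) : m.start - 1])
        return (utr3 + tail)[:limit]

    def _upstream(self, gb: _GeneBuild, edit: tuple[int, str, str] | None = None) -> str:
        """Promoter plus 5'UTR in coding orientation, optionally with a
        genomic-space edit (pos, ref, alt) applied, window endpoints lifted
        onto the mutated sequence the way the pipeline extracts them."""
        m = gb.model
        chrom_seq = self.genome[m.chrom]
        if edit is not None:
            pos, ref, alt = edit
            assert chrom_seq[pos - 1 : pos - 1 + len(ref)] == ref
            chrom_seq = chrom_seq[: pos - 1] + alt + chrom_seq[pos - 1 + len(ref) :]
            net = len(alt) - len(ref)
        else:
            pos, ref, net = None, "", 0

        def lift(c: int) -> int:
            if pos is None or c < pos:
                return c
            if c >= pos + len(ref):
                return c + net
            return pos

        plen = self.cfg.promoter_length
        if m.strand == "+":
            gs = lift(m.start)
            utr_end = lift(m.start + gb.utr5_len - 1)
            prom = chrom_seq[max(gs - 1 - plen, 0) : gs - 1]
            utr5 = chrom_seq[gs - 1 : utr_end]
        else:
            ge = lift(m.end)
            utr_start = lift(m.end - gb.utr5_len + 1)
            prom = _revcomp(chrom_seq[ge : ge + plen])
            utr5 = _revcomp(chrom_seq[utr_start - 1 : ge])
        return prom + utr5

    # -- genomic representation of coding-space edits

    def _snp_record(self, gb: _GeneBuild, local_x: int, alt_local: str) -> tuple[int, str, str]:
        g = gb.local_to_genomic(local_x)
        if gb.model.strand == "+":
            return g, gb.local[local_x - 1], alt_local
        return g, gb.local[local_x - 1].translate(_COMP), alt_local.translate(_COMP)

    def _insertion_record(self, gb: _GeneBuild, after_local: int, ins: str) -> tuple[int, str, str]:
        chrom_seq = self.genome[gb.model.chrom]
        if gb.model.strand == "+":
            pos = gb.local_to_genomic(after_local)
            ref = chrom_seq[pos - 1]
            return pos, ref, ref + ins
        pos = gb.local_to_genomic(after_local) - 1
        ref = chrom_seq[pos - 1]
        return pos, ref, ref + _revcomp(ins)

    def _deletion_record(self, gb: _GeneBuild, first_local: int, k: int) -> tuple[int, str, str]:
        chrom_seq = self.genome[gb.model.chrom]
        if gb.model.strand == "+":
            g = gb.local_to_genomic(first_local)
            pos = g - 1
        else:
            g_hi = gb.local_to_genomic(first_local)
            pos = g_hi - k
        ref = chrom_seq[pos - 1 : pos + k]
        return pos, ref, ref[0]


def plant_parental_variants(
    genome: SequenceSet,
    builds: list[_GeneBuild],
    config: SimulationConfig,
) -> list[TruthRecord]:
    """Plant every configured variant and return the truth records."""
    planter = _Planter(config, genome, builds)
    truths: list[TruthRecord] = []
    gene_idx = 0
    for spec in config.planted_variants:
        planted = None
        for trial in range(len(builds)):
            gb = builds[(gene_idx + trial) % len(builds)]
            planted = _try_plant(planter, gb, spec)
            if planted is not None:
                break
        gene_idx += 1
        if planted is None:
            raise SpecError(f"could not realize spec {spec}")
        truths.append(planted)
    return truths


def _carriers(config: SimulationConfig, spec: PlantSpec) -> tuple[str, ...]:
    if spec.carrier == "both":
        return (config.p1_name, config.p2_name)
    return (config.p1_name if spec.carrier == "P1" else config.p2_name,)


def _try_plant(pl: _Planter, gb: _GeneBuild, spec: PlantSpec) -> TruthRecord | None:
    cfg = pl.cfg
    m = gb.model
    cds = gb.spliced_cds
    n_codons = len(cds) // 3 - 1  # sense codons incl. ATG
    rng = pl.rng

    def finish(pos, ref, alt, feature, consequence, aa_change="",
               plen_ref=None, plen_alt=None, fs=None) -> TruthRecord:
        lo, hi = pos, pos + len(ref) - 1
        pl._reserve(m.chrom, lo, hi)
        ref_prot, _ = _translate(cds)
        if plen_ref is None:
            plen_ref = len(ref_prot)
        if plen_alt is None:
            plen_alt = plen_ref
        return TruthRecord(
            gene_id=m.gene_id, chrom=m.chrom, pos=pos, ref=ref, alt=alt,
            vtype="snp" if len(ref) == len(alt) == 1 else "indel",
            feature=feature, consequence=consequence, aa_change=aa_change,
            protein_length_ref=plen_ref, protein_length_alt=plen_alt,
            frame_shift_start=fs, carriers=_carriers(cfg, spec),
            quality=spec.quality, zygosity=spec.zygosity,
            ref1_only=spec.ref1_only,
            pos_ref2=pos + cfg.second_reference_shift.get(m.chrom, 0),
        )

    def site_ok(pos, ref_len) -> bool:
        return pl._free(m.chrom, pos, pos + ref_len - 1)

    ref_prot, _ = _translate(cds)

    if spec.feature == "exon":
        codon_order = list(rng.permutation(np.arange(3, n_codons - 2)))
        if spec.consequence in ("synonymous", "missense", "stop_gain"):
            for c in codon_order:
                codon = cds[3 * c - 3 : 3 * c]
                choices = []
                for bi in range(3):
                    for nb in _SNP_ALTS[codon[bi]]:
                        nc = codon[:bi] + nb + codon[bi + 1 :]
                        aa0, aa1 = _T[codon], _T[nc]
                        if spec.consequence == "synonymous" and aa1 == aa0:
                            choices.append((bi, nb, nc))
                        elif spec.consequence == "missense" and aa1 not in (aa0, "*"):
                            choices.append((bi, nb, nc))
                        elif spec.consequence == "stop_gain" and aa1 == "*":
                            choices.append((bi, nb, nc))
                if not choices:
                    continue
                bi, nb, nc = choices[int(rng.integers(0, len(choices)))]
                spl = 3 * c - 2 + bi  # spliced offset of edited base
                if not gb.segment_room(spl, 1):
                    continue
                local_x = gb.spliced_to_local(spl)
                pos, ref, alt = pl._snp_record(gb, local_x, nc[bi])
                if not site_ok(pos, len(ref)):
                    continue
                if spec.consequence == "synonymous":
                    return finish(pos, ref, alt, "exon_cds", "synonymous")
                if spec.consequence == "missense":
                    return finish(
                        pos, ref, alt, "exon_cds", "missense",
                        aa_change=f"{_T[codon]} {c} {_T[nc]}",
                    )
                return finish(
                    pos, ref, alt, "exon_cds", "stop_gain", plen_alt=c - 1
                )
            return None

        if spec.consequence == "stop_loss":
            if m.gene_id in pl.stop_used:
                return None
            stop = cds[-3:]
            for bi in range(3):
                for nb in _SNP_ALTS[stop[bi]]:
                    nc = stop[:bi] + nb + stop[bi + 1 :]
                    if _T[nc] in (None, "*"):
                        continue
                    spl = len(cds) - 3 + bi + 1
                    if not gb.segment_room(spl, 1):
                        continue
                    local_x = gb.spliced_to_local(spl)
                    pos, ref, alt = pl._snp_record(gb, local_x, nc[bi])
                    if not site_ok(pos, len(ref)):
                        continue
                    alt_cds = cds[:-3] + nc
                    prot, no_stop = _translate(alt_cds + pl._downstream(gb))
                    pl.stop_used.add(m.gene_id)
                    return finish(
                        pos, ref, alt, "exon_cds", "stop_loss", plen_alt=len(prot)
                    )
            return None

        if spec.consequence == "inframe_indel":
            k = abs(spec.net) // 3
            if spec.net % 3 != 0 or k == 0:
                raise SpecError("inframe_indel requires net multiple of 3")
            for c in codon_order:
                if spec.net > 0:
                    spl = 3 * c  # insert after codon c
                    if not gb.segment_room(spl, 2):
                        continue
                    local_x = gb.spliced_to_local(spl)
                    ins = "GCT" * k
                    pos, ref, alt = pl._insertion_record(gb, local_x, ins)
                    if not site_ok(pos, len(ref)):
                        continue
                    return finish(
                        pos, ref, alt, "exon_cds", "inframe_indel",
                        plen_alt=len(ref_prot) + k,
                    )
                spl = 3 * c + 1  # delete codons c+1..c+k
                if c + k >= n_codons - 1 or not gb.segment_room(spl - 1, 3 * k + 2):
                    continue
                local_x = gb.spliced_to_local(spl)
                pos, ref, alt = pl._deletion_record(gb, local_x, 3 * k)
                if not site_ok(pos, len(ref)):
                    continue
                return finish(
                    pos, ref, alt, "exon_cds", "inframe_indel",
                    plen_alt=len(ref_prot) - k,
                )
            return None

        if spec.consequence == "frameshift":
            net = spec.net if spec.net % 3 else 1
            for c in codon_order:
                if net > 0:
                    spl = 3 * c
                    if not gb.segment_room(spl, 2):
                        continue
                    local_x = gb.spliced_to_local(spl)
                    ins = "".join(
                        _BASES[i] for i in rng.integers(0, 4, net)
                    )
                    pos, ref, alt = pl._insertion_record(gb, local_x, ins)
                    if not site_ok(pos, len(ref)):
                        continue
                    alt_cds = cds[:spl] + ins + cds[spl:]
                else:
                    k = -net
                    spl = 3 * c + 1
                    if not gb.segment_room(spl - 1, k + 2):
                        continue
                    local_x = gb.spliced_to_local(spl)
                    pos, ref, alt = pl._deletion_record(gb, local_x, k)
                    if not site_ok(pos, len(ref)):
                        continue
                    alt_cds = cds[: spl - 1] + cds[spl - 1 + k :]
                prot, no_stop = _translate(alt_cds + pl._downstream(gb))
                fs = None
                for i, (x, y) in enumerate(zip(ref_prot, prot), 1):
                    if x != y:
                        fs = i
                        break
                if fs is None:
                    fs = min(len(ref_prot), len(prot)) + 1
                return finish(
                    pos, ref, alt, "exon_cds", "frameshift",
                    plen_alt=len(prot), fs=fs,
                )
            return None

        raise SpecError(f"unknown exon consequence {spec.consequence}")

    if spec.consequence == "start_gain":
        upstream_ref = pl._upstream(gb)
        ref_starts = _scan_upstream_starts(upstream_ref)
        n = len(upstream_ref)
        # candidate in-frame triplets one substitution away from ATG, nearest
        # to the annotated start first
        lo_i = 0 if spec.feature == "promoter" else n - gb.utr5_len
        hi_i = (n - gb.utr5_len - 3) if spec.feature == "promoter" else n - 3
        cand = [
            i for i in range(hi_i, lo_i - 1, -1)
            if (n - i) % 3 == 0
        ]
        for i in cand:
            tri = upstream_ref[i : i + 3]
            diffs = [bi for bi in range(3) if tri[bi] != "ATG"[bi]]
            if len(diffs) != 1:
                continue
            bi = diffs[0]
            alt_up = upstream_ref[:i] + "ATG" + upstream_ref[i + 3 :]
            new = _scan_upstream_starts(alt_up) - ref_starts
            want = (n - i) // 3
            if want not in new or min(new) != want:
                continue
            # genomic representation: upstream index i+bi (0-based) counts
            # back from the start codon
            back = n - (i + bi)  # 1 = base immediately 5' of CDS start
            if m.strand == "+":
                cds_g = gb.local_to_genomic(gb.utr5_len + 1)
                pos = cds_g - back
                ref = pl.genome[m.chrom][pos - 1]
                alt = "ATG"[bi]
            else:
                cds_g = gb.local_to_genomic(gb.utr5_len + 1)
                pos = cds_g + back
                ref = pl.genome[m.chrom][pos - 1]
                alt = "ATG"[bi].translate(_COMP)
            if ref == alt or not site_ok(pos, 1):
                continue
            feature = spec.feature if spec.feature == "promoter" else "5utr"
            return finish(
                pos, ref, alt, feature, "start_gain",
                plen_alt=len(ref_prot) + want,
            )
        return None

    # noncoding variants in intron / 3utr / 5utr / promoter / intergenic
    region = _noncoding_region(pl, gb, spec.feature)
    if region is None:
        return None
    lo, hi = region
    for _ in range(60):
        if spec.vtype == "snp" or spec.net == 0:
            pos = int(rng.integers(lo, hi + 1))
            ref = pl.genome[m.chrom][pos - 1]
            alt = _SNP_ALTS[ref][int(rng.integers(0, 3))]
            rec = (pos, ref, alt)
        elif spec.net > 0:
            pos = int(rng.integers(lo, hi - 1))
            anchor = pl.genome[m.chrom][pos - 1]
            ins = "".join(_BASES[i] for i in rng.integers(0, 4, spec.net))
            rec = (pos, anchor, anchor + ins)
        else:
            k = -spec.net
            pos = int(rng.integers(lo, hi - k))
            ref = pl.genome[m.chrom][pos - 1 : pos + k]
            rec = (pos, ref, ref[0])
        pos, ref, alt = rec
        span_hi = pos + len(ref) - 1
        if not (lo <= pos and span_hi <= hi) or not site_ok(pos, len(ref)):
            continue
        if spec.feature in ("promoter", "5utr"):
            # must not incidentally create an upstream in-frame start
            base = _scan_upstream_starts(pl._upstream(gb))
            new = _scan_upstream_starts(pl._upstream(gb, rec)) - base
            if new:
                continue
        return finish(pos, ref, alt, spec.feature, "noncoding")
    return None


def _noncoding_region(pl: _Planter, gb: _GeneBuild, feature: str) -> tuple[int, int] | None:
    """Genomic interval (with safety margins) for a noncoding feature of a gene."""
    m = gb.model
    margin = 8
    if feature == "intron":
        s, e = gb.intron_local[0]
        a, b = gb.local_to_genomic(s), gb.local_to_genomic(e)
        lo, hi = min(a, b) + margin, max(a, b) - margin
        return (lo, hi) if lo < hi else None
    if feature == "3utr":
        ivs = m.three_prime_utr
    elif feature == "5utr":
        ivs = m.five_prime_utr
    elif feature == "promoter":
        if m.strand == "+":
            ivs = [(m.start - pl.cfg.promoter_length, m.start - 1)]
        else:
            ivs = [(m.end + 1, m.end + pl.cfg.promoter_length)]
    elif feature == "intergenic":
        if m.strand == "+":
            ivs = [(m.start - pl.cfg.promoter_length - 360, m.start - pl.cfg.promoter_length - 60)]
        else:
            ivs = [(m.end + pl.cfg.promoter_length + 60, m.end + pl.cfg.promoter_length + 360)]
    else:
        raise SpecError(f"unknown feature {feature}")
    if not ivs:
        return None
    s, e = ivs[0]
    lo, hi = s + margin, e - margin
    if lo >= hi or lo < 1 or hi > len(pl.genome[m.chrom]):
        return None
    return lo, hi


# ---------------------------------------------------------------------------
# Panel


def generate_panel(
    genome: SequenceSet,
    indel_truths: list[TruthRecord],
    config: SimulationConfig,
    flank: int = 50,
):
    """Assign ref/alt alleles to panel lines per planted InDel locus.

    Returns (line names, genotype dict ``(line, locus_id) -> "ref"|"alt"``,
    sequence dict ``(line, locus_id) -> str``, truth carriers per locus).
    """
    rng = np.random.default_rng(config.seed + 15485863)
    n_named = len(config.donor_lines)
    lines = list(config.donor_lines) + [
        f"L{i + 1:03d}" for i in range(config.panel_size - n_named)
    ]
    freqs = config.panel_allele_frequencies
    genotypes: dict[tuple[str, str], str] = {}
    sequences: dict[tuple[str, str], str] = {}
    carriers: dict[str, list[str]] = {}
    for li, tr in enumerate(indel_truths):
        freq = freqs[li % len(freqs)] if freqs else 0.0
        locus = tr.locus_id
        carriers[locus] = []
        ref_slice = genome.fetch(tr.chrom, tr.pos - flank, tr.pos + len(tr.ref) - 1 + flank)
        off = flank  # 0-based offset of tr.pos within the slice
        alt_slice = ref_slice[:off] + tr.alt + ref_slice[off + len(tr.ref) :]
        for line in lines:
            if line in config.donor_lines:
                call = "alt"
            else:
                call = "alt" if rng.random() < freq else "ref"
            genotypes[(line, locus)] = call
            sequences[(line, locus)] = alt_slice if call == "alt" else ref_slice
            if call == "alt":
                carriers[locus].append(line)
    return lines, genotypes, sequences, carriers


# ---------------------------------------------------------------------------
# Study bundle

_TRUTH_COLUMNS = [
    "gene_id", "chrom", "pos", "ref", "alt", "vtype", "feature", "consequence",
    "aa_change", "protein_length_ref", "protein_length_alt", "frame_shift_start",
    "carriers", "quality", "zygosity", "ref1_only", "pos_ref2",
]


def emit_truth_table(truths: list[TruthRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TRUTH_COLUMNS) + "\n")
        for t in sorted(truths, key=lambda t: (t.gene_id, t.chrom, t.pos)):
            row = [
                t.gene_id, t.chrom, t.pos, t.ref, t.alt, t.vtype, t.feature,
                t.consequence, t.aa_change, t.protein_length_ref,
                t.protein_length_alt,
                "" if t.frame_shift_start is None else t.frame_shift_start,
                ",".join(t.carriers), f"{t.quality:g}", t.zygosity,
                int(t.ref1_only), t.pos_ref2,
            ]
            fh.write("\t".join(str(x) for x in row) + "\n")


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    genome1: SequenceSet
    genome2: SequenceSet
    genes1: list[GeneModel]
    genes2: list[GeneModel]
    hotspots1: list[QTLHotspot]
    hotspots2: list[QTLHotspot]
    anchors: list[tuple[str, GenomicInterval, GenomicInterval]]
    truths: list[TruthRecord]
    panel_lines: list[str]
    panel_genotypes: dict[tuple[str, str], str]
    panel_sequences: dict[tuple[str, str], str]
    panel_truth_carriers: dict[str, list[str]]

    @property
    def stress_gene_ids(self) -> set[str]:
        return {t.gene_id for t in self.truths if t.feature == "exon_cds"}

    def variants_for(self, parent: str, reference: str) -> list[VariantRecord]:
        cfg = self.config
        out = []
        for t in self.truths:
            if parent not in t.carriers:
                continue
            if reference == cfg.ref2_name:
                if t.ref1_only:
                    continue
                pos = t.pos_ref2
            else:
                pos = t.pos
            out.append(
                VariantRecord(
                    chrom=t.chrom, pos=pos, ref=t.ref, alt=t.alt,
                    qual=t.quality, zygosity=t.zygosity,
                    sample_id=parent, reference_id=reference,
                )
            )
        return sorted(out, key=lambda v: (v.chrom, v.pos))

    def write(self, outdir: str | os.PathLike) -> dict[str, str]:
        cfg = self.config
        outdir = str(outdir)
        os.makedirs(outdir, exist_ok=True)
        paths: dict[str, str] = {}

        def p(name: str) -> str:
            paths[name] = os.path.join(outdir, name)
            return paths[name]

        write_fasta(self.genome1, p("ref1.fasta"))
        write_fasta(self.genome2, p("ref2.fasta"))
        write_gff3(self.genes1, p("genes_ref1.gff3"))
        write_gff3(self.genes2, p("genes_ref2.gff3"))
        write_hotspot_bed(self.hotspots1, p("hotspots_ref1.bed"))
        write_hotspot_bed(self.hotspots2, p("hotspots_ref2.bed"))
        with open(p("stress_genes.tsv"), "w") as fh:
            for gid in sorted(self.stress_gene_ids):
                fh.write(gid + "\n")
        with open(p("donor_lines.tsv"), "w") as fh:
            for line in cfg.donor_lines:
                fh.write(line + "\n")
        for parent, pname in ((cfg.p1_name, "P1"), (cfg.p2_name, "P2")):
            for ref_name, genome in (
                (cfg.ref1_name, self.genome1),
                (cfg.ref2_name, self.genome2),
            ):
                write_vcf(
                    self.variants_for(parent, ref_name),
                    p(f"{pname}_vs_{ref_name}.vcf"),
                    genome.lengths,
                    sample_name=parent,
                )
        emit_truth_table(self.truths, p("truth.tsv"))
        with open(p("anchors.tsv"), "w") as fh:
            fh.write("gene_id\tchrom\tstart1\tend1\tstart2\tend2\n")
            for gid, iv1, iv2 in self.anchors:
                fh.write(
                    f"{gid}\t{iv1.chrom}\t{iv1.start}\t{iv1.end}\t{iv2.start}\t{iv2.end}\n"
                )
        with open(p("panel_genotypes.tsv"), "w") as fh:
            loci = sorted({loc for _, loc in self.panel_genotypes})
            fh.write("line\t" + "\t".join(loci) + "\n")
            for line in self.panel_lines:
                fh.write(
                    line
                    + "\t"
                    + "\t".join(self.panel_genotypes[(line, loc)] for loc in loci)
                    + "\n"
                )
        with open(p("panel_sequences.fasta"), "w") as fh:
            for (line, loc), seq in sorted(self.panel_sequences.items()):
                fh.write(f">{line}|{loc}\n{seq}\n")
        return paths


def simulate_study(config: SimulationConfig | None = None) -> SimulatedStudy:
    """Run the full generator: genome, second reference, variants, panel."""
    cfg = config or SimulationConfig()
    genome1, genes1, hotspots1, builds = _generate_with_builds(cfg)
    truths = plant_parental_variants(genome1, builds, cfg)
    genome2, genes2, anchors = derive_second_reference(
        genome1, genes1, cfg.second_reference_shift, seed=cfg.seed
    )
    hotspots2 = [
        QTLHotspot(
            GenomicInterval(
                h.interval.id,
                h.interval.chrom,
                h.interval.start + cfg.second_reference_shift.get(h.interval.chrom, 0),
                h.interval.end + cfg.second_reference_shift.get(h.interval.chrom, 0),
            ),
            h.hotspot_id,
            h.donor_parent,
        )
        for h in hotspots1
    ]
    indel_truths = [
        t for t in truths if t.vtype == "indel" and t.feature == "exon_cds"
    ]
    lines, genotypes, sequences, carriers = generate_panel(genome1, indel_truths, cfg)
    return SimulatedStudy(
        config=cfg,
        genome1=genome1, genome2=genome2,
        genes1=genes1, genes2=genes2,
        hotspots1=hotspots1, hotspots2=hotspots2,
        anchors=anchors, truths=truths,
        panel_lines=lines, panel_genotypes=genotypes,
        panel_sequences=sequences, panel_truth_carriers=carriers,
    )


def concordance_demo_config(seed: int = 0) -> SimulationConfig:
    """A study in which 34 genes carry defining InDel candidates and exactly
    two of them are planted only against the first reference, so the
    dual-reference concordance filter confirms 32."""
    plan: list[PlantSpec] = []
    for i in range(34):
        plan.append(
            PlantSpec(
                "exon", "indel", "frameshift",
                carrier="P1" if i % 2 else "P2",
                net=[2, -2, 1, -1][i % 4],
                ref1_only=i in (5, 20),
            )
        )
    return SimulationConfig(seed=seed, n_genes=34, planted_variants=plan)


# ---------------------------------------------------------------------------
# Printed-allele fixture construction


def synthesize_cds_locus(
    n_codons: int,
    alleles: list[tuple[str, str]],
    seed: int = 0,
    chrom: str = "chrS",
    flank: int = 1500,
    codon_offsets: list[int] | None = None,
) -> tuple[SequenceSet, GeneModel, list[VariantRecord]]:
    """Build a single-exon locus embedding printed allele pairs in a
    stop-free CDS backbone.

    The CDS has ``n_codons`` sense codons (ATG start) plus a terminal stop;
    each (ref, alt) allele pair is embedded at a codon-aligned offset with
    alanine (GCC) filler codons elsewhere, and returned as an anchored
    variant record.  Construction fails loudly if the backbone or any
    single-allele haplotype contains an unintended stop codon.
    """
    rng = np.random.default_rng(seed)
    cds = list("ATG" + "GCC" * (n_codons - 1) + "TAA")
    if codon_offsets is None:
        codon_offsets = []
        c = 12
        for ref, _ in alleles:
            codon_offsets.append(c)
            c += (len(ref) + 2) // 3 + 10
    variants = []
    for (ref, alt), c in zip(alleles, codon_offsets):
        start = 3 * c  # 0-based CDS offset, codon boundary
        if start + len(ref) > 3 * n_codons - 3:
            raise SpecError(f"allele {ref}->{alt} does not fit a {n_codons}-codon CDS")
        cds[start : start + len(ref)] = list(ref)
        variants.append((start, ref, alt))
    cds = "".join(cds)
    prot, no_stop = _translate(cds)
    if len(prot) != n_codons or no_stop:
        raise SpecError("backbone contains an unintended stop codon")
    for start, ref, alt in variants:
        alt_cds = cds[:start] + alt + cds[start + len(ref) :]
        net = len(alt) - len(ref)
        if net != 0 and net % 3 == 0:
            aprot, _ = _translate(alt_cds)
            if len(aprot) != n_codons + net // 3:
                raise SpecError(
                    f"allele {ref}->{alt} creates an unintended stop codon"
                )
    left = "".join(np.random.default_rng(seed + 1).choice(list(_BASES), flank))
    right = "".join(rng.choice(list(_BASES), flank))
    chrom_seq = left + cds + right
    genome = SequenceSet({chrom: chrom_seq})
    gene = GeneModel(
        gene_id="GSYN",
        chrom=chrom,
        strand="+",
        start=flank + 1,
        end=flank + len(cds),
        exons=[(flank + 1, flank + len(cds))],
        cds_segments=[(flank + 1, flank + len(cds))],
    )
    records = [
        VariantRecord(
            chrom=chrom, pos=flank + start + 1, ref=ref, alt=alt,
            qual=150.0, zygosity="hom", sample_id="P1", reference_id="ref1",
        )
        for start, ref, alt in variants
    ]
    return genome, gene, records
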