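"""Genic-feature classification and coding-consequence prediction.

Given a gene model, a reference genome and a variant (or a haplotype of
several variants on the same gene), this module rebuilds the spliced CDS
for both alleles, translates them with the standard genetic code, and
classifies the effect: synonymous, missense (reported as ``"N 70 S"``),
in-frame indel, frameshift, stop gain, stop loss (with read-through into
downstream genomic sequence) or start gain (a new in-frame ATG upstream of
the annotated start).

Effect taxonomy notes: a coding indel whose net length is not a multiple
of 3 is always a frameshift, even when it also bypasses the annotated
stop; stop_loss is reserved for variants that disrupt the stop codon
itself or for in-frame events that read through it.  Reports additionally
carry a conventional "frame shift" style label for any length-changing
coding indel, the way such events are commonly tabulated in rice
re-sequencing studies.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import reverse_complement

from .io import GeneModel, SequenceSet, VariantRecord

__all__ = [
    "ConsequenceCall",
    "TranscriptModel",
    "classify_feature",
    "apply_variants_to_sequence",
    "translate_cds",
    "annotate_consequence",
    "annotate_haplotype",
    "find_longest_orf",
    "normalize_variant",
    "NON_SYNONYMOUS_EFFECTS",
]

_CODON_TABLE = dict(standard_dna_table.forward_table)
_STOP_CODONS = frozenset(standard_dna_table.stop_codons)

NON_SYNONYMOUS_EFFECTS = frozenset(
    {"missense", "inframe_indel", "frameshift", "stop_gain", "stop_loss", "start_gain"}
)

DEFAULT_PROMOTER_LENGTH = 1000
DEFAULT_READTHROUGH_LIMIT = 3000


@dataclass
class TranscriptModel:
    """The spliced coding sequence of a gene plus its flanking context.

    ``cds`` is 5'->3' in coding orientation; ``downstream`` continues past
    the annotated stop (for read-through after stop loss); ``upstream``
    precedes the annotated start (5'UTR plus promoter, for start-gain
    scanning).
    """

    gene_id: str
    cds: str
    upstream: str
    downstream: str


@dataclass
class ConsequenceCall:
    gene_id: str
    variant: VariantRecord
    feature: str
    effect: str
    aa_change: str = ""
    protein_length_ref: int = 0
    protein_length_alt: int = 0
    frame_shift_start: int | None = None
    no_stop_found: bool = False
    splice_region: bool = False

    @property
    def report_label(self) -> str:
        """The label a conventional candidate-gene report prints for this call."""
        if self.effect in ("inframe_indel", "frameshift"):
            return "frame shift"
        if self.effect == "missense":
            return self.aa_change
        return self.effect.replace("_", " ")


def _overlaps(span: tuple[int, int], iv: tuple[int, int]) -> bool:
    return span[0] <= iv[1] and iv[0] <= span[1]


def classify_feature(
    variant: VariantRecord,
    gene: GeneModel,
    promoter_length: int = DEFAULT_PROMOTER_LENGTH,
) -> str:
    """Classify a variant's location relative to one gene.

    Precedence: CDS exon > UTR > intron > promoter > intergenic, judged by
    overlap of the reference-allele span.  The promoter is the
    ``promoter_length`` bases immediately 5' of the gene span,
    strand-aware.
    """
    span = variant.ref_span
    if any(_overlaps(span, iv) for iv in gene.cds_segments):
        return "exon_cds"
    if any(_overlaps(span, iv) for iv in gene.five_prime_utr):
        return "5utr"
    if any(_overlaps(span, iv) for iv in gene.three_prime_utr):
        return "3utr"
    if _overlaps(span, (gene.start, gene.end)):
        return "intron"
    if gene.strand == "+":
        promoter = (gene.start - promoter_length, gene.start - 1)
    else:
        promoter = (gene.end + 1, gene.end + promoter_length)
    if _overlaps(span, promoter):
        return "promoter"
    return "intergenic"


def apply_variants_to_sequence(
    seq: str, variants: list[tuple[int, str, str]]
) -> str:
    """Apply non-overlapping (1-based pos, ref, alt) substitutions to ``seq``.

    Substitutions are applied right-to-left so earlier coordinates stay
    valid.  Each ref allele must match the sequence at its position.
    """
    ordered = sorted(variants, key=lambda v: v[0], reverse=True)
    prev_start = None
    for pos, ref, alt in ordered:
        if prev_start is not None and pos + len(ref) - 1 >= prev_start:
            raise ValueError("overlapping variants")
        prev_start = pos
        if seq[pos - 1 : pos - 1 + len(ref)] != ref:
            raise ValueError(
                f"ref mismatch at {pos}: expected {ref}, "
                f"found {seq[pos - 1 : pos - 1 + len(ref)]}"
            )
        seq = seq[: pos - 1] + alt + seq[pos - 1 + len(ref) :]
    return seq


def translate_cds(cds: str) -> tuple[str, bool]:
    """Translate from position 1 with the standard code.

    Returns the protein up to (and excluding) the first stop codon and a
    ``no_stop_found`` flag.  A trailing partial codon is ignored.
    """
    protein = []
    for i in range(0, len(cds) - 2, 3):
        codon = cds[i : i + 3]
        if codon in _STOP_CODONS:
            return "".join(protein), False
        protein.append(_CODON_TABLE.get(codon, "X"))
    return "".join(protein), True


def normalize_variant(variant: VariantRecord, genome: SequenceSet) -> VariantRecord:
    """Left-normalize an indel to its leftmost representation with one anchor base.

    SNPs and already-minimal records are returned unchanged (after trimming
    shared flanking bases).  Follows the usual VCF normalization algorithm.
    """
    pos, ref, alt = variant.pos, variant.ref, variant.alt
    seq = genome[variant.chrom]
    while True:
        if len(ref) >= 1 and len(alt) >= 1 and ref[-1] == alt[-1] and (
            len(ref) > 1 or len(alt) > 1
        ):
            if len(ref) == 1 or len(alt) == 1:
                if pos == 1:
                    break
                pos -= 1
                base = seq[pos - 1]
                ref = base + ref[:-1]
                alt = base + alt[:-1]
            else:
                ref = ref[:-1]
                alt = alt[:-1]
        elif len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
            ref = ref[1:]
            alt = alt[1:]
            pos += 1
        else:
            break
    if (pos, ref, alt) == (variant.pos, variant.ref, variant.alt):
        return variant
    from dataclasses import replace

    return replace(variant, pos=pos, ref=ref, alt=alt)


# ---------------------------------------------------------------------------
# Consequence annotation


def _liftover(coord: int, variants: list[VariantRecord]) -> int:
    """Map a reference coordinate onto the mutated sequence.

    Coordinates inside a replaced span are clamped to the span start (only
    reachable when a feature boundary falls inside a deleted tract).
    """
    shift = 0
    for v in sorted(variants, key=lambda v: v.pos):
        lo, hi = v.ref_span
        if coord < lo:
            break
        if coord > hi:
            shift += v.net_length
        else:
            return lo + shift + min(coord - lo, len(v.alt) - 1)
    return coord + shift


def build_transcript_model(
    gene: GeneModel,
    genome: SequenceSet,
    variants: list[VariantRecord] | None = None,
    promoter_length: int = DEFAULT_PROMOTER_LENGTH,
    readthrough_limit: int = DEFAULT_READTHROUGH_LIMIT,
) -> TranscriptModel:
    """Assemble the spliced CDS plus upstream/downstream context.

    With ``variants`` given, the model reflects the alternate haplotype:
    the chromosome is mutated and feature boundaries are lifted over.
    """
    chrom_seq = genome[gene.chrom]
    variants = variants or []
    if variants:
        chrom_seq = apply_variants_to_sequence(
            chrom_seq, [(v.pos, v.ref, v.alt) for v in variants]
        )
        lift = lambda c: _liftover(c, variants)  # noqa: E731
    else:
        lift = lambda c: c  # noqa: E731

    def fetch(start: int, end: int) -> str:
        return chrom_seq[max(start - 1, 0) : min(end, len(chrom_seq))]

    cds_parts = [fetch(lift(s), lift(e)) for s, e in gene.cds_segments]
    cds = "".join(cds_parts)
    utr5 = "".join(fetch(lift(s), lift(e)) for s, e in gene.five_prime_utr)
    utr3 = "".join(fetch(lift(s), lift(e)) for s, e in gene.three_prime_utr)
    if gene.strand == "+":
        downstream = utr3 + fetch(lift(gene.end) + 1, lift(gene.end) + readthrough_limit)
        promoter = fetch(lift(gene.start) - promoter_length, lift(gene.start) - 1)
        upstream = promoter + utr5
    else:
        cds = reverse_complement(cds)
        utr5 = reverse_complement(utr5)
        utr3 = reverse_complement(utr3)
        downstream = utr3 + reverse_complement(
            fetch(lift(gene.start) - readthrough_limit, lift(gene.start) - 1)
        )
        promoter = reverse_complement(
            fetch(lift(gene.end) + 1, lift(gene.end) + promoter_length)
        )
        upstream = promoter + utr5
    downstream = downstream[:readthrough_limit]
    return TranscriptModel(gene.gene_id, cds, upstream, downstream)


def _first_difference(a: str, b: str) -> int | None:
    """1-based index of the first differing residue, None if one is a prefix."""
    for i, (x, y) in enumerate(zip(a, b), 1):
        if x != y:
            return i
    return None


def _inframe_atg_starts(upstream: str) -> set[int]:
    """Offsets (residues upstream of the annotated start) of in-frame ATGs
    from which translation reaches the annotated start without a stop."""
    n = len(upstream)
    starts = set()
    for i in range(n - 2):
        if upstream[i : i + 3] != "ATG":
            continue
        if (n - i) % 3 != 0:
            continue
        path = upstream[i:n]
        if any(path[j : j + 3] in _STOP_CODONS for j in range(0, len(path), 3)):
            continue
        starts.add((n - i) // 3)
    return starts


def annotate_haplotype(
    gene: GeneModel,
    variants: list[VariantRecord],
    genome: SequenceSet,
    promoter_length: int = DEFAULT_PROMOTER_LENGTH,
    readthrough_limit: int = DEFAULT_READTHROUGH_LIMIT,
) -> ConsequenceCall:
    """Annotate the joint effect of one or more variants on one gene.

    The reported ``variant`` field carries the first (leftmost) variant;
    the effect reflects the combined haplotype.
    """
    variants = sorted(variants, key=lambda v: v.pos)
    lead = variants[0]
    features = [classify_feature(v, gene, promoter_length) for v in variants]
    coding = [v for v, f in zip(variants, features) if f == "exon_cds"]
    # A variant spanning an exon-intron boundary counts as coding and is flagged.
    splice = any(
        f == "exon_cds"
        and not any(s <= v.pos and v.ref_span[1] <= e for s, e in gene.cds_segments)
        for v, f in zip(variants, features)
    )
    feature = features[0]

    ref_model = build_transcript_model(
        gene, genome, None, promoter_length, readthrough_limit
    )
    alt_model = build_transcript_model(
        gene, genome, variants, promoter_length, readthrough_limit
    )
    ref_prot, _ = translate_cds(ref_model.cds)
    call = ConsequenceCall(
        gene_id=gene.gene_id,
        variant=lead,
        feature=feature,
        effect="noncoding",
        protein_length_ref=len(ref_prot),
        protein_length_alt=len(ref_prot),
        splice_region=splice,
    )

    if coding:
        extended = alt_model.cds + alt_model.downstream
        alt_prot, no_stop = translate_cds(extended)
        read_through = 3 * (len(alt_prot) + 1) > len(alt_model.cds)
        call.protein_length_alt = len(alt_prot)
        call.no_stop_found = no_stop
        net = sum(v.net_length for v in coding)
        if net == 0:
            if alt_prot == ref_prot:
                call.effect = "synonymous"
            elif len(alt_prot) < len(ref_prot) and not read_through:
                call.effect = "stop_gain"
            elif read_through:
                call.effect = "stop_loss"
            else:
                i = _first_difference(ref_prot, alt_prot)
                call.effect = "missense"
                call.aa_change = f"{ref_prot[i - 1]} {i} {alt_prot[i - 1]}"
        elif net % 3 == 0:
            expected = len(ref_prot) + net // 3
            if read_through:
                call.effect = "stop_loss"
            elif len(alt_prot) < expected:
                call.effect = "stop_gain"
            else:
                call.effect = "inframe_indel"
        else:
            call.effect = "frameshift"
            i = _first_difference(ref_prot, alt_prot)
            call.frame_shift_start = i if i is not None else min(
                len(ref_prot), len(alt_prot)
            ) + 1
        return call

    if feature in ("5utr", "promoter"):
        new_starts = _inframe_atg_starts(alt_model.upstream) - _inframe_atg_starts(
            ref_model.upstream
        )
        if new_starts:
            offset = min(new_starts)
            call.effect = "start_gain"
            call.protein_length_alt = len(ref_prot) + offset
            call.frame_shift_start = None
    return call


def annotate_consequence(
    gene: GeneModel,
    variant: VariantRecord,
    genome: SequenceSet,
    promoter_length: int = DEFAULT_PROMOTER_LENGTH,
    readthrough_limit: int = DEFAULT_READTHROUGH_LIMIT,
) -> ConsequenceCall:
    """Annotate a single variant's effect on one gene."""
    return annotate_haplotype(
        gene, [variant], genome, promoter_length, readthrough_limit
    )


def find_longest_orf(
    seq: str, min_length: int = 30, both_strands: bool = False
) -> tuple[int, int, int, str] | None:
    """Longest ATG..stop open reading frame across the 3 forward frames.

    Returns (1-based start, 1-based end of stop codon, frame 0-2, protein)
    or None when no ORF reaches ``min_length`` codons (protein residues).
    Ties break to the smallest start coordinate.  With ``both_strands`` the
    reverse complement is also scanned (coordinates on the forward strand
    are not remapped; the frame is offset by 3).
    """
    seq = seq.upper()
    candidates: list[tuple[int, int, int, str]] = []

    def scan(s: str, frame_offset: int) -> None:
        for frame in range(3):
            i = frame
            while i <= len(s) - 3:
                if s[i : i + 3] == "ATG":
                    j = i + 3
                    while j <= len(s) - 3:
                        if s[j : j + 3] in _STOP_CODONS:
                            protein, _ = translate_cds(s[i:j])
                            if len(protein) >= min_length:
                                candidates.append(
                                    (i + 1, j + 3, frame + frame_offset, protein)
                                )
                            break
                        j += 3
                i += 3

    scan(seq, 0)
    if both_strands:
        scan(reverse_complement(seq), 3)
    if not candidates:
        return None
    return max(candidates, key=lambda c: (len(c[3]), -c[0]))
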