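"""Candidate-gene selection: between-parent polymorphism, non-synonymous
filter, dual-reference concordance and InDel-marker amplicon prediction.

A site is polymorphic between two inbred parents called against the same
reference iff its normalized (pos, ref, alt) key appears in exactly one
parent's call set — absence in the other parent means the reference
allele, since both were called against the same assembly.  Candidate
genes carry at least one polymorphic exonic variant with a non-synonymous
effect; a candidate whose defining InDels all lack a counterpart against
the second reference is dropped as a putative artefact of the first
assembly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .consequence import NON_SYNONYMOUS_EFFECTS, ConsequenceCall
from .io import GeneModel, QTLHotspot, SequenceSet, VariantRecord
from .qtl import AnchorMap

__all__ = [
    "PolymorphicVariant",
    "CandidateGene",
    "MarkerDesign",
    "parental_difference",
    "screen_candidates",
    "dual_reference_concordance",
    "design_indel_marker",
]


@dataclass(frozen=True)
class PolymorphicVariant:
    variant: VariantRecord
    carrier: str  # parent holding the alternate allele


@dataclass
class CandidateGene:
    gene_id: str
    hotspot_id: int | str  # hotspot number or "non-QTL"
    donor_parent: str | None
    variants: list[tuple[PolymorphicVariant, ConsequenceCall]]
    confirmed_in_second_reference: bool = True
    unassessable: bool = False
    drop_reasons: list[str] = field(default_factory=list)

    @property
    def defining_indels(self) -> list[PolymorphicVariant]:
        return [pv for pv, call in self.variants if pv.variant.is_indel]


def parental_difference(
    variants_p1: list[VariantRecord], variants_p2: list[VariantRecord]
) -> list[PolymorphicVariant]:
    """Symmetric difference of the two parents' call sets, keyed on
    (chrom, pos, ref, alt); the carrier is the parent holding the
    alternate allele."""
    refs = {v.reference_id for v in variants_p1 + variants_p2}
    if len(refs) > 1:
        raise ValueError(f"call sets are against different references: {sorted(refs)}")
    k1 = {v.key(): v for v in variants_p1}
    k2 = {v.key(): v for v in variants_p2}
    out = []
    for key in sorted(set(k1) ^ set(k2)):
        v = k1.get(key) or k2[key]
        out.append(PolymorphicVariant(v, v.sample_id))
    return out


def _hotspot_of(
    gene: GeneModel, hotspots: list[QTLHotspot]
) -> tuple[int | str, str | None]:
    for h in hotspots:
        if gene.span.overlaps(h.interval):
            return h.hotspot_id, h.donor_parent
    return "non-QTL", None


def screen_candidates(
    stress_genes: list[GeneModel],
    polymorphic: list[PolymorphicVariant],
    consequences: dict[tuple[str, int, str, str], ConsequenceCall],
    hotspots: list[QTLHotspot] | None = None,
) -> list[CandidateGene]:
    """Keep genes with >=1 polymorphic exonic variant whose effect is
    non-synonymous (missense, in-frame indel, frameshift, stop gain/loss
    or start gain); genes with only synonymous polymorphisms are dropped.

    ``consequences`` maps each polymorphic variant's key to its
    ConsequenceCall (gene-resolved upstream).
    """
    hotspots = hotspots or []
    by_gene: dict[str, list[tuple[PolymorphicVariant, ConsequenceCall]]] = {}
    for pv in polymorphic:
        call = consequences.get(pv.variant.key())
        if call is None:
            continue
        if call.feature != "exon_cds" or call.effect not in NON_SYNONYMOUS_EFFECTS:
            continue
        by_gene.setdefault(call.gene_id, []).append((pv, call))
    candidates = []
    for gene in stress_genes:
        pairs = by_gene.get(gene.gene_id)
        if not pairs:
            continue
        hid, donor = _hotspot_of(gene, hotspots)
        candidates.append(
            CandidateGene(
                gene_id=gene.gene_id,
                hotspot_id=hid,
                donor_parent=donor,
                variants=sorted(pairs, key=lambda p: p[0].variant.pos),
            )
        )
    return candidates


def dual_reference_concordance(
    candidates_ref1: list[CandidateGene],
    variants_ref2: list[VariantRecord],
    anchors: AnchorMap,
    tolerance: int = 10,
) -> tuple[list[CandidateGene], list[CandidateGene]]:
    """Confirm candidates against the second-reference call sets.

    A defining variant is confirmed iff the second-reference call set holds
    a variant with the identical allele change within ``tolerance`` bases
    of its anchor-projected position.  A candidate is dropped iff it has
    defining InDels and all of them fail confirmation.  Genes absent from
    the anchor map are kept, flagged unassessable.
    """
    by_allele: dict[tuple[str, str, str], list[int]] = {}
    for v in variants_ref2:
        by_allele.setdefault((v.chrom, v.ref, v.alt), []).append(v.pos)

    confirmed, dropped = [], []
    for cand in candidates_ref1:
        offset = anchors.gene_offset(cand.gene_id)
        if offset is None:
            cand.unassessable = True
            cand.confirmed_in_second_reference = True
            confirmed.append(cand)
            continue
        indels = cand.defining_indels
        if not indels:
            cand.confirmed_in_second_reference = True
            confirmed.append(cand)
            continue
        any_ok = False
        reasons = []
        for pv in indels:
            v = pv.variant
            expected = v.pos + offset
            positions = by_allele.get((v.chrom, v.ref, v.alt), [])
            if any(abs(p - expected) <= tolerance for p in positions):
                any_ok = True
            else:
                reasons.append(
                    f"{v.chrom}:{v.pos} {v.ref}>{v.alt} absent in second reference"
                )
        if any_ok:
            cand.confirmed_in_second_reference = True
            confirmed.append(cand)
        else:
            cand.confirmed_in_second_reference = False
            cand.drop_reasons = reasons
            dropped.append(cand)
    return confirmed, dropped


@dataclass(frozen=True)
class MarkerDesign:
    forward_primer: tuple[int, int]  # 1-based inclusive span on the reference
    reverse_primer: tuple[int, int]
    amplicon_length_ref: int
    amplicon_length_alt: int

    @property
    def size_difference(self) -> int:
        return self.amplicon_length_alt - self.amplicon_length_ref


def design_indel_marker(
    genome: SequenceSet, indel: VariantRecord, flank: int = 20
) -> MarkerDesign:
    """Positional InDel-marker design: primer sites are the flank-length
    spans immediately outside the indel window; the amplicon size
    difference between alleles equals the indel's net length."""
    if flank < 18:
        raise ValueError("flank must be >= 18 bases")
    lo, hi = indel.ref_span
    chrom_len = genome.lengths[indel.chrom]
    fwd = (lo - flank, lo - 1)
    rev = (hi + 1, hi + flank)
    if fwd[0] < 1 or rev[1] > chrom_len:
        raise ValueError(
            f"indel at {indel.chrom}:{indel.pos} lacks {flank}-bp primer clearance"
        )
    amplicon_ref = rev[1] - fwd[0] + 1
    return MarkerDesign(
        forward_primer=fwd,
        reverse_primer=rev,
        amplicon_length_ref=amplicon_ref,
        amplicon_length_alt=amplicon_ref + indel.net_length,
    )
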