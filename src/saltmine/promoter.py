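"""Promoter extraction per parent haplotype and cis-element scanning.

Promoters are the configurable number of bases (default 1000) immediately
5' of the gene span in coding orientation, with the parent's overlapping
variants applied.  Motifs are IUPAC degenerate consensi scanned on both
strands by default; every overlapping occurrence is reported.

The packaged motif table covers the nine abiotic-stress element classes
commonly screened in rice promoter studies (ABRE, CAAT box, DPBF, GAGA,
GBOX, IBOX, ROOT motif, SEF3, SEF4), with PLACE-style consensi.  The
table is editable convenience, not ground truth; analyses can supply
their own.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .consequence import apply_variants_to_sequence
from .io import GeneModel, SequenceSet, VariantRecord

__all__ = [
    "MotifDefinition",
    "MotifHit",
    "load_motif_table",
    "extract_promoter",
    "scan_motifs",
    "compare_element_counts",
]

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def _revcomp_iupac(s: str) -> str:
    return s.translate(_COMP)[::-1]


@dataclass(frozen=True)
class MotifDefinition:
    name: str
    consensus: str
    stress_related: bool = True
    source_id: str = ""

    def __post_init__(self) -> None:
        if not self.consensus or any(c not in _IUPAC for c in self.consensus.upper()):
            raise ValueError(f"{self.name}: consensus must be non-empty IUPAC")


@dataclass(frozen=True)
class MotifHit:
    gene_id: str
    sample_id: str
    element: str
    strand: str
    offset: int  # 1-based within the promoter


def load_motif_table(path: str | os.PathLike | None = None) -> list[MotifDefinition]:
    """Load motif definitions from TSV (name, consensus, stress flag, source).

    Without a path, the packaged default table is used.
    """
    if path is None:
        with resources.files("saltmine.data").joinpath("motifs.tsv").open() as fh:
            df = pd.read_csv(fh, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    return [
        MotifDefinition(
            name=row["name"],
            consensus=row["consensus"],
            stress_related=bool(row.get("stress_related", True)),
            source_id=str(row.get("source_id", "")),
        )
        for _, row in df.iterrows()
    ]


def extract_promoter(
    gene: GeneModel,
    genome: SequenceSet,
    variants_for_sample: list[VariantRecord] | None = None,
    length: int = 1000,
) -> tuple[str, bool]:
    """The ``length`` bases immediately 5' of the gene span, coding
    orientation, with the sample's overlapping variants applied.

    Returns (sequence, truncated) — truncated is set when the chromosome
    end leaves fewer than ``length`` bases.
    """
    chrom_len = genome.lengths[gene.chrom]
    if gene.strand == "+":
        lo, hi = gene.start - length, gene.start - 1
    else:
        lo, hi = gene.end + 1, gene.end + length
    truncated = lo < 1 or hi > chrom_len
    lo_c, hi_c = max(lo, 1), min(hi, chrom_len)
    if hi_c < lo_c:
        return "", True
    seq = genome.fetch(gene.chrom, lo_c, hi_c)
    edits = []
    for v in variants_for_sample or []:
        s, e = v.ref_span
        if v.chrom == gene.chrom and s >= lo_c and e <= hi_c:
            edits.append((s - lo_c + 1, v.ref, v.alt))
    if edits:
        seq = apply_variants_to_sequence(seq, edits)
    if gene.strand == "-":
        from Bio.Seq import reverse_complement

        seq = reverse_complement(seq)
    return seq, truncated


def _consensus_regex(consensus: str) -> re.Pattern:
    return re.compile(
        "(?=(" + "".join(f"[{_IUPAC[c]}]" for c in consensus.upper()) + "))"
    )


def scan_motifs(
    promoter: str,
    motifs: list[MotifDefinition],
    both_strands: bool = True,
    gene_id: str = "",
    sample_id: str = "",
) -> list[MotifHit]:
    """All (overlapping) IUPAC-consensus matches in a promoter.

    Reverse-strand hits are reported at the 1-based offset of the match's
    leftmost base on the given (forward) sequence.
    """
    promoter = promoter.upper()
    hits: list[MotifHit] = []
    for m in motifs:
        for match in _consensus_regex(m.consensus).finditer(promoter):
            hits.append(MotifHit(gene_id, sample_id, m.name, "+", match.start() + 1))
        if both_strands:
            rc = _revcomp_iupac(m.consensus)
            if rc == m.consensus.upper():
                continue  # palindromic consensus: forward scan already found it
            for match in _consensus_regex(rc).finditer(promoter):
                hits.append(
                    MotifHit(gene_id, sample_id, m.name, "-", match.start() + 1)
                )
    return sorted(hits, key=lambda h: (h.element, h.offset, h.strand))


def compare_element_counts(
    hits_p1: list[MotifHit],
    hits_p2: list[MotifHit],
    stress_elements: set[str] | None = None,
) -> pd.DataFrame:
    """Per-gene, per-element counts in each parent with differences and
    absent-in-one-parent flags.

    ``stress_elements`` restricts the table to those element names.
    """
    rows = []
    keys = set()
    counts: dict[tuple[str, str, int], int] = {}
    for who, hits in ((1, hits_p1), (2, hits_p2)):
        for h in hits:
            if stress_elements is not None and h.element not in stress_elements:
                continue
            counts[(h.gene_id, h.element, who)] = (
                counts.get((h.gene_id, h.element, who), 0) + 1
            )
            keys.add((h.gene_id, h.element))
    for gene_id, element in sorted(keys):
        c1 = counts.get((gene_id, element, 1), 0)
        c2 = counts.get((gene_id, element, 2), 0)
        rows.append(
            {
                "gene_id": gene_id,
                "element": element,
                "count_p1": c1,
                "count_p2": c2,
                "difference": c1 - c2,
                "absent_in_p1": c1 == 0,
                "absent_in_p2": c2 == 0,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "element", "count_p1", "count_p2",
            "difference", "absent_in_p1", "absent_in_p2",
        ],
    )
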