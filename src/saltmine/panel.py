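"""Cultivar-panel genotyping at candidate InDel loci.

Panel lines are inbred rice cultivars, treated as homozygous: one call per
line per locus, from the 3-symbol alphabet {ref, alt, missing}.  Calling
compares each line's local sequence against the two expected haplotypes
over a window around the normalized locus, tolerant to incidental SNPs
outside the indel core.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .io import SequenceSet, VariantRecord

__all__ = [
    "PanelGenotypes",
    "call_panel_alleles",
    "indel_allele_frequency",
    "donor_presence_flags",
]

CALL_ALPHABET = ("ref", "alt", "missing")


@dataclass
class PanelGenotypes:
    """Line x locus call matrix (values "ref", "alt" or "missing")."""

    calls: pd.DataFrame  # index: line labels, columns: locus ids

    def __post_init__(self) -> None:
        bad = set(self.calls.values.ravel()) - set(CALL_ALPHABET)
        if bad:
            raise ValueError(f"invalid panel calls: {sorted(bad)}")

    @property
    def lines(self) -> list[str]:
        return list(self.calls.index)

    @property
    def loci(self) -> list[str]:
        return list(self.calls.columns)


def call_panel_alleles(
    line_sequences: dict[str, str],
    locus: VariantRecord,
    genome: SequenceSet,
    window: int = 20,
) -> pd.Series:
    """Call ref/alt/missing per line from local sequences spanning the locus.

    The expected haplotypes are the reference slice ``locus +/- window``
    and the same slice with the alternate allele substituted; a line is
    called by which core haplotype (allele plus ``window`` anchor bases on
    each side, clipped at chromosome ends) its sequence contains.
    Sequences matching neither, or too short to span the locus, are
    missing.
    """
    lo, hi = locus.ref_span
    ref_core = genome.fetch(locus.chrom, lo - window, hi + window)
    left = genome.fetch(locus.chrom, lo - window, lo - 1)
    right = genome.fetch(locus.chrom, hi + 1, hi + window)
    alt_core = left + locus.alt + right
    calls = {}
    for line, seq in line_sequences.items():
        seq = seq.upper()
        if len(seq) < min(len(ref_core), len(alt_core)):
            calls[line] = "missing"
        elif alt_core in seq:
            calls[line] = "alt"
        elif ref_core in seq:
            calls[line] = "ref"
        else:
            calls[line] = "missing"
    return pd.Series(calls, name=f"{locus.chrom}:{locus.pos}")


def indel_allele_frequency(genotypes: PanelGenotypes, locus: str) -> float | None:
    """Alternate-allele frequency at one locus: alt / non-missing calls.

    None when every call is missing.
    """
    col = genotypes.calls[locus]
    informative = col[col != "missing"]
    if informative.empty:
        return None
    return float((informative == "alt").sum() / len(informative))


def donor_presence_flags(
    genotypes: PanelGenotypes, donor_lines: list[str]
) -> dict[str, dict[str, str]]:
    """Per-locus calls of the named salt-tolerant donor lines.

    Donors absent from the panel are warned about and skipped.
    """
    out: dict[str, dict[str, str]] = {locus: {} for locus in genotypes.loci}
    for donor in donor_lines:
        if donor not in genotypes.calls.index:
            warnings.warn(f"donor line {donor!r} not in panel; skipped", stacklevel=2)
            continue
        for locus in genotypes.loci:
            out[locus][donor] = genotypes.calls.at[donor, locus]
    return out
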