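"""Quality/zygosity filtering and variant summary statistics.

Implements the post-calling filter (variant quality >= 100 and homozygous
genotype), transition/transversion classification, per-chromosome SNP and
InDel densities per 100 kb, and 100-kb window counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import VariantRecord

__all__ = [
    "ChromSummary",
    "filter_variants",
    "is_transition",
    "ts_tv_ratio",
    "density_per_window",
    "summarize_chromosomes",
]

DEFAULT_MIN_QUAL = 100.0
_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


@dataclass
class ChromSummary:
    chrom: str
    length: int
    n_snps: int
    n_indels: int
    n_mnps: int
    snp_density: float
    indel_density: float
    ts_tv: float | None


def filter_variants(
    variants: list[VariantRecord],
    min_qual: float = DEFAULT_MIN_QUAL,
    homozygous_only: bool = True,
) -> list[VariantRecord]:
    """Keep records with qual >= min_qual (threshold inclusive) and, when
    requested, homozygous genotype.  Order is preserved; idempotent."""
    return [
        v
        for v in variants
        if v.qual >= min_qual and (not homozygous_only or v.zygosity == "hom")
    ]


def is_transition(ref: str, alt: str) -> bool:
    """True iff the base change is purine<->purine or pyrimidine<->pyrimidine."""
    if len(ref) != 1 or len(alt) != 1 or ref == alt:
        raise ValueError("is_transition requires two distinct single bases")
    return (ref in _PURINES and alt in _PURINES) or (
        ref in _PYRIMIDINES and alt in _PYRIMIDINES
    )


def ts_tv_ratio(variants: list[VariantRecord]) -> float | None:
    """Transitions / transversions over the SNP records; None if no
    transversions (or no SNPs)."""
    ts = tv = 0
    for v in variants:
        if not v.is_snp:
            continue
        if is_transition(v.ref, v.alt):
            ts += 1
        else:
            tv += 1
    if tv == 0:
        return None
    return ts / tv


def density_per_window(
    variants: list[VariantRecord],
    chrom_lengths: dict[str, int],
    window: int = 100_000,
) -> tuple[dict[str, np.ndarray], dict[str, float]]:
    """Tile each chromosome with half-open windows of ``window`` bases (last
    partial window included) and count variants per window.

    Returns (per-chromosome window counts, per-chromosome density =
    count x 100000 / chromosome length).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    counts = {
        chrom: np.zeros(max((length + window - 1) // window, 1), dtype=int)
        for chrom, length in chrom_lengths.items()
    }
    for v in variants:
        if v.chrom not in counts:
            raise ValueError(f"variant on unknown chromosome {v.chrom}")
        if v.pos > chrom_lengths[v.chrom]:
            raise ValueError(
                f"variant at {v.chrom}:{v.pos} beyond chromosome end "
                f"{chrom_lengths[v.chrom]}"
            )
        counts[v.chrom][(v.pos - 1) // window] += 1
    density = {
        chrom: counts[chrom].sum() * 100_000 / length
        for chrom, length in chrom_lengths.items()
    }
    return counts, density


def summarize_chromosomes(
    variants: list[VariantRecord], chrom_lengths: dict[str, int]
) -> list[ChromSummary]:
    """Per-chromosome SNP/InDel counts, densities per 100 kb and Ts/Tv.

    SNP vs InDel is decided purely by allele lengths (after biallelic
    splitting); equal-length multi-base substitutions are counted as
    neither and reported in ``n_mnps``.
    """
    out = []
    for chrom in chrom_lengths:
        on_chrom = [v for v in variants if v.chrom == chrom]
        snps = [v for v in on_chrom if v.is_snp]
        indels = [v for v in on_chrom if v.is_indel]
        n_mnps = len(on_chrom) - len(snps) - len(indels)
        length = chrom_lengths[chrom]
        out.append(
            ChromSummary(
                chrom=chrom,
                length=length,
                n_snps=len(snps),
                n_indels=len(indels),
                n_mnps=n_mnps,
                snp_density=len(snps) * 100_000 / length,
                indel_density=len(indels) * 100_000 / length,
                ts_tv=ts_tv_ratio(snps),
            )
        )
    return out
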