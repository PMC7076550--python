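"""QTL-hotspot gene mining and interval projection between references.

Genes are assigned to every hotspot their span overlaps by at least one
base.  Interval projection between the two reference assemblies uses gene
anchors (the same gene located in both references) rather than sequence
re-alignment: the nearest flanking anchors supply per-end offsets.
"""

from __future__ import annotations

from dataclasses import dataclass

from intervaltree import IntervalTree

from .io import GeneModel, GenomicInterval, QTLHotspot

__all__ = [
    "AnchorMap",
    "ProjectionError",
    "genes_in_intervals",
    "select_stress_genes",
    "project_interval_by_anchors",
]


class ProjectionError(ValueError):
    """No anchors are available on the interval's chromosome."""


@dataclass
class AnchorMap:
    """Gene spans paired between reference A and reference B.

    Colinearity (anchor order preserved per chromosome) is assumed; the
    constructor sorts anchors by their reference-A start.
    """

    pairs: list[tuple[str, GenomicInterval, GenomicInterval]]

    def __post_init__(self) -> None:
        self.pairs = sorted(self.pairs, key=lambda p: (p[1].chrom, p[1].start))

    def on_chrom(self, chrom: str) -> list[tuple[str, GenomicInterval, GenomicInterval]]:
        return [p for p in self.pairs if p[1].chrom == chrom]

    def gene_offset(self, gene_id: str) -> int | None:
        for gid, a, b in self.pairs:
            if gid == gene_id:
                return b.start - a.start
        return None


def genes_in_intervals(
    genes: list[GeneModel], hotspots: list[QTLHotspot]
) -> tuple[dict[int, list[GeneModel]], list[GeneModel]]:
    """Assign genes to hotspots by >=1-base overlap of the gene span.

    Returns (hotspot_id -> genes, genes overlapping no hotspot).
    """
    trees: dict[str, IntervalTree] = {}
    known_chroms = {g.chrom for g in genes}
    for h in hotspots:
        iv = h.interval
        if genes and iv.chrom not in known_chroms:
            raise ValueError(
                f"hotspot {h.hotspot_id} on {iv.chrom}: no genes on that chromosome"
            )
        # half-open tree coordinates; +1 makes the inclusive end queryable
        trees.setdefault(iv.chrom, IntervalTree()).addi(
            iv.start, iv.end + 1, h.hotspot_id
        )
    assigned: dict[int, list[GeneModel]] = {h.hotspot_id: [] for h in hotspots}
    outside: list[GeneModel] = []
    for g in genes:
        tree = trees.get(g.chrom)
        hits = sorted(iv.data for iv in tree.overlap(g.start, g.end + 1)) if tree else []
        if not hits:
            outside.append(g)
        for hid in hits:
            assigned[hid].append(g)
    return assigned, outside


def select_stress_genes(
    genes: list[GeneModel], extra_gene_ids: set[str] | frozenset[str] = frozenset()
) -> tuple[list[GeneModel], list[str]]:
    """Union of stress-flagged genes and the supplied extra gene ids.

    Returns (selected genes without duplicates, warnings for extra ids not
    present in the annotation).
    """
    by_id = {g.gene_id: g for g in genes}
    warnings = [
        f"extra gene id {gid!r} absent from annotation; skipped"
        for gid in sorted(extra_gene_ids)
        if gid not in by_id
    ]
    selected: dict[str, GeneModel] = {}
    for g in genes:
        if g.stress_related or g.gene_id in extra_gene_ids:
            selected[g.gene_id] = g
    return list(selected.values()), warnings


def project_interval_by_anchors(
    interval: GenomicInterval, anchors: AnchorMap
) -> tuple[GenomicInterval, tuple[int, int]]:
    """Project an interval from reference A onto reference B via gene anchors.

    The start is shifted by the offset of the nearest anchor at or left of
    it (falling back to the leftmost anchor); likewise the end with the
    nearest anchor at or right of it (falling back to the rightmost).
    Returns the projected interval and the absolute per-end deviations.
    """
    on_chrom = anchors.on_chrom(interval.chrom)
    if not on_chrom:
        raise ProjectionError(f"no anchors on chromosome {interval.chrom}")
    lefts = [p for p in on_chrom if p[1].start <= interval.start]
    left = lefts[-1] if lefts else on_chrom[0]
    rights = [p for p in on_chrom if p[1].start >= interval.end]
    right = rights[0] if rights else on_chrom[-1]
    off_start = left[2].start - left[1].start
    off_end = right[2].start - right[1].start
    new_start = interval.start + off_start
    new_end = interval.end + off_end
    if new_start > new_end:
        new_start, new_end = min(new_start, new_end), max(new_start, new_end)
    projected = GenomicInterval(interval.id, interval.chrom, new_start, new_end)
    return projected, (abs(off_start), abs(off_end))
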