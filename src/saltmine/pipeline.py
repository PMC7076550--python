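"""End-to-end pipeline orchestration over the file layout the generator writes.

Each stage reads the standard-format files produced by ``simulate`` (or
supplied by the user in the same layout), runs one analysis step and
writes TSV reports under ``<workdir>/results``.  A JSON manifest beside
the outputs records package version, seed and a config hash, so re-runs
on unchanged inputs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

from . import __version__
from .consequence import ConsequenceCall, annotate_consequence, classify_feature
from .io import (
    GeneModel,
    SequenceSet,
    read_fasta,
    read_gff3_genes,
    read_hotspot_bed,
    read_vcf_variants,
    write_report_table,
)
from .panel import PanelGenotypes, call_panel_alleles, donor_presence_flags, indel_allele_frequency
from .promoter import extract_promoter, load_motif_table, scan_motifs, compare_element_counts
from .qtl import AnchorMap, genes_in_intervals, project_interval_by_anchors, select_stress_genes
from .screen import (
    design_indel_marker,
    dual_reference_concordance,
    parental_difference,
    screen_candidates,
)
from .simulate import SimulationConfig, simulate_study
from .stats import filter_variants, summarize_chromosomes, density_per_window
import pandas as pd

from .io import GenomicInterval

__all__ = ["PipelineConfig", "StudyFiles", "run_stage", "run_all", "STAGES"]

STAGES = ("simulate", "stats", "mine", "annotate", "screen", "panel", "promoter", "all")


@dataclass
class PipelineConfig:
    workdir: str = "saltmine_work"
    seed: int = 0
    min_qual: float = 100.0
    promoter_length: int = 1000
    concordance_tolerance: int = 10
    readthrough_limit: int = 3000
    marker_flank: int = 20
    motif_table: str | None = None
    p1_name: str = "At354"
    p2_name: str = "Bg352"
    ref1_name: str = "ref1"
    ref2_name: str = "ref2"

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class StudyFiles:
    """Resolved input paths in the generator's layout under a directory."""

    root: str

    def path(self, name: str) -> str:
        return os.path.join(self.root, name)

    def require(self, name: str) -> str:
        p = self.path(name)
        if not os.path.exists(p):
            raise FileNotFoundError(f"missing input file: {p}")
        return p


def _results_dir(cfg: PipelineConfig) -> str:
    d = os.path.join(cfg.workdir, "results")
    os.makedirs(d, exist_ok=True)
    return d


def _write_manifest(cfg: PipelineConfig, stage: str, outputs: list[str]) -> None:
    manifest = {
        "tool": "saltmine",
        "version": __version__,
        "stage": stage,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "outputs": sorted(os.path.basename(o) for o in outputs),
    }
    with open(os.path.join(_results_dir(cfg), f"manifest_{stage}.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def _load_inputs(cfg: PipelineConfig):
    files = StudyFiles(cfg.workdir)
    genome1 = read_fasta(files.require("ref1.fasta"))
    genome2 = read_fasta(files.require("ref2.fasta"))
    stress_ids = set()
    sg = files.path("stress_genes.tsv")
    if os.path.exists(sg):
        with open(sg) as fh:
            stress_ids = {line.strip() for line in fh if line.strip()}
    genes1 = read_gff3_genes(files.require("genes_ref1.gff3"), stress_ids)
    genes2 = read_gff3_genes(files.require("genes_ref2.gff3"), stress_ids)
    hotspots = read_hotspot_bed(files.require("hotspots_ref1.bed"))
    variants = {}
    for pname, sample in (("P1", cfg.p1_name), ("P2", cfg.p2_name)):
        for ref_label, ref_name in (("ref1", cfg.ref1_name), ("ref2", cfg.ref2_name)):
            variants[(pname, ref_label)] = read_vcf_variants(
                files.require(f"{pname}_vs_{ref_label}.vcf"), sample, ref_name
            )
    anchors = _read_anchor_tsv(files.require("anchors.tsv"))
    return files, genome1, genome2, genes1, genes2, hotspots, variants, anchors


def _read_anchor_tsv(path: str) -> AnchorMap:
    df = pd.read_csv(path, sep="\t")
    pairs = [
        (
            row.gene_id,
            GenomicInterval(row.gene_id, row.chrom, int(row.start1), int(row.end1)),
            GenomicInterval(row.gene_id, row.chrom, int(row.start2), int(row.end2)),
        )
        for row in df.itertuples()
    ]
    return AnchorMap(pairs)


def _gene_for_variant(
    variant, genes: list[GeneModel], promoter_length: int
) -> tuple[GeneModel, str] | None:
    """The gene (and feature) a variant belongs to, or None if intergenic
    everywhere.  CDS overlap wins over UTR/intron/promoter across genes."""
    best = None
    rank = {"exon_cds": 0, "5utr": 1, "3utr": 2, "intron": 3, "promoter": 4}
    for g in genes:
        if g.chrom != variant.chrom:
            continue
        if variant.pos < g.start - promoter_length - 1 or variant.pos > g.end + promoter_length + 1:
            continue
        feat = classify_feature(variant, g, promoter_length)
        if feat == "intergenic":
            continue
        if best is None or rank[feat] < rank[best[1]]:
            best = (g, feat)
    return best


# ---------------------------------------------------------------------------
# Stages


def stage_simulate(cfg: PipelineConfig, sim_config: SimulationConfig | None = None) -> list[str]:
    sim = sim_config or SimulationConfig(seed=cfg.seed)
    study = simulate_study(sim)
    paths = study.write(cfg.workdir)
    _write_manifest(cfg, "simulate", list(paths.values()))
    return list(paths.values())


def stage_stats(cfg: PipelineConfig) -> list[str]:
    files, g1, g2, genes1, genes2, hotspots, variants, anchors = _load_inputs(cfg)
    outdir = _results_dir(cfg)
    outputs = []
    rows = []
    window_rows = []
    for (pname, ref_label), recs in sorted(variants.items()):
        genome = g1 if ref_label == "ref1" else g2
        kept = filter_variants(recs, cfg.min_qual, True)
        for s in summarize_chromosomes(kept, genome.lengths):
            rows.append(
                {
                    "sample": pname,
                    "reference": ref_label,
                    "chrom": s.chrom,
                    "n_snps": s.n_snps,
                    "n_indels": s.n_indels,
                    "snp_density_per_100kb": round(s.snp_density, 3),
                    "indel_density_per_100kb": round(s.indel_density, 3),
                    "ts_tv": "" if s.ts_tv is None else round(s.ts_tv, 3),
                }
            )
        counts, _dens = density_per_window(kept, genome.lengths)
        for chrom, arr in counts.items():
            for w, n in enumerate(arr):
                window_rows.append(
                    {
                        "sample": pname,
                        "reference": ref_label,
                        "chrom": chrom,
                        "window_start": w * 100_000 + 1,
                        "count": int(n),
                    }
                )
    p = os.path.join(outdir, "variant_summary.tsv")
    pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
    outputs.append(p)
    p = os.path.join(outdir, "window_counts.tsv")
    pd.DataFrame(window_rows).to_csv(p, sep="\t", index=False)
    outputs.append(p)
    _write_manifest(cfg, "stats", outputs)
    return outputs


def stage_mine(cfg: PipelineConfig) -> list[str]:
    files, g1, g2, genes1, genes2, hotspots, variants, anchors = _load_inputs(cfg)
    outdir = _results_dir(cfg)
    assigned, outside = genes_in_intervals(genes1, hotspots)
    rows = []
    for hid in sorted(assigned):
        for g in assigned[hid]:
            rows.append(
                {"hotspot_id": hid, "gene_id": g.gene_id, "stress_related": g.stress_related}
            )
    for g in outside:
        rows.append(
            {"hotspot_id": "non-QTL", "gene_id": g.gene_id, "stress_related": g.stress_related}
        )
    p1 = os.path.join(outdir, "hotspot_genes.tsv")
    pd.DataFrame(rows).to_csv(p1, sep="\t", index=False)
    proj_rows = []
    for h in hotspots:
        projected, (dev_s, dev_e) = project_interval_by_anchors(h.interval, anchors)
        proj_rows.append(
            {
                "hotspot_id": h.hotspot_id,
                "chrom": h.interval.chrom,
                "start_ref1": h.interval.start,
                "end_ref1": h.interval.end,
                "start_ref2": projected.start,
                "end_ref2": projected.end,
                "deviation_start": dev_s,
                "deviation_end": dev_e,
            }
        )
    p2 = os.path.join(outdir, "hotspot_projection.tsv")
    pd.DataFrame(proj_rows).to_csv(p2, sep="\t", index=False)
    _write_manifest(cfg, "mine", [p1, p2])
    return [p1, p2]


def _annotate_all(cfg: PipelineConfig, genome, genes, variants) -> list[ConsequenceCall]:
    calls = []
    for v in variants:
        hit = _gene_for_variant(v, genes, cfg.promoter_length)
        if hit is None:
            continue
        gene, _feat = hit
        calls.append(
            annotate_consequence(
                gene, v, genome, cfg.promoter_length, cfg.readthrough_limit
            )
        )
    return calls


def stage_annotate(cfg: PipelineConfig) -> list[str]:
    files, g1, g2, genes1, genes2, hotspots, variants, anchors = _load_inputs(cfg)
    outdir = _results_dir(cfg)
    rows = []
    for pname in ("P1", "P2"):
        kept = filter_variants(variants[(pname, "ref1")], cfg.min_qual, True)
        for call in _annotate_all(cfg, g1, genes1, kept):
            v = call.variant
            rows.append(
                {
                    "gene_id": call.gene_id,
                    "sample": pname,
                    "reference_id": v.reference_id,
                    "chrom": v.chrom,
                    "pos": v.pos,
                    "ref": v.ref,
                    "alt": v.alt,
                    "feature": call.feature,
                    "effect": call.effect,
                    "aa_change": call.aa_change,
                    "protein_length_ref": call.protein_length_ref,
                    "protein_length_alt": call.protein_length_alt,
                    "report_label": call.report_label,
                }
            )
    p = os.path.join(outdir, "consequences.tsv")
    write_report_table(rows, p)
    _write_manifest(cfg, "annotate", [p])
    return [p]


def _screen(cfg: PipelineConfig):
    """Shared screening logic: returns confirmed/dropped candidates plus context."""
    files, g1, g2, genes1, genes2, hotspots, variants, anchors = _load_inputs(cfg)
    p1 = filter_variants(variants[("P1", "ref1")], cfg.min_qual, True)
    p2 = filter_variants(variants[("P2", "ref1")], cfg.min_qual, True)
    poly = parental_difference(p1, p2)
    consequences = {}
    for pv in poly:
        hit = _gene_for_variant(pv.variant, genes1, cfg.promoter_length)
        if hit is None:
            continue
        gene, _ = hit
        consequences[pv.variant.key()] = annotate_consequence(
            gene, pv.variant, g1, cfg.promoter_length, cfg.readthrough_limit
        )
    stress, _warn = select_stress_genes(genes1)
    candidates = screen_candidates(stress, poly, consequences, hotspots)
    ref2_calls = filter_variants(
        variants[("P1", "ref2")] + variants[("P2", "ref2")], cfg.min_qual, True
    )
    confirmed, dropped = dual_reference_concordance(
        candidates, ref2_calls, anchors, cfg.concordance_tolerance
    )
    return files, g1, confirmed, dropped, anchors


def stage_screen(cfg: PipelineConfig) -> list[str]:
    files, genome1, confirmed, dropped, anchors = _screen(cfg)
    outdir = _results_dir(cfg)
    rows = []
    for cand, status in [(c, "confirmed") for c in confirmed] + [
        (c, "dropped") for c in dropped
    ]:
        for pv, call in cand.variants:
            v = pv.variant
            offset = anchors.gene_offset(cand.gene_id) or 0
            rows.append(
                {
                    "gene_id": cand.gene_id,
                    "hotspot_id": cand.hotspot_id,
                    "donor_parent": cand.donor_parent or "",
                    "variation_type": "Indel" if v.is_indel else "SNP",
                    "pos": v.pos,
                    "pos_ref2": v.pos + offset,
                    "ref_allele": v.ref,
                    "alt_allele": v.alt,
                    "carrier": pv.carrier,
                    "effect": call.effect,
                    "amino_acid_position": call.report_label,
                    "status": status,
                    "drop_reason": "; ".join(cand.drop_reasons),
                }
            )
    p1 = os.path.join(outdir, "candidates.tsv")
    write_report_table(rows, p1)
    marker_rows = []
    for cand in confirmed:
        for pv in cand.defining_indels:
            v = pv.variant
            design = design_indel_marker(genome1, v, cfg.marker_flank)
            marker_rows.append(
                {
                    "gene_id": cand.gene_id,
                    "pos": v.pos,
                    "ref": v.ref,
                    "alt": v.alt,
                    "forward_primer": f"{design.forward_primer[0]}-{design.forward_primer[1]}",
                    "reverse_primer": f"{design.reverse_primer[0]}-{design.reverse_primer[1]}",
                    "amplicon_length_ref": design.amplicon_length_ref,
                    "amplicon_length_alt": design.amplicon_length_alt,
                    "size_difference": design.size_difference,
                }
            )
    p2 = os.path.join(outdir, "indel_markers.tsv")
    write_report_table(marker_rows, p2)
    _write_manifest(cfg, "screen", [p1, p2])
    return [p1, p2]


def _candidate_indel_loci(cfg: PipelineConfig):
    files, genome1, confirmed, dropped, anchors = _screen(cfg)
    loci = []
    for cand in confirmed:
        for pv in cand.defining_indels:
            loci.append((cand.gene_id, pv.variant))
    return files, genome1, loci


def stage_panel(cfg: PipelineConfig) -> list[str]:
    files, genome1, loci = _candidate_indel_loci(cfg)
    outdir = _results_dir(cfg)
    seqs = read_fasta(files.require("panel_sequences.fasta"))
    donor_path = files.path("donor_lines.tsv")
    donors = []
    if os.path.exists(donor_path):
        with open(donor_path) as fh:
            donors = [line.strip() for line in fh if line.strip()]
    columns = {}
    for gene_id, v in loci:
        locus_id = f"{gene_id}:{v.pos}"
        line_seqs = {}
        for name, seq in seqs.entries.items():
            line, _, loc = name.partition("|")
            if loc == locus_id:
                line_seqs[line] = seq
        if not line_seqs:
            continue
        columns[locus_id] = call_panel_alleles(line_seqs, v, genome1)
    genotypes = PanelGenotypes(pd.DataFrame(columns))
    freq_rows = []
    flags = donor_presence_flags(genotypes, donors)
    for locus in genotypes.loci:
        freq = indel_allele_frequency(genotypes, locus)
        row = {
            "locus": locus,
            "alt_frequency": "" if freq is None else round(freq, 4),
        }
        for d in donors:
            row[f"donor_{d}"] = flags[locus].get(d, "")
        freq_rows.append(row)
    p1 = os.path.join(outdir, "panel_frequencies.tsv")
    pd.DataFrame(freq_rows).to_csv(p1, sep="\t", index=False)
    p2 = os.path.join(outdir, "panel_calls.tsv")
    genotypes.calls.to_csv(p2, sep="\t", index_label="line")
    _write_manifest(cfg, "panel", [p1, p2])
    return [p1, p2]


def stage_promoter(cfg: PipelineConfig) -> list[str]:
    files, g1, g2, genes1, genes2, hotspots, variants, anchors = _load_inputs(cfg)
    _files, _genome1, loci = _candidate_indel_loci(cfg)
    outdir = _results_dir(cfg)
    motifs = load_motif_table(cfg.motif_table)
    stress = {m.name for m in motifs if m.stress_related}
    genes_by_id = {g.gene_id: g for g in genes1}
    p1_vars = filter_variants(variants[("P1", "ref1")], cfg.min_qual, True)
    p2_vars = filter_variants(variants[("P2", "ref1")], cfg.min_qual, True)
    hits1, hits2 = [], []
    for gene_id in sorted({gid for gid, _ in loci}):
        gene = genes_by_id[gene_id]
        for sample, varset, sink in (
            ("P1", p1_vars, hits1),
            ("P2", p2_vars, hits2),
        ):
            seq, _trunc = extract_promoter(gene, g1, varset, cfg.promoter_length)
            sink.extend(scan_motifs(seq, motifs, True, gene_id, sample))
    table = compare_element_counts(hits1, hits2, stress)
    p = os.path.join(outdir, "promoter_elements.tsv")
    table.to_csv(p, sep="\t", index=False)
    _write_manifest(cfg, "promoter", [p])
    return [p]


def run_stage(
    name: str, cfg: PipelineConfig, sim_config: SimulationConfig | None = None
) -> list[str]:
    stages = {
        "simulate": lambda: stage_simulate(cfg, sim_config),
        "stats": lambda: stage_stats(cfg),
        "mine": lambda: stage_mine(cfg),
        "annotate": lambda: stage_annotate(cfg),
        "screen": lambda: stage_screen(cfg),
        "panel": lambda: stage_panel(cfg),
        "promoter": lambda: stage_promoter(cfg),
        "all": lambda: run_all(cfg, sim_config),
    }
    if name not in stages:
        raise KeyError(name)
    return stages[name]()


def run_all(
    cfg: PipelineConfig, sim_config: SimulationConfig | None = None
) -> list[str]:
    outputs = []
    outputs += stage_simulate(cfg, sim_config)
    for stage in ("stats", "mine", "annotate", "screen", "panel", "promoter"):
        outputs += run_stage(stage, cfg)
    return outputs
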