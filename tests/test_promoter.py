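"""Promoter extraction and IUPAC motif scanning."""

import numpy as np
import pytest

from saltmine.io import GeneModel, SequenceSet, VariantRecord
from saltmine.promoter import (
    MotifDefinition,
    compare_element_counts,
    extract_promoter,
    load_motif_table,
    scan_motifs,
)

_IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T", "R": "AG", "Y": "CT", "S": "CG",
    "W": "AT", "K": "GT", "M": "AC", "B": "CGT", "D": "AGT", "H": "ACT",
    "V": "ACG", "N": "ACGT",
}
_RC = str.maketrans("ACGT", "TGCA")


def _gene(strand, start, end, chrom="c1"):
    return GeneModel("g", chrom, strand, start, end, exons=[(start, end)],
                     cds_segments=[(start, end)])


def V(pos, ref, alt):
    return VariantRecord("c1", pos, ref, alt, 150.0, "hom", "At354", "ref1")


class TestExtract:
    def _genome(self, n=8000, seed=2):
        rng = np.random.default_rng(seed)
        return SequenceSet({"c1": "".join(rng.choice(list("ACGT"), n))})

    def test_plus_strand_window(self):
        genome = self._genome()
        seq, trunc = extract_promoter(_gene("+", 2001, 3000), genome)
        assert seq == genome.fetch("c1", 1001, 2000)
        assert not trunc

    def test_minus_strand_is_reverse_complement_downstream(self):
        genome = self._genome()
        seq, trunc = extract_promoter(_gene("-", 4001, 5000), genome)
        assert seq == genome.fetch("c1", 5001, 6000).translate(_RC)[::-1]
        assert not trunc

    def test_truncated_at_chromosome_start(self):
        genome = self._genome()
        seq, trunc = extract_promoter(_gene("+", 501, 1500), genome)
        assert trunc and len(seq) == 500

    def test_sample_snp_changes_exactly_one_position(self):
        genome = self._genome()
        gene = _gene("+", 2001, 3000)
        base, _ = extract_promoter(gene, genome)
        ref = genome.fetch("c1", 1500, 1500)
        alt = "A" if ref != "A" else "C"
        mut, _ = extract_promoter(gene, genome, [V(1500, ref, alt)])
        diffs = [i for i, (a, b) in enumerate(zip(base, mut)) if a != b]
        assert diffs == [499]


class TestScan:
    def test_literal_match_offset(self):
        hits = scan_motifs("AACCAATT", [MotifDefinition("CAAT", "CCAAT")],
                           both_strands=False)
        assert [(h.element, h.offset) for h in hits] == [("CAAT", 3)]

    def test_degenerate_iupac(self):
        m = [MotifDefinition("X", "ACGTR")]
        assert len(scan_motifs("ACGTA", m, both_strands=False)) == 1
        assert len(scan_motifs("ACGTG", m, both_strands=False)) == 1
        assert len(scan_motifs("ACGTC", m, both_strands=False)) == 0

    def test_overlapping_matches_all_reported(self):
        hits = scan_motifs("AAAA", [MotifDefinition("A2", "AA")], both_strands=False)
        assert [h.offset for h in hits] == [1, 2, 3]

    def test_translation_invariance(self):
        motifs = [MotifDefinition("G", "GGWCC")]
        seq = "ATGGACCTTGGTCCA"
        base = scan_motifs(seq, motifs)
        shifted = scan_motifs("TTTT" + seq, motifs)
        assert [(h.element, h.strand, h.offset + 4) for h in base] == [
            (h.element, h.strand, h.offset) for h in shifted
        ]

    def test_reverse_strand_equals_forward_on_revcomp(self):
        rng = np.random.default_rng(6)
        seq = "".join(rng.choice(list("ACGT"), 400))
        motifs = [MotifDefinition("M", "GATAAG")]
        rc = seq.translate(_RC)[::-1]
        minus = [h for h in scan_motifs(seq, motifs) if h.strand == "-"]
        plus_on_rc = [h for h in scan_motifs(rc, motifs, both_strands=False)]
        n = len(seq)
        mapped = sorted(n - (h.offset - 1) - len("GATAAG") + 1 for h in plus_on_rc)
        assert sorted(h.offset for h in minus) == mapped

    def test_matches_positionwise_oracle_on_random_pairs(self):
        rng = np.random.default_rng(13)
        codes = list(_IUPAC_SETS)
        for _ in range(1000):
            seq = "".join(rng.choice(list("ACGT"), 60))
            motif = "".join(rng.choice(codes, int(rng.integers(3, 7))))
            got = {h.offset for h in scan_motifs(seq, [MotifDefinition("m", motif)],
                                                 both_strands=False)}
            expect = set()
            for i in range(len(seq) - len(motif) + 1):
                if all(seq[i + j] in _IUPAC_SETS[motif[j]] for j in range(len(motif))):
                    expect.add(i + 1)
            assert got == expect

    def test_packaged_table_loads_nine_stress_elements(self):
        motifs = load_motif_table()
        assert {m.name for m in motifs} == {
            "ABRE", "CAAT", "DPBF", "GAGA", "GBOX", "IBOX", "ROOT", "SEF3", "SEF4"
        }
        assert all(m.stress_related for m in motifs)


class TestCompare:
    def test_identical_promoters_zero_differences(self):
        motifs = [MotifDefinition("GBOX", "CACGTG")]
        seq = "TTCACGTGTTCACGTGTT"
        h1 = scan_motifs(seq, motifs, gene_id="g", sample_id="P1")
        h2 = scan_motifs(seq, motifs, gene_id="g", sample_id="P2")
        table = compare_element_counts(h1, h2)
        assert (table["difference"] == 0).all()
        assert not table["absent_in_p1"].any()

    def test_destroyed_gbox_differs_by_one_and_total_conserved(self):
        motifs = [MotifDefinition("GBOX", "CACGTG"), MotifDefinition("ABRE", "ACGTG")]
        p2_seq = "TTCACGTGTTTTCACGTGTT"
        p1_seq = p2_seq.replace("CACGTG", "CATGTG", 1)  # SNP kills one GBOX
        h1 = scan_motifs(p1_seq, motifs, gene_id="g", sample_id="P1")
        h2 = scan_motifs(p2_seq, motifs, gene_id="g", sample_id="P2")
        table = compare_element_counts(h1, h2).set_index("element")
        assert table.loc["GBOX", "count_p2"] - table.loc["GBOX", "count_p1"] == 1
        # totals equal the sum over elements (conservation)
        assert table["count_p1"].sum() == len(h1)
        assert table["count_p2"].sum() == len(h2)

    def test_element_present_in_one_parent_only_flagged(self):
        motifs = [MotifDefinition("DPBF", "ACACTTG")]
        h2 = scan_motifs("AAACACTTGAA", motifs, gene_id="g", sample_id="P2")
        table = compare_element_counts([], h2)
        row = table.iloc[0]
        assert row["absent_in_p1"] and not row["absent_in_p2"]
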