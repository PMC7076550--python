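"""Feature classification, sequence editing, translation and effect calls."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from saltmine.consequence import (
    annotate_consequence,
    apply_variants_to_sequence,
    classify_feature,
    find_longest_orf,
    normalize_variant,
    translate_cds,
)
from saltmine.io import GeneModel, SequenceSet, VariantRecord
from saltmine.simulate import synthesize_cds_locus

# independent codon oracle for translation tests (deliberately not the
# implementation's table object)
_ORACLE = {}
_BASES = "TCAG"
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, (_a, _b, _c) in enumerate(
    (a, b, c) for a in _BASES for b in _BASES for c in _BASES
):
    _ORACLE[_a + _b + _c] = _AA[_i]


def V(chrom, pos, ref, alt):
    return VariantRecord(chrom, pos, ref, alt, 150.0, "hom", "At354", "ref1")


class TestClassifyFeature:
    def _gene(self, strand="+"):
        return GeneModel(
            "g", "c1", strand, 2001, 2600,
            exons=[(2001, 2200), (2301, 2600)],
            cds_segments=[(2101, 2200), (2301, 2500)],
        )

    @pytest.mark.parametrize(
        "pos,expected",
        [
            (2150, "exon_cds"),
            (2050, "5utr"),
            (2550, "3utr"),
            (2250, "intron"),
            (1501, "promoter"),
            (900, "intergenic"),
        ],
    )
    def test_plus_strand_features(self, pos, expected):
        assert classify_feature(V("c1", pos, "A", "G"), self._gene()) == expected

    def test_minus_strand_promoter_is_downstream_in_genomic_coords(self):
        g = self._gene("-")
        assert classify_feature(V("c1", 2700, "A", "G"), g) == "promoter"
        assert classify_feature(V("c1", 1900, "A", "G"), g) == "intergenic"

    def test_all_planted_variants_classified_to_truth(self, study, genes_by_id):
        for t in study.truths:
            v = V(t.chrom, t.pos, t.ref, t.alt)
            assert classify_feature(v, genes_by_id[t.gene_id]) == t.feature


class TestApplyVariants:
    def test_identity_and_involution(self):
        seq = "ACGTACGTACGT"
        assert apply_variants_to_sequence(seq, []) == seq
        edits = [(2, "C", "TT"), (7, "GTA", "G")]
        mutated = apply_variants_to_sequence(seq, edits)
        # invert at updated positions: +1 offset after the first edit
        inverse = [(2, "TT", "C"), (8, "G", "GTA")]
        assert apply_variants_to_sequence(mutated, inverse) == seq

    def test_ref_mismatch_and_overlap_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            apply_variants_to_sequence("AAAA", [(2, "C", "G")])
        with pytest.raises(ValueError, match="overlap"):
            apply_variants_to_sequence("AAAA", [(1, "AA", "A"), (2, "AA", "A")])

    @settings(max_examples=100, deadline=None)
    @given(st.data())
    def test_length_arithmetic(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        seq = "".join(rng.choice(list("ACGT"), 200))
        edits, cursor = [], 1
        while cursor < 190:
            pos = cursor + int(rng.integers(0, 5))
            ref = seq[pos - 1 : pos - 1 + int(rng.integers(1, 4))]
            if not ref:
                break
            alt = "".join(rng.choice(list("ACGT"), int(rng.integers(1, 5))))
            if alt == ref:
                alt = ref + "A"
            edits.append((pos, ref, alt))
            cursor = pos + len(ref) + 1
        out = apply_variants_to_sequence(seq, edits)
        assert len(out) == len(seq) + sum(len(a) - len(r) for _, r, a in edits)


class TestTranslate:
    def test_basic_and_no_stop_flag(self):
        assert translate_cds("ATGAAATAA") == ("MK", False)
        assert translate_cds("ATGAAA") == ("MK", True)
        assert translate_cds("ATGAAAT") == ("MK", True)  # trailing partial codon

    def test_matches_codon_table_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(300):
            n = int(rng.integers(1, 60))
            seq = "".join(rng.choice(list("ACGT"), 3 * n))
            prot, no_stop = translate_cds(seq)
            expected = []
            found_stop = False
            for i in range(0, len(seq), 3):
                aa = _ORACLE[seq[i : i + 3]]
                if aa == "*":
                    found_stop = True
                    break
                expected.append(aa)
            assert prot == "".join(expected)
            assert no_stop == (not found_stop)


class TestNormalize:
    def test_left_alignment_in_repeat_tract(self):
        genome = SequenceSet({"c1": "GGTACACACACATT"})
        # deleting one AC unit is ambiguous; leftmost anchored form expected
        v = V("c1", 7, "CAC", "C")
        n = normalize_variant(v, genome)
        assert (n.pos, n.ref, n.alt) == (3, "TAC", "T")

    def test_snp_unchanged(self):
        genome = SequenceSet({"c1": "ACGT"})
        v = V("c1", 2, "C", "T")
        assert normalize_variant(v, genome) is v


class TestAnnotate:
    def test_printed_twelve_bp_deletion_truncates_to_761(self):
        genome, gene, recs = synthesize_cds_locus(765, [("ACTGCGGCGGCGGC", "AC")])
        call = annotate_consequence(gene, recs[0], genome)
        assert call.effect == "inframe_indel"
        assert call.report_label == "frame shift"
        assert (call.protein_length_ref, call.protein_length_alt) == (765, 761)

    def test_ile_to_met_missense_notation(self):
        # ATA -> ATG is the only single-base Ile->Met change
        genome, gene, recs = synthesize_cds_locus(100, [("ATA", "ATG")], codon_offsets=[19])
        call = annotate_consequence(gene, recs[0], genome)
        assert call.effect == "missense"
        assert call.aa_change == "I 20 M"
        assert call.protein_length_ref == call.protein_length_alt == 100

    def test_asn_to_ser_missense(self):
        # A->G at the 2nd base of an Asn codon: AAT -> AGT is N -> S
        genome, gene, recs = synthesize_cds_locus(100, [("AAT", "AGT")], codon_offsets=[69])
        call = annotate_consequence(gene, recs[0], genome)
        assert call.effect == "missense"
        assert call.aa_change == "N 70 S"

    def test_synonymous_third_base_change(self):
        genome, gene, recs = synthesize_cds_locus(50, [("GCC", "GCT")], codon_offsets=[20])
        call = annotate_consequence(gene, recs[0], genome)
        assert call.effect == "synonymous"
        assert call.protein_length_ref == call.protein_length_alt == 50

    def test_stop_gain_shortens_protein(self):
        genome, gene, recs = synthesize_cds_locus(80, [("GCC", "TAA")], codon_offsets=[30])
        call = annotate_consequence(gene, recs[0], genome)
        assert call.effect == "stop_gain"
        assert call.protein_length_alt == 30

    def test_stop_loss_reads_through(self, study, genes_by_id):
        losses = [t for t in study.truths if t.consequence == "stop_loss"]
        assert losses
        for t in losses[:5]:
            call = annotate_consequence(
                genes_by_id[t.gene_id], V(t.chrom, t.pos, t.ref, t.alt), study.genome1
            )
            assert call.effect == "stop_loss"
            assert call.protein_length_alt >= call.protein_length_ref

    def test_frameshift_divergence_matches_codon_arithmetic(self):
        # +1 insertion at the boundary after codon 40 diverges from residue 41
        genome, gene, recs = synthesize_cds_locus(120, [("G", "GA")], codon_offsets=[40])
        call = annotate_consequence(gene, recs[0], genome)
        assert call.effect == "frameshift"
        assert call.frame_shift_start == 41

    def test_strand_mirror_yields_identical_call(self, study, genes_by_id):
        # annotate a minus-strand gene and its mirrored plus-strand copy
        minus = [t for t in study.truths
                 if genes_by_id[t.gene_id].strand == "-" and t.feature == "exon_cds"]
        assert minus
        for t in minus[:8]:
            g = genes_by_id[t.gene_id]
            L = len(study.genome1[t.chrom])
            rc = str(__import__("Bio.Seq", fromlist=["Seq"]).Seq(
                study.genome1[t.chrom]).reverse_complement())
            mirror_genome = SequenceSet({t.chrom: rc})

            def flip(iv):
                s, e = iv
                return (L - e + 1, L - s + 1)

            mirror_gene = GeneModel(
                g.gene_id, g.chrom, "+", L - g.end + 1, L - g.start + 1,
                exons=sorted(flip(iv) for iv in g.exons),
                cds_segments=sorted(flip(iv) for iv in g.cds_segments),
            )
            comp = str.maketrans("ACGT", "TGCA")
            m_ref = t.ref.translate(comp)[::-1]
            m_alt = t.alt.translate(comp)[::-1]
            m_pos = L - (t.pos + len(t.ref) - 1) + 1
            call1 = annotate_consequence(g, V(t.chrom, t.pos, t.ref, t.alt), study.genome1)
            call2 = annotate_consequence(
                mirror_gene, V(t.chrom, m_pos, m_ref, m_alt), mirror_genome
            )
            assert (call1.effect, call1.aa_change, call1.protein_length_ref,
                    call1.protein_length_alt) == (
                call2.effect, call2.aa_change, call2.protein_length_ref,
                call2.protein_length_alt)

    def test_inframe_length_arithmetic_on_planted_indels(self, study, genes_by_id):
        for t in study.truths:
            if t.consequence != "inframe_indel":
                continue
            d = len(t.alt) - len(t.ref)
            assert t.protein_length_alt - t.protein_length_ref == d // 3
            call = annotate_consequence(
                genes_by_id[t.gene_id], V(t.chrom, t.pos, t.ref, t.alt), study.genome1
            )
            assert call.protein_length_alt - call.protein_length_ref == d // 3


class TestFindLongestOrf:
    def test_minimal_orf(self):
        assert find_longest_orf("ATGAAATAA", min_length=1) == (1, 9, 0, "MK")

    def test_tie_breaks_to_leftmost(self):
        seq = "ATGAAATAA" + "C" + "ATGCCCTAA"
        start, end, frame, prot = find_longest_orf(seq, min_length=1)
        assert start == 1 and prot == "MK"

    def test_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(21)
        stops = {"TAA", "TAG", "TGA"}
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), 3000))
            best = None
            for frame in range(3):
                i = frame
                while i <= len(seq) - 3:
                    if seq[i : i + 3] == "ATG":
                        j = i + 3
                        while j <= len(seq) - 3 and seq[j : j + 3] not in stops:
                            j += 3
                        if j <= len(seq) - 3:
                            n_codons = (j - i) // 3
                            key = (n_codons, -(i + 1))
                            if n_codons >= 5 and (best is None or key > best[0]):
                                best = (key, (i + 1, j + 3))
                    i += 3
            got = find_longest_orf(seq, min_length=5)
            if best is None:
                assert got is None
            else:
                assert (got[0], got[1]) == best[1]
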