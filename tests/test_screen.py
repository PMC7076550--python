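"""Parental polymorphism, candidate filtering, concordance and markers."""

import numpy as np
import pytest

from saltmine.consequence import ConsequenceCall
from saltmine.io import GeneModel, GenomicInterval, SequenceSet, VariantRecord
from saltmine.qtl import AnchorMap
from saltmine.screen import (
    design_indel_marker,
    dual_reference_concordance,
    parental_difference,
    screen_candidates,
    CandidateGene,
    PolymorphicVariant,
)


def V(pos, ref="A", alt="G", sample="At354", reference="ref1", chrom="c1"):
    return VariantRecord(chrom, pos, ref, alt, 150.0, "hom", sample, reference)


class TestParentalDifference:
    def test_identical_sets_empty(self):
        vs = [V(1), V(5, "C", "CAT", sample="At354")]
        mirror = [VariantRecord(v.chrom, v.pos, v.ref, v.alt, v.qual, v.zygosity,
                                "Bg352", v.reference_id) for v in vs]
        assert parental_difference(vs, mirror) == []

    def test_one_sided_variant_carries_its_parent(self):
        out = parental_difference([V(10)], [])
        assert len(out) == 1 and out[0].carrier == "At354"

    def test_symmetry(self):
        a = [V(1), V(3)]
        b = [V(3, sample="Bg352"), V(9, sample="Bg352")]
        fwd = parental_difference(a, b)
        rev = parental_difference(b, a)
        assert {pv.variant.key() for pv in fwd} == {pv.variant.key() for pv in rev}
        assert {pv.carrier for pv in fwd} == {"At354", "Bg352"}

    def test_reference_mismatch_rejected(self):
        with pytest.raises(ValueError):
            parental_difference([V(1)], [V(2, reference="ref2", sample="Bg352")])

    def test_matches_set_algebra_bruteforce(self):
        rng = np.random.default_rng(17)
        keys = rng.integers(1, 4000, size=(10_000, 1))
        a = [V(int(k)) for k in np.unique(keys[:5000])]
        b = [V(int(k), sample="Bg352") for k in np.unique(keys[5000:])]
        got = {pv.variant.key() for pv in parental_difference(a, b)}
        expect = {v.key() for v in a} ^ {v.key() for v in b}
        assert got == expect


def _call(gene_id, variant, effect, feature="exon_cds"):
    return ConsequenceCall(gene_id=gene_id, variant=variant, feature=feature,
                           effect=effect)


class TestScreen:
    def _gene(self, gid, start=100, end=200):
        return GeneModel(gid, "c1", "+", start, end, exons=[(start, end)],
                         cds_segments=[(start, end - 2)], stress_related=True)

    def test_synonymous_only_gene_excluded(self):
        g = self._gene("g1")
        v = V(150)
        poly = [PolymorphicVariant(v, "At354")]
        cands = screen_candidates([g], poly, {v.key(): _call("g1", v, "synonymous")})
        assert cands == []

    def test_missense_gene_included(self):
        g = self._gene("g1")
        v = V(150)
        cands = screen_candidates([g], [PolymorphicVariant(v, "At354")],
                                  {v.key(): _call("g1", v, "missense")})
        assert [c.gene_id for c in cands] == ["g1"]
        assert cands[0].hotspot_id == "non-QTL"

    def test_truth_candidates_recovered_exactly(self, study, genes_by_id):
        # genes with >=1 single-parent exonic non-synonymous planted variant
        expected = {
            t.gene_id
            for t in study.truths
            if t.feature == "exon_cds" and t.consequence != "synonymous"
            and len(t.carriers) == 1
        }
        from saltmine.consequence import annotate_consequence
        from saltmine.stats import filter_variants

        p1 = filter_variants(study.variants_for("At354", "ref1"))
        p2 = filter_variants(study.variants_for("Bg352", "ref1"))
        poly = parental_difference(p1, p2)
        truth_by_key = {t.key(): t for t in study.truths}
        consequences = {}
        for pv in poly:
            t = truth_by_key[pv.variant.key()]
            consequences[pv.variant.key()] = annotate_consequence(
                genes_by_id[t.gene_id], pv.variant, study.genome1
            )
        stress = [g for g in study.genes1 if g.gene_id in study.stress_gene_ids]
        cands = screen_candidates(stress, poly, consequences, study.hotspots1)
        assert {c.gene_id for c in cands} == expected


class TestConcordance:
    def _candidate(self, gid, variant):
        return CandidateGene(
            gene_id=gid, hotspot_id=1, donor_parent="At354",
            variants=[(PolymorphicVariant(variant, "At354"),
                       _call(gid, variant, "frameshift"))],
        )

    def _anchors(self, gid, offset):
        a = GenomicInterval(gid, "c1", 100, 200)
        b = GenomicInterval(gid, "c1", 100 + offset, 200 + offset)
        return AnchorMap([(gid, a, b)])

    def test_variant_present_in_both_references_confirmed(self):
        v = V(150, "AT", "A")
        cand = self._candidate("g1", v)
        confirmed, dropped = dual_reference_concordance(
            [cand], [V(650, "AT", "A")], self._anchors("g1", 500)
        )
        assert [c.gene_id for c in confirmed] == ["g1"] and not dropped

    def test_ref1_only_variant_dropped_with_reason(self):
        v = V(150, "AT", "A")
        cand = self._candidate("g1", v)
        confirmed, dropped = dual_reference_concordance(
            [cand], [], self._anchors("g1", 500)
        )
        assert not confirmed and dropped[0].gene_id == "g1"
        assert "absent in second reference" in dropped[0].drop_reasons[0]

    def test_gene_missing_from_anchor_map_kept_flagged(self):
        v = V(150, "AT", "A")
        cand = self._candidate("gX", v)
        confirmed, dropped = dual_reference_concordance(
            [cand], [], self._anchors("g1", 0)
        )
        assert confirmed[0].unassessable and not dropped

    def test_partition_and_thirty_four_to_thirty_two(self, demo_screen):
        confirmed, dropped = demo_screen
        assert len(confirmed) + len(dropped) == 34
        assert len(confirmed) == 32
        assert len(dropped) == 2
        assert not {c.gene_id for c in confirmed} & {c.gene_id for c in dropped}


class TestMarkerDesign:
    def _genome(self, n=2000, seed=0):
        rng = np.random.default_rng(seed)
        return SequenceSet({"c1": "".join(rng.choice(list("ACGT"), n))})

    def test_snp_gives_equal_amplicons(self):
        genome = self._genome()
        d = design_indel_marker(genome, V(1000, "A" , "G"), 20)
        assert d.amplicon_length_ref == d.amplicon_length_alt

    def test_twelve_bp_deletion_difference(self):
        genome = self._genome()
        ref = genome.fetch("c1", 1000, 1013)
        d = design_indel_marker(genome, V(1000, ref, ref[:2]), 20)
        assert d.size_difference == -12

    def test_difference_equals_net_length_for_random_indels(self):
        genome = self._genome(5000, seed=3)
        rng = np.random.default_rng(4)
        for _ in range(100):
            pos = int(rng.integers(100, 4800))
            if rng.random() < 0.5:
                k = int(rng.integers(1, 20))
                ref = genome.fetch("c1", pos, pos + k)
                alt = ref[0]
            else:
                ref = genome.fetch("c1", pos, pos)
                alt = ref + "".join(rng.choice(list("ACGT"), int(rng.integers(1, 20))))
            d = design_indel_marker(genome, V(pos, ref, alt), 25)
            assert d.size_difference == len(alt) - len(ref)

    def test_clearance_and_flank_validation(self):
        genome = self._genome()
        with pytest.raises(ValueError):
            design_indel_marker(genome, V(5, "A", "AT"), 20)
        with pytest.raises(ValueError):
            design_indel_marker(genome, V(1000, "A", "AT"), 10)
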