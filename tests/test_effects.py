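"""Consequence classification against transcript models, with
whole-protein translation as the independent oracle."""
from __future__ import annotations

import numpy as np
import pytest
from Bio.Seq import Seq

from tetseq.effects import (
    AnnotationError,
    DictReference,
    MCAP_THRESHOLD,
    classify_consequence,
    classify_most_severe,
    effect_tally,
    impact_flags,
)
from tetseq.models import EffectClass, GeneModel, MutationRecord

_COMP = dict(zip("ACGT", "TGCA"))


def spliced_cds(model: GeneModel, reference) -> str:
    fwd = "".join(reference.seq(model.chrom, s, e) for s, e in model.cds_exons)
    if model.strand == "-":
        fwd = "".join(_COMP[b] for b in reversed(fwd))
    return fwd


def oracle_snv_class(model, reference, pos, alt):
    """Brute force: translate the whole mutated CDS and compare proteins."""
    cds_positions = [p for s, e in model.cds_exons for p in range(s, e + 1)]
    if model.strand == "-":
        cds_positions = cds_positions[::-1]
    idx = cds_positions.index(pos)
    cds = list(spliced_cds(model, reference))
    cds[idx] = alt if model.strand == "+" else _COMP[alt]
    ref_prot = str(Seq(spliced_cds(model, reference)).translate())
    alt_prot = str(Seq("".join(cds)).translate())
    if ref_prot == alt_prot:
        return EffectClass.SILENT
    ci = idx // 3
    if alt_prot[ci] == "*":
        return EffectClass.NONSENSE
    if ref_prot[ci] == "*":
        return EffectClass.NONSTOP
    return EffectClass.MISSENSE


class TestCodingSnvs:
    def test_agrees_with_translation_oracle_plus_strand(self, plus_gene, reference):
        for pos in [p for s, e in plus_gene.cds_exons for p in range(s, e + 1)]:
            ref = reference.seq("chrT", pos, pos)
            for alt in "ACGT":
                if alt == ref:
                    continue
                effect, _ = classify_consequence(
                    "chrT", pos, ref, alt, plus_gene, reference
                )
                assert effect is oracle_snv_class(plus_gene, reference, pos, alt), (
                    pos, ref, alt
                )

    def test_agrees_with_translation_oracle_minus_strand(self, minus_gene, reference):
        for pos in [p for s, e in minus_gene.cds_exons for p in range(s, e + 1)]:
            ref = reference.seq("chrU", pos, pos)
            for alt in "ACGT":
                if alt == ref:
                    continue
                effect, _ = classify_consequence(
                    "chrU", pos, ref, alt, minus_gene, reference
                )
                assert effect is oracle_snv_class(minus_gene, reference, pos, alt), (
                    pos, ref, alt
                )

    def test_recurrent_driver_style_missense_change(self):
        """A Leu->His change at codon 424 is reported as L424H."""
        n_codons = 430
        cds = "ATG" + "CTG" * (n_codons - 2) + "TAA"
        cds = cds[: 423 * 3] + "CTC" + cds[423 * 3 + 3:]
        reference = DictReference({"chr7s": "A" * 50 + cds + "A" * 50})
        model = GeneModel("GTF2I_LIKE", "chr7s", "+",
                          cds_exons=[(51, 50 + len(cds))])
        pos = 51 + 423 * 3 + 1  # middle base of codon 424 (CTC -> CAC)
        effect, change = classify_consequence("chr7s", pos, "T", "A", model,
                                              reference)
        assert effect is EffectClass.MISSENSE
        assert change == "L424H"

    def test_stop_gain_at_codon_37(self):
        """G>T turning Glu37 (GAA) into a stop is E37*."""
        cds = "ATG" + "GGT" * 35 + "GAA" + "GGT" * 20 + "TAA"
        reference = DictReference({"chrL": "T" * 20 + cds + "T" * 20})
        model = GeneModel("MLH1_LIKE", "chrL", "+", cds_exons=[(21, 20 + len(cds))])
        pos = 21 + 36 * 3
        effect, change = classify_consequence("chrL", pos, "G", "T", model,
                                              reference)
        assert effect is EffectClass.NONSENSE
        assert change == "E37*"

    def test_reference_mismatch_names_locus(self, plus_gene, reference):
        pos = plus_gene.cds_exons[0][0]
        ref = reference.seq("chrT", pos, pos)
        wrong = "A" if ref != "A" else "C"
        with pytest.raises(AnnotationError, match=f"chrT:{pos}"):
            classify_consequence("chrT", pos, wrong, ref, plus_gene, reference)


class TestIndelsAndNonCoding:
    @pytest.mark.parametrize(
        "ref_len, alt_len, expected",
        [
            (1, 2, EffectClass.FRAMESHIFT_INSERTION),
            (1, 4, EffectClass.INFRAME_INSERTION),
            (2, 1, EffectClass.FRAMESHIFT_DELETION),
            (4, 1, EffectClass.INFRAME_DELETION),
            (3, 3, EffectClass.NONFRAMESHIFT_SUBSTITUTION),
            (2, 2, EffectClass.NONFRAMESHIFT_SUBSTITUTION),
        ],
    )
    def test_cds_indel_classes_by_length(self, plus_gene, reference,
                                         ref_len, alt_len, expected):
        pos = plus_gene.cds_exons[1][0] + 10
        ref = reference.seq("chrT", pos, pos + ref_len - 1)
        alt = "".join("TG"[(i + 1) % 2] for i in range(alt_len))
        if alt == ref:
            alt = "C" * alt_len
        effect, _ = classify_consequence("chrT", pos, ref, alt, plus_gene,
                                         reference)
        assert effect is expected

    def test_splice_site_inside_window(self, plus_gene, reference):
        exon_end = plus_gene.cds_exons[0][1]
        for offset in (1, 2):
            pos = exon_end + offset
            ref = reference.seq("chrT", pos, pos)
            alt = "A" if ref != "A" else "G"
            effect, _ = classify_consequence("chrT", pos, ref, alt,
                                             plus_gene, reference)
            assert effect is EffectClass.SPLICE_SITE

    def test_deep_intron_beyond_window(self, plus_gene, reference):
        pos = plus_gene.cds_exons[0][1] + 3
        ref = reference.seq("chrT", pos, pos)
        alt = "A" if ref != "A" else "G"
        effect, _ = classify_consequence("chrT", pos, ref, alt, plus_gene,
                                         reference)
        assert effect is EffectClass.INTRON

    def test_utr_flank_intergenic_layers(self, plus_gene, reference):
        def at(pos):
            ref = reference.seq("chrT", pos, pos)
            alt = "A" if ref != "A" else "G"
            return classify_consequence("chrT", pos, ref, alt, plus_gene,
                                        reference)[0]

        assert at(110) is EffectClass.UTR5
        assert at(520) is EffectClass.UTR3
        assert at(90) is EffectClass.FLANK5
        assert at(600) is EffectClass.FLANK3
        assert at(1900) is EffectClass.INTERGENIC

    def test_minus_strand_flank_orientation(self, minus_gene, reference):
        # upstream of a minus-strand gene sits at high coordinates
        def at(pos):
            ref = reference.seq("chrU", pos, pos)
            alt = "A" if ref != "A" else "G"
            return classify_consequence("chrU", pos, ref, alt, minus_gene,
                                        reference)[0]

        assert at(500) is EffectClass.FLANK5
        assert at(120) is EffectClass.FLANK3

    def test_ncrna_model(self, reference):
        model = GeneModel("NC", "chrT", "+", cds_exons=[(700, 800)], ncrna=True)
        ref = reference.seq("chrT", 750, 750)
        alt = "A" if ref != "A" else "G"
        effect, _ = classify_consequence("chrT", 750, ref, alt, model, reference)
        assert effect is EffectClass.NCRNA

    def test_most_severe_wins_across_transcripts(self, plus_gene, reference):
        ncrna = GeneModel("NC", "chrT", "+", cds_exons=[(100, 600)], ncrna=True)
        pos = plus_gene.cds_exons[0][1] + 1  # splice for coding model
        ref = reference.seq("chrT", pos, pos)
        alt = "A" if ref != "A" else "G"
        effect, _, gene = classify_most_severe(
            "chrT", pos, ref, alt, [ncrna, plus_gene], reference
        )
        assert effect is EffectClass.SPLICE_SITE
        assert gene == plus_gene.gene


class TestImpactFlags:
    def _record(self, gene="HRAS", change="A146V"):
        return MutationRecord("s1", "st", gene, "chr11", 534286, "C", "T",
                              EffectClass.MISSENSE, change, "A")

    def test_score_above_threshold_significant(self):
        call = impact_flags(self._record(), {("HRAS", "A146V"): 0.3},
                            {("HRAS", "A146V")})
        assert call.mcap_significant and call.driver_flag

    def test_driver_independent_of_score(self):
        call = impact_flags(self._record("GTF2I", "L424H"),
                            {("GTF2I", "L424H"): 0.01},
                            {("GTF2I", "L424H")})
        assert not call.mcap_significant
        assert call.driver_flag

    def test_exact_threshold_not_significant(self):
        call = impact_flags(self._record(), {("HRAS", "A146V"): MCAP_THRESHOLD},
                            set())
        assert not call.mcap_significant

    def test_missing_score(self):
        call = impact_flags(self._record(), {}, set())
        assert call.mcap_score is None and not call.mcap_significant


class TestEffectTally:
    def test_partition_and_totals(self):
        classes = [EffectClass.MISSENSE] * 2 + [EffectClass.INTRON] * 3 + [
            EffectClass.SILENT, EffectClass.SPLICE_SITE
        ]
        tally = effect_tally(classes)
        assert tally.total == 7
        assert tally.coding_subtotal == 4
        assert sum(tally.counts.values()) == tally.total

    def test_empty(self):
        tally = effect_tally([])
        assert tally.total == 0 and tally.coding_subtotal == 0
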