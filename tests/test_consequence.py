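"""ORF consequence classification, NMD prediction, efficiency estimation."""

import numpy as np
import pandas as pd
import pytest

from splicegain.consequence import (
    OrfConsequence,
    annotate_orf_consequence,
    build_variant_transcript,
    estimate_nmd_efficiency,
    predict_nmd,
    ptc_fraction,
)
from splicegain.core import (
    GenomeSequence,
    GenomicInterval,
    TranscriptModel,
    ValidationError,
    spliced_sequence,
    translate,
)
from splicegain.synth import make_random_gene_with_insertion

from .oracles import orf_consequence_oracle
from .test_core import toy_transcript


class TestBuildVariantTranscript:
    def test_exon_inserted_between_flanks(self, mga):
        var = build_variant_transcript(mga.transcript, mga.novel_exon)
        assert len(var.intervals) == 4
        assert var.intervals[2] == mga.novel_exon
        assert var.spliced_length == mga.transcript.spliced_length + 145

    def test_minus_strand_order_preserved(self):
        t = toy_transcript([(0, 10), (50, 60), (100, 110)], strand="-")
        var = build_variant_transcript(t, GenomicInterval("c", 70, 80, "-"))
        assert [iv.start for iv in var.intervals] == [0, 50, 70, 100]

    def test_overlapping_exon_rejected(self, mga):
        overlapping = GenomicInterval("chrMga", 1835, 1900, "+")
        with pytest.raises(ValidationError):
            build_variant_transcript(mga.transcript, overlapping)

    def test_exon_outside_gene_rejected(self, mga):
        with pytest.raises(ValidationError):
            build_variant_transcript(
                mga.transcript, GenomicInterval("chrMga", 2500, 2550, "+")
            )


class TestAnnotateOrfConsequence:
    def test_mga_fixture_is_a_five_codon_ptc(self, mga):
        var = build_variant_transcript(mga.transcript, mga.novel_exon)
        cons = annotate_orf_consequence(var, mga.transcript, mga.genome, mga.domains)
        assert cons.category == "ptc_in_novel_exon"
        assert cons.added_codons_before_stop == 5
        assert "bHLHZ" in cons.lost_domains
        assert "T-box" not in cons.lost_domains
        assert cons.nmd_sensitive

    def test_frame_preserving_stop_free_exon_adds_residues(self):
        # a 9-nt GCA-repeat exon mid-CDS adds exactly AAA to the protein
        genome = GenomeSequence(
            "c", "ATGAAACCC" + "GT" + "GCAGCAGCA" + "AG" + "TTTTAAGGG"
        )
        t = TranscriptModel(
            "t", "g",
            (GenomicInterval("c", 0, 9), GenomicInterval("c", 22, 31)),
            0, 28,
        )
        var = build_variant_transcript(t, GenomicInterval("c", 11, 20))
        cons = annotate_orf_consequence(var, t, genome)
        assert cons.category == "in_frame_addition"
        assert cons.lost_domains == ()
        prot_canon = translate(spliced_sequence(t, genome))
        prot_var = translate(spliced_sequence(var, genome))
        assert prot_var == prot_canon[:3] + "AAA" + prot_canon[3:]

    def test_invalid_canonical_cds_rejected(self):
        genome = GenomeSequence("c", "CCCAAACCCGGGTTTCCCAAA")
        t = TranscriptModel(
            "t", "g",
            (GenomicInterval("c", 0, 9), GenomicInterval("c", 15, 21)),
            0, 21,
        )
        var = build_variant_transcript(t, GenomicInterval("c", 10, 14))
        with pytest.raises(ValidationError, match="ATG"):
            annotate_orf_consequence(var, t, genome)

    def test_categories_match_brute_force_oracle(self, rng):
        mismatches = []
        for i in range(300):
            g, t, novel, domains = make_random_gene_with_insertion(rng)
            var = build_variant_transcript(t, novel)
            cons = annotate_orf_consequence(var, t, g, domains)
            oracle = orf_consequence_oracle(var, t, g, domains)
            if cons.category != oracle["category"]:
                mismatches.append((i, cons.category, oracle["category"]))
                continue
            if cons.category in ("ptc_in_novel_exon", "frameshift_ptc"):
                assert cons.ptc_transcript_position == oracle["ptc_position"]
                assert cons.distance_ptc_to_last_junction == oracle["distance"]
                assert cons.truncated_protein_length == oracle[
                    "truncated_protein_length"
                ]
                assert cons.lost_domains == oracle["lost_domains"]
                assert cons.nmd_sensitive == oracle["nmd"]
            if cons.category == "ptc_in_novel_exon":
                assert cons.added_codons_before_stop == oracle["added_codons"]
        assert not mismatches

    def test_in_frame_addition_inserts_contiguous_peptide(self, rng):
        checked = 0
        for _ in range(400):
            g, t, novel, domains = make_random_gene_with_insertion(rng)
            var = build_variant_transcript(t, novel)
            cons = annotate_orf_consequence(var, t, g, domains)
            if cons.category != "in_frame_addition":
                continue
            checked += 1
            # compare proteins from the start codon to the first stop
            s0, _ = t.cds_spliced_span()
            prot_c = translate(spliced_sequence(t, g)[s0:])
            prot_c = prot_c[: prot_c.index("*")]
            sv = var.genomic_to_spliced(
                t.cds_start if t.strand == "+" else t.cds_end - 1
            )
            prot_v = translate(spliced_sequence(var, g)[sv:])
            prot_v = prot_v[: prot_v.index("*")]
            extra = len(prot_v) - len(prot_c)
            assert extra == novel.length // 3
            # prefix and suffix of the canonical protein are intact; a
            # mid-codon insertion may substitute the single split-codon
            # residue at the boundary
            n = 0
            while n < len(prot_c) and prot_c[n] == prot_v[n]:
                n += 1
            assert (
                prot_v[n + extra :] == prot_c[n:]
                or prot_v[n + extra + 1 :] == prot_c[n + 1 :]
            )
        assert checked >= 10


class TestPredictNmd:
    def ptc(self, distance):
        return OrfConsequence(
            "ptc_in_novel_exon",
            added_codons_before_stop=1,
            ptc_transcript_position=10,
            distance_ptc_to_last_junction=distance,
        )

    def test_far_upstream_ptc_is_sensitive(self):
        assert predict_nmd(self.ptc(200))

    def test_ptc_in_last_exon_escapes(self):
        assert not predict_nmd(self.ptc(-20))

    def test_boundary_is_strict(self):
        assert not predict_nmd(self.ptc(50))
        assert predict_nmd(self.ptc(51))

    def test_rejects_non_ptc_category(self):
        with pytest.raises(ValidationError):
            predict_nmd(OrfConsequence("in_frame_addition"))


class TestPtcFraction:
    def test_hand_built_half_and_half(self):
        cons = [
            OrfConsequence("ptc_in_novel_exon"),
            OrfConsequence("frameshift_ptc"),
            OrfConsequence("in_frame_addition"),
            OrfConsequence("in_frame_addition"),
        ]
        out = ptc_fraction(cons)
        assert out["ptc_fraction"] == pytest.approx(0.5)
        assert out["in_frame_fraction"] == pytest.approx(0.5)
        assert out["frameshift_fraction"] == pytest.approx(0.25)

    def test_all_in_frame_gives_zero(self):
        out = ptc_fraction([OrfConsequence("in_frame_addition")] * 3)
        assert out["ptc_fraction"] == 0.0

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValidationError):
            ptc_fraction([])


class TestNmdEfficiency:
    @staticmethod
    def table(rows):
        return pd.DataFrame(
            rows, columns=["stage", "replicate", "treated", "abundance"]
        )

    def test_ratio_form(self):
        out = estimate_nmd_efficiency(
            self.table([("ESC", 1, 0, 1.0), ("ESC", 1, 1, 4.0)])
        )
        assert out[0].efficiency == pytest.approx(0.75)
        assert not out[0].flagged_low_nmd

    def test_equal_abundance_is_zero_and_low_flagged(self):
        out = estimate_nmd_efficiency(
            self.table([("SC", 1, 0, 2.0), ("SC", 1, 1, 2.0)])
        )
        assert out[0].efficiency == 0.0
        assert out[0].flagged_low_nmd

    def test_negative_raw_efficiency_clips_to_zero(self):
        out = estimate_nmd_efficiency(
            self.table([("RS", 1, 0, 3.0), ("RS", 1, 1, 2.0)])
        )
        assert out[0].efficiency == 0.0

    def test_nonpositive_abundance_rejected(self):
        with pytest.raises(ValidationError):
            estimate_nmd_efficiency(
                self.table([("x", 1, 0, 0.0), ("x", 1, 1, 1.0)])
            )

    def test_stage_order_preserved(self):
        out = estimate_nmd_efficiency(
            self.table(
                [("b", 1, 0, 1.0), ("b", 1, 1, 2.0), ("a", 1, 0, 1.0), ("a", 1, 1, 2.0)]
            )
        )
        assert [e.stage for e in out] == ["b", "a"]
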