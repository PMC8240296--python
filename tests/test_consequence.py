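"""Spliced CDS extraction, codon-level consequence calls, region classes.

The exhaustive check rebuilds the full mutant protein with Biopython and
diffs it against the reference — an independent route to the same
classification the production code reaches through single-codon lookup.
"""

import pytest
from Bio.Seq import Seq

from txannot._errors import NoCdsError
from txannot.annotation_store import Exon, GenomeSequence, TranscriptModel
from txannot.consequence import (
    TranscriptIndex,
    annotate_consequence,
    classify_region,
    classify_substitution,
    codon_index,
    spliced_cds_sequence,
)
from txannot.coordinate_mapping import cds_to_transcript, transcript_to_genomic
from txannot.variant_parsing import CdsChange, GenomicVariant

from conftest import TX1_CDS, TX2_CDS


def naive_classify(cds: str, cds_pos: int, alt: str) -> tuple[str, str, str]:
    """Full-protein translate-and-diff oracle; returns (function, ref_aa, alt_aa)."""
    alt_cds = cds[: cds_pos - 1] + alt + cds[cds_pos:]
    ref_prot = str(Seq(cds).translate())
    alt_prot = str(Seq(alt_cds).translate())
    codon = (cds_pos + 2) // 3
    ref_aa = ref_prot[codon - 1].replace("*", "X")
    alt_aa = alt_prot[codon - 1].replace("*", "X")
    if ref_prot == alt_prot:
        return "synonymous SNV", ref_aa, alt_aa
    if alt_aa == "X":
        return "stopgain", ref_aa, alt_aa
    if ref_aa == "X":
        return "stoploss", ref_aa, alt_aa
    if codon == 1 and ref_aa == "M" and alt_aa != "M":
        return "startloss", ref_aa, alt_aa
    return "nonsynonymous SNV", ref_aa, alt_aa


class TestSplicedCds:
    def test_plus_strand_planted_cds_recovered(self, tx1, toy_genome):
        assert spliced_cds_sequence(tx1, toy_genome) == TX1_CDS

    def test_minus_strand_reverse_complement(self, tx2, toy_genome):
        assert spliced_cds_sequence(tx2, toy_genome) == TX2_CDS
        assert spliced_cds_sequence(tx2, toy_genome).startswith("ATGAAA")

    def test_noncoding_model_rejected(self, toy_genome):
        m = TranscriptModel("TXnc", "G", "chrT", "+", [Exon("e", 101, 130, 1)])
        with pytest.raises(NoCdsError):
            spliced_cds_sequence(m, toy_genome)


class TestCodonArithmetic:
    @pytest.mark.parametrize(
        "cds_pos,codon,pos_in_codon",
        [(1, 1, 1), (3, 1, 3), (4, 2, 1), (947, 316, 2), (482, 161, 2), (3109, 1037, 1), (4599, 1533, 3)],
    )
    def test_codon_index(self, cds_pos, codon, pos_in_codon):
        assert codon_index(cds_pos) == (codon, pos_in_codon)


class TestClassification:
    def test_caa_to_taa_is_stopgain(self):
        assert classify_substitution("CAA", "TAA", 10) == "stopgain"

    def test_aaa_to_aac_is_missense(self):
        # K -> N, the classic third-position nonsynonymous change
        assert classify_substitution("AAA", "AAC", 1533) == "nonsynonymous SNV"

    def test_stoploss_and_startloss(self):
        assert classify_substitution("TAA", "CAA", 40) == "stoploss"
        assert classify_substitution("ATG", "ATA", 1) == "startloss"

    def test_synonymous(self):
        assert classify_substitution("CTA", "CTG", 7) == "synonymous SNV"


class TestAnnotateConsequence:
    def test_full_annotation_fields(self, tx1, toy_genome):
        # TX1 CDS is ATG repeated; position 5 (codon 2, pos 2) T>A gives ATG->AAG (M->K)
        csq = annotate_consequence(tx1, toy_genome, CdsChange("T", 5, "A"))
        assert (csq.codon_number, csq.pos_in_codon) == (2, 2)
        assert (csq.ref_codon, csq.alt_codon) == ("ATG", "AAG")
        assert (csq.ref_aa, csq.alt_aa) == ("M", "K")
        assert csq.exonic_function == "nonsynonymous SNV"
        assert csq.aachange == "GENEA:TX1:exon1:c.T5A:p.M2K"
        assert not csq.ref_mismatch

    def test_reference_mismatch_flagged_not_dropped(self, tx1, toy_genome):
        csq = annotate_consequence(tx1, toy_genome, CdsChange("C", 5, "A"))
        assert csq.ref_mismatch
        assert csq.exonic_function == "nonsynonymous SNV"  # genome base is used

    def test_minus_strand_genome_alleles_complemented(self, tx2, toy_genome):
        csq = annotate_consequence(tx2, toy_genome, CdsChange("A", 6, "C"))
        assert (csq.g_ref, csq.g_alt) == ("T", "G")

    def test_minus_strand_agrees_with_plus_strand_oracle(self, tx2, toy_genome):
        """Annotating in CDS space equals reading the genome at the mapped locus."""
        for cds_pos in range(1, 91):
            ref = TX2_CDS[cds_pos - 1]
            for alt in "ACGT":
                if alt == ref:
                    continue
                csq = annotate_consequence(tx2, toy_genome, CdsChange(ref, cds_pos, alt))
                loc = transcript_to_genomic(tx2, cds_to_transcript(tx2, cds_pos))
                genome_base = toy_genome.fetch("chrT", loc.g_start, loc.g_start)
                # the genome-strand ref is the complement of the coding-strand ref
                assert csq.g_ref == genome_base
                fn, ref_aa, alt_aa = naive_classify(TX2_CDS, cds_pos, alt)
                assert (csq.exonic_function, csq.ref_aa, csq.alt_aa) == (fn, ref_aa, alt_aa)


class TestExhaustiveEquivalence:
    def test_all_substitutions_of_a_120_codon_cds(self, tx1, toy_genome):
        """All 360 positions x 3 alternates agree with the protein-diff oracle."""
        # extend TX1's CDS to 120 codons on a dedicated single-exon transcript
        import random

        rng = random.Random(7)
        nonstop = [
            a + b + c
            for a in "ACGT"
            for b in "ACGT"
            for c in "ACGT"
            if a + b + c not in ("TAA", "TAG", "TGA")
        ]
        cds = "ATG" + "".join(rng.choice(nonstop) for _ in range(118)) + "TGA"
        model = TranscriptModel(
            "TXBIG", "GENEC", "chrB", "+", [Exon("eb", 1, 360, 1)], 1, 360
        )
        genome = GenomeSequence.from_dict({"chrB": cds})
        checked = 0
        for cds_pos in range(1, 361):
            ref = cds[cds_pos - 1]
            for alt in "ACGT":
                if alt == ref:
                    continue
                csq = annotate_consequence(model, genome, CdsChange(ref, cds_pos, alt), cds_seq=cds)
                fn, ref_aa, alt_aa = naive_classify(cds, cds_pos, alt)
                assert csq.exonic_function == fn, (cds_pos, alt)
                assert (csq.ref_aa, csq.alt_aa) == (ref_aa, alt_aa)
                if fn == "synonymous SNV":
                    # synonymous really means: identical full protein strings
                    alt_cds = cds[: cds_pos - 1] + alt + cds[cds_pos:]
                    assert str(Seq(cds).translate()) == str(Seq(alt_cds).translate())
                checked += 1
        assert checked == 1080


class TestClassifyRegion:
    @pytest.fixture()
    def index(self, tx1, tx2):
        return TranscriptIndex([tx1, tx2])

    @staticmethod
    def var(pos, ref="A", alt="G"):
        return GenomicVariant("chrT", pos, pos, ref, alt)

    def test_cds_base_is_exonic_with_gene(self, index):
        region, genes = classify_region(index, self.var(205))
        assert region == "exonic" and genes == ["GENEA"]

    def test_utr5_and_utr3(self, index):
        assert classify_region(index, self.var(105))[0] == "UTR5"  # tx 5 < cds start 11
        assert classify_region(index, self.var(335))[0] == "UTR3"  # tx 145 > cds end 130

    def test_splicing_within_two_bases_of_exon_end(self, index):
        assert classify_region(index, self.var(152))[0] == "splicing"
        assert classify_region(index, self.var(199))[0] == "splicing"

    def test_deep_intron_is_intronic(self, index):
        assert classify_region(index, self.var(175))[0] == "intronic"

    def test_intergenic_outside_all_transcripts(self, index):
        region, genes = classify_region(index, self.var(780))
        assert region == "intergenic" and genes == []

    def test_minus_strand_utr5_is_genomically_right(self, index):
        # TX2 tx positions 1..10 are UTR5 at genomic 650..641
        assert classify_region(index, self.var(645))[0] == "UTR5"
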