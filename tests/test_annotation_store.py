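"""Transcript-model loading, cross-reference lookup, and ID resolution."""

import io

import pytest

from txannot.annotation_store import (
    load_crossref,
    load_refflat,
    load_transcript_models,
    models_to_gtf,
    resolve_transcript,
    strip_version,
)
from txannot._errors import (
    CrossRefError,
    GtfParseError,
    MissingModelError,
    ModelConsistencyError,
    UnresolvedIdError,
)

TX1_GTF = """\
chrT\tsrc\texon\t101\t150\t.\t+\t.\ttranscript_id "TX1"; gene_name "GENEA"; exon_number "1"; exon_id "E1.1";
chrT\tsrc\texon\t201\t260\t.\t+\t.\ttranscript_id "TX1"; gene_name "GENEA"; exon_number "2"; exon_id "E1.2";
chrT\tsrc\texon\t301\t340\t.\t+\t.\ttranscript_id "TX1"; gene_name "GENEA"; exon_number "3"; exon_id "E1.3";
chrT\tsrc\tCDS\t111\t150\t.\t+\t0\ttranscript_id "TX1"; gene_name "GENEA";
chrT\tsrc\tCDS\t201\t260\t.\t+\t0\ttranscript_id "TX1"; gene_name "GENEA";
chrT\tsrc\tCDS\t301\t320\t.\t+\t0\ttranscript_id "TX1"; gene_name "GENEA";
"""

CROSSREF_TSV = """\
refseq_id\tucsc_id\tensembl_transcript_id\thgnc_symbol\tcanonical_flag
NM_005359\tuc010xdp.2\tENST00000342988\tSMAD4\tTrue
NM_000059\tuc001uub.1\tENST00000544455\tBRCA2\tTrue
NM_000059\tuc001uua.1\tENST00000530893\tBRCA2\tFalse
"""


class TestGtfLoading:
    def test_multi_exon_coding_model(self):
        models = load_transcript_models(io.StringIO(TX1_GTF))
        m = models["TX1"]
        assert len(m.exons) == 3
        assert m.transcript_length == 150
        assert (m.cds_tx_start, m.cds_tx_end) == (11, 130)
        assert m.cds_length == 120
        assert m.coding_complete
        assert [e.rank for e in m.exons] == [1, 2, 3]

    def test_exon_only_transcript_is_noncoding(self):
        gtf = 'chrT\tsrc\texon\t10\t60\t.\t+\t.\ttranscript_id "TXnc"; gene_name "G";\n'
        m = load_transcript_models(io.StringIO(gtf))["TXnc"]
        assert not m.is_coding
        assert m.cds_tx_start is None and m.cds_tx_end is None

    def test_cds_outside_exons_rejected(self):
        bad = TX1_GTF + 'chrT\tsrc\tCDS\t400\t410\t.\t+\t0\ttranscript_id "TX1"; gene_name "GENEA";\n'
        with pytest.raises(ModelConsistencyError, match="TX1"):
            load_transcript_models(io.StringIO(bad))

    def test_malformed_line_reports_line_number(self):
        bad = TX1_GTF.splitlines()
        bad.insert(2, "not a gtf line at all")
        with pytest.raises(GtfParseError) as exc:
            load_transcript_models(io.StringIO("\n".join(bad) + "\n"))
        assert exc.value.line_number == 3

    def test_gtf_roundtrip_is_identity(self, bundle):
        """Serializing loaded models to GTF and re-loading reproduces them."""
        reloaded = load_transcript_models(io.StringIO(models_to_gtf(bundle.models.values())))
        assert set(reloaded) == set(bundle.models)
        for tid, m in bundle.models.items():
            r = reloaded[tid]
            assert r.exons == m.exons
            assert (r.chrom, r.strand, r.gene_symbol) == (m.chrom, m.strand, m.gene_symbol)
            assert (r.cds_tx_start, r.cds_tx_end) == (m.cds_tx_start, m.cds_tx_end)

    def test_bundle_models_satisfy_length_invariants(self, bundle):
        for m in bundle.models.values():
            assert sum(e.width for e in m.exons) == m.transcript_length
            if m.is_coding:
                assert m.cds_tx_end <= m.transcript_length
                assert m.cds_length % 3 == 0


class TestRefFlat:
    def test_refflat_matches_gtf_models(self):
        # same TX1 structure in genePred convention (0-based starts)
        line = (
            "GENEA\tTX1\tchrT\t+\t100\t340\t110\t320\t3\t"
            "100,200,300,\t150,260,340,\n"
        )
        m = load_refflat(io.StringIO(line))["TX1"]
        g = load_transcript_models(io.StringIO(TX1_GTF))["TX1"]
        assert [(e.g_start, e.g_end, e.rank) for e in m.exons] == [
            (e.g_start, e.g_end, e.rank) for e in g.exons
        ]
        assert (m.cds_tx_start, m.cds_tx_end) == (g.cds_tx_start, g.cds_tx_end)

    def test_minus_strand_refflat_exon_order(self):
        line = "G\tTXm\tchrT\t-\t450\t650\t450\t450\t2\t450,600,\t500,650,\n"
        m = load_refflat(io.StringIO(line))["TXm"]
        assert not m.is_coding
        assert [e.g_start for e in m.exons] == [601, 451]  # rank 1 is rightmost


class TestCrossRef:
    def test_lookup_by_each_namespace(self):
        xr = load_crossref(io.StringIO(CROSSREF_TSV))
        assert xr.lookup("NM_005359")["ensembl_transcript_id"].tolist() == ["ENST00000342988"]
        assert xr.lookup("uc010xdp.2")["ensembl_transcript_id"].tolist() == ["ENST00000342988"]
        assert xr.lookup("NM_999999").empty

    def test_versionless_fallback(self):
        xr = load_crossref(io.StringIO(CROSSREF_TSV))
        assert xr.lookup("NM_000059.3")["ensembl_transcript_id"].tolist() == [
            "ENST00000544455",
            "ENST00000530893",
        ]

    def test_conflicting_versioned_duplicates_rejected(self):
        tsv = (
            "refseq_id\tucsc_id\tensembl_transcript_id\thgnc_symbol\n"
            "NM_1.1\tuc1.1\tENST1\tG1\n"
            "NM_1.1\tuc2.1\tENST2\tG2\n"
        )
        with pytest.raises(CrossRefError, match="NM_1.1"):
            load_crossref(io.StringIO(tsv))

    def test_strip_version(self):
        assert strip_version("NM_000059.3") == "NM_000059"
        assert strip_version("uc010xdp.2") == "uc010xdp"
        assert strip_version("ENST00000342988") == "ENST00000342988"


class TestResolve:
    @pytest.fixture()
    def setup(self, tx1, tx2):
        models = {"ENST00000342988": tx1, "ENST00000544455": tx2}
        xr = load_crossref(io.StringIO(CROSSREF_TSV))
        return models, xr

    def test_refseq_resolves_via_crossref(self, setup):
        models, xr = setup
        assert resolve_transcript("NM_005359", xr, models).transcript_id == "TX1"

    def test_ensembl_id_bypasses_crossref(self, setup):
        models, _ = setup
        assert resolve_transcript("ENST00000342988", None, models).transcript_id == "TX1"

    def test_versioned_query_matches_versionless_row(self, setup):
        models, xr = setup
        a = resolve_transcript("NM_000059.3", xr, models)
        b = resolve_transcript("NM_000059", xr, models)
        assert a.transcript_id == b.transcript_id

    def test_one_to_many_prefers_canonical_then_lexicographic(self, setup):
        models, xr = setup
        # NM_000059 maps to ENST00000544455 (canonical) and ENST00000530893
        m = resolve_transcript("NM_000059", xr, models)
        assert m.transcript_id == "TX2"  # the canonical row's model
        # determinism: repeated calls agree
        assert resolve_transcript("NM_000059", xr, models) is m

    def test_unknown_id_raises(self, setup):
        models, xr = setup
        with pytest.raises(UnresolvedIdError):
            resolve_transcript("NM_999999", xr, models)

    def test_crossref_row_without_model_raises(self, tx1):
        xr = load_crossref(io.StringIO(CROSSREF_TSV))
        with pytest.raises(MissingModelError):
            resolve_transcript("NM_000059", xr, {"other": tx1})

    def test_resolution_on_generated_bundle_is_deterministic(self, bundle):
        # the generated crossref contains one RefSeq shared by two transcripts
        shared = bundle.crossref.table["refseq_id"].value_counts().idxmax()
        first = resolve_transcript(shared, bundle.crossref, bundle.models)
        assert all(
            resolve_transcript(shared, bundle.crossref, bundle.models) is first
            for _ in range(3)
        )
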