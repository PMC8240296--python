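"""Shared fixtures: hand-built two-transcript toy models and a seeded
100-transcript synthetic bundle (generated once per session)."""

from __future__ import annotations

import pytest
from Bio.Seq import reverse_complement

from txannot.annotation_store import Exon, GenomeSequence, TranscriptModel
from txannot.fixtures import FixtureSpec, generate_bundle
from txannot.pipeline import Bundle

# TX1: plus strand, 3 exons 101-150 / 201-260 / 301-340 (tx length 150),
# CDS at transcript 11..130 (40 codons).  The CDS is planted as ATG x 40.
TX1_CDS = "ATG" * 40
TX1_UTR5 = "GCGCGCGCGC"  # tx 1..10
TX1_UTR3 = "TTTTGGGGCCCCAAAATTTT"  # tx 131..150
TX1_SEQ = TX1_UTR5 + TX1_CDS + TX1_UTR3

# TX2: minus strand, exons in transcript order are genomic 601-650 then
# 451-500 (tx length 100), CDS at transcript 11..100 (30 codons).
TX2_CDS = "ATG" + "AAA" * 28 + "TAA"
TX2_UTR5 = "CACACACACA"
TX2_SEQ = TX2_UTR5 + TX2_CDS


def _place(chrom: list[str], exons: list[Exon], strand: str, tx_seq: str) -> None:
    """Write a transcript's spliced sequence into a mutable chromosome."""
    acc = 0
    for ex in exons:
        chunk = tx_seq[acc : acc + ex.width]
        if strand == "-":
            chunk = reverse_complement(chunk)
        chrom[ex.g_start - 1 : ex.g_end] = list(chunk)
        acc += ex.width


def make_tx1() -> TranscriptModel:
    return TranscriptModel(
        transcript_id="TX1",
        gene_symbol="GENEA",
        chrom="chrT",
        strand="+",
        exons=[
            Exon("E1.1", 101, 150, 1),
            Exon("E1.2", 201, 260, 2),
            Exon("E1.3", 301, 340, 3),
        ],
        cds_tx_start=11,
        cds_tx_end=130,
    )


def make_tx2() -> TranscriptModel:
    return TranscriptModel(
        transcript_id="TX2",
        gene_symbol="GENEB",
        chrom="chrT",
        strand="-",
        exons=[Exon("E2.1", 601, 650, 1), Exon("E2.2", 451, 500, 2)],
        cds_tx_start=11,
        cds_tx_end=100,
    )


@pytest.fixture(scope="session")
def tx1() -> TranscriptModel:
    return make_tx1()


@pytest.fixture(scope="session")
def tx2() -> TranscriptModel:
    return make_tx2()


@pytest.fixture(scope="session")
def toy_genome(tx1, tx2) -> GenomeSequence:
    chrom = list("ACGT" * 200)  # 800 bp backdrop
    _place(chrom, tx1.exons, "+", TX1_SEQ)
    _place(chrom, tx2.exons, "-", TX2_SEQ)
    return GenomeSequence.from_dict({"chrT": "".join(chrom)})


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory):
    d = tmp_path_factory.mktemp("bundle") / "seed42"
    generate_bundle(FixtureSpec(seed=42), d)
    return d


@pytest.fixture(scope="session")
def bundle(bundle_dir) -> Bundle:
    return Bundle.load(bundle_dir)


@pytest.fixture(scope="session")
def small_bundle_dir(tmp_path_factory):
    d = tmp_path_factory.mktemp("bundle_small") / "seed7"
    generate_bundle(FixtureSpec(seed=7, n_transcripts=12, n_panel_variants=10), d)
    return d


@pytest.fixture(scope="session")
def small_bundle(small_bundle_dir) -> Bundle:
    return Bundle.load(small_bundle_dir)
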