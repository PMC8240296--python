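"""Coding-consequence calling and genomic region classification.

The spliced CDS is rebuilt from the genome and the transcript model, a
single-base substitution is applied in CDS coordinates, and the affected
codon is translated under the standard genetic code (stop written as X,
matching the p.Q1037X style of clinical annotation output).

Region classes follow the ANNOVAR knownGene convention: exonic (inside a
CDS base), UTR5/UTR3 (exonic but outside the CDS), splicing (intronic
within 2 bp of an exon boundary), intronic, intergenic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import reverse_complement
from intervaltree import IntervalTree

from ._errors import NoCdsError, OutOfCdsError
from .annotation_store import GenomeSequence, TranscriptModel, cds_genomic_intervals
from .coordinate_mapping import cds_to_transcript, transcript_to_genomic
from .variant_parsing import CdsChange, GenomicVariant

# distance from an exon boundary (in bp, intron side) treated as splice-relevant
SPLICE_WINDOW = 2

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# standard genetic code with stop codons mapped to 'X'
CODON_TO_AA: dict[str, str] = dict(standard_dna_table.forward_table)
CODON_TO_AA.update({codon: "X" for codon in standard_dna_table.stop_codons})


def complement_base(base: str) -> str:
    return base.translate(_COMPLEMENT)


@dataclass(frozen=True)
class Consequence:
    """The codon-level effect of one CDS substitution on one transcript."""

    codon_number: int
    pos_in_codon: int  # 1, 2 or 3
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str
    exonic_function: str
    aachange: str
    exon_rank: int
    g_pos: int
    g_ref: str  # genome (plus) strand alleles; complemented on minus-strand models
    g_alt: str
    ref_mismatch: bool = False  # genome base at the site differed from the declared ref


def spliced_cds_sequence(model: TranscriptModel, genome: GenomeSequence) -> str:
    """The transcript's CDS as spelled on the coding strand.

    Exonic genome sequence is concatenated in transcript order (each exon
    reverse-complemented on the minus strand) and sliced to the CDS span.
    """
    if not model.is_coding:
        raise NoCdsError(f"{model.transcript_id} is non-coding; no CDS sequence")
    parts = []
    for ex in model.exons:
        s = genome.fetch(model.chrom, ex.g_start, ex.g_end)
        parts.append(reverse_complement(s) if model.strand == "-" else s)
    tx_seq = "".join(parts)
    return tx_seq[model.cds_tx_start - 1 : model.cds_tx_end]


def codon_index(cds_pos: int) -> tuple[int, int]:
    """(codon_number, pos_in_codon) for a 1-based CDS position."""
    return (cds_pos + 2) // 3, (cds_pos - 1) % 3 + 1


def classify_substitution(ref_codon: str, alt_codon: str, codon_number: int) -> str:
    ref_aa = CODON_TO_AA.get(ref_codon, "?")
    alt_aa = CODON_TO_AA.get(alt_codon, "?")
    if "?" in (ref_aa, alt_aa):
        return "unknown"
    if ref_aa == alt_aa:
        return "synonymous SNV"
    if alt_aa == "X":
        return "stopgain"
    if ref_aa == "X":
        return "stoploss"
    if codon_number == 1 and ref_codon == "ATG":
        return "startloss"
    return "nonsynonymous SNV"


def annotate_consequence(
    model: TranscriptModel,
    genome: GenomeSequence,
    change: CdsChange,
    cds_seq: str | None = None,
) -> Consequence:
    """Annotate one CDS substitution on one coding transcript.

    The change's alleles are read in coding-strand orientation.  When the
    genome base at the site differs from the declared reference, the result
    is flagged (``ref_mismatch``) rather than rejected, and the genome base
    is used as the reference codon content.  ``cds_seq`` may be passed to
    avoid re-splicing the CDS in tight loops.
    """
    if not model.is_coding:
        raise NoCdsError(f"{model.transcript_id} is non-coding")
    if not 1 <= change.cds_pos <= model.cds_length:
        raise OutOfCdsError(
            f"{model.transcript_id}: CDS position {change.cds_pos} outside "
            f"1..{model.cds_length}"
        )
    cds = cds_seq if cds_seq is not None else spliced_cds_sequence(model, genome)
    codon_number, pos_in_codon = codon_index(change.cds_pos)
    ref_mismatch = cds[change.cds_pos - 1] != change.ref

    start = 3 * (codon_number - 1)
    ref_codon = cds[start : start + 3]
    if len(ref_codon) < 3:  # coding-incomplete model truncated mid-codon
        ref_codon = ref_codon.ljust(3, "N")
    alt_codon = ref_codon[: pos_in_codon - 1] + change.alt + ref_codon[pos_in_codon:]
    ref_aa = CODON_TO_AA.get(ref_codon, "?")
    alt_aa = CODON_TO_AA.get(alt_codon, "?")
    function = classify_substitution(ref_codon, alt_codon, codon_number)

    locus = transcript_to_genomic(model, cds_to_transcript(model, change.cds_pos))
    if model.strand == "-":
        g_ref, g_alt = complement_base(change.ref), complement_base(change.alt)
    else:
        g_ref, g_alt = change.ref, change.alt
    aachange = (
        f"{model.gene_symbol}:{model.transcript_id}:exon{locus.exon_rank}:"
        f"c.{change.ref}{change.cds_pos}{change.alt}:p.{ref_aa}{codon_number}{alt_aa}"
    )
    return Consequence(
        codon_number=codon_number,
        pos_in_codon=pos_in_codon,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        exonic_function=function,
        aachange=aachange,
        exon_rank=locus.exon_rank,
        g_pos=locus.g_start,
        g_ref=g_ref,
        g_alt=g_alt,
        ref_mismatch=ref_mismatch,
    )


# ---------------------------------------------------------------------------
# Region classification over a model set


_REGION_PRIORITY = ["exonic", "UTR5", "UTR3", "splicing", "intronic", "intergenic"]


class TranscriptIndex:
    """Interval index of transcript spans per chromosome, for overlap queries."""

    def __init__(self, models: Iterable[TranscriptModel]):
        self._trees: dict[str, IntervalTree] = {}
        for m in models:
            lo, hi = m.g_span
            # IntervalTree is half-open; store [lo, hi] as [lo, hi+1)
            self._trees.setdefault(m.chrom, IntervalTree()).addi(lo, hi + 1, m)

    def overlapping(self, chrom: str, g_pos: int) -> list[TranscriptModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = sorted(tree.at(g_pos), key=lambda iv: iv.data.transcript_id)
        return [iv.data for iv in hits]


def _classify_one(model: TranscriptModel, g_pos: int) -> str:
    """Region class of a position known to lie within this model's span."""
    for ex in model.exons:
        if ex.g_start <= g_pos <= ex.g_end:
            if not model.is_coding:
                return "exonic"
            for cs, ce in cds_genomic_intervals(model):
                if cs <= g_pos <= ce:
                    return "exonic"
            # exonic but outside CDS: 5' or 3' UTR by transcript coordinate
            from .coordinate_mapping import genomic_to_transcript

            tx = genomic_to_transcript(model, model.chrom, g_pos)
            return "UTR5" if tx < model.cds_tx_start else "UTR3"
    # intronic; splice-adjacent if within SPLICE_WINDOW of any exon edge
    for ex in model.exons:
        if 0 < ex.g_start - g_pos <= SPLICE_WINDOW or 0 < g_pos - ex.g_end <= SPLICE_WINDOW:
            return "splicing"
    return "intronic"


def classify_region(
    index: TranscriptIndex | Iterable[TranscriptModel],
    variant: GenomicVariant,
) -> tuple[str, list[str]]:
    """(region class, overlapping gene symbols) for a genomic variant.

    With several overlapping transcripts the highest-priority class wins
    (exonic > UTR5 > UTR3 > splicing > intronic).  Always classifiable:
    positions in no transcript are intergenic with an empty gene list.
    """
    if not isinstance(index, TranscriptIndex):
        index = TranscriptIndex(index)
    models = index.overlapping(variant.chrom, variant.g_start)
    if not models:
        return "intergenic", []
    genes: list[str] = []
    best = "intergenic"
    for m in models:
        if m.gene_symbol and m.gene_symbol not in genes:
            genes.append(m.gene_symbol)
        cls = _classify_one(m, variant.g_start)
        if _REGION_PRIORITY.index(cls) < _REGION_PRIORITY.index(best):
            best = cls
    return best, genes
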