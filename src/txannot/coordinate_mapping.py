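"""Projection between CDS, transcript, and genomic coordinate systems.

All three systems are 1-based.  Transcript coordinates run 5'->3' along
the spliced mRNA (UTRs included); CDS coordinates start at the A of the
start codon, so ``tx = cds + len(5'UTR)``.  On the minus strand transcript
base 1 is the genomically *rightmost* base of exon 1.

The fast path (:func:`transcript_to_genomic`) uses binary search over
cumulative exon widths; :func:`per_base_map` is the deliberately naive
linear construction kept as an in-package oracle.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass

from ._errors import NoCdsError, NotExonicError, OutOfCdsError, OutOfTranscriptError
from .annotation_store import TranscriptModel


@dataclass(frozen=True)
class GenomicLocus:
    """A genomic window with its transcript context (SNV: width 1, tx_start == tx_end)."""

    chrom: str
    g_start: int
    g_end: int
    strand: str
    exon_id: str
    exon_rank: int
    tx_start: int
    tx_end: int

    @property
    def width(self) -> int:
        return self.g_end - self.g_start + 1


def cds_to_transcript(model: TranscriptModel, cds_pos: int) -> int:
    """Transcript coordinate of CDS base ``cds_pos``: cds_tx_start + cds_pos - 1."""
    if not model.is_coding:
        raise NoCdsError(f"{model.transcript_id} is non-coding; CDS coordinates undefined")
    if not 1 <= cds_pos <= model.cds_length:
        raise OutOfCdsError(
            f"{model.transcript_id}: CDS position {cds_pos} outside 1..{model.cds_length}"
        )
    return model.cds_tx_start + cds_pos - 1


def transcript_to_genomic(model: TranscriptModel, tx_pos: int) -> GenomicLocus:
    """Genomic position of transcript base ``tx_pos``, with exon context."""
    if not 1 <= tx_pos <= model.transcript_length:
        raise OutOfTranscriptError(
            f"{model.transcript_id}: transcript position {tx_pos} outside "
            f"1..{model.transcript_length}"
        )
    # find the exon whose cumulative span contains tx_pos
    idx = bisect_left(model._cum, tx_pos) - 1
    exon = model.exons[idx]
    lo, _ = model.exon_tx_range(idx)
    offset = tx_pos - lo
    g = exon.g_start + offset if model.strand == "+" else exon.g_end - offset
    return GenomicLocus(
        chrom=model.chrom,
        g_start=g,
        g_end=g,
        strand=model.strand,
        exon_id=exon.exon_id,
        exon_rank=exon.rank,
        tx_start=tx_pos,
        tx_end=tx_pos,
    )


def genomic_to_transcript(model: TranscriptModel, chrom: str, g_pos: int) -> int:
    """Inverse of :func:`transcript_to_genomic` for exonic bases.

    Raises :class:`NotExonicError` for intronic or out-of-span positions,
    reporting the distance to the nearest exon boundary.
    """
    if chrom != model.chrom:
        raise NotExonicError(
            f"{model.transcript_id} is on {model.chrom}, not {chrom}"
        )
    nearest = None
    for idx, ex in enumerate(model.exons):
        if ex.g_start <= g_pos <= ex.g_end:
            lo, _ = model.exon_tx_range(idx)
            offset = g_pos - ex.g_start if model.strand == "+" else ex.g_end - g_pos
            return lo + offset
        d = min(abs(g_pos - ex.g_start), abs(g_pos - ex.g_end))
        nearest = d if nearest is None else min(nearest, d)
    raise NotExonicError(
        f"{model.transcript_id}: {chrom}:{g_pos} is not exonic "
        f"(nearest exon boundary {nearest} bp away)"
    )


def per_base_map(model: TranscriptModel) -> list[int]:
    """Genomic position of every transcript base, by naive concatenation.

    Element ``i`` (0-based here) is the genomic coordinate of transcript
    base ``i + 1``.  Exon base runs are reversed per-exon on the minus
    strand.  Linear-time; serves as the brute-force oracle for the binary
    search mapping.
    """
    out: list[int] = []
    for ex in model.exons:
        run = list(range(ex.g_start, ex.g_end + 1))
        if model.strand == "-":
            run.reverse()
        out.extend(run)
    return out
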