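"""Parsers for nucleotide-change tokens and the two user input tables.

Two token dialects are accepted for a single-nucleotide CDS change:
compact ``A947G`` (ref, position, alt) and HGVS-like ``c.947A>G``.  The
canonical formatted form is the compact one without a ``c.`` prefix.

Variant tables come as CSV (columns Chr,Start,End,Ref,Alt) or 5-column
BED.  BED handling needs an explicit dialect because SNV rows printed with
Start == End are 1-based inclusive, not standard 0-based half-open BED:
``table1`` (default) passes coordinates through, ``standard0`` shifts
Start by +1.  Outputs are always normalized to 1-based inclusive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import IO, Iterable, Mapping

import pandas as pd

from ._errors import (
    ChangeParseError,
    CoordinateError,
    DegenerateChangeError,
    TableSchemaError,
)

_BASES = set("ACGT")
_COMPACT_RE = re.compile(r"^(?:c\.)?([ACGT])([0-9]+)([ACGT])$")
_HGVS_RE = re.compile(r"^(?:c\.)?([0-9]+)([ACGT])>([ACGT])$")


@dataclass(frozen=True)
class CdsChange:
    """A single-nucleotide substitution in CDS coordinates (coding strand)."""

    ref: str
    cds_pos: int
    alt: str

    def __post_init__(self):
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ChangeParseError(f"alleles must be A/C/G/T: {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise DegenerateChangeError(f"ref equals alt in {self.ref}{self.cds_pos}{self.alt}")
        if self.cds_pos < 1:
            raise ChangeParseError(f"CDS position must be >= 1, got {self.cds_pos}")

    def format(self) -> str:
        """Canonical compact token, e.g. ``A947G``."""
        return f"{self.ref}{self.cds_pos}{self.alt}"


@dataclass(frozen=True)
class GenomicVariant:
    """A genomic substitution, 1-based inclusive, genome (plus) strand alleles."""

    chrom: str
    g_start: int
    g_end: int
    ref: str
    alt: str

    def __post_init__(self):
        if self.g_start > self.g_end:
            raise CoordinateError(
                f"{self.chrom}: Start {self.g_start} > End {self.g_end}"
            )
        if self.ref not in _BASES or self.alt not in _BASES:
            raise CoordinateError(
                f"{self.chrom}:{self.g_start}: non-ACGT allele {self.ref}>{self.alt}"
            )
        if self.ref == self.alt:
            raise CoordinateError(
                f"{self.chrom}:{self.g_start}: ref equals alt ({self.ref})"
            )


def parse_change(token: str) -> CdsChange:
    """Parse one nucleotide-change token in either dialect.

    >>> parse_change("A947G")
    CdsChange(ref='A', cds_pos=947, alt='G')
    >>> parse_change("c.3109C>T").format()
    'C3109T'
    """
    t = token.strip()
    m = _COMPACT_RE.match(t)
    if m:
        return CdsChange(ref=m.group(1), cds_pos=int(m.group(2)), alt=m.group(3))
    m = _HGVS_RE.match(t)
    if m:
        return CdsChange(ref=m.group(2), cds_pos=int(m.group(1)), alt=m.group(3))
    raise ChangeParseError(f"unrecognized nucleotide-change token: {token!r}")


@dataclass
class TranscriptChangeRow:
    """One row of the transcript-change table, parsed or carrying its error."""

    row_number: int  # 1-based data-row index
    transcript_id: str
    token: str
    change: CdsChange | None
    error: str | None = None


def read_transcript_table(stream: IO | str) -> list[TranscriptChangeRow]:
    """Read the two-column transcript CSV (Transcript_version, Nucleotide_changes).

    Rows are preserved in input order.  A bad token fails only its own row:
    the row is returned with ``change=None`` and ``error`` set, so callers
    can report diagnostics without aborting the batch.
    """
    df = pd.read_csv(stream, dtype=str)
    required = ["Transcript_version", "Nucleotide_changes"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableSchemaError(
            f"transcript table missing column(s) {missing}; expected header "
            f"{','.join(required)}"
        )
    rows: list[TranscriptChangeRow] = []
    for i, rec in enumerate(df.itertuples(index=False), start=1):
        tx = str(getattr(rec, "Transcript_version")).strip()
        token = str(getattr(rec, "Nucleotide_changes")).strip()
        try:
            rows.append(TranscriptChangeRow(i, tx, token, parse_change(token)))
        except ChangeParseError as exc:
            rows.append(TranscriptChangeRow(i, tx, token, None, error=str(exc)))
    return rows


def read_variant_table(
    stream: IO | str,
    format: str = "csv",
    bed_dialect: str = "table1",
    chrom_aliases: Mapping[str, str] | None = None,
) -> list[GenomicVariant]:
    """Read a genomic variant table as CSV (with header) or 5-column BED.

    ``bed_dialect='standard0'`` treats Start as 0-based (BED proper) and
    shifts it by +1; ``'table1'`` takes Start/End as already 1-based
    inclusive with Start == End for SNVs.  Chromosome names pass through
    verbatim unless ``chrom_aliases`` maps them.
    """
    if format == "csv":
        df = pd.read_csv(stream, dtype=str)
        required = ["Chr", "Start", "End", "Ref", "Alt"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise TableSchemaError(
                f"variant table missing column(s) {missing}; expected header "
                f"{','.join(required)}"
            )
        records = df[required].itertuples(index=False)
        shift = 0
    elif format == "bed":
        df = pd.read_csv(stream, sep="\t", header=None, dtype=str)
        if df.shape[1] < 5:
            raise TableSchemaError("BED variant table requires >= 5 columns")
        df = df.iloc[:, :5]
        df.columns = ["Chr", "Start", "End", "Ref", "Alt"]
        records = df.itertuples(index=False)
        if bed_dialect == "standard0":
            shift = 1
        elif bed_dialect == "table1":
            shift = 0
        else:
            raise ValueError(f"unknown bed_dialect {bed_dialect!r}")
    else:
        raise ValueError(f"unknown variant table format {format!r}")

    aliases = chrom_aliases or {}
    out: list[GenomicVariant] = []
    for rec in records:
        chrom = str(rec.Chr).strip()
        chrom = aliases.get(chrom, chrom)
        start = _parse_coord(rec.Start) + shift
        end = _parse_coord(rec.End)
        out.append(
            GenomicVariant(
                chrom=chrom,
                g_start=start,
                g_end=end,
                ref=str(rec.Ref).strip().upper(),
                alt=str(rec.Alt).strip().upper(),
            )
        )
    return out


def _parse_coord(value) -> int:
    """Coordinates may be printed with thousands separators (``48,586,278``)."""
    s = str(value).strip().replace(",", "")
    try:
        return int(s)
    except ValueError as exc:
        raise CoordinateError(f"non-integer coordinate {value!r}") from exc


def variants_to_frame(variants: Iterable[GenomicVariant]) -> pd.DataFrame:
    """Tabulate variants with the canonical Chr,Start,End,Ref,Alt header."""
    return pd.DataFrame(
        [(v.chrom, v.g_start, v.g_end, v.ref, v.alt) for v in variants],
        columns=["Chr", "Start", "End", "Ref", "Alt"],
    )
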