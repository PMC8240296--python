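"""Transcript models, genome sequence, and ID cross-references.

The annotation bundle replaces online lookups with local files: a GTF (or
refFlat) of transcript models, a genome FASTA, and a TSV cross-referencing
RefSeq / UCSC / Ensembl accessions to gene symbols.  Everything here is
loaded eagerly into plain in-memory structures; bundles are small enough
(one species' transcriptome) that no lazy indexing is needed.

Coordinate conventions: genomic positions are 1-based inclusive (GTF
convention); transcript and CDS coordinates are 1-based from the spliced
transcript's 5' end.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

import pandas as pd
from gffutils.feature import feature_from_line
from pyfaidx import Fasta

from ._errors import (
    CrossRefError,
    GtfParseError,
    MissingModelError,
    ModelConsistencyError,
    UnresolvedIdError,
)

logger = logging.getLogger("txannot")

_VERSION_RE = re.compile(r"\.\d+$")


def strip_version(accession: str) -> str:
    """Drop a trailing ``.N`` version suffix: ``NM_000059.3`` -> ``NM_000059``."""
    return _VERSION_RE.sub("", accession)


@dataclass(frozen=True)
class Exon:
    """One exon in genomic coordinates, with its 1-based transcript-order rank."""

    exon_id: str
    g_start: int  # 1-based inclusive
    g_end: int  # 1-based inclusive
    rank: int

    def __post_init__(self):
        if self.g_start > self.g_end:
            raise ModelConsistencyError(
                f"exon {self.exon_id}: g_start {self.g_start} > g_end {self.g_end}"
            )

    @property
    def width(self) -> int:
        return self.g_end - self.g_start + 1


@dataclass
class TranscriptModel:
    """A transcript's exon structure, strand, and CDS span.

    ``exons`` are in transcript (5'->3') order: ascending genomic start on
    the plus strand, descending on the minus strand.  ``cds_tx_start`` /
    ``cds_tx_end`` are 1-based transcript coordinates of the first and last
    CDS base, or ``None`` for non-coding transcripts.
    """

    transcript_id: str
    gene_symbol: str
    chrom: str
    strand: str
    exons: list[Exon]
    cds_tx_start: int | None = None
    cds_tx_end: int | None = None
    # cumulative exon widths; entry i = total width of exons[:i]
    _cum: list[int] = field(default_factory=list, repr=False)

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ModelConsistencyError(
                f"{self.transcript_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        self._validate_exons()
        cum = [0]
        for ex in self.exons:
            cum.append(cum[-1] + ex.width)
        self._cum = cum
        if self.is_coding:
            if not (1 <= self.cds_tx_start <= self.cds_tx_end <= self.transcript_length):
                raise ModelConsistencyError(
                    f"{self.transcript_id}: CDS span [{self.cds_tx_start}, "
                    f"{self.cds_tx_end}] outside transcript of length "
                    f"{self.transcript_length}"
                )

    def _validate_exons(self):
        if not self.exons:
            raise ModelConsistencyError(f"{self.transcript_id}: no exons")
        ivs = sorted((e.g_start, e.g_end) for e in self.exons)
        for (s1, e1), (s2, _) in zip(ivs, ivs[1:]):
            if s2 <= e1:
                raise ModelConsistencyError(
                    f"{self.transcript_id}: exons overlap on the genome near {s2}"
                )
        key = [e.g_start for e in self.exons]
        expect = sorted(key, reverse=self.strand == "-")
        if key != expect:
            raise ModelConsistencyError(
                f"{self.transcript_id}: exons not in transcript order for strand "
                f"{self.strand}"
            )
        if [e.rank for e in self.exons] != list(range(1, len(self.exons) + 1)):
            raise ModelConsistencyError(
                f"{self.transcript_id}: exon ranks must be 1..n in transcript order"
            )

    @property
    def transcript_length(self) -> int:
        return self._cum[-1]

    @property
    def is_coding(self) -> bool:
        return self.cds_tx_start is not None

    @property
    def cds_length(self) -> int | None:
        if not self.is_coding:
            return None
        return self.cds_tx_end - self.cds_tx_start + 1

    @property
    def coding_complete(self) -> bool:
        """True when the CDS length is a whole number of codons."""
        return self.is_coding and self.cds_length % 3 == 0

    def exon_tx_range(self, idx: int) -> tuple[int, int]:
        """Transcript-coordinate span [lo, hi] covered by ``exons[idx]``."""
        return self._cum[idx] + 1, self._cum[idx + 1]

    @property
    def g_span(self) -> tuple[int, int]:
        """Genomic [min, max] span of the transcript."""
        return (
            min(e.g_start for e in self.exons),
            max(e.g_end for e in self.exons),
        )


class GenomeSequence:
    """Uppercase nucleotide sequence per chromosome, 1-based inclusive fetch.

    Backed either by a pyfaidx ``Fasta`` (for bundles on disk) or by a plain
    dict of strings (for in-memory tests).
    """

    def __init__(self, backend: Mapping[str, str] | Fasta):
        self._backend = backend

    @classmethod
    def from_fasta(cls, path: str) -> "GenomeSequence":
        return cls(Fasta(str(path), as_raw=False, sequence_always_upper=True))

    @classmethod
    def from_dict(cls, seqs: Mapping[str, str]) -> "GenomeSequence":
        return cls({k: v.upper() for k, v in seqs.items()})

    def __contains__(self, chrom: str) -> bool:
        if isinstance(self._backend, Fasta):
            return chrom in self._backend.keys()
        return chrom in self._backend

    def chrom_length(self, chrom: str) -> int:
        return len(self._backend[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of ``chrom`` over the 1-based inclusive window [start, end]."""
        if start < 1 or end > self.chrom_length(chrom) or start > end:
            raise ValueError(
                f"fetch window {chrom}:{start}-{end} outside sequence bounds"
            )
        if isinstance(self._backend, Fasta):
            return str(self._backend[chrom][start - 1 : end]).upper()
        return self._backend[chrom][start - 1 : end]


# ---------------------------------------------------------------------------
# GTF reading / writing


def _open_lines(stream: IO[str] | str | Iterable[str]) -> Iterable[str]:
    if isinstance(stream, str):
        with open(stream) as fh:
            yield from fh
    else:
        yield from stream


def load_transcript_models(gtf_stream) -> dict[str, TranscriptModel]:
    """Parse a GTF2.2 stream into :class:`TranscriptModel` objects.

    Exon features define the transcript structure (ordered by their
    ``exon_number`` attribute when present, genomic order per strand
    otherwise); CDS features define the coding span in transcript
    coordinates.  Transcripts without CDS features are kept as non-coding.

    Raises
    ------
    GtfParseError
        on a malformed line, naming its 1-based line number.
    ModelConsistencyError
        when a CDS segment does not fall inside any exon of its transcript.
    """
    exon_feats: dict[str, list] = {}
    cds_feats: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tx -> (chrom, strand, gene)

    for lineno, raw in enumerate(_open_lines(gtf_stream), start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        try:
            feat = feature_from_line(line, dialect=None)
        except Exception as exc:  # gffutils raises bare exceptions on bad input
            raise GtfParseError(lineno, str(exc)) from exc
        if len(line.split("\t")) < 8:
            raise GtfParseError(lineno, "fewer than 8 tab-separated fields")
        if feat.featuretype not in ("exon", "CDS"):
            continue
        try:
            tx = feat.attributes["transcript_id"][0]
        except KeyError as exc:
            raise GtfParseError(lineno, "missing transcript_id attribute") from exc
        gene = (feat.attributes.get("gene_name") or [""])[0]
        prev = meta.get(tx)
        if prev is None:
            meta[tx] = (feat.seqid, feat.strand, gene)
        elif prev[0] != feat.seqid or prev[1] != feat.strand:
            raise ModelConsistencyError(
                f"{tx}: features on inconsistent chrom/strand (line {lineno})"
            )
        if feat.featuretype == "exon":
            num = feat.attributes.get("exon_number")
            exon_id = (feat.attributes.get("exon_id") or [""])[0]
            exon_feats.setdefault(tx, []).append(
                (int(num[0]) if num else None, exon_id, feat.start, feat.end)
            )
        else:
            cds_feats.setdefault(tx, []).append((feat.start, feat.end))

    models: dict[str, TranscriptModel] = {}
    for tx, (chrom, strand, gene) in meta.items():
        feats = exon_feats.get(tx)
        if not feats:
            raise ModelConsistencyError(f"{tx}: CDS features but no exon features")
        if all(f[0] is not None for f in feats):
            feats.sort(key=lambda f: f[0])
        else:
            feats.sort(key=lambda f: f[2], reverse=strand == "-")
        exons = [
            Exon(exon_id=eid or f"{tx}.exon{i}", g_start=gs, g_end=ge, rank=i)
            for i, (_, eid, gs, ge) in enumerate(feats, start=1)
        ]
        model = TranscriptModel(
            transcript_id=tx,
            gene_symbol=gene,
            chrom=chrom,
            strand=strand,
            exons=exons,
        )
        segs = cds_feats.get(tx)
        if segs:
            lo, hi = _cds_tx_span(model, segs)
            model = TranscriptModel(
                transcript_id=tx,
                gene_symbol=gene,
                chrom=chrom,
                strand=strand,
                exons=exons,
                cds_tx_start=lo,
                cds_tx_end=hi,
            )
        models[tx] = model
    return models


def _cds_tx_span(model: TranscriptModel, segs: list[tuple[int, int]]) -> tuple[int, int]:
    """Map genomic CDS segments into one transcript-coordinate span."""
    positions: list[int] = []
    for gs, ge in segs:
        for idx, ex in enumerate(model.exons):
            if ex.g_start <= gs and ge <= ex.g_end:
                lo, _ = model.exon_tx_range(idx)
                if model.strand == "+":
                    positions += [lo + (gs - ex.g_start), lo + (ge - ex.g_start)]
                else:
                    positions += [lo + (ex.g_end - ge), lo + (ex.g_end - gs)]
                break
        else:
            raise ModelConsistencyError(
                f"{model.transcript_id}: CDS segment {gs}-{ge} not inside any exon"
            )
    return min(positions), max(positions)


def cds_genomic_intervals(model: TranscriptModel) -> list[tuple[int, int]]:
    """Genomic (start, end) intervals covered by the CDS, ascending order."""
    if not model.is_coding:
        return []
    out = []
    for idx, ex in enumerate(model.exons):
        lo, hi = model.exon_tx_range(idx)
        s, e = max(lo, model.cds_tx_start), min(hi, model.cds_tx_end)
        if s > e:
            continue
        if model.strand == "+":
            out.append((ex.g_start + (s - lo), ex.g_start + (e - lo)))
        else:
            out.append((ex.g_end - (e - lo), ex.g_end - (s - lo)))
    return sorted(out)


def models_to_gtf(models: Iterable[TranscriptModel]) -> str:
    """Serialize models back to GTF (exon + CDS features); inverse of loading."""
    lines = []
    for m in models:
        for ex in m.exons:
            attrs = (
                f'transcript_id "{m.transcript_id}"; gene_name "{m.gene_symbol}"; '
                f'exon_number "{ex.rank}"; exon_id "{ex.exon_id}";'
            )
            lines.append(
                "\t".join(
                    [
                        m.chrom,
                        "txannot",
                        "exon",
                        str(ex.g_start),
                        str(ex.g_end),
                        ".",
                        m.strand,
                        ".",
                        attrs,
                    ]
                )
            )
        for gs, ge in cds_genomic_intervals(m):
            attrs = f'transcript_id "{m.transcript_id}"; gene_name "{m.gene_symbol}";'
            lines.append(
                "\t".join(
                    [m.chrom, "txannot", "CDS", str(gs), str(ge), ".", m.strand, "0", attrs]
                )
            )
    return "\n".join(lines) + "\n"


def load_refflat(stream) -> dict[str, TranscriptModel]:
    """Read UCSC refFlat / genePred-style 11-column transcript models.

    Columns: geneName, name, chrom, strand, txStart, txEnd, cdsStart,
    cdsEnd, exonCount, exonStarts, exonEnds — starts 0-based, ends 1-based
    half-open, per UCSC convention.
    """
    models: dict[str, TranscriptModel] = {}
    for lineno, raw in enumerate(_open_lines(stream), start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 11:
            raise GtfParseError(lineno, "refFlat requires 11 columns")
        gene, name, chrom, strand = fields[0], fields[1], fields[2], fields[3]
        cds_g_start, cds_g_end = int(fields[6]), int(fields[7])
        starts = [int(x) for x in fields[9].rstrip(",").split(",")]
        ends = [int(x) for x in fields[10].rstrip(",").split(",")]
        pairs = [(s + 1, e) for s, e in zip(starts, ends)]  # -> 1-based inclusive
        if strand == "-":
            pairs = pairs[::-1]
        exons = [
            Exon(exon_id=f"{name}.exon{i}", g_start=s, g_end=e, rank=i)
            for i, (s, e) in enumerate(pairs, start=1)
        ]
        model = TranscriptModel(name, gene, chrom, strand, exons)
        if cds_g_start < cds_g_end:  # equal means non-coding in genePred
            lo, hi = _cds_tx_span(model, [(cds_g_start + 1, cds_g_end)] if len(pairs) == 1
                                  else _clip_cds_segments(pairs, cds_g_start + 1, cds_g_end))
            model = TranscriptModel(name, gene, chrom, strand, exons, lo, hi)
        models[name] = model
    return models


def _clip_cds_segments(
    exon_pairs: list[tuple[int, int]], cds_lo: int, cds_hi: int
) -> list[tuple[int, int]]:
    segs = []
    for s, e in exon_pairs:
        a, b = max(s, cds_lo), min(e, cds_hi)
        if a <= b:
            segs.append((a, b))
    return segs


# ---------------------------------------------------------------------------
# Cross-reference map and resolution


class CrossRefMap:
    """Accession cross-reference indexed by every ID namespace.

    Lookups accept versioned or versionless accessions; an exact (as-written)
    match is preferred over a versionless one.  Arbitrary extra columns in
    the source TSV are retained in :attr:`table` and passed through.
    """

    REQUIRED = ("refseq_id", "ucsc_id", "ensembl_transcript_id", "hgnc_symbol")
    ID_COLUMNS = ("refseq_id", "ucsc_id", "ensembl_transcript_id")

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in table.columns]
        if missing:
            raise CrossRefError(f"crossref table missing columns: {missing}")
        if "canonical_flag" not in table.columns:
            table = table.assign(canonical_flag=False)
        table = table.copy()
        table["canonical_flag"] = table["canonical_flag"].astype(bool)
        self.table = table.reset_index(drop=True)
        self._exact: dict[str, list[int]] = {}
        self._bare: dict[str, list[int]] = {}
        for i, row in self.table.iterrows():
            for col in self.ID_COLUMNS:
                key = row[col]
                if not isinstance(key, str) or not key:
                    continue
                self._exact.setdefault(key, []).append(i)
                self._bare.setdefault(strip_version(key), []).append(i)
        self._check_duplicates()

    def _check_duplicates(self):
        dups = []
        for key, idxs in self._exact.items():
            targets = {self.table.at[i, "ensembl_transcript_id"] for i in idxs}
            # a versioned key (as written) mapping to >1 Ensembl target is ambiguous
            if _VERSION_RE.search(key) and len(targets) > 1:
                dups.append(f"{key} -> {sorted(targets)}")
        if dups:
            raise CrossRefError("duplicate versioned keys with conflicting targets: " + "; ".join(dups))

    def lookup(self, accession: str) -> pd.DataFrame:
        """Rows matching ``accession``; empty frame when unknown."""
        idxs = self._exact.get(accession)
        if idxs is None:
            idxs = self._bare.get(strip_version(accession), [])
        return self.table.loc[idxs]


def load_crossref(stream) -> CrossRefMap:
    """Read a tab-separated cross-reference table with a header row."""
    table = pd.read_csv(stream, sep="\t", dtype={c: str for c in CrossRefMap.REQUIRED[:3]})
    return CrossRefMap(table)


def resolve_transcript(
    query_id: str,
    crossref: CrossRefMap | None,
    models: Mapping[str, TranscriptModel],
) -> TranscriptModel:
    """Resolve a RefSeq / UCSC / Ensembl accession to exactly one loaded model.

    A query that directly names a loaded model (versioned or versionless)
    bypasses the cross-reference.  When one RefSeq ID maps to several
    Ensembl transcripts, the canonical-flagged row wins, then the
    lexicographically smallest Ensembl ID — a deterministic tie-break.
    """
    if query_id in models:
        return models[query_id]
    bare = strip_version(query_id)
    if bare in models:
        return models[bare]
    bare_index = {strip_version(k): k for k in models}
    if bare in bare_index:
        return models[bare_index[bare]]

    if crossref is None:
        raise UnresolvedIdError(f"{query_id}: no model and no crossref loaded")
    rows = crossref.lookup(query_id)
    if rows.empty:
        raise UnresolvedIdError(f"{query_id}: not found in cross-reference")
    candidates = rows.sort_values(
        ["canonical_flag", "ensembl_transcript_id"], ascending=[False, True]
    )["ensembl_transcript_id"].tolist()
    for enst in candidates:
        target = enst if enst in models else bare_index.get(strip_version(enst))
        if target is None and strip_version(enst) in models:
            target = strip_version(enst)
        if target is not None and target in models:
            if len(set(candidates)) > 1:
                logger.info(
                    "resolved %s -> %s (of %d candidate transcripts)",
                    query_id, target, len(set(candidates)),
                )
            return models[target]
    raise MissingModelError(
        f"{query_id}: crossref names {sorted(set(candidates))} but none is in the bundle"
    )
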