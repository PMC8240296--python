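"""Seeded synthetic annotation bundles for testing and demonstration.

:func:`generate_bundle` writes a complete, self-consistent bundle — genome
FASTA, transcript GTF, ID cross-reference TSV, dbSNP-style VCF, frequency
panels, a ``bundle.toml`` — plus input tables of planted variants and gold
CSVs of the expected outputs.

The gold values are computed here by deliberately naive code (explicit
per-base list concatenation, full-protein translation and diffing via
Biopython) and never by the production mapping/consequence modules, so the
tests compare two independent routes to the same answers.  Generation is
fully deterministic: the same spec reproduces byte-identical files.

The generator aims for structural variety (multi-exon, both strands,
varying UTR lengths, shared RefSeq accessions), not for realism of human
gene architecture.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from Bio.Seq import Seq, reverse_complement

from ._errors import FixtureSpecError
from .variant_db import GNOMAD_SUBPOPS, KG_SUBPOPS

_BASES = "ACGT"
_STOPS = ("TAA", "TAG", "TGA")
_NONSTOP_CODONS = [
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS
]
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class FixtureSpec:
    """Parameters of one synthetic bundle."""

    seed: int = 42
    n_transcripts: int = 100
    exon_count_range: tuple[int, int] = (1, 6)
    exon_width_range: tuple[int, int] = (30, 120)
    intron_width_range: tuple[int, int] = (20, 200)
    utr5_range: tuple[int, int] = (0, 60)
    utr3_range: tuple[int, int] = (0, 60)
    minus_strand_fraction: float = 0.5
    n_panel_variants: int = 30
    n_chromosomes: int = 4
    codon_count_range: tuple[int, int] = (40, 200)

    def validate(self) -> None:
        for name in (
            "exon_count_range",
            "exon_width_range",
            "intron_width_range",
            "codon_count_range",
        ):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise FixtureSpecError(f"{name} must be positive and ordered: ({lo}, {hi})")
        for name in ("utr5_range", "utr3_range"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise FixtureSpecError(f"{name} must be non-negative and ordered")
        if not 0 <= self.minus_strand_fraction <= 1:
            raise FixtureSpecError("minus_strand_fraction must be in [0, 1]")
        if self.n_transcripts < 0 or self.n_panel_variants < 0:
            raise FixtureSpecError("counts must be non-negative")
        if self.n_chromosomes < 1:
            raise FixtureSpecError("need at least one chromosome")


@dataclass
class _TxLayout:
    """Everything the generator knows about one planted transcript."""

    transcript_id: str
    refseq_id: str
    ucsc_id: str
    gene_symbol: str
    chrom: str
    strand: str
    exons: list[tuple[str, int, int]]  # (exon_id, g_start, g_end), transcript order
    tx_seq: str  # spliced transcript, coding-strand, 5'->3'
    utr5: int
    n_codons: int
    caa_codon: int | None  # 1-based codon index planted as CAA, if any
    pbm: list[int] = field(default_factory=list)  # naive per-base map

    @property
    def cds_len(self) -> int:
        return 3 * self.n_codons

    @property
    def cds_seq(self) -> str:
        return self.tx_seq[self.utr5 : self.utr5 + self.cds_len]


@dataclass
class _PlantedVariant:
    tx: _TxLayout
    cds_pos: int
    ref: str  # coding strand
    alt: str
    rsid: str
    in_panel: bool
    all_af: float | None  # alt freq in the overall population, None = absent cell
    sub_afs: dict[str, float]


def _naive_per_base_map(layout: _TxLayout) -> list[int]:
    """Per-base transcript->genome map by plain list concatenation."""
    out: list[int] = []
    for _, gs, ge in layout.exons:
        run = list(range(gs, ge + 1))
        if layout.strand == "-":
            run = run[::-1]
        out += run
    return out


def _naive_exon_of(layout: _TxLayout, tx_pos: int) -> tuple[str, int]:
    """(exon_id, rank) containing a transcript position, by linear scan."""
    acc = 0
    for rank, (eid, gs, ge) in enumerate(layout.exons, start=1):
        acc += ge - gs + 1
        if tx_pos <= acc:
            return eid, rank
    raise AssertionError("tx_pos beyond transcript")


def _naive_classification(cds: str, cds_pos: int, alt: str) -> tuple[str, str, str, int]:
    """(function, ref_aa, alt_aa, codon_number) by full-protein translation and diff."""
    alt_cds = cds[: cds_pos - 1] + alt + cds[cds_pos:]
    ref_prot = str(Seq(cds).translate())
    alt_prot = str(Seq(alt_cds).translate())
    codon_number = (cds_pos + 2) // 3
    ref_aa = ref_prot[codon_number - 1].replace("*", "X")
    alt_aa = alt_prot[codon_number - 1].replace("*", "X")
    if ref_prot == alt_prot:
        fn = "synonymous SNV"
    elif alt_aa == "X":
        fn = "stopgain"
    elif ref_aa == "X":
        fn = "stoploss"
    elif codon_number == 1 and ref_aa == "M" and alt_aa != "M":
        fn = "startloss"
    else:
        fn = "nonsynonymous SNV"
    return fn, ref_aa, alt_aa, codon_number


def _wrap_fasta(seq: str, width: int = 60) -> str:
    return "\n".join(seq[i : i + width] for i in range(0, len(seq), width))


def generate_bundle(spec: FixtureSpec, out_dir: str | Path) -> Path:
    """Write a complete synthetic bundle plus gold expected outputs.

    Returns the bundle directory.  Raises :class:`FixtureSpecError` before
    writing anything if the spec is inconsistent.
    """
    spec.validate()
    out = Path(out_dir)
    rng = random.Random(spec.seed)

    # ---- transcripts --------------------------------------------------
    layouts: list[_TxLayout] = []
    cursors = {f"chrS{c + 1}": 0 for c in range(spec.n_chromosomes)}
    for i in range(spec.n_transcripts):
        chrom = f"chrS{1 + i % spec.n_chromosomes}"
        strand = "-" if rng.random() < spec.minus_strand_fraction else "+"
        n_exons = rng.randint(*spec.exon_count_range)
        widths = [rng.randint(*spec.exon_width_range) for _ in range(n_exons)]
        utr5 = rng.randint(*spec.utr5_range)
        utr3 = rng.randint(*spec.utr3_range)
        n_codons = rng.randint(*spec.codon_count_range)
        need = utr5 + 3 * n_codons + utr3
        deficit = need - sum(widths)
        if deficit > 0:
            widths[-1] += deficit
        else:
            utr3 += -deficit  # spare transcript length becomes 3' UTR
        tx_len = sum(widths)
        assert tx_len == utr5 + 3 * n_codons + utr3

        codons = ["ATG"]
        codons += [rng.choice(_NONSTOP_CODONS) for _ in range(n_codons - 2)]
        codons.append(rng.choice(_STOPS))
        caa_codon = None
        if n_codons >= 4:
            caa_codon = max(2, n_codons // 2)
            codons[caa_codon - 1] = "CAA"
        tx_seq = (
            "".join(rng.choice(_BASES) for _ in range(utr5))
            + "".join(codons)
            + "".join(rng.choice(_BASES) for _ in range(utr3))
        )

        # genomic placement: exons left-to-right, introns between
        g_exons_asc: list[tuple[int, int]] = []
        pos = cursors[chrom] + rng.randint(100, 400)
        for w in widths if strand == "+" else widths[::-1]:
            g_exons_asc.append((pos + 1, pos + w))
            pos += w + rng.randint(*spec.intron_width_range)
        cursors[chrom] = g_exons_asc[-1][1]
        tx_order = g_exons_asc if strand == "+" else g_exons_asc[::-1]
        tid = f"ENSTS{i:07d}"
        exons = [
            (f"ENSES{i:05d}.{rank}", gs, ge)
            for rank, (gs, ge) in enumerate(tx_order, start=1)
        ]
        layout = _TxLayout(
            transcript_id=tid,
            refseq_id=f"NMS_{i:06d}",
            ucsc_id=f"ucs{i:05d}.1",
            gene_symbol=f"SYNG{i:04d}",
            chrom=chrom,
            strand=strand,
            exons=exons,
            tx_seq=tx_seq,
            utr5=utr5,
            n_codons=n_codons,
            caa_codon=caa_codon,
        )
        layout.pbm = _naive_per_base_map(layout)
        layouts.append(layout)

    # ---- genome -------------------------------------------------------
    chrom_len = {c: cursors[c] + 200 for c in cursors}
    genome = {c: [rng.choice(_BASES) for _ in range(chrom_len[c])] for c in sorted(cursors)}
    for lay in layouts:
        acc = 0
        for _, gs, ge in lay.exons:
            w = ge - gs + 1
            chunk = lay.tx_seq[acc : acc + w]
            if lay.strand == "-":
                chunk = reverse_complement(chunk)
            genome[lay.chrom][gs - 1 : ge] = list(chunk)
            acc += w
    genome_str = {c: "".join(b) for c, b in genome.items()}

    # ---- planted variants --------------------------------------------
    variants: list[_PlantedVariant] = []
    used: set[tuple[str, int]] = set()
    stopgain_targets = [lay for lay in layouts if lay.caa_codon is not None][:5]
    for lay in stopgain_targets:
        cds_pos = 3 * (lay.caa_codon - 1) + 1  # first base of the CAA codon
        variants.append(_make_variant(lay, cds_pos, "T", rng, len(variants)))
        used.add((lay.transcript_id, cds_pos))
    while len(variants) < spec.n_panel_variants and layouts:
        lay = rng.choice(layouts)
        if lay.n_codons < 4:
            continue
        cds_pos = rng.randint(4, lay.cds_len - 3)  # spare start and stop codons
        if (lay.transcript_id, cds_pos) in used:
            continue
        used.add((lay.transcript_id, cds_pos))
        ref = lay.cds_seq[cds_pos - 1]
        alt = rng.choice([b for b in _BASES if b != ref])
        variants.append(_make_variant(lay, cds_pos, alt, rng, len(variants)))

    # frequency assignment: a deterministic mixture of the interesting cases
    for j, pv in enumerate(variants):
        if j % 4 == 3:
            pv.in_panel = False  # absent from the panel entirely
            continue
        pv.in_panel = True
        if j % 4 == 0:
            pv.all_af = 1.0e-4
        elif j % 4 == 1:
            pv.all_af = 0.5
        else:
            pv.all_af = round(rng.uniform(1e-5, 0.2), 6)
        for pop in GNOMAD_SUBPOPS[1:]:
            if rng.random() < 0.5:
                pv.sub_afs[pop] = round(rng.uniform(0, 0.3), 6)

    # ---- write files --------------------------------------------------
    out.mkdir(parents=True, exist_ok=True)
    (out / "gold").mkdir(exist_ok=True)

    with open(out / "genome.fa", "w") as fh:
        for c in sorted(genome_str):
            fh.write(f">{c}\n{_wrap_fasta(genome_str[c])}\n")

    _write_gtf(out / "models.gtf", layouts)
    _write_crossref(out / "crossref.tsv", layouts)
    snp_rows = _write_dbsnp(out / "dbsnp.vcf", variants, genome_str, chrom_len)
    _write_gnomad_tsv(out / "panel_gnomad_exome.tsv", variants)
    _write_kg_vcf(out / "panel_1000g.vcf", variants, chrom_len, rng)
    _write_inputs(out, variants)
    _write_gold(out / "gold", layouts, variants)
    _write_bundle_toml(out / "bundle.toml")
    return out


def _make_variant(
    lay: _TxLayout, cds_pos: int, alt: str, rng: random.Random, idx: int
) -> _PlantedVariant:
    ref = lay.cds_seq[cds_pos - 1]
    if alt == ref:  # only possible for the random plants; pick another base
        alt = next(b for b in _BASES if b != ref)
    return _PlantedVariant(
        tx=lay,
        cds_pos=cds_pos,
        ref=ref,
        alt=alt,
        rsid=f"rsF{idx:04d}",
        in_panel=False,
        all_af=None,
        sub_afs={},
    )


def _g_alleles(pv: _PlantedVariant) -> tuple[str, str]:
    if pv.tx.strand == "-":
        return pv.ref.translate(_COMPLEMENT), pv.alt.translate(_COMPLEMENT)
    return pv.ref, pv.alt


def _g_pos(pv: _PlantedVariant) -> int:
    return pv.tx.pbm[pv.tx.utr5 + pv.cds_pos - 1]


def _write_gtf(path: Path, layouts: list[_TxLayout]) -> None:
    lines = []
    for lay in layouts:
        for rank, (eid, gs, ge) in enumerate(lay.exons, start=1):
            attrs = (
                f'transcript_id "{lay.transcript_id}"; gene_name "{lay.gene_symbol}"; '
                f'exon_number "{rank}"; exon_id "{eid}";'
            )
            lines.append(
                f"{lay.chrom}\tsynthetic\texon\t{gs}\t{ge}\t.\t{lay.strand}\t.\t{attrs}"
            )
        # CDS genomic segments: clip the CDS tx-span against each exon
        cds_lo, cds_hi = lay.utr5 + 1, lay.utr5 + lay.cds_len
        acc = 0
        for eid, gs, ge in lay.exons:
            w = ge - gs + 1
            lo, hi = acc + 1, acc + w
            s, e = max(lo, cds_lo), min(hi, cds_hi)
            if s <= e:
                if lay.strand == "+":
                    g1, g2 = gs + (s - lo), gs + (e - lo)
                else:
                    g1, g2 = ge - (e - lo), ge - (s - lo)
                attrs = f'transcript_id "{lay.transcript_id}"; gene_name "{lay.gene_symbol}";'
                lines.append(
                    f"{lay.chrom}\tsynthetic\tCDS\t{g1}\t{g2}\t.\t{lay.strand}\t0\t{attrs}"
                )
            acc += w
    path.write_text("\n".join(lines) + ("\n" if lines else ""))


def _write_crossref(path: Path, layouts: list[_TxLayout]) -> None:
    rows = ["refseq_id\tucsc_id\tensembl_transcript_id\thgnc_symbol\tcanonical_flag"]
    for lay in layouts:
        rows.append(
            f"{lay.refseq_id}\t{lay.ucsc_id}\t{lay.transcript_id}\t{lay.gene_symbol}\tTrue"
        )
    # one RefSeq ID shared by two Ensembl transcripts, to exercise the tie-break
    if len(layouts) >= 2:
        rows.append(
            f"{layouts[0].refseq_id}\t{layouts[1].ucsc_id}\t"
            f"{layouts[1].transcript_id}\t{layouts[1].gene_symbol}\tFalse"
        )
    path.write_text("\n".join(rows) + "\n")


def _write_dbsnp(
    path: Path,
    variants: list[_PlantedVariant],
    genome: dict[str, str],
    chrom_len: dict[str, int],
) -> list[tuple]:
    rows = []
    for pv in variants:
        g_ref, g_alt = _g_alleles(pv)
        rows.append((pv.tx.chrom, _g_pos(pv), pv.rsid, g_ref, g_alt))
    # one multi-allelic record at a fixed intergenic spot
    first = sorted(chrom_len)[0]
    base = genome[first][49]
    alts = ",".join([b for b in "ACGT" if b != base][:2])
    rows.append((first, 50, "rsMULTI01", base, alts))
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    header = ["##fileformat=VCFv4.2"]
    for c in sorted(chrom_len):
        header.append(f"##contig=<ID={c},length={chrom_len[c]}>")
    header.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    body = [f"{c}\t{p}\t{rid}\t{ref}\t{alt}\t.\t.\t." for c, p, rid, ref, alt in rows]
    path.write_text("\n".join(header + body) + "\n")
    return rows


def _write_gnomad_tsv(path: Path, variants: list[_PlantedVariant]) -> None:
    cols = ["Chr", "Pos", "Ref", "Alt"] + GNOMAD_SUBPOPS
    lines = ["\t".join(cols)]
    for pv in variants:
        if not pv.in_panel:
            continue
        g_ref, g_alt = _g_alleles(pv)
        cells = [pv.tx.chrom, str(_g_pos(pv)), g_ref, g_alt, repr(pv.all_af)]
        for pop in GNOMAD_SUBPOPS[1:]:
            cells.append(repr(pv.sub_afs[pop]) if pop in pv.sub_afs else "")
        lines.append("\t".join(cells))
    path.write_text("\n".join(lines) + "\n")


def _write_kg_vcf(
    path: Path,
    variants: list[_PlantedVariant],
    chrom_len: dict[str, int],
    rng: random.Random,
) -> None:
    header = ["##fileformat=VCFv4.2"]
    for c in sorted(chrom_len):
        header.append(f"##contig=<ID={c},length={chrom_len[c]}>")
    for pop in KG_SUBPOPS:
        header.append(
            f'##INFO=<ID=AF_{pop},Number=A,Type=Float,Description="{pop} alternate allele frequency">'
        )
    header.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    rows = []
    for pv in variants:
        if not pv.in_panel:
            continue
        g_ref, g_alt = _g_alleles(pv)
        info = ";".join(
            f"AF_{pop}={round(rng.uniform(0, 0.4), 6):g}" for pop in KG_SUBPOPS
        )
        rows.append((pv.tx.chrom, _g_pos(pv), pv.rsid, g_ref, g_alt, info))
    rows.sort(key=lambda r: (r[0], r[1]))
    body = [f"{c}\t{p}\t{rid}\t{ref}\t{alt}\t.\t.\t{info}" for c, p, rid, ref, alt, info in rows]
    path.write_text("\n".join(header + body) + "\n")


def _write_inputs(out: Path, variants: list[_PlantedVariant]) -> None:
    lines = ["Transcript_version,Nucleotide_changes"]
    for pv in variants:
        lines.append(f"{pv.tx.refseq_id},{pv.ref}{pv.cds_pos}{pv.alt}")
    (out / "input_transcript_table.csv").write_text("\n".join(lines) + "\n")

    lines = ["Chr,Start,End,Ref,Alt"]
    for pv in variants:
        g_ref, g_alt = _g_alleles(pv)
        g = _g_pos(pv)
        lines.append(f"{pv.tx.chrom},{g},{g},{g_ref},{g_alt}")
    (out / "input_variant_table.csv").write_text("\n".join(lines) + "\n")


def _write_gold(gold: Path, layouts: list[_TxLayout], variants: list[_PlantedVariant]) -> None:
    # per-base transcript->genome map, from the naive construction
    lines = ["transcript_id,tx_pos,g_pos"]
    for lay in layouts:
        for i, g in enumerate(lay.pbm, start=1):
            lines.append(f"{lay.transcript_id},{i},{g}")
    (gold / "per_base_map.csv").write_text("\n".join(lines) + "\n")

    # expected conversion rows
    cols = (
        "Transcript_version,Nucleotide_changes,CDS_start_loc,Ref,Alt,Chr,"
        "ensembl_transcript_id,hgnc_symbol,start,end,width,strand,exon_id,"
        "exon_rank,tx_start,tx_end,refsnp_id"
    )
    lines = [cols]
    for pv in variants:
        lay = pv.tx
        tx_pos = lay.utr5 + pv.cds_pos
        g = _g_pos(pv)
        eid, rank = _naive_exon_of(lay, tx_pos)
        lines.append(
            f"{lay.refseq_id},{pv.ref}{pv.cds_pos}{pv.alt},{pv.cds_pos},{pv.ref},"
            f"{pv.alt},{lay.chrom},{lay.transcript_id},{lay.gene_symbol},{g},{g},1,"
            f"{lay.strand},{eid},{rank},{tx_pos},{tx_pos},{pv.rsid}"
        )
    (gold / "conversion_rows.csv").write_text("\n".join(lines) + "\n")

    # expected annotation rows (region, function, amino-acid change, key freqs)
    lines = [
        "Chr,Start,End,Ref,Alt,Func.knownGene,Gene.knownGene,ExonicFunc.knownGene,"
        "AAChange.knownGene,ALL_Ref_freq,ALL_Alt_freq"
    ]
    for pv in variants:
        lay = pv.tx
        fn, ref_aa, alt_aa, codon = _naive_classification(lay.cds_seq, pv.cds_pos, pv.alt)
        tx_pos = lay.utr5 + pv.cds_pos
        _, rank = _naive_exon_of(lay, tx_pos)
        aachange = (
            f"{lay.gene_symbol}:{lay.transcript_id}:exon{rank}:"
            f"c.{pv.ref}{pv.cds_pos}{pv.alt}:p.{ref_aa}{codon}{alt_aa}"
        )
        g_ref, g_alt = _g_alleles(pv)
        g = _g_pos(pv)
        af = pv.all_af if (pv.in_panel and pv.all_af is not None) else 0.0
        lines.append(
            f"{lay.chrom},{g},{g},{g_ref},{g_alt},exonic,{lay.gene_symbol},{fn},"
            f"{aachange},{1.0 - af!r},{af!r}"
        )
    (gold / "annotation_rows.csv").write_text("\n".join(lines) + "\n")


def _write_bundle_toml(path: Path) -> None:
    kg_keys = "\n".join(f'{pop} = "AF_{pop}"' for pop in KG_SUBPOPS)
    gnomad_pops = ", ".join(f'"{p}"' for p in GNOMAD_SUBPOPS)
    kg_pops = ", ".join(f'"{p}"' for p in KG_SUBPOPS)
    path.write_text(
        f"""species = "synthetic"
gtf = "models.gtf"
fasta = "genome.fa"
crossref = "crossref.tsv"
dbsnp_vcf = "dbsnp.vcf"
default_panel = "db_gnomAD_exome_freq"

[panels.db_gnomAD_exome_freq]
path = "panel_gnomad_exome.tsv"
format = "tsv"
subpops = [{gnomad_pops}]

[panels.db_1000Genomes_5pop_freq]
path = "panel_1000g.vcf"
format = "vcf"
subpops = [{kg_pops}]

[panels.db_1000Genomes_5pop_freq.info_keys]
{kg_keys}
"""
    )
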