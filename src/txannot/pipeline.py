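"""The two user-facing commands: transcript conversion and variant annotation.

``convert_transcript_id`` takes a table of (transcript accession, CDS
change) rows and emits one output row per input row with the genomic
position, exon context, and rsID.  ``pop_freq`` takes a genomic variant
table — the conversion output or any independently produced table — and
emits allele frequencies per subpopulation plus gene-based annotation
columns (region class, gene, exonic function, amino-acid change).

Row-level problems (unparseable token, unknown accession, CDS position out
of range) never abort a run: the offending row is emitted with its data
columns empty and the diagnosis in a trailing ``note`` column.
"""

from __future__ import annotations

import argparse
import logging
import sys
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from ._errors import (
    BundleConfigError,
    PanelConfigError,
    TxAnnotError,
)
from .annotation_store import (
    GenomeSequence,
    TranscriptModel,
    cds_genomic_intervals,
    load_crossref,
    load_refflat,
    load_transcript_models,
    resolve_transcript,
)
from .consequence import (
    TranscriptIndex,
    annotate_consequence,
    complement_base,
)
from .consequence import classify_region as _classify_region
from .coordinate_mapping import cds_to_transcript, genomic_to_transcript, transcript_to_genomic
from .variant_db import (
    BUILTIN_PANEL_SUBPOPS,
    FrequencyPanel,
    SnpDatabase,
    annotate_frequencies,
    format_frequency,
    maf_summary,
)
from .variant_parsing import (
    CdsChange,
    GenomicVariant,
    TranscriptChangeRow,
    read_transcript_table,
    read_variant_table,
)

logger = logging.getLogger("txannot")

#: fixed column order of the conversion output (diagnostic columns trail)
CONVERSION_COLUMNS = [
    "Transcript_version",
    "Nucleotide_changes",
    "CDS_start_loc",
    "Ref",
    "Alt",
    "Chr",
    "ensembl_transcript_id",
    "hgnc_symbol",
    "start",
    "end",
    "width",
    "strand",
    "exon_id",
    "exon_rank",
    "tx_start",
    "tx_end",
    "refsnp_id",
    "g_ref",
    "g_alt",
    "note",
]

ANNOTATION_TRAILING = [
    "Func.knownGene",
    "Gene.knownGene",
    "ExonicFunc.knownGene",
    "AAChange.knownGene",
]


@dataclass
class BundleConfig:
    """Paths and panel definitions of one local annotation bundle."""

    root: Path
    species: str = "hsapiens"
    gtf: Path | None = None
    refflat: Path | None = None
    fasta: Path | None = None
    crossref: Path | None = None
    dbsnp_vcf: Path | None = None
    default_panel: str = "db_gnomAD_exome_freq"
    panels: dict[str, FrequencyPanel] = field(default_factory=dict)

    @classmethod
    def load(cls, path: str | Path) -> "BundleConfig":
        """Read ``bundle.toml`` from a bundle directory (or a direct file path)."""
        path = Path(path)
        toml_path = path / "bundle.toml" if path.is_dir() else path
        if not toml_path.exists():
            raise BundleConfigError(f"no bundle config at {toml_path}")
        with open(toml_path, "rb") as fh:
            cfg = tomllib.load(fh)
        root = toml_path.parent

        def _p(key: str) -> Path | None:
            if key not in cfg:
                return None
            p = root / cfg[key]
            if not p.exists():
                raise BundleConfigError(f"bundle file for {key!r} missing: {p}")
            return p

        panels: dict[str, FrequencyPanel] = {}
        for name, pcfg in cfg.get("panels", {}).items():
            src = root / pcfg["path"]
            if not src.exists():
                raise BundleConfigError(f"panel {name}: file missing: {src}")
            subpops = pcfg.get("subpops") or BUILTIN_PANEL_SUBPOPS.get(name)
            if not subpops:
                raise BundleConfigError(f"panel {name}: subpops not given and not built-in")
            panels[name] = FrequencyPanel(
                panel_name=name,
                subpops=list(subpops),
                source_path=src,
                format=pcfg.get("format", "tsv"),
                info_keys=pcfg.get("info_keys"),
            )
        return cls(
            root=root,
            species=cfg.get("species", "hsapiens"),
            gtf=_p("gtf"),
            refflat=_p("refflat"),
            fasta=_p("fasta"),
            crossref=_p("crossref"),
            dbsnp_vcf=_p("dbsnp_vcf"),
            default_panel=cfg.get("default_panel", "db_gnomAD_exome_freq"),
            panels=panels,
        )


class Bundle:
    """A fully loaded annotation bundle: models + genome + crossref + databases."""

    def __init__(self, config: BundleConfig):
        self.config = config
        if config.gtf is not None:
            self.models: dict[str, TranscriptModel] = load_transcript_models(str(config.gtf))
        elif config.refflat is not None:
            self.models = load_refflat(str(config.refflat))
        else:
            raise BundleConfigError("bundle defines neither gtf nor refflat")
        self.genome = (
            GenomeSequence.from_fasta(str(config.fasta)) if config.fasta else None
        )
        self.crossref = load_crossref(str(config.crossref)) if config.crossref else None
        self.snp_db = (
            SnpDatabase.from_vcf(config.dbsnp_vcf) if config.dbsnp_vcf else None
        )
        self.panels = config.panels
        self.index = TranscriptIndex(self.models.values())

    @classmethod
    def load(cls, path: str | Path) -> "Bundle":
        return cls(BundleConfig.load(path))

    def panel(self, name: str | None) -> FrequencyPanel:
        name = name or self.config.default_panel
        if name not in self.panels:
            raise PanelConfigError(
                f"unknown panel {name!r}; known panels: {sorted(self.panels)}"
            )
        return self.panels[name]


# ---------------------------------------------------------------------------
# Command 1: transcript conversion


def convert_transcript_id(
    rows: Sequence[TranscriptChangeRow], bundle: Bundle
) -> pd.DataFrame:
    """Map each (transcript, CDS change) row to its genomic locus and rsID.

    Emits exactly one row per input row, in input order.  Unresolvable rows
    keep their input columns and carry the diagnosis in ``note``.
    """
    out = []
    for row in rows:
        rec = {c: "" for c in CONVERSION_COLUMNS}
        rec["Transcript_version"] = row.transcript_id
        rec["Nucleotide_changes"] = row.token
        if row.error is not None:
            rec["note"] = row.error
            out.append(rec)
            continue
        change = row.change
        rec["CDS_start_loc"] = change.cds_pos
        rec["Ref"] = change.ref
        rec["Alt"] = change.alt
        try:
            model = resolve_transcript(row.transcript_id, bundle.crossref, bundle.models)
            tx_pos = cds_to_transcript(model, change.cds_pos)
            locus = transcript_to_genomic(model, tx_pos)
        except TxAnnotError as exc:
            rec["note"] = str(exc)
            out.append(rec)
            continue
        g_ref = complement_base(change.ref) if model.strand == "-" else change.ref
        g_alt = complement_base(change.alt) if model.strand == "-" else change.alt
        rec.update(
            {
                "Chr": locus.chrom,
                "ensembl_transcript_id": model.transcript_id,
                "hgnc_symbol": model.gene_symbol,
                "start": locus.g_start,
                "end": locus.g_end,
                "width": locus.width,
                "strand": model.strand,
                "exon_id": locus.exon_id,
                "exon_rank": locus.exon_rank,
                "tx_start": locus.tx_start,
                "tx_end": locus.tx_end,
                "g_ref": g_ref,
                "g_alt": g_alt,
            }
        )
        if bundle.genome is not None:
            genome_base = bundle.genome.fetch(locus.chrom, locus.g_start, locus.g_start)
            if genome_base != g_ref:
                rec["note"] = f"reference mismatch: genome has {genome_base}, declared {g_ref}"
        if bundle.snp_db is not None:
            try:
                gv = GenomicVariant(locus.chrom, locus.g_start, locus.g_end, g_ref, g_alt)
                rec["refsnp_id"] = bundle.snp_db.lookup_rsid(gv)
            except TxAnnotError:
                rec["refsnp_id"] = ""
        out.append(rec)
    return pd.DataFrame(out, columns=CONVERSION_COLUMNS)


# ---------------------------------------------------------------------------
# Command 2: population frequencies + gene-based annotation


def _coding_hits(bundle: Bundle, variant: GenomicVariant) -> list[tuple[TranscriptModel, CdsChange]]:
    """Coding models whose CDS contains the variant, with the coding-strand change."""
    hits = []
    for model in bundle.index.overlapping(variant.chrom, variant.g_start):
        if not model.is_coding:
            continue
        if not any(s <= variant.g_start <= e for s, e in cds_genomic_intervals(model)):
            continue
        tx_pos = genomic_to_transcript(model, variant.chrom, variant.g_start)
        cds_pos = tx_pos - model.cds_tx_start + 1
        if model.strand == "-":
            ref, alt = complement_base(variant.ref), complement_base(variant.alt)
        else:
            ref, alt = variant.ref, variant.alt
        hits.append((model, CdsChange(ref=ref, cds_pos=cds_pos, alt=alt)))
    return hits


def pop_freq(
    variants: Sequence[GenomicVariant],
    panel_name: str | None,
    bundle: Bundle,
) -> pd.DataFrame:
    """Annotate genomic variants with subpopulation frequencies and gene context.

    Column layout: Chr, Start, End, Ref, Alt; the panel's Ref_freq/Alt_freq
    pairs in panel order; then Func/Gene/ExonicFunc/AAChange (knownGene
    style) always last.  Accepts any variant table — the conversion step is
    not required upstream.
    """
    panel = bundle.panel(panel_name)
    df = annotate_frequencies(variants, panel)
    func_col, gene_col, exfunc_col, aachange_col = [], [], [], []
    for v in variants:
        region, genes = _classify_region(bundle.index, v)
        functions: list[str] = []
        aachanges: list[str] = []
        if region == "exonic" and bundle.genome is not None:
            for model, change in _coding_hits(bundle, v):
                csq = annotate_consequence(model, bundle.genome, change)
                if csq.exonic_function not in functions:
                    functions.append(csq.exonic_function)
                aachanges.append(csq.aachange)
        func_col.append(region)
        gene_col.append(";".join(genes))
        exfunc_col.append(";".join(functions))
        aachange_col.append(",".join(aachanges))
    df["Func.knownGene"] = func_col
    df["Gene.knownGene"] = gene_col
    df["ExonicFunc.knownGene"] = exfunc_col
    df["AAChange.knownGene"] = aachange_col
    return df


def write_annotation_csv(df: pd.DataFrame, path, panel: FrequencyPanel) -> None:
    """Write the annotation table, formatting frequency cells for display."""
    out = df.copy()
    for col in out.columns:
        if col.endswith("_Ref_freq") or col.endswith("_Alt_freq"):
            out[col] = out[col].map(format_frequency)
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# CLI


def _build_parser() -> argparse.ArgumentParser:
    parser = argparse.ArgumentParser(
        prog="txannot",
        description="Offline transcript-to-genome variant annotation",
    )
    sub = parser.add_subparsers(dest="command", required=True)

    def common(p):
        p.add_argument("--input", required=True, help="input table (CSV, or BED for popfreq)")
        p.add_argument("--bundle", required=True, help="annotation bundle directory")
        p.add_argument("--output", default="-", help="output CSV path (default stdout)")
        p.add_argument("--species", default=None, help="expected bundle species label")
        p.add_argument("--log-level", default="WARNING")
        p.add_argument(
            "--seed-bundle",
            type=int,
            default=None,
            metavar="SEED",
            help="generate a synthetic bundle at --bundle (if absent) with this seed",
        )

    p_conv = sub.add_parser("convert", help="map transcript CDS changes to genomic variants")
    common(p_conv)

    p_pop = sub.add_parser("popfreq", help="annotate variants with population frequencies")
    common(p_pop)
    p_pop.add_argument("--panel", default=None, help="frequency panel name")
    p_pop.add_argument("--format", default=None, choices=["csv", "bed"], help="input format (default: by extension)")
    p_pop.add_argument("--bed-dialect", default="table1", choices=["table1", "standard0"])
    p_pop.add_argument("--maf-plot", default=None, help="write a MAF bar plot (PNG) here")
    return parser


def run_cli(argv: Sequence[str]) -> int:
    """Entry point; returns a process exit code (2 on usage errors)."""
    parser = _build_parser()
    try:
        args = parser.parse_args(list(argv))
    except SystemExit as exc:
        return int(exc.code or 0)
    logging.basicConfig(stream=sys.stderr, level=args.log_level.upper())

    try:
        bundle_dir = Path(args.bundle)
        if args.seed_bundle is not None and not (bundle_dir / "bundle.toml").exists():
            from .fixtures import FixtureSpec, generate_bundle

            logger.info("generating synthetic bundle (seed %d) at %s", args.seed_bundle, bundle_dir)
            generate_bundle(FixtureSpec(seed=args.seed_bundle), bundle_dir)
        bundle = Bundle.load(bundle_dir)
        if args.species and args.species != bundle.config.species:
            logger.warning(
                "bundle species %r differs from requested %r",
                bundle.config.species,
                args.species,
            )
        if args.command == "convert":
            rows = read_transcript_table(args.input)
            df = convert_transcript_id(rows, bundle)
            for r in df.itertuples(index=False):
                if r.note:
                    logger.warning("row %s %s: %s", r.Transcript_version, r.Nucleotide_changes, r.note)
            _write_csv(df, args.output)
        else:
            fmt = args.format or ("bed" if str(args.input).endswith(".bed") else "csv")
            variants = read_variant_table(args.input, format=fmt, bed_dialect=args.bed_dialect)
            panel = bundle.panel(args.panel)
            df = pop_freq(variants, args.panel, bundle)
            if args.output == "-":
                write_annotation_csv(df, sys.stdout, panel)
            else:
                write_annotation_csv(df, args.output, panel)
            if args.maf_plot:
                from .variant_db import plot_maf_bars

                plot_maf_bars(maf_summary(df, panel), args.maf_plot)
        return 0
    except TxAnnotError as exc:
        print(f"error: {exc}", file=sys.stderr)
        return 1


def _write_csv(df: pd.DataFrame, output: str) -> None:
    if output == "-":
        df.to_csv(sys.stdout, index=False)
    else:
        df.to_csv(output, index=False)


def main() -> None:
    sys.exit(run_cli(sys.argv[1:]))
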