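"""rsID lookup and multi-population allele-frequency annotation.

Frequency panels are local files — either a wide TSV (Chr, Pos, Ref, Alt,
one column per subpopulation) or a VCF with per-subpopulation AF INFO keys
(gnomAD style, ``AF_afr``).  Both readers normalize to the same in-memory
record: alternate-allele frequency per subpopulation code.

Convention for variants absent from a panel (or subpopulations with no
stored value): Ref_freq = 1 and Alt_freq = 0.  This mirrors the tabular
output convention of population-annotation reports, but note that "absent
from the panel" is not biologically the same as "monomorphic".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

from ._errors import PanelConfigError, VcfLoadError
from .variant_parsing import GenomicVariant

GNOMAD_SUBPOPS = ["ALL", "AFR", "AMR", "ASJ", "EAS", "FIN", "NFE", "SAS", "OTH"]
KG_SUBPOPS = ["EAS", "AMR", "AFR", "EUR", "SAS"]
TWB_SUBPOPS = ["TWB"]

#: subpopulation sets of the named panels a bundle may provide
BUILTIN_PANEL_SUBPOPS: dict[str, list[str]] = {
    "db_gnomAD_exome_freq": GNOMAD_SUBPOPS,
    "db_gnomAD_genome_freq": GNOMAD_SUBPOPS,
    "db_1000Genomes_5pop_freq": KG_SUBPOPS,
    "db_TWB_GWG_freq": TWB_SUBPOPS,
    "db_TWB_NGS_freq": TWB_SUBPOPS,
}

VariantKey = tuple[str, int, str, str]  # chrom, pos, ref, alt


@dataclass
class FrequencyPanel:
    """A named allele-frequency panel backed by a TSV or VCF file.

    ``info_keys`` maps subpopulation code -> VCF INFO key; by default the
    overall population uses ``AF`` and subpopulations ``AF_<code lower>``.
    Records are loaded lazily on first query and cached.
    """

    panel_name: str
    subpops: Sequence[str]
    source_path: str | Path
    format: str = "tsv"  # or "vcf"
    info_keys: Mapping[str, str] | None = None
    _records: dict[VariantKey, dict[str, float]] | None = field(
        default=None, repr=False
    )

    def __post_init__(self):
        if not self.subpops:
            raise PanelConfigError(f"{self.panel_name}: subpops must be non-empty")
        if len(set(self.subpops)) != len(list(self.subpops)):
            raise PanelConfigError(f"{self.panel_name}: duplicate subpop codes")

    def _info_key(self, pop: str) -> str:
        if self.info_keys and pop in self.info_keys:
            return self.info_keys[pop]
        return "AF" if pop == "ALL" else f"AF_{pop.lower()}"

    def load(self) -> dict[VariantKey, dict[str, float]]:
        if self._records is not None:
            return self._records
        if self.format == "tsv":
            self._records = self._load_tsv()
        elif self.format == "vcf":
            self._records = self._load_vcf()
        else:
            raise PanelConfigError(
                f"{self.panel_name}: unknown panel format {self.format!r}"
            )
        return self._records

    def _load_tsv(self) -> dict[VariantKey, dict[str, float]]:
        df = pd.read_csv(self.source_path, sep="\t", dtype={"Chr": str, "Ref": str, "Alt": str})
        records: dict[VariantKey, dict[str, float]] = {}
        for rec in df.itertuples(index=False):
            key = (str(rec.Chr), int(rec.Pos), rec.Ref, rec.Alt)
            freqs = {}
            for pop in self.subpops:
                val = getattr(rec, pop, None)
                if val is not None and pd.notna(val):
                    freqs[pop] = float(val)
            records[key] = freqs
        return records

    def _load_vcf(self) -> dict[VariantKey, dict[str, float]]:
        records: dict[VariantKey, dict[str, float]] = {}
        try:
            vcf = pysam.VariantFile(str(self.source_path))
        except Exception as exc:
            raise VcfLoadError(f"{self.panel_name}: cannot read {self.source_path}: {exc}")
        with vcf:
            for rec in vcf:
                alts = rec.alts or ()
                for ai, alt in enumerate(alts):
                    freqs = {}
                    for pop in self.subpops:
                        key = self._info_key(pop)
                        if key in rec.info:
                            val = rec.info[key]
                            if isinstance(val, tuple):
                                val = val[ai]
                            if val is not None:
                                freqs[pop] = float(val)
                    records[(rec.chrom, rec.pos, rec.ref, alt)] = freqs
        return records

    def alt_freqs(self, variant: GenomicVariant) -> dict[str, float]:
        """Alternate-allele frequency per subpop; missing codes omitted."""
        return self.load().get(
            (variant.chrom, variant.g_start, variant.ref, variant.alt), {}
        )


class SnpDatabase:
    """dbSNP-style rsID lookup from a position-sorted VCF."""

    def __init__(self, records: dict[tuple[str, int], list[tuple[str, str, tuple[str, ...]]]]):
        self._records = records

    @classmethod
    def from_vcf(cls, path: str | Path) -> "SnpDatabase":
        records: dict[tuple[str, int], list[tuple[str, str, tuple[str, ...]]]] = {}
        last: dict[str, int] = {}
        try:
            vcf = pysam.VariantFile(str(path))
        except Exception as exc:
            raise VcfLoadError(f"cannot read VCF {path}: {exc}")
        with vcf:
            for rec in vcf:
                if rec.chrom in last and rec.pos < last[rec.chrom]:
                    raise VcfLoadError(
                        f"{path}: VCF not position-sorted at {rec.chrom}:{rec.pos}"
                    )
                last[rec.chrom] = rec.pos
                records.setdefault((rec.chrom, rec.pos), []).append(
                    (rec.id or "", rec.ref, tuple(rec.alts or ()))
                )
        return cls(records)

    def lookup_rsid(self, variant: GenomicVariant) -> str:
        """rsID whose ref matches and whose ALT list contains the alt; '' if none."""
        for rsid, ref, alts in self._records.get((variant.chrom, variant.g_start), []):
            if ref == variant.ref and variant.alt in alts:
                return rsid
        return ""


def lookup_rsid(snp_db: SnpDatabase, variant: GenomicVariant) -> str:
    """Functional wrapper over :meth:`SnpDatabase.lookup_rsid`."""
    return snp_db.lookup_rsid(variant)


def annotate_frequencies(
    variants: Iterable[GenomicVariant], panel: FrequencyPanel
) -> pd.DataFrame:
    """Per-variant Ref_freq/Alt_freq for every panel subpopulation.

    Output columns: Chr, Start, End, Ref, Alt, then
    ``{panel}_{POP}_Ref_freq`` / ``{panel}_{POP}_Alt_freq`` pairs in panel
    order.  Ref_freq = 1 - alt_freq; absent variants or subpop values get
    (1, 0).  Total: one output row per input variant, always.
    """
    rows = []
    for v in variants:
        freqs = panel.alt_freqs(v)
        row: dict[str, object] = {
            "Chr": v.chrom,
            "Start": v.g_start,
            "End": v.g_end,
            "Ref": v.ref,
            "Alt": v.alt,
        }
        for pop in panel.subpops:
            af = freqs.get(pop, 0.0)
            row[f"{panel.panel_name}_{pop}_Ref_freq"] = 1.0 - af
            row[f"{panel.panel_name}_{pop}_Alt_freq"] = af
        rows.append(row)
    columns = ["Chr", "Start", "End", "Ref", "Alt"]
    for pop in panel.subpops:
        columns += [
            f"{panel.panel_name}_{pop}_Ref_freq",
            f"{panel.panel_name}_{pop}_Alt_freq",
        ]
    return pd.DataFrame(rows, columns=columns)


def maf_summary(annotated: pd.DataFrame, panel: FrequencyPanel) -> pd.DataFrame:
    """Tidy (variant, subpop, maf) table; MAF = min(Ref_freq, Alt_freq) <= 0.5."""
    rows = []
    for rec in annotated.itertuples(index=False):
        label = f"{rec.Chr}:{rec.Start}{rec.Ref}>{rec.Alt}"
        for pop in panel.subpops:
            ref = getattr(rec, f"{panel.panel_name}_{pop}_Ref_freq")
            alt = getattr(rec, f"{panel.panel_name}_{pop}_Alt_freq")
            rows.append((label, pop, min(float(ref), float(alt))))
    return pd.DataFrame(rows, columns=["variant", "subpop", "maf"])


def plot_maf_bars(summary: pd.DataFrame, out_path: str | Path | None = None):
    """Bar plot of MAF per subpopulation, one panel per variant (optional)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    variants = summary["variant"].unique()
    fig, axes = plt.subplots(
        len(variants), 1, figsize=(6, 2.2 * len(variants)), squeeze=False
    )
    for ax, var in zip(axes.ravel(), variants):
        sub = summary[summary["variant"] == var]
        ax.bar(sub["subpop"], sub["maf"], color="#4878a8")
        ax.set_title(var, fontsize=9)
        ax.set_ylabel("MAF")
        ax.set_ylim(0, max(0.5, float(sub["maf"].max()) * 1.1 or 0.5))
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=100)
    return fig


def format_frequency(x: float) -> str:
    """Render a frequency for CSV output.

    Values below 1e-3 (but above 0) print in scientific notation with two
    decimals (``1.00E-04``); everything else as a plain decimal with
    trailing zeros trimmed.  Full precision is retained internally — this
    is display formatting only.
    """
    if 0 < x < 1e-3:
        return f"{x:.2E}"
    s = f"{x:.4f}".rstrip("0").rstrip(".")
    return s if s else "0"
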