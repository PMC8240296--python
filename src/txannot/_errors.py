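"""Exception hierarchy.

Every error a caller might want to tolerate at row level derives from
:class:`TxAnnotError`; bundle-level failures (bad files, broken config)
are fatal and raised eagerly at load time.
"""


class TxAnnotError(Exception):
    """Base class for all package errors."""


class GtfParseError(TxAnnotError):
    """A GTF/refFlat line could not be parsed; carries the 1-based line number."""

    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"line {line_number}: {message}")


class ModelConsistencyError(TxAnnotError):
    """A transcript model violates a structural invariant (e.g. CDS outside exons)."""


class CrossRefError(TxAnnotError):
    """The ID cross-reference table is malformed (duplicate conflicting keys, missing columns)."""


class UnresolvedIdError(TxAnnotError):
    """A query accession matches no cross-reference row and no loaded model."""


class MissingModelError(TxAnnotError):
    """A cross-reference row points at a transcript absent from the loaded bundle."""


class NoCdsError(TxAnnotError):
    """A CDS-dependent operation was applied to a non-coding transcript."""


class OutOfCdsError(TxAnnotError):
    """A CDS position lies outside 1..cds_length."""


class OutOfTranscriptError(TxAnnotError):
    """A transcript position lies outside 1..transcript_length."""


class NotExonicError(TxAnnotError):
    """A genomic position falls in an intron or outside the transcript span."""


class ChangeParseError(TxAnnotError):
    """A nucleotide-change token did not match any accepted dialect."""


class DegenerateChangeError(ChangeParseError):
    """Reference and alternate allele are identical."""


class TableSchemaError(TxAnnotError):
    """An input table is missing a required column."""


class CoordinateError(TxAnnotError):
    """A variant record has inconsistent coordinates (Start > End) or bad alleles."""


class VcfLoadError(TxAnnotError):
    """A VCF could not be read or is not position-sorted."""


class PanelConfigError(TxAnnotError):
    """An unknown frequency panel was requested; message lists known panels."""


class BundleConfigError(TxAnnotError):
    """The annotation-bundle configuration is invalid or references missing files."""


class FixtureSpecError(TxAnnotError):
    """A synthetic-bundle specification violates its invariants."""
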