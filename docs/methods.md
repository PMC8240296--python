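# Methods

## Coordinate systems and the projection model

Three 1-based coordinate systems are used throughout. Genomic positions
are inclusive (GTF convention: an SNV has `start == end`). Transcript
positions count along the spliced mRNA from its 5' end, UTRs included; on
a minus-strand transcript, position 1 is the genomically *rightmost* base
of exon rank 1. CDS positions start at the A of the initiator ATG, so
`tx = cds + len(5'UTR)`.

A transcript model is an ordered exon list (rank 1..n in 5'→3' order:
ascending genomic start on `+`, descending on `−`) plus a CDS span in
transcript coordinates, derived at load time by mapping the GTF's CDS
features through the exon structure. CDS segments that fall outside every
exon are a hard model-consistency error. The CDS span is taken verbatim
from the CDS features; the bundled synthetic models include the stop codon
in it, so `cds_length` is always a whole number of codons there. Models
without CDS features are retained as non-coding and rejected with a clear
error only when a CDS-dependent operation touches them.

`transcript_to_genomic` binary-searches the cumulative exon widths
(O(log n)); the per-base map built by plain list concatenation is kept as
its in-package brute-force oracle and is compared exhaustively in the
tests. A position exactly on an exon boundary belongs to that exon; there
is no splice-window logic at the projection level. Only width-1
substitutions are projected — insertions/deletions are out of scope.

## Accession resolution

Queries may be RefSeq (`NM_*`), UCSC (`uc*`), or Ensembl (`ENST*`)
accessions, optionally versioned. Resolution prefers an exact as-written
match, then a versionless match (inputs are typically versionless while
cross-reference tables may quote versions). When one RefSeq accession maps
to several Ensembl transcripts the canonical-flagged row wins, then the
lexicographically smallest Ensembl ID — determinism was chosen here
because no disambiguation rule is otherwise defined; the chosen mapping is
logged. A query naming a loaded model directly bypasses the
cross-reference.

## Consequence calling

The spliced CDS is rebuilt from the genome (per-exon reverse complement on
`−`), the affected codon is `⌈c/3⌉` with offset `((c−1) mod 3) + 1`, and
both codons are translated under the standard genetic code with stop
written `X` (the `p.Q1037X` convention). Classification order:
synonymous → stopgain → stoploss → startloss (codon 1, reference ATG) →
nonsynonymous. Input alleles are interpreted on the coding strand, because
that is how CDS changes are reported; genome-strand alleles (complemented
on `−`) are emitted in separate `g_ref`/`g_alt` columns so both
orientations are explicit. A genome base that contradicts the declared
reference **flags** the row (`ref_mismatch`, and a `note` in the
conversion output) rather than failing it — patient tables routinely
carry annotation-version drift — and the genome base is what is
translated.

The independent oracle used in the tests rebuilds the *entire* mutant CDS,
translates both proteins with Biopython, and diffs them; implementation
and oracle agree over all 1,080 substitutions of a 120-codon transcript
and over every planted bundle variant.

## Region classification

Per transcript the ladder is: exonic (inside a CDS base) → UTR5/UTR3
(exonic, outside the CDS, by transcript coordinate relative to the CDS
span) → splicing (intronic, within 2 bp of an exon boundary) → intronic.
Positions in no transcript span are intergenic. Across overlapping
transcripts the highest-priority class wins
(exonic > UTR5 > UTR3 > splicing > intronic), and the gene column lists
every overlapping gene symbol. The 2 bp splice window is this package's
documented choice; exonic bases of non-coding transcripts are reported as
exonic with no consequence columns. Interval queries use an interval tree
over transcript spans.

## Frequency panels and conventions

Panels are local files: a wide TSV (`Chr, Pos, Ref, Alt`, one column per
subpopulation code) or a VCF with per-subpopulation AF INFO keys
(`AF` for the overall population, `AF_<code>` otherwise, remappable per
panel). Built-in panel names carry their conventional subpopulation sets
(gnomAD exome/genome: ALL, AFR, AMR, ASJ, EAS, FIN, NFE, SAS, OTH;
1000 Genomes: EAS, AMR, AFR, EUR, SAS; TWB array/NGS: TWB). `Ref_freq =
1 − Alt_freq` per cell; a variant absent from the panel, or a
subpopulation with no stored value, is emitted as `(1, 0)`. That
convention matches tabular annotation reports but deliberately conflates
"absent from the panel" with "monomorphic" — callers needing the
distinction should query the panel directly. Frequencies below 1e-3 are
*printed* as two-decimal scientific notation (`1.00E-04`); full precision
is retained internally and in the DataFrame API. rsID lookup requires
reference equality and membership of the alternate allele in the VCF ALT
list; no match is an empty string, not an error. The dbSNP-style VCF must
be position-sorted (checked at load).

## The synthetic bundle generator

`fixtures.generate_bundle` emits a complete bundle — genome FASTA, GTF,
cross-reference TSV (including one RefSeq accession shared by two
transcripts, to exercise the tie-break), dbSNP-style VCF (with one
multi-allelic record), a gnomAD-style TSV panel and a 1000 Genomes-style
VCF panel — plus input tables of planted variants and gold CSVs of the
expected outputs. Defaults: 100 transcripts over 4 chromosomes, 1–6 exons
of 30–120 bp, introns 20–200 bp, UTRs 0–60 bp, half the transcripts on the
minus strand, 40–200 codons per CDS, 30 planted variants. Every CDS starts
ATG, ends with a stop, and contains no internal stop codons; a CAA codon
is planted mid-CDS so that at least five variants are deliberate
C→T stopgains. Planted alternate frequencies cycle through the
informative cases (1e-4, 0.5, random, absent-from-panel).

Gold values are computed inside the generator by deliberately naive code —
explicit per-base list concatenation and full-protein translate-and-diff —
never by the production modules, so the test suite always compares two
independent routes. Generation is byte-deterministic per seed (verified by
hashing).

What the generator does **not** emulate: realistic human exon-length and
intron-length distributions, overlapping isoforms of one gene, non-coding
RNA biotypes, indels, multi-nucleotide variants, or linkage between
variants. Passing tests therefore demonstrate coordinate, consequence, and
frequency *arithmetic* correctness, not robustness to the full messiness
of real annotation releases.

## Numerical and formatting choices

- Frequencies compare exactly where constructed (`1 − p` in double
  precision); the sum invariant `Ref + Alt = 1` is asserted to 1e-12.
- Output row order always equals input row order; row-level failures
  (unparseable token, unknown accession, out-of-range CDS position) fill a
  trailing `note` column and never abort a batch; bundle-level failures
  (missing files, unknown panel) are fatal.
- The conversion schema appends `g_ref`, `g_alt`, `note` after the
  seventeen primary columns so minus-strand genome alleles and per-row
  diagnostics are explicit without disturbing the primary column order.
- BED input defaults to the 1-based `Start == End` SNV dialect used by
  variant tables; standard 0-based half-open BED is selected with
  `--bed-dialect standard0`. Chromosome names pass through verbatim, with
  an optional alias map applied before lookups.

## Problem sizes

The default test suite and the acceptance script work on the seeded
100-transcript bundle (~40,000 transcript bases checked exhaustively for
round-trip identity and oracle agreement), 1,080 exhaustive substitutions
of a 120-codon CDS, and 30 planted variants across both panels; the whole
suite runs in a few seconds on one CPU.

## Known limitations

- Single-nucleotide substitutions only; no indels, MNVs, or duplications,
  and no protein-level (`p.`) input parsing.
- Standard genetic code only (no mitochondrial/plastid tables), stop as
  `X`.
- No assembly liftover: bundle and input coordinates must share one
  assembly.
- Exact reproduction of published human coordinates requires assembling a
  real GRCh37 bundle (Ensembl GTF + genome + dbSNP + gnomAD extracts);
  the offline suite instead verifies the mapping arithmetic on synthetic
  bundles and the internal consistency of the published example
  coordinates.
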