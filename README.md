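# txannot

Offline annotation of transcript-specific genetic variants.

Clinical sequencing reports often describe a patient's variant in
*transcript* terms — a RefSeq/UCSC/Ensembl accession plus a coding-sequence
change such as `NM_005359, A947G` — while every downstream resource (dbSNP,
gnomAD, 1000 Genomes, gene-based annotation) is keyed by *genomic* position.
`txannot` bridges the two directions in two commands, entirely from local
files (an "annotation bundle"), so no database connection is needed:

1. **convert** — resolve the accession to a transcript model, project the
   CDS position through the exon structure onto the genome, and report the
   variant's chromosome, position, strand, exon id/rank, transcript
   position, and rsID;
2. **popfreq** — take any genomic variant table (the conversion output or
   an independent CSV/BED) and attach reference/alternate allele
   frequencies for each subpopulation of a chosen panel, plus ANNOVAR-style
   gene-based columns (region class, gene, exonic function, amino-acid
   change).

It is aimed at bioinformaticians and clinician-researchers who need
reproducible variant annotation in pipelines and air-gapped environments.

## The model

For a transcript with 5'→3' exon ranks 1..n and cumulative spliced widths
`W_0 = 0, W_k = W_{k-1} + width_k`:

- **CDS → transcript:** `tx = cds_tx_start + c − 1`, i.e. the CDS position
  plus the 5'UTR length (`tx = c + |UTR5|`).
- **transcript → genome:** find the exon k with `W_{k-1} < tx ≤ W_k`; the
  offset into it is `o = tx − W_{k-1} − 1`; then `g = g_startₖ + o` on the
  plus strand and `g = g_endₖ − o` on the minus strand. The search is a
  binary search over `W`; an exhaustive per-base map serves as its oracle.
- **codon arithmetic:** the affected codon is `⌈c/3⌉` with position
  `((c−1) mod 3) + 1` inside it; the reference codon is read from the
  spliced CDS (reverse-complemented per exon on the minus strand), the
  alternate base substituted, and both translated under the standard
  genetic code (stop written `X`). Classification: synonymous /
  nonsynonymous SNV, stopgain, stoploss, startloss.
- **frequencies:** for a biallelic site with stored alternate-allele
  frequency `p`, `Ref_freq = 1 − p` and `Alt_freq = p`; variants (or
  subpopulation cells) absent from the panel are reported as `(1, 0)`;
  `MAF = min(Ref_freq, Alt_freq) ≤ 0.5`.

## Worked example

A seeded synthetic bundle ships with the package generator, so the full
workflow runs without any download (`--seed-bundle` creates the bundle on
first use):

```bash
txannot convert \
    --input bundle/input_transcript_table.csv \
    --bundle bundle --seed-bundle 42 \
    --output conv.csv
head -3 conv.csv
```

```
Transcript_version,Nucleotide_changes,CDS_start_loc,Ref,Alt,Chr,ensembl_transcript_id,hgnc_symbol,start,end,width,strand,exon_id,exon_rank,tx_start,tx_end,refsnp_id,g_ref,g_alt,note
NMS_000000,C109T,109,C,T,chrS1,ENSTS0000000,SYNG0000,257,257,1,+,ENSES00000.1,1,124,124,rsF0000,C,T,
NMS_000002,C157T,157,C,T,chrS3,ENSTS0000002,SYNG0002,528,528,1,-,ENSES00002.3,3,170,170,rsF0002,G,A,
```

Row 1: the change `C109T` on transcript `NMS_000000` (resolved via the
bundle's cross-reference to `ENSTS0000000`, gene `SYNG0000`) maps to
`chrS1:257` in exon rank 1; transcript position 124 = CDS position 109 +
a 15-base 5'UTR; the bundle's dbSNP-style VCF yields `rsF0000`. Row 2 is a
minus-strand transcript: the coding-strand change `C>T` appears on the
genome as `G>A` (`g_ref`/`g_alt`).

```bash
txannot popfreq --input bundle/input_variant_table.csv \
    --bundle bundle --panel db_gnomAD_exome_freq --output ann.csv
```

```
Chr,Start,...,db_gnomAD_exome_freq_ALL_Ref_freq,db_gnomAD_exome_freq_ALL_Alt_freq,...,Func.knownGene,Gene.knownGene,ExonicFunc.knownGene,AAChange.knownGene
chrS1,257,...,0.9999,1.00E-04,...,exonic,SYNG0000,stopgain,SYNG0000:ENSTS0000000:exon1:c.C109T:p.Q37X
```

The first variant carries an alternate-allele frequency of 1.00E-04 in the
overall population (so `Ref_freq = 0.9999`), and the `C→T` change turns a
CAA (glutamine) codon into TAA — a stopgain at protein position 37.
`--maf-plot out.png` additionally writes per-subpopulation MAF bar plots.

Real bundles are assembled the same way: a genome FASTA, transcript models
as GTF (or refFlat), a cross-reference TSV, a dbSNP-style VCF, and
frequency panels (wide TSV or VCF with `AF_*` INFO keys), declared in a
`bundle.toml`.

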