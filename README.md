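# isofit

Isoform-resolved functional transcriptomics for two-group RNA-seq designs.
Given a transcript-level structural + functional annotation, a transcript x
sample count matrix and a two-condition design, `isofit` computes:

- **FDA** — functional diversity analysis: presence/positional varying calls
  per gene and annotation category, structural variation (alternative polyA,
  UTR lengths, CDS), and feature-ID-level Fisher enrichment.
- **DGE / DIU / DCU** — negative-binomial likelihood-ratio tests for
  differential gene expression and differential isoform / coding-region
  usage, with total usage change (% expression redistribution), per-condition
  major isoforms, and switching calls.
- **DFI / co-DFI** — differential feature inclusion: feature inclusion rates
  (FI), ΔFI, favored condition, 0.5-crossing switches, per-category
  enrichment and condition-bias tests, and co-inclusion / mutual exclusion of
  feature pairs.
- **DPA / UTRL** — polyA-site library construction (75-bp merge, 10 %
  expression floor), distal polyA usage (DPAU) testing, and usage-weighted
  UTR length shifts with a Wilcoxon signed-rank global test.
- **Enrichment** — two-sided Fisher enrichment of any gene list against any
  background over any annotation category.
- **Synthetic data** — a fully deterministic generator of annotation +
  counts + design + ground truth with planted usage/inclusion/polyA/UTR
  effects, used throughout the test suite.

Counts are TMM + sequencing-depth normalized (factors match edgeR's
`calcNormFactors` to 7 significant digits); usage tests run on raw counts
with effective library sizes as offsets; metrics use normalized condition
means.

## Input formats

- **Annotation**: 9-column tab-separated dialect. Structural rows
  (`source = structural`; categories `genomic`, `exon`, `CDS`, `polyA`) carry
  genomic coordinates and `Chr=...;Strand=...;Gene=...` attributes; feature
  rows carry layer-space coordinates and `ID=...;Desc=...;Layer=transcript|
  protein|none`. See `src/isofit/annotation_io.py` for the full definition.
- **Counts**: TSV, first column `transcript_id`, one column per sample.
- **Design**: TSV with `sample` and `condition` columns (exactly two
  conditions, at least two replicates each).

## CLI

```sh
isofit validate-annotation annotation.txt
isofit normalize --counts counts.tsv --design design.tsv --min-cpm 1
isofit fda --annotation annotation.txt --mode positional --tol 9
isofit dge|diu|dcu --annotation ... --counts ... --design ... [--prefilter proportion:0.1]
isofit dfi --annotation ... --counts ... --design ... --categories MOTIF,PFAM-domain
isofit codfi --annotation ... --counts ... --design ... --min-genes 5
isofit dpa --annotation ... --counts ... --design ... --merge 75 --min-frac 0.10 --min-dist 60
isofit utrl --annotation ... --counts ... --design ... --end utr3
isofit enrich --annotation ... --test genes.txt --category MOTIF
isofit simulate --seed 1 --out sim/ [--spec spec.yaml]
```

All commands write TSV to stdout or `--out`.

## Layout

```
src/isofit/
  models.py         transcript/feature/gene domain types
  annotation_io.py  dialect parser/writer, genomic projection, 50-nt NMD rule
  expression.py     TMM normalization, filters, aggregation, isoform usage
  stats.py          BH correction, NB-GLM interaction/condition LRT engine
  fda.py            functional diversity analysis
  differential.py   DGE, DIU/DCU, usage change, majors, switching
  dfi.py            feature inclusion, co-DFI, category statistics
  polya.py          polyA library, DPAU, weighted UTR lengths
  enrichment.py     Fisher enrichment
  synthetic.py      planted-effect data generator
  cli.py            click-based CLI
```
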