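# imf-pipeline

Downstream analysis pipeline for sheep intramuscular-fat (IMF) marker
studies. IMF — the "marbling" fat deposited between muscle fibers — drives
meat tenderness and flavor, and breeding programs screen candidate genes
(e.g. *PIK3R1*, *PPARA*) and SNP markers for it by combining RNA-seq,
qPCR validation, histology, and population-genetic marker evaluation.
This package implements every computational stage of that workflow for
two-population designs (a purebred control such as Small-tail Han sheep,
STH, and a cross such as Suffolk × STH F1):

- **Read QC** — removal of adapter-containing reads, reads with N content
  > 10%, and low-quality reads (> 50% of bases at Phred Q ≤ 20).
- **Expression screening** — FPKM normalization
  (counts × 10⁹ / (library size × gene length)), an FPKM ≥ 0.1 expression
  floor, and a two-group DEG screen (Welch t on log₂(FPKM+1),
  Benjamini–Hochberg FDR): a DEG has FDR < 0.01 and |log₂FC| > 1.
- **Gene-set selection** — hypergeometric enrichment of DEGs against
  GO/KEGG-style gene sets (significant at p ≤ 0.05), selection of genes
  recurring in ≥ 5 lipid-metabolism terms, merge/dedup into core genes.
- **Co-expression hubs** — Pearson correlation network (edge iff
  cor > 0.6), hub genes by connectivity.
- **qPCR quantification** — 2^−ΔΔCt relative expression with a reference
  gene (GAPDH) and a calibrator group, plus Welch-t group comparison.
- **Image quantification** — positive-staining area fraction for IHC /
  Oil-red-O images; Pearson colocalization Rr and Manders overlap
  R = ΣS₁S₂ / √(ΣS₁²·ΣS₂²) for immunofluorescence channel pairs.
- **SNP marker statistics** — for a biallelic locus per population:
  allele frequencies, observed/expected heterozygosity, effective allele
  number Ne = 1/(p²+q²), Botstein PIC = 1 − (p²+q²) − 2p²q², and a
  Hardy–Weinberg χ² test. Two conventions: `exact` (standard), and
  `paper_rounded` (spreadsheet-style cascade of two-decimal rounding)
  matching how published livestock diversity tables are computed.
- **Protein physicochemistry** — CDS variant application, translation
  with explicit selenocysteine (U) recoding, and a ProtParam-style report
  (average MW, theoretical pI, Asp+Glu / Arg+Lys counts, Guruprasad
  instability index, Kyte–Doolittle GRAVY).

A `synthetic_data` module generates every input the pipeline consumes
(FASTQ, count matrices, GMT annotation, Ct tables, image pairs, genotype
cohorts, CDS) with known ground truth, so the whole pipeline is testable
without any external data.

## Worked example: evaluating a SNP marker

The package ships the genotype counts of a *PIK3R1* exon-7 SNP (C1146T)
in two sheep populations. The full marker report:

```sh
$ imf popgen
 locus population  n  n_AA  n_AB  n_BB  f_AA  f_AB  f_BB    p    q  ho_obs  he_obs  hom_exp  het_exp   Ne  PIC   X2    P
C1146T        STH 25     6    12     7  0.24  0.48  0.28 0.48 0.52    0.52    0.48     0.50     0.50 1.99 0.37 0.04 0.98
C1146T  SFK x STH 30    12    14     4  0.40  0.47  0.13 0.64 0.36    0.53    0.47     0.54     0.46 1.85 0.35 0.01 0.99
C1146T        All 55    18    26    11  0.33  0.47  0.20 0.57 0.43    0.53    0.47     0.51     0.49 1.96 0.37 0.10 0.95
```

Reading the STH row: the C allele frequency is p = 0.48, expected
heterozygosity 2pq ≈ 0.50 (maximal diversity is 0.5 for a biallelic
locus), Ne = 1.99 effective alleles (out of a possible 2), and the HWE
χ² = 0.04 (p = 0.98) — genotype counts are fully compatible with
random-mating proportions, so the marker segregates freely in both
populations. This report is produced with the `paper_rounded` convention
and the df = 2 compatibility p-value; pass `--convention exact --df 1`
for the statistically standard computation on new data.

The full synthetic demo (simulation → QC → DEG screen → enrichment →
network → qPCR → colocalization → popgen → protein report):

```sh
imf -v run --config cfg.yaml   # cfg.yaml: seed, outdir, optional stage list
```

Every run writes a `manifest.json` with parameters, seed and SHA-256
checksums of all outputs; reruns with the same seed are byte-identical.

## Layout

```
src/imf/
  synthetic_data.py  # seeded generators + ground truth for every input
  read_qc.py         # FASTQ filtering rules and QC report
  expression.py      # FPKM, expression floor, BH, DEG screen
  geneset.py         # GMT IO, hypergeometric enrichment, candidate selection
  coexpression.py    # Pearson network, hub genes
  qpcr.py            # 2^-ddCt, group comparison
  image_quant.py     # area fraction, Pearson Rr, Manders overlap R
  popgen.py          # diversity + HWE statistics, report table
  protein.py         # variant, translation, ProtParam-style report
  pipeline.py, cli.py
```

See `docs/methods.md` for the statistical model, conventions and known
limitations.
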