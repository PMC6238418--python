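# promarch

Promoter-architecture analysis for strand-resolved functional genomics: an
analysis layer for studying how a chromatin factor (e.g. the FACT histone
chaperone in mouse ES cells) shapes promoter-proximal RNA polymerase II
pausing, divergent antisense transcription and promoter nucleosome
organisation, from NET-seq, MNase-seq, ATAC-seq and RNA-seq data.

It is aimed at computational genomicists who have aligned, strand-resolved
single-nucleotide NET-seq tags, paired-end MNase/ATAC fragments and a gene
count matrix, and who want the standard promoter metrics reproducibly and
testably — plus a fully synthetic multi-assay generator with ground-truth
labels, so the whole pipeline can be validated end to end without any
download.

## What it computes

* **NET-seq cleanup** — UMI-aware PCR-duplicate removal and removal of
  splicing intermediates (tags mapping exactly to the strand-oriented last
  base of an annotated exon or intron).
* **Tracks and metaprofiles** — strand-separated 1-bp tracks, 1× (RPGC)
  normalization to mean per-bp signal 1, 20-bp smoothing, TSS-anchored
  mean/SE/95%-CI profiles with orientation flipping, bedGraph I/O.
* **Travelling ratio** — per gene, the sense NET-seq density over the
  proximal promoter (−30/+250 bp around the TSS) divided by the density over
  the gene body (TSS+300 to TES−200):

      TR = d(proximal) / d(body),   d(region) = Σ signal / length

  High TR indicates promoter-proximal pausing.
* **Antisense transcription** — opposite-strand tag density in the 1,000 bp
  upstream of the TSS, and its knockdown-vs-control change
  `log2((d_KD + ε)/(d_ctrl + ε))`.
* **Fragment partitioning** — MNase fragments into <80 bp (TF-sized) and
  135–170 bp (mononucleosome) classes; short-fragment ATAC NFR selection.
* **Gene classes** — a plain two-condition DE caller (CPM > 1 filter, TMM
  normalization, Welch t on log2-CPM, Benjamini–Hochberg), classes
  up (logFC > 1, adj-p < 0.01), down (logFC < −1, adj-p < 0.01),
  unchanged (adj-p > 0.05), crossed with a factor-bound flag; RPKM quartile
  expression classes.
* **Statistics** — Welch's t with Welch–Satterthwaite df, BH adjustment,
  log-log regression of gene-body coverage on mRNA level, and the
  slope-comparison statistic

      z = (β₁ − β₂) / √(s²_β₁ + s²_β₂)

* **Promoter isolation filter** — genes with another gene within 2.5 kb
  upstream of the TSS are excluded; a deterministic sliding-subwindow filter
  removes TSS rows dominated by short high-occupancy units (unannotated
  short ncRNAs).

## Worked example

```python
from promarch import RunConfig, TruthConfig, run_pipeline

cfg = RunConfig(truth=TruthConfig(genes_per_class=50, seed=1), seed=1)
res = run_pipeline(cfg)
print(res.contrasts[["metric", "de_class", "t", "p"]])
```

prints (abridged) the bound-vs-unbound Welch contrasts per DE class:

```
             metric   de_class          t             p
0  antisense_log2fc       down   0.370682  7.117652e-01
2  antisense_log2fc         up  12.802586  1.495445e-21
3  occupancy_log2fc       down  -1.420668  1.591086e-01
5  occupancy_log2fc         up -10.233446  1.075105e-15
```

The generator plants a 2× antisense gain and a 40% upstream-nucleosome loss
only at knockdown-responsive, factor-bound ("bound-up") genes; the pipeline
recovers exactly that contrast — a strongly significant increase in
antisense transcription (positive t) and loss of upstream nucleosome
occupancy (negative t) at bound-up genes, and null results for the other
classes. `res.slopes.attrs["slope_z"]` compares the log-log slopes of
gene-body coverage vs mRNA level between bound and unbound genes
(bound slope 1.19 vs unbound 0.88, z ≈ 7.1 in this run).

The same run is available from the shell:

```sh
promarch run --config config.yaml --outdir out/   # TSV bundle + manifest.json
promarch simulate --outdir data/                  # FASTA/BED/TSV synthetic data
promarch clean --tags data/netseq_control.bed --genes data/genes.bed --out clean.bed
```

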