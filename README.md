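# tagem

Quantification and demultiplexing of **deterministic 14-bp genetic
barcodes** — heritable DNA tags expressed from a transgene that identify a
fly line (or any tagged genotype) in a pooled experiment. The tags are read
out two ways, and this package implements the complete computational side
of both:

* **Amplicon sequencing** of pooled DNA: a fixed 20-bp PCR handle sits
  immediately upstream of the barcode, amplified with a frameshifted
  (0/2/4/6-base spacer) primer pool. `tagem` locates the handle near the
  read start, extracts the following 14 bp, and assigns it to a reference
  barcode allowing at most 2 substitutions. Counts become per-pool
  abundance fractions, which feed behavioral statistics: fly-count scaling,
  the preference index P.I. = (N_toward − N_away)/(N_toward + N_away),
  replicate mean/SEM/CV, observed-vs-expected fits for structured pools
  (R² = squared Pearson correlation), and cumulative passage curves with
  median transit times for gut-motility timepoint assays.
* **Droplet scRNA-seq multiplexing**: tags appear both as features in the
  gene-expression (GE) matrix and as an enriched amplicon library of
  (cell barcode, UMI, tag read) molecules. `tagem` deduplicates enriched
  records per (cell, UMI) with majority-vote chimera suppression, computes
  per-cell **purity** (top-tag UMIs / total tag UMIs), calls a barcode per
  cell (enriched calls require purity > 0.75; conflicting calls defer to
  the tag seen directly in GE), flags cells co-expressing ≥ 2 tags as
  doublets, and reports overlap statistics against external doublet-caller
  output.

A synthetic-data module (`tagem.simulate`) generates all of these inputs —
structured amplicon pools with sequencing error and PCR chimeras,
phototaxis experiments with known true preference indices, single-cell tag
evidence with ambient and chimeric noise, and transit-time tables — with
per-read/per-cell ground truth, so every stage is testable end to end
without any external data.

Intended users: labs running pooled, sequencing-based phenotyping or
multiplexed single-cell experiments with deterministic genetic barcodes.

## Worked example

Simulate an even 20-barcode pool (100,000 reads, 0.5% per-base error, 1%
chimera rate), then demultiplex it:

```bash
tagem simulate amplicon --config pools.yaml --seed 1 --out sim
tagem count --fastq sim/reads.fastq --reference sim/reference.fasta --out counts
```

with `pools.yaml`:

```yaml
n_barcodes: 20
depth: 100000
per_base_error: 0.005
chimera_rate: 0.01
```

The QC table (`counts/qc.tsv`) shows where every read went:

```
        n_total  n_no_handle  n_too_short  n_no_match  n_ambiguous  n_assigned
reads    100000          498            0           5            0       99497
```

498 reads (≈0.5%) lost the handle to ≥ 2 substitutions in its 20 bases and
5 reads had ≥ 3 errors inside the barcode window; 99.5% of reads were
assigned. The abundance table (`counts/abundance.tsv`, fractions of
assigned reads) recovers the even pool — each barcode expected at 5%:

```
BC01    4.97
BC02    4.88
BC03    5.00
BC04    4.97
BC05    5.11
BC06    4.95      (all 20 barcodes fall between 4.86% and 5.14%)
```

The same library functions run the whole pipeline in Python; see
`tagem.demux`, `tagem.behavior`, `tagem.sc` and `tagem.simulate`.

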