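# atackit

A toolkit for profiling genome-wide chromatin accessibility from aligned
ATAC-seq data. It covers the post-alignment workflow end to end:

- **QC** — organelle (mitochondrial/plastid) read removal, PCR duplicate
  collapse, fragment-size selection, fragment-length histograms, and
  FFT-based estimation of the nucleosome periodicity of the length
  distribution.
- **Accessible-region detection** — base-resolution coverage in two modes
  (full fragments, or Tn5 integration sites with a symmetric window), a
  bundled Poisson local-background peak caller with BH correction
  (externally called peak BEDs are accepted everywhere downstream), and
  RPKM peak abundances.
- **Annotation & profiling** — GTF/GFF3 parsing into eight genomic feature
  sets (promoter, gene body, exon, intron, 5'UTR, CDS, 3'UTR, IGR), log2
  fold enrichment of peaks per feature against the genome background,
  gene-scaled and peak-centered signal matrices (heatmap + metaplot), and
  IGV-loadable BED12 junction tracks (fragments < 150 bp blue, >= 150 bp
  red).
- **Differential accessibility** — multi-set candidate regions (sweep-line
  partition), Welch t-test on log2(RPKM+1) with a >= 2-fold gate for
  replicated designs, group-specific peaks for unreplicated designs, an
  overlap-reproducibility filter (pluggable stand-in for IDR), and
  Gaussian-mixture outlier detection for differentially accessible
  promoters.
- **Integration** — hypergeometric overlap testing against a second peak
  set (ChIP-seq/DNase/MNase) with shared-interval export, and
  expression-quantile accessibility profiles against RNA-seq RPKM tables.
- **Fixtures** — a deterministic simulator producing toy genomes, GTFs,
  and paired-end fragments with planted nucleosome spacing, accessible
  regions, organelle contamination, and duplicates, plus a truth manifest.

## CLI

Everything is reachable through `atackit` subcommands; each run writes its
outputs plus a `run_info.json` parameter log into `--out`:

```sh
atackit simulate --seed 1 --out sim/                  # synthetic dataset
atackit filter sim/fragments.bed --genome sim/chrom.sizes --out filt/
atackit fragsize filt/fragments.filtered.bed --genome sim/chrom.sizes --out fs/ --cutoff 150
atackit fft filt/fragments.filtered.bed --genome sim/chrom.sizes --out fft/
atackit callpeak filt/fragments.filtered.bed --genome sim/chrom.sizes --out peaks/
atackit enrich peaks/peaks.narrowPeak sim/genes.gtf --genome sim/chrom.sizes --out enr/
atackit profile filt/fragments.filtered.bed --genome sim/chrom.sizes \
    --gtf sim/genes.gtf --peaks peaks/peaks.narrowPeak --out prof/
atackit junctions filt/fragments.filtered.bed --genome sim/chrom.sizes --out jct/
```

Comparison subcommands: `diffpeak` (replicated differential peaks),
`specific` (no-replicate group-specific peaks), `diffpromoter` (GMM
promoter outliers), `overlap` (hypergeometric peak-set overlap), `expr`
(expression-group accessibility). Inputs are plain BAM/SAM, fragment BED,
GTF/GFF3, chrom.sizes TSV, and TSV tables; outputs are TSV/JSON/BED/
BED12/bedGraph plus PNG renderings.

Coordinates are 0-based half-open everywhere; conversion from 1-based
sources (GTF, SAM) happens at the parser boundaries.

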