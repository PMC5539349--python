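# coolsuite

A tested library and CLI for joint single-cell chromatin accessibility and
DNA methylation analysis from NOMe-seq-style bisulfite data, plus a
synthetic data generator that plants ground truth for every pipeline stage.

One assay yields two channels per cell: cytosines in GCH context
(H = A/C/T) report enzyme-deposited accessibility, cytosines in WCG
context (W = A/T) report endogenous CpG methylation, and GCG/CCG sites
are excluded as ambiguous/off-target. On top of that separation the
package implements:

| module | what it does |
| --- | --- |
| `coolsuite.synthdata` | synthetic genomes, planted NDRs/nucleosomes/SNPs, per-cell call tables, read records, spike-in counts — deterministic per seed |
| `coolsuite.ioformats` | cytosine reports (Bismark-style, 1-based on disk), BED, SNP/TSS TSVs, FASTA, YAML config; 0-based half-open internally |
| `coolsuite.context` | trinucleotide classification of every cytosine on both strands; WCG/GCH channel routing |
| `coolsuite.quantify` | site/region/tile/global levels with depth filters, TSS meta-profiles, coverage fractions |
| `coolsuite.chromatin` | NDR calling (120-bp windows / 20-bp step, chi-square vs genomic background, p ≤ 1e-15) and nucleosome-occupied-region calling (40-bp windows, p ≤ 1e-3); promoter/proximal/distal classes; differential NDRs |
| `coolsuite.promoter_state` | per-cell open/closed/undefined promoter calls and population labels (homogeneously open/closed, divergent); sensitivity worked example |
| `coolsuite.meth_dynamics` | de novo / demethylated WCG sites and CGIs between stages (Fisher exact + BH FDR), methylation CV, cross-omics correlations |
| `coolsuite.allele` | parental partitioning of reads by heterozygous SNPs with bisulfite-aware strand restrictions; allelic asymmetry summaries |
| `coolsuite.ploidy_cnv` | lambda spike-in ploidy estimation, 1-Mb CNV binning with GC correction and median normalization, chromosome gain/loss flags, replication lead/lag, sex inference |

## CLI

All stages are exposed as `coolsuite` subcommands:

```sh
# generate a synthetic data set (config keys = SimulationConfig fields)
coolsuite simulate --config cfg.yaml --seed 1 --outdir data/

# split one cell's calls into WCG / GCH channels
coolsuite context --genome data/genome.fa --calls data/ES_c00.cx.tsv --out-prefix ES_c00

# global / per-region levels for every cell in a directory
coolsuite quantify --cells data/ --regions ndrs.bed --min-depth 2 --out levels.tsv

# NDRs and nucleosome-occupied regions from merged cells
coolsuite call-ndr --cells data/ --genome data/genome.fa --tss data/tss.tsv --out ndrs.bed
coolsuite call-nucleosomes --cells data/ --genome data/genome.fa --out nucs.bed

# promoter chromatin-state heterogeneity
coolsuite classify-promoters --cells data/ --ndrs ndrs.bed --tss data/tss.tsv --out states.tsv

# de novo methylated sites between two stages
coolsuite denovo --stages stages.tsv --cells data/ --from-stage zygote --to-stage twocell --out denovo.tsv

# allele partitioning, ploidy, CNV, replication timing
coolsuite allele-split --reads data/ES_c00.reads.tsv --snps data/snps.tsv --out assigned.tsv
coolsuite ploidy --counts data/read_counts.tsv --reference-cells ES_c00,ES_c01 --out ploidy.tsv
coolsuite cnv --bins bins.tsv --genome data/genome.fa --out cnv.tsv
coolsuite replication --tiles tiles.tsv --labels domains.bed --out repl.json
```

## Conventions

- Coordinates are 0-based half-open internally; cytosine reports and SNP
  tables are 1-based on disk and converted at the I/O boundary.
- Undefined values are NaN everywhere, never silently 0.
- Plus- and minus-strand cytosines are distinct sites (no collapsing).
- Region and global levels are unweighted means of per-site levels;
  the NDR caller operates on pooled read counts.
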