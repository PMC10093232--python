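# eccdiff

Differential genic circular-DNA (eccDNA) analysis from split-read circle
call tables. Starting from per-sample BED-like tables (chrom, start, end,
split reads) produced by a split-read circle caller, the pipeline:

1. **filters and merges** each catalog — drops mitochondrial circles and
   circles longer than 10 kb, merges clusters whose breakpoints lie within
   10 bp (summing split reads), then drops circles with fewer than 2 split
   reads;
2. **quantifies** per-gene circle production (PpGC): split reads of all
   circles overlapping a gene are summed, scaled by `L_Max / L_i` (longest
   gene over gene length), and equalized as `log2(x + 1)`;
3. **selects** differentially produced genes (DPpGC) between two groups:
   absolute difference of group means ≥ 5 log2 units AND a pooled-variance
   Student's t-test at α = 0.01, with group-specificity and
   fragment-vs-whole-gene flags;
4. computes **count and length statistics** — per-sample unique-circle
   counts, exact Wilcoxon rank-sum comparison with fold ratio, smoothed
   length densities with local-maxima calling, cumulative length curves,
   rhomboid (µ, σ) summaries;
5. runs **hypergeometric over-representation** of the up-regulated gene
   set against user-supplied GMT collections, plus plain gene-list
   intersection;
6. ships a **synthetic cohort generator** with planted case-specific genes
   and full ground truth, so every stage is testable without external data.

## CLI

Full pipeline from a YAML config:

```bash
eccdiff run -c config.yaml
```

```yaml
# config.yaml
manifest: manifest.tsv        # TSV: sample_id <TAB> path <TAB> group
gene_bed: genes.bed           # BED4: chrom start end gene_name
gmt: [sets.gmt]               # optional GMT collections
case_group: SLE
control_group: HC
outdir: results
params:                       # all optional; defaults shown
  l_max: 10000
  d_min: 10
  jt_min: 2
  theta_dppgc: 5
  alpha_dppgc: 0.01
```

Stage-wise subcommands (each runs exactly one module):

```bash
eccdiff simulate --seed 1 -o cohort/            # synthetic cohort + truth
eccdiff filter -i calls.tsv -o filtered.tsv     # filter -> merge -> filter
eccdiff quantify -m manifest.tsv -g genes.bed -o out/
eccdiff diff --ppgc-dir out/ -m manifest.tsv --case SLE --control HC -o dppgc.tsv
eccdiff lengths -m manifest.tsv --case SLE --control HC -o out/
eccdiff enrich --signal up.txt --background assayed.txt --gmt sets.gmt -o enr.tsv
```

All outputs are plain TSV/JSON; identical config and inputs produce
byte-identical results.

## Layout

```
src/eccdiff/
  model.py        # domain types (circles, catalogs, genes, params)
  circle_io.py    # TSV/BED/GMT/manifest readers and writers
  filtermerge.py  # mito/length filter, breakpoint merging, read filter
  quantify.py     # gene annotation, PpGC matrix, whole-gene carriage
  differential.py # DPpGC selection, specificity, fragment-vs-whole
  lengthstats.py  # counts, exact rank-sum, densities, CDFs, rhomboids
  enrichment.py   # hypergeometric ORA and gene-list overlap
  synth.py        # synthetic cohort generator with ground truth
  pipeline.py     # end-to-end driver with run manifest
  cli.py          # click CLI
```
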