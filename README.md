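# te-spread

Analysis pipeline for heterochromatin spreading from transposable-element
(TE) families into flanking low-copy DNA:

- **formats_io** — readers/writers for BED/GFF3 repeat and gene
  annotations, probe/signal TSVs, per-cytosine bisulfite reports, SAM (or
  tabular) read alignments and FASTA; all coordinates are 0-based
  half-open internally.
- **flank_profiler** — assigns single-copy probes to their unique closest
  repeat and builds per-family mean enrichment profiles in 200 bp distance
  bins, both flanks collapsed.
- **spreading_classifier** — permutation null from randomly placed
  pseudo-insertions; per-family per-bin add-one empirical p-values;
  families with p < 0.001 in every bin through 800 bp for both 5mC and
  H3K9me2 are *spreading (both)*, for H3K9me2 only *spreading (H3K9)*,
  otherwise *non-spreading*. H3K27me3 is profiled as a negative control.
- **methylation_context** — CG/CHG/CHH context calling against the genome,
  weighted percent methylation for low-copy 1 kb flanks, TE interiors and
  random-region baselines, rank-sum group comparisons and chromosomal
  positional profiles.
- **empty_sites** — detects TE insertions absent from a query haplotype
  from flank-anchored reads with long junction overhangs (>50 bp aligned
  outside, ≥94% identity, >20 bp overhang anchored ±3 bp at the boundary,
  ≤20 bp opposite tail, no junction-covering reads), then Welch-tests
  nearest-probe methylation between genotypes with/without the insertion.
- **expression_proximity** — per-gene RPKM, closest upstream TE distance
  (strand-aware), and rank-sum comparisons of expression across spreading
  classes within 500/1000/2500/5000 bp strata.
- **family_characterization** — superfamily composition, family-attribute
  comparisons, normalized chromosomal distributions and small-RNA coverage
  per family.
- **synthetic_data** — a ground-truth generator (genome, repeats, probes,
  bisulfite counts, two-haplotype reads, genes, small RNAs, attributes,
  `truth.json`) with family-specific exponential decay of flank
  enrichment, so the whole pipeline is testable offline.
- **pipeline / cli** — single-config orchestration with a JSON report and
  truth metrics.

## CLI

```sh
te-spread simulate --seed 1 --out sim/
te-spread profile --repeats sim/repeats.bed --probes sim/probes.tsv \
    --signals sim/signals.tsv --min-probes 50 --out profiles.tsv
te-spread classify --repeats sim/repeats.bed --probes sim/probes.tsv \
    --signals sim/signals.tsv --min-probes 50 --n-null 2000 --B 2000 \
    --seed 17 --out classes.tsv
te-spread bsmeth --cx sim/cx_report.tsv --genome sim/genome.fa \
    --repeats sim/repeats.bed --out bsmeth.tsv
te-spread emptysites --aln sim/hap2.sam --repeats sim/repeats.bed \
    --probes sim/probes.tsv --signals sim/signals.tsv --out empty.tsv
te-spread expression --genes sim/genes.gff3 --counts sim/counts.tsv \
    --libsizes sim/libsizes.tsv --repeats sim/repeats.bed \
    --classes classes.tsv --sample hap1_leaf --out expr.tsv
te-spread characterize --repeats sim/repeats.bed --classes classes.tsv \
    --attributes sim/attributes.tsv --smallrna sim/smallrna.bed \
    --out-prefix char
te-spread run --config pipeline.yaml   # full pipeline from one YAML
```

A minimal `pipeline.yaml`:

```yaml
outdir: out/
seed: 17
simulate: {}          # default synthetic bundle; or add families/sizes
params:
  min_probes: 50
  n_null: 2000
  B: 2000
```

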