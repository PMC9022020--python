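# pks

Strain tracking and pathway presence/absence pattern analysis for
longitudinal metagenomic cohorts.

The package combines two analyses:

- **WSS** (windowed SNV similarity): two samples' SNV calls against one
  species reference are compared per 1000-bp genome window (Jaccard over
  `(position, alt)` sets, averaged over informative windows, scaled to
  0–100). Scores above a calibrated per-species cutoff call the pair
  *related* (same strain).
- **PKS** (pathway pattern analysis): EC numbers are extracted from GFF3
  annotations (`eC_number` attributes), the minimum set of pathways
  covering them is solved exactly (MinPath-style parsimony), and each
  sample becomes a binary presence/absence vector over a *standard
  pathway list* (the union of calls across WSS-related pairs at a fixed
  read depth). Longitudinal series are scanned for clusters of time
  points with identical vectors, including extinction/reappearance
  events and whether the series resolves to a unique pattern.

Supporting stages: FASTQ quality trimming (sliding window then minimum
length), seeded subsampling (deterministic, order-preserving,
mate-consistent), rarefaction depth sweeps with plateau-based depth
selection, and synthetic generators for every input with planted ground
truth.

## CLI

`pks --help` lists all subcommands. The main ones:

```sh
# QC + subsampling
pks qc in.fastq out.fastq --min-len 50 --window 50 --min-q 20
pks subsample in.fastq out.fastq -n 5000000 --seed 1000

# strain relatedness
pks calibrate --related rel.txt --unrelated unrel.txt --species sp -o cutoffs.tsv
pks wss A.vcf B.vcf --species sp --window 1000 --cutoff-table cutoffs.tsv

# pathway calls and pattern analysis
pks pathways sample.gff --db pathway_db.tsv
pks compare pks_grid.tsv --reference last
pks clusters pks_grid.tsv -o clusters.json

# rarefaction sweep on simulated inputs
pks simulate rarefaction -o rare/
pks rarefy rare/ --depths 100,300,400 --repeats 3 --seed 1000 --tol 1.0

# synthetic fixtures and the full pipeline
pks simulate cohort -o cohort/ --seed 1000
pks run cohort/config.yaml --out results/
```

`pks run` reads a YAML config (per-sample VCF/GFF/optional FASTQ paths,
individual IDs and days, species, pathway DB, cutoff table, depth, seed,
reference policy) and writes `wss.tsv`, `pks_grid.tsv`, `clusters.json`,
`summary.tsv` and `run.log`. Re-runs with the same config and seed are
byte-identical.

### File formats

- pathway DB: two-column TSV (`map_id`, `ec_number`), one pair per line;
  partial EC numbers (`2.7.1.-`) match component-wise
- cutoff table: TSV (`species_id`, `cutoff`, `n_related`, `n_unrelated`)
- grid: TSV, rows = pathway map IDs, columns = `sample|day`, cells 0/1,
  with a leading comment line carrying species and depth

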