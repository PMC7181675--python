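# popgenkit

Population-genomic analysis of diploid biallelic SNP-array genotypes:

- **genotype_io** — binary fileset (bed/bim/fam dialect) reading/writing,
  sample/marker quality control with a reconciling removal ledger, and
  windowed LD pruning.
- **synthetic_data** — Balding–Nichols population simulation with
  within-individual inbreeding, planted autozygous (ROH) tracts, duplicate
  and parent–offspring constructions, and full ground truth for every
  downstream stage.
- **roh_detection** — runs of homozygosity under per-run SNP-count, length,
  heterozygote, missing-call, and gap constraints; cumulative length-bin
  summaries; per-SNP ROH incidence; genomic inbreeding F_ROH.
- **roh_clustering** — consensus ROH clusters (max-of-starts to min-of-ends
  over members at a coverage peak), sample-by-cluster membership, and the
  two-group homozygosity association test (Fisher exact primary, chi-square
  alongside, Bonferroni + Benjamini–Hochberg corrections).
- **selection_fst** — per-marker Weir–Cockerham theta between two groups,
  the 7-sigma-seed / 5-sigma-extension region caller with 1-Mb padding,
  and multilocus (ratio-of-sums) pairwise population fixation indices.
- **population_structure** — method-of-moments pairwise IBD (pi-hat),
  individual inbreeding f, decade trends, Welch group comparison, PCA with
  HWE-theoretical-SD normalization, and hemizygous haplotype tabulation.
- **pipeline / cli** — seeded end-to-end orchestration with per-stage
  artifacts, a manifest, and report tables.

## Command line

All verbs take a YAML config (see `popgenkit.pipeline.PipelineConfig` for
keys; defaults reproduce the published parameter choices):

```yaml
# config.yaml
simulation:
  n_pops: 2
  n_per_pop: 25
  n_chromosomes: 2
  chrom_length_bp: 20000000
  divergence_F: 0.1
  pop_labels: [ISL, USA]
  planted_roh:
    - {selector: ISL, chromosome: "1", start_bp: 2000000, end_bp: 4500000,
       carrier_fraction: 0.8}
  seed: 7
group_a: ISL
group_b: USA
out_dir: out
```

```sh
popgenkit all config.yaml            # full pipeline -> out/report.txt
popgenkit simulate config.yaml       # fileset + truth tables only
popgenkit qc config.yaml             # QC ledger
popgenkit fst config.yaml --seed 7   # stage verbs re-run deterministically
```

Use a real dataset by replacing `simulation:` with `fileset: /path/prefix`
(pointing at `.bed/.bim/.fam`).

## Conventions

Genotypes are alternate-allele counts 0/1/2 (1 = heterozygote, always) with
-1 for missing.  Coordinates are 1-based bp; intervals are inclusive of
terminal SNP positions with length = end − start.  Call-rate/MAF thresholds
are strict (`>`).  All stochastic behavior flows from a single seed.
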