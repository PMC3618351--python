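# xomap

Crossover mapping for mouse backcross designs: genotype quality control,
crossover event calling between consecutive informative SNPs, genetic-map
and group-comparison statistics, plus a synthetic-meiosis simulator with
crossover interference so the whole pipeline is testable without external
data.

The toolkit targets (C57BL/6J × BALB/c)F1 × C57BL/6J backcross cohorts
genotyped on a sparse SNP panel. Genotype calls are `B` (homozygous
C57BL/6J), `H` (heterozygous) or `N` (missing); a recombination event is a
B↔H state change between two consecutive retained SNPs on the same
chromosome. Four analysis groups are supported (`FWT`, `FKO`, `MWT`,
`MKO`), encoding the sex and genotype of the transmitting F1 parent.

## What's included

- **`xomap.model`** — marker panels, genotype matrices, TSV readers/writers
  and panel spacing summaries. A bundled 130-SNP / 19-autosome reference
  panel (111 intervals, mean gap 18.57 Mbp) ships in `xomap.datasets`,
  along with the per-chromosome crossover-count table for the four groups.
- **`xomap.simulate`** — backcross gamete simulator: stationary gamma
  renewal chiasma process on the bundle (shape `nu`, two chiasmata per
  Morgan) with 1/2 thinning, so the expected crossover count per gamete is
  `map_cM/100` for any interference strength; sex-specific per-chromosome
  maps, genotyping error and missing-call corruption, and full ground-truth
  retention for power analyses.
- **`xomap.qc`** — marker call-rate filter (> 95%), transmission-ratio
  distortion filter (exact two-sided binomial test at α = 0.01), sample
  call-rate filter (> 90%), and the two extreme missing-data scenarios
  (`conservative` = no event at a missing call, `liberal` = event-maximising
  assignment) that bracket every event total.
- **`xomap.calling`** — event calling to a samples × intervals binary
  matrix, per-chromosome counts, cM and cM/Mbp tables, group means ± SEM,
  sex-averaged rates.
- **`xomap.stats`** — Mann-Whitney group comparisons with Bonferroni
  families, Agresti-Coull 95% CIs and two-sided Fisher exact tests per
  interval (family derived from the post-QC interval set), centromeric /
  telomeric region comparisons, chromosome-size effect ratios, and
  detection power against simulator truth with a loss decomposition.
- **`xomap.pipeline` / `xomap.cli`** — an end-to-end driver
  (`simulate → qc → call → stats → summary.json`) and a `click` CLI.

## CLI

```sh
# simulate a 314-offspring cohort on the bundled panel
xomap simulate --groups FWT=79,FKO=79,MWT=78,MKO=78 --nu 10 --seed 1 \
    --out-genotypes geno.tsv --out-truth truth.tsv

# QC, event calling, statistics
xomap qc --genotypes geno.tsv --out geno_qc.tsv --report qc_report.tsv
xomap call --genotypes geno_qc.tsv --scenario conservative \
    --out-events events.tsv --out-chrom chrom_stats.tsv
xomap stats --events events.tsv --out stats_out/
xomap power --events events.tsv --truth truth.tsv

# or everything at once from a YAML config
xomap run --config config.yaml
```

A minimal `config.yaml` for a synthetic run:

```yaml
out_dir: out
seed: 1
sim:
  group_sizes: {FWT: 79, FKO: 79, MWT: 78, MKO: 78}
  interference_shape: 10
  missing_rate: 0.005
qc:
  scenario: both
```

Custom panels are TSVs with columns `chrom`, `pos_bp`, `marker_id` plus a
chromosome-size table (`chrom`, `size_mbp`); genotype tables are
`sample_id`, `group`, then one `B/H/N` column per marker in panel order.

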