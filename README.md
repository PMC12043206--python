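# core-responder

Comparative root-microbiome inference for a multi-genotype stress study:
per-genotype ("ecotype") differential-abundance calling, cross-ecotype
core-responsive ASV identification, co-occurrence network topology and
cohesion, neighbor-shift (NESH) driver-taxon detection between control and
stressed networks, and matching of ASVs to a cultured-isolate 16S database.
A synthetic-data generator with planted ground truth stands in for real
sequencing data and drives the parameter-recovery test suite.

## Layout

| Module | Purpose |
| --- | --- |
| `core_responder.io_model` | Count/design/taxonomy tables, TSV + BIOM-style JSON I/O, singleton filtering, rank aggregation |
| `core_responder.synthetic_data` | Dirichlet-multinomial community generator with planted fold effects, correlated modules, sequences, phenotypes |
| `core_responder.diversity` | Shannon/richness, Bray-Curtis, PCoA, one-factor + sequential PERMANOVA, pairwise contrasts |
| `core_responder.differential` | Exact/approximate rank-sum and Welch tests, per-ecotype DA, core-responsive calls, tolerant-vs-sensitive fold contrast |
| `core_responder.network` | Spearman co-occurrence networks (abundance/prevalence/|rho|/FDR filters), topology metrics, cohesion |
| `core_responder.netshift` | NESH scoring, driver identification, cross-ecotype core-driver aggregation |
| `core_responder.strain_match` | Semi-global identity, dereplication, greedy 97% OTU clustering, ASV matching |
| `core_responder.phenotype` | Wilting index, relative fresh weight, microbiome protection effect |
| `core_responder.pipeline` | End-to-end orchestrator with per-stage seeded substreams and a JSON run log |

## CLI

Full run from a config file:

```sh
core-responder run --config config.yaml
```

Minimal config (omit `input:` to synthesize data; all thresholds shown are
the defaults):

```yaml
seed: 0
synthetic:
  n_ecotypes: 10
  n_reps: 4
  n_taxa: 300
  n_bulk_reps: 4
sequences: {n_isolates: 50, divergence: 0.01}
thresholds:
  abundance_min: 0.001   # DA candidate filter (0.1%)
  alpha: 0.05
  k_core: 5              # ecotypes required for a core call
  f_min: 1.2             # fold threshold for core enrichment
  net_abund_min: 0.002   # network candidate filter (0.2%)
  rho_min: 0.9
  q_max: 0.05
  id_min: 0.97
output_dir: results/run
```

To analyze real data instead, point `input:` at files:

```yaml
input:
  counts: counts.tsv       # samples x taxa; header starts with sample_id
  design: design.tsv       # sample_id, ecotype, treatment, tolerance_class, replicate
  taxonomy: taxonomy.tsv   # taxon_id + 7 rank columns
  asv_fasta: asvs.fasta    # optional, enables isolate matching
  isolate_fasta: isolates.fasta
```

Stage subcommands: `simulate`, `diversity`, `differential`, `network`,
`netshift`, `match` (see `core-responder <cmd> --help`).

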