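# transomic

Trans-omic upstream-regulator discovery pipeline: from differential
transcript/protein tables through promoter binding-site enrichment,
composite-module optimisation and master-regulator network search, to
druggability ranking.  A seeded synthetic-data generator produces every
input with planted structure, so the whole chain is testable offline.

## Pipeline stages

1. **diff** — Benjamini–Hochberg significance calling per omics layer,
   transcript–protein concordance classes, top-N gene selection.
2. **enrich** — PWM scanning of fixed 1100 bp promoters (−1000..+100
   relative to the TSS) on both strands with min–max-normalised log-odds
   scores; one-sided Fisher enrichment of the Yes (differential) vs No
   (unchanged) promoter sets with BH control across matrices.
3. **cma** — genetic-algorithm search for a weighted cluster of ≤10
   matrices inside a 200–300 bp sliding window that minimises the
   one-sided Wilcoxon rank-sum p-value separating Yes from No promoter
   scores; per-TF regulatory scores by drop-one contribution.
4. **master** — bounded-radius (default 12 steps) reverse reachability
   from the discovered TFs in a directed signaling network; key-node score
   `sum(1/(1+d))`; empirical significance by resampling same-size TF sets
   (default 10,000 runs) with BH-controlled FDR; total rank fuses key-node,
   module and omics evidence.
5. **drugs** — curated drug ranking (target-activity, disease-activity and
   clinical-validity components) and PASS-style predicted scoring from
   precomputed activity probabilities (Pa), yielding per-gene druggability
   scores.

Up- and downregulated gene sets run as two independent passes sharing one
No set, producing paired TF / master-regulator reports.

## CLI

Generate a synthetic bundle (all input files plus a `truth.json` manifest
of planted signal):

```sh
transomic synth --seed 1 --out data/
```

Run the full pipeline from a YAML config:

```sh
transomic run --config config.yaml [--seed N] [--fast] [--from-stage cma]
```

Minimal config:

```yaml
seed: 1
out_dir: results
inputs:
  transcriptome: data/transcriptome.tsv
  proteome: data/proteome.tsv
  promoters: data/promoters.fasta
  pwms: data/pwms.transfac
  network_edges: data/network_edges.tsv
  network_nodes: data/network_nodes.tsv
  drug_targets: data/drug_targets.tsv
  compound_activities: data/compound_activities.tsv
  gene_weights: data/gene_weights.tsv
```

Per-stage blocks (`significance`, `enrichment`, `cma`, `master`, `drugs`)
override defaults; unknown keys are rejected.  Identical config + seed
produces byte-identical reports.  `--from-stage` resumes from artifacts on
disk; stage subcommands (`transomic diff|enrich|cma|master|drugs`) do the
same.

## Acceptance

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The script runs the seeded synthetic bundle through every stage and writes
the acceptance target map.  There are no numeric point targets for this
artifact (the source study's numbers depend on unavailable data and
proprietary databases), so the map is empty and acceptance is the
property-based suite in `tests/test_acceptance.py`: scanner and
reachability oracle equivalence, exact small-sample statistics,
planted-motif / composite-module / master-regulator recovery, druggability
formula exactness, and end-to-end determinism.

## File formats

- differential tables: TSV with `id`, `logFC`, `p` columns
- PWM library: TRANSFAC-style flat file (`ID`/`BF` lines, numbered count
  rows, `//` terminators; frequency matrices accepted)
- promoters: FASTA, 1100 bp per record (optional 5′ N-padding of short
  records)
- network: edge TSV (`source`, `target`, `label`) plus node TSV (`node`,
  `gene_symbols`, `is_tf`)
- drug/compound tables: TSV; compound activities carry class
  (`mechanism`/`disease_effect`/`toxicity`), Pa and mapped genes, with a
  separate per-gene IAP/optWeight table

All writers emit a commented header recording package version, config hash
and seed.
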