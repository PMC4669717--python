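# cmapscreen

A signature-reversal drug repurposing screen, packaged as a tested,
reproducible pipeline:

1. **expression** — read/validate case-vs-control expression matrices
   (TSV or GCT v1.2, log2 scale), quantile-normalize, and restrict probes to
   a query platform list.
2. **signature** — volcano selection of up/down probe tags by pooled-variance
   two-sample t-test (default P < 1e-4) and fold change (default fourfold,
   measured as the difference of group means on the log2 scale).
3. **connectivity** — score the signature against a compendium of
   drug-treatment rank profiles with a signed KS tag statistic: per-instance
   enrichment `es = ks_up − ks_down` (zero when both sides share a sign),
   instance scores scaled into [−1, 1], drug-level KS enrichment over the
   score ordering, and an exact or seeded Monte-Carlo p-value under the
   random-position null. A drug is a *hit* when its enrichment is negative
   (treatment reverses the disease signature) and p < 0.05.
4. **fusion** — union per-cohort hit lists with support counts and Venn
   region sizes, plus functional-category annotation.
5. **synthetic** — generators for cohorts and compendia with planted ground
   truth (differential probes; "reverser"/"mimicker" drugs), pure functions
   of their seeds, so every stage is testable without any downloads.

## CLI

`cmapscreen` exposes `simulate`, `signature`, `query`, `fuse` and `run`.
The quickest end-to-end tour is a synthetic screen:

```sh
cmapscreen simulate --seed 11 --out demo           # 5 cohorts + compendium + config.yaml
cmapscreen run --config demo/config.yaml --out demo/results
```

`run` writes, per cohort, the signature (`<cohort>_up.grp`, `<cohort>_dn.grp`,
`<cohort>_stats.tsv`) and connectivity reports (`<cohort>_instances.tsv`,
`<cohort>_drugs.tsv`), then `fusion.tsv`, `venn.tsv` and a `manifest.json`
(config echo, seed, versions, per-stage counts) that makes reruns
byte-identical under a fixed seed.

Individual stages run standalone, e.g.:

```sh
cmapscreen signature --matrix cohort.tsv --labels cohort_labels.tsv \
    --platform platform.txt --name c1 --out sig/
cmapscreen query --up sig/c1_up.grp --down sig/c1_dn.grp \
    --ranks compendium_ranks.tsv --instances compendium_instances.tsv \
    --name c1 --seed 1 --out query/       # add --exact-p or --mc-p to force a p mode
cmapscreen fuse query/*_drugs.tsv --out fused/
```

### Config file

```yaml
cohorts:
  - {id: cohort1, matrix: cohort1.tsv, labels: cohort1_labels.tsv}  # format: tsv|gct
platform: platform.txt            # optional probe list
compendium: {ranks: compendium_ranks.tsv, instances: compendium_instances.tsv}
thresholds: {p_signature: 1.0e-4, fold: 4.0, p_drug: 0.05}
normalize: none                   # none | quantile | log2_quantile
n_permutations: 10000
p_mode: auto                      # auto | exact | permutation
seed: 11
```

Relative paths resolve against the config file's directory.

## File formats

- **Expression**: TSV (`probe_id` + one column per sample) or GCT v1.2, with
  a two-column `sample_id<TAB>group` label file (`case`/`control`).
- **Signature**: GRP tag lists (one probe id per line) + a stats TSV
  (`probe_id, mean_case, mean_control, delta_log2, t, p`).
- **Compendium**: ranks TSV (`probe_id` + one integer column per instance,
  rank 1 = most up-regulated by treatment) + instance metadata TSV
  (`instance_id, drug, ...`); per-drug instance sets exportable as GMT.
- **Reports**: per-instance and per-drug TSVs, fusion/venn TSVs.

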