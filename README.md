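# capcontact

Fragment-level Capture-C interaction quantification with windowed
paired-rank differential testing, spike-in reference-normalized ChIP
quantification, super-/typical-enhancer classification, and a truth-tagged
synthetic-data generator so the whole pipeline is testable end to end
without any external downloads.

## What it does

- **`capcontact.fragmap`** — in-silico restriction digestion (cut 5′ of every
  motif occurrence, DpnII `^GATC` convention) into gapless fragment maps
  (0-based half-open, BED4), and normalization of per-fragment interaction
  counts to a fixed number of reported cis reads per
  (viewpoint, replicate, condition) after removing the ±1 kb probe exclusion
  zone. Trans fragments are flagged, never dropped.
- **`capcontact.diffloop`** — the core statistic: 10 kb windows centered on
  binding peaks; trans/domain/probe-proximity filters; a two-sided Wilcoxon
  signed-rank test on (fragment, replicate) pairs (exact DP null for ≤ 25
  pairs, tie- and continuity-corrected normal approximation beyond; zero
  differences dropped; ≥ 5 nonzero pairs required); Holm–Bonferroni
  adjustment over the pooled tested family; per-replicate and mean log2
  fold-changes; family summaries; and the feature-vs-interaction enrichment
  ratio over interaction domains.
- **`capcontact.chipnorm`** — spike-in (two-genome) reference normalization
  factors, per-10⁷ track scaling, interval quantification, metaprofiles,
  promoter/enhancer score ranking, and Pearson correlation with
  average-linkage clustering of datasets.
- **`capcontact.enhancers`** — peak stitching (edge-to-edge gap ≤ 12.5 kb),
  super-enhancer calling by the scaled-rank slope rule, typical-enhancer
  definition (H3K27ac ∩ H3K4me1, > 1 kb from any TSS, outside SEs),
  nearest-TSS gene assignment, 1 kb eRNA windows at intergenic accessible
  sites, and SE-vs-TE rank-sum response comparisons.
- **`capcontact.simgen`** — deterministic synthetic data: geometric fragment
  maps (optionally with sequences that digest back to the map exactly),
  power-law distance-decay contact profiles with domain contrast, localized
  enhancer windows and multiplicative treatment effects, negative-binomial
  replicate noise, two-genome spike-in mixtures with a planted depletion
  factor, bimodal SE/TE signal, and class-dependent eRNA responses — each
  with a truth table.
- **`capcontact.iohub`** — BED/bedGraph/TSV readers and writers, YAML run
  configuration, and the orchestrated pipeline with a checksummed run report.

## CLI

```bash
capcontact simulate  --config cfg.yaml       # generate synthetic inputs
capcontact digest    --fasta genome.fa --motif GATC --out fragments.bed
capcontact diff      --config cfg.yaml       # normalize + windowed testing
capcontact chip-norm --spike spike.tsv --reference dmso --out factors.tsv
capcontact enhancers --peaks peaks.bed --out stitched.tsv
capcontact erna      --counts erna.tsv --out erna_summary.tsv
capcontact report    --config cfg.yaml       # full pipeline + report.json
```

Exit codes: 0 success, 2 configuration/parse error, 1 computation error.

A config file names either a `simulate` block (synthetic inputs are
generated under `<outdir>/inputs/`) or a `paths` block pointing at existing
files, plus a `design` block (conditions, comparisons) and optional `params`
overrides (window width, minimum pairs, pseudocount, alpha, normalization
scale, stitch distance). See `tests/test_iohub.py::BASE_CONFIG` for a
complete example. Results land in `<outdir>/results/`:
`interactions_norm.tsv`, `diff_<b>_vs_<a>.tsv`, `diff_summary.tsv`,
`spike_factors.tsv`, `stitched_enhancers.tsv`, `erna_class_response.tsv`,
and `report.json` with sha256 checksums of every output.

## File formats

All text, tab-separated, UTF-8, 0-based half-open; comments start with `#`.
Fragment maps are BED4 (`chrom start end fragment_id`), peaks/domains are
BED (domain names carry the owning viewpoint), signal tracks are bedGraph
(with `#depth=` / `#scale_state=` headers), interaction tables are TSV with
columns `viewpoint fragment_id chrom start end replicate condition
raw_count norm_count flags`.
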