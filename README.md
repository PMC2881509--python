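# overlapkit

Gene-list overlap analysis for two-group expression studies:

- **`overlapkit.dge`** — per-gene one-sided (upper-tail) t-tests for
  upregulation (Welch by default, pooled by flag) and strict-cutoff up-list
  construction, optionally with a linear fold-change filter and optional
  Benjamini–Hochberg adjustment.
- **`overlapkit.setops`** — hypergeometric upper-tail significance of
  gene-list intersections over a caller-supplied universe, 2/3-list Venn
  region counts, and cross-species symbol harmonization (case-folding plus
  optional ortholog maps). Tail sums are computed in log space from
  log-gamma binomials, so genome-scale configurations do not overflow.
- **`overlapkit.enrichment`** — GMT parsing and an overlap-counting
  enrichment scan of a query list against a gene-set collection, scored with
  the same hypergeometric p-value (no rank statistic).
- **`overlapkit.panels`** — curated gene panels (packaged as TSV fixtures
  with printed p-value strings and membership flags) cross-tabulated against
  reference gene lists.
- **`overlapkit.simulate`** — planted-truth simulator: two-group Gaussian
  log2-intensity matrices with a configurable fraction of upregulated genes,
  and paired studies sharing a controlled planted overlap.
- **`overlapkit.pipeline`** — end-to-end orchestration (simulate → tests →
  lists → overlap/Venn → enrichment → panels → heatmap row selection) with a
  deterministic plain-text output bundle and a JSON manifest.

Expression values are log2-scale throughout; fold changes are reported both
as log2 differences and linear ratios (`FC > 2.0` means ratio > 2.0).

## CLI

All subcommands read/write plain text (TSV tables, GMT collections,
one-identifier-per-line gene lists):

```sh
overlapkit simulate --genes 2000 --n1 25 --n2 25 --frac-up 0.1 --effect 2.0 \
    --noise-sd 0.5 --shared-frac 0.5 --seed 1 --paired --out-dir sim/
overlapkit dge --matrix sim/matrix_a.tsv --groups sim/groups_a.tsv \
    --alpha 0.05 --out sim/dge_a
overlapkit overlap --list-x sim/dge_a.up.txt --list-y sim/dge_b.up.txt \
    --universe sim/universe.txt --out sim/overlap
overlapkit venn --lists sim/dge_a.up.txt,sim/dge_b.up.txt \
    --universe sim/universe.txt --out sim/venn.tsv
overlapkit enrich --query sim/dge_a.up.txt --gmt sets.gmt \
    --universe sim/universe.txt --out sim/enrichment.tsv
overlapkit panel --name collagen_tumor --out xtab.tsv
overlapkit heatmap --matrix sim/matrix_a.tsv --groups sim/groups_a.tsv \
    --other sim/dge_b.up.txt --fc 1.5 --alpha 0.05 --out heatmap.tsv
overlapkit run --genes 2000 --seed 1 --panels collagen_tumor --out-dir run/
```

`overlapkit run` also accepts `--config file` with flat `key = value` lines
(keys: `genes, n1, n2, frac_up, effect, noise_sd, shared_frac, alpha, fc,
heatmap_fc, heatmap_alpha, gmt, panels, seed, no_sim`); CLI flags override
file values.

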