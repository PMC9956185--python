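# ecoassembly

Community-ecology analysis of OTU tables: alpha/beta diversity, NMDS
ordination, environment correlations, geographic distance-decay, and
two-stage null-model quantification of community assembly processes
(phylogenetic βNTI stage followed by a Raup–Crick Bray–Curtis stage), plus a
synthetic metacommunity generator that makes every stage testable without
external data.

## What it computes

| Stage | Contents |
| --- | --- |
| `ecoassembly.io` | OTU table / metadata / taxonomy I/O, relative-proportion transform, strict 90/90 taxonomy filter, >1% dominant-group aggregation, DO < 2 mg/L hypoxia flag |
| `ecoassembly.diversity` | Shannon index (natural log), Welch t-test, one-way ANOVA, Spearman environment correlations, Bray–Curtis, nonmetric MDS (SMACOF with pool-adjacent-violators monotone regression, Kruskal stress-1, seeded restarts) |
| `ecoassembly.spatial` | haversine distance matrices, distance-decay of similarity (1 − Bray–Curtis vs km) with a Mantel-style label-permutation p-value |
| `ecoassembly.assembly` | patristic distances, abundance-weighted βMNTD, βNTI against a taxa-shuffle null, Raup–Crick with Bray–Curtis (occurrence-weighted richness draw, abundance-weighted allocation), per-pair process classification (&#124;βNTI&#124; > 2, &#124;RC&#124; > 0.95) and per-stratum process fractions |
| `ecoassembly.simulate` | birth–death trees, Brownian niche optima, estuarine-gradient landscapes, OTU tables under four assembly regimes (selection, dispersal limitation, homogenizing dispersal, drift) |
| `ecoassembly.pipeline` | end-to-end orchestration with validation, per-stage TSV outputs, JSON manifest (inputs, checksums, seed) and a human-readable summary |

## CLI

```bash
# generate a synthetic scenario
ecoassembly simulate --regime dispersal_limitation --n-taxa 300 --seed 7 --out scenario/

# individual stages
ecoassembly diversity alpha --otu scenario/table.tsv --out alpha.tsv
ecoassembly diversity nmds  --otu scenario/table.tsv --seed 42 --out nmds.tsv
ecoassembly spatial decay   --otu scenario/table.tsv --meta scenario/meta.csv \
    --layer surface --permutations 999 --seed 42 --out decay.json
ecoassembly assembly run    --otu scenario/table.tsv --tree scenario/tree.nwk \
    --meta scenario/meta.csv --reps 999 --seed 42 --out assembly/

# everything at once (flags override --config TOML values)
ecoassembly pipeline run --otu scenario/table.tsv --tree scenario/tree.nwk \
    --meta scenario/meta.csv --out results/run1 --reps 999 --seed 42
```

Pipeline exit codes: 0 ok, 2 validation failure, 3 stage failure.  Reruns of
the same configuration and inputs are byte-identical; pairwise null-model
computations use per-pair derived seeds, so `--n-jobs` parallelism matches
serial execution bitwise.

## Input formats

* **OTU table** — TSV, taxa as rows (first column ids, header row sample
  ids); transposed tables are auto-detected or forced with `orientation`.
* **Tree** — rooted Newick with branch lengths; tip labels match OTU ids.
* **Metadata** — CSV with `sample_id`, `site_id`, `layer`
  (surface/bottom), `latitude`, `longitude`; any further numeric column is
  treated as an environmental variable (e.g. DO, salinity, turbidity, TALK,
  depth, offshore_distance).
* **Taxonomy** (optional) — TSV with `taxon_id`, `lineage`,
  `percent_identity`, `percent_coverage`.

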