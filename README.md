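# cagscape

Co-abundance group (CAG) discovery and host-association statistics for 16S
rRNA microbiome cohorts.

Gut-microbiome cohorts often fail to split into the discrete community
types ("enterotypes") that early studies promised: composition instead
varies smoothly along a gradient.  `cagscape` implements the inference
chain for working in that regime.  Starting from a sample × OTU abundance
table (plus a phylogenetic tree, taxonomy and host metadata), it

1. tests discrete-cluster support by scanning partitioning-around-medoids
   solutions over k = 2..20 on √Jensen-Shannon and UniFrac distances and
   scoring them with the average silhouette index (SI < 0.50: no support;
   the gradient alternative correlates each abundant OTU with the leading
   PCoA axes);
2. groups the abundant OTUs (across-sample median abundance ≥ 0.01%) into
   **co-abundance groups** — consortia of positively co-varying OTUs — by
   Ward clustering of `1 − ρ` on the pairwise Spearman matrix, validated
   by a split-half Mantel test and a SparCC compositional network;
3. selects **single-CAG-dominated** samples (one and only one CAG at or
   above its cohort-wide 95th percentile) and measures their separability
   with the out-of-bag accuracy of a 1,000-tree bagged ensemble;
4. links CAG structure to host variables (PERMANOVA on distance matrices,
   ANOVA-on-logs + Tukey and chi-squared group profiles, whole-cohort
   Spearman correlations, one-sided marker-genus t-tests, all BH-FDR
   adjusted) and to inferred community function (projection through a
   per-OTU genome-content table, module collapse, ternary coordinates,
   Kruskal-Wallis tests).

Because real deposited cohorts need upstream read processing that is out
of scope here, the package ships a first-class **synthetic-cohort
generator** (`cagscape.synthetic_data`) that plants known structure —
five co-abundance blocks with heavy-tailed activities, a low-diversity
"pathogen-like" block, covariate effects, block-coherent phylogeny,
block-exclusive marker functions — and records the ground truth, so every
stage of the chain is tested by recovery.

## Worked example

```python
import cagscape as cs

cfg = cs.SimulationConfig(seed=42)          # 441 samples, 120 OTUs, 5 blocks
bundle = cs.simulate_all(cfg)

rel = cs.to_relative(bundle.table)
abundant = cs.filter_by_median_abundance(rel, 1e-4)   # median >= 0.01%
print(f"retained OTUs: {abundant.n_otus}")

jsd = cs.jsd_sqrt_matrix(rel)
scan = cs.enterotype_scan(jsd, 2, 20)
print(f"max silhouette over k=2..20: {scan.best_si:.3f} -> verdict: {scan.verdict}")

rho = cs.spearman_coabundance(abundant)
model = cs.ward_cags(rho, abundant, 5)
print("CAGs:", ", ".join(model.names))

mantel = cs.split_half_mantel(abundant, n_perm=1000, n_boot=1000, seed=1)
print(f"split-half Mantel r = {mantel.r:.3f} "
      f"[{mantel.ci_lower:.3f}, {mantel.ci_upper:.3f}], p = {mantel.p_value:.4f}")

sel = cs.select_dominated(model.profile, percentile=95)
print(f"single-CAG-dominated samples: {len(sel.selected)} of {bundle.table.n_samples}")

report = cs.reclassify(abundant, sel, n_trees=1000, seed=2)
print(f"out-of-bag reclassification accuracy: {report.oob_accuracy:.1%}")
```

Output:

```
retained OTUs: 100
max silhouette over k=2..20: 0.155 -> verdict: none
CAGs: OTU_031-CAG, OTU_058-CAG, OTU_014-CAG, OTU_069-CAG, OTU_090-CAG
split-half Mantel r = 0.945 [0.934, 0.956], p = 0.0010
single-CAG-dominated samples: 115 of 441
out-of-bag reclassification accuracy: 100.0%
```

Reading it: of 120 simulated OTUs the 0.01% median-abundance rule keeps
100; the silhouette never approaches the 0.50 support threshold, so the
cohort is a gradient, not a set of enterotypes; Ward clustering recovers
five CAGs (each named after its top-median member OTU) whose correlation
structure reproduces across random cohort halves (Mantel r = 0.945,
permutation p at its 1/1001 floor); 115 of 441 samples are dominated by
exactly one CAG (≈ 5% per CAG, no overlaps), and those five dominated
groups are perfectly separable from OTU profiles alone.  On this seeded
cohort the discovered CAGs match the planted blocks exactly (adjusted
Rand index 1.0 — see `scripts/acceptance.py`).

## Command line

Every stage is also a `cagscape` subcommand operating on TSV/newick files:

```bash
cagscape simulate --seed 3 --output sim/
cagscape diversity --input sim/table.tsv --tree sim/tree.nwk --output div/
cagscape enterotype --distance div/distance_sqrt_jsd.tsv --output ent/
cagscape cags --input sim/table.tsv --output cags/
cagscape dominance --profile cags/cag_profile.tsv --input sim/table.tsv --output dom/
cagscape run-all --seed 3 --output run/     # the whole chain + manifest
```

`run-all` writes a `manifest.json` with parameters, per-stage seeds
(derived by hashing the master seed with the stage name) and SHA-256
checksums of every output, so reruns are verifiably identical.

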