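# trophoscape

Tools for analysing the **community trophic structure of large mammals** (or
any assemblage) across a geographic grid: which feeding guilds exist, which
recurring guild configurations ("trophic structures") communities fall into,
how those structures track climate, and where human impacts have pushed them
into simpler states.

The package is aimed at macroecologists working with species × diet tables
and gridded presence/absence data. It ships synthetic-data generators that
emulate the statistical structure of such data, so the whole pipeline runs
and is testable end to end with no downloads.

## The core statistic: average membership degree (AMD)

Whether well-defined community types exist — and how many — is decided with
fuzzy c-means clustering plus a validity index on its memberships. For a
partition of n samples into c fuzzy clusters with memberships u_jk,

```
AMD = (1/n) Σ_j max_k u_jk − 1/c
```

the mean membership of each sample to its nearest cluster, minus the chance
level 1/c. Structureless data give AMD ≈ 0; crisp clusters push it toward
1 − 1/c. Scanning c over a range with many random restarts per value and
keeping the best-AMD solution, the argmax of the curve is the number of
clusters actually present, and the peak height measures how well defined
they are.

Around that core the package provides:

* `fuzzy_core` — vectorised fuzzy c-means, the AMD index, the restart scan;
* `guilds` — trophic guild inference from species × resource diet
  percentages, with heuristic or explicit guild naming;
* `structures` — cell × guild trophic space, low-human-impact filtering,
  structure classification, random-forest interpolation to remaining cells,
  and a PCA decomposition of richness;
* `climate_tree` — globally optimised classification trees (evolutionary
  search over split variables and thresholds, complexity-penalised), plus a
  greedy CART baseline and threshold reports;
* `transitions` — observed-vs-climate-predicted comparison, disagreement
  typing (type I: depauperate where boreal/temperate is expected; type II:
  semi-arid where tropical is expected; islands), Cohen's kappa, Student's
  t tests and impact trees on human-impact indicators;
* `networks` — bipartite resource → guild energy-flow networks with
  conserved fluxes, exported as GraphML/GEXF/CSV;
* `synthetic_data` / `pipeline` / `cli` — generators, the one-command
  end-to-end run, and the `trophoscape` command-line tool.

## Worked example

Plant six Gaussian clusters in an 11-dimensional space and ask the scan how
many there are:

```python
from trophoscape.synthetic_data import generate_cluster_benchmark
from trophoscape.fuzzy_core import amd_scan

bench = generate_cluster_benchmark(n=2000, d=11, k=6, sd=1.0, seed=42)
scan = amd_scan(bench.samples, c_min=2, c_max=9, replicates=30, seed=0)
print(scan.amd_curve.to_string(index=False))
print("selected_c:", scan.selected_c)
```

```
 c  best_amd  replicates
 2  0.224990          30
 3  0.342035          30
 4  0.443690          30
 5  0.505011          30
 6  0.559233          30
 7  0.503430          30
 8  0.448400          30
 9  0.422028          30
selected_c: 6
```

The curve peaks exactly at the planted cluster count, and the peak height
(0.56 here) reflects how crisply the clusters are defined — tighter clusters
raise it, fuzzier ones lower it.

The full synthetic pipeline — simulate diets and a gridded world, infer 11
guilds, detect structures on low-impact cells, interpolate the rest, fit the
climate tree, type the transitions and export the energy networks — is one
command:

```bash
trophoscape run --seed 7 --n-cells 3000 --out-dir my_run
```

Outputs land in `my_run/`: the guild assignment, the AMD curve, the per-cell
structure classification with membership degrees and provenance, the climate
tree with its threshold report, the transition map with kappa and t-test
tables, per-structure GraphML networks, and a `manifest.json` whose
checksums make the run bit-reproducible.

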