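# Methods

`trophoscape` reconstructs, as a reusable pipeline, an analysis of how the
trophic structure of large-mammal communities is organised across the globe:
species are grouped into feeding guilds from their diets, grid cells are
grouped into recurring community trophic structures from their guild
composition, structures are related to climate through threshold models, and
departures of the observed structures from their climatic expectation are
attributed to human impacts. This note documents the models, the tunable
parameters, the synthetic data that stands in for the original global
datasets, and the numerical choices made where the design was open.

## Fuzzy c-means and the AMD validity index

All clustering uses fuzzy c-means under squared Euclidean distance. For
samples x_j and centres v_k, memberships follow the standard update

    u_jk = 1 / Σ_l (||x_j − v_k||² / ||x_j − v_l||²)^(1/(m−1)),

centres are the u^m-weighted means, and the objective J = Σ_jk u_jk^m
||x_j − v_k||² is non-increasing across iterations (asserted in tests).
Defaults: fuzzifier m = 2 (the common default of c-means implementations;
the analysis this package reimplements did not state one), convergence when
the relative change of J drops below 1e-9 or after 300 sweeps,
initialisation by drawing c distinct sample rows, replicate r seeded as
`base_seed + r`. A sample coinciding with a centre receives membership 1 to
the first such centre and 0 elsewhere. If the data hold fewer distinct rows
than clusters the fit is flagged `converged=False` rather than crashing.

The average membership degree index of a partition is

    AMD = (1/n) Σ_j max_k u_jk − 1/c,

the mean membership of each sample to its nearest cluster (the one of
maximal membership; identical to the nearest centre under c-means), minus
the chance level 1/c. AMD is 0 for structureless data and approaches
1 − 1/c for crisp clusters; it is provably confined to [0, 1 − 1/c]
because a row maximum is at least the row mean. The cluster-count scan runs
many restarts per candidate c (200 by default), keeps the highest-AMD
replicate per c, and selects the c with the highest best AMD, breaking ties
toward the smaller c (parsimony). Restart batches are vectorised across
replicates; results are identical to sequential fits.

**Known limitation (dimensionality).** Cluster-count detection by AMD relies
on multidimensional geometry: a split boundary placed inside a true cluster
must cross dense mass and blur memberships. In one dimension this fails —
subdividing a tight 1-D Gaussian still produces crisp intervals, and the
best-of-replicates AMD curve rises monotonically with c (measured 0.50,
0.62, 0.68, 0.73 for c = 2..5 on two 1-D clusters at distance 100σ). The
same two-cluster configuration in 11 dimensions is detected correctly. The
scan therefore exposes the full AMD-vs-c curve rather than only the argmax,
and the curve should be read, not trusted blindly, in very low dimension.
Secondary local maxima (e.g. coarse groupings nested above finer ones) are
likewise left to the user's interpretation.

## Synthetic data

The package is exercisable end to end without any external data; the
generators emulate the statistical structure of the original global data
sets at three levels.

**Cluster benchmark.** n = 8000 samples (d = 11, k = 6 by default) around
centres drawn i.i.d. uniform per dimension. The centre box defaults to
[0, 11]: the convention was frozen after brute-force simulation showed that
with this box the best-of-restarts AMD peak sits at ≈ 0.6 for within-cluster
sd 1 and ≈ 0.39 for sd 1.7 (the two definition levels the validation is
meant to reproduce); [0, 10] gave 0.60/0.33 and [0, 12] gave 0.64/0.43.

**Diet matrices.** Eleven guild archetypes over the 12 printed resource
codes (grass gr, leaves lv, fruits fr, flowers fw, forbs fb, seeds sd,
invertebrates inv, fish fs, small vertebrates sv, and mammals in three mass
classes sm/mm/lm); the resource schema is configurable up to the full
19-resource set. Species diets are archetype + Gaussian noise (default sd 5
percentage points), clipped at zero and renormalised to sum to 100. Rows
loaded from files must sum to 100 within ±0.5 before renormalisation;
offending species are reported, not silently fixed.

**Gridded world.** Each cell carries 19 bioclim-style variables. Only the
five named drivers matter — mean annual temperature (bio1), isothermality
(bio3), temperature seasonality (bio4), maximum temperature of the warmest
month (bio5), annual precipitation (bio12) — wired to the true structure
label by a planted decision tree with the thresholds 17.6 °C, 21.3/46.8
(isothermality), 11.6 °C, 10.9 (seasonality) and 144/588/1608 mm; the
remaining 14 variables are correlated noise so that the tree learner's
variable selection is genuinely exercised. Climate is sampled uniformly
within each leaf's bounding box, with cells allocated to leaves
proportionally to realistic label weights (every leaf represented). Guild
counts are Poisson around per-structure archetype means (negative-binomial
under an overdispersion knob). The archetype table was tuned once so that
mean between-archetype distance exceeds 3× the mean within-structure Poisson
sd (ratio 1.10) — the separation needed for the scan to detect the planted
count — while preserving the qualitative contrasts: semi-arid richest
(~76 species) and omnivore/grazer/plant-feeder-led, humid tropical
frugivore-led, seasonal tropical led by small carnivores and invertebrate
feeders, temperate plant-feeder-led, boreal omnivore-led and poor, and
depauperate nearly empty (~3).

Human impacts: a cell is "impacted" with probability 0.3; impacted and
unimpacted cells draw the six indicators (cropland, pasture, primary and
secondary vegetation, urban %, population density) from different ranges.
Degradation rules transform the true into the observed label: boreal or
temperate cells with urban ≥ 5 %, cropland ≥ 54 % or primary < 1 % become
depauperate; seasonal- or humid-tropical cells with population > 3.6
hab/km² become semi-arid; islands (5 % of cells by default) are always
observed depauperate. Unimpacted cells are constructed to pass the
low-impact filter (primary ≥ 25 %, urban < 0.003 %, population < 26
hab/km²) and impacted cells to fail it, so the filtered calibration set is
clean by design — as in the original study design, which restricted
structure identification to low-impact cells.

**What the generators do not emulate:** spatial autocorrelation of climate
or land use, coastlines and realistic island geography, species-level range
cohesion (presences are drawn independently per cell given the guild
counts), collinearity structure of the real bioclim set, and
literature-derived diet uncertainty. Passing tests therefore demonstrate
that the algorithms recover planted structure under the stated statistical
conditions, not that the original ecological findings are reproduced.

## Guilds and structures

Guild inference clusters diet vectors with best-of-50-restart c-means
(lowest objective kept) and hard-assigns each species to its
maximal-membership guild; display names come from dominant-resource
heuristics (e.g. a fish-dominated centre is the piscivore guild PS) with a
mandatory explicit-override path, since naming is ultimately expert
judgement. The trophic space counts species per guild per cell; cells with
zero species are retained as zero rows (they are real depauperate
candidates; exclusion is configurable). Structure classification runs the
AMD scan (or a fixed c) on the low-impact cells; remaining cells are
interpolated with a random forest on the guild-count vectors. Forest
settings are pinned (500 trees, √p features per split, seeded) because
"default" settings differ across ecosystems and reproducibility was judged
more important than fidelity to an unstated default; an interpolated cell's
membership degree is the forest's vote fraction, flagged
`provenance="interpolated"`.

The richness decomposition is a PCA of the cells × guilds matrix with
column centring only — no variance scaling — so that the first axis keeps
its species-count interpretation; both the per-axis variance shares and
r²(axis-1 scores, richness) are reported.

## Evolutionary classification trees

Climate–structure and impact–transition models are axis-aligned binary
trees fitted by a genetic algorithm over the joint space of split variables
and thresholds, with fitness = training misclassification rate + α ×
n_leaves (minimised). Candidate thresholds are midpoints between
consecutive distinct feature values ("all possible thresholds" over a
finite set); routing is `< threshold` left, `≥` right, fixed and
documented. Leaf labels are always the majority class, so the genome is
structure + thresholds only; splits whose children would fall under the
minimum leaf size are collapsed on the fly. Defaults: population 200, 500
generations with early stop after 100 stall generations, tournament size 4,
crossover 0.6, threshold/variable/prune/grow mutations, α = 0.01 (one extra
leaf must buy ≥ 1 % accuracy — the parsimony stance of the analysis),
max depth 5, min 5 samples per leaf. Elitism keeps the best individual;
its fitness trace is recorded and is monotone non-increasing. Misclassification
(not Gini) is the impurity because classification agreement is what the
tree is asked to optimise; islands are excluded from climate-model
calibration, mirroring the study design. A greedy CART-style learner under
the same constraints, fitness, candidate thresholds and routing serves as
the locally-optimal baseline; on lattice checkerboard (XOR) data no single
split reduces its error while the evolutionary learner solves the problem
exactly. On tiny two-feature instances the evolved fitness is checked
against an exhaustive depth-2 global optimum.

## Transitions and agreement

Observed-vs-predicted disagreements are typed: type I (observed
depauperate, predicted boreal or temperate), type II (observed semi-arid,
predicted seasonal or humid tropical), island (overrides everything),
none, other. Agreement is Cohen's kappa with marginal-product chance
agreement. Indicator comparisons between changed and unchanged cells use
the classical equal-variance Student's t test (Welch behind a flag); the
"unchanged" group is restricted to cells whose matching labels belong to
the same climatic super-group as the disagreement type (cold for type I,
tropical for type II), and no multiple-testing correction is applied across
the six indicators (raw significance bands are reported). Kappa against an
external biome map needs a user-supplied label alignment; none is shipped
because no canonical alignment exists between structure and biome
vocabularies.

## Pipeline and reproducibility

The one-command run fans a single global seed out to fixed per-stage
offsets, writes every table with the generating seed and a parameter hash
in a header comment, and records SHA-256 checksums per stage in
`manifest.json`; two runs with the same configuration are bit-identical
(the hash excludes the output directory). Problem sizes used by the test
suite and the acceptance script — a 2000–3000-cell world, 330–689 species,
25–60 clustering restarts and GA populations of 100–150 — were chosen as
the smallest scales at which the planted-recovery margins are comfortable;
the AMD validation itself always runs at the full benchmark scale
(n = 8000, d = 11, 200 restarts).

## Known limitations

* AMD cluster-count detection degrades in very low dimension (see above).
* The evolutionary learner offers no optimality guarantee beyond the
  exhaustive checks at tiny scale; with few generations it can return a
  locally imperfect tree (the greedy baseline bounds it from above).
* The t tests assume independent cells; real grid cells are spatially
  autocorrelated, so the synthetic p values are optimistic relative to any
  real-data use.
* Real-data headline quantities (kappa against biomes, per-structure cell
  counts, the exact fitted climate tree) depend on proprietary-scale global
  data sets and are out of scope; the pipeline accepts equivalent CSVs if a
  user supplies them.
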