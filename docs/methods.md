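# Methods

This note documents the models and procedures implemented in `reefrules`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic data does and does not emulate.

## Station model

A station is a ~78.5 m² (5-m radius) sea-floor observation with thirteen
base attributes: depth (m), topography and complexity (ordinal 1–5,
fractional after frame averaging), five substrate percent covers that
partition the observed area (sand, debris, boulder, rock, slab; sum = 100
within a 0.5-point annotation tolerance), and five biotic overlay covers
(live coral, dead coral, erect algae, algal turf, seagrass).  Three
composites are derived, never stored: algae = erect algae + algal turf;
hard coral = live + dead coral; hard substrate = debris + boulder + rock
+ slab.  Because the substrate is a partition, hard substrate equals
100 − sand up to the tolerance — a fact the exclusivity checker exploits.

Biotic covers overlay the same area (turf can grow on dead coral), so
their sum is constrained to ≤ 100 as a configurable feasibility
constraint, not a hard ingest error; the substrate-sum check warns by
default and errors only in strict mode, since field annotations are
visual estimates.

Aggregation arithmetic: habitat attributes are the arithmetic mean of six
60° frames of one rotation; fish abundance per species is the mean count
over three rotations, converted to density as mean / area × 100
(ind/100 m²) with the area a parameter defaulting to 78.5 m²; species
richness counts species seen in *any* rotation (presence is not
averaged).  Stations with fewer than three rotations are computed over
the available rotations and flagged.

## Typology

Construction is unsupervised-then-supervised:

1. **Ordination.** Attributes are standardized to zero mean / unit
   variance and ordinated by PCA.  Axes are retained up to 90% cumulative
   explained variance (configurable).  80% was considered and rejected:
   in a 13-attribute space the axis separating the two sand-dominated
   habitats (Sandy vs Seagrass) carries little variance, and truncating
   at 80% discards it, degrading label recovery from ARI ≈ 0.98 to
   ≈ 0.89 on the reference synthetic conditions.  Retaining more axes is
   cheap at this dimensionality.
2. **Clustering.** Ward-linkage agglomerative clustering on the retained
   axes, cut at n_clusters (default 5).  Ward is the conventional partner
   of "hierarchical ascending clustering" on standardized ecological
   attribute tables.
3. **Naming.** Each cluster is named for the cover attribute with the
   largest standardized positive deviation of the cluster mean from the
   global mean, mapped to habitats (seagrass → Seagrass, erect algae or
   turf → Macroalgae, sand → Sandy, debris/boulder/rock/slab → Debris,
   live or dead coral → Live Coral).  Clusters claim names in decreasing
   order of their peak deviation; a duplicate archetype raises an error
   asking for manual names rather than guessing.
4. **Consolidation.** Stations whose habitat's archetypical attribute
   (seagrass, algae, sand, debris or live coral cover respectively) falls
   below the threshold (default 15%) are set aside; a 1,000-tree random
   forest (features-per-split = √p, out-of-bag scoring, fixed seed) is
   trained on the rest and re-assigns them.  Consolidation is idempotent:
   stations re-assigned once keep their forest label on a second pass.
   The OOB error is recorded on the model but not gated in library code;
   recovery is gated only in tests on synthetic data.
5. **Projection.** A second forest, trained on the consolidated
   typology, predicts habitat (and class-vote shares) for new stations.

Cluster characterization compares each habitat's attribute mean against
the all-station mean with two-sided Welch t-tests, Holm-corrected across
attributes within a habitat; attributes with corrected p < 0.05 are
listed as higher or lower by the sign of the difference, sorted by
increasing p, and tiered "highly significant" below 10⁻⁵⁰.  The original
mean-difference test behind that tier convention is not published in
reproducible form; Welch + Holm is the package's choice of a standard
equivalent.

Model serialization stores ordination parameters, assignments,
hyperparameters, OOB errors and the training matrix as JSON; forests are
refit from the stored matrix on load (exact under a fixed seed and
library version), since serializing 1,000 fitted trees is impractical.

## Rule mining

Transactions are built by discretizing each attribute against a cutpoint
grid (defaults: covers {1, 5, 15, 20, 40, 60, 80}, ordinals {1.5, 2, 3},
depth {10}); each cutpoint t yields two atoms, x ≥ t and x < t, and a
station's transaction is the set of atoms it satisfies.  Composites are
discretized alongside base covers.

A *canonical antecedent* has, per attribute, at most one lower and one
upper bound with lower < upper; a two-sided interval counts as **one**
condition toward the length cap (default 3), matching how published rule
tables write `t₁ ≤ x < t₂`.  Support of a rule A ⇒ h is the number of
transactions satisfying A and labeled h; confidence is support divided by
the antecedent-match count (the antecedent-only count is also reported).

The miner is a best-first expansion of the canonical antecedent lattice
in fixed atom order (each antecedent generated exactly once).  A node's
priority is its best achievable rule support — the largest per-class
count inside its match set, which is anti-monotone under extension — and
the dynamic minimum support rises to the K-th best support found so far,
pruning every branch whose bound falls below it; the search stops when
the best remaining bound cannot tie the K-th rule.  The result is exact:
for any K it equals the brute-force enumeration truncated to K under the
documented tie order (support desc, confidence desc, lexicographic
antecedent, consequent).  Ties with the K-th support are collected and
then truncated deterministically.  The brute-force oracle is guarded to
≤ 20 atoms × ≤ 500 transactions.

Mining is global across habitats by default (rule-poor habitats can
receive zero top-K rules, which is informative); per-habitat mining is a
flag.

## Rule engine

Rules live in a line-oriented grammar (see the `engine` module docstring)
with explicit attribute sums like `(slab + boulder + rock)` treated as a
single composite condition.  Thresholds compare exactly as written — no
tolerance band — so firing is bit-reproducible.  The packaged ruleset
`expert_rules_nc_v1` carries 26 expert-selected rules across the five
habitats; its confidence/support/confusion metadata are provenance values
computed on the original survey and are never silently recomputed
(`evaluate_rule` recomputes statistics explicitly on whatever data it is
given).  One encoded rule's printed metadata sums to 103% (independent
rounding in the source table); the parser allows a few points of slack
for exactly this reason.

Prediction evaluates every rule.  No fired rule ⇔ UNCLASSIFIED.  When
several rules fire, all are reported, the conflict flag is set, and the
label is taken from the highest-confidence fired rule — a resolution is
required because a label must exist whenever any rule fires; conflicts
remain fully diagnosable from the prediction object.  Assessment reports,
per habitat, % classified and confidence (correct / classified), pooled
station-weighted by default (habitat-averaged by flag: the choice is not
determined by the published tables).

Mutual exclusivity of a rule pair is decided by linear-programming
feasibility over the thirteen base attributes: box bounds, substrate sum
within the 0.5-point annotation tolerance of 100 (an exact equality is
deliberately not used — two of the packaged Sandy rules combine
sand < 60 with hard substrate < 40 and are only satisfiable inside the
tolerance), optional biotic sum ≤ 100, and the two antecedents with
strict bounds shrunk by 10⁻⁴.  A feasible solution is verified by
re-evaluating both antecedents (with a small randomized nudge off strict
boundaries); unverifiable cases are reported INCONCLUSIVE rather than
guessed.  The checker reports witnesses for non-exclusive pairs: the
packaged rules are pairwise exclusive *within* habitats' cover bands but
many cross-habitat pairs admit geometric witnesses (e.g. a high-algae
overlay on a debris substrate), which is exactly the diagnostic the
report is for.

## Community metrics

Per-habitat 0.25/0.5/0.75 quantiles of overall density and species
richness use linear interpolation (no convention is fixed by the source
figures).  Family frequency is the percentage of a habitat's stations
where the family is present; families at or below the overall-frequency
floor (default 1%) are dropped.  GLM habitat-effect tests (gamma for
density, negative binomial for richness) are exposed only as a thin,
clearly non-core wrapper over statsmodels.

## Synthetic data

Each habitat archetype draws: substrate composition from a Dirichlet on
the 5-simplex scaled to 100 (sums are exact by construction); biotic
overlays from truncated normals on [0, 100], rescaled if the overlay sum
exceeds 100; ordinal scores from truncated normals on the continuous
[1, 5] frame-averaged scale; per-family fish presence as a Bernoulli with
habitat-specific occurrence probability, and counts as Poisson across 1–3
species of the family and 3 rotations.  Strict mode enforces the
archetype minimum (15% cover) by rejection sampling; the overlap
parameter scales all spreads to blur the between-habitat continuum.

The packaged defaults (`data/default_archetypes.yaml`, version 1) were
parameterized once so that habitats are well separated (a nearest-centroid
classifier on covers exceeds 95% accuracy in strict mode) and most
stations fall in the high-confidence bands of the expert ruleset; under
these defaults the 26 rules route ≈ 88% of stations to their generating
habitat.  The residual error is concentrated where the ruleset itself
says habitats overlap: simulated Live Coral stations with intermediate
coral cover over sandy bottoms fire Sandy rules.  Reference problem
sizes used throughout tests and the acceptance script — 200 stations per
habitat for recovery checks, 100 per habitat for holdouts, 100 random
miner-oracle instances of ≤ 500 transactions × ≤ 20 atoms — are the
package's chosen balance of statistical resolution against quick,
repeatable runs.

Not emulated: spatial autocorrelation, site/MPA effects, temporal
dynamics, annotator disagreement, and the coastal/remote contrast in
coral cover.  Passing recovery tests on these data therefore shows the
pipeline is correct and well-calibrated on cleanly separated
communities; it does not certify performance on field data, where
between-habitat continua are wider and label noise exists.

## Known limitations

- Cluster naming requires distinct archetypes; degenerate inputs (e.g.
  all stations from one habitat) correctly refuse to name five clusters.
- The miner's complexity grows with the atom vocabulary; the default
  grid (~220 atoms) with K = 1000 runs in seconds-to-tens-of-seconds on
  hundreds of stations, but much denser grids call for per-habitat
  mining or a higher confidence floor.
- LP feasibility treats ordinals as continuous, which matches their
  frame-averaged semantics but admits witnesses at non-integer scores.
- Forest-backed consolidation/projection is deterministic only under a
  fixed seed and scikit-learn version.
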