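# Methods

This note documents the models, conventions and numerical choices behind
`shootarch`, and what the synthetic data generator does and does not
emulate.

## Plant representation and coordinate conventions

A plant image is described by two files: a VOC-style XML listing pod
bounding boxes, the plant's top/bottom anchors and a scale object of
declared physical length, and a skeleton JSON of role-labeled polylines
(exactly one `main`, any number of `primary`; secondary branches are out of
scope). Pixel coordinates have the origin at the top-left with y downward.
Calibration divides by px_per_cm (derived from the scale object, or
overridden) and flips the y axis so height is measured in cm upward from
the labeled bottom anchor — the soil-line cut, which is where all
height-type traits are anchored. Pods that land marginally below ground
under labeling noise are clipped to 0 with a warning.

Polylines are assembled into a tree: the main polyline is oriented
base-to-top, and each primary's first vertex is snapped to the *nearest*
main-branch vertex within a tolerance (default 2 px). Hand labeling is
never vertex-exact, so first-within-tolerance snapping would occasionally
attach a primary to a neighboring junction when junctions sit closer than
the tolerance; nearest-vertex snapping is exact whenever the labeled
junction coincides with a skeleton vertex. Validation rejects cycles,
disconnected components, multiple mains, and primaries that do not start
on the main branch.

## Geometric traits

* PH is the vertical base-to-top distance; MBL the arc length of the main
  polyline. On a perfectly vertical main they coincide; kinks make
  MBL ≥ PH.
* APBL is TBL divided by the number of branches *including the main*
  (TBL/(NPB+1)). The literature also uses the primaries-only convention;
  both are implemented (`TraitConfig.apbl_main_in_denominator`), the
  main-included form is the default.
* FNH is the arc length from the base to the first junction along the main
  branch (a vertical-height variant is available via
  `TraitConfig.fnh_vertical`); FIL/SIL/TIL are successive junction gaps.
  Junction pairs closer than the short-internode threshold (default
  0.5 cm; no standard value exists, so it is configuration) are merged
  onto the earlier junction before internodes are indexed, and the SIN
  flag is set. Traits beyond the available junctions are missing values,
  not errors.
* P1H/P5H use the nearest-rank quantile — the height of the ⌈q·PN⌉-th
  lowest pod — which is exact for small pod counts and reads as the
  counting definition ("the height at which q of all pods have been
  seen"). PN10 counts pods *strictly* above 10 cm; a pod at exactly the
  boundary is treated as at-risk (low), the conservative choice for
  harvest-loss estimation.
* Front/back records of a plant are averaged arithmetically; SIN is OR'd
  (a short internode seen on either side is real); a trait observed on one
  side only uses that side's value with a logged warning.

## Topological traits

The geodesic distance d(v) from the base is computed on the tree (unique
paths, so Dijkstra is just an accumulation). The barcode is the
0-dimensional persistence of the superlevel filtration {d ≥ t}: sweeping t
downward, a component is born at each branch tip at its d value and dies
when it merges into a component with a larger birth (elder rule; ties are
broken toward the smaller birth-vertex id, and the persistence multiset is
invariant to that choice). The last component dies at 0, giving exactly
one essential bar and one bar per tip. The sublevel filtration would be
useless here — a tree filtered upward from its root has a single trivial
component — which is why the superlevel direction is the informative one
for branching patterns.

The bottleneck distance is computed exactly: the optimum is attained at
one of the finitely many candidate costs (pairwise L∞ interval costs and
half-persistences), so a binary search over the sorted candidates with a
bipartite feasibility check (augmenting paths on the diagonal-augmented
graph) returns the exact value. Tests verify it against exhaustive
matching enumeration, metric axioms, and the ≤ ε stability property under
≤ ε interval perturbations.

Classical (Torgerson) MDS double-centers −½·J·D²·J and eigendecomposes.
Coordinates use the positive eigenvalues only; variance explained is
λᵢ/Σ_{λ>0}λ. Since the embedding is defined only up to reflection, the
sign of each dimension is fixed by making its largest-magnitude loading
positive; cross-implementation comparisons should nevertheless use
distances, not raw coordinates. Only MDS1–3 are written to the trait
table; higher dimensions are computed but carry little variance in
practice. If a stress-minimizing (SMACOF-style) MDS were substituted, the
coordinates would differ and variance-explained figures would not be
comparable.

## Heritability

The one-way random-effects model y_ij = μ + g_i + e_ij is fitted by REML,
profiled down to the variance ratio λ = σ²_g/σ²_e: for fixed λ the GLS
mean and σ²_e have closed forms, and the scalar criterion
(N−1)·log Q(λ) + Σ log(1+λnᵢ) + log Σ wᵢ is minimized over log λ ∈
[−30, 30] (tolerance 1e-8); the lower bound implements truncation of
negative genetic variance at zero. The estimates agree with statsmodels'
MixedLM REML to ~4 decimal places on the same data. Entry-mean
heritability uses the harmonic-mean replicate count r̄, which is the
standard correction for unbalanced replication. Zero-truncated REML has a
small positive bias under σ²_g = 0 (mean Ĥ² ≈ 0.11 on a 24×3 design —
matched by the reference implementation), which is inherent to the
estimator, not a defect. All-singleton designs are rejected as
unidentifiable.

## Association statistics

Pearson correlations report two-sided p-values from the Fisher z
transform, z = atanh(r), SE = 1/√(n−3) — matching the convention of
`cor.test`. The Fisher exact test uses the probability-mass two-sided
rule (sum of hypergeometric probabilities ≤ that of the observed table),
computed with log-factorials and a 1e-9 relative slack for float ties;
tests verify exact agreement with integer-rational enumeration for every
table with N ≤ 30. High/low pod-number classes split at the population
mean with ties going to "low" (a median split is available). Heterozygous
and missing calls are excluded from the 2×2 tables; markers with an empty
marginal are flagged untestable rather than tested. No multiple-testing
correction is applied by default (Benjamini–Hochberg is opt-in), matching
common practice for small candidate-marker panels.

## Synthetic data generator

The generator emulates the statistical structure of a two-to-four
replicate accession panel imaged front and back, not photorealistic
plants:

* **Geometry.** One vertical main branch; junctions placed at
  first_node_height + cumulative internode gaps; primaries alternate
  left/right at a fixed angle with length = fraction × main length;
  pods are spaced evenly along the pod-bearing segments (main branch above
  the branching zone, plus every primary), with counts proportional to
  segment length. Junction positions are rescaled into the lower 90% of
  the main branch if a draw would overshoot it.
* **Variance structure.** Accessions draw genetic targets for the five
  generative dials (main length, first node height, internode mean, NPB,
  PN); replicates realize target + residual noise. The internode spacing
  *profile* (the per-gap wiggle) is drawn once per accession and shared by
  its replicates — treating phyllotaxis pattern as accession identity —
  so that zeroing the residual SDs makes replicates identical and zeroing
  all SDs makes every plant identical. Defaults (main 55 cm, first node
  5.5 cm, internodes 2.5 cm, ~5 primaries, ~60 pods; genetic SDs several
  times the residual SDs) are chosen to resemble a field edamame panel
  with strong genetic control of height- and pod-related traits.
* **Imaging noise.** Each plant is emitted as a front and a mirrored back
  image. Vertex and pod coordinates receive independent Gaussian labeling
  jitter per image (default 0.15 cm ≈ 1.5 px at the default 10 px/cm);
  junction vertices are shared between the main and primary polylines, as
  a labeler clicks a junction once. Optional junction-occlusion noise
  displaces a junction along the main branch with some probability per
  image, mimicking attachment points hidden on one side of a flattened
  plant — this corrupts FNH/FIL/SIL/TIL while leaving lengths and pod
  counts intact, which reproduces the characteristic concordance ordering
  (PH/MBL/PN/TBL/APBL high, internode traits low).
* **Genetics.** Biallelic markers on one chromosome with MAF ~ U(0.2,
  0.5); exactly one causal marker shifts the accession's pod-number target
  by marker_effect per non-reference allele before plants are realized.
  By default heterozygous draws are collapsed to homozygotes so the 2×2
  tables stay full; het/missing rates are configurable.

What passing tests on synthetic data do **not** show: real plants have
curved, sagging branches, secondary branching, pods clustered at nodes,
correlated (not independent) labeling errors, and genetic architectures
far more polygenic than one causal marker. Synthetic results certify the
computational pipeline — trait extraction, topology, estimation — not
biological claims.

## Problem sizes and determinism

Simulation-based checks use sizes matched to the study design they mimic:
24 accessions × 2–4 replicates for heritability (500 seeds per H² level in
the test suite), 8–16 accessions for end-to-end runs, 200 random trees and
~1,000 random barcode pairs for the topology oracles. Every stochastic
path is driven by an explicit integer seed; identical inputs + seed give
byte-identical output files. The pairwise bottleneck stage is cached by a
content hash of the barcodes, so statistics-only reruns skip it.

## Known limitations

* FNH/internode traits assume junctions are labeled on the main polyline;
  skeletons whose primaries attach far (> snap tolerance) from any main
  vertex are rejected rather than repaired.
* The bottleneck feasibility check is O((n+m)³) per candidate; fine for
  plant barcodes (tens of bars), not intended for thousands of intervals.
* Heritability fits one variance component; block/replication effects are
  not modeled.
* The generator's phyllotaxis rules are pragmatic stand-ins; no
  quantitative model of edamame node placement is claimed.
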