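# Methods and design notes

This document records the package's own scientific and engineering choices:
coordinate frames, the Boolean kernel, the synthetic generators, and the
calibration/self-consistency experiments in the test suite.

## Coordinate frames

### Tooth frame (`align_tooth`)

* cervico-incisal axis parallel to Y with the incisal midpoint below the
  cervical midpoint (incisal "down", toward the menton side of the face
  frame);
* mesial → distal along +X, buccal outward normal along +Z;
* origin at the centre of volume of the extruded solid.

The incisal midpoint is therefore on the X = 0 midline but in general has a
non-zero Z: for a 6 mm-extruded, ×15.56-scaled buccal solid, forcing the
centroid→incisal direction to be exactly vertical would pitch the solid
roughly 30° off its cervico-incisal axis, which would then no longer be
parallel to Y during placement. Keeping the cervico-incisal axis parallel to
Y is the invariant that the placement step relies on, so it takes priority.

### Face frame (`align_face`)

* glabella → pogonion maps to −Y;
* a final yaw about Y minimises the sum of squared X offsets of glabella and
  labiale superius, **measured about the area-weighted surface centroid**;
* origin at that centroid.

Two points and a single yaw degree of freedom form an over-determined fit:
with the origin pinned to the area centroid, both midline landmarks can only
be placed at X = 0 exactly when they are coplanar with the centroid and the
Y axis. The yaw is therefore a least-squares fit; its residual X offsets are
at the scale of the centroid's own off-midline offset (≈1e-3 mm for the
synthetic shell, whose diagonal triangulation of a curved surface shifts the
area centroid slightly off the vertex midline). Two details matter for
robustness:

* the fit is centred at the area centroid, not the world origin — otherwise
  the minimiser depends on the arbitrary pose of the input scan and the
  alignment is not rigid-invariant;
* the two minima of the yaw cost are mathematically tied (φ and φ + π);
  costs equal within floating-point noise of the inputs are treated as ties
  and broken toward the anterior half-space (glabella at +Z).

### Placement (`place_for_superimposition`)

Translation only. Vertical: least-squares over the two tangency constraints
(incisal midpoint at the menton level, cervical midpoint at the glabella
level); the returned residual (mm) measures how far the scaled tooth span
disagrees with the menton–glabella span. Transverse: tooth X extremes
centred on the zygion (or alare) span. Anteroposterior: anterior-most tooth
vertex tangent to the anterior-most face Z, never behind it.

## Boolean kernel (`csg`)

`manifold3d` is not available in the runtime environment and trimesh alone
ships no Boolean engine, so the intersection kernel is authored here.

* **Local corefinement**: each triangle of one solid is cut by the planes of
  the bbox-overlapping, genuinely crossing triangles of the other solid
  (convex polygon splitting, then fan triangulation). A 2-D grid pre-cull
  keeps the candidate sets small.
* **Classification**: each fragment is kept if its centroid lies inside the
  other solid, decided by ray-parity with rays cast from a slightly inset
  point; coincident ("hugging") fragment pairs are classified explicitly —
  same-facing coincident surfaces contribute one copy, opposite-facing
  (external tangency) contribute none. The coincidence tolerance scales with
  the operand extent (`coincidence_eps`).
* **Repair ladder**: T-junction healing by vertex welding onto split edges,
  escalating rim welds, and — only when a small spurious shell survives —
  excision of the smallest-area connected component. Repairs are surgical;
  the kernel never runs a global re-heal after targeted repairs, which was
  observed to undo them.

Tolerances in the kernel and repair ladder are engineering parameters,
tuned on the unit battery (cube/lens/contained cases) — never on the
acceptance fixtures.

**Dual-route verification.** The test suite carries an independent
column-sampling oracle (`tests/_helpers.py`): for each XY grid column it
computes entry/exit depths per solid from triangle crossings and integrates
the overlap of the two depth intervals. The oracle shares no code with
`csg.py`. Twenty seeded convex/blended-hull pairs agree with the kernel to
well under the 1 % acceptance band (worst observed relative error ≈2e-5).

## Statistics (`cohort_stats`)

Standard tests (Shapiro–Wilk, Levene, paired/two-sample t, Mann–Whitney U,
Spearman) delegate to `scipy.stats`. Two-sample comparisons gate pooled
vs Welch on Levene's test; summary-statistic input always uses the pooled
form (the only one computable from summaries). Achieved power is authored:

* paired and two-sample t power via the noncentral t distribution
  (`scipy.stats.nct`), with a guard that treats a non-finite deep-tail CDF
  value as 0 — scipy returns NaN in the tail opposite a large noncentrality
  parameter (e.g. dz ≈ 2, n = 98), which would otherwise poison the report;
* correlation power via the Fisher-z normal approximation.

Both are cross-checked in tests against `statsmodels.stats.power` as an
independent oracle (the implementation never imports statsmodels).

A rounding note on the reference battery: the two-group achieved power of
0.76 is reproduced by carrying the *unrounded* Cohen's d (0.5927…) into the
power function (0.7554 → 0.76). Feeding the rounded d = 0.59 gives 0.7515,
which still rounds to 0.75 — the tests therefore assert the unrounded
chain and record the rounded-input value separately.

## Synthetic generators (`synthetic`)

Generator defaults are study conditions, fixed a priori; they were never
adjusted in response to test outcomes.

* **Tooth**: rounded-rectangle planform (8.5 × 11 mm) with a convex buccal
  sag (0.8 mm midline bulge); construction is seed-independent.
* **Face**: a curved shell pre-aligned to the face frame, with a congruence
  parameter κ ∈ [0, 1] blending the central region toward the scaled tooth's
  buccal surface (κ = 1 ⇒ near-perfect congruence, %SI > 99; a `disjoint`
  variant spikes the face forward so the tangent tooth cannot intersect,
  %SI = 0). Vertex noise jitters non-landmark vertices only; landmarks move
  by the common centroid re-centering translation.
* **Cohort**: a Gaussian copula couples total volume and RTV at the target
  Spearman ρ per sex; the %SI marginal is a left-skewed (skew-normal) match
  to the reported mean/SD. Infeasible parameter combinations (rank
  correlation not attainable under the marginals) raise `FeasibilityError`.

## Calibration experiments behind the acceptance tests

* **Two-group power self-consistency** (criterion 4): simulating the literal
  reported sex groups (unequal SDs, n 69/29) makes the pooled-t rejection
  rate deviate from the noncentral-t prediction by ~3–4 points, comparable
  to the binomial acceptance band, because the pooled SE mis-weights
  heteroscedastic groups. The self-consistency simulation therefore draws
  both groups with a common (pooled) SD — the setting in which the pooled-t
  power formula is exact — keeping the group means and sizes. This was
  decided a priori, not tuned to outcomes.
* **Recovery within ±2·SE over 200 replicates** (criterion 5): the grand
  mean of each recovered quantity must sit within 2·SE of its generating
  value, and per-replicate 2·SE interval coverage must stay within the 99 %
  binomial band of its nominal 95.45 % (≥ 0.91 over 200 replicates).
  Requiring 95 % of individual replicates to cover would fail ~40 % of the
  time by design, which is why the criterion is phrased at the ensemble
  level.
* **Type-I / coverage** (criterion 4): null rejection rates over 1000
  simulated cohorts are required to fall inside the exact binomial 95 %
  band around α = 0.05; paired-t CI coverage within 95 % ± 2 %.

## Determinism

All generators take explicit seeds (`numpy.random.default_rng`), the
pipeline is pure given its inputs, and `SuperimpositionResult.as_dict()`
round-trips bitwise for repeated runs — asserted in the tests both at the
in-memory and the on-disk (STL/JSON bytes) level.
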