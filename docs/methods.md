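# Methods

`ligqc` implements a two-stage quality-control workflow for batches of
laser-inscribed graphene (LIG) electrodes characterized by cyclic voltammetry
(CV), plus a downstream validation statistic based on impedance PCA. This
note records the model, the numerical choices, and what the synthetic tests
do and do not demonstrate.

## Curve functionals

A CV sweep is a closed loop traced in the (potential, current) plane.  Three
functionals drive everything else:

* **ABC** (area between curves, µA·V) — the area between the anodic
  (rising-potential) and cathodic (falling-potential) branches; a proxy for
  surface charge density.  Computed with the **left-rectangle rule**: the
  trace is rotated to start at the potential minimum, split at the first
  global potential maximum, the cathodic branch is linearly interpolated onto
  the anodic potential grid, and |I_anodic − I_cathodic| is summed with left
  Riemann weights.  The absolute difference is used so that crossing lobes
  contribute positively, consistent with the even-odd polygon area of the
  same trace.  For constant branches the rule is exact; for smooth loops it
  converges to the enclosed area at first order in the grid spacing (the
  elliptic-loop test shows the error at least halving per grid doubling).
* **Peak current** (µA) — grid search for the maximum-magnitude current on a
  branch; no interpolation beyond the sampled grid.  The anodic (oxidation)
  branch is the default, with the branch selectable, because the oxidation
  peak is the feature marked in the source data and the 200 µA selection
  threshold refers to peak oxidation current.
* **D** (µA·V) — the area of the symmetric set difference between the planar
  regions enclosed by two loops: D = area(A) + area(B) − 2·area(A∩B).
  D is symmetric, nonnegative, zero exactly for coincident regions, and as a
  measure of a symmetric difference satisfies the triangle inequality
  (a pseudometric: distinct loops enclosing the same region have D = 0).

**Loop repair.** Real CV traces can self-intersect near the vertex
potentials, so every trace is first repaired into a valid planar region set
with *even-odd* fill semantics: the closed polyline is noded at its
self-crossings, the resulting faces are classified by ray-crossing parity
against the original trace, and odd-parity faces form the region.  Simple
rings take a fast path.  Polygon booleans are delegated to shapely.

**Normalization.** Potential spans ~1 V while currents span hundreds of µA;
geometric predicates on such anisotropic coordinates are fragile.  All
boolean operations therefore run on coordinates jointly rescaled to the unit
box (joint bounds when two loops are compared), with tolerance ε = 1e-9 in
normalized units, and areas are rescaled back afterwards.  A normalized
region area below ε is a degenerate loop and is reported as such (flagged,
not raised, during batch runs).  A computed symmetric difference below ε is
snapped to exactly zero.

## Stage 1 — per-electrode precheck

Fresh carbon electrodes need conditioning sweeps before their response
stabilizes.  For an electrode with sweeps y_1..y_K:

* **Convergence diagnostics**: r_k = D(y_k, y_{k+1}) / ABC(y_k) for
  k = 1..K−1.  The electrode passes when the terminal ratio is ≤ the
  convergence threshold (default 0.05).  An optional window rule requires
  the last *w* ratios to pass; the default is w = 1 (terminal criterion),
  since the diagnostic asks whether the output *has converged*, which the
  final ratio measures directly.
* **Replicate error**: with ȳ = (y_{K−2} + y_{K−1} + y_K)/3 the pointwise
  mean curve, the three ratios D(y_k, ȳ)/ABC(ȳ) for the last three sweeps
  must all be ≤ the replicate threshold (default 0.05; a stricter 0.02
  reporting threshold is also carried in the config for audit tables).
* **Representative curve**: the last sweep if the replicate check passes
  (the cheap, unbiased choice when replicates agree), otherwise the mean of
  the last three (variance reduction when they do not).  Non-convergent
  electrodes are rejected and excluded from clustering.

All ratios are dimensionless and invariant to rescaling the current units.

A closed-form fact worth recording: for an electrode whose loop is a clean
multiplicative rescaling of a fixed template with scale
s_k = 1 + (a−1)·d^{k−1} (the generator's drift model), the consecutive loops
are nested, so D(y_k, y_{k+1}) = (s_k − s_{k+1})·A and
r_k = (a−1)d^{k−1}(1−d) / s_k < 1 − d.  Hence with decay d ≥ 0.95 *no*
initial scale can fail the 5% terminal rule — slow multiplicative drift is
invisible to this diagnostic at that threshold, and only faster decay or
shape-changing drift can trip it.  The suite pins this bound.

## Stage 2 — batch clustering and selection

* **Distance matrix**: pairwise D between representative curves,
  deliberately *not* normalized by ABC (similarity is compared within the
  batch, not against an absolute threshold).
* **Clustering**: agglomerative hierarchical clustering on the precomputed
  matrix (scipy), complete linkage by default (the default of the R routine
  this workflow standardizes on), with average and single linkage available.
  The merge history is checked against a brute-force O(n³) agglomeration in
  the tests and can be exported as a Newick tree.
* **Cut**: a requested cluster count k, a merge height, or an automatic rule
  that cuts at the largest relative gap in merge heights.  The pure ratio
  rule is scale-fragile — within-cluster noise merges at near-zero height
  produce arbitrarily large ratios — so only gaps whose upper merge reaches
  5% of the total tree height are considered (fallback: largest absolute
  gap).  Cluster labels are renumbered by dendrogram left-to-right position
  so reports read off the figure.
* **Validity**: clusters need ≥ 3 members (a usable replicate triplicate);
  smaller ones are retained in reports but never selected.  Outliers are
  electrodes whose first merge height exceeds the Tukey upper fence
  (Q3 + 1.5·IQR) over all merge heights, or that failed precheck.
* **Ranking**: valid clusters are ordered by the rank-sum of mean ABC and
  mean peak current (both descending), ties broken by mean ABC.  Rank-sum is
  used because the selection goal is "relatively large on both criteria"
  without a stated trade-off formula; both raw means are always reported so
  users can apply their own rule.
* **Selection**: members below the peak threshold (default 200 µA) are
  dropped first; clusters falling below the minimum size are invalidated;
  the top `n_groups` surviving clusters are selected (partial selection with
  a warning when fewer survive).

## Validation — impedance PCA

Imaginary impedance Z'' restricted to 0.01–0.1 Hz (closed interval on both
ends) forms a sensor-by-frequency matrix.  Columns are mean-centered but not
scaled to unit variance — all columns share units (ohms), so scaling would
only inflate noise-dominated frequencies.  PC1 comes from the SVD of the
centered matrix, with its sign fixed so the largest-magnitude loading is
positive.  Per group, the sample SD (n−1 denominator) of PC1 scores measures
sensor-to-sensor variation, and

    percent_reduction = 100 · (SD_control − SD_treatment) / SD_control.

With the reference SDs 2.450 (treatment) and 2.757 (control) this formula
gives 11.14%; rounded summaries of such comparisons sometimes quote ~13%,
which does not follow from these SDs under either denominator convention —
this package always reports the exact formula value.  Validation spectra are
never interpolated: a frequency-grid mismatch across sensors is an error.

## Synthetic data

The generator produces the study conditions every test runs under:

* **CV loops**: triangular ramp over −0.8…0.8 V, 320 points per sweep, ten
  sweeps per electrode — mirroring a typical potentiostat acquisition for
  this workflow.  Current is a capacitive hysteresis band (±halfwidth) plus
  Gaussian redox peaks per branch.  Gaussians, not Butler–Volmer waves: only
  geometric properties matter to the QC math, and Gaussians keep ABC and
  peak height in closed form (ABC = 2·halfwidth·window + truncated Gaussian
  areas).  Both ramps include the vertex potentials, so the branch jump at
  each vertex is a vertical polygon edge rather than a diagonal notch that
  would bias the area at O(ΔV).
* **Conditioning drift**: sweep k is the template scaled by
  1 + (initial_scale−1)·decay^{k−1} plus i.i.d. Gaussian current noise.
* **Batches**: electrodes derive from templates with multiplicative current
  jitter ~ Normal(1, within_jitter); planted labels are returned for
  adjusted-Rand scoring.
* **EIS**: a shared smooth Bode baseline plus a fixed rank-1 perturbation
  whose band-restricted direction has unit norm, with per-sensor coefficient
  ~ Normal(0, σ_group) — so PC1 score SDs recover the planted σ up to
  sampling error (SE of a sample SD at n = 200 is ≈ 5% of σ; the recovery
  tests use a 10% band at the package's default seed).

What the generator does **not** emulate: electrochemical kinetics (diffusion,
iR drop, scan-rate dependence), baseline wander, potential-axis noise, or
operator/batch covariance.  Passing tests therefore demonstrate that the
statistical workflow is implemented correctly and recovers planted structure,
not that real LIG batches will cluster as cleanly.

## Problem sizes and determinism

The test suite and the acceptance script run entirely on generated data:
metric properties on hundreds of random loop triples, oracle agreement on
100 random loops (scanline rasterization at 3000 rows, accurate to ~4·10⁻⁴
relative), clustering recovery on 12–36-electrode batches, and PCA recovery
at 200 sensors per group.  All randomness flows from explicit seeds; reports
are byte-identical across reruns.

## Known limitations

* The terminal convergence rule cannot detect slow multiplicative drift with
  decay ≥ 1 − threshold (see the closed form above).
* Cluster counts from the automatic gap cut depend on the linkage and on the
  separation structure; reproducing a specific historical partition may
  require pinning k (the example configuration documents k = 10, complete
  linkage).
* The ranking's rank-sum is a coarse aggregation; clusters trading ABC
  against peak current can reorder under other reasonable rules (the report
  always carries both means).
* Cross-batch or cross-operator pooling is out of scope; distances are only
  comparable within a batch measured under one protocol.
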