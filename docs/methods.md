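# Methods

## The screen being modeled

The package analyzes antagonist-mode qHTS data: every library compound is
tested as a 7-point concentration series (46 µM down to 1.5 nM) against a
cell-based luciferase reporter co-treated with a reference agonist, with a
fluorescent viability readout taken from the same wells before the
luminescent read. Each 1536-well plate (32 rows × 48 columns) carries two
vehicle-control columns (DMSO, defining 0% activity), one positive-control
column (a reference antagonist at saturation, defining −100%), and one
cytotoxicity-control column that anchors the viability scale. Titration is
inter-plate: one plate per concentration level, each compound occupying
the same well position across the stack.

## Normalization and plate quality

% activity uses control *medians* (robust to occasional dead wells):
`(V − V_DMSO)/(V_DMSO − V_pos) × 100`. The luminescence channel is
anchored on the antagonist positive control; the fluorescence channel on
the cytotoxicity control, so both readouts share the 0 / −100 convention.

Spatial background is estimated from DMSO-only plates flanking the
compound stack: the per-well median of their normalized activity is
subtracted from every compound plate at the same position. Two details
matter. First, on a DMSO-only plate the vehicle-median anchor is
restricted to the designated vehicle columns — otherwise the artifact
itself would set the plate's baseline and the background estimate would
collapse to zero. Second, background is subtracted only at positions that
read vehicle on the DMSO plates; the control columns (which carry controls
there too) pass through unchanged. The estimator is deliberately the
simplest one consistent with its inputs and is replaceable; with d DMSO
plates the correction adds noise of roughly σ_well/√d per well, so small
artifacts are only worth correcting when several DMSO plates are
available.

Plate QC uses the standard definitions on raw signal: CV = SD/mean of
vehicle wells ×100, S/B = mean vehicle / mean positive control, and
Z′ = 1 − 3(σ_pos + σ_veh)/|µ_veh − µ_pos|.

## Hill fitting

The four-parameter model is fitted by bounded nonlinear least squares
(trust-region reflective) in log-k, from three deterministic starting
points (the concentration nearest the half-range response and two
geometric blends toward the upper potency bound); ties are broken toward
the smaller k so reruns are bit-identical. Bounds: k within
[c_min/10, c_max·10], n within [0.3, 8], asymptotes within the data range
±50%. With fewer than four points n is fixed at 1. Failure returns a
non-converged result instead of raising, which downstream classification
treats as "no fit support".

Outlier handling: after a first fit on ≥5 points, the worst residual is
compared against 3× the robust SD (1.4826·MAD) of the *other* residuals —
a gross outlier drags a free 4PL toward itself, so its own residual
understates the deviation — and if flagged, that point is dropped and the
fit repeated once.

Precision at the screen's operating point: with a single 7-point series at
~5.6-fold spacing and the calibrated well noise (7.04% CV on raw signal,
≈ 9.8% SD on the % activity scale at baseline), the per-curve IC50 is
determined to a median relative error of roughly 20–25%. This is the
Fisher-information limit of the design with four free parameters (the
fitted loss never exceeds the loss at the true parameters in simulation),
not an optimizer artifact; averaging over replicate series shrinks it as
1/√m, which is why 35-replicate means recover the true potency to a few
percent. Anchoring a₀ = 0 would cut the per-curve error by about a third
but is not done, because real screens show baseline drift that the free
intercept absorbs.

## Curve classes, rank, and activity outcome

A response is "active" at a point when it exceeds the noise band, defined
as 3 SDs of the pooled vehicle-well % activity (≈ 29% at the default noise
calibration). Classes: 4 if no point is outside the band; 3 if exactly one
point is outside, or if more are but the fit gives no support (a single
point of activity cannot define a curve); otherwise 1 when both asymptotes
are observed — the lowest response on the fitted a₀ plateau and the top
*two* responses on the a_inf plateau (a plateau cannot be claimed from one
point) — and 2 when only the lower asymptote is. Subclass .1 requires
|efficacy| ≥ 80% and r² ≥ 0.9, else .2; the sign follows the response
direction. Both thresholds are arguments, since the conventions vary
between laboratories.

Rank maps (class, efficacy) to an integer: 1.1 → 8/9, 1.2 → 6/7,
2.1 → 4/5, 2.2 → 2/3, 3 → 1/2, 4 → 0, taking the upper value of each pair
at |efficacy| ≥ 80%, signed by the class. This preserves the intended
ordering — better-quality, more efficacious curves get larger magnitudes,
±9 is attainable only by a high-quality complete curve, and 0 is exactly
the inactive class.

The activity outcome joins both readouts: **active** requires rank < −1,
efficacy < −50%, and a clean counter-screen — either the viability readout
is inactive (class 4; an absent counter-screen is treated the same) or the
antagonist readout is at least 6-fold more potent than the viability
readout (fitted IC50 ratio). **inactive** is |rank| < 1; everything else
is **inconclusive**. The 6-fold clause is what rescues genuinely potent
antagonists that are also weakly cytotoxic at the top of the series, while
compounds whose reporter loss merely tracks their viability loss (ratio
≈ 1) stay inconclusive. Selection helpers apply the conjunctive filters
used for screen triage (confirmation: E < −50%, IC50 < 10 µM, no apparent
toxicity; follow-up: the tighter E < −75%).

## Cluster enrichment

Each structural cluster is tested for an excess of actives with a
one-sided Fisher's exact test on [[a, m−a], [A−a, N−m−A+a]] (a actives in
a cluster of m, A actives in a library of N); `enriched` means p < 0.05.
No multiple-testing correction is applied by default — the screen-triage
convention is per-cluster significance — but Benjamini–Hochberg can be
switched on. Clustering accepts precomputed labels directly (the usual
case when fingerprints come from an external pipeline) or computes a
self-organizing map over any equal-length fingerprint vectors: a
rectangular lattice (default 10×10), classic online updates with linearly
decaying learning rate (0.5 → 0) and Gaussian neighborhood (radius
max(grid)/2 → 0.5) over 20 epochs, fully deterministic for a fixed seed.
The SOM is written in-package; clustering quality is not the statistical
contribution here, the enrichment test is.

## Follow-up analyses

**IC50 shift.** Each agonist co-treatment condition's titration is fitted
independently; the shift is the ratio of the largest to smallest fitted
IC50 and the receptor-dependence flag requires a shift strictly greater
than 2-fold. Any non-converged condition makes the result indeterminate
rather than silently passing.

**qPCR.** ΔCt = Ct_target − Ct_housekeeping per replicate; ΔΔCt is taken
against the mean control ΔCt; fold = 2^−ΔΔCt is computed per replicate and
then summarized, so reported spreads are spreads of folds, not propagated
Ct errors. Group testing is one-way ANOVA plus Dunnett's many-to-one
comparisons against the control, evaluated through the equicorrelated
multivariate-t distribution of the max-|t| statistic (with the randomized
quadrature seeded for reproducibility), with stars at p < 0.05 / 0.01 /
0.001. For a single comparison Dunnett collapses to the two-sample t-test
(up to ~1e−3 quadrature error); the critical value for three comparisons
at eight error degrees of freedom reproduces the published 2.88.

## The synthetic generator

The generator emulates the screen's statistical structure, not its
biology. Raw vehicle luminescence is 10,000 AU; the positive-control mean
is set by the signal-to-background ratio (default 3.54); well noise is
multiplicative Gaussian (vehicle CV default 7.04%), consistent with plate
quality being quoted as a CV. The positive-control CV defaults to the
value that closes the Z′ identity at 0.572 given the vehicle CV and S/B
(≈ 11.3%), so the three plate statistics are jointly reproduced. The
dilution series is exactly geometric between the printed endpoints
(46 µM, 1.5 nM; ~5.6-fold steps) — the endpoints do not lie on a round
fixed-ratio series, so geometric spacing between them is the one choice
consistent with both.

Planted truths: 5% of compounds are antagonists (IC50 log-uniform
0.01–5 µM, i.e. comfortably inside the tested range; efficacy uniform
−100…−70%; Hill n uniform 0.8–2.5) and a disjoint 3% are cytotoxic (IC50
log-uniform 1–20 µM, slope 1.5, full viability loss). Cytotoxicity couples
into the luminescence channel multiplicatively (a dying well loses
reporter signal in proportion to its viability), which is exactly what
makes the 6-fold separation rule meaningful. Cluster labels come from a
mixture: two designated clusters absorb 60% of the antagonists, the rest
of the library is uniform over 50 clusters, so enrichment is genuinely
planted. The reference positive-control titration uses IC50 0.169 µM,
efficacy −100%, slope 1.2.

What the generator does *not* emulate: liquid-handling mechanics, edge
evaporation gradients (spatial artifacts must be injected explicitly),
compound fluorescence interference, correlated well-to-well noise, or any
real structure–activity relationship (cluster labels are sampled, not
computed from structures). Passing the recovery tests therefore
demonstrates that the pipeline's statistics behave correctly under the
assay's nominal noise model — not that any particular real screen would
reach the same recall.

## Problem sizes and numerical choices

The test suite runs the full pipeline on a 5,099-compound library (28
titration plates) once and on a 500-compound library for module-level
checks; the acceptance script uses 35 replicate control titrations and a
35-plate control set. The class-4 fast path (series entirely inside the
noise band are not fitted) keeps the large screen to well under a minute
of fitting. Fisher p-values are exact, not simulated; the hypergeometric
tail is cross-checked against direct binomial-coefficient summation to
1e−12 in tests. All randomness flows from explicit integer seeds;
repeated runs are byte-identical (Dunnett p-values to quadrature
precision).

## Known limitations

- The pattern-correction estimator is a per-well median; it cannot remove
  artifacts that differ between the DMSO plates and the compound plates,
  and it adds √(1/d)-scaled noise.
- Curve-rank arithmetic within a class uses a single efficacy threshold
  (80%); laboratories using finer efficacy grading will rank borderline
  curves one step differently.
- The 6-fold separation rule needs both fits to converge; compounds with
  unfittable viability data are treated as viability-inactive, which is
  permissive by design.
- Per-curve IC50s from single 7-point series carry ~20% median relative
  error at the default noise; treat single-series potencies as
  screen-grade, not assay-grade.
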