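# Methods

`flocknet` analyses how heat-stress conditions shape the proximity-based
social network of a GPS-tracked livestock flock. This note documents the
models and procedures it implements, the choices made where the design was
genuinely open, and what the synthetic-data experiments do and do not show.

## Thermal environment

Heat load is quantified with the sheep temperature–humidity index

    THI = T − (0.31 − 0.31·RH/100) · (T − 14.4)

with dry-bulb temperature `T` in °C and relative humidity `RH` in percent
(Marai-style index). At `RH = 100` the index equals the temperature; at
`T = 14.4 °C` the humidity correction vanishes; below 14.4 °C the
correction changes sign and the index is not meaningful for heat stress,
so the weather simulator rejects target ranges below that pivot. Some
sources print the formula with ambiguous brace placement; the standard
form above is used, and the literal alternative grouping is available as
`compute_thi(..., literal_bracketing=True)` for sensitivity checks only.

Heat-stress categories use the standard half-open sheep thresholds:
no stress < 22.2 ≤ moderate < 23.3 ≤ severe < 25.6 ≤ extreme severe.

The analysis window of each day is the 3-h midday period — 1.5 h either
side of solar noon, when radiation and shade value peak. Solar noon is
approximated by mean solar time (UTC noon − longitude/15 h); the omitted
equation-of-time correction is at most ±16 min, immaterial against a 3-h
window, and an explicit clock-time centre can override it. The daily THI
is the mean over weather records falling inside the window.

## Trajectory cleaning

Raw collar fixes pass three removal-only filters, in a fixed order:

1. **Satellites / bounds** — fixes computed from fewer than 3 satellites,
   or lying outside the paddock rectangle (plus a configurable buffer,
   default 0 m), are dropped.
2. **Speed** — a forward pass drops any fix whose distance from the *last
   retained* fix exceeds 180 m per 2 min scaled by the actual elapsed
   time. Anchoring at the last retained fix (rather than the previous raw
   fix) stops a single teleport from cascading into removals of the
   genuine fixes after it, and makes the filter idempotent.
3. **Spikes** — an interior fix is an out-and-back spike when both legs
   exceed 0.8 × the scaled speed cap *and* the heading change is ≥ 160°.
   The leg fraction and turn threshold are free parameters; the defaults
   make "near-maximal speed with a sharp reversal" operational while
   leaving ordinary fast, straight travel untouched.

Cleaned trajectories are linearly interpolated onto the exact common 2-min
grid of each daily window (half-open, so a 3-h window has 90 instants and
82 days have 7 380). Grid instants outside an individual's observed span,
or bracketed by a gap longer than 10 min, are missing. Linear
interpolation (not splines) is deliberate: at 2-min resolution sheep
displacement between fixes is small and a spline would invent curvature.

Collar accuracy is estimated from a stationary unit as the median (with
quartiles) of distances from each fix to the coordinate-wise median of all
its fixes.

## Network construction

Two sheep are associated when within the association threshold

    threshold = body length + 2 × per-collar accuracy  (1 + 2×2 = 5 m)

at the same grid instant, with each collar in a dyad contributing its own
(rounded-up) positional error. Per instant, present individuals are
clustered by single linkage at the threshold (the "chain rule": A–B and
B–C within 5 m puts A, B, C in one group even if A–C is 8 m). Every
cluster, singletons included, is one grouping event; stacking a day's
events gives its group-by-individual (GBI) matrix. A strict
nearest-neighbour variant is available for users who prefer a more
conservative dyadic criterion.

Edge weights are the simple ratio association index,

    SRI(i, j) = (instants i and j shared a group) / (instants both recorded),

a proportion in [0, 1]. The denominator counts co-availability — time
alone, with others, or together — which for gambit-of-the-group telemetry
equals the classical simple-ratio denominator whenever "observed" means
"has a fix".

Whole-network metrics per day:

- **density** — dyads with SRI > 0 over n(n−1)/2 (exact zeros are absent
  edges; no epsilon thresholding);
- **modularity** — weighted Q of the partition found by greedy
  agglomerative (Clauset–Newman–Moore fast-greedy) merging, the classic
  fast-greedy community algorithm; undefined (error) on an edgeless day;
- **CV of edge weights** — sample SD over mean of all n(n−1)/2 dyadic
  weights, zeros included (the social-differentiation convention);
  `nonzero_only=True` restricts to existing edges.

Node metrics per individual per day: degree (associates with SRI > 0),
strength (sum of SRI weights) and betweenness centrality on weighted
shortest paths with edge length 1/SRI (strong associations are short),
unnormalised, equal-length paths splitting a pair's contribution. Raw
counts are appropriate because all comparisons are within networks of
fixed size.

## Shade use

Each of the mapped tree patches is a polygon; patches shorter than 1 m
cannot shade a standing sheep and are excluded. Shade use per individual
per day is the number of present grid positions inside the union of
eligible polygons, times 2 min. Boundary points count as shaded (a sheep
at the drip line is under the canopy); the union makes the measure
invariant to how patches are split or ordered.

## Statistical models

- Whole-network: three OLS regressions of daily density, modularity and
  CV on daily THI.
- Shade response: Gaussian linear mixed model, shade minutes ~ THI with a
  random intercept per individual, fitted by REML.
- Node level: each metric ~ scaled shade use + (scaled shade use)² with a
  random intercept per individual; degree uses a Poisson family with log
  link, strength and betweenness are Gaussian. Shade use is centred and
  scaled to unit SD over the analysis sample before squaring.

The Gaussian mixed models use a profiled-REML solver specialised to the
single-random-intercept design: for a given variance ratio λ = σ²ᵤ/σ²ₑ the
GLS step is closed-form through the Sherman–Morrison identity, leaving a
1-D optimisation in log λ. This is exact (it agrees with general-purpose
REML software to ~1e-5; the test suite verifies against statsmodels
MixedLM) and fast enough to re-fit hundreds of thousands of times inside
permutation loops. The Poisson mixed model maximises the marginal
likelihood with the random intercept integrated by 25-node Gauss–Hermite
quadrature; the test suite pins it against a frozen `lme4::glmer`
(nAGQ = 25) reference fit. Reported standard errors are asymptotic and
used for scale only — inference rests on permutations.

## Permutation inference

Network data violate independence assumptions, so each coefficient is
compared with its distribution over randomised data; the two-sided p-value
is twice the smaller tail count divided by the number of permutations,
ties counting as extreme, capped at 1. (The literal doubled-count rule can
return 0 when the observed value is beyond every permuted one.)

**Whole-network effects — pre-network (data-stream) randomisation.** The
null randomises group composition before any network is built, conserving
each day's group sizes (GBI row sums) and each individual's observation
count (column sums). Three samplers are provided:

- *instant-scope, independent* (default): per grid instant, the present
  individuals are randomly permuted among that instant's groups. Each
  emission is an exact, independent draw from the uniform distribution
  over reassignments given every instant's group sizes — the sharpest
  null that conserves the observed grouping structure — and every
  emission is itself a valid synchronous grouping.
- *instant-scope chain*: the same null explored by sequential swaps
  between two groups of one instant, with burn-in and thinning.
- *day-scope chain*: the classic GBI swap randomisation — any two groups
  of the same day may trade members. This matches the widely used
  field-software idiom but has two caveats the default avoids: an
  emission may book an individual into two groups at one instant, and
  successive emissions are serially correlated, which blunts the tails of
  the null distribution.

The default was chosen on calibration grounds: under a synthetic null
flock the day-scope chain's type-I error for the THI–density test fell
well outside the nominal band, while the independent instant-scope
sampler is calibrated (see below). All three conserve the row/column
margins, which the suite asserts on every emission.

**Node-level effects — node-label randomisation.** Shade-use values are
shuffled across individuals within each day, the full mixed model is
re-fitted to every shuffled data set, and both quadratic-term coefficients
are tested against their null distributions.

### Calibration

The type-I error of both schemes is measured on 200 seeded replicates of
a null flock (no shade–THI coupling) at 200 permutations each, demanding
rejection rates inside the exact binomial 99% band around α = 0.05. The
null flock for this experiment is *memoryless*: persistence 0 and step
noise much larger than the paddock, so positions are independent uniform
draws at every instant. This is deliberate. With continuous movement
paths, proximity persists across consecutive 2-min fixes, so group
composition is genuinely autocorrelated within a day; permutations that
condition only on group sizes are then not exchangeable with the observed
data and *any* GBI-based scheme over-rejects (we measured ≈ 0.10–0.12 at
nominal 0.05). That inflation is a property of data-stream permutation
tests under temporal autocorrelation — worth knowing when interpreting
field results — not an implementation artefact, and the calibration
experiment therefore targets the regime the schemes' exchangeability
assumption actually covers. Passing it shows the machinery is correct; it
does not license ignoring autocorrelation in real data.

Problem sizes for the calibration experiment (10 individuals, 12 days,
1-h windows, 300 × 150 m paddock) keep the full 200 × 200 design
comfortably inside a single-CPU test run while leaving every day's network
non-degenerate.

## Synthetic flock generator

The generator's contract is statistical, not behavioural. Defaults mirror
the study design the pipeline targets: 48 individuals, 82 consecutive
days, 2-min synchronous fixes in a daily 3-h midday window, a 6 × 1 km
paddock with 106 convex shade polygons (log-normal areas, log-normal tree
heights around ~2 m so a few fall under the 1-m eligibility cut), and
daily midday THI filling 20.72–34.29, which spans all four heat-stress
categories.

Weather: daily THI targets are stratified over the configured range and
shuffled, per-day humidity is uniform in 25–65%, and the in-window
temperature is computed by inverting the THI formula, so the window-mean
THI reproduces each target exactly; off-window hours follow a cosine
diurnal curve.

Movement is a discrete-time biased correlated random walk. Per 2-min step
each individual adds:

- an AR(1) heading (persistence 0.4, isotropic noise SD 12 m) carrying
  the stochastic exploration,
- attraction toward the flock centroid (gain 0.08), which is also the
  mean-reversion that keeps the simulated flock contained,
- attraction toward the nearest eligible shade patch with weight
  `min(1, slope × propensity_i × max(THI_d − 22.2, 0))` (default slope
  0.08 per THI unit); inside a patch the same weight damps movement, so
  hot days hold shade-seeking sheep in place.

Steps are capped at 160 m (safely under the 180 m cleaning cap) and the
paddock boundary reflects by exact billiard folding, which maps a uniform
position distribution to itself. Per-individual shade propensities are
Beta(2, 2) by default — individuals vary, extremes are rare — and can be
overridden; the literature reports repeatable individual shade use but no
distributional form, so this is an explicit modelling choice, recorded in
the dataset's `truth` block along with every other generating parameter.

With both couplings at zero the rule degenerates to independent correlated
random walks whose marginal position stays uniform — the null substrate
for the calibration experiments. With the coupling on, the generator
reproduces the qualitative field pattern as an emergent property: hot
days pull sheep into patches, midday networks become denser, less modular
and more homogeneous, and the package's own suite checks exactly these
signs at full scale (48 × 82). Magnitudes are not calibrated to any field
estimate and should not be compared to one.

`inject_artifacts` corrupts a clean dataset with labelled defects aimed at
each cleaning filter: low-satellite fixes (nsat < 3, offset positions),
teleports (displacements ≥ 1.5 × the speed cap), out-and-back spikes
placed perpendicular to the local path at ~0.9 × cap so they pass the
speed filter but trip the turn rule, random fix deletion, and a per-collar
clock offset up to ±30 s (exercising the asynchronous-recording path of
the interpolator). Ground truth labels survive in the fixes table and the
`truth` block.

### What the synthetic experiments do not show

The generator produces no diel activity outside the midday window, no
water-point visits, no social preference structure beyond global cohesion,
and no behaviourally realistic locomotion. Passing recovery and sign
checks on it demonstrates that the pipeline measures what the generator
encodes — it does not validate the movement model against real sheep, and
field-data coefficient magnitudes are outside its reach.

## Numerical conventions

- Grid windows are half-open `[start, end)`; containment tests count
  polygon boundaries as inside; category bins are half-open at the
  printed thresholds.
- SRI denominators of zero give weight 0; edgeless days raise for
  modularity and CV rather than returning a silent placeholder.
- The greedy modularity merge is deterministic for a given graph; the
  suite pins its Q against an independent fast-greedy implementation
  (igraph) to 1e-9 on random small graphs.
- All randomness flows through `numpy` Generators seeded from explicit
  integers; identical configs give bit-identical datasets, and the
  pipeline manifest records a config hash plus a checksum per artefact.
- Mixed-model singular fits (variance ratio at the zero boundary) are
  reported via a `singular` flag, never silently dropped; the Gaussian
  solver then degenerates exactly to OLS.

## Known limitations

- Data-stream permutation p-values inherit the temporal-autocorrelation
  caveat above; with strongly persistent movement they are anti-
  conservative, and no option in this package removes that.
- The Poisson quadrature is non-adaptive; with very large random-intercept
  variances (σᵤ ≫ 1) more nodes may be needed than the default 25.
- Solar noon ignores the equation of time (≤ ±16 min).
- The day-scope swap chain's burn-in and thinning defaults (1000 / 10) are
  conventional, not derived; users of that mode should check mixing for
  their matrix sizes.
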