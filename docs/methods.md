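# Methods

This note documents the models, numerical choices, and design decisions
behind the package, and what the synthetic-data generator does and does not
emulate.

## AIS geometry

Skeletons (SWC, nm) are the geometric substrate throughout; mesh-based
measurements (ray-traced radii, surface geodesics) are replaced by stored
per-node radii and along-skeleton distances. The AIS domain between two
anchor points is the geodesic ellipse

    d_top(v) + d_bottom(v) <= d_AIS + padding,

with padding defaulting to 1000 nm so the domain wraps smoothly around
short protrusions near the path. A squared-comparison variant
(`comparison="squared"`) is available for sensitivity checks, since the
exact algebraic form of the published inequality is ambiguous in the
source material; the sum form is the default because it implements the
stated purpose directly. Analyses use the first 37 µm of arclength —
measured along the skeleton, another spot where a straightened-axis
reading would be possible — and the mean AIS radius averages node radii
with arclength in the inclusive window [5, 38] µm, skipping the
soma/dendrite transition. All other intervals in the package are
half-open `[lo, hi)`.

Per-synapse coordinates are (depth, orientation): depth is the arclength
of the nearest AIS node; orientation is the angle of the synapse around
the local cross-section centroid (nodes within a 400-nm depth slice),
measured in the plane orthogonal to the depth axis with 0 at +x and range
[-π, π). A synapse with (near-)zero radial offset has no defined angle; it
is assigned 0 and flagged, rather than dropped.

## Potential connectivity

A potential connection is an axon/AIS pair whose point clouds approach
within a Euclidean distance threshold (default 7.5 µm; the analysis is
meaningful over roughly 5–15 µm). Distance is point-cloud-to-point-cloud
minimum — axon skeleton points against AIS skeleton nodes, not meshes —
accelerated with a k-d tree but defined (and tested) against the
brute-force all-pairs scan. Cells whose threshold tube leaves the imaged
volume are excluded when more than 10% of a regular grid sample of the
tube (default spacing 250 nm) falls outside the bounds; grid sampling
replaces segmentation voxels, which this pipeline does not consume. Cells
excluded this way are dropped from `f_con` analyses but retained in the
synapse census.

## Structural components and regression

The six perisomatic features are z-scored, decomposed with FastICA
(k = 3, unit-variance whitening, logcosh contrast), and the target is
regressed on the scores with standardized OLS. FastICA is stochastic and
its iteration-delta convergence test can cycle indefinitely on some
datasets, so the fit is restarted (default 50; 25 in the pipeline) and the
returned solution is the one minimizing mean dissimilarity to the other
restarts — mean absolute loading difference after Hungarian matching of
components with sign freedom. Restarts that hit the iteration cap are kept
as candidates; the robustness selection is what rejects unstable
solutions, and an error is raised only when no restart produces a
solution at all. Components are signed so the largest-magnitude loading
is positive. The dissimilarity metric is this package's choice; other
robust-selection metrics would be defensible.

Because the scores are uncorrelated, R² equals the sum of squared
standardized coefficients. Confidence intervals come from the standard
OLS normal-theory formula (t quantiles); Holm–Šidák families are one per
correlation screen (15 feature pairs) and one per regression (3
coefficients). Sample SD uses the n−1 denominator throughout. Residual
scatter plots regress the target on the non-focal components and bootstrap
cells (N = 1000) for a percentile band; for a noiseless target the band
width decays as 1/sqrt(n) (the pairs bootstrap leaves O(n^-1/2) intercept
noise at finite n).

## Connection sizes and cisternal organelles

Connection sizes are fit with the support-1 geometric distribution,
`P(k) = p (1-p)^(k-1)`, whose MLE is `p = 1/mean`; the package treats the
reference "exponent" 0.44 as this success parameter because only that
reading is consistent with the reported mean of 2.3 synapses per
connection (1/0.44 = 2.27). A shifted-Poisson fit (1 + Poisson) is
provided for comparison. Goodness of fit is a chi-square with tail bins
pooled to expected counts >= 5 and one degree of freedom deducted for the
estimated parameter.

CO locations are DBSCAN clusters of annotation points per AIS in
cylindrical surface coordinates, d = sqrt(Δdepth² + (r·Δθ_wrapped)²) with
r the AIS mean radius — an analytic stand-in for mesh-surface geodesics
that is exact on a straight cylinder. The proximity test statistic is the
mean distance from each ChC synapse to the nearest same-AIS CO cluster;
the null reassigns each synapse to a random AIS at a candidate position
matched in depth within 200 nm and nearest in orientation (bounded
retries, dropped synapses counted). A within-AIS-only shuffle mode is
provided as a flag.

## Motif statistics

The bifan connectivity fraction counts, among potential edges whose
other three bifan edges are actual, the fraction that are themselves
actual; an edge participating in several bifans counts once (including
during biased selection — weight α is applied once per candidate edge
regardless of how many bifans it would close, an assumption the source
description leaves open). The shuffle iterates the actual edges in a
fresh random order each of 5 passes; each step removes an edge and redraws
the target cell's partner from its potential, not-currently-connected
axons (the removed one included), so per-target degree is preserved
exactly while source degrees float. Bifan-completion weights are
evaluated against the mid-shuffle actual set at selection time.
Two-sided significance is reported as 2·min(p_>, p_<) alongside the
one-sided 95% thresholds. Internally the shuffle and the fraction run on
boolean incidence matrices (the fraction via co-target count matrices),
verified in tests against exhaustive enumeration.

Power analysis generates replicate networks by biased shuffles of a
template (same potential graph and degree sequence) and tests each
against the unbiased null. At the problem sizes used in the test suite
(up to 90 axons × 110 cells, 100-shuffle nulls, 10–16 replicates) the
lower detection boundary (α ≈ 0.4) reproduces clearly while upper-side
power (α ≈ 1.5–2.5) is reduced relative to a full-scale analysis with
1000-shuffle nulls; the tests therefore assert detection below the lower
boundary, non-detection inside the undetectable band, and monotone power
in |log α|.

## Surrogate neuron and inhibition scenarios

The biophysically detailed all-active models used in the original
simulations are out of scope here. The driven cell is a two-compartment
conductance-based leaky integrate-and-fire neuron: a soma (180 pF, 12 nS
leak) electrically coupled (25 nS) to a small AIS compartment (12 pF,
1.5 nS leak) where spikes initiate at −52 mV with a 3-ms refractory
period; excitation (τ = 2 ms, E = 0 mV) enters the soma as a lumped
dendrite, inhibition (τ = 8 ms, E = −78 mV) enters either compartment.
Integration is forward Euler at 0.1 ms with exponential synaptic decay.
Parameters were set for a plausible f-I range (~0–200 Hz output over
0–500 Hz excitation) before any scenario comparison; all are exposed in
`NeuronParams`. Quantitative firing rates are not comparable to
morphologically detailed models — only the qualitative orderings between
scenarios and inhibition sites are claimed, and those emerge from the
conductance nonlinearity rather than from tuning: steady (asynchronous)
inhibition suppresses more than bursty (synchronous) input of equal rate
because suppression saturates during synchronous peaks, and AIS inhibition
outperforms somatic inhibition because it shunts the small
spike-initiation compartment directly.

Scenario trains share one 100-Hz homogeneous Poisson realization per
cluster (synchronous: one cluster; asynchronous: singleton clusters;
biologically inspired: cluster sizes drawn from an empirical
connection-size table with the final draw truncated). Barrages are
inhomogeneous Poisson by thinning under a Gaussian rate profile; the
profile width is not specified by the reference description and defaults
to 50 ms (configurable). The 25 excitatory connections share one train
per connection (two synapses each), with an independent-synapse flag.
Comparisons use one-sided Wilcoxon signed-rank tests across repetitions
with Benjamini–Hochberg control at 5% FDR (the FDR procedure itself being
unspecified in the source description).

## Activity statistics

Traces are Fourier-resampled (e.g. 30 → 12 Hz) before correlation.
Spontaneous periods are whatever mask the caller supplies — the synthetic
generator emits an all-true mask, since its "stimulus" is uniform.
Pairwise and cell-behavior correlations are plain Pearson r on masked
samples (Pearson is invariant to the affine scaling that z-scored display
traces undergo); zero-variance traces are flagged and excluded with a
count rather than failing the batch. Unpaired group comparisons use the
Mann–Whitney U test, matched cell-behavior comparisons the Wilcoxon
signed-rank test, both two-sided.

## Synthetic-data generator

The generator emulates the statistical structure the analyses assume,
not the biology of the tissue:

- Three latent per-cell components (depth, perisomatic inhibition,
  perisomatic size) are independent unit-variance Laplace draws. They are
  uncorrelated and standardized as the component model assumes; the
  Laplace choice (rather than Gaussian) is what makes the ICA mixing
  identifiable, since a rotation of Gaussian factors is observationally
  equivalent. Observed features are loadings·z plus Gaussian feature
  noise, mapped to realistic units; count-valued features are rounded.
- N_pot is Poisson with log-rate linear in depth (the published material
  reports no functional form for the depth gradient; log-linear is this
  package's modeling choice), f_con is logistic in the size and
  inhibition components, and synapses-per-connection is geometric
  (p = 0.44 in the calibrated preset).
- Axon "geometry" is a point cloud with one contact point 2 µm from a
  node of each potential target's AIS; somata sit on a 40-µm lateral
  grid, so the distance-threshold operation recovers the generated
  potential graph exactly for any threshold in [2, ~19] µm. Synapse
  depths are truncated-normal (23 ± 7.5 µm), placing ~97% above the
  37-µm cutoff. There is no axon branching, no boutons, and no volume
  curvature: passing tests certify the statistics, not morphological
  realism.
- Calcium traces are shared_gain · s + private_noise_sd · n per cell,
  where s is a unit-variance Ornstein–Uhlenbeck arousal filtered through
  an exponential indicator kernel and n is matched-filtered private
  noise, both standardized — so pairwise correlation has the closed form
  g²/(g² + σ²), which is what the tests check. Pupil is smoothed arousal
  plus noise; locomotion is thresholded arousal bursts. The reported
  in vivo correlation values are properties of real recordings and serve
  only as calibration references for these defaults.
- All randomness flows from one seed through named `SeedSequence` child
  streams (latents, noise, npot, edges, sizes, geometry, nonchc).

The `"paper"` preset holds parameters calibrated once, during
development, so that the full pipeline at n_cells = 113 sits at the
reference operating point: mean ~3.3 connections and ~7.5 ChC synapses
per AIS, standardized coefficients near (−0.47, +0.33, +0.34), R² near
0.45, top-3 PCA variance near 84%, f_con spanning 0–1. The calibrated
numbers live in `presets/paper.json`, not in logic. The preset's synapse
mean (7.5 = 3.3/0.44) differs from the reference 7.4 by ~2% because the
reference mean itself is slightly inconsistent with its own geometric
parameter; the generator is exactly geometric.

## Problem sizes in the test suite

Monte-Carlo checks run at sizes chosen to make their statistical claims
decidable while keeping the suite fast on a single CPU: geometric
goodness-of-fit on ~20k aggregated connection sizes, sign recovery at
n_cells = 500, R² calibration over 20 seeds at n = 113, scenario and
barrage orderings over 50 seeds, shuffle calibration with 100-shuffle
nulls and 16 replicates, and the near-paper-scale motif power analysis at
90 × 110 nodes. `scripts/acceptance.py` recomputes the two headline
quantities (geometric p from 1127 generated connection sizes; 100·R² at
n = 113 averaged over 20 seeds) in under a minute.

## Known limitations

- Skeleton-based distances understate mesh-surface proximity for thick
  processes; the potential threshold partially absorbs this.
- The CO proximity test's cylindrical metric ignores non-circular AIS
  cross-sections.
- The surrogate neuron has no dendritic nonlinearity, no sodium-channel
  kinetics at the AIS, and no GABA reversal dynamics; claims are
  restricted to orderings.
- The biased-network generator and shuffle treat bifan completion as a
  binary property per candidate edge; weighting by bifan multiplicity
  would sharpen strong-bias regimes.
- `generate_biased_network` builds clustering sequentially from an empty
  network, so very sparse potential graphs can leave some target degrees
  unmet (they are capped at the potential degree).
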