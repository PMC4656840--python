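# Methods

This note documents the statistical models implemented in `fosmap`, the
numerical choices behind them, what the synthetic-data generators do and do
not emulate, and the package's known limitations.

## Spike-train metrics

All per-cell metrics operate on the superimposition of a cell's sweeps
(sorted concatenation of sweep-relative spike times; `merge_sweeps`).

**Autocorrelogram.** Histogram of all ordered spike-pair time differences in
[−2 s, +2 s], 100 ms bins centered on multiples of the bin width, divided by
the lag-zero count. Self-pairs are included, so the lag-zero bin is at least
the spike count and the normalized value at lag 0 is exactly 1; the
histogram is symmetric by construction. Trains with fewer than two spikes
return an all-zero histogram with the lag-zero bin set to 1 and a
`degenerate` flag, so batch runs survive silent cells.

**Power spectrum.** Squared magnitude of the discrete Fourier transform of
the 41 autocorrelogram bins, frequencies 0 to ~5 Hz (the Nyquist limit of
the 100 ms binning, spectral resolution ≈ 0.244 Hz), normalized to unit
total power. Squaring matters: the lag-zero impulse of the normalized
autocorrelogram spreads a constant magnitude across all bins, and on the
squared scale that floor — and the sampling noise riding on it — stays well
below the fixed 0.008 peak threshold while genuine oscillations concentrate
a large power fraction in one peak. With magnitude (unsquared) spectra the
same thresholds misclassify roughly half of Poisson null trains as
periodic; with power spectra ≥ 90 % are correctly rejected (see the
acceptance suite).

**Periodicity Index.** Spectral local maxima are searched outside the DC
bin (the DC term reflects mean rate, not rhythm). A peak's height is its
value minus the lower of its two flanking local minima (spectrum endpoints
count as minima); peaks with height ≥ 0.008 are detected. For the highest
detected peak, PI = height / (frequency span between the flanking minima).
No detected peak, or PI < 0.003, classifies the cell as non-periodic;
otherwise the peak frequency is the predominant firing frequency. Both
thresholds are fixed, scale-free by the unit-power normalization, and
exposed as parameters.

**Bursting vs non-bursting.** Periodic cells are split by the
autocorrelogram central-peak dilation ratio: max(value at lag ±1 bin) /
value at lag 0, with bursting declared above 0.2. Rationale: single-spike
(or two-spike, sub-bin) periodic trains put essentially nothing in the bins
adjacent to lag zero, while bursts spanning a substantial part of the
100 ms bin spill intra-burst pair lags into them ("dilated peaks"). A
spectral-harmonic criterion was considered and rejected: bursts much
shorter than half the period barely attenuate the first harmonic, so
harmonic presence cannot separate the two modes at this bin width. The
0.2 threshold sits between the ratio of ≤ 2-spike trains (≈ 0) and of
4-to-5-spike, 30 ms-ISI bursts (≥ 0.3); the rule is flagged as heuristic in
the result object.

**Discrimination Index.** `D = (A1 − A2)/(A1 + A2)`, A1 the spikes in
[onset, onset + 1 s), A2 in the next second. D is undefined (flagged, not
an error) when A1 + A2 = 0. The ON/OFF class is the sign of D in the
control condition.

**Standardized ISI entropy.** Inter-spike intervals are taken from the
peristimulus window [onset − 1 s, pulse end + 1 s]; with
`pᵢ = ISIᵢ/Σ ISIⱼ`, `H = −Σ pᵢ ln pᵢ` and `Hs = H/ln n`. Hs ∈ [0, 1],
equals 1 iff all intervals are equal, and is invariant to a common
rescaling of the intervals. Fewer than two intervals → undefined (ln 1 = 0
would divide by zero) and flagged.

**Success/failure mixed model.** For each cell × condition, spikes in the
class-appropriate window (during the pulse for ON cells, right after for
OFF) are successes, all others failures. The model is binomial-logistic in
the 4-AP indicator with Gaussian random intercepts for rat and for cell,
fitted by a joint Laplace approximation: inner Newton on the penalized
log-likelihood over all random effects, outer Nelder–Mead over the fixed
effects and the two standard deviations, and a Wald p for the condition
coefficient from the numerical Hessian of the profile marginal likelihood.
With both SDs pinned at zero the fit coincides with plain logistic
regression to < 1e−3, which the tests verify against an independent GLM
implementation. All-success or all-failure tables are flagged as separated
with no estimate.

## Spatial statistics

**Clipped Voronoi areas.** The Voronoi cell of point *i* restricted to the
section polygon is the polygon clipped by the perpendicular-bisector
half-planes against the other points. The kernel clips the (CCW) region
ring with Sutherland–Hodgman, visiting neighbors in order of increasing
distance and stopping once the next point is farther than twice the current
cell's maximal vertex distance (its bisector can no longer cut). Clipping a
non-convex ring by a half-plane can create degenerate bridge edges; they
lie on the clip line and cancel exactly in the shoelace area. The kernel is
jit-compiled and agrees with an independent polygon-overlay computation
(GEOS Voronoi diagram intersected with the region) to a relative 1e−9 in
the tests; clipped areas sum to the region area to 1e−6 relative. Exact
duplicate points are perturbed by 1e−9 µm with a warning; points outside
the region are an error.

**Voronoi entropy and its Monte Carlo null.** `H = −Σ (Aᵢ/ΣA) ln(Aᵢ/ΣA)`
over the clipped areas; H ≤ ln n with equality iff all areas are equal, so
clustering lowers H. The null draws N_sim subsamples of size n_cFos
*without replacement* (a subsample of real cells cannot repeat a cell) from
the NeuN point set and computes `p = #(H_sim < H_obs)/N_sim`, ties counted
as not-below (conservative). The observed entropy is computed through the
same kernel and summation order as the simulated ones, so the degenerate
case n_cFos = n_NeuN yields `n_below = 0` bit-exactly. A zero count is
reported as "< 1/N_sim" rather than p = 0; the raw count is stored.
Defaults: N_sim = 50 000 for the entropy null and 10 000 for the median
test below, both configurable.

**Stripe partition and G-test.** Stripes are distance bands parallel to the
lateral edge: a point with lateral distance d lands in stripe
⌊d/thickness⌋, the most medial stripe absorbing the remainder. Band areas
come from intersecting the region with buffers of the edge polyline, so
they sum to the region area and counts are conserved. The shared stripe
rule for one dLGN sets k = round(√N_max) stripes, where N_max is the NeuN
count of that animal's densest section, and thickness = (latero-medial
extent of that section)/k — expected per-stripe counts of order √N_max keep
the count index away from very small values. The uniformity test is
`G = 2 Σ Oᵢ ln(Oᵢ/Eᵢ)` with area-proportional expectations and the
convention 0·ln(0/E) = 0, referred to χ²(k−1); a stripe with zero expected
area but observed counts is an error.

**Median lateralization test.** Observed statistic: median distance of the
activated cells to the lateral-edge polyline (minimum point-to-segment
distance). Null: medians of N_sim NeuN subsamples of size n_cFos;
`p = #(median_sim < median_obs)/N_sim`, small when activation hugs the
edge. Across sections, p-values are Holm-adjusted (step-down, monotonicity
enforced, capped at 1, returned in input order).

Coordinates are Cartesian micrometres, image convention (origin top-left, y
down). All tests are bit-reproducible for a fixed seed; the entire pipeline
is invariant under rigid motions of the section geometry.

## GAD-cell fluorescence scoring

ROI means are taken over pixels whose centers lie within a 20-pixel radius
of the cell center (no anti-aliasing, bit-reproducible); the disc must lie
fully inside the image. The background distribution is built from 1000 disc
placements drawn uniformly over valid centers by rejection sampling
(capped at 10⁶ attempts): the disc must fit in the image and must not
intersect the exclusion mask of putative c-Fos-positive regions; background
discs may overlap each other. A cell is c-Fos positive iff its ROI mean
*strictly* exceeds background mean + 2·SD — ties are negative. The
threshold shifts 1:1 with a constant added to the image, so calls are
offset-invariant. Downstream: logistic regressions of the call on the
treatment indicator and on the ordinal medio-lateral position (1 = lateral,
3 = medial; ordinal because µm positions are generally unavailable for the
3×3 field grid), with complete separation detected and flagged; and a
Poisson log-linear likelihood-ratio test of count homogeneity across field
locations (χ², #locations − 1 df; all-zero tables return p = 1 with a
degeneracy flag).

## Count model

Counts per section follow `ln λ = (α₀ + α₁ I_t) + (α₂ + α₃ I_t)·area + b`,
with `b ~ N(0, σ²)` shared within rat — random intercepts only, matching a
single between-rat dependency, and area as a covariate (not an offset),
following the model's printed parameterization. The marginal likelihood
factorizes over rats; each factor is integrated by a Laplace approximation
around the 1-D mode (damped Newton), and the whole negative log-likelihood
is jit-compiled because the bootstrap refits it thousands of times.
Nelder–Mead maximizes over (α, σ); σ enters through |σ| and σ < 1e−10
reduces exactly to the fixed-effect Poisson GLM (verified against an
independent GLM fit to < 1e−3). The treatment null H₀: α₁ = α₃ = 0 is
tested by LRT = 2(ll_full − ll_null), clipped at 0; its p-value is the
proportion of B parametric-bootstrap replicates — counts re-simulated from
the fitted null, including fresh rat intercepts — with LRT at least the
observed value. A parametric bootstrap (rather than case resampling)
respects the Poisson/random-intercept structure at small group counts.
Warm starts from the observed null fit keep a B = 200 bootstrap to a few
seconds. Estimates are equivariant under area rescaling (slopes scale
inversely).

## VEP metrics and permutation tests

Windows: ON = 0–150 ms and OFF = 300–450 ms from stimulus onset (the OFF
window is the 150 ms after the 300 ms stimulus ends). The peak metric is
the height, relative to the mean of the 50 ms pre-onset baseline, of the
first positive local maximum in the window with prominence of at least a
quarter of the window's peak-to-peak excursion — the recording chain is
DC-decoupled, so only baseline-relative heights are meaningful, and the
prominence floor keeps noise crests from masquerading as the P wave while
remaining scale-free. Windows with no such maximum (e.g. constant traces)
report 0 with a flag. The RMS integral is window-RMS × 0.15 s (V·s) on the
raw trace, choosing window-RMS × duration over a running-RMS integral; the
choice is recorded here and in the result metadata. Condition comparisons
permute group labels of the pooled per-sweep metrics and use the two-sided
pooled-variance t statistic with `p = (1 + #{|t*| ≥ |t|})/(1 + n_perm)`
(add-one so p is never 0). The pooled values are canonicalized (sorted,
smaller group size first) so swapping the groups leaves p exactly
unchanged; `exact=True` enumerates all label assignments instead and
returns the plain proportion, which includes the identity assignment.

## Synthetic-data generators

The generators emulate the statistical structure the analyses assume, with
ground truth recorded for round-trip tests; they are seed-deterministic.

*Sections.* The region is the set difference of an outer disc and a
medially offset disc, vertically stretched (y-scale 1.2) into elliptical
arcs; the lateral edge is the central 60 % of the outer arc, since retinal
fibers enter across the lateral border rather than the whole perimeter.
Defaults give ≈ 2.5 mm² area and ≈ 1.2 mm latero-medial extent. NeuN and
GAD points are independent homogeneous Poisson processes at 1704 and 278
cells/mm²; the activated subset (default density 228 cells/mm²) is drawn
from the NeuN points without replacement with weight exp(−d_lateral/scale)
via Gumbel keys — scale 0 is exactly uniform. Monte Carlo calibrations in
the tests use the same crescent at quarter scale (≈ 0.16 mm², ≈ 270 NeuN
cells) to keep 200-section runs to minutes; the calibration properties do
not depend on the section size.

*Spike trains.* 20 cells from 8 rats, 9 ON / 11 OFF. Control: spontaneous
homogeneous Poisson at 1.5 Hz (a typical RGC maintained rate; the source
tables do not state one) and stimulated sweeps with a ×6 rate gain in the
class-appropriate 1 s window, which puts the population mean |D| near 0.7.
Under 4-AP the spontaneous rate is multiplied by 6.2; 12 of 20 cells
switch to jittered renewal burst trains with frequency ~ N(3.52, 0.86)
truncated to (0.5, 5] Hz (respecting the 5 Hz spectral limit), per-cell
burst sizes drawn from {1, 2, 4, 5} at 30 ms intra-burst intervals with 5 %
period jitter. Two-spike bursts at this spacing are deliberate
"non-bursting" periodic cells (groups of one or two spikes); 4–5-spike
bursts span ≳ 100 ms and dilate the autocorrelogram peak. Stimulus gains
collapse to 1 + 0.05·(gain − 1) under 4-AP, dropping mean |D| below 0.1.
An 8 ms intra-burst interval was considered and rejected: such bursts fit
entirely inside one 100 ms autocorrelogram bin and are mathematically
indistinguishable from single-spike trains at this resolution.

*Fields.* I.i.d. Gaussian background noise (clipped at 0) plus
Gaussian-profile blobs: planted GAD-cell effects are specified in units of
the theoretical ROI-mean SD (σ_pixel/√m, m = disc pixels) and scaled so the
ROI mean rises by exactly that amount; bright non-GAD c-Fos blobs and any
GAD blob at ≥ 2 SD join the exclusion mask, mirroring the "avoid putative
positives" sampling rule.

*VEPs.* Damped sinusoids whose first crest is placed analytically at the
target latency (P wave at 40 ms from onset; OFF response 70 ms after
stimulus end) plus Gaussian noise low-pass filtered at 1 kHz like the
acquisition chain. The OFF window inherits a small (few percent) tail of
the ON component — a real superposition, which the tests tolerate.

*Counts.* Poisson draws from the mixed model itself, treatment assigned
per rat (half and half), areas ~ Uniform(0.4, 0.9) mm² unless given.

What the generators do **not** emulate: inhomogeneous NeuN density,
section-to-section staining variability, spatially correlated fluorescence
background, refractory periods and adaptation in spike trains, and
trial-to-trial VEP latency drift. Passing tests therefore demonstrate
correctness of the statistics under their stated assumptions, not
robustness to every failure mode of real histology or electrophysiology.

## Problem sizes and tolerances

The test suite runs the Monte Carlo calibrations at 200 sections ×
N_sim = 2000 (null size asserted within [0.03, 0.08]), the bootstrap LRT at
200 replicates × B = 200 (size within [0.02, 0.09]), parameter recovery at
50 simulations of the 8-rat × 9-slice design (mean estimates within 0.1 of
truth), and 500-replicate calibrations for the G-test and the VEP
permutation test. `scripts/acceptance.py` uses 60 calibration sections at
N_sim = 1000 and one bootstrap pair at B = 200 so a full run stays within a
few minutes on one CPU. Spectral frequency recovery is asserted to one
spectral bin (0.244 Hz); geometric identities to 1e−6 relative; oracle
agreements (G-test formula, exact permutation enumeration, zero-variance
GLMM reductions) to 1e−9 … 1e−3 as stated above.

## Known limitations

- The Laplace approximation can bias variance components toward zero for
  very small groups; the bootstrap LRT inherits its null from the same
  approximation (consistently, so the test stays calibrated — verified).
- The bursting classifier is a heuristic tied to the 100 ms bin width;
  bursts much shorter than the bin are reported as non-bursting by design.
- The Monte Carlo entropy test conditions on the observed NeuN pattern; it
  tests random *subsampling*, not complete spatial randomness of NeuN
  itself (that is the G-test's job).
- `lateral_distance` treats the edge polyline as exact; digitization error
  in traced edges propagates directly into stripe assignment near stripe
  boundaries.
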