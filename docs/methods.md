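# Methods

This note documents the models, parameter conventions and numerical choices
behind `spnlab`, and what the synthetic cohort does and does not emulate.

## Sensor geometry and neighbor graph

Cluster formation needs a scalp adjacency structure. Two sensors are
neighbors when their 3-D Euclidean distance is *strictly* below a threshold
(default 35 mm). Isolated sensors stay in the graph: they cannot join
multi-sensor clusters but still carry univariate statistics and can form
single-sensor clusters.

The packaged fixture (`spnlab/data/acticap64.tsv`) holds the 64 actiCAP
labels of the extended 10-20 system at standard idealized 10-05 positions
on a realistic head shape, uniformly scaled to an 89 mm mean sensor radius.
That scale was chosen so the 35 mm rule reproduces the qualitative
adjacency structure expected of this cap: ~3 neighbors per sensor on
average, with the below-ear sites (TP9/TP10, and here also FT9/FT10)
having no neighbors. On a perfect sphere these two features are mutually
exclusive — equidistant spacing makes the degree distribution collapse at a
single threshold — so a realistic (non-spherical) template is used. Exact
mean degree depends on the coordinate template and is only meaningful to
roughly ±1.

## Stimulus generator

Octagons are inscribed in a circle of radius 0.75° of visual angle. The
regular-octagon template places vertices at 22.5° + k·45°, deliberately off
the mirror axes. Each vertex is rotated about the origin by an angular
jitter uniform in ±20° (radial distance fixed). Asymmetric stimuli jitter
all eight vertices independently. Symmetric stimuli jitter two anchors —
one from each orbit of the template under
{identity, reflect-vertical, reflect-horizontal, rotate-180°} — and
complete the set by those reflections, guaranteeing eight distinct vertices
forming two orbits of four; the whole shape is then rotated by 45° or 135°.
Vertices are sorted by polar angle before export so perimeter/area code can
treat the octagon as a simple polygon. Near-coincident vertices
(probability ≈ 0) are resampled.

Mirror symmetry is verified by reflecting the vertex set about a candidate
axis and matching it to the original with optimal bipartite assignment; the
elongation axis is the principal eigenvector of the centered second-moment
tensor, with the eigenvalue ratio as anisotropy (flagged undefined within
1e-9 of isotropy).

One structural caveat: radial distance is matched *exactly* across
conditions by construction, but perimeter and enclosed area are matched
only approximately. The reflections correlate the angular gaps of symmetric
octagons (mean gap variance 3σ² instead of the asymmetric condition's 2σ²),
which lowers the expected perimeter by ~0.5% and the expected area by ~2%.
The invariant tests assert these bands rather than exact equality.

## Synthetic cohort

`SimulationConfig` defaults are the study conditions the pipeline is meant
to analyze: 23 participants × 120 trials, symmetric/asymmetric split drawn
per trial with p = 0.5, 64 channels, epochs −500…+1000 ms at 256 Hz.

**Behavior.** Each participant draws sensitivity d′ ~ N(1.88, 0.65)
(truncated at 0) and criterion c ~ N(−0.14, 0.23). Under the equal-variance
Gaussian model the probability of responding "symmetric" is Φ(d′/2 − c) on
symmetric and Φ(−d′/2 − c) on asymmetric trials. At the population means
this implies ~0.824 accuracy.

**EEG.** Each epoch is the sum of

* 1/f^χ background noise (default χ = 1, 10 μV per-sample SD), synthesized
  spectrally per channel and trial with an analytic variance calibration —
  epochs are *not* pre-baselined, so downstream baseline correction has
  real work to do;
* condition-common P1/N1-like deflections (Gaussian bumps, +2.5 μV at
  100 ms and −3 μV at 170 ms) with a posterior spatial profile — these
  cancel in S − A and exercise the condition-common signal path;
* on symmetric trials, the SPN: a subject amplitude
  A_i ~ N(−0.45, 0.63) μV times a Gaussian spatial profile over sensor
  distance to the occipito-parietal ROI centroid (σ = 45 mm) and a
  raised-cosine temporal profile spanning 250–600 ms peaking at 390 ms
  (a boxcar variant exists for exact analytic tests).

**Amplitude convention.** The injected profile is normalized so that the
*average-referenced* mean of the effect over the canonical ROI electrodes
and the SPN window equals A_i exactly. Without this, the temporal taper
alone would halve the measured window mean and the spatial profile and
common-average projection would attenuate it further, leaving the
amplitude parameter uninterpretable. With it, the canonical-ROI estimator
is unbiased for the population mean, which the parameter-recovery tests
verify (20 seeds at full size; across-seed mean within ±0.15 μV).

The between-subject SD default of 0.63 μV makes the implied within-subject
effect size d_z ≈ −0.71 under noise-free measurement; realized subject
variance is larger because trial-limited averaging adds measurement noise
(~0.5–0.7 μV at the default trial counts), so realized |d_z| is somewhat
smaller. The SPN is injected on *all* symmetric trials (a config flag
restricts it to correct ones): the analysis averages correct trials only,
and injecting everywhere keeps the generative model independent of the
behavioral stream while still exercising the correct-only filter.

Randomness is organized as named substreams spawned from the master seed
(behavior / noise / amplitude per participant), so any participant subset
is bit-reproducible regardless of cohort size.

**What the generator does not emulate:** volume-conducted channel
correlations (noise is independent per channel), eye/muscle artifacts,
drifting impedances, latency jitter of the SPN across trials or subjects,
and any earlier symmetry effects on P1/N1. Passing tests therefore
demonstrate correctness of the *statistics* under a controlled generative
model, not robustness to real-recording pathologies.

## Epoch screening

Windows are specified in ms and mapped to the sampling grid by including
every sample at or inside each bound. Screening operates per participant on
the epochs retained at entry, *after* the correct-trial filter (the
distributional kurtosis thresholds make the order observable; a constructed
counterexample in the tests shows retained counts can differ if the order
is swapped).

* **Amplitude**: any |value| > 120 μV within −200…600 ms.
* **Trend**: per channel, the least-squares line over the full epoch; flag
  when the *total fitted change* exceeds 75 μV with R² > 0.50. The
  threshold is interpreted as change-over-window (μV), the convention of
  minimal-slope rejection in common EEG practice, since a per-second slope
  would carry different units.
* **Kurtosis**: per channel per epoch excess kurtosis; "local" z-scores
  each channel's kurtosis across the participant's epochs and flags |z| > 7
  on any channel; "global" does the same for the across-channel mean.
  The z-scoring axes are a documented interpretation of the usual
  local/global distinction, not a canonical definition. Note a single
  outlying epoch among n can reach at most z ≈ √n, so the kurtosis screen
  is inert for small epoch counts — as intended for a 7 SD rule.

## Cluster-based permutation inference

The test statistic at each (electrode, sample) is the one-sample t of the
per-subject S − A difference (df = n − 1); zero-variance points get t = 0
with a warning rather than ±∞. Suprathreshold points (|t| above the
two-sided p < .05 critical value) are partitioned into same-sign connected
components under sensor-neighbor adjacency at the same sample plus
same-sensor adjacency at consecutive samples; diagonal links are not
connected (the common default for sensor-time clustering). The cluster mass
is the summed t.

The null distribution records, per permutation, the maximum |mass| over all
clusters of either sign, with each permutation flipping the sign of whole
subject difference maps independently — the exact exchangeability of a
paired design ("condition labels exchanged within participants"). A
trial-level label-shuffle variant exists behind a flag but is not the
default: with subject-level averaging the sign-flip scheme is the standard
choice. Corrected p = (1 + #{null ≥ |mass|}) / (B + 1), so p is never 0 and
the observed labeling is effectively included; significance is p ≤ .05,
two-sided by construction of the max-|mass| null.

For cohorts of ≤ 16 subjects `exhaustive_null` enumerates all 2ⁿ sign
assignments and returns exact p values; the Monte Carlo engine is validated
against it (±0.02 at B = 5000) and its family-wise error rate is checked on
200 zero-effect datasets against the exact central binomial band around
0.05. A useful algebraic fact keeps permutations cheap: the pointwise sum
of squares is sign-invariant, so each permutation's t-map costs one matrix
product.

## SPN quantification and derived statistics

The per-participant SPN follows the order: window mean per electrode per
condition → electrode-wise S − A → mean over ROI electrodes. All steps are
linear, so this order is a reporting convention; a regression test asserts
order-equivalence to 1e-12. The cluster-derived ROI is recomputed from the
pipeline's own significant cluster (union of electrodes, cluster time
window) — never hard-coded. Peak latency is the earliest minimizing sample
of the group ROI difference within the window.

Hemispheric sets split ROI electrodes by the 10-20 numeric suffix (odd =
left, even = right, z-midline excluded). The lateralization index
(R − L)/(|L| + |R|) is bounded in [−1, 1] and flagged undefined (NaN) at
zero denominator. Effect size d_z = t/√n. Correlations use Pearson r with
Fisher-z intervals (SE = 1/√(n−3)); the analytic power of a two-sided
correlation test uses the same approximation.

## Behavior statistics

The chance gate uses the binomial (1 − α) quantile — smallest k with
P(X ≤ k) ≥ 1 − α — which gives 69/120 at α = .05; the stricter tail
convention (smallest k with P(X ≥ k) < α) is available behind a flag and
can differ by one. Hit/false-alarm rates are clamped to
[1/(2N), 1 − 1/(2N)] per class before the probit transform. One-sample
t-tests report one- or two-sided p with the matching one-sided half-line
CI. Mixed-model intercepts are summarized on the probability scale by the
inverse logit of the estimate and its Wald interval; the GLMM fit itself is
out of scope.

## Subsampling reliability

Epoch-level ROI/window means are computed once and resampled — numerically
identical to re-averaging epochs and far cheaper. The cohort is fixed and
balanced: every participant contributes m epochs per condition, so the
largest testable m is capped by the participant with the fewest usable
epochs in either condition; a participant below the cap raises an error
naming them rather than being dropped silently. Draws use independent
substreams per (m, permutation, participant), making any sub-curve
reproducible. The test direction is fixed at H₁: SPN < 0.

Within one cohort the permutation p values all share the cohort's realized
effect, so under a zero-effect generative model the rejection rate is 0.05
only *in expectation over cohorts* — the calibration test averages over
independent cohorts accordingly.

## Problem sizes and defaults used in the checks

The validation suite runs the permutation engine's error-rate calibration
on 200 zero-effect datasets of 12 subjects × 16 channels × 64 samples at
B = 1000; oracle comparisons on an 8-subject instance (2⁸ enumerable);
parameter recovery at the full study conditions over 20 seeds; stimulus
geometry over 10,000 octagons; and the reliability curve at B = 1000 on one
full-size cohort, with m capped by the realized balanced count. The
acceptance script uses B = 2000 for the cluster test and B = 500 for the
reliability curve of its single synthetic run.

## Known limitations

* Adjacency depends on the coordinate template; graphs from digitized
  positions will differ in detail.
* The noise model's channel independence understates spatial correlation,
  making cluster masses smaller than in volume-conducted data at matched
  SNR; the calibration guarantees concern error rates, not realistic mass
  magnitudes.
* The cluster-derived ROI inherits the selection bias intrinsic to
  data-driven windows (its SPN magnitudes exceed canonical-ROI ones).
* The trial-level permutation variant re-averages per permutation and is
  markedly slower; it is provided for comparison, not tuned for scale.
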