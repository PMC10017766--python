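# Methods

This note records the models behind each analysis stage, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical decisions taken where the procedures left room.

## Line-scan segmentation

**Model.** A line scan across one endomysial span is a two-channel trace
`(position μm, red, green)`: red is laminin α2 marking the two basement
membranes (BM), green is a co-stained ECM component. The red channel is
modelled as two peaks over a flat background; each peak is either one
Gaussian or a two-Gaussian mixture (a BM cross-section may be asymmetric or
doubled). Segment points sit at the effective mean ± 2 effective SD of each
fitted peak — for a mixture, the area-weighted first and second moments —
capturing 95.45% of the fitted mass. BM regions are `[s1,s2]` and
`[s3,s4]`; the IM is `[s2,s3]`. Abundance is the trapezoidal AUC of the
basal-corrected channel over each region (intensity·μm); the red-derived
points are applied unchanged to the green channel so both channels are
quantified on the same anatomy.

**Stage order and which trace feeds what.** Basal correction first, then
zero-phase smoothing. The *smoothed* trace is used only to locate the two
peaks and define per-peak fit windows (the half-spans on either side of the
inter-peak midpoint). The Gaussian fits and the AUCs use the *unsmoothed*
basal-corrected trace, for two measured reasons: (i) forward–backward
filtering correlates neighbouring residuals, which makes an RSS-based BIC
drastically overstate the evidence for the six-parameter mixture and
inflates the effective SD; on white residuals the penalty is honest.
(ii) A zero-phase filter preserves total area but redistributes mass across
segment boundaries, visibly at sharp IM edges (~2% of the IM AUC at the
default bandwidth); integrating the raw trace avoids the bias, and noise
largely cancels in the integral anyway.

**Basal value.** Default estimator is an iterative two-sided sigma-clipped
mean seeded from the lowest quartile; it is unbiased for the background
level under additive noise and robust to the peaks and the IM plateau. The
simpler percentile-of-trace estimator (`basal_method="percentile"`,
default 5th percentile) is retained but sits a predictable ≈1.3 noise-SD
below the true background, which would inflate every AUC by (offset ×
window width). Subtraction, not division, keeps abundances in
intensity·μm. After segmentation, the mean of the structure-free exterior
of the BM windows (beyond a 2σ buffer) is measured per channel and removed
before integration (`refine_background=True`); this second pass cancels the
residual bias of any first-pass estimator (including the ≈+0.2 noise-SD
tail contamination of the clipped mean), at the cost of a small variance
term set by the number of exterior samples. The red peaks are refit on the
refined trace.

**Smoothing.** Butterworth low-pass, order 3, cutoff 0.2 × Nyquist,
applied forward–backward (zero phase). The defaults are recorded in every
result's parameter block and configurable via `FilterSettings`.

**Peak finding.** The two highest local maxima separated by at least
`min_separation` (default 4 × median sample spacing) *and* with topographic
prominence ≥ 5% of the trace's dynamic range. The prominence requirement is
what "distinct" means operationally: at fine sampling, residual noise
ripple on one physical peak produces local maxima that pass any small
distance threshold. Spans without two qualifying peaks raise a structured
"no distinct basement membrane" error and are excluded (and logged by the
pipeline driver), never silently skipped. Equal heights tie-break leftmost.

**Model selection.** Both gauss1 and gauss2 are fitted by bounded
nonlinear least squares; gauss2 is kept only if (a) it lowers
`BIC = n·ln(RSS/n) + k·ln n` by more than 2 and (b) it is a valid
description of *this* peak — both component means within two
FWHM-equivalents of the apex and neither component below 5% of the total
area. Guard (b) exists because an unconstrained second component otherwise
wanders off to model baseline structure, which blows up the mixture SD and
the segment window. If both windows overlap, the midpoint is assigned to
both s2 and s3 and the result flagged `no_distinct_im` (fibrotic spans with
expanded laminin still yield BM abundances) rather than erroring.

**Stoichiometry.** Green BM AUC / red BM AUC by default (a perfectly
co-localised component at equal scaled intensity gives 1); the reciprocal
convention is available. An overlap-style coefficient was considered and
rejected as a default because it conflates localisation with abundance.

## Remodeling index

Control ("myoscaffold") and treated ("myoscaffold + cells") sections are
different physical samples, so locations cannot be paired;
`RI_i = mean(control)/treated_i` gives one RI per treated location, and the
summary is the arithmetic mean ± SD. The reverse orientation is available
behind a flag. RI is scale-invariant, so any per-location intensity
convention (pixel max or local line-scan peak) works as long as it is
consistent across conditions.

## Motility, adhesion, fusion

Speeds are per-interval Euclidean displacements in μm/TI; gaps in a track
yield no entry rather than a spanning pseudo-speed. Windows are half-open
`[t0, t1)` with each interval assigned to its start time. "Total
displacement" over 15 h (exactly 90 intervals at TI = 10 min) is cumulative
path length — consistent with summing per-interval displacements — with
net start-to-end displacement reported as a secondary column; cells not
observed in every frame of the window raise a typed exclusion. Fusion
scoring classifies α-actinin⁺ regions by nucleus count (≥3 myotube, 1–2
myocyte), uses centroid-inside-region membership with boundaries counted
inside, and reports 100 × (myotube nuclei)/(all nuclei).

## AFM mechanics

**Contact point.** The approach baseline (including linear drift) is fitted
over the first 30% of the segment; contact is the first sample whose
corrected force exceeds 5 × the baseline noise SD for 5 consecutive
samples, backtracked to where the force last left the baseline. The
baseline is then refit over the whole pre-contact region and the detection
repeated — the two-pass scheme roughly halves the tilt error extrapolated
under the contact data.

**Modulus.** `F = (2/π)·tan(α)·E/(1−ν²)·δ²` with δ = contact − separation,
fitted over forces up to the trigger (3 nN default, mirroring acquisition).
With forces in nN and separations in μm, E comes out in kPa directly.
Defaults: equivalent cone of half-angle 35° (the standard approximation for
pyramidal soft-matter probes; the four-sided-pyramid constant 0.7453·tanα
is selectable), ν = 0.5 (incompressible limit). By the model formula,
fitting the same curve at ν = 0.5 yields exactly 0.75 × the E obtained at
ν = 0. The contact point is co-refined by default: for any candidate
offset the best E is a closed-form linear solution, so the refinement is a
profiled one-dimensional search over the offset with a band of pre-contact
samples included — a plain two-parameter optimiser stalls on the flat
gradients of the clipped quadratic, and threshold detection alone is
biased late by a large fraction of the indentation depth once noise is
present. Co-estimating the contact point is also the accuracy bottleneck:
at force noise of 10% of the *peak* (trigger) force, the maximum-likelihood
error of any free-contact fit is ≈6% median, which is why the recovery
studies quote noise relative to the mean contact force (≈ trigger/3).

**Rupture force.** Magnitude of the deepest negative excursion of the
baseline-corrected retraction, 0 if no dip exceeds 3 × the post-pull-off
noise SD. On noisy curves a 5-sample moving average precedes the extremum:
the raw minimum of a long noisy trace overstates the dip by the expected
extreme of the noise (≈1.8 SD at these lengths), while the smoothing
attenuates a realistic dip by well under 1%.

## Synthetic generators and what passing tests show

All generators are pure functions of (parameters, seed) with explicit
seeds, and each stores ground truth sufficient to predict every downstream
result exactly (noiseless) or within stated statistical tolerance (noisy).

- **Line scans** — red: baseline + two Gaussians + i.i.d. Gaussian noise;
  green: a configurable fraction (default 0.8) of the BM peaks plus an IM
  plateau with erf-shaped edges (width 0.4 μm) and the same baseline and
  noise. The soft plateau edges exist because a step ending exactly at the
  truth segment points would make the truth AUC discontinuously sensitive
  to window placement; no real interstitial boundary is a step function.
  Defaults (20 μm span at 0.05 μm spacing, peak SNR 20, IM level
  comparable to the BM signal) describe a bright confocal immunostain;
  closed-form region integrals are verified against high-resolution
  quadrature in the tests.
- **Remodeling fields** — the per-location remodeling ratio is lognormal
  with mean = factor and CV as configured, and treated = control_mean /
  ratio; placing the noise on the ratio keeps the mean RI unbiased for the
  factor (noise multiplying the treated intensity instead would bias the
  mean of `1/treated` upward by exp(σ²) ≈ 4% at CV 0.2). Control
  intensities are lognormal about the control mean. The lognormal choice
  is a stand-in — no distributional description of endomysial intensity
  variability is available to fit.
- **Tracks** — persistent random walks: heading increments are
  `(1−persistence)·U(−π,π)`, step lengths Normal(speed_mean, speed_sd)
  clipped at 0, 10-min intervals; dropout truncates a track at a random
  frame. Persistence 1 with zero speed SD gives exact straight lines.
- **Fusion fields** — non-overlapping axis-aligned ellipses placed by
  bounded reject-and-retry (error if the field cannot hold them); myotubes
  hold 3 + Poisson nuclei, myocytes 1–2, plus background mononuclear
  cells. An optional rasterizer emits integer label masks for the
  image-based code path.
- **Force curves** — exact Hertzian approach truncated at the trigger
  force with ≥ 30% pre-contact baseline; retraction retraces the contact
  and adds a Gaussian-shaped adhesion dip normalised so its sampled
  minimum is exactly −depth; Gaussian force noise throughout.

What the generators do **not** emulate: optical blur and bleaching,
spatially correlated (structured) background, tracking/linking errors,
cantilever calibration error, thin-sample (bottom-effect) corrections, and
any biology of the remodeling process itself. Passing tests therefore
certify the *quantification* chain — segmentation, fitting, integration,
counting, contact mechanics — against known truth, not robustness to every
artefact of real microscopy.

## Degenerate inputs and tie-breaks

Constant-zero channels pass through basal scaling unchanged, with a
warning flag; equal-height peak candidates tie-break leftmost;
nuclei exactly on a region boundary count as inside; a retraction with no
dip below threshold reports 0 nN, not an error; profiles shorter than the
zero-phase filter's stability limit, windows with fewer than 8 samples,
and fits with fewer than 10 indentation points raise typed errors naming
the limit. Abundances are floored at zero (relevant only when integration
windows cover pure noise).

## Study sizes

The recovery studies use 200 line-scan replicates, 2000 remodeling
locations, 100 fusion fields, and 200 force curves — large enough that the
binomial/statistical tolerances quoted above are meaningful, while a full
test-plus-acceptance run completes in about a minute on one CPU.

## Known limitations

- The segmentation assumes exactly two BM peaks per span; three-fiber
  junctions or grazing sections are rejected rather than partitioned.
- Outlier removal across profiles (done downstream in the original
  workflow's statistics software) is out of scope; batch summaries report
  plain mean ± SD.
- The Hertz fit has no bottom-effect correction, so moduli from sections
  thinner than ~10 × the indentation depth would be overestimated.
- Fusion membership is centroid-based; a nucleus straddling a region edge
  is assigned by its centre alone.
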