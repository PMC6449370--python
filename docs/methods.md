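# Methods

This note documents the models, estimators, numerical choices and known
limitations behind each module, and what the synthetic-data generators do and
do not emulate.

## Vesicle Ca²⁺ influx

**Model.** Each vesicle is a diffraction-limited spot whose brightness tracks
the intravesicular Ca²⁺-dye signal. Three phases are acquired with the field
held registered: background (intact vesicles, baseline dye signal), sample
(partial influx through aggregate-permeabilized membranes) and ionomycin
(ionophore-saturated, the full-influx reference). The per-vesicle influx
fraction is `(F_s − F_b) / (F_i − F_b)`; it is affine invariant (adding a
constant to all three F, or rescaling all three about F_b, cancels), which is
why the photometry only needs to be *linear* in spot brightness, not
calibrated.

**Estimators and defaults.**
- Detection runs on the background phase: temporal mean → difference of
  Gaussians (σ = 1.3 px and 2σ, matching the PSF scale) → local maxima above
  5× the filtered image's robust noise (MAD), minimum separation 2× the ROI
  radius, centroids refined by local centre of mass. The emulated acquisition
  protocol dictates no particular detector, so this standard spot-detection
  chain is a design choice favouring robustness on diffraction-limited spots.
- Photometry: fixed 3 px disk mean minus the median of a surrounding annulus
  (gap 2 px, width 3 px), averaged over frames, identical ROI geometry across
  phases. Annulus subtraction makes F invariant to additive offsets; because
  the median of `bg + A·g(x)` over a fixed pixel set is linear in the
  amplitude A, the influx ratio is *exact* on noiseless data even though the
  annulus clips PSF tails.
- QC: the denominator must exceed `3 × noise` (noise = per-pixel sd of the
  temporal mean); otherwise the vesicle is dye-free or unresponsive and the
  ratio is noise-dominated. Influx values outside [0, 1] are flagged but kept:
  truncation would bias condition means upward/downward asymmetrically.
- Phases are assumed registered (the acquisition avoids moving the slide); an
  optional rigid-shift correction by phase cross-correlation exists for drift
  testing, off by default.
- Condition comparison defaults to pooling vesicles within a field and
  comparing per-field means with a pooled t-test; pooling across fields is
  also available but per-field means are the replication unit.

**Generator.** Spots are isotropic 2-D Gaussians (σ in px) on a constant
background with i.i.d. Gaussian read noise per frame; per-vesicle baseline
amplitudes are uniform in [80, 160] a.u. with an ionomycin gain of 400 a.u.,
giving SNR ≈ 10 per frame at the default noise sd of 10. True influx
fractions are drawn from a mean/sd-parametrized Beta so every draw lies in
[0, 1]. Defaults follow the acquisition protocol: 50 frames per phase, 50 ms
exposure, 100 nm pixels. Not emulated: photobleaching, EMCCD gain statistics,
vectorial PSF shape, vesicle size dispersity. Passing tests therefore show
estimator correctness under Gaussian noise and a stationary PSF, not
robustness to bleaching or optical aberrations.

## FRET bursts

**Model.** Aggregates carrying both donor- and acceptor-labelled monomers
transit a confocal volume under flow; photons are binned at 0.2 ms (chosen
near the expected residence time). A burst is a maximal run of bins whose
*summed* channel count exceeds `bg + m√bg` — the search is channel-blind so
detection does not bias the efficiency distribution. The relative efficiency
is the proximity ratio `E = I_A / (I_A + γ·I_D)` with γ = 1 and no spectral
crosstalk by default (both configurable); background-corrected channel sums
are clamped at zero, and bursts with non-positive corrected totals are
dropped with a reason.

**Numerics.** Background is an iteratively sigma-clipped mean of the summed
channel (clip at mean + 5√mean, the Poisson scale) — a plain median fails at
rates below ~0.7/bin where the Poisson median is 0. The E histogram (50 bins
over [0, 1]) is fitted with a single Gaussian by least squares, initialized
from the histogram moments; the amplitude is bounded by 10× the tallest bin
because sparse symmetric histograms otherwise admit a degenerate
narrow-spike ridge (amp → ∞, σ → 0) along which the optimizer never formally
converges although the centre estimate is already exact — near-zero-cost
solutions are therefore accepted as converged. Non-convergence falls back to
the raw mode with a flag.

**Generator.** Burst starts are Bernoulli per bin at the configured event
rate with a short dead time (10 bins) so ground-truth spans stay unambiguous;
durations are geometric (memoryless transit); per-population brightnesses are
Poisson per bin on top of Poisson background, so `E_true = a/(a+d)` exactly
and binomial photon partitioning keeps the estimator unbiased. Not emulated:
diffusion-shaped intensity profiles within a burst, interphoton timing,
detector afterpulsing. The trace length is configurable; the stated
acquisition's bin count (10⁵ bins of 0.2 ms) is self-inconsistent with its
10 min duration, so the simulator takes `n_bins` explicitly and makes no
claim about wall-clock duration.

## AFM morphometry

**Flattening and noise.** Raw maps carry per-scanline offsets/tilt. Each row
is fitted with a polynomial (order 1 by default, ≤ 3 enforced) over
*background* pixels only: a global particle mask (pixels above 3× the MAD
scale of the residual map, one-sided since features protrude upward) is
rebuilt and the fits repeated until stable. On noiseless maps the MAD is
floored at a tiny relative scale so features are still masked. Noise is the
RMS of the sigma-clipped background, matching the sub-ångström roughness
regime of the emulated experiments (0.05 nm default, SNR ≈ 10 for a single
monomer).

**Measurement.** Segmentation is 8-connected above `3 × noise`, minimum area
4 px, border-touching regions excluded from statistics (incomplete geometry).
Peak height is read from a Gaussian-smoothed map when the map is noisy — the
smoothing scale is fixed in nm (0.5 nm) so its bias is grid-independent; at
0.05 nm roughness this keeps the height error well below 0.05 nm (max-pixel
reading on the raw map would be biased upward by the noise maximum over the
region). On effectively noiseless maps the raw map is used. Widths are full
widths at half maximum along the profile through the peak perpendicular to
the region's major axis (principal component of the pixel coordinates),
sub-pixel by linear interpolation, averaging three parallel profiles when
noisy. Length is the extent along the major axis.

**Tip deconvolution.** The probe apex is modelled as a sphere of radius R
(10 nm default). For a convex spherical-cap particle (true cap radius `R_s`,
height h) the recorded surface is exactly the dilation of the cap by the tip
sphere: a cap of radius `R_s + R` with the same apex height. A width w
measured at height `t` on the apparent profile therefore determines

    R_s + R = ((w/2)² + (h−t)²) / (2(h−t)),
    d_true  = 2·√(2·R_s·h − h²)        (base diameter)

which is inverted exactly at t = h/2 (the FWHM). The correction vanishes as
R → 0. Validity requires h < 2R (the apex must envelope the feature) and
caps at most hemispherical (h ≤ d/2, the geometry of surface-flattened
aggregates); outside validity the measured width is returned flagged, and
degenerate inversions are floored at 0.1 nm. This contact-geometry inversion
was chosen over the steep-wall broadening formula
`w − 2√(2Rh − h²)` (exact for mesa-like cross-sections, not for caps): only
the cap inversion survives the round trip against the simulator's grey-scale
dilation oracle across d ∈ [1, 10] nm at R = 10 nm. Known limitation: for
sub-tip features (d ≪ R) the inversion is ill-conditioned — the particle's
contribution to the apparent width scales as `d²/(8Rh)·(d/w)`, so at d = 1 nm
a 0.03 nm width error already moves the estimate by ~15%. The validation
round trip is therefore run noiseless on fine grids (0.05–0.25 nm/px chosen
so the discrete-dilation bias, which scales as px², stays below that budget);
at experimental roughness the deconvolved diameter of ~1 nm particles should
be treated as qualitative. Heights carry no such limit.

**Classification.** Shape-first precedence resolves the overlapping height
bands: protofilament (aspect ≥ 3, length ≥ 100 nm, height 0.4–1 nm), then
monomer [0.3, 0.5) nm, oligomer [0.5, 2] nm, higher-order > 2 nm, else
unclassified. Elongation is checked before height because protofilaments are
distinguished morphologically from spherical species.

**Generator.** True shapes are spherical caps (height + base diameter) and
filaments (a cap cross-section swept along a spine with rounded ends);
imaging is grey-scale dilation with the spherical-tip structuring element
(entries = −sag, trimmed where the sag exceeds the tallest feature since such
offsets can never win against the substrate), then a tilt plane and Gaussian
roughness. The dilation is the brute-force physical model and doubles as the
oracle for the deconvolution. Not emulated: tip wear/asymmetry, feedback
artefacts, scanner creep, particle deformation under the tip.

## Spectral hydrophobicity

Dispersion is calibrated as a least-squares line from (spectral pixel,
wavelength) bead pairs; the RMS residual is reported so grating nonlinearity
is visible. "Mean emission" is operationalized as the intensity-weighted
spectral centroid (robust at low photon counts; a smoothed-argmax variant
exists for comparison). Localizations are grouped per aggregate by DBSCAN
(eps = 100 nm — well above the 20 nm localization precision and well below
the ≥ 500 nm aggregate spacing; min 3 points per core), clusters below 10
localizations are discarded, and cluster ids are relabelled by centroid
position so results are independent of input order. Group shift is
`mean(B) − mean(A)`; positive = group A blueshifted = more hydrophobic
(Nile-red solvatochromism). The generator adds a per-aggregate offset
(sd 3 nm) on top of the group mean and a 5 nm within-aggregate spectral sd —
aggregate-to-aggregate heterogeneity is what makes the aggregate (not the
localization) the replication unit. Not emulated: overlapping emitters on the
spectral axis, drift, photon-count-dependent centroid precision.

## Spot counting

A spot is a local maximum with prominence ≥ the noise tolerance. Prominences
are computed exactly by activating pixels in descending order and merging
components (union-find): when a component joins one with a strictly higher
peak, its maxima die at the current level and their prominence is
peak − saddle. Plateaus are handled by processing equal values in a fixed
order: plateau components forming at their own level merge without spawning
extra maxima, and a "maximum" that touches higher ground at its own level has
zero prominence and is discarded. Equal-peak maxima joined through a lower
saddle are both retained and die together at the saddle to strictly higher
ground. The globally highest maximum never meets higher ground; its
prominence is referenced to the image median (the background level), which is
what makes a blank noise field count zero at a tolerance of several noise sd
(a min-referenced definition would count the global noise maximum, since the
max−min range of a 64×64 Gaussian field is ~6.8σ). Counting is translation
invariant and equivariant under joint intensity/tolerance scaling; agreement
with an exhaustive per-maximum flood-fill oracle is tested on random
quantized images including ties and plateaus. Multi-frame stacks are reduced
to their temporal mean before counting. The numeric tolerance is a required
user parameter — no equivalence to any particular instrument setting is
claimed.

## Dose–response statistics

The unpaired two-sample t-test defaults to the pooled-variance form
(mirroring the default of the spreadsheet-style tools these assays are
usually analysed with); Welch is available and preferable when variances
differ. Zero-variance degenerate inputs follow the convention p = 1 for equal
means and p = 0 otherwise. No multiple-testing correction is applied (single
pairwise comparisons); Bonferroni is left to users running panels.
Half-inhibition concentrations interpolate the 0.5 crossing of response vs
log₁₀ concentration between the bracketing measured pair — the dose–response
convention — and never extrapolate: an uncrossed curve returns an explicit
"not reached". Untreated (zero-concentration) points cannot sit on a log axis
and are excluded from interpolation.

Small-sample caveat: at n = 3 vs 3 the exact permutation null of the t
statistic has only 10 distinct two-sided levels (granularity 0.1), so a
t-test p-value can sit up to ~0.05 from the plain permutation p on any single
dataset even when both are correct; the mid-p convention centres the cells
but per-dataset differences of ~0.05–0.1 remain typical. Agreement between
the two should be judged across datasets (no systematic offset), not
pointwise; the test suite checks exactly that.

## Problem sizes

The shipped validation scenarios use 100-vesicle fields (256² px, 50 frames)
and 3 × 1000-vesicle fields (768² px, 15 frames) for the influx assay;
1.5–2.2 × 10⁵ bin traces for FRET (plus 5000 direct draws for the
histogram-fit check); single-particle AFM maps at 0.05–0.25 nm/px for the
deconvolution round trip and 420² px maps at 1 nm/px for classification;
2 × 30 aggregates for the spectral comparison; and 64–128 px spot fields.
These sizes were chosen so every recovery check is comfortably
statistics-limited rather than fixture-limited while the whole suite runs in
a few minutes.
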