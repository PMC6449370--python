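# aggresense

Quantification toolkit for single-aggregate biophysics of amyloid-β (Aβ42)
oligomers — the small soluble aggregates implicated in Alzheimer's disease.
Size-fractionated Aβ42 aggregates are characterized one particle at a time by
five complementary single-aggregate assays; `aggresense` implements the
quantitative analysis of each assay, together with a synthetic-data subpackage
that generates ground-truthed inputs for every stage so the entire pipeline is
testable without any instrument data.

Intended users: biophysicists and microscopists analysing single-vesicle
permeabilization assays, single-molecule FRET traces, high-resolution AFM maps
of protein aggregates, spectrally resolved PAINT data or single-aggregate ThT
images — and developers who need a fully simulatable reference pipeline.

## What it computes

**Vesicle Ca²⁺ influx** (`aggresense.vesicles`). Surface-tethered, dye-loaded
lipid vesicles are imaged by TIRF in three phases: background, after adding
the aggregate sample, and after saturation with the ionophore ionomycin. Per
vesicle,

```
Ca²⁺ influx = (F_sample − F_background) / (F_ionomycin − F_background)
```

with F the annulus-subtracted spot intensity averaged over the 50 frames of a
phase. The module detects vesicles (difference-of-Gaussians band-pass + local
maxima), measures the three phase intensities with identical ROI geometry,
applies the ratio with QC on the denominator, and summarizes fields and
conditions (ratio of means + unpaired t-test).

**FRET burst analysis** (`aggresense.fret`). Two-colour photon traces binned
at 0.2 ms are searched for bursts — runs of bins whose summed-channel count
exceeds background by `m·√background` (m = 10 by default). Each burst's
relative FRET efficiency is the proximity ratio `E = I_A / (I_A + I_D)` of the
background-corrected channel sums; per-fraction E histograms over [0, 1] are
summarized by the maximum of a least-squares Gaussian fit.

**AFM morphometry** (`aggresense.afm`). Height maps are flattened per
scanline, particles segmented above `3 × noise`, and each particle measured
for peak height, FWHM, length and aspect ratio. Apparent widths are broadened
by the ~10 nm probe apex; the deconvolution inverts the spherical-tip /
spherical-cap contact model (the apparent profile of a convex cap of radius
`R_s` imaged by a tip of radius `R` is a cap of radius `R_s + R`) to recover
the true base diameter. Species classes follow cross-sectional height bands —
monomer 0.3–0.5 nm, spherical oligomer 0.5–2 nm, higher-order > 2 nm — with
elongated particles of 0.4–1 nm height and ≥ 100 nm length classified as
protofilaments.

**Spectral hydrophobicity** (`aggresense.spectral`). Nile-red PAINT
localizations carry per-event emission spectra; after a linear dispersion
calibration each localization reduces to its spectral centroid, localizations
cluster per aggregate (DBSCAN), and group comparisons report the emission
shift (blueshift = more hydrophobic) with a t-test.

**ThT spot counting** (`aggresense.spots`). Local maxima are counted by exact
prominence (height above the highest saddle toward higher ground) against a
constant noise tolerance, with plateau maxima counted once — the semantics of
noise-tolerance maxima finding, computed by a union-find watershed sweep.

**Dose–response statistics** (`aggresense.stats`). Pooled or Welch unpaired
t-tests, normalization to untreated controls, and half-inhibition
concentrations by interpolation of the 50% crossing in log₁₀ concentration.

**Synthetic data** (`aggresense.simulate`). Ground-truthed generators for all
five assays: three-phase vesicle stacks obeying the influx ratio by
construction, Poisson burst traces with known spans and efficiencies, AFM maps
rendered and then tip-convolved by grey-scale dilation with a spherical
structuring element (the brute-force oracle the deconvolution is validated
against), clustered spectral localization streams, and sparse spot images.
All generators are bit-reproducible from a seed (PCG64).

## Worked example

```
$ python examples/vesicle_influx.py
vesicles simulated     : 100
vesicles detected      : 98
mean influx (measured) : 0.518 +- 0.015
mean influx (true)     : 0.515
```

A 100-vesicle field at SNR ≈ 10 is simulated with true influx fractions
drawn around 0.5; the pipeline recovers 98/100 vesicles with no false
positives and a pooled mean influx within one standard error of the truth —
the detector, photometry and ratio chain is unbiased at this noise level.
The other scripts in `examples/` exercise the remaining assays the same way
(burst recall and fitted E maxima, AFM heights/diameters/classes, the 10 nm
spectral blueshift, exact spot counts, a 2 µM half-inhibition recovery).

## Command line

Every stage is also exposed as a thin CLI over the same functions:

```
aggresense simulate vesicles --config cfg.yaml --out data/
aggresense influx --background b.tif --sample s.tif --ionomycin i.tif --out out/
aggresense fret --trace trace.csv --out out/
aggresense afm --map map.tif --pixel-size 0.25 --tip-radius 10 --out out/
aggresense spectral --locs locs.csv --out out/
aggresense spots --image img.tif --tolerance 50 --out out/
aggresense stats ttest --csv tidy.csv --condition-a early --condition-b late
```

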