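# Methods

This note documents the models, estimators, numerical choices and known
limitations of `hcsquant`. It complements the README, which describes what
the package computes; here we explain *how*, and why the defaults are what
they are.

## Nuclear-translocation scoring

**Per-cell ratio.** For each segmented cell, the score is the mean
ATF6-channel intensity over the nucleus mask divided by the mean over the
ER mask. No background correction is applied at this stage: the ratio of
two means over regions of comparable background is insensitive to a common
additive offset at typical signal levels, and any scaling of the camera
cancels exactly. Cells with a non-positive ER mean cannot produce a ratio
and are dropped with a logged count.

**Plate-adaptive threshold.** Both control populations (stressed and
unstressed) are histogrammed on common bins of width 0.05 ratio units
anchored at 0. Bins are right-closed, (lo, lo+w]: a ratio exactly on a bin
edge belongs to the lower bin, mirroring the strict ">" comparison used
everywhere else (a cell exactly at the threshold is *not* activated).
Counts are normalized to each population's size by default, making the
rule invariant to unequal well populations; raw-count comparison is
available via `count_mode="raw"`. The threshold is the lower edge of the
lowest bin whose left edge exceeds 1 in which the stressed frequency is
strictly above the unstressed one, provided the following two bins do not
contradict it (stressed ≥ unstressed). This run-length guard (default 3,
disable with `run_length=1`) suppresses single-bin sampling artifacts; the
successor condition is non-strict so that an isolated stressed excess at
the top of the ratio range — where both histograms are otherwise empty —
still qualifies. If no bin qualifies, a `ThresholdDerivationError` names
both wells: a stressed control that does not separate from its unstressed
partner is a failed plate, not a quiet zero.

Bin width 0.05 is fine enough to resolve the >1 boundary and coarse enough
that ~300-cell wells give stable per-bin frequencies. The threshold is
derived per plate from designated control wells and never shared across
plates. Whether the "threshold" is a bin edge or center is a convention;
the lower edge is used and reported together with the bin width.

**Percent activation and hit calling.** Percent activation is the
percentage of a well's cells strictly above the threshold (wells below 50
cells are scored but flagged as noisy). Test wells are hits when their
percent activation is strictly below mean − 3·SD of the stressed-control
wells, with the sample standard deviation (n−1) over at least two control
wells. With m control wells the plug-in rule's null false-hit probability
is not the Gaussian 3σ tail but P(T_{m−1} < −3/√(1+1/m)) for Student's T
(≈ 6.1% at m = 3, ≈ 0.4% at m = 8); the acceptance tests verify the
Monte-Carlo rate against this closed form. More control replicates tighten
the rule considerably.

## Segmentation

Nuclei: median background subtraction, global Otsu threshold, hole
filling, then a distance-transform watershed whose seeds are intensity
maxima at least 6 μm apart (half a typical U2-OS nucleus diameter), and an
area gate of 40–400 μm². All parameters are exposed in the config. Blank
images yield empty label maps, not errors.

Cells: the GRP94-positive region (Otsu on the background-subtracted ER
channel, union the nuclei) is partitioned among nuclei by a watershed
seeded from the nucleus labels on the inverted ER intensity. A cell's "ER
mask" is its assigned ER-positive territory minus its nucleus, so the two
masks are disjoint by construction (asserted on every record). Nuclei with
no ER territory are dropped and counted. Cells touching the image border
are flagged and excluded from scoring by default, since partial cells bias
region means. No mitotic/apoptotic filter is implemented.

## ERES detection and colocalization

**Product mask.** Each channel has its median subtracted (negatives
clamped to 0) before the Sec31A × Sec16 multiplication. Without this, the
product of two positive camera backgrounds is non-zero everywhere and the
double-positive interpretation of the product fails.

**Detection and declumping.** Objects are found on the product image by a
global Otsu threshold (switchable to a mean threshold). Clumps are split by
a watershed seeded at intensity maxima; the seed image is a smoothed copy
(Gaussian σ = d_max/4 ≈ 3.8 px at 0.11 μm/px) so that pixel noise on one
large punctum cannot shatter it into several gate-passing fragments, and a
connected plateau of tied maxima collapses to a single seed so flat-topped
objects are never fragmented.

**Size calibration.** The footprint of each object is then re-measured at
25% of its own product-image peak. The product of two like Gaussian spots
squares the profile, so quarter-max in the product is half-max per channel:
the equivalent diameter of this footprint estimates the punctum's FWHM on
the single-channel scale, independently of where the global threshold
happened to fall for that object's brightness. Objects whose refined
footprints coincide (two seeds on one noise-split punctum) are merged. For
flat-topped objects the quarter-max footprint is the full object, so
uniform test targets measure their literal diameter. The 0.167–1.67 μm
gate applies to these calibrated diameters and is asserted on every run.

**Correlation.** Colocalization is the Pearson correlation of two raw
(unprocessed) channels over the pixels of a cell's retained ERES in one
z-slice, pooled across the cell's objects. Per-object correlation on 3–10
pixel spots is numerically unstable; it remains available via
`mode="per_object"`. Slices with fewer than 3 pooled pixels or a constant
channel are skipped and counted. Per-cell mean and SD across slices, and
treatment/experiment level means of per-cell means, follow by plain
averaging; the experiment mean equals the mean of its cells' means by
definition. Slices are analyzed independently in 2D.

## Synthetic scenes

The generator produces the statistical structure the estimators must
recover, not photorealistic cells:

* **Geometry.** Cells are non-overlapping disks (rejection-sampled
  centers; an error is raised if placement fails, rather than silently
  overlapping), with the nucleus a concentric disk and the ER the
  remaining annulus. Real ER morphology is irrelevant to region-mean
  statistics. Defaults: 12 μm nuclei in 26 μm cells at 0.8 μm/px for the
  translocation assay (20x objective, EMCCD-class camera), 10 μm in 22 μm
  at 0.11 μm/px for the ERES assay (100x with tube lens), ~8 cells per
  512×512 translocation field.
* **Ratios.** Per-cell true nuclear:ER ratios are lognormal about the
  component median — 0.8 for inactive cells, 2.5 for activated, σ(log) =
  0.25 — producing the overlapping unimodal/bimodal histograms the
  threshold rule must handle. The ATF6 channel is rendered so the
  mean-over-true-masks ratio equals the drawn value *exactly* before
  noise (the ATF6 background is confined to outside the cells).
* **Puncta.** Diffraction-limited spots are 2D Gaussians with FWHM equal
  to the nominal diameter, truncated at 10% of peak; placement enforces a
  separation of twice the largest diameter and a full diameter of
  clearance from the ER-annulus edges, so puncta from different channels
  or adjacent cells never overlap in the product image. The ground-truth
  pixel set of a punctum is its half-max (FWHM) disk. A punctum marked
  colocalized appears in both Sec31A and Sec16; otherwise in exactly one.
* **Correlation.** Within a cell's colocalized puncta the ATF6 values are
  built from the standardized clean Sec31A profile z and an independent
  standard normal n as μ + σ(ρz + √(1−ρ²)·n), so the pooled within-puncta
  Pearson correlation has expectation ρ, is exactly ±1 at ρ = ±1 with
  noise off, and recovers ρ within Fisher-z sampling error (±0.05 needs
  ≥ 2000 pooled pixels). Photon noise attenuates the measured correlation
  toward 0, as in real data; recovery under noise is therefore checked as
  monotonicity in ρ rather than as an absolute bound.
* **Noise.** Poisson shot noise (`photon_scale` photons per intensity
  unit) followed by additive Gaussian read noise, clipped at 0. The helper
  `noise_for_snr` solves for the photon scale that gives a requested
  foreground SNR. Defaults (photon_scale 1.0, read 2.0) give SNR ≈ 13 at
  the default stain intensities.

What the generator does **not** emulate: irregular cell and nucleus
shapes, ER texture structure, spatially varying background and
illumination, cell-to-cell stain variability beyond the per-punctum
amplitude lognormal, z-PSF blur between slices, photobleaching, drift, or
mitotic/apoptotic morphologies. Passing recovery tests therefore
demonstrates correctness of the estimators under the assay's statistical
model, not robustness to every real-world artifact; on real plates the
segmentation parameters in particular should be re-tuned on control
wells.

## Statistics

The two-sample t-test uses the pooled-variance (Student) form, consistent
with reporting an F test supporting equal variances alongside it; Welch is
available via a flag. One-way ANOVA uses the standard (k−1, N−k)
decomposition; for two groups F = t² exactly, which is asserted to 1e-10
in tests. The variance-ratio F test puts the larger sample variance in the
numerator and doubles the upper tail. Degenerate inputs (all values
identical) report statistic 0, p = 1, flagged, rather than raising, so
batch reports keep running; zero-variance groups with different means
report p = 0, flagged. No multiple-testing correction is applied — raw
p-values are reported with a note in the run metadata.

Confidence limits on treatment means are t-based 95% intervals. Box plots
drawn by the reporting module use min/max whiskers.

## Problem sizes used in validation

The recovery suites run at desk scale: 20-cell fields for segmentation
(SNR 5 and 10), two- or three-field ERES scenes with 15–60 puncta per cell
for detection and correlation, 24 wells × 300 cells (sampled from the
ratio mixture directly) for percent-activation recovery, 1000 simulated
plates for the null hit-rate calibration, and 2000 replicates for the
type-I-error checks. The acceptance script simulates 100 well pairs of 300
cells. These sizes put Monte-Carlo error comfortably inside each stated
tolerance while keeping the full suite to a few minutes on one CPU.

## Known limitations

* The ERES diameter calibration assumes near-Gaussian spots; for markedly
  non-Gaussian objects the quarter-max footprint no longer equals the
  channel half-max (flat objects measure their literal extent, which is
  the sensible fallback).
* The threshold rule needs a working stressed control; plates without
  stressed/unstressed separation fail loudly by design.
* Correlations are pooled per cell and slice; biological heterogeneity
  *between* a cell's ERES contributes to the pooled value.
* 2D only: z-stacks are processed slice-wise and aggregated; there is no
  volumetric segmentation or linking of objects across slices.
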