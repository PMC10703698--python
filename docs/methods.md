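# Methods

This note documents the models, conventions and numerical choices behind
`gemquant`, and what the synthetic-data generators do and do not emulate.

## Coordinate and unit conventions

Volumes are stored `[z, y, x]` (MRC section/row/column order); physical
coordinates are `(x, y, z)` in nanometres with the origin at the **centre of
the corner voxel**, so voxel index `i` sits at `i · voxel_size`. Voxels are
isotropic; anisotropic headers are rejected at configuration time (the
tomograms this pipeline targets are reconstructed at isotropic 13.48/13.70 Å
bins). MRC headers carry ångström; conversion (1 nm = 10 Å) happens only at
the I/O boundary. Particle tables are CSV in physical nm.

## Tomographic preprocessing

The filter chain is: Fourier Gaussian low-pass, Gaussian high-pass,
zero-mean/unit-sd normalization, clamping at ±3 sd — in that fixed order,
with no re-normalization after the clamp. Both filters are parameterized in
cycles/voxel with amplitude `exp(−f²/(2c²))`; the low-pass uses `c = 0.25`
and the high-pass is the complement with `c = 1/5` (i.e. a 5-pixel cutoff).
Gaussian-filter dialects differ between packages in where the factor of 2
sits; this parameterization is fixed and tested against the closed-form
transfer ratio on white noise, so any alternative dialect is a documented
one-line change.

A constant input volume has no defined normalization and raises rather than
returning NaNs.

## Probability-map postprocessing

Maps are binarized at 0.5, zeroed outside the lamella mask, and labeled with
26-connectivity (the conservative choice: it never splits one blob's diagonal
voxels into two particles; the 6-connected variant is available). Component
size bounds (5,000–50,000 voxels) are interpreted as **physical-volume
bounds anchored at the 1.37 nm reference voxel**: a component of `n` voxels
at voxel size `v` counts as `n · (v/1.37)³`, making accept/reject decisions
invariant to binning. The particle coordinate is the probability-weighted
(sub-voxel) centroid, matching downstream use of refined coordinates; the
score is the component's maximum probability.

Masking commutes with thresholding, so applying the lamella mask before or
after binarization is identical (tested).

## Shell matched filter

`detect_shells` is a classical stand-in for a learned detector: normalized
cross-correlation against a zero-mean, unit-norm hollow-shell template
(negative contrast — protein is dark), followed by greedy non-maximum
suppression (highest score first, ties broken by lexicographic voxel order,
minimum separation in nm). It is exact on clean data and is used to validate
the geometry pipeline, not to compete with CNN detectors on noisy tomograms.

## Distances and enrichment

Surface distance = (trilinearly interpolated Euclidean distance transform of
the structure complement at the particle centre) − particle radius
(12.5 nm). Nearest-voxel sampling is available as a compatibility switch.
Interpolation error is bounded by half a voxel diagonal (≈1.19 nm at
1.37 nm voxels) and tested against brute-force nearest-voxel search.

"Within 50 nm" is inclusive and negative surface distances count as within
(physical overlap is maximal proximity). `fraction_within` raises on an
empty record set rather than silently returning zero.

Dilation is exact Euclidean (EDT of the complement ≤ radius), tested against
lattice-ball enumeration. A dilation radius below one voxel cannot change
the mask and returns a copy with a warning.

Enrichment uses the lamella mask volume as the denominator for `f_V`
(equating the "imaged cellular volume" with the geometric lamella;
organelle-interior exclusion is possible by pre-masking the lamella).
Pooling across tomograms sums counts and voxel volumes before dividing —
not a mean of per-tomogram folds.

Two asymmetries worth knowing:

* The particle criterion (surface distance ≤ 50 nm, i.e. centre distance
  ≤ 62.5 nm) and the volume region (structure dilated by 50 nm) differ by
  the radius subtraction, so even under uniform placement the fold exceeds 1
  slightly for finite-radius particles. This is intrinsic to the statistic
  as defined; the uniform-null convergence test therefore uses point
  particles (radius 0), for which the two regions coincide.
* A closed structure (sphere/tube) has an interior that particles cannot
  occupy but whose dilated shell still counts in `f_V`; a uniform null is
  only exactly 1 for structures without excluded interior (a membrane
  plane).

## Synthetic scenes

`simulate_scene` builds a slab lamella (optional tilt about y) containing a
membrane plane, sphere, or tube rendered as a one-voxel-thick surface (the
plane is snapped to a voxel plane so analytic and rasterized geometry
agree). Bound particles draw surface distances from N(mean, sd) and sit at
`distance + radius` from the structure surface along a random surface
normal; draws are rejected and retried (≤1000 per particle) until the centre
lies inside the lamella, inside the volume, and respects the hard-sphere
separation (2 × radius by default; `min_separation` overrides it, and
`edge_margin` additionally keeps centres away from volume/lamella faces so
rendered blobs are never clipped in detection studies). "Inside the
lamella" constrains the particle **centre**, which keeps uniform background
placement exactly uniform over the lamella.

Consequences of rejection sampling to be aware of: at dense packings the
hard-sphere constraint preferentially rejects draws near the mode, inflating
the *spread* of accepted surface distances (e.g. sd ≈ 8.6 nm for 200
particles generated at sd 6 nm on one plane) while leaving the *mean*
unbiased by symmetry — recovery targets therefore concern the mean. Scene
volumes must give the packing room: the 200-particle distance-recovery
condition uses a 700 × 700 × 218 nm volume (512 × 512 × 160 voxels at
1.37 nm).

Probability maps paint uniform-valued spheres (peak drawn from
`peak_prob_range ⊂ (0.5, 1]`) at true centres, plus optional decoys sized to
fall below / inside / above the size-filter band, plus clamped Gaussian
noise. The default blob radius is the 13.7 nm training-label radius; note a
uniform sphere at that radius rasterizes to ~4,170 voxels at 1.37 nm —
*below* the 5,000-voxel minimum (real detector blobs are larger than their
training label). End-to-end detection studies therefore pass an in-band blob
radius (16.4 nm ≈ 7,150 voxels) explicitly.

Density volumes render particles as negative-contrast hollow shells
(inner radius 9 nm, outer = particle radius) over Gaussian noise, with an
optional missing wedge (tilt axis y, ±60° default) applied by zeroing the
unsampled Fourier region; the wedge is off by default and no detection stage
relies on it.

## Recruitment kinetics

The generator's stated structure is first-order saturation: the expected
on-target fraction at time `t` is `f_max · (1 − e^(−t/τ))`, realized
per cell/timepoint as a binomial draw; puncta are Gaussian spots, "on
target" meaning the spot centre falls inside the target disk. This is a
modeling choice for exercising the statistics, not a mechanistic claim.
Measurement by Otsu segmentation + centroid-in-mask is accurate when puncta
are resolvable; overlapping puncta merge and bias fractions, so fidelity
tests use sparse configurations (≈15 puncta in 256² px).

Group comparison is Kruskal–Wallis (tie-corrected) followed by Dunn's test
against the baseline group only, two-sided z from pooled mean ranks with the
standard tie correction, Bonferroni-multiplied by the number of baseline
comparisons and capped at 1 (the baseline-only family). If all observations
are identical the comparison degenerates to H = 0, all p = 1. The
expression–specificity correlation defaults to Spearman (robust to monotone
scale effects); Pearson is a flag away.

## FRAP

Single normalization only: background-subtract, divide by the prebleach
mean (ten prebleach frames at 50 ms by default). Frame `bleach_index` is the
first frame *acquired after* the bleach pulse; the fit's time origin sits
there, and a frame recorded during bleaching — ill-defined in real data —
is simply not part of this trace convention. Fitting is
Levenberg–Marquardt on `I(t) = I∞ − (I∞ − I₀)e^(−kt)` with transparent
initialization (I₀ = first post-bleach value, I∞ = mean of the last 10% of
frames, k from log-linear regression of I∞ − I); noise-free model data are
recovered to machine precision. Non-recovering traces (k ≤ 0 or I∞ ≤ I₀
within a small amplitude tolerance that guards against float dust in flat
traces) raise an identifiability error with diagnostics. Both per-trace
fits (mean ± sd across traces) and the mean-trace fit are provided and
labeled; the generator's `noise_sd` is expressed as a fraction of prebleach
intensity so normalized traces carry exactly that noise sd.

## Problem sizes and determinism

Every generator consumes a `numpy` `default_rng(seed)`; identical configs and
seeds give bit-identical outputs, and the pipeline writes byte-identical
artifacts for identical config + seed. Study problem sizes were chosen as
the smallest that leave the statistics well-resolved: 100 FRAP traces of 200
frames; 200 particles for distance recovery (tolerance 3σ/√n ≈ 1.27 nm);
2,000 point particles for the uniform-enrichment null (≈0.08 relative
Monte-Carlo SE).

## What the synthetic data does not emulate

No tomographic image formation (CTF, dose weighting, tilt-series projection
or reconstruction noise), no icosahedral symmetry (spherical shells carry
the detection geometry), no detector-specific blob shapes, no chromatic or
registration errors on the fluorescence side, and no mechanistic recruitment
kinetics. Passing tests demonstrate that the measurement code is correct on
data matching its stated assumptions — not that a learned detector would
reach the same recall on real tomograms.
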