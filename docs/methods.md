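# Methods

## Data model and coordinate conventions

A cell is represented by the point objects an upstream segmentation tool
exports: per accumulation a continuous 3D centroid in voxel coordinates
(origin at the corner of voxel (0,0,0)), a volume in voxels `n_i ≥ 1`,
and a mean intensity `I_i ≥ 0`. Whether the exported centroid is
geometric or intensity-weighted is the segmentation tool's choice; we
accept it as given. The nucleus reference point is computed from
nucleus-channel objects with the same virtual-mass center-of-mass
formula as receptor distributions, so nuclei and receptors share one
representation throughout (including in simulation).

Physical calibration is a per-axis voxel edge length in µm. The default
is isotropic, the cube root of the 0.0037 µm³ voxel volume typical of
the confocal stacks this analysis targets. Voxel coordinates are
converted to µm per axis *before* any distance is taken; in voxel units
the two orders agree only for isotropic voxels.

## Metrics

The distribution center of mass weights each object by `I_i·n_i`; the
global-intensity normalization `I_g` cancels algebraically, and a test
asserts the cancellation numerically. The reference metric is the
Euclidean norm of the µm-converted difference between the receptor COM
and the nucleus COM. The spread metric averages, unweighted, the
µm-distance of each accumulation to the distribution COM: each
accumulation counts once regardless of its mass. A `weighted=True`
switch averages with virtual masses instead, since the averaging rule is
a genuinely open choice; unweighted is the default because the metric is
defined over *detected accumulations*, not over intensity.

Both metrics are translation invariant and invariant under a global
rescaling of intensities; property tests assert both, and an exact
rational-arithmetic (fractions-based) oracle pins the COM itself to
1e-9.

## Simulation engine

The empirical sampler inverts the empirical CDF with linear
interpolation between order statistics (`u = 0` → sample minimum,
`u = 1` → maximum). Interpolation rather than step-function inversion
keeps small sources from producing duplicate-only draws; draws never
leave the source range.

Perturbations are applied to the *pooled* source values of a variable
before the sampler is built:

- shift: `x → x + n·x̄`;
- spread: `x → x + n·x̄·(x_rnd − x̄)/b`, with `x_rnd` an
  inverse-transform draw from the source values and
  `b = max_i |x_i − x̄|` (degenerate sources with `b = 0` are rejected).

`x̄` and `b` are computed on the pooled values of the whole source
group, not per cell. Note the shift and spread scales are proportional
to `x̄` and therefore depend on the coordinate origin; with image-frame
coordinates (cells roughly centered in the field) even `n = 0.2`
displaces by a fifth of the cell's distance from the frame origin, which
is why small `n` are already detectable.

Per simulated cell, the object count is resampled from the source's
per-cell counts, and x, y, z, volume and intensity are drawn
independently from their per-variable samplers — inter-variable
correlation in the source is deliberately not preserved (the sampling is
one-dimensional by construction). Perturbations default to the spatial
coordinates; flags extend them to volume/intensity. Reference points are
always drawn from the unperturbed pooled reference coordinates.
Randomness uses one root `SeedSequence` with hierarchical spawning, so
reruns are bit-identical.

Simulation fidelity is scored on shared bins spanning the union of both
samples (bin count by Sturges' rule on the larger sample, edges recorded
in the report): cosine distance `1 − cosθ` of the count vectors,
histogram overlap `Σ min(p_i, q_i)` of the probability-normalized
histograms, and the discrete Hellinger distance
`(1/√2)·sqrt(Σ(√p_i − √q_i)²)`. Unnormalized inputs to the latter two
are normalized internally.

### Detection decisions

The simulation study compares, for each perturbation mode and each
`n`, an equal-size simulated group against the source with a two-sided
Mann–Whitney U on both metrics. One such comparison is a Bernoulli
trial: even under the null it rejects with probability ~α. The study
therefore runs R independent simulation replicates per (mode, n)
(default R = 9) and takes the decision from the **median p-value** — a
majority vote at level α — reporting the per-replicate rejection
fraction alongside. This stabilizes the detection threshold (the
smallest significant `n`) without changing what is estimated.

A random-split control (source halved at random, halves compared on both
metrics) runs alongside; on homogeneous data it rejects at about the
nominal rate.

One behavior reported for real data is *not* reproduced here: on
heterogeneous experimental cells, pooling all coordinates makes
simulated per-cell spread values much tighter than experimental ones,
which can spuriously flag the spread metric for shifted data. The
synthetic cells are homogeneous (one cluster scale for all cells), so
pooling loses nothing and a pure shift leaves the spread metric exactly
invariant.

## Colocalization

Pearson's score is the standard correlation of per-pixel intensities;
the formula's range is [−1, 1] and no clamping to a sub-range is done.
Li's ICQ is the fraction of pixels whose mean-centered channel
intensities agree in sign, minus 0.5; pixels exactly on a channel mean
count in the denominator only. Channel means are taken over the whole
included region (optionally masked); 3D stacks are pooled as one pixel
population, one score per cell. No thresholding or background
subtraction is applied. Note that on sparse spot images most pixels sit
below both channel means, which biases ICQ upward even for independent
channels; ICQ ≈ 0 for independent channels holds only when the
intensity distribution is roughly balanced around its mean (dense
fields, or the uniform-noise images used in the bound checks).

## Statistics

Group comparisons use the two-sided Mann–Whitney U: exact null
distribution when the combined sample is ≤ 30 without ties, otherwise
the normal approximation with continuity and tie correction. Stars
follow the ladder `*` p<0.05, `**` p<0.01, `***` p<0.001, `****`
p<0.0001, `-` otherwise. Raw p-values are reported by default (many
comparisons, hypothesis-generating setting); Benjamini–Hochberg
adjustment is available behind a config flag.

## Synthetic data generator

The generator emulates the object tables of single cells on 50 µm
micropatterns imaged as confocal stacks, not the images themselves (no
PSF, no shot noise, no segmentation errors). Defaults, chosen once as
plausible study conditions:

| parameter | default | meaning |
|---|---|---|
| frame | 512×512×40 voxels | field of view, ~79×79×6 µm at 0.0037 µm³/voxel |
| pattern diameter | 50 µm | adhesive island; circle or crossbow footprint |
| objects/cell | Poisson(150) | detected accumulations per cell |
| cluster σ | (8, 8, 0.8) µm | receptor cloud scale (planted spread) |
| COM offset | (12, 0, 0) µm | receptor cloud center relative to nucleus (planted shift) |
| nucleus jitter | (0.5, 0.5, 0.15) µm | cell-to-cell nucleus placement scatter |
| nucleus | 20 objects, σ (2.5, 2.5, 0.8) µm | nucleus-channel objects defining the reference |
| volumes | lognormal, median 30 vox, σ_log 0.6 | accumulation sizes |
| intensities | Gamma(3, 40) | mean intensities |

Receptor positions are Gaussian about the (offset) nucleus, rejection-
sampled into the footprint and frame. The crossbow footprint contract:
upper half-disc of the pattern circle plus a stem rectangle of width
0.2·radius reaching down to the circle's lowest point. The thin z-range
(~10% of the xy diameter) mimics adherent-cell stacks.

The planted COM offset is the expected reference metric and, for an
isotropic cluster of scale σ, the expected spread metric is the 3D
half-normal radial mean `2σ·√(2/π)`; both identities hold exactly only
without footprint clipping and with small nucleus noise, so the recovery
tests use an unclipped isotropic spec. With the clipped defaults the
realized offset is ~10.8 µm rather than the planted 12 µm — the
footprint truncates the outward tail.

Because cells are homogeneous and coordinates live in a common frame,
passing the simulation-study checks on these fixtures demonstrates the
*mechanics* of detection (what each metric responds to, at what
magnitude, at the study's group size of 36 cells), not performance on
heterogeneous real cells, where between-cell variability adds noise the
generator does not model.

The paired-image generator places Gaussian spots (amplitude 200, σ 2 px,
additive noise clipped at zero); a fraction ρ of channel-B spots reuses
channel-A centers, the rest are uniform. Both colocalization scores
increase monotonically with ρ.

## Problem sizes and numerical choices

The shipped study configuration uses 36 cells per group, ~150 objects
per cell, the `n` ladder {0, 0.2, 1, 2}, 9 replicates per (mode, n), and
runs in seconds. Histogram scores clip floating-point residue so that
identical inputs give exactly 0 (distances) and 1 (overlap). Table
round-trips are exact: floats are written at full precision and parsed
with round-trip precision. Degenerate inputs fail loudly as domain
errors: empty object lists, all-zero virtual masses, constant channels
(Pearson), all-equal values (spread transform), groups of fewer than 2
(comparison) or 4 (split control) cells.

## Known limitations

- Independent per-variable sampling cannot represent joint structure
  (e.g., brighter accumulations being larger or more peripheral).
- The spread transform's magnitude depends on the coordinate origin via
  `x̄`; it is a perturbation of image-frame coordinates, not an
  origin-free dilation.
- ICQ's background-sign bias on sparse images (above).
- The generator's cells are statistically identical; it does not emulate
  biological between-cell heterogeneity, segmentation artifacts, or
  anisotropic confocal PSFs.
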