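# Methods

## Problem setting

A short-axis cine CMR study is a sequence of T timeframes covering the
cardiac cycle. After manual contouring, each frame reduces to a binary
left-ventricular myocardium mask. The task is to recover, for every frame,
the dense in-plane displacement of myocardial material points relative to
the first frame (the Lagrangian convention; frame 0 ≈ end-diastole), and
from it regional strain. In the in-vivo setting the supervision comes from
tagged acquisitions processed with a sine-wave-modeling motion estimator;
in this package a synthetic phantom with analytic motion plays that
reference role, because the strain pipeline can then be checked against
closed forms rather than against another estimator.

## Displacement normalization

Reference displacement fields are signed mm values. For network training
they are mapped affinely to the 8-bit-style range: intensity
`32 + (d + d_max)·(255−32)/(2·d_max)`, then divided by 255, giving
foreground values in [32/255 ≈ 0.1255, 1] and background exactly 0. The
printed bounds "0.125 to 1" are inconsistent for any single divisor
(32/255 ≈ 0.1255 but 32/256 = 0.125 with 255/256 < 1); we divide by 255 so
the upper bound is exactly 1 and treat 0.125 as the rounded lower bound —
conveniently, 0.125 then separates background (0) from foreground
(≥ 0.1255) strictly, and is used as the one foreground threshold
everywhere (custom loss, denormalization). d_max is the maximum absolute
displacement over the *training* scans, padded by 10% so unseen scans
rarely clip; one symmetric scale is shared by both components, making the
map a single invertible affine with a one-line JSON sidecar. Everything
downstream of the network (error metrics, strain) operates after the exact
inverse map.

## Networks

Both variants are 5-level encoder–decoders over `(1, T, H, W)` inputs.
Each level applies a spatial conv (1×3×3) and a temporal conv (3×1×1),
each followed by batch normalization and ReLU; the deepest two encoder
levels dilate the spatial conv by (1,2,2) and the temporal conv by (2,1,1)
(receptive-field growth without resolution loss). Pooling is spatial-only
(1×2×2 max): a 20-frame sequence cannot be halved five times, and temporal
context is instead integrated by the stacked 3-tap temporal convolutions.
The decoder mirrors the encoder with nearest-neighbour (1,2,2) upsampling
and skip concatenation (checkerboard-free, unlike transposed convolution);
the head is a 1×1×1 conv to 2 channels with a sigmoid, which bounds
outputs to the normalized displacement range. The residual variant
replaces each block with main path conv→norm→ReLU→conv→norm plus an
identity (or 1×1×1 projection) shortcut, summed and passed through tanh.

Channel schedule: `base_channels · 2^level`, capped at 256 (16→256 at full
scale; 8→128 in the reduced validation runs). Initialization is
Kaiming-style fan-in scaling with zero biases from a seeded generator, so
two builds from the same configuration and seed are bit-identical.

The compute backend is a deliberately small reverse-mode autodiff engine
over numpy arrays (`myostrain.nn`): a gradient tape with exactly the
operators the architecture needs, convolutions evaluated tap-by-tap as
BLAS channel contractions, and a plain RMSprop implementation
(α = 0.99, ε = 1e-8). It is single-threaded-deterministic: two runs from
one seed reproduce training histories bitwise, which the test suite
asserts.

## Losses and training

The objective is the unweighted sum of three terms on normalized images
(per-pixel means, so the loss is independent of image area): the MSE of
both components; a Huber-style term that is quadratic where both component
errors are below 1 and linear (|Δx| + |Δy| − 0.5) otherwise — the
condition couples the components, and the mixed case falls to the linear
branch; and a foreground term that averages the squared error over the
pixels where *both target components* exceed 0.125, per frame (frames with
no foreground contribute 0). Thresholding on the target rather than the
prediction keeps gradients alive exactly where learning is needed.

Training: RMSprop at a constant 1e-3 (no schedule is assumed beyond the
stated initial rate), batch size 4, scan-level 80/10/10 split with
`max(1, round(0.1·N))` scans in validation and test so small cohorts are
never left without them, random horizontal/vertical flips (probability 0.5
per axis, training set only) with the displacement component parallel to
the flip negated on the signed scale, and model selection by the best
validation total loss. Scan-level splitting prevents leakage between sets
when scans contribute several slices; the training loop additionally
rejects any sample marked as belonging to a validation/test scan. Accuracy
is reported as 1 − MSE of the normalized fields; since the normalized
dynamic range is 1, this is 1 minus the normalized mean squared error.

## Strain

Per frame, displacement in mm is converted to pixel units and
differentiated by central differences where both neighbours lie in the
myocardium mask, one-sided where exactly one does (dropping the boundary
ring instead would discard much of a thin wall), and marked invalid where
neither does. F = I + ∇u is dimensionless; E = ½(FᵀF − I) is symmetric by
construction and exactly zero for rigid motion — central differences are
exact on affine fields, so rigid and uniform-scaling test fields reproduce
their closed forms to round-off. Ecc and Err are the projections of E on
the circumferential and radial unit vectors about the automatically
located LV center (mask centroid); the projection is quadratic, so the
sign convention of the basis is immaterial. Segment analysis averages
valid pixels within six 60° sectors (counterclockwise from a configurable
reference angle, default 90° = image "up") and reports percent strain with
a pixel-count-weighted global row. A per-segment peak is taken as the
maximum-magnitude value over the cycle with its frame index, since a
single reported value per segment requires some temporal reduction and
end-systole is not annotated.

## Phantom

The phantom is an annulus (defaults: Ri = 2.2 mm, Ro = 3.8 mm, 0.1 mm/px,
128×128, 20 frames) deformed by φ_t = radial contraction ∘ rigid twist,
both modulated by a raised-cosine ramp 0→1→0 peaking at `peak_frame`
(default 9). The radial profile is `r' = r − a(t)·g(r)` with
`g(r) = Ri·cos²((π/2)(r−Ri)/(Ro−Ri))`: maximal at the endocardium — so
`contraction_amplitude` is the peak fractional endocardial excursion — and
zero with zero slope at the epicardium. Its stretches are closed-form
(λ_c = r'/r, λ_r = 1 − a·g′), giving Ecc ≤ 0 and Err ≥ 0, the physiologic
systolic signs; the twist is rigid and strain-free. Segment ground truth
is the area-weighted wall average by adaptive quadrature (all six segments
are equal by axisymmetry). Masks are rendered by thresholding the signed
distance of the deformed annulus at pixel centers — deterministic, no
anti-aliasing ambiguity. Displacements are stored on the frame-0 grid and
are identically zero at frame 0.

Cohorts mirror a multi-slice study: 3 slices per scan (≈ the 64-slices-
from-22-scans structure of a typical rodent cohort), with scan-level
variation of radii, center, contraction (±30%) and twist, and milder
within-scan slice variation; slices share their scan's motion amplitudes.
Magnitudes are configurable rather than claimed physiologically exact —
the displacement range of real rodent data is not publicly specified.

What the phantom does *not* emulate: image contrast, tag lines, noise,
through-plane motion, and — importantly — shape irregularity. A perfect
annulus is rotationally symmetric, so its binary masks carry no
information about the twist component at all (and flips make its sign
unidentifiable); the learnable signal is the contraction, which is visible
as sub-pixel-to-few-pixel boundary motion. Passing end-to-end tests on the
phantom therefore demonstrates that the pipeline is correct and that the
networks can recover contraction-driven strain from mask sequences; it
does not demonstrate performance on real cine images, whose masks are
textured by papillary insertions and wall irregularities.

## Agreement statistics

SSIM uses the standard Gaussian-weighted form (window 11, σ = 1.5,
K1 = 0.01, K2 = 0.03, reflect-padded filtering, half-window border cropped
before averaging) on the normalized displacement images with unit dynamic
range. RMSE (per component) and mean endpoint error are computed in mm
over mask pixels. Strain agreement uses ICC(2,1) — two-way random effects,
absolute agreement, single measurement, the appropriate form for two fixed
"rater" methods scoring the same segments; unlike Pearson r it penalizes
systematic and multiplicative offsets. CV is reported per method
(100·SD/|mean| of that method's values). Bland–Altman reports the mean
difference and bias ± 1.96·SD limits. Per-segment paired t-tests (pairing
across slices, since both methods score identical segments of identical
slices) are Bonferroni-corrected by 6, the segments within one strain
family.

## Validation scale and known limitations

Desk-scale validation runs use a reduced fixture: 8 scans × 3 slices at
32×32, 8 frames (0.3 mm/px, ≈ 5 px across the wall), `base_channels` 8,
30 epochs — chosen so the full phantom→train→predict→strain→statistics
chain completes in ≈ 40 s per variant on one CPU. At this scale the
training budget is 150 optimizer steps, and the two variants reproduce the
qualitative finding the architectures were designed around: the residual
variant reaches the plain variant's final training loss in roughly a third
of the epochs.

Known limitations, measured on this fixture:

* At 30 epochs the predicted displacement fields are spatially smoothed
  and amplitude-shrunken relative to the reference (regression toward the
  cohort mean under a small training budget). Segment-strain Pearson
  correlation against the analytic truth exceeds 0.8, but ICC(2,1) —
  which additionally penalizes the shrinkage bias — typically lands near
  0.7–0.78 for the plain variant; training the same fixture to 100 epochs
  brings it above 0.8.
* Finite-difference strain amplifies field noise at coarse resolution;
  with ≈ 5 px across the wall, segment averaging pools only ~45 pixels.
  The full-scale geometry (16 px wall, ~500 px per segment) is markedly
  more favourable.
* Long-axis slices, through-plane (3-D) strain, torsion, and the
  17-segment model are out of scope; the segment model is the 6-sector
  single-slice partition.
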