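# Methods

This note documents the models, numerical choices and validation designs
behind `qsmoef`, in the order the pipeline runs.

## Forward model and units

All susceptibilities are stored in ppm, SI convention, in a single internal
unit system to prevent silent 4π errors; the CGS value of the blood
susceptibility constant (1.8 × 10⁻⁷ per unit hematocrit) is converted once,
`χ_SI = 4π·χ_CGS`, giving `Δχ_do = 2.262 ppm`. A `unit_system='CGS'`
configuration accepts raw CGS volumes with `Δχ_do = 1.8e-7` and produces
identical OEF values on consistently converted inputs (validated to
floating precision).

The induced field is the spectral product `F⁻¹(D·F(χ))` with the unit
dipole kernel `D(k) = 1/3 − k_B0²/|k|²`. `D(0)` is set to 0: a spatially
uniform susceptibility produces no observable internal field offset, so
reconstructions are mean-free and all downstream quantities that matter
(Δχ is a difference) are invariant to this gauge. B0 is taken along the
third array axis (axial slices) unless configured otherwise; frequencies
are computed in cycles/mm so anisotropic voxels (the target acquisition is
0.6 × 0.6 × 2.0 mm) are handled by physical distance throughout.

Phase accrual is single-echo: `φ = γ·B0·TE·δB/B0`, with γ the proton
gyromagnetic ratio, B0 = 3 T, TE = 14 ms by default (`phase_per_ppm` ≈
11.24 rad/ppm, so a 0.46 ppm vein wraps several times — enough to exercise
the unwrapper).

## Phantom generator

The phantom is a uniform tissue susceptibility (default 0.02 ppm) inside an
ellipsoidal brain mask, plus cylindrical veins whose offset over tissue is
`Δχ_do·Hct·OEF_true` — the OEF model solved for Δχ with a partial-volume
factor of 1, so the estimator's target is known exactly. Veins are
rasterized with sub-voxel coverage fractions (4³ subsamples per boundary
voxel): edge voxels carry a diluted offset, which is precisely the
partial-volume effect `P_v` corrects. The factor the rasterization implies,
`rasterization_pv`, is the ratio of the intravascular offset to the mean
offset over a voxel set; computed over the detector's own vein mask it is
the exact correction for the truth volume (≈1.2 for a 2.5-voxel radius).

Background fields are generated only from sources strictly outside the
brain mask — point dipoles placed at random exterior voxels plus low-order
harmonic polynomials (`x`, `xy`, `x²−y²`, `2z²−x²−y²`, …) — guaranteeing
harmonicity inside the mask, the property V-SHARP exploits, so the
background-removal validation is exact in principle. Complex Gaussian noise
is added to the unit-magnitude signal before taking magnitude and phase, so
phase noise scales as 1/SNR, matching MR physics.

What the generator does **not** emulate: pulse-sequence signal levels
(magnitude is a geometric stand-in; no TR/flip-angle modelling), multi-echo
acquisitions, vessel curvature and branching, tissue susceptibility
texture from iron and myelin, flow effects, and scanner-specific phase
offsets. Passing phantom tests therefore demonstrates correctness of the
algorithms under their stated assumptions, not clinical accuracy on real
brains.

The cohort generator draws per-subject regional means as independent
normals from printed (mean, SD, n) group summaries. Real regional OEF
values are strongly correlated across regions within subject; independence
is a deliberate simplification sufficient for calibrating univariate
two-group tests.

## Phase processing

Stored phase dialects (signed/unsigned integer, custom range) are mapped
affinely onto (−π, π]. Unwrapping uses the Laplacian identity
`∇²φ = cos φ·∇²(sin φ) − sin φ·∇²(cos φ)`, evaluated with spectral
derivatives and inverted with the spectral inverse Laplacian (k = 0 set to
zero). Volumes are zero-padded by 16 voxels per side (configurable) to
suppress periodic wrap-around. The inverse Laplacian leaves an arbitrary
constant; it is pinned by adding the circular mean of the in-mask
difference to the input, which matches the input's masked mean modulo 2π
while keeping the output pointwise congruent to the input — so re-wrapping
the output reproduces the input and any residual offset is a single global
2π multiple. On a smooth 6π-peak phase at 64³ the recovery error is
≈0.002% RMS.

The magnitude-based mask (threshold at 0.4 × the 99th-percentile magnitude,
largest connected component, morphological closing of radius 2) is a
reproducible, dependency-free stand-in for dedicated brain-extraction
tools; externally computed masks are accepted everywhere a mask is.

## Background removal (V-SHARP)

The spherical-mean-value (SMV) operator is convolution with a normalized
sphere, defined in millimetres (radius × smallest voxel edge) and
rasterized per axis. `(I − SMV_r)` annihilates fields harmonic inside the
sphere. V-SHARP applies the largest radius whose sphere fits inside the
mask at each voxel — the fit region is computed with a Euclidean distance
transform of the mask in mm — and deconvolves the combined high-passed
field by `(I − SMV_rmax)` in k-space. The truncation threshold is
*relative* to `max|1 − SMV_rmax|`: modes at or below `threshold × max` are
zeroed, so a threshold of 1 truncates everything and thresholds near 0
approach plain deconvolution. Default schedule 25, 20, 15, 10, 5, 3, 2, 1
voxel-units for brain-sized volumes; the 96-voxel phantom experiments use
12, 10, 8, 6, 4, which keeps a usable eroded mask on a desk-scale brain
while averaging over several voxels. Values outside the eroded mask are
undefined and set to zero.

Known limitation: near the mask boundary the small-kernel high-pass is
deconvolved by the large-kernel operator, so tissue-field fidelity degrades
in the outer annuli (correlation with a vein's true field drops from >0.99
in the deep interior to ≈0.93 within a few voxels of the boundary). This
is the classic boundary/accuracy trade-off of variable-kernel SMV methods.

## Dipole inversion

Thresholded k-space division (TKD): `χ(k) = f(k)/D(k)` where `|D| ≥ t`,
else `f(k)/(sign(D)·t)` — sign-preserving replacement rather than zeroing,
which reduces ringing and keeps the operator linear and bit-reproducible.
Default `t = 0.1`.

The two-pass method targets streaking from strong sources: pass 1 runs TKD
with heavy regularization (`t = 0.25`), keeps voxels with `|χ| ≥ 0.2 ppm`,
subtracts their forward field, and pass 2 inverts the residual with light
regularization (`t = 0.08`); the output is the sum. This preserves the
strong-source field-separation mechanism of streak-reduced QSM solvers
with a closed-form, oracle-testable inner solver; it is a variant, not a
re-implementation of any published ℓ1-regularized solver, and no
equivalence to external implementations is claimed. With no voxel above
the strong cutoff the result equals the weak pass exactly. On a 64³
phantom with a B0-perpendicular vein (the streak-generating geometry) the
two-pass reconstruction roughly halves the truth-subtracted RMS in a
tissue shell around the vein relative to plain TKD at the same weak
threshold.

## OEF estimation

Vein detection uses an **upper** one-sided threshold `mean + 2·SD` over
in-mask VOI voxels: veins are paramagnetic relative to tissue, and a
two-sided rule would mislabel diamagnetic voxels as veins. Windows need at
least 27 in-mask voxels and a non-degenerate SD; detections below 5 vein
voxels (configurable) are discarded as noise-dominated order statistics.
Δχ is the vein-mean minus non-vein-mean within the VOI, requiring at least
27 tissue voxels; negative Δχ windows are flagged undefined by default
(config switch to retain them). OEF follows the model equation with no
clamping — out-of-range values stay visible downstream.

The VOI geometry default is 64 × 64 × 30 voxels, read as the window's voxel
dimensions (the other published reading — the number of tiles — is
expressible through the same config). The sliding-window stride defaults to
half the window per axis, final windows are flush with the volume edge, and
overlaps are resolved by the unweighted mean of defined window values.
Undefined voxels are NaN with a per-voxel window count, never silent zeros.
Per-window re-detection (rather than one global vein mask) is used, which
is what a local threshold implies. ROI means are taken over defined voxels
against an integer label volume and reported in percent; hematocrit is a
global 0.45 by default (per-subject override via config), and the model's
inverse-Hct scaling is exact by construction.

## Statistics

Pooled-SD Cohen's d, `d = |m_b − m_a| / s_p` with
`s_p² = ((n_a−1)s_a² + (n_b−1)s_b²)/(n_a+n_b−2)`, is computable from
printed summaries alone; the companion effect size uses the standard
`r = d/√(d² + (n_a+n_b)²/(n_a·n_b))` conversion from summaries and
`r = Z/√N` from raw samples. Interpretation cutoffs are closed on the left
exactly as conventionally printed (d = 0.8 → large, 0.79 → medium).
The pooled (Student) t-test is the default because the bundled regional
table's printed effect sizes match pooled-SD d; Welch is a config option.
Normality screening is a Kolmogorov–Smirnov test against a normal with the
sample's own moments at α = 0.05 (conservative for small samples, so
normal data route to the t-test and the procedure's empirical type-I error
at study-sized groups, n = 15 vs 16, stays within the binomial interval of
the nominal 5% over 2000 null replicates). Mann–Whitney is exact for
tie-free samples up to n = 25 per group, asymptotic with tie correction
otherwise. Categorical 2×2 tables route to Fisher's exact test when any
expected cell is below 5, else chi-square without continuity correction.
Bonferroni is `min(1, m·p)` with `m` defaulting to the family size; raw
and adjusted p are reported side by side since published tables do not
always state which is printed.

Three of the fifteen bundled regional OEF rows have printed effect sizes
inconsistent with pooled-SD d recomputed from their own printed means and
SDs; they are flagged non-reproducible in `qsmoef.reference` and excluded
from reproduction checks rather than reinterpreted.

## Validation experiment sizes

The acceptance script and end-to-end tests use: a 96³ three-vein phantom
(OEF 0.30/0.45/0.60) for recovery, 96 × 96 × 48 for background removal,
64³ for inversion round trips and unwrapping, and 2000 replicates for the
type-I calibration — sizes chosen so the full suite runs in well under a
minute of FFT time on one CPU while keeping ≥10⁴ in-mask voxels per
metric. Recovery on phantom-truth susceptibility is exact to <0.1%
(detection-consistent P_v); through the full noiseless reconstruction
chain the error grows with vein susceptibility (V-SHARP and TKD both
attenuate strong compact sources) to ≈22% at OEF 0.60, with the estimate
strictly monotone in the true OEF on both paths.
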