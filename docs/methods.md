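# Methods

## Motion model

Each simulated spermatocyte nucleus is a sphere of radius R = 5 µm (consistent
with the ~10 µm nuclei in published micrographs; configurable). Envelope-
attached telomeres perform a persistent random walk on the sphere: per
sampling interval each focus takes one great-circle step whose arc length is
Gamma-distributed (CV `speed_cv`, default 0.35) along its heading, and the
heading is re-drawn with von Mises concentration `kappa` (default 4) about the
parallel-transported previous heading. Persistence stands in for rail-tracking
along MT cables, which the model does not resolve. Superimposed on the walk,
the whole chromatin configuration — telomeres, heterochromatin, envelope mode
axes, but not the MTOC — rotates rigidly at `omega` (default 0.005 rad/s for
rotating stages; no rotation rate is published, only unidirectionality, so any
small positive value exercises the estimator). Attached telomeres sit exactly
on the instantaneous envelope surface at all times.

An excluded-volume rule keeps distinct foci at least 0.7 µm apart during
stepping (1.0 µm at initialization, with an extra anti-axial-stacking
condition matched to the elongated PSF), mimicking chromatin territory
exclusion; without it, free mixing makes a large fraction of foci transiently
unresolvable and focus counts unstable.

Stage structure enters through presets:

- **leptozygotene** — 80 unpaired foci, v_target 0.12 µm/s, rotation on;
- **pachytene** — 40 merged homolog end pairs (80 ends → 40 foci),
  v_target 0.13 µm/s, rotation on;
- **bouquet** — 25% of telomeres confined to a 0.6 rad cap around the MTOC
  direction (reflecting boundary), slowed to 0.04 µm/s; rotation suppressed;
- **diplotene** — 40 tethered pairs, v_target 0.083 µm/s, no rotation.
  Short-arm (centromeric) pairs ride mobile pericentromeric heterochromatin
  anchors (anchor walk at 0.9× the free step so both arm classes show matched
  measured speeds) with separation kept in [0.55, 0.85] µm; long-arm pairs
  walk freely but are projected back whenever their 3D separation exceeds
  4.2 µm. Both caps sit below the published 1 / 4.5 µm bounds so that
  *measured* distances including localization error still respect them;
- **sun1_null** — 5 merged pairs (75 foci), 15 telomeres detached into the
  interior (radial fraction 0.3–0.7, confined Gaussian steps), slow motion;
- **sun1_rescue** — 23 merged pairs (57 foci), 2 internal telomeres.

Drug modes transform a preset the way the inhibitor acts: nocodazole zeroes
telomere steps and rotation (MT-dependent), cytochalasin D reduces the
oscillatory envelope amplitude to 0.01 (actin-dependent), "both" combines
them, "dmso" is the vehicle control.

## Envelope shape and the rendered chromatin channel

The envelope radius is modulated by degree-2 and degree-3 Legendre modes with
random axes: an oscillatory family (amplitude 0.10, period 120 s — the
actin-driven shape oscillation) and a static asphericity (amplitude 0.08)
that co-rotates with the nucleus; prophase nuclei are visibly non-spherical,
and this is what makes pure rotation register in the 2D outline. In addition,
the chromatin channel renders a small envelope protrusion at every attached
telomere (the LINC-anchored chromosome end deflects the envelope), so
MT-driven telomere motion itself perturbs the projected outline. These three
ingredients give the four drug conditions distinct, mechanistically ordered
XOR signals: vehicle (oscillation + rotation + moving protrusions) >
nocodazole (oscillation only) > cytochalasin D (motion only) > both (floor).

Rendering uses widefield surrogates: anisotropic Gaussian PSF (σ_xy 0.15 µm,
σ_z 0.5 µm), voxels 0.1 × 0.1 × 1.0 µm with 12 optical sections (enough 1 µm
sections to cover the nucleus; within the 7–12 range used for live imaging),
Poisson shot noise plus Gaussian read noise (SD 2). No defocus structure,
photobleaching, or chromosome-axis morphology is modelled; axes appear only
as faint texture in spreads.

## Speed calibration

`v_target` is defined as the expected *measured* per-interval 3D speed at the
stage's sampling interval, because the published numbers are measurements.
For each (preset, R, Δt) the free step-length mean is found by bisection on
deterministic pilot simulations. For the three stages whose velocities are
profiled (leptozygotene, pachytene, diplotene) the pilot measurement applies
the same operator as the analysis: ground-truth sites are collapsed by the
optical-merge rule, linked with the gated Hungarian linker, tracks with 10
continuous intervals are selected (longest first, five per cell) and their
interval speeds pooled. This matters: the squared-cost assignment is
systematically biased low by ~5–8% at these densities (identity swaps during
close encounters choose the cheaper displacement), so the underlying true
motion is correspondingly faster than the measured value — the ground-truth
mean speed sits a few percent above `v_target` by design. Bouquet-clustered
steps are calibrated against the plain group mean.

## Measurement pipeline

- **Spot detection**: scale-normalized anisotropic Laplacian-of-Gaussian
  matched to the PSF; 3D local maxima above k = 6 robust SDs (MAD) of the
  response over the search region; per-axis log-parabolic sub-voxel
  localization on the matched-filtered intensity (exact for Gaussian
  profiles); detections closer than 0.5 µm merged to the brightest. On
  default renders this is exact by construction (recall = precision = 1 under
  the separation rule) with ~5 nm lateral and ~0.1 µm axial RMSE.
- **Heterochromatin blobs**: same machinery at the chromocenter scale
  (σ 0.5 µm), restricted to the nucleus interior eroded by 1.2 µm (the
  envelope edge is itself a coarse-scale ridge), with a relative-quality
  floor of 0.35 of the strongest blob.
- **Nucleus masks**: max-intensity projection, 1.5 px Gaussian smoothing
  (suppresses shot-noise edge flicker that would dominate the XOR statistic),
  Otsu, largest component, hole filling. Otsu thresholds ~2/3 up the blurred
  edge, so masks are a few percent smaller than the geometric cross-section;
  the XOR ratio divides by A_T and is insensitive to this. The 3D boundary
  stacks per-slice Otsu masks (guarded against empty cap slices) into a
  signed Euclidean distance function with anisotropic sampling.
- **Linking**: per-frame-pair Hungarian assignment minimizing total squared
  displacement within a gate (default 3·v_target·Δt, floor 1 µm), one-frame
  gap closing at twice the gate, order-independent. Velocities are raw 3D
  chord displacements per interval of tracks with 10 continuous gap-free
  intervals, drift-corrected by the per-frame nucleus centroid (a flag
  disables this). No smoothing, no motion-model prediction.
- **Rotation**: Kabsch/orthogonal-Procrustes fit (proper rotation enforced)
  of matched heterochromatin positions about the nucleus centroid.
  Per-interval angles at default noise are dominated by blob localization
  (~0.3 µm on a ~3.5 µm lever); accumulating over a 10-interval window
  recovers the axis to ~2° and the angle to a few percent. The
  unidirectionality index U = ‖mean(angle·axis)‖ / mean(angle) is 1 for
  persistent rotation.
- **Internal telomeres**: a focus is internal when it lies more than 0.8 µm
  inside the segmented surface — attached foci read up to ~0.6 µm "inside"
  (threshold bias plus their envelope protrusion) while detached foci sit
  > 1.2 µm deep, so the margin bisects the empirical gap.
- **Colocalization**: Sato ridge filter at the cable half-width, Otsu on the
  ridge response, small-component removal, skeletonization; a peripheral
  focus (inside the NE annulus) is on-cable when it lies within 0.3 µm of the
  skeleton (rasterized half-width + localization error). Spreads assign the
  on-cable count per cell by stratified rounding of p_on·n, so the per-cell
  mean estimates p_on with minimal variance while remaining within binomial
  bounds.
- **Statistics**: two-tailed Welch t-test (unequal variances,
  Welch–Satterthwaite df) for all group comparisons.

## Problem sizes

Velocimetry runs 5 cells × 11 frames per stage (250 pooled intervals),
pair distances one cell × 31 frames at 7 s (20 + 20 pairs), shape experiments
5 cells × 11 frames at 30 s per condition, colocalization 15 (WT) and
21 (Sun1-null) spreads of ~25 peripheral foci. These match the published
sampling designs; larger runs only tighten the errors.

## What the simulator does and does not establish

Passing tests show that the measurement operators are unbiased and exact on
data whose generative process matches their assumptions: Gaussian spots of
known scale, a single convex nucleus, rigid chromocenters, stationary noise,
and separations that respect the excluded-volume rule. Real spermatocyte
movies add model mismatch the simulator does not emulate — photobleaching,
z-dependent aberrations, chromatin texture in the GFP channel, manual rather
than algorithmic tracing, non-rigid heterochromatin, cell-to-cell parameter
spread — so quantitative agreement here validates the pipeline, not the
biology. Identity assignment is the binding limitation: with ~40–80 foci
moving ~0.9 µm per interval, no gated nearest-structure linker traces every
telomere perfectly (roughly 60–70% of traceable tracks keep a single identity
for 10 intervals), which is why speed calibration goes through the
measurement operator and why pair analyses assign identity per frame-run
against ground truth.

## Numerical choices

Bisection calibrations use fixed internal seeds (deterministic, cached per
preset/radius/interval). Tether and cap projections run a bounded fixed-point
loop with a hard final projection, so diplotene separations and bouquet
containment hold exactly at every exported frame. Headings are
re-orthonormalized after constraint projections so geodesic steps never leave
the sphere. All public simulate/render entry points require explicit seeds;
there is no hidden global RNG state. Degenerate inputs raise: empty masks,
< 3 or collinear points for rotation fitting, empty velocity windows,
missing channels, impossible packings (with the remedy named in the message).
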