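# Methods

## The measurement problem

Lipid droplets (LDs) are spherical, micron-scale organelles bounded by a
phospholipid monolayer. Calling a homotypic fusion event from a confocal
z-stack time series is deceptively hard: droplets cluster tightly (often a
majority sit within 300 nm of a neighbour), axial resolution is 3–4× worse
than lateral, and 3D renderings or z-projections merge juxtaposed droplets
into a single apparent object. A naive screening rule — two droplets close
together become one object that persists — therefore counts docking as
fusion. `ldfuse` implements both that screening rule and a stricter,
artifact-aware rule, and the geometric analysis that separates the two
physical conservation hypotheses of a true fusion.

## Criteria

**Screening criteria** (as published for LD fusion screening): donors no
more than 3.5 µm apart at the last two-droplet frame; fused volume at most
150% of the combined donor volumes; the fused droplet present at the next
timepoint without a change in volume (the published phrasing carries no
tolerance; we default to ≤ 10% relative volume change, configurable). The
donor distance defaults to the surface-to-surface gap — the physically
meaningful contact quantity; the center-to-center value is always computed
and reported alongside, and the convention is switchable
(`CriteriaConfig.bostrom_distance_convention`).

**Refined criteria**: (1) the fused droplet persists as a single entity for
the remainder of the capture, and the remaining capture must cover at least
half of it (events merging later are *indeterminate*, a first-class verdict
distinct from fail); (2) no discontinuity in a single x–y or x–z plane at
any post-merge frame — evaluated on unrendered planes, never projections;
(3) the droplet becomes increasingly spherical, reaching a circularity
threshold within a bounded window (120 s) and staying above it. The
sphericity threshold is a quantitative surrogate for "increasingly
spherical": circularity ≥ 0.9 in the bisecting plane, deliberately above
the 0.8 floor of the roundness particle filter. "Never splits" is
operationalized as no consecutive-frame volume drop beyond 35% (a genuine
split halves the volume in one step; shape relaxation during core merging
loses at most a few percent per frame).

**Staging.** Accepted events are one-stage if the droplet is already at
the sphericity threshold in its first merged frame, else two-stage; the
core-merge time runs from the last frame showing two droplets to the first
frame at the threshold, and the membrane-merge time is bounded by one frame
interval (membrane continuity is sub-frame at 10–30 s intervals).

## Conservation geometry

Fusing two spheres into one can conserve volume or surface area, not both:

- volume hypothesis: `V = 4π/3 (r₁³ + r₂³)`
- surface-area hypothesis: `r = (r₁² + r₂²)^{1/2}`, `V = 4π/3 (r₁²+r₂²)^{3/2}`

Ordinary least squares of *measured* final volume on each *predicted*
volume discriminates the hypotheses. On volume-conserving events the volume
hypothesis fits with slope 1; the surface-area prediction overshoots, and
for equal donors the slope is exactly `2^{-1/2} = 0.7071` (each measured
volume is `2^{-1/2}` of the SA-predicted one). The regression orientation is
measured-on-predicted — the only orientation under which both slopes take
these values — and is recorded in the result object. The intercept is
fitted and expected near zero; the slope is the reported statistic.

Volume conservation destroys membrane: the fused sphere's area deficit
`1 − (r₁³+r₂³)^{2/3}/(r₁²+r₂²)` is maximal for equal donors at
`1 − 2^{-1/3} ≈ 20.63%` and vanishes as one donor vanishes. A sphere's area
is `4πr²`; because the constant cancels in both slopes and in the loss
fraction, any convention for it leaves every reported quantity unchanged
(this invariance is asserted in the tests).

## Synthetic scenes

The generator emulates confocal 4D imaging of fibroblast-scale droplets.
Defaults (all per-field `SceneConfig` parameters):

| parameter | default | rationale |
|---|---|---|
| frame interval | 30 s (10 s for fusion detail) | typical z-stack cadence |
| radius range | 0.3–1.0 µm | fibroblast LDs (~0.7 µm typical) |
| diffusion coefficient | 5×10⁻⁴ µm²/s | µm-scale wander, sub-µm net displacement over tens of minutes |
| cluster fraction | 0.65 | majority of droplets within 300 nm of a neighbour |
| voxel size | 0.1 × 0.1 × 0.3 µm | 63×/NA 1.4 confocal sampling |
| PSF σ (xy, z) | 0.08, 0.25 µm | diffraction-limited NA 1.4 confocal |
| photons at peak | 200 | moderate-SNR live imaging |
| read noise | 2 counts | CCD-class |

Motion is a reflected-boundary Brownian walk (per-axis step SD
`√(2 D Δt)`); moves that would interpenetrate another droplet are rejected.
Scripted pairs (fusion donors, docking partners) move jointly. Fusion
donors approach laterally and sit at a resolvable 0.4 µm gap until their
scripted contact frame: a pre-contact gap along the optical axis would be
sub-resolution and erase the two-droplet history the tracker needs.
Docking pairs do the opposite by design — they lean along z and dock at a
0–150 nm gap, reproducing the rendered-3D false-fusion artifact. Scripted
pairs keep a 4 µm mutual clearance so concurrent merge events remain
spatially attributable, and partners are similar-sized (ratio ≥ 0.7), as
droplets within clusters are.

**Merge kinetics.** From the membrane-merge frame the pair is rendered as a
two-sphere union: center separation `d = (1 − p)(r₁ + r₂)` at merge
progress `p`, with both radii scaled by the common factor (bracketed
monotone root search, relative tolerance < 1e-9) that keeps the union
volume equal to the conserved total. Progress follows a convex power law in
time, `p = (t/T)⁵` over the core-merge duration `T`: the pair stays visibly
elongated for most of the core merge and snaps spherical near its end, so
the time at which the bisecting-plane circularity crosses the 0.9 threshold
coincides with `T` to within one frame for durations up to ~10 frames. (A
linear ramp would cross the threshold at ~45% of `T`, because the union
cross-section rounds up quickly once the centers overlap; under it, no
threshold-based reading of the core-merge time can match the programmed
duration.) A frame acquired at the scripted start already shows one
interval of core merging — membrane merging is sub-frame — so a merge
scripted to take *n* intervals is spherical *n−1* frames after its first
merged frame.

Rendering voxelizes filled droplets (core stain) or shells
(surface marker) with a one-voxel partial-volume ramp, applies anisotropic
Gaussian blur, Poisson shot noise and Gaussian read noise, and quantizes to
8 or 16 bits. Identical configuration and seed give bit-identical movies.

**The emulated-detection route.** `SceneGroundTruth.detection_like_table`
produces the droplet table an ideal detector would output — merging pairs
and sub-resolution docked pairs collapse into single apparent objects with
the analytic equivalent radius and cross-section circularity of the
two-disc union, plus measurement noise (1% radius CV, 20 nm centroid SD by
default). Classifier tests use this fast route at scale (dozens of scripted
events) and the fully rendered route end-to-end at small scale; both give
the same verdicts on matching fixtures.

What the generator does *not* emulate: directed microtubule transport,
photobleaching, spectral bleed-through, non-Gaussian PSF structure, cell
boundaries, or droplet size changes outside fusion. Passing tests therefore
say nothing about those aspects of real data.

## Detection

Per timepoint: local-contrast background subtraction (image minus a
Gaussian at 20–40 µm scale, default 30), Otsu thresholding, 26-connected
3D labelling. In surface-marker mode the shell interiors are filled per
x–y slice (every slice of a closed shell is a closed ring) before
labelling. Each component is measured in the x–y plane with the largest
cross-section: the boundary is re-traced at half of the component's
in-plane peak on a lightly smoothed plane (marching squares, subpixel),
giving `radius = √(area/π)` from the enclosed polygon area and
`circularity = 4π·area/perimeter²` from the traced length, clipped at 1.
Components outside the circularity band (0.8–1) or below the minimum
radius are reported in a rejected list; the movie-level pipeline keeps
sub-roundness objects for tracking, since fusing dumbbells and docked
doublets necessarily fail a roundness filter built for counting round
particles.

Half-maximum sizing of an axially blurred ball is biased low once the
radius approaches the axial PSF extent (the in-plane peak is suppressed, so
half-peak sits high on the profile). `DetectionConfig.psf_sigma` supplies
the instrument's PSF calibration; the detector then numerically simulates
blurred balls once per configuration, builds the true→apparent radius
mapping under its own measurement convention, and inverts it — the software
analogue of sizing calibration beads. With the default PSF this keeps the
median radius error under 5% down to 3-voxel radii. A small negative
residual (1–4%) from finite z-sampling (the bisecting plane can miss the
true equator by up to half a z-step) remains and is accepted.

Single-plane continuity flags (`connected_in_xy`, `connected_in_xz`) record
whether the component's half-maximum mask is a single 8-connected piece in
the x–y and x–z planes through its centroid; these feed refined criterion 2
without re-reading the images.

## Tracking

Frame-to-frame linking is an optimal bipartite assignment (Hungarian
algorithm) under squared displacement, with links beyond the search radius
(default 20 µm) forbidden, as appropriate for Brownian motion. Links that
grow the volume by more than 30% in one step are also forbidden: droplets
do not gain volume frame-to-frame, while a merged object roughly doubles
it, so merged blobs start fresh tracks and fusion surfaces as track
topology. Track ends re-link to later track starts across up to 2 missing
frames (gap closing, greedy nearest with deterministic tie-breaks). Gap
limits are sometimes quoted with a length unit, but a gap is a frame count
in every tracking tool we know of, so the default is 2 frames and the
parameter is exposed. Merge candidates are emitted wherever
two tracks end at the same frame and exactly one new track appears in the
next frame within the search radius of both donors; candidates carry no
verdict.

## Statistics

Per-track path length (sum of steps) and net displacement (first-to-last
distance) aggregate as mean ± SEM; singleton tracks are excluded and
counted. Clustering is the fraction of droplets whose minimal
surface-to-surface gap to a neighbour is at or below 300 nm — edge-to-edge,
since a center-to-center reading would be vacuous for droplets larger than
the threshold; the default aggregation is per frame. Count changes between
the first and last frames use the classical paired t-test; size comparisons
use Welch's unequal-variance two-tailed t-test (which reduces to Student's
t for equal variances, asserted in the tests). Degenerate inputs (zero
variance) are reported explicitly rather than returning unstable
statistics.

## Problem sizes and numerical choices

Classifier validation runs on eight scripted scenes of 30 droplets × 24
frames at 10 s intervals (56 fusion events, 24 docking distractors) via the
emulated-detection route, plus a rendered 10-droplet scene end-to-end;
detection validation uses 224 rendered spheres across 8 fields; the
conservation regressions use 60 simulated events, matching the study scale.
Root searches use Brent's method with relative tolerance 1e-15; the
two-sphere union volume agrees with a 0.02 µm voxel-counting oracle within
1%. Linking ties resolve toward low indices; all randomness flows from
explicit seeds, and fixed seeds give bit-identical scenes and movies.

## Known limitations

- Recovered core-merge times match scripted durations to ±1 frame only up
  to ~10-frame durations; much slower merges (the tail up to 17.5 min) are
  read increasingly early, and events whose shape recovery exceeds the
  2-minute window fail refined criterion 3 by design.
- Sub-resolution docked pairs bridged by the PSF can pass the single-plane
  continuity test when their separation vector lies in-plane; rejection
  then rests on criterion 3, which is why the refined verdict requires all
  three criteria.
- The detector assumes square in-plane pixels and a uniform core stain;
  surface-marker mode sizes droplets from the filled shell without PSF
  correction.
- Concurrent merges closer than the link radius are not attributable and
  are dropped at the candidate stage.
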