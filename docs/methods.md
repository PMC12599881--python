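# Methods

This note documents the models, parameter choices and numerical decisions
behind `axoshed`, and what the synthetic validation does and does not
demonstrate about real data.

## Synthetic scene model

The generator simulates a ~30 µm diameter optic nerve imaged at a single
focal plane, 60 frames at 1 Hz, 0.2 µm pixels. Axons are straight parallel
lanes spanning the nerve width; the +s (anterograde) direction is the
eye→brain axis, increasing x. Each cargo particle draws a movement state
from the configurable mixture — default (0.50, 0.25, 0.25) for
stationary/anterograde/retrograde, the baseline composition of healthy RGC
axonal mitochondria — and movers travel at a constant speed drawn from a
Gaussian with means 0.63 (anterograde) and 0.78 µm/s (retrograde),
SD 0.15 µm/s, resampled to stay at or above 0.1 µm/s so that the ground
truth is never ambiguous against the stationary/moving boundary.
Stationary particles jitter (SD 0.05 µm per frame) with net velocity
constrained below 0.09 µm/s for the same reason. Mover start positions are
drawn so the particle stays in the field for the whole minute; position
distributions are therefore slightly non-uniform for fast movers, which is
irrelevant to the measured statistics.

Particles render as isotropic Gaussian spots (PSF σ = 0.25 µm). An
optional capsule (spherocylinder) phantom renderer provides elongated
objects for shape analyses. Noise is scaled-Poisson shot noise plus
additive Gaussian read noise; the default amplitude (36) and read noise
(SD 3) give SNR ≈ 5 at spot peaks. The stated imaging SNR and amplitudes
are free parameters of the generator (no published values exist for them)
and are exposed in `SceneConfig`. A second channel (OPTN) renders a spot
only where the particle carries the partner flag, drawn per state from the
coupling probabilities — default {stationary 0.6, moving 0.2},
a stationary-enriched co-localization structure. A third channel carries a
diffuse cytoplasmic fill across the nerve band (the LC3b axoplasm signal)
used for contour tracing. Drift is linear in time, applied by bilinear
interpolation, and limited to 25 % of the field.

### Z-stack mode

Z-scans (1 µm steps) model the sparse-labelling geometry: six axon tubes
of 3 µm diameter inside the nerve cylinder. With a 1 µm axial step a tube
is only 2–3 voxel planes thick, so sub-voxel placement matters; tube axes
are snapped to voxel centers and every punctum center is snapped to the
voxel grid so that each punctum has an identical discrete footprint. This
makes the constructed extra-axonal volume fraction exact by bookkeeping:
given the stationary puncta rendered inside tubes (movers are excluded —
frame-averaged z-scans blur them out), the generator adds
`round(n_in · f/(1−f))` outside puncta so the outside fraction of puncta
equals `extra_axonal_fraction` up to rounding. Puncta are discrete
organelles and never fuse: a minimum 1.5 µm separation is enforced,
because fused puncta would share supra-threshold voxels and bias the
constructed fraction. Outside puncta split between a nerve-surface shell
(placed just outside the nerve radius) and the parenchyma per
`surface_share_of_outside` (default 0.239). Per-voxel compartment labels
and the punctum table are attached as ground truth.

### Protrusion events

Dystrophy event series follow the two repetitive z-scan schedules
(30-s intervals for 5 min, or 2-min intervals for 10 min) on a small
sub-volume containing one axon tube (radius 0.8 µm) and one lateral bud
(radius 1 µm). Four scripted kinds: *swelling* (symmetric bulge, static
intensities), *loading* (bud signal rises linearly while the axon directly
beneath loses the same integrated amount — conservation by construction),
*pinching-off* (attached until the pinch index, then the gap opens by
0.8 µm per interval — acute on the sampling scale), and *detached*
(constant gap). Sparse-axon 2-D images with planted asymmetric protrusions
(half-discs of radius 1.8 µm on one side) and symmetric swellings serve
the detection tests; planted protrusions default to the observed field
statistics (0.47 per 100 µm, 60.3 % mitochondria-positive).

## Measurement pipeline

**Registration** uses phase cross-correlation with 10× upsampled subpixel
refinement against the first frame (or temporal mean), reimplementing
rigid-translation stack registration. Flat frames get zero shift with a
warning. Accuracy on synthetic scenes: cumulative error < 0.5 px at frame
10 for drifts up to 0.5 px/frame; per-frame errors can reach ~0.5 px when
moving objects dominate the texture, which is why contour-stable scenes
are used for single-frame accuracy checks.

**Contour and swaths.** The nerve contour is the boundary of the largest
supra-threshold component of a temporal projection (Otsu or quantile
threshold; a manual polygon bypasses detection). The principal axis comes
from the component's second moments; the diameter is the extent across the
minor axis. Swaths are abutting parallel bands of width 0.9–1.8 µm
(default 1.5 µm, the mid-range; out-of-range requests are clamped with a
warning) tiling the contour interior — whether swaths abut or overlap is a
genuinely open choice; abutting was chosen and the width is exposed for
sensitivity analysis. Kymographs reduce intensity across the swath width
(default max, which preserves punctate ridges; mean available).

**Detection and linking.** Per time row, peaks above a prominence
threshold (default 12, ≈ 4 background SDs) are refined to subpixel by
parabolic interpolation. Linking is greedy nearest-neighbour against each
active trace's predicted position (velocity continuity resolves
crossings), with jumps over 2 µm refused, gaps ≤ 2 frames bridged, and two
quality gates: traces observed < 5 frames are dropped (the record is too
short to classify against a 0.1 µm/s boundary over a 1-min protocol), and
traces whose RMS deviation from their least-squares line exceeds 0.3 µm
are dropped as chimeras — a constant-velocity object deviates from its
line only by jitter and localization noise (≈ 0.1 µm RMS), while linking
mistakes that ratchet across neighbouring objects produce large residuals.
The residual gate would also remove genuinely direction-reversing objects;
the generator contains none, and the gate can be disabled
(`max_residual_um=None`) when reversals are expected. A final gap-closing
pass merges time-disjoint fragments that lie on one kymograph line (same
line fit within the residual gate), countering detection dropouts longer
than the bridging window.

**Classification** is by net end-to-end velocity over the observed span —
not the mean of instantaneous speeds, which is dominated by jitter — with
the moving boundary at 0.1 µm/s inclusive. Class percentages are computed
per animal (summing to 100 exactly), then averaged across animals; N is
always the number of animals. Speeds are unsigned means over moving traces
only.

**Swath double-counting.** A spot straddling a swath boundary can be
detected in both swaths. This duplication is class-independent in the
straight-lane geometry (it inflates counts, not fractions);
`deduplicate_stationary` collapses stationary duplicates across adjacent
swaths so both raw and de-duplicated stationary counts can be reported.

**Co-localization.** A reference (mito) trace is co-localized when a
partner (OPTN) trace from the same kymograph stays within 0.5 µm for at
least 50 % of the reference trace's observed frames; assignment is
one-to-one, greedy by mean distance with longer overlap breaking ties.
The distance and overlap criteria have no published numeric counterpart
(the original analyses were manual); both are exposed in the API and
covered by sensitivity of the recovery tests.

**Volumetry.** The axon mask is built from the LC3b channel by Otsu
threshold (the LC3b histogram is genuinely bimodal), small-component
removal and morphological closing. Signal channels use a different default
("robust": background median + 8 robust SDs, noise scale estimated from
the 84.1 % quantile spread) because global Otsu degenerates when the
foreground is a sparse punctate fraction of voxels, and the background is
zero-clipped so MAD-based scales collapse. Percent outside is computed on
voxel volumes (matching volume-based, not count-based, quantification);
an object-wise variant assigns whole connected components by centroid.
Residual systematic error on synthetic stacks is ≈ +1 point (partial
volume at the 1 µm axial step), well inside the ±4-point validation band.
The surface shell is all extra-axonal voxels within 3 µm of the nerve
boundary (an astrocyte-soma-scale depth; no published numeric definition
of "on the nerve surface" exists). The surface-vs-outside trend is OLS
with R² = 1 − SS_res/SS_tot, defined as 0 when SS_tot = 0.

**Morphometry.** Objects are connected supra-threshold components; volume
is voxel count × voxel volume, surface area comes from a marching-cubes
mesh in physical (anisotropic) spacing after Gaussian smoothing (σ = 1
voxel) of the padded binary component — meshing raw binary voxels
overestimates area via the staircase artefact (a voxelized unit-radius
sphere reads Ψ ≈ 0.92 unsmoothed, ≈ 1.00 smoothed at 0.05 µm voxels).
Sphericity is Wadell's Ψ = π^(1/3)(6V)^(2/3)/A (the definition used by
common 3-D analysis suites; no formula is otherwise standard in imaging
papers).

**Protrusion detection** measures the supra-threshold radial extent above
and below the axon midline along the centerline; a contiguous one-sided
excursion ≥ 0.5 µm high and ≥ 0.5 µm wide is a protrusion when its
excursion exceeds 2× the contralateral one (asymmetry ratio k = 2 — the
symmetric/asymmetric distinction has no published numeric rule).
Symmetric swellings are rejected by the same test. Density is
100 × count / axon length; axons shorter than 10 µm are skipped.

**Event tracking** isolates the bud as the largest supra-threshold
component off a 0.3 µm-dilated axon mask (the dilation absorbs the PSF
halo, without which the off-axon residue is a thin shell along the entire
tube). Minimum distance is 3-D (the 2-D/3-D choice is open; 3-D chosen),
Euclidean with anisotropic sampling, and exactly 0 while the components
touch (26-connectivity against the dilated mask). Intensities in the bud
and in the axon directly beneath it (axon voxels within the bud's
footprint ± 1 µm along the axis) are normalized per timepoint by the
same-axon mean ≥ 5 µm away from the dystrophy, so the away baseline is 1
by construction. Kinds: distance ≡ 0 with rising bud / falling beneath
slopes → loading, distance ≡ 0 otherwise → swelling, 0 → positive →
pinching-off (pinch time = first positive distance), positive throughout →
detached; losing the bud censors the event at the last observation. The
persistence bound is survivors × span / tracked — survivors persisted at
least the span, non-survivors count as zero, so the bound is conservative.

**Statistics.** Aggregation order is fixed: objects → animal means →
group mean ± SEM (an unbalanced-animals regression test guards the
order). Comparisons run on per-animal values: unpaired two-tailed t-test
for two groups; one-way ANOVA with Tukey's post hoc for several; two-way
ANOVA (group × movement class) with Tukey over all cell combinations for
class panels, where by display convention only chosen classes'
comparisons are surfaced while the adjustment spans all cells. Stars:
* p<0.05, ** p<0.01, *** p<0.001. The default test's type-I error is
calibrated (0.05 ± 0.02 over 1000 null simulations at n = 6 per group).

## Validation scale and runtime choices

The transport/co-localization recovery study uses 8 synthetic animals ×
500 particles (4000 total) on 250 µm fields with drift (0.2, 0.1)
px/frame — enough that binomial noise on a 25 % class is ~0.7 points,
well under the ±3-point recovery band, while the study completes in a few
minutes on one CPU. Volumetry recovery uses one 300-particle scene per
outside fraction {5, 15, 35} %. The demo pipeline defaults to 2 animals ×
150 particles for a fast smoke run; all sizes are configuration, not
method, choices.

## What passing tests do and do not show

The generator matches the analysis' structural assumptions: straight
parallel axons, constant-velocity runs, isotropic Gaussian spots, linear
drift, discrete non-overlapping puncta. Passing recovery tests therefore
demonstrates correctness of the measurement code under those assumptions,
not robustness to curved axons, direction reversals, photobleaching,
myelin autofluorescence, fluorophore maturation/persistence differences
between reporters, or non-rigid tissue motion — none of which are
modelled. The stationary/moving boundary behaviour is exact by
construction; real data near the boundary will be sensitive to
localization noise in a way the truth-separated generator deliberately is
not.

## Known limitations

- Rigid translation registration only; no rotation/affine or non-rigid.
- Greedy linking without probabilistic data association; dense crossings
  beyond the synthetic regime may fragment or swap.
- The residual quality gate removes direction-reversing objects unless
  disabled.
- Voxel-grid snapping in the z-stack generator trades sub-voxel placement
  realism for exact volume bookkeeping.
- The object-wise outside fraction assigns whole components by centroid;
  components genuinely straddling the mask boundary are all-or-nothing.
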