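# Methods

`myonuc` quantifies the nuclei of isolated skeletal-muscle fibres: how many
there are, what shape they have, how they are arranged along the fibre, and
how much cytoplasm each one serves. This note records the models behind each
stage, the defaults and why they were chosen, and the limits of what the
synthetic-data tests demonstrate.

## Fibre and nucleus model

A fibre is an elliptic cylinder of length L with cross-section axes w
(width) and t (thickness), long axis aligned with image x. Its
cross-section area is the ellipse area

    CSA = π (w/2)(t/2)        [µm²]

and the volume of a 100 µm segment is `CSA × 100` µm³. Myonuclei are
triaxial ellipsoids (default semi-axes 6 × 2.5 × 2 µm, i.e. a 12 µm long,
flattened nucleus) whose geometric centres sit at a configurable
sub-sarcolemmal depth (default 2 µm) below the fibre surface, reflecting
the peripheral position of myonuclei in mature fibres.

## Synthetic-data generator

The generator is first-class, tested code: it defines the statistical
structure every downstream estimator is validated against.

**Nucleus placement.** The nucleus count on a fibre is Poisson with mean
`density × L/100` (default density 6 nuclei/100 µm, the typical value for
young-adult Tibialis anterior fibres). Centres are uniform in axial
position and in the cross-section ellipse parameter angle, then thinned by
a hard-core constraint: candidates closer than `min_spacing` to an accepted
centre are rejected, with a bounded budget (200 attempts per nucleus).
Nuclei that cannot be placed are dropped with a warning; if fewer than half
of the drawn count can be placed the density is declared incompatible with
the spacing and the call fails. `min_spacing = 0` recovers the pure Poisson
null model. The default `min_spacing = 15 µm` emulates the orderly
(repulsive) arrangement of myonuclei; on the default geometry it produces
3D nearest-neighbour distances around 28–30 µm, the magnitude observed in
mature fibres. An `axial_placement="regular"` mode places the rounded mean
count on an even axial lattice — the idealized limit of perfectly orderly
spacing — which is used for estimator-consistency checks (see MND below).

**Orientation law.** Nucleus in-plane orientation (major axis vs fibre
axis, θ ∈ [0°, 180°)) follows an axial von Mises law: 2θ ~ von Mises(0, κ).
κ = 0 gives the uniform law (mean sinus 2/π ≈ 0.637); increasing κ
concentrates nuclei along the fibre axis (κ = 2, the default, gives mean
sinus ≈ 0.31). The analytic mean sinus is computed by numerical quadrature
(`expected_mean_sinus`) and used as the oracle in calibration tests. This
is the simplest wrapped axial family that reproduces graded shifts of the
sinus histogram toward alignment; no claim is made that real nuclei follow
it exactly.

**Rendering.** Each nucleus is rasterised as a filled ellipsoid on a grid
with anisotropic voxel size (default 0.5 × 0.5 × 0.5 µm; the 0.5 µm z step
matches the confocal z-series convention), convolved with an isotropic
Gaussian PSF (σ = 0.3 µm, a typical lateral confocal width) and corrupted
by noise (default Gaussian, σ = 2% of the dynamic range; Poisson shot noise
available). The grid extends one margin (max semi-axis + 2 µm) beyond the
fibre envelope on all axes so edge nuclei are not clipped; the grid origin
is stored with the stack so segmented centroids and ground truth share one
µm coordinate frame.

**Time-lapse movies.** 2D fields of point nuclei rendered as Gaussian
spots, sampled every `frame_interval` minutes for `duration` minutes
(default 20 min / 24 h → 73 frames). Motion models: stationary; constant
drift at v µm/min in a random per-nucleus direction; intermittent motion
(each interval is a move with probability p at speed v). Truth tracks are
returned alongside the movie.

**Section fixtures.** Transverse-section counting is modelled at the table
level: a jittered grid of fibre centroids/radii plus satellite points
placed 1 µm outside randomly chosen fibre boundaries,
`round(n_fibers × fraction/100)` points in total. Detection of
Pax7-positive cells from raw images is out of scope.

**What the generator does not emulate:** depth-dependent attenuation and
spherical aberration, intensity heterochromatin texture, fibre curvature
and tapering, fibre-to-fibre CSA variability (exposed as parameters but not
calibrated to data), myotube fusion. Passing recovery tests therefore shows
the estimators are correct for well-behaved peripheral nuclei on straight
fibres, not that segmentation would be error-free on real, lower-contrast
stacks.

## Segmentation

Foreground is `intensity > threshold` (Otsu by default; a fixed threshold
can be given — the choice is declared, not derived from any published
setting). Components are 26-connected in 3D; an optional distance-transform
watershed splits touching nuclei (off by default). Components are filtered
by physical volume (default minimum 30 µm³, far below any plausible
myonucleus, to suppress noise specks; no maximum by default). The geometric
centre is the unweighted mean of member voxel centres scaled by the voxel
size — a geometric, not intensity-weighted, centroid. IDs are assigned in
descending volume with ties broken by scan order. Degenerate inputs: an
all-zero stack returns an empty list; a constant non-zero stack under Otsu
raises an explicit degenerate-threshold error.

## Morphometry

Measured on the xy projection (union over z) of each nucleus mask:

- **area** = pixel count × dx·dy;
- **major/minor axes** from the second central moments of pixel centres
  (best-fit-ellipse convention, axis = 4√λ), computed in µm so anisotropic
  pixels are handled; a unit-pixel moment is added so one-pixel-thin
  regions keep finite width;
- **roundness** = minor/major ∈ (0, 1];
- **maximum diameter** = maximum Feret diameter over pixel corners (convex
  hull + exhaustive pair search), whose direction, folded into [0°, 180°)
  relative to the fibre axis, defines the orientation angle;
- **sinus** = sin(angle) ∈ [0, 1], invariant under θ ↦ 180° − θ.

The max Feret diameter may slightly exceed the fitted major axis; the two
are deliberately distinct (Feret direction for orientation, moment axes for
roundness). Near-circular regions (roundness > 0.95) have no reliable
direction; their sinus is reported but flagged indeterminate.

Fibre width and thickness are generator inputs here; on real data they
would be measured at mid-length of the analyzed segment (the measurement
position is configurable in principle but not part of this pipeline's
image path).

## Spatial statistics

**Nearest neighbour (NN).** Euclidean distance in µm (z calibrated by the
0.5 µm step) from each nucleus's 3D centre to the closest other nucleus of
the same fibre, via a k-d tree; the per-fibre mean and sample SD (ddof = 1)
summarise regularity. Fewer than two nuclei gives an explicitly undefined
result, never zero. No cross-fibre pooling.

**Myonuclear domain (MND).** A segment (default 375 µm) starting at the
fibre origin is cut into slices (default 20 µm): nuclei are binned by x
into half-open slices, and each occupied slice contributes `v/n` with
v = CSA × slice length. 375/20 leaves a 15 µm remainder; the partial slice
is included with its true volume (CSA × 15) by default and can be dropped.
Empty slices are excluded from the mean/SD (v/0 is undefined) but counted
and reported.

Note the estimator's finite-occupancy bias: under Poisson placement the
expected mean of v/n over occupied slices is `v·E[1/n | n ≥ 1]`, which at
1.2 nuclei per slice is ~13% below the density-based value `CSA × 100/d`.
The two agree when slice occupancy is deterministic, i.e. for evenly spaced
nuclei — which is how the consistency check is run (regular placement, an
18-slice segment). A unit test pins the Poisson-case bias against the
analytic conditional expectation. This bias is a property of the slice
method itself, inherited faithfully rather than corrected.

**Orientation distribution.** Sinus values are histogrammed into ten
half-open bins of width 0.1 (last bin closed at 1) as percentages, plus the
three aggregate ranges 0–0.3 (within ~20° of the axis), 0.3–0.6, 0.6–1
(40°–140°).

## Tracking

Per-frame detections are linked greedily between consecutive frames:
candidate pairs within `max_link_distance` are taken in order of increasing
distance (ties by lowest index), each detection used once; leftovers start
or terminate tracks. No gap closing — a missed detection ends a track.
Detections with several in-radius candidates are counted as ambiguities so
confusable configurations (e.g. two nuclei swapping) are flagged rather
than silently mis-linked.

A frame interval is "in motion" iff its displacement exceeds
`motion_threshold` (default 0.5 µm, roughly the localization noise floor of
the synthetic movies; with a zero threshold any noise makes every interval
"moving", which motivates the positive default). Percentage time in motion
is `100 × moving/total intervals`; average velocity is the mean of
displacement/interval over moving intervals only — a track that never moves
has 0% and an undefined (flagged) velocity.

## Group statistics

Two-sided tests throughout. The Student t-test is the classic
pooled-variance form (Welch available); two zero-variance groups with equal
means give t = 0, p = 1, unequal means are flagged degenerate. The
Mann-Whitney U test uses the exact small-sample distribution when the
pooled sample is small and tie-free. One-way ANOVA is followed by Tukey HSD
pairwise comparisons; with fewer than three groups it falls back to the
t-test.

The two-group regression comparison fits OLS per group and proceeds
sequentially: an extra-sum-of-squares F-test of slope equality
(separate-slopes vs common-slope model); only when slopes are compatible at
α = 0.05, an F-test of equal elevation (intercept under the common-slope
model); plus per-group slope-vs-zero p-values and R². Elevation is never
reported when slopes differ, since intercept comparison is meaningless
across non-parallel lines. Calibration is verified by simulation: the slope
test's null p-value is uniform (KS check), and power against a 2× slope
difference at n = 60/group exceeds 95%.

The unit of analysis is per-fibre for counts, NN and MND, per-nucleus for
shape metrics, and per-track for motion; fibres are pooled across animals.
Fibre-within-mouse clustering is not modelled (no mixed effects) — a known
limitation that inflates effective n for between-animal inference.

## Pipeline

`pipeline.run` spawns per-cohort and per-fibre seeds from one global seed
via `numpy` seed sequences, analyzes each fibre (optionally through the
full render → segment path; by default directly from ground-truth
centroids, which is exact for the noise-free estimators and keeps cohort
runs fast), writes per-cohort and combined tidy CSVs, a stats report, a
JSON-lines log and a manifest with SHA-256 hashes of every output. A
failing fibre is logged, skipped and recorded; reruns with the same
configuration are bit-identical. Outputs are sorted by cohort and fibre id
so the result is order-independent.

## Problem sizes used in validation

The shipped checks use 100–120 µm test fibres for rendered-stack work and
100–1000 replicates for Monte-Carlo recoveries (3-SEM criteria), 1000
simulations for null-uniformity of the slope test and 200 for power. These
sizes make all Monte-Carlo conclusions stable at the 3-standard-error level
while keeping a full run in well under a minute per module.

## Known limitations

- The slice-MND estimator's occupancy bias (above) is reproduced, not
  corrected; a 3D tessellation estimator would behave differently and is
  deliberately out of scope.
- Greedy linking is not globally optimal; dense, fast-moving fields need a
  probabilistic tracker.
- Otsu thresholding assumes a bimodal intensity histogram; very sparse or
  very noisy stacks may need a fixed threshold.
- Width/thickness (hence CSA) come from the generator specification rather
  than being measured from the rendered envelope.
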