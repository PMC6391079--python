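# Methods

This note documents the models and procedures implemented in `sheetflow`,
the defaults and why they were chosen, the numerical edge rules, and what
the synthetic generator does and does not emulate.

## Motion representation

**Superpixel grid.** The first frame is partitioned into a regular grid of
near-square tiles. For a target count `n` on an `H×W` frame the nominal
tile width is `w = sqrt(H·W/n)`; row and column counts are the integer
pair bracketing `H/w` and `W/w` whose product is closest to `n` (ties go
to more regions). A perfectly matching near-square tiling does not exist
for every `n` (e.g. `n = 3` on a square frame); the implementation
guarantees the closest achievable count and records the exact `w` as the
length unit used by every radius parameter. Coordinates are `x = column`,
`y = row`, 0-based, origin top-left.

**Dense optical flow.** Flow backends are pluggable
(`register_flow_backend`); the default is scikit-image's iterative
Lucas–Kanade (`ilk`), with TV-L1 registered as a slower, smoother
alternative. The backend contract is an `(H, W, 2)` array of `(dx, dy)`
per pixel with positive `dx` meaning rightward motion from the first to
the second frame (verified in the tests by recovering a known circular
shift). Like all local flow estimators, iLK is unreliable on featureless
regions; the tracker tolerates this because superpixels average flow over
their whole footprint, and the sheet-assignment stage removes background
tracks by motion thresholding.

**Track propagation.** Each superpixel's footprint is its frame-0 label
mask translated by the integer cumulative displacement and clipped to the
frame; the update is

    r(t+1) = r(t) + round( mean of flow over the footprint at t )

Rounding displacement increments to the nearest integer keeps footprints
on the pixel lattice; a `round_displacement=False` option gives sub-pixel
tracks when the downstream statistics warrant it. Footprints never deform:
area lost off-frame is not recovered, and a footprint with zero in-frame
pixels freezes its track at the last position for the remaining frames.
Footprints of different superpixels may overlap after motion converges;
this is allowed. In dense mode, grid cells of the original tiling that no
longer contain any track centroid are re-seeded each frame with a new
superpixel (spawn frame recorded; positions before spawning are filled
with the spawn position), so newly exposed image area stays covered.

## Sheet assignment

Assignment to moving sheets uses motion only, per channel: (1) threshold
on the cumulative path length over the first 2 frame pairs — the default
threshold is `0.1·w`, i.e. a superpixel must move a tenth of its width in
two hours to count as moving; (2) keep the largest connected component of
the movers under a radius graph at `1.2·w`; (3) when a channel claims more
frame-0 area than a plausibility cut-off (default 0.70, appropriate for
50:50 platings), superpixels claimed by both channels are awarded to the
channel with the larger early path length; (4) with fixed-grid tracking,
non-kept superpixels are activated frame-by-frame when their tracked
centroid enters the area currently covered by kept footprints; (5) steps
1–2 are re-run on the enlarged set (a flag disables this); (6) all
non-kept tracks are reset to constants at their frame-0 centroids, so
every video in a cohort has the same track count. The activation area in
step 4 is the union of translated kept footprints — the most literal
reading of "the joint area occupied".

## Mesh statistics

**Meshes.** The static mesh links superpixels whose *frame-0* centroids
lie within `1.2·w` (on a regular grid this is the 4-connected lattice:
diagonals sit at `sqrt(2)·w ≈ 1.414·w` and are excluded); it is frozen for
the video, so all distortion is measured against the initial geometry. The
radius-neighbour graph uses current positions and a larger default cutoff
(`5·w`) matched to the spatial scale of boundary formation, which spans
the frame height. All distance comparisons are inclusive (`≤`), making the
exact-distance case deterministic. A kNN graph (union-symmetrized,
distance ties broken by lower index) is provided for analyses where
topological rather than metric neighbourhoods are wanted.

**Strain.** Per superpixel, strain is the mean absolute change of
neighbour distances from frame 0 (an L1 form — most neighbour distances
exceed 1 px, where the L1 norm is less sensitive to occasional flow
outliers than a quadratic); the video curve is the mean over non-isolated
superpixels, and multi-channel videos average the per-channel curves
unweighted. Normalization divides by the curve maximum within a common
comparison window; an identically-zero curve (rigid or static motion)
normalizes to zero rather than 0/0.

**Stability index.** Time is rescaled to [0, 1]; the end gradient is the
mean first-order difference over the last `tail` frames divided by
`1/(T−1)`, and the index is `1 − gradient`. Defaults: `tail = max(10,
ceil(0.1·T))`, capped at `T−1`. A plateaued or identically-zero curve
scores 1; a linear rise to the maximum scores 0; a curve still steepening
scores negative. The index is bounded above by 1 for non-decreasing
normalized curves but is not clamped: values above 1 would flag a
decreasing tail (relaxation), worth seeing.

**Strain vectors and mesh order.** The resultant strain vector of node i
at frame t is `Σ_{j∈N_i} [(r_i(t)−r_j(t)) − (r_i(t−1)−r_j(t−1))]` — the
frame-to-frame change of each relative displacement, summed over
neighbours. Among the candidate readings of a "displacement relative to
neighbours" vector, this one was chosen because it is exactly zero under
rigid translation (so collective drift does not masquerade as order) and
varies smoothly in time. The mesh order parameter applies the standard
mean-resultant-length formula to these vectors; vectors with norm below
1e−8 px are excluded, and a frame where every vector vanishes (perfectly
rigid motion) scores 1 — rigid collective motion is maximal order. The
velocity order parameter uses the same formula on instantaneous
velocities; there a frame with no motion is reported as NaN instead,
since "the order of nothing moving" has no velocity-based answer.

**MSD / RMSD.** `MSD(Δt) = ⟨|r(t+Δt) − r(t)|²⟩` over all start times and
tracks; the exponent α comes from ordinary least squares on log–log
values over the first `max(3, 10%)` lags. An identically-zero MSD raises a
degenerate-input error rather than returning a fabricated exponent.
`RMSD(t) = sqrt(⟨|r(t) − r(0)|²⟩)` — the square root is applied so the
quantity has the units its name implies; the normalized variant divides by
the curve maximum in a common window, or by the value at a reference frame
when cohorts of different durations must be compared.

**Correlations.** The spatial correlation at radius r averages, over
superpixels, the mean temporal correlation between a superpixel's 2-D
velocity series and each neighbour within `r·w` of its frame-0 centroid;
the 2-D covariance sums both components and is normalized by total
standard deviations. Because neighbourhoods are discs (not annuli), the
curve at r mixes all pairs closer than r; the exponential fit `a·e^(−r/b)`
is therefore an effective description, and the tests validate the
estimator against the analytic expectation under the same disc averaging.
The VCC standardizes each velocity series by its 2-D mean and total
standard deviation (population convention, so self-correlation at zero
lag is exactly 1), computes the zero-padded cross-correlation over all
lags, and reports the maximum absolute value, which Cauchy–Schwarz bounds
by 1. Constant-velocity series have undefined normalization and raise a
degenerate-input error. Sheet-level VCC averages the per-pair statistic
over all red×green pairings (optionally a seeded subsample) separately on
windows ending 5 frames before and starting 5 frames after gap closure —
the ±5 margin reflects the accuracy of automatic closure detection.

**Saliency and boundary formation.** Per frame a radius graph at `5·w` is
built on current positions and each superpixel's degree is added into an
image at its rounded position; the image is averaged over frames and then
over the frame-0 partition (each region replaced by its mean). The
boundary formation index Otsu-splits the region values and reports
`(mean(high) − mean(low)) / mean(high)`; means rather than extremes
because the map is sparse (one sample per superpixel per frame). A
constant map — Otsu undefined — scores 0 by definition.

## Boundary analysis

**Segmentation.** The k-means strategy median-filters with a square kernel
of one superpixel width, clusters pixel intensities into k classes (k = 2
by default; k = 3 accommodates dim leading-edge cells), keeps everything
brighter than the darkest class, then applies binary closing (disk 5),
removal of components below 5% of frame area, hole filling and
largest-component selection. The entropy strategy uses edge-preserving
(bilateral) smoothing, a local-entropy transform, Otsu thresholding, and a
row-raster hole fill (each row filled between its first and last mask
pixel — adequate because the sheets span rows).

**Gap closure.** Fronts are the per-strip extreme-x mask pixels over 100
horizontal strips; each red front point pairs with its nearest green front
point and the per-frame mean pair distance forms the gap curve. The floor
of this curve — the residual distance due to segmentation error — is
estimated by an asymmetric least squares (Whittaker) baseline with the
smoothness penalty on *first* differences (a slope penalty drives the
asymmetric fit to a flat floor; the classic second-difference penalty
admits a tilted line at zero cost and tracks the decline instead).
Defaults: smoothness 1e5, asymmetry 0.01, 10 iterations. The curve itself
is approximated by a linear smoothing spline whose budget is set from a
robust noise estimate (`s = n·σ²`, σ from the MAD of first differences).
Closure is the first frame where the spline falls below
`baseline + 2·max(std(baseline), σ)`, required to have first exceeded
that threshold; curves whose excursion above the floor never reaches 10
noise scales (configurable) carry no resolvable open gap and return None.
On noiseless piecewise-linear curves the detector lands on the corner
frame; with σ = 5 px noise it stays within ±5 frames in all 100 seeded
test runs.

**Descriptors.** Boundary lines come either from the intersection of the
two sheet masks or from matched opposing tracks (moved-since-last-frame
superpixels with a cross-colour partner within `2·w`, density-filtered by
requiring ≥ 5 candidates within `3·w`), reduced to one mean x per unique y
with an interpolating spline. Points exactly on the line count as
non-invading (deterministic tie rule). The shape index is arc length over
chord; intermixing is reported both as boundary-mask area fraction and as
the Otsu-thresholded saliency-map area fraction. Kymographs bin median
x-velocities by x-position with `2 ×` the number of unique frame-0
centroid columns by default (Nyquist for the grid sampling).

## Phenotyping

Motion signatures are normalized strain curves linearly resampled to a
common grid (97 points by default — one per hour over 0–96 h at the
assay's standard cadence). Motion maps are plain 2-component PCA without
whitening; projection of held-out signatures uses the frozen mean and
components and is affine. Track clustering fits Gaussian mixtures to the
(n × T) matrix of per-superpixel local strain curves for k = 1..k_max
with 5 restarts and a fixed seed, selecting k by BIC. The shared ("tied")
covariance default keeps the parameter count far below the track count for
typical curve lengths; per-component full covariance is selectable but at
cohort sizes of a few hundred tracks its BIC penalty suppresses all
structure, and the skewed within-group strain distribution tempts
diagonal models into over-splitting. Control-based cut-offs are
`mean ± 1 sample SD` (ddof = 1) of pooled control values, assuming
approximately normal control statistics.

## Synthetic data

The generator renders the two-sheet assay at desk scale: 256×320 frames
(the acquired assays are 512×672 and upward), a 120 px gap, symmetric
3 px/frame fronts, 60 frames at one frame per nominal hour, blob texture
with ~8 px grain over a sheet-interior intensity floor of 100 grey levels,
a faint static background field (amplitude 8) standing in for camera
fixed-pattern structure and autofluorescence, and additive Gaussian noise
(σ = 2). The intensity model matters: dye-filled confluent sheets are
uniformly bright with granular modulation, and real backgrounds are dark
but not featureless — a pitch-black background with pure i.i.d. flicker is
untrackable by any dense-flow method and segments arbitrarily, which
misrepresents the assay. Scenario kinematics are piecewise-constant
velocities (advance until contact, then stop / keep advancing and displace
the other sheet / briefly interpenetrate); no mechanics, proliferation,
mitosis or intensity bleaching are simulated, fronts are straight, and
sheets move rigidly. Passing tests on this generator therefore validate
the measurement pipeline — flow → tracks → meshes → statistics →
detection — not biological realism: finger-like fronts, cell-scale
velocity heterogeneity and division events in real data will degrade flow
quality in ways the simulator does not probe. Ground truth (closure frame
`= ceil(gap/(v_L+v_R))`, interface trajectory, per-frame masks) is
computed from the kinematics, not from the rendering.

Point-process generators provide Brownian tracks (i.i.d. Gaussian steps)
and ballistic tracks (constant random headings), whose MSD exponents
(1 and 2) and RMSD closed forms anchor the kinematic statistics. Saliency
fixtures encode the boundary-index semantics: a constant map (index 0), a
single line or point over empty background (index 1), and two
Gaussian-profile hotspots carrying the same total mass as the line, whose
graded tails lift the Otsu low class above zero and pull the index below
the line's.

## Problem sizes and determinism

Test and acceptance runs use scaled-down geometries chosen to exercise
every code path: 160×224 two-sheet videos with 150 superpixels and 42
frames for full-pipeline checks, 100–1000 point-process tracks for
kinematics, 10–20 seeds for scenario-ordering and clustering-recovery
properties, and 100 seeded noisy curves for closure detection. All
randomness flows through explicit integer seeds (`numpy.random.default_rng`);
the pipeline is deterministic given config + seed. Flow estimation is the
runtime bottleneck; the pipeline tests pass `radius=7, num_warp=3` to iLK,
which on the synthetic texture matches the default-parameter flow to
within rounding while running ~3× faster.

## Known limitations

- Rigid footprints: superpixels translate but never deform or rotate, so
  strain is measured between centroids only.
- Motion-based assignment needs the background to be trackable as static;
  severe full-frame flicker or stage jitter should be corrected upstream.
- The boundary-line-from-tracks reconstruction (match radius, density
  filter) has three free radii; defaults are expressed in superpixel
  widths and exposed, but have only been validated on synthetic stalls.
- The spatial-correlation fit conflates all pairs within r (disc, not
  annulus); compare fitted `(a, b)` only across analyses using the same
  radii.
- Gap-closure detection assumes the gap is open at the start of the video
  and its curve reaches a floor; assays that begin after contact return
  None.
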