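# Methods

This note documents the models behind `smlmpipe`, the conventions and
defaults its estimators use, what the synthetic generators do and do not
emulate, and the limitations a user should know before applying the
pipeline to real data.

## Scope and assumptions

The pipeline targets 2-D surface imaging: ligands immobilised on a flat
substrate and adhesion proteins in the ventral (TIRF-illuminated) plane
of adherent cells.  All geometry is planar; coordinates are in
nanometres throughout, densities in molecules per µm².  Axial structure,
spectral crosstalk and channel registration beyond a shared drift model
are out of scope.

## Synthetic scenes

**CSR fields.** `simulate_csr` draws a homogeneous Poisson process:
Poisson(λ·A) points, i.i.d. uniform.  This is the null model for the
density→spacing conversion and for the Ripley and colocalisation
calibrations.

**Clustered fields.** `simulate_thomas` draws a Thomas process — Poisson
parents, Poisson(µ) offspring per parent, isotropic Gaussian offsets of
standard deviation σ.  Parents are drawn in a window buffered by 4σ so
the restriction to the observation window is stationary (no edge
deficit).  Its pair-correlation function is known in closed form,
`g(r) = 1 + exp(−r²/4σ²)/(4πσ²κ)`, which the tests use as an oracle.
The defaults used in colocalisation scenes (σ = 50 nm, µ = 30) place the
cluster length scale inside the 60–160 nm band where nanoscale
heterogeneity of surface-coupled ligand fields is typically observed.

**Two-colour scenes.** Three reference constructions with known truth:
a *colocalized* pair (channel 2 = channel 1 plus Gaussian jitter,
reflected at the window boundary; jitter models labelling displacement
plus localisation error), an *independent* pair (two CSR draws) and a
*segregated* pair (channels confined to complementary half-planes).  The
colocalized base is CSR by default and a Thomas field with
`base="clustered"`; the clustered base is the relevant condition for
validating the DoC score, because a rank correlation of density
gradients needs an actual density landscape to correlate (see below).

**Adhesion scenes.** `simulate_adhesion_scene` samples the
adhesion-protein channel at one density inside the union of adhesion
polygons and another in the rest of the cell footprint, with the ligand
channel CSR over the whole window and independent of the ROIs.  This
encodes the null in which adhesive structures do *not* sit on ligand
hot-spots, and carries exact per-molecule ground-truth labels.

**Blinking movies.** `render_blinking_stack` gives each molecule a
geometric number of blinks, geometric on-times and off-gaps (memoryless
kinetics — the simplest model compatible with radius/on-time/off-gap
grouping rules), Poisson photons per on-frame, and renders each emission
as an error-function-integrated Gaussian PSF on the pixel grid.
Fiducials are ideal constant emitters.  Background is Poisson per pixel;
with `shot_noise=True` (default) the whole expected image is
Poisson-resampled.  The camera gain is a pure unit conversion:
EM-register excess noise, read noise and pixel non-uniformity are not
modelled.  Defaults (1000 photons/frame, 2-frame on-time, 20-frame
off-gap, 3 blinks, 10 background photons/pixel/frame) describe a
generic organic-dye regime; they are parameters of the scene, not
measurements.

## Localisation

**Detection.** Per frame: Gaussian filter (σ = 1 px), threshold
`I − M > k·S` with `M`, `S` the mean and standard deviation of the
*filtered* frame (per-frame statistics are robust to bleaching trends;
the thresholded statistic is the filtered intensity).  Local maxima
closer than one fit window merge into the brighter one.  `k = 6` by
default.

**Fitting.** Each window (half-width 4 px by default; 3 px suits the
smaller PSF of photoactivatable proteins) is fitted with
amplitude·integrated-Gaussian + constant background by least squares
with Poisson weights refreshed from the model, which approximates the
photon maximum-likelihood estimate.  Windows holding 2–3 candidates are
fitted jointly as a multi-emitter model; more crowded windows are
discarded and counted.  Pixel (i, j) has its centre at
((i+½)a, (j+½)a) nm.

**Precision.** The per-event precision is
`σ²_loc = (σ²ₐ/N)(16/9 + 8π σ²ₐ b²/(N a²))` with `σ²ₐ = σ² + a²/12`,
evaluated from the fitted photon count, width and background.  On
rendered movies at N ≈ 1000 photons and b² = 10 photons/pixel the
measured per-axis RMSE is ~0.99 of this prediction (the acceptance
script recomputes this).

**Grouping.** Events chain into one molecule while they stay within the
grouping radius of the group's running photon-weighted centre and are
temporally linked: consecutive-frame runs of at most `max_on` frames,
dark gaps of at most `max_gap` frames.  A run that would exceed
`max_on` starts a new group (conservative split), and two events in the
same frame never share a group.  Merged records take the
photon-weighted mean position, summed photons, first frame, and a
photon-weighted combination of precisions.  Defaults: 100 nm, 5 frames
on, 50 frames gap.

**Drift.** Fiducials are tracked by per-frame nearest-neighbour linking
from seed positions (the search re-centres every frame, so total drift
far beyond the search radius is followed).  Displacements relative to
each fiducial's first observation are averaged across fiducials, then
summarised per knot (default every 100 frames) by a local linear fit
evaluated at the knot — unbiased at the movie edges where the averaging
span is one-sided — and interpolated linearly, anchored to zero
displacement at frame 0.  The estimator covers the piecewise-linear
drift model class; it is not a reimplementation of any vendor's
estimator.

## Spatial statistics

Ripley's K uses the unbiased pairwise estimator
`K(r) = A/(n(n−1)) Σ_{i≠j} w_ij 1[d_ij ≤ r]`.  Edge corrections:
`toroidal` (exact for periodic synthetic data, the default for
simulations), `isotropic` (closed-form circle-arc weights for
rectangular windows, for real ROIs), `none`.  A guard warns when the
largest radius exceeds a quarter of the shorter window side.  The
density→spacing conversion is the CSR mean nearest-neighbour distance
`d = 1/(2√λ)` — e.g. 0.01 µm⁻² ↔ 5 µm, 600 µm⁻² ↔ 20.41 nm — and is the
exact inverse of `λ = 1/(4d²)`.

## Clustering

DBSCAN follows the original neighbourhood convention: a core point has
at least ε points *including itself* within the search radius, so the
smallest reportable cluster has ε members.  Border points reachable from
several clusters go to the first-discovered cluster in input order.
Cluster area is the convex hull of member coordinates (degenerate hulls
report zero area and an undefined density, flagged); convex hulls
overestimate the area of strongly concave structures, which matters for
elongated adhesions — densities of such clusters are lower bounds.

## Degree of colocalisation

For each molecule, cumulative neighbour counts of both channels are
taken at radii 10–500 nm (10 nm steps), converted to densities
(count/πr²; the molecule itself is excluded from its own channel's
counts), normalised by the largest-radius value (rank-invariant, kept
for reporting comparability), and rank-correlated (Spearman) across the
radius grid.  The score is attenuated by the molecule's
nearest-neighbour distance to the other channel:

    DoC = ρ_s · exp(−d / R_max),   R_max = 500 nm.

The exponential form of the nearest-neighbour correction is this
package's documented convention (the literature states that a correction
is applied but not its formula); both the form and R_max are
configurable.  Molecules whose largest-radius disc exits the window are
excluded by default (`edge_policy="exclude"`); `"clip"` instead divides
counts by the exact circle–rectangle intersection area.

Molecules with a constant gradient vector in either channel — typically
molecules that see no other-channel point within R_max, i.e. locally
single-species — have an undefined rank correlation; they carry
`doc = 0` and a `degenerate` flag.  Summary means are taken over
non-degenerate scores (molecules for which the score is defined);
including the flagged zeros would dilute population means toward zero in
proportion to the single-species fraction, which is a composition
effect, not a colocalisation signal.

Behaviour on the reference scenes (recomputed by the acceptance
script): clustered fields with 20 nm channel jitter score a mean DoC of
~0.85 with ~99 % of molecules above the 0.4 threshold; segregated
half-planes score ~−0.23; independent CSR fields at 50 µm⁻² score
+0.11.  Two properties of the statistic are worth stating explicitly:

- On *structureless* (CSR) colocalised pairs the mean DoC plateaus near
  0.6 at every density — there is no density landscape for the rank
  correlation to recover, so jittered CSR copies are not a usable
  positive control.  Colocalisation validation uses clustered fields,
  which is also the regime of real SMLM maps.
- At very sparse densities the score acquires a small positive bias
  under independence (+0.11 at 50 µm⁻², shrinking to +0.03 at
  500 µm⁻²): radii below both channels' nearest-neighbour spacing
  contribute matching zero-count ties at the bottom of both rank
  vectors.  Near-zero means under independence should therefore only be
  expected at the densities where the analysis is normally run
  (hundreds of molecules per µm²).

## ROI analysis

ROIs are labelled polygons in nm (`cell`, `adhesion`); overlapping
polygons of one label are unioned before any area is computed, and
boundary points count as inside.  `density_in_out` compares the adhesion
union against the cell footprint minus adhesions; no guard band is
applied around adhesion boundaries.  `surface_vs_undercell_density`
compares the whole-window average with the average over the union of
cell footprints.  The tethering threshold (0.8 µm⁻², strict) and
spreading range (4–7 µm⁻²) used by `classify_adhesion_support` are
reported empirical constants exposed as configuration, not quantities
this package estimates.

## Numerical choices and problem sizes

Validation runs use problem sizes that keep the full suite fast while
leaving comfortable statistical margins: Ripley calibration averages 100
CSR fields of n ≈ 5000; DBSCAN is checked against an exhaustive
density-connectivity oracle on 100 instances of ≤ 50 points; DoC scenes
use 10×10 µm windows at 50–500 µm⁻²; localisation recovery uses
1500-frame movies of nine emitters at ~1000 photons/frame; drift
recovery uses one fiducial over 2000 frames.  Random draws all flow from
explicit integer seeds; generators are bit-reproducible given a seed.

## Known limitations

- Camera model omits EM excess noise and read noise; measured photon
  counts on EMCCD data will carry ~√2 extra variance that the precision
  formula does not include.
- The multi-emitter fit handles at most three overlapping candidates;
  denser overlap is discarded rather than modelled.
- Convex-hull areas overestimate concave cluster footprints (an
  alpha-shape alternative is a natural extension).
- The DoC nearest-neighbour correction is one reasonable convention;
  absolute DoC values are comparable only between analyses using the
  same functional form and R_max.
- Drift estimation requires at least one trackable fiducial; no
  cross-correlation fallback is provided.
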