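# Methods

This note records the models, conventions and numerical choices behind
`volscape`, in the order the pipeline uses them.

## Problem setting

A cryo-EM 3D classification of a flexible two-body complex — here a
proteasome-like particle with a fixed core (CP) and a mobile regulatory cap
(RP) that rotates about the long axis — produces many class-average volumes,
each with a particle count. Because class occupancy under thermal equilibrium
follows a Boltzmann distribution, relative counts over a conformational
coordinate can be inverted into a free-energy landscape. The package
implements that chain (align on the fixed body, PCA over the ensemble,
Boltzmann inversion, barrier analysis), the upstream two-state particle
classifier used for counting rotated vs non-rotated particles, and two
atomic-model analyses (segment B-factor truncation, hexameric ring geometry).

## Conventions

* Volumes are float32 arrays indexed `[x, y, z]`, isotropic voxels (1%
  tolerance on read), MRC/CCP4 mode-2 files via gemmi; masks are 0/1 maps.
* Rotations are active, right-handed, about the geometric box center;
  a positive angle about an axis is counterclockwise seen from the axis tip.
  The long axis defaults to +z and is user-supplied, never auto-detected.
* Projections integrate along z after rotating the volume; trilinear
  interpolation everywhere (documented as swappable; adequate at phantom
  scale).
* Free energies are reported in units of kT with the most occupied bin at 0,
  sidestepping any explicit temperature.
* The low-pass filter uses a soft cosine edge (two Fourier shells wide)
  ending exactly at the cutoff. A soft-edged filter is not a projection, so
  it is idempotent only where the edge band carries negligible signal power —
  true for the Gaussian phantoms at any resolution past their spectral
  falloff, and how the idempotency check is posed.

## Synthetic phantom (the test-bed conditions)

`default_phantom_spec` builds a two-body Gaussian pseudo-atom phantom in a
48-voxel box at 4 A/voxel (192 A box, about the size of a single-capped
26S particle):

* **CP**: 10 on-axis Gaussians (sigma 8 A) forming a barrel along z, plus two
  off-axis surface ridges at different azimuths and a bump. The ridges are
  essential, not decoration: they make the barrel's azimuthal orientation
  observable, so (a) CP-only rigid alignment is fully determined and (b) a
  global rotation of the whole complex cannot mimic a rotation of the cap
  alone. Their combined mass is comparable to the cap's; with weaker ridges
  the two-state classifier's discrimination margin collapses.
* **RP**: 14 Gaussians (sigma 8 A) in an off-axis cluster confined to an
  ~80-degree azimuthal sector at radius 0.30-0.45 of the half-box, above the
  barrel. The sector confinement makes the rotation angle strongly visible in
  projections; mass is ~1.3x the CP mass (the real regulatory particle is
  heavier than the core).
* Rotating the cap moves pseudo-atom *coordinates* before rendering, so total
  density is exactly angle-independent and rendering is linear in weights.
* `default_masks` are z-slabs: the CP mask stops two RP sigmas below the body
  boundary so the cap's Gaussian skirt cannot leak into the alignment region;
  the RP mask is the upper half-space. Slabs are invariant under rotation
  about the axis, so they cover the moving body at every angle.

Class ensembles place classes on an even angle grid over the energy
function's domain and draw counts from one multinomial with
p_i proportional to exp(-E(theta_i)). Energy functions: flat; harmonic
(0.5 kappa (theta-theta0)^2, default kappa 0.02 kT/deg^2); quartic double
well with exact well/barrier values for symmetric wells (an optional tanh
tilt approximates unequal well depths). Defaults for the double well: wells
at +-15 deg, barrier 3 kT, domain +-25 deg.

Two-state particle stacks choose each particle's state by a Bernoulli draw,
project at a uniformly random orientation and add white Gaussian noise with
variance `var(clean image)/snr`. No CTF is simulated: the classification this
feeds operates downstream of per-particle CTF correction in the original
protocol. The mixture presets use the three measured conditions (41%
control, 13% Oprozomib, 25% Epoxomicin rotated) at a 25-degree separation,
n=400, snr=2.

What the generator does *not* emulate: CTF and envelope decay, stain/ice
artifacts, non-rigid (melting) motion within bodies, correlated noise,
picking errors. Passing tests therefore demonstrate correctness of the
analysis chain under rigid-body motion with white noise, not robustness to
every property of real micrographs.

## Subcomplex alignment

Masked normalized cross-correlation (NCC), exhaustive over an intrinsic
Euler-angle grid (default +-6 deg at 2-deg steps) with the best translation
per rotation from FFT cross-correlation of the masked, mean-centered
densities (parabolic sub-voxel peak refinement, clipped to the search range).
The best rotation is refined by two passes of per-axis coordinate descent
with parabolic interpolation (steps h and h/2). Scores are masked NCC in
[-1, 1]; results under 0.2 are flagged, not rejected. On the default phantom
a 3-degree jitter about a random axis is recovered to ~0.5 deg (half the
coarse step) and 2-voxel shifts to well under 0.25 voxel.

The RP rotation angle of an aligned volume maximizes masked NCC between the
volume and the reference rotated about the axis, over a 0.5-deg grid with
parabolic sub-step refinement. `RPRotationEstimator` precomputes the rotated
reference library once; batch estimation over an ensemble reuses it. A
correlation profile with range < 1e-3 raises an indeterminate-angle error.

## Eigenvolume PCA

With N classes and ~10^5 voxels the covariance is intractable but the N x N
Gram matrix of masked, mean-centered, flattened volumes is not;
eigendecomposition of the Gram matrix yields the same eigenvolumes as a
direct SVD (verified to 1e-8 in tests). Coefficients ("linear factors") are
masked inner products with the orthonormal eigenvolumes. PCA is unweighted:
particle counts enter only the landscape. A count-weighted variant
(sqrt-count row weights) sits behind a flag. Volumes are centered but not
variance-normalized — normalizing would distort occupancy geometry.
Eigenvolume signs follow one convention: the largest-magnitude masked voxel
is positive, making coefficients reproducible across platforms. Eigenvalues
are sums of squared coefficients (so they total the full centered variance
at K=N-1); explained-variance fractions divide by that total.

## Energy landscape

Each class deposits its full count at its coefficient point on a 2D grid
(default 32x32 over the data extent plus 5% margin; the paper-scale choice of
bin count is open, so it is a parameter). Optional Gaussian smoothing acts on
occupancy *before* the logarithm (default sigma 1 bin; 0 gives exactly
E_b = -ln(n_b/n_max)). Empty bins are NaN, or capped at (max defined energy
+ 1) under a flag. Minima are non-strict local minima over 8-neighborhoods;
the barrier between the two lowest minima is the minimax-path bottleneck —
the lowest possible maximal energy along any 8-connected path (heap-based
Dijkstra with max-edge relaxation) — minus the higher minimum. Disconnected
minima raise an infinite-barrier flag rather than a number.

Discretization caveat: binned occupancy measures density x bin measure, so a
bin holding two classes reads ~ln 2 deeper than its neighbors. Quantitative
barrier checks therefore match the bin width to the class spacing (one class
per bin); the Spearman-based harmonic check is rank-based and immune to the
monotone reparameterization between rotation angle and the first coefficient.

## Two-state classifier

Competitive projection matching over a quasi-uniform Fibonacci view grid
(default 10-deg spacing) x in-plane rotations (5 deg) x integer shifts
(+-3 px, step 3). Templates and (shifted) particles are multiplied by a soft
circular support mask, zero-mean normalized, and compared by dot product
(one large float32 matrix product per reference per iteration); exact ties
assign to the non-rotated state. After each of the (default 3) iterations
both references are rebuilt from their assigned particles by ramp-filtered
real-space backprojection (images smeared along their viewing axes, divided
by a coverage map floored at 10% of its maximum), blended with the previous
reference (damped update, default weight 0.5 on the old reference), low-pass
filtered to a common resolution (default 20 A), normalized, and multiplied by
a fixed soft support envelope derived once from the *initial* references.

Grid density matters more than noise here: at snr=2 the per-particle error
against the true references is dominated by differential orientation
mismatch between the two template libraries, not by the noise itself
(measured accuracies are identical noise-free and at snr=2). A 15-deg view
grid leaves only ~0.75 accuracy on the default phantom; 10 deg/5 deg reaches
~0.99, which is why the finer grid is the default.

The support envelope, the ramp filter and the damped update all exist to
keep the iterative reference update stable: reconstructions from a few tens
of images carry coverage artifacts that otherwise accumulate and bias the
competition against the smaller class — without damping, a 13%-rotated
mixture can collapse toward zero within three iterations on unlucky draws.
Damping trades convergence speed for stability; with ground-truth-quality
starting references this costs nothing, and with crude starting references
more iterations simply achieve the same refinement.

## Atomic-model metrics

Segment classification cuts each chain into consecutive 5-residue windows
(trailing shorter window classified by its own mean) and averages B over
*atoms*, not residues. Classes: mean < 110 A^2 keeps side chains; 110 to
150 A^2 inclusive truncates to poly-alanine (N, CA, C, O, CB kept, residue
renamed ALA; glycine simply has no CB); above 150 A^2 the segment is
removed. Boundary values land in poly-alanine ("between" read inclusively,
"smaller than" strictly); thresholds are arguments.

Ring geometry: six labeled C-alpha atoms are projected onto their
least-squares plane (or the plane normal to a supplied axis), closed into a
hexagon in the given order, and the interior angle at each vertex is computed
from adjacent edges with the polygon's signed area fixing orientation, so
reflex vertices of non-convex rings report angles above 180 deg. A perfect
ring gives six 120-deg angles; `max |angle - 120|` summarizes asymmetry.

## Pipeline, configuration, determinism

One YAML config (unknown keys rejected) drives align -> PCA -> landscape ->
barrier; outputs land under `run-<config hash>` so distinct configurations
never collide, and `summary.json` stamps the hash and seed. All randomness
flows from a single integer seed; reruns are byte-identical on the text
artifacts. Fixture presets regenerate every dataset used in testing.

## Problem sizes used in the test suite

Unit tests run the same physical phantom on a 32-voxel lattice (6 A voxels);
recovery tests use the production 48-voxel box. Classifier recovery uses
n=400 particles per condition; Boltzmann-inversion checks use 41 classes and
1e5 particles. These sizes keep each check comfortably inside a desk-scale
run while leaving the estimators in the same regime the method targets.

## Known limitations

* Real-space backprojection is inherently blurrier than Fourier-gridded
  reconstruction; the ramp filter compensates approximately and only under
  reasonably uniform view coverage.
* The iterative classifier can still destabilize when one class becomes very
  small (a couple dozen particles), because its reconstruction quality
  degrades faster than the other's; the support envelope and damped update
  mitigate but do not remove this.
* The landscape treats each class as a point mass; no per-class resolution
  spreading rule is attempted beyond the single smoothing knob.
* Alignment assumes the search range brackets the true transform; there is
  no global (full-sphere) search.
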