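# Methods

## Segmentation model

Each channel is treated as a 3D scalar field indexed `(z, y, x)` with
anisotropic voxels (defaults 0.3977 µm axial, 0.2636 µm in-plane, matching a
63x confocal acquisition). Blob enhancement uses a difference of Gaussians
with σ = 1 and 4 in *pixel* units; all filtering and thresholding operate in
voxel coordinates, never physical units, so the anisotropy metadata is
carried but does not enter the computation.

Two filtering modes are provided. The default, `slice2d`, applies the 2D DoG
independently to every z-slice: macro-style image filters parameterized "in
pixels" conventionally act slice-wise, and the default keeps that behavior.
`3d` applies one isotropic 3D convolution for users who want true volumetric
smoothing. Boundaries are handled by reflection, which keeps Gaussian kernels
mass-preserving at the edges (a constant image filters to numerically zero)
and avoids spurious edge blobs from zero padding.

The threshold is `mean + 2·sd` of the *entire filtered stack* (sample SD,
n−1 denominator). Per-stack rather than per-slice statistics follow from the
mask being a single 3D object with one threshold; at stack scale (10⁵–10⁷
voxels) the n−1 choice is numerically irrelevant but makes small hand-checked
examples exact. Mask membership uses strict inequality (`value > t`), so a
constant image yields an empty mask rather than a full one. Because both the
filter and the threshold are linear in the input, the mask is exactly
invariant to positive rescaling of the raw image — exposure changes do not
move the segmentation.

No minimum blob size, watershed, or per-cell ROI is applied: the mask is the
bare supra-threshold set.

## Manders coefficients

`M_A` is the fraction of channel A's in-mask intensity that lies in the mask
intersection, and symmetrically for `M_B`. The numerator and denominator use
**raw** intensities, not DoG-filtered values: filtered values can be negative
and would break the [0, 1] range. When a denominator is zero (empty mask or
zero in-mask signal) the coefficient is *undefined* and carried with a reason
code; group summaries exclude undefined values and count them, so "no
signal" is never conflated with "no overlap". No significance test between
groups is computed — the output is descriptive boxplot data (n, mean, median,
SD, SEM, min, max, plus the raw values).

## Synthetic scenes

A scene is a pair of stacks of isotropic 3D Gaussian puncta (peak
`amplitude`, width `punctum_sigma`, in voxels) over a constant background
with additive Gaussian noise, clipped at zero. Channel A has `n_puncta_a`
puncta placed uniformly in the grid interior (margin 2σ); a fraction
`coloc_fraction` of channel B's puncta are placed at distinct, randomly
chosen A centers (sampling without replacement, so the colocalized count is
exactly `round(coloc_fraction · n_puncta_b)`) with Gaussian positional jitter
`jitter_sd`, and the rest are placed independently. Gaussians are rendered
exactly over the full grid (no truncation), so rendering is strictly additive
and total intensity matches the analytic sum.

Defaults: 16×256×256 voxels, 40 puncta per channel, σ = 1.5 voxels, amplitude
100 over background 10, noise SD 2, jitter SD 0.5, and a minimum
center-to-center separation of 4·σ between independently placed puncta.
The separation default keeps puncta discrete and resolvable, as they appear
in real fields of cytoplasmic granules; the spacing constraint is *not*
applied between a colocalized punctum and its partner. The two experimental
conditions bundled in the pipeline driver use colocalized fractions 0.9
(wild-type-like) and 0.1 (5xPIE-like) with n = 10 scenes per condition,
mirroring the quantification design the pipeline reproduces.

What the generator deliberately does **not** model: a microscope point-spread
function (puncta are already Gaussian), Poisson photon statistics (noise is
additive Gaussian — the simplest model that stresses the threshold rule),
cell and nucleus geometry, a DAPI channel, photobleaching, or chromatic
misregistration. Passing tests therefore demonstrate that the algorithm
recovers programmed overlap from blob-like signal in noise; they do not
certify performance on aberrated or densely packed real images.

One property worth knowing: because the threshold is global, mask *tightness*
depends on puncta density. In sparse fields the 2·SD threshold sits lower
relative to the blob tails and masks extend further beyond the true punctum
cores; the mask-specificity check in the test suite is therefore run at a
realistic density. This mirrors the behavior any mean + k·SD rule has on
mostly-empty images.

## Densitometry

Lane profiles are 1D non-negative signals over a strictly increasing
migration coordinate. Band quantification integrates `intensity − baseline`
over a user-supplied window by the trapezoid rule, where the baseline is the
straight line joining the (interpolated) profile values at the window
endpoints, and negative corrected values are clipped to zero first. The
endpoint-baseline-plus-trapezoid rule is the standard 1D lane-profile
workflow; it is a declared convention of this package, chosen because it is
closed-form testable. Band windows are supplied by the user, not
auto-detected — peak detection would add unverifiable behavior.

The ratio readout divides the band area by a reference band's area from the
same lane (undefined and flagged if the reference is ≤ 0), and replicates are
summarized as mean ± SEM with SEM = sample SD / √n (undefined for n = 1;
triplicate, n = 3, in the bundled design). Synthetic lanes place Gaussian
bands of known integrated area on a linear baseline with seeded noise; a
window of ±6 band sigmas captures the analytic area to well under 1 %.

## Numerical and design choices

- Coordinates are 0-based, axis order `(z, y, x)`, z the acquisition order.
- Gaussian smoothing kernels are sampled and truncated at 4σ (the scipy
  convention); the test suite checks the impulse response against an
  independently sampled analytic kernel at 1e−6 relative tolerance and the
  full filter against a direct-summation convolution oracle.
- All RNGs are numpy `default_rng` seeded explicitly; identical specs
  (including seed) give bit-identical scenes, and the experiment driver
  derives per-scene seeds deterministically from the run seed, so result
  CSVs are byte-identical across reruns.
- Stacks are written as OME-TIFF (axes CZYX, float64) with physical voxel
  sizes embedded; files lacking voxel-size metadata fall back to the
  acquisition defaults with a logged warning.
- Degenerate inputs fail loudly: single-voxel grids (SD undefined),
  non-finite intensities, DoG sigmas at or above half the in-plane extent,
  windows with fewer than three interior samples, and scenes smaller than
  4·punctum_sigma per axis are all rejected with specific errors.

## Problem sizes

The bundled experiment analyzes 16×256×256-voxel scenes (≈1 M voxels, ~0.7 s
per scene to generate and score), 10 scenes per condition; oracle-equivalence
checks run on 8³–8×64×64 grids where brute-force reference implementations
are exact and fast. These sizes make the full validation suite and the
reproduction script quick on a single CPU while keeping every quantity
computed, never hard-coded.

## Known limitations

- The slice-wise default means axially elongated structures are segmented
  from their in-plane appearance only; use `mode="3d"` if axial smoothing is
  wanted.
- The global threshold couples mask extent to field density (see above); the
  pipeline does not attempt per-cell normalization.
- Only Manders coefficients are implemented — no Pearson, Costes
  randomization, Li ICQ, or object-based (centroid-distance) statistics.
- Densitometry assumes already-extracted 1D profiles; 2D gel-image lane
  boxing and rolling-ball background subtraction are out of scope.
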