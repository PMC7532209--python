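# Methods notes

## Scope and model

`roqa` quantifies populations of compact, convex, bright objects in 3D
grayscale volumes under an explicit shape model: each object is summarized
by the ellipsoid best fitting its polygonized surface. The model is
appropriate for cell nuclei, which are smooth and roundish; it is not a
general segmentation framework. Everything downstream of segmentation
(filters, statistics, bookkeeping) treats the *particle* — one 26-connected
component of foreground voxels — as the unit of analysis.

Conventions used everywhere: arrays are indexed `(z, y, x)`, 0-based, with
"bottom" the lowest z index; physical quantities are µm/µm²/µm³ derived
from the declared voxel spacing `(dz, dy, dx)`; intensities stay in native
detector counts; morphological structuring elements are defined in voxel
units (as acquisition software defines them), so anisotropic voxels make
elements physically anisotropic — intentional, since thresholds and
kernels are calibrated per dataset anyway.

## Segmentation

The white top-hat (WTH) transform `v − opening(v)` removes any background
structure larger than the structuring element, making one global threshold
act locally adaptive. The element is a cube of side `wth_kernel` voxels by
default (separable, fast); a ball variant is available. Threshold bounds
are inclusive at both ends, so a band reaching the dtype maximum keeps the
brightest voxels — necessary when the label is the densest material in the
sample. The volume sieve interprets "smaller than X µm³" strictly: a
particle of exactly X survives.

The WTH threshold controls how far particles extend into the blurred
intensity falloff and therefore sets apparent object size. `tune_threshold`
automates the usual practice of matching segmented particles to reference
measurements: it grid-searches candidate thresholds, matches each
reference location to the nearest particle centroid (within a 20 µm match
radius by default), projects the particle along the reference view axis,
and minimizes the mean relative error of the silhouette's longest/shortest
caliper (Feret) diameters. Ties break toward the higher threshold (the
more conservative segmentation). A grid of size one reproduces a fully
manual choice. Note the caliper of a voxelized silhouette is measured over
pixel corners and systematically overestimates by up to ~1.5 voxels; the
bias is absorbed by the threshold search, which is the point of tuning
rather than trusting absolute calibration.

Non-local means denoising is the standard exact algorithm (patch 3³,
search window 10³, strength h expressed on intensities normalized to
[0, 1]). The `spatial_sd` parameter of adaptive-manifold variants is
accepted for config compatibility but has no exact-NLM analog and is
ignored; equivalence with proprietary implementations is not claimed.

## Meshing and ellipsoid fitting

Surfaces come from marching cubes at the 0.5 iso-level of the 1-voxel
zero-padded binary mask; padding guarantees a closed, consistently
oriented 2-manifold. Mesh area is the triangle-area sum; enclosed volume
is the absolute signed-tetrahedron sum (divergence theorem), so the global
orientation convention cannot flip the result. Particles thinner than two
voxels along any axis cannot support a meaningful iso-surface and are
flagged degenerate — recorded per particle, never raised, so bookkeeping
stays exhaustive. Binary iso-surfaces carry staircase faceting: the area
of a voxelized sphere is ~8–10 % above the analytic value, which pushes
measured sphericities below 1 even for perfect spheres at ~1 µm voxels.
Comparisons between groups measured at the same resolution are unaffected;
absolute sphericities should be read with this bias in mind.

The ellipsoid fit solves the general quadric `x'Qx + b'x + d = 0` in all
ten parameters by SVD with a unit-norm constraint, after centering the
points and scaling them to unit RMS for conditioning. Points lying exactly
on a quadric make the design matrix rank-9 (its null vector *is* the
solution), so rank ≥ 9 is required, not 10. The centered form is
eigen-decomposed; any non-positive or non-real squared semi-axis means the
best-fitting quadric is not an ellipsoid and the fit is flagged
`hyperboloid` — these are treated as anomalies, not coerced. Fewer than 9
points, coplanar input, or a singular center solve are `degenerate`. On
noiseless surfaces the fit recovers center and semi-axes to ≤ 1e-6
relative and is exactly invariant under rigid motions.

The quality statistic is the ellipsoid-to-voxels volume ratio. For a
well-segmented convex particle it converges to 1 as voxel size shrinks;
fused aggregates inflate the fitted ellipsoid and typically push it past
1.2. The accept band [0.8, 1.2] is inclusive; invalid fits are always
rejected. Every record lands in exactly one of accepted/rejected —
conservation of counts is asserted in tests and in the pipeline
bookkeeping.

## Aggregate disintegration

Rejected anomalies are reprocessed per particle on a padded crop of the
original grayscale volume: unsharp mask (Gaussian low-pass with
σ = edge_size/2 voxels, gain `edge_contrast`, clipped — never rescaled —
back to the integer range), mask to the aggregate, H-maxima markers
(regional maxima with dynamic ≥ h, 26-connected, via grayscale
reconstruction), then marker-based watershed on the inverted enhanced
intensity restricted to the aggregate. Watershed-line voxels are removed
from every daughter, accepting a one-voxel erosion at the interfaces in
exchange for guaranteed disjointness; daughter sets are subsets of the
parent and never outnumber the markers. Flooding order ties are resolved
deterministically by the queue discipline of the watershed implementation,
so repeated runs are bit-identical. Zero markers return the parent unsplit
and flagged. Daughters below the re-sieve minimum are dropped and counted.

The H-maxima dynamic `h` is an intensity contrast and must be scaled to
the data: the published 900 counts belongs to 16-bit byte-scaled µCT
reconstructions; the phantom preset uses 2500 counts, about a quarter of
the phantom's nominal dome amplitude, chosen the same way (above the
noise-induced prominences, well below the core-to-neck contrast).

## Group statistics

Shape-measure distributions are skewed by construction (ratio measures
bounded in (0, 1], volume high-pass filters), so location and spread are
the median and SIQR with linear-interpolation (type-7) quantiles.
Significance is the two-sided Wilcoxon–Mann–Whitney test: exact
enumeration when min(n) ≤ 25 and the pooled sample is tie-free, otherwise
the normal approximation with tie and continuity corrections. Because
thousands of particles make p values tiny even for heavily overlapping
distributions, the reported `well_resolved` flag additionally requires
|Δmedian| > average SIQR. Raw p values are reported without
multiple-testing correction; measures are read jointly against the SIQR
criterion rather than against a corrected α. Missing values (e.g. failed
mesh volumes) are excluded pairwise per measure.

## Synthetic phantoms

The generator emulates what labeled nuclei look like at the image level in
tube-source µCT: voxelized rotated ellipsoids with a dome intensity
profile `peak·(1 − r²/2)` (brightest at the core, half-peak at the
surface), per-nucleus peak variation, a flat or radially graded
background, Gaussian PSF-surrogate blur, and detector noise with a
0.5-voxel correlation length (reconstruction kernels band-limit noise;
white noise would create unphysical voxel-scale maxima). Overlapping
nuclei combine by maximum, not addition — labels do not stack. Defaults:
longest semi-axis U[10, 14] µm, elongation N(0.80, 0.06), flatness
N(0.45, 0.08) (truncated to (0.05, 1]), peak 10 000 ± 400 counts over
background 1000, blur σ 0.8 µm, noise SD 200 counts, 1.1 µm isotropic
voxels — sized to nuclei of ~20–28 µm longest diameter at the dry-scan
resolution. Fused pairs place the companion at 0.9 × the sum of the
directional surface radii along the joining line: distinct bodies in
contact whose interfaces blur together, the geometry the watershed stage
exists for. One master seed spawns per-nucleus substreams, so scenes are
bit-reproducible and truth tables are independent of rendering
(`render=False` yields truth-only replicates for statistical calibration).

Ground-truth sphericity uses the exact Legendre elliptic-integral surface
area by default; the Knud Thomsen approximation (p = 1.6075, ≤ 1.06 %
error) is available for quick tables.

What phantoms do *not* model: streak/ring artifacts, beam-hardening
cupping beyond a smooth gradient, the sub-voxel granularity of particulate
labels, spatially varying PSFs, and correlated multi-object occlusions.
Passing phantom tests therefore validates the geometry and statistics
chain, not robustness to reconstruction artifacts — on real scans the
reference-tuning step and visual QC of rejected particles remain
essential.

## Presets and calibrated values

The four sample-class presets carry the parameter bundles for wet/dry
scaffold µCT (WTH kernel 5/10, lower threshold 5400/2700 counts, sieve
100/15 µm³, 88 µm bottom crop for wet scans), flat-substrate µCT (kernel
5, threshold 13 700, sieve 13 µm³; the NLM variant thresholds at 5000
after denoising), and confocal stacks (8-bit, kernel 33, threshold 50,
ball closing 3, first sieve 13 µm³, binary smoothing 3/0.5, ball closing
12, volume band-pass 120–2290 µm³). The disintegration bundle is unsharp
edge size 7 / contrast 3 / brightness threshold 0, h = 900, re-sieve
15 µm³; the ratio band is 0.8–1.2 everywhere. The `phantom` preset
(kernel 31, threshold 3500, h 2500) was calibrated against the generator
defaults with the package's own reference-tuning search; its loss is flat
over roughly 3000–4500 counts.

## Problem sizes in the test suite

Phantom-based tests use FOVs of 96³–288×224² voxels, 2–50 nuclei per FOV;
the two-condition experiment runs 300 nuclei per arm through the full
imaging pipeline in 20 FOVs of 15, and the null calibration uses 40
truth-only replicates of the same design. Oracle-equivalence suites run 50
seeded instances per primitive on ≤ 12³ grids, where brute-force
definitions are exact and fast. These sizes were chosen so the full suite
exercises every pipeline path at realistic resolution while remaining
convenient to run locally.

## Known limitations

- The ellipsoid model under-describes lobed or concave nuclei; such
  particles surface as ratio-band rejections rather than being force-fit.
- Watershed daughters lose a one-voxel shell at cut interfaces, biasing
  daughter volumes slightly low relative to never-fused neighbors.
- Axis calipers from voxel silhouettes are biased high by up to ~1.5
  voxels; use them through the tuning loss, not as absolute lengths.
- RAW input requires the JSON sidecar; nothing is inferred from file
  sizes, so undocumented export dialects must be described once by the
  user.
- Structural equivalence with proprietary acquisition-software modules
  (top-hat variants, adaptive-manifold NLM, H-maxima internals) is not
  claimed; parameters with the same names may need recalibration when
  migrating a protocol.
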