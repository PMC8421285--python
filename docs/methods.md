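# Methods

## The question and the experiment

Cortical gray-matter areas differ in cyto- and myeloarchitecture, and the
angular profile of the diffusion MRI signal at the cortical surface carries
some of that contrast. Given a fixed scan-time budget of two or three HARDI
acquisitions, the package asks whether it is more informative to repeat one
b-value (improving SNR on one diffusion weighting) or to spread the
acquisitions over different b-values (probing different microstructural
length scales at lower per-shell SNR). The experiment is fully data-driven:
no biophysical model is inverted; per-vertex feature vectors are fed to a
binary classifier and the per-ROI-pair correct-classification rate is the
measure of information content.

## Feature model

Per acquisition, the DWI signal at a vertex is normalized by that
acquisition's mean b0 signal (nonpositive normalized values are clipped to
1e-6) and expanded in a real, antipodally symmetric spherical-harmonic
basis of order 6 — 28 coefficients, even orders only, with sin-type terms
at m < 0, the zonal harmonic at m = 0 and cos-type terms at m > 0
("descoteaux-style" ordering). The least-squares fit minimizes
`|B c − s|² + λ |L c|²` with the Laplace–Beltrami penalty
`L = diag(l(l+1))`; the default is λ = 0, which is well-posed for ≥ 28
directions (all schemes used here have 30 or 64), with λ = 0.006 the
documented fallback for noisier or subsampled schemes.

The 28 coefficients are reduced to 9 features. Four are fully rotation
invariant: the per-order powers `p_l = sqrt(Σ_m c_lm²)`, l = 0, 2, 4, 6
(`p_0` equals `2√π` times the spherical mean of the normalized signal).
The remaining five are referenced to the local surface normal: after
rotating the profile so the normal points along +z (rotation about
`n × z` by the angle between them; the identity or a π flip about x when
the normal is already (anti-)parallel to z), they are the zonal
coefficients `c'_20, c'_40, c'_60` and the transverse powers
`t_l = sqrt(Σ_{m≠0} c'_lm²)` for l = 2, 4. These are invariant to rotations
about the normal and satisfy the closure `t_l² + c'_l0² = p_l²`. This
particular 9-feature set is fixed here because it realizes exactly the
required invariance split (4 fully invariant, 5 normal-referenced) and
every property of it is testable; other invariant sets with the same split
exist.

Coefficient rotation is implemented by evaluating the band-limited function
on a fixed 64-direction quadrature set rotated by the inverse rotation and
refitting — exact for band-limited input and far less error-prone than
Wigner-matrix bookkeeping. The quadrature set is generated once with a
fixed seed, so rotation is deterministic.

Feature vectors from the acquisitions of a condition are concatenated in
ascending-b order (same-b repeats in acquisition order) into 18- or
27-vectors; repeats are never averaged, so repeated- and mixed-b conditions
use identical amounts of data.

## Direction sets and shell splitting

Diffusion directions are axial, so all direction-set energies use the
antipodally symmetrized Coulomb objective
`E = Σ_{i<j} 1/|u_i − u_j| + 1/|u_i + u_j|`. Even direction sets are
produced by projected-gradient descent of E on the product of spheres with
a backtracking step, deterministic per (n, seed). Splitting a shell into k
balanced subsets minimizes the summed intra-subset energy by seeded random
balanced initialization followed by best-improvement pairwise swaps until
no swap helps, with 10 restarts; on small instances this provably reaches
the exhaustive optimum, and it is verified to beat random balanced
partitions. The exponent-1 (Coulomb) objective with antipodal
symmetrization is fixed by this package for determinism; published
splitting schemes vary and are not reproduced here.

## Surface sampling

The sample point of a vertex is `position + 0.5 · thickness · normal` in
world mm — the 50 % point of the local cortical thickness outward from the
GM/WM surface. The signal is read from the voxel *containing* that point
(inverse affine, 0-based half-open indexing, `floor`), not interpolated.
Vertices outside the volume are excluded with a logged warning. Because
surface tessellations are finer than DWI grids, vertices sharing a voxel
are reduced (per ROI, before any train/test split) to the vertex nearest
the group's mean world position; distances equal within a 1e-9 relative
tolerance count as ties and go to the lowest vertex id — in two-vertex
groups both members are exactly equidistant from their midpoint, so a
tolerance-free comparison would depend on floating-point reduction order.

## Classification and statistics

Each ROI pair × condition experiment runs leave-one-out cross validation
with a 15-tree random forest (scikit-learn defaults otherwise); one fixed
forest seed per (pair, condition) is derived from the master seed by
hashing the tags, so grids are reproducible and experiments independent.
Accuracy is the fraction of correctly classified vertices, recomputed from
the aggregated confusion counts; per-ROI F1 is the harmonic mean of
precision and recall with that ROI as the positive class, averaged across
all tests involving the ROI. No class rebalancing is performed; per-ROI
vertex counts are reported so chance level stays interpretable.

Conditions are compared across the grid with a one-sided Wilcoxon rank-sum
(Mann–Whitney) test of "mixed beats repeated", exact when both groups have
≤ 25 entries and no ties, otherwise the normal approximation with tie
correction. The rank-sum test (not the paired signed-rank test) is the
default deliberately; a signed-rank option exists behind a flag. Results
are reported as mean ± sd accuracy difference in percentage points with
the one-sided p.

## Synthetic data: what it emulates and what it does not

A cortical patch is a sinusoidal sheet `z = a sin(2πx/λ)` (defaults a = 3
mm, λ = 20 mm) sampled on a 1 mm vertex grid — finer than the 1.7 mm
isotropic DWI voxels, as in real surface pipelines — with analytic unit
normals, truncated-normal thickness (2.5 ± 0.3 mm, > 0.5 mm) and
contiguous ROI bands. Microstructure per ROI is a mixture of axially
symmetric tensors (default eigenvalues 1.2/0.5 × 10⁻³ mm²/s, low
anisotropy as in cortex) oriented radially or tangentially to the sheet,
with axes drawn per vertex from a Watson distribution (default
concentration κ = 6, i.e. substantial orientation dispersion) — drawn once
per vertex, since repeated acquisitions image the same tissue. The
b-dependence departs from mono-exponential through a kurtosis-like factor
`exp((b·adc)² K/6)` applied per compartment; the signed exponential form
keeps signals positive and monotone-controllable and is a modeling choice,
not a claim about cortex. Noise is Rician
(`sqrt((S+ε₁)² + ε₂²)`, ε ~ N(0, σ)) with σ set by the b0 SNR (default
20); magnitude MR data leaves no Gaussian option.

The benchmark ROI family varies the radial fraction (0.35–0.70) and the
kurtosis term (0.2–1.3) and calibrates every ROI's eigenvalue scale (by
1-D root finding on a dense spherical quadrature) so all ROIs share the
same direction-averaged signal at the middle b-value. A single mid-b shell
therefore sees only the angular (radial-vs-tangential) contrast plus
noise, while low/high b-values additionally see the kurtosis contrast —
the hypothesized mechanism by which different b-values probe different
microstructural properties. The default acquisition set is one low, three
middle and one high b-value at 800/1400/2000 s/mm², 30 directions per
shell (shared across shells, as in repeated-shell protocols) plus 4 b0
volumes.

The generator does not emulate anatomically realistic folding, laminar
(depth-resolved) profiles, partial-volume mixing with WM/CSF, susceptibility
or eddy-current distortion, or spatially correlated noise. Passing
benchmarks therefore show that the pipeline detects the encoded
b-dependence/orientation contrasts under Rician noise at realistic SNR —
not that real cortical areas differ in this way or by this much.

## Problem sizes and determinism

The standard benchmark uses 600 vertices (two ROIs × 300) for the paired
condition comparison, five master seeds, and a seven-ROI grid at 60
vertices per ROI for the 21-pair rank-sum comparison — sizes chosen so a
full reproduction runs in minutes on a single CPU while keeping
leave-one-out training sets in the several-hundred range. All randomness
flows from one master seed through named substreams (patch geometry,
per-vertex axes, per-acquisition noise, per-experiment forests); identical
seeds give byte-identical outputs.

## Known limitations

* The 9-feature set matches the stated invariance structure but is one of
  several possible choices; absolute accuracies depend on it.
* The rank-sum test treats the per-pair accuracies of the two conditions
  as independent samples although they share vertices; this mirrors the
  stated analysis but is anticonservative relative to a paired test.
* LOO with a per-fold forest is O(n) forest fits per experiment; very
  large vertex counts call for a cheaper CV scheme.
* Shell splitting fixes its own repulsion objective; other published
  subset algorithms will give different (equally valid) partitions.
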