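# Methods

This note records the model, the numerical choices and the limits of
what the test suite demonstrates.

## Geometry and conventions

All arrays are ordered (X, Y, Z); the slice index is Z. Multipage TIFF
stores one Z slice per page, transposed on I/O. Intensities from integer
sources are rescaled to [0, 1] at load time so that σ-scaled derivative
magnitudes are comparable across 8- and 16-bit acquisitions (the choice
of normalization is the package's own; float inputs are passed through).
The anisotropy factor ρ = s_z / s_x is always derived from the voxel
size, never stored separately. Label ids default to 0 = unlabeled
(ignored in training), 1 = background, 2 = synapse, 3 = mitochondrion.

## Feature extraction

The per-scale operator set is the Gaussian-smoothed image, the two (or
three) first derivatives scaled by σ, and the second derivatives scaled
by σ². The per-scale feature vector is (s00, |∇|, λ₁, λ₂) in 2D and
(s000, |∇|, λ₁, λ₂, λ₃) in 3D, with eigenvalues sorted descending.
Scales form a half-octave ladder σ_i = 2^(i/2) σ₀; the user sets only σ₀
and n (default n = 4, matching the usual 4→11.31 px working range).

Numerical choices:

- **Boundary rule:** mirror reflection for every convolution; avoids
  spurious gradients at slice borders. Gaussians are truncated at 4σ.
- **Kernel calibration.** Truncated sampled derivative kernels have a
  small non-zero DC component (second order) and a ≈0.03 % ramp-gain
  bias (first order). Second-derivative responses are DC-corrected by
  subtracting `(kernel sum) × smoothed image`, and first-derivative
  responses are rescaled so a unit-slope ramp reports exactly σ. With
  this, constants and linear ramps are annihilated/reported exactly —
  the discrete operators behave like their continuous definitions on
  polynomials up to their order.
- **2D Hessian eigenvalues** use the closed form
  ½[(s20+s02) ± √((s20−s02)² + 4 s11²)]. Note the discriminant uses the
  *difference* of the diagonal responses: that, and only that, gives the
  eigenvalues of [[s20, s11],[s11, s02]] (diagonal example: s20=s02=1,
  s11=0 must give 1 and 1, not 2 and 0).
- **F2D** is computed as a 3D separable filter with σ_z = 0, which is
  exactly independent per-slice filtering (tested: no cross-slice
  mixing). **F3D** is used automatically when ρ ≤ 1.5 and warns above.

## Classification

PCA is fitted on the cloud of all feature vectors of the training stack,
uniformly subsampled to ≤ 10⁶ vectors with a fixed seed; the retained
dimension k′ is the smallest number of leading axes whose cumulative
explained variance reaches 99 %. Per label, the class-conditional
Gaussian uses the sample mean and covariance of the projected labeled
voxels; the prior is the labeled-voxel frequency. Covariances are
regularized with ε·tr(Σ)/k′·I (ε = 1e-6, absolute ε floor for zero-trace
degenerate classes) — PCA removes most rank deficiency, but sparse
scribbles can still produce singular class covariances. Posteriors are
computed as log density (cached Cholesky factor per label) plus log
prior, normalized by log-sum-exp, so features hundreds of σ from every
class mean still yield finite normalized posteriors. Argmax ties break
to the lowest label id.

## CRF regularization

Unary terms are −log P(y|f) with posteriors floored at 1e-12. The
pairwise structure is the 6-connected grid split into in-plane (E_XY)
and across-slice (E_Z) edges, weighted θ_XY and θ_Z = θ_XY/ρ by default
(both overridable). The label distance matrix has zero diagonal, 1
between compatible labels and ∞ between synapse and mitochondrion; ∞ is
realized as the finite surrogate 10⁶·(max unary + θ_XY + θ_Z) and the
energy of the returned labeling is checked against it, raising an
infeasibility error if a forbidden adjacency survived.

Minimization uses `scipy.sparse.csgraph.maximum_flow`, which requires
integer capacities: capacities are converted at an adaptive fixed-point
scale (2²⁹ divided by the largest finite capacity, capped at 10⁷), with
∞ surrogates saturating at 2³⁰. The quantization error is ≤ a few 1e-6
of the energy on small instances (the exactness tests compare against
exhaustive enumeration at 1e-4) and is negligible relative to the
energies of realistic volumes. An exactly indifferent voxel is biased to
the lower label id so the θ → 0 limit reproduces the argmax labeling
bit for bit.

For ≥ 3 labels, αβ-swap visits label pairs in ascending lexicographic
order; each swap solves the restricted binary problem exactly (neighbors
outside the pair enter as unary context), is accepted only if the total
energy strictly decreases, and the algorithm stops after a full sweep
without improvement (hard cap 20 sweeps). Energy is non-increasing by
construction and re-running on its own output is a no-op.

Large volumes are partitioned into disjoint tiles (default 256×256×64),
each extended by a 10-voxel margin, minimized with full context, and
only core voxels are written back. The margin makes the tile seams
invisible when the decisive image evidence lies within the margin of the
cut; the tests verify exact tiled/untiled agreement for objects ≥ 12
voxels from the cuts, and seam-free labelings for objects straddling a
cut.

## Surface smoothing

Hard labels give v = ±1 (inside/outside one object label) and margins
m = 0 on both voxel layers at the interface, 1 elsewhere. The field f
minimizes Σ over axes of (f[+d] + f[−d] − 2f)², with the Z term divided
by ρ⁴ so coarse-section curvature is not over-penalized, subject to
v·f ≥ m. Axial second-difference terms are accumulated **only where the
full 3-point stencil lies inside the volume**; this discretization makes
constants and linear ramps exact zero-energy minimizers (the half-space
solution is a unit-slope ramp), which a replicated-border stencil would
not.

The constraint set is a per-voxel box (f ≥ m where v = +1, f ≤ −m where
v = −1), so projection is a clip. The solver is *damped* projected
Jacobi on the normal equations: plain Jacobi diverges for the biharmonic
stencil [1, −4, 6, −4, 1] (iteration-matrix spectral radius 5/3), and
any damping below 3/4 is stable; the default is 0.6. Defaults tol = 1e-4
(max absolute update), max_iter = 1000; non-convergence sets a flag and
never raises. Output satisfies the constraints exactly by construction;
on ≤ 200-unknown instances the objective matches an independent
bound-constrained least-squares solver within 1e-4. Meshes come from
marching cubes at the zero level set, vertices scaled to nm, normals
oriented outward; smoothing never touches the label volume.

## Evaluation

One-vs-rest confusion counts give TPR, FPR, ACC, JAC and
VOE = |FP−FN|/(TP+FN) (reported as % by the CLI). Undefined ratios
(empty foreground) are NaN, not errors. Component counting uses
6-connectivity to match the CRF graph (26 available); the count-error
statistic averages |count(t) − true count| over the threshold range
T = [10, 2000] voxels (configurable — the upper bound is dataset-scale
dependent). Cross-validation blocks are contiguous in Z because adjacent
sections are strongly correlated; random folds would leak.

## Phantom: what it emulates, and what passing means

The generator defines geometry continuously in nm and samples it at the
voxel grid, so anisotropy arises exactly as in acquisition. Defaults —
128×128×32 voxels at 10×10×20 nm (ρ = 2), 4 mitochondria of 240–400 nm
diameter with sinusoidal cristae-like stripes, 3 curved synaptic sheets
40 nm thick, 3 faint membrane sheets, class mean intensities
0.72/0.60/0.40/0.33/0.20 (background/membrane/mitochondrion/cristae/
synapse), additive Gaussian noise σ = 0.06, partial-volume edge width
0.4 px — were fixed once as a plausible cortical-neuropil geometry.
Mitochondria and sheets never overlap and keep a 2-voxel clearance, so
the forbidden-adjacency prior is true in the ground truth. All
randomness flows through one seeded generator.

The default (σ₀ = 1, θ_XY = 1, n = 4) configuration was selected by
running the package's own cross-validation grid on the phantom — the
same calibration a user would run on annotated data. The grid showed σ₀
dominating the metrics while θ_XY moved them by < 1 %, consistent with
the regularizer's role being primarily structural (it enforces the
adjacency exclusion and removes speckle).

What the phantom does **not** model: texture inside non-organelle
cytoplasm (vesicles, microtubules), imaging artifacts (charging, curtain
noise, slice-to-slice intensity drift), deformation between sections,
and structures touching the volume faces. Passing the end-to-end tests
therefore shows the pipeline's machinery is correct and well-calibrated
on clean, geometrically realistic data; it does not certify accuracy
levels on real tissue, where contrast is weaker and boundaries are
genuinely ambiguous.

## Problem sizes in the tests

Exhaustive-enumeration checks run on grids up to 3×3×2 (2¹⁸ labelings,
200 seeded instances); swap contracts on 100 seeded 4×4×2 three-label
instances; QP-oracle agreement on ≤ 200-unknown smoothing instances; the
end-to-end recovery on the full 128×128×32 phantom. These sizes were
chosen so the whole suite runs in well under a minute per property while
still covering every code path (both edge classes, both extractors,
tiling, the ∞ exclusion).

## Known limitations

- The fixed-point capacity conversion makes the binary cut exact only up
  to quantization; ties closer than ~1e-6 of the energy may resolve to a
  different but equal-cost labeling.
- αβ-swap is a local search: it guarantees monotone energy and the hard
  exclusion, not global optimality (that is inherent to multilabel
  Potts).
- The feasibility surrogate for ∞ can, in principle, flag a false
  infeasibility on volumes whose total finite energy exceeds
  10⁶·(max unary + θ); this needs ≳ 10⁶ voxels of near-floor posteriors
  and has not been observed.
- Damped Jacobi converges slowly on large smooth regions (it is a local
  relaxation of a fourth-order operator); for display-quality meshes the
  default 1000 iterations suffice, but tight QP-level convergence on
  large volumes needs many more sweeps.
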