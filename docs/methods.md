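# Methods

This note documents the models, parameter choices and numerical decisions
behind `mtukit`, and what its synthetic benchmarks do and do not show about
laboratory data.

## Construct geometry and meshing

An MTU is modeled as a rectilinear assembly: a central muscle section of
length 9 mm flanked by two 3 mm tendon anchors, total 6 × 3 × 15 mm, with
2 × 1 mm rectangular through-holes in the anchors standing in for the
mounting loops. Units are mm throughout; the origin is the construct
center and z the long (contraction) axis. The sparse design splits the
muscle section into `n_bridges` slabs spanning the full 6 mm width with
equal gaps. The width of the printed four-bridge design is not known
numerically, so the package default — total in-plane bridge width 3 mm,
i.e. w_b = 0.75 mm with 1 mm gaps — is an explicit assumption, chosen once
so that bridges and gaps are the same order of size, and held fixed across
all comparisons.

Because the geometry is rectilinear, meshing is a tensor-product grid whose
grid lines sit exactly on every geometric boundary, each segment subdivided
to elements of size ≤ h; voxelization is therefore *exact* (mesh volume =
design volume to machine precision, asserted in tests). Meshing fails
loudly if a bridge would be thinner than two elements. The contractile set
is the muscle-region surface layer (default depth 1 element), reflecting
that viable tissue forms only within a thin (~150–200 μm) shell of the
printed construct; at the default h = 0.5 mm the shell is geometrically
exaggerated, which is acceptable because only relative comparisons across
designs are made. Analyses run at h = 0.5 mm (10³–10⁴ vertices); meshing at
h = 0.125 mm reproduces the order-10⁵ vertex counts of the original
simulations and is covered by a mesh-only test, since the FEM at that size
is unnecessary for the trends studied here.

## Contraction model

Elasticity is corotational: per element, the rotation R from the polar
decomposition of the center deformation gradient is factored out and
isotropic linear elasticity (trilinear hexahedra, full 2×2×2 Gauss
quadrature; E_muscle = 49.7 kPa, E_tendon = 158.9 kPa, ν = 0.4,
ρ = 1000 kg/m³) is applied in the rotated frame. Elements are grouped by
edge-vector signature so each distinct geometry is integrated once;
arbitrary (e.g. rigidly rotated) rest meshes are supported, and an
objectivity test confirms the deformation metric is invariant under rest
rotations.

Actuation is a rest-shape modification: each contractile element targets a
rest configuration shortened by (1−ε) along the contraction direction. The
contractile strain ε is a free parameter (default 0.10); every sweep
comparison holds it fixed, so conclusions are trends, not absolute
displacements. A free homogeneous bar with all elements contractile then
has an exact stress-free equilibrium — the bar scaled by (1−ε) — which the
solver reproduces to ~1e-8, the package's main analytic oracle.

Time integration is backward Euler (duration 0.4 s, dt = 10 ms, linear
ramp) with lumped mass and Rayleigh damping (α = 10 s⁻¹, β = 0.002 s).
At these moduli and sizes inertia is negligible (elastic wave transit
~2 ms « dt), so the dynamics are effectively a damped quasistatic path;
only the first and last frames are analyzed. Each step solves the implicit
balance with a warped-stiffness Newton loop (tangent ΣR K Rᵀ, rotation
derivatives neglected) with backtracking line search; the factorized
tangent is cached across iterations and steps and rebuilt when the line
search stalls. After the time window, the final frame is settled to elastic
equilibrium by quasistatic Newton with a weak inertial regularizer
(10⁻⁴·M/dt²) that pins the six rigid-body modes without slowing the soft
elastic modes; convergence is residual ∞-norm < 1e-8·E_muscle·h² (mN), cap
200 iterations, with a hard error on failure or element inversion.

The deformation metric is max_i |x_i(T) − x_i(0)| after removing the
best-fit rigid transform (Kabsch) between first and last frames — the
construct floats freely (no anchor contact is simulated), so drift must not
count as deformation. Ties in the design sweep's "optimal design" break
toward fewer bridges (manufacturability).

## Optical-flow contractility

Flow is estimated with scikit-image's dense estimators (iterative
Lucas-Kanade by default, TV-L1 as an alternative) behind a pluggable
backend; correctness is defined by an accuracy contract on synthetic
ground-truth videos (mean endpoint error < 0.2 px for ≤ 5 px translations
at default noise), not by matching any specific implementation.

Angles use display orientation: counter-clockwise from +x after flipping
the image y axis, so "135°" means up-left on screen. Directional alignment
counts vectors within ±22.5° (an 8-bin hue-wheel quantization) of the
contraction angle, above a magnitude floor of 0.1 px/frame that discards
noise vectors; both are parameters.

The volumetric contractile kinetic energy is E_k = (ρ/2)·⟨v_i²⟩ over tissue
pixels with v_i in m/s (px/frame × pixel size × frame rate) and ρ =
1000 kg/m³ (tissue ≈ water; the symbol is used without a value in the
source protocol). Since pixels volumize uniformly, normalizing the summed
pixel kinetic energy by total tissue volume reduces to a masked mean and
the section depth cancels; it is retained only as metadata. Void areas are
masked by SLIC superpixels thresholded on mean brightness (defaults:
400 segments, compactness 0.03, threshold 0.15 on the [0,1]-normalized
frame); the threshold is deliberately explicit because real datasets need
per-dataset tuning. Image-subtraction lateral displacement is the 1-D shift
maximizing the cross-correlation of mean intensity profiles along the
chosen axis, with parabolic sub-pixel refinement; featureless frames return
NaN rather than a spurious zero.

## Mechanics fits

Indentation uses the Hertz sphere-on-halfspace model with a rigid-indenter
reduced modulus E* = E/(1−ν²) (cubic-zirconia indenter vs kPa-scale gel
justifies neglecting indenter compliance), R = 100 μm, and validity capped
at δ ≤ 0.1·R — curves beyond that are rejected, not truncated. The fit is
linear in E after the δ^{3/2} transform and therefore closed-form and
deterministic; an optional two-parameter (E, δ₀) contact-offset fit exists
but is off by default since no contact-point procedure is specified by the
protocol. Tensile curves are summarized by the stress–strain slope over a
configurable window (default 2–10% strain) and a fracture detector
triggering on a >50% drop from the running force maximum once the curve has
loaded past 20% of its peak (the latter guard keeps baseline noise from
faking a fracture); the fracture point is the last sample before the drop.

## Synthetic data

Videos are band-limited Gaussian textures (spatial correlation length
`texture_scale_px`, default 4 px) warped by exactly known motion models
(translation, uniaxial contraction about a center, rigid rotation) with
bilinear sampling from a padded texture and additive Gaussian noise; the
per-pair ground-truth displacement fields are closed-form. Defaults
(192 px, 25 fps, noise SD 0.01) emulate the stimulation recordings; pixel
size and bit depth are not reported for the originals and are configurable
package choices. Indentation and tensile curves come from the forward
models above with seeded Gaussian noise; morphometry scenes are packed
rotated-rectangle myotubes with axes drawn from a von-Mises-type angular
distribution about the tension axis and exactly round(fusion_fraction ×
n_nuclei) nuclei planted inside marker-positive tubes.

What passing these benchmarks shows: the estimators are correctly
implemented, unbiased at the stated noise levels, and internally
consistent. What it does not show: robustness to out-of-focus frames,
photobleaching, non-affine tissue deformation, segmentation errors in real
fluorescence images, or instrument drift — laboratory values such as
absolute E_k magnitudes or force outputs depend on living tissue and are
context, not oracles.

## Morphometry conventions

Nucleus-in-tube membership uses the nucleus centroid rounded to the nearest
pixel (nuclei are counted, not nuclear areas); boundary pixels count as
inside. Tube principal axes come from second central moments; tubes with
major/minor axis ratio < 1.2 are excluded from shift angles with a log
entry. Myotube width is 2 × median medial-axis distance minus 1 px (the
distance transform reaches the *center* of the nearest background pixel),
converted to μm; how width was sampled in the original protocol is
unspecified, so the medial-axis median is this package's documented choice.
Tubes thinner than 2 px are flagged unreliable.

## Orchestration and determinism

All randomness flows through explicit `numpy.random.Generator` seeds; the
demo pipeline fans one global seed into per-stage child seeds via
`SeedSequence.spawn`, rejects unknown config keys before any stage runs,
and echoes every effective value into the report directory. Identical
config + seed yields byte-identical CSV outputs (tested).

## Known limitations

- No anchor/pillar contact, self-collision, viscoelasticity or calibrated
  muscle dynamics; the simulation speaks only to equilibrium deformation
  trends across designs.
- The interdigitated interface enters the geometry only through the
  interpenetration metric (100·r_i/L); meshes do not resolve the
  invaginations.
- The warped-stiffness Newton tangent is inexact; convergence is linear
  away from stress-free states, which the tolerance/caps and line search
  accommodate but very stiff or near-inverted configurations may reject.
- Flow estimation assumes textured, band-limited imagery; displacements
  beyond half the texture scale trigger an explicit ill-posedness warning.
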