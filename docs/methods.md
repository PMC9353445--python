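# Methods

`scatvam` models, corrects and evaluates tomographic volumetric additive
manufacturing (VAM) in turbid photoresins. This note records the models the
package implements, the defaults it ships, the numerical choices behind
them, and what its synthetic experiments do and do not show.

## Printing model

A tomographic volumetric printer projects nonnegative amplitude patterns
P_theta(s, z) into a rotating cylindrical vial of photoresin from angles
theta covering a full rotation. In a transparent resin the accumulated
volumetric dose is the backprojection of the pattern set, so pattern
computation is an inverse Radon problem with a positivity constraint (a
light projector cannot emit negative intensity). Voxels whose cumulative
dose exceeds the resin's gelation threshold solidify; the rest is washed
away.

The projector pair is pixel-driven: each voxel inside the reconstruction
circle splats into its two nearest detector bins with linear weights
(scaled by the pitch, so sinogram values approximate line integrals in mm),
and `back_project` is the exact sparse transpose. This choice makes the
forward/adjoint identity ⟨Ax, y⟩ = ⟨x, Aᵀy⟩ hold to machine precision —
important because the optimizer and the dose simulator must agree about the
geometry — at the cost of slightly larger discretization error at oblique
angles than a ray-driven integrator (relative L2 error on the analytic disk
chord profile: ≈0.3 % at axis-aligned angles, up to ≈7 % at 45°, n = 256).

Projection angles span [0, 2π), not [0, π): attenuation in a turbid medium
breaks the parallel-beam symmetry, so opposite directions are not
equivalent. The default is 360 angles (1° steps), which satisfies the
angular sampling rule n_angles ≳ (π/2)·n for grids up to ≈230 px; demo
configurations at 256 px keep 360 angles.

Patterns are initialized by filtered backprojection (Ram-Lak ramp filter in
the Fourier domain, zero-padded to the next power of two, scaled by
π/(n_angles·pitch)) with negative values clipped to zero, then refined by
projected gradient descent (Landweber iteration with clipping at zero after
every step) on the plain least-squares loss ‖back_project(P) − D‖². The
step defaults to the inverse Lipschitz constant of the gradient, estimated
by twelve power iterations with a fixed internal seed so runs are
reproducible. Iterations default to 30 with a relative-loss-change stopping
tolerance of 1e-4; three consecutive loss increases abort with advice to
reduce the step. Note that when the angular sampling is already adequate,
clipped FBP is close to optimal for threshold extraction and least-squares
refinement mainly redistributes residual; the refinement is load-bearing in
angularly undersampled configurations.

## Turbid-medium model

Real measurements of a scattering resin show two signatures: the ballistic
(undeviated) component decays as exp(−z/l_s) with the scattering mean free
path l_s (Beer–Lambert), and spatial detail blurs progressively with depth
— the medium is a depth-increasing low-pass filter. The package's
parametric stand-in for the medium's frequency response is

    T(k, z) = exp(−z/l_a) · [ exp(−z/l_s) + (1 − exp(−z/l_s)) ·
                              exp(−2π² σ(z)² k²) ],   σ(z) = σ0 + α·z

with k the transverse spatial frequency (cycles/mm) and z the depth (mm).
The first bracketed term is the surviving ballistic light (full contrast at
all k); the second is the scattered halo, a Gaussian of width σ(z) that
carries power but progressively less contrast. With l_a = ∞ the DC term is
exactly conserved (scattering redistributes power in-plane without
destroying it); finite l_a models net in-plane loss — true absorption and,
in practice more importantly, wide-angle scattering that throws light out
of the printing plane and is lost to that slice. A `ballistic_only` flag
drops the halo term entirely (T = exp(−z/l_s − z/l_a) at every k),
emulating a purely absorptive resin whose mean intensity itself decays.

Propagation applies T multiplicatively in frequency space — 1D along the
structured axis for thin characterization beams and for the per-slice print
simulation, radially isotropic 2D for `propagate_pattern`. Depth slices are
treated independently (no beam divergence beyond the parametric σ(z)), and
transverse anisotropy, coherence, speckle, polarization and refraction at
the vial wall are not modeled.

In `simulate_print_dose` the depth of a propagation plane is measured from
a flat entry plane tangent to the vial wall: depth = t + R along the
optical axis, where R is the vial inner radius, so the rotation axis sits
at depth R (8 mm in a 16 mm vial). A per-ray curved-wall entry depth would
make depth depend on the lateral coordinate and break the per-plane FFT
propagation; the flat-plane approximation is exact on the optical axis and
mild elsewhere. The blurred, attenuated field of each pattern is
accumulated into the volume in the frame rotated by its angle, using the
same per-angle interpolation weights as the projector, so through a
transparent medium the simulated dose equals the backprojection exactly
(up to the pitch scale).

## Characterization and correction

Side-view characterization projects a set of thin structured patterns
(default: 100 random binary line patterns, 50 % fill) through the resin
while a camera orthogonal to the optical axis records one image per
pattern with axes (transverse position, depth). Per depth column, 1D
magnitude spectra along the structured axis are averaged over patterns;
magnitude (not power) is averaged, and the DC term is kept so the mask can
encode net attenuation. A Hann window (configurable, recorded in the
artifact metadata) suppresses edge leakage on measured stacks; on synthetic
circular stacks its 3-tap leakage biases the spectral ratios by ≲2 %,
within every stated tolerance.

The correction mask divides the incident spectrum at z = 0 by the spectrum
at each depth:

    C(k, z) = S(k, 0) / max(S(k, z), ε·max S),  clipped to [0, C_max],
    C(k, 0) ≡ 1.

Unbounded inverse filtering amplifies noise, so the inverse is regularized
twice: a noise floor ε (default 1e-3 of the global spectrum maximum) and a
hard cap C_max (default 10). Frequencies whose *incident* spectrum falls
below the floor cannot be inverted at all; they are flagged in the mask
metadata and set to 1.

`correct_target_dose` applies the mask to the binary target with the
rotating-vial depth convention d(r) = R − r (the effective penetration
depth of a voxel at radius r is its closest-approach depth over the
rotation, maximal on the axis). The spatially varying filter is realized as
a bank of n_depth_bins (default 16) global 2D filters at depths spanning
[0, R] — the 1D k-axis mask applied radially in the slice frequency plane,
clamped beyond its tabulated k range — with per-voxel linear interpolation
between the two bracketing depth bins. Negative ringing is clipped at zero
and the dose is confined to the target support (for capped low-pass
inverses the filtered field is negative outside the support anyway, so this
mask is nearly a no-op; it guarantees the support-preservation invariant
exactly). The result is normalized to a maximum of 1; absolute dose scale
belongs to exposure time and laser power, outside this package's scope.
Thresholding only depends on the ordering of dose values, so the
normalization is lossless.

For absorptive, non-scattering resins `amplitude_correction` implements the
real-space alternative: a log-linear fit of mean transverse intensity
versus depth yields the attenuation length l, and each voxel is scaled by
exp(d(r)/l). The two correction paths are mutually exclusive per run.

## Phantoms

- **Gear** (fidelity benchmark): body annulus with rectangular cogs
  protruding outward on the rim and inward on the bore. Defaults: outer
  radius 5.5 mm, bore radius 2 mm, 16 outer cogs of 750 μm width, 12 inner
  cogs of 460 μm width, protrusion depths equal to the widths, height
  2 mm. The cog angular extent is set so the arc width at the mid-cog
  radius equals the specified width exactly, which makes the width
  measurable from the voxel grid (`cog_arc_width` samples the mid-height
  slice around the mid-cog circle and averages the occupied run lengths).
- **Vascular construct**: an 11 mm solid cylinder with a 4 mm core
  surrounded by four vertical 1 mm channels on a 3.5 mm orbit, open at both
  end faces; an optional mid-height ring manifold interconnects them. Real
  vascular models have branching, non-vertical channels; straight tubes
  keep the geometry analytic and the open-channel test exact.
- **STL voxelization**: occupancy decided by point-in-solid tests at voxel
  centers, implemented as z-column crossing parity with vectorized
  barycentric rasterization of the (watertight) mesh's triangles. Columns
  with tangential (odd-parity) grazes are left empty; rays are jittered by
  1e-6 pitch to avoid shared-edge degeneracies.

Phantom voxelization happens at cell centers with no antialiasing, so
phantoms are strictly binary and deterministic; a pitch coarser than a
quarter of the narrowest feature is rejected rather than silently aliased.

## Fidelity evaluation

Simulated doses have no physical exposure control, so the canonical print
extraction is best-threshold binarization: an exhaustive sweep over 256
dose quantiles, reporting the threshold with the highest intersection over
union (IoU) against the model. For micro-CT-style volumes the protocol is
Otsu thresholding (256-bin between-class variance), coarse alignment by
center-of-mass translation plus principal-axes rotation about the vertical
axis (the π-ambiguity resolved by trying both orientations), then an
exhaustive deterministic grid of affine perturbations — in-plane
translations ±2 voxels (step 1), rotations ±4° (step 2°), isotropic scales
{0.98, 1.0, 1.02}, no shear — reporting mean, standard deviation and best
IoU. A declared grid was chosen over random sampling so reports are
bit-reproducible; the grid is configurable when wider capture ranges are
needed. IoU of two empty volumes is defined as 1 (both perfectly match
nothing). Thickness is the count of positive voxels.

## The corrected-versus-uncorrected demonstration

`scatvam print-demo` (or `pipeline.run_print_demo`) runs the full loop on
one phantom and medium: characterize the medium synthetically, correct the
target, compute patterns from both the binary and the corrected dose,
normalize the corrected set to the same total pattern energy (matched total
dose), simulate all prints through the medium plus a transparent baseline,
and score each by best-threshold IoU.

Default demo conditions: the gear phantom at 62.5 μm pitch (256² × 32
voxels) in a 16 mm vial; medium l_s = 6.1 mm (l_s/L = 0.38), σ0 = 0.1 mm,
α = 0.3, l_a = 5.0 mm; 100 characterization patterns, ε = 1e-3, C_max =
10; 360 angles, 30 optimizer iterations. The loss length l_a ≈ l_s encodes
that most scattered light leaves the printing plane: TiO2-like scatterers
deflect at wide angles, so only a small forward-peaked halo (σ(8 mm) =
2.6 mm) survives in-plane. Under these conditions the simulation
reproduces the qualitative failure signature of uncorrected printing in a
strongly turbid resin — the outer annulus between part and vial wall
over-doses (every ray crosses it at near-full strength) while the center
under-doses, so no single gelation threshold prints both the rim and the
inner cogs — and the correction restores the ordering: typical scores are
IoU ≈ 0.51 uncorrected, ≈ 0.64 corrected, ≈ 0.92 transparent.

What this does and does not show: the demonstration establishes the
direction and mechanism of the correction under the parametric medium. It
is not a quantitative prediction for any physical resin — the synthetic
medium is a three-parameter stand-in for a measured frequency response,
the simulation is noiseless (a real process window adds dose-response
width, oxygen inhibition and mechanical deformation), and best-threshold
extraction is an idealized exposure control. Two further idealizations
bound the corrected print's ceiling: the d(r) = R − r depth convention is
the closest-approach depth, whereas rotational accumulation averages
attenuation over depths in [R − r, R + r], so the DC correction
systematically over-boosts the center; and positivity clips the negative
lobes of the inverse-filtered dose, so the requested high-frequency
pre-emphasis is only partially realizable.

## Reproducibility

Every stochastic element (characterization patterns, synthetic noise,
power iteration) derives from an explicit seed; the CLI writes a
provenance record with a configuration digest that excludes the output
location, and timings go to stderr logging only — rerunning any pipeline
with the same configuration and seed produces bit-identical JSON reports
and mask artifacts.
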