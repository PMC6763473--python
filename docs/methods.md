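# Methods

## Model

A brightfield OPT measurement of a 2D attenuation image `f` at angle `α`
and detector offset `s` is modeled as a nested convolution: the image is
first blurred transversally with the depth-dependent beam kernel and then
integrated along the detection line,

    y(α, s) = ∫ ∫ K(τ, z_L) f( x(z_L; s+τ, α), y(z_L; s+τ, α) ) dτ dz_L + n,

with the line parametrized by `x = z_L sin α + s cos α`,
`y = −z_L cos α + s sin α`. The kernel is the normalized transverse
intensity of a Gaussian detection beam,

    K(τ, z) = sqrt(2/(π w(z))) · exp(−2 τ² / w(z)),
    w(z)    = w₀ (1 + ((z − z₀)/(c_S z_r))²),

where `z₀` is the focal offset, `z_r = λ/(π NA²)` the Rayleigh range,
`w₀ = NA z_r` the waist, and `c_S ≥ 1` the stretching constant (`c_S = 1`
is the plain GBM; `c_S → ∞` with a Dirac flag reduces to the straight-line
Radon beam). Blur and projection do not commute: the blur depends on the
depth along the beam, which the projection integral destroys. Assumptions:
parallel detection beams, monochromatic light, 2D (slice-by-slice)
geometry, additive Gaussian measurement noise.

### Unit convention

The width profile above is implemented literally as printed in its source,
with `w` (a length) rather than `w²` in the exponent denominator. That
form is dimensionally inconsistent, so its numerical value depends on the
unit of length; this package fixes **micrometers** everywhere. This choice
reproduces the published worked values exactly (`z_r = 9.7 μm` for NA 0.14
at 600 nm; `c_S ≈ 23.2 / 9.5 / 7.7`) and yields physically plausible blur
widths (`e⁻²` half-support `√w`, e.g. ≈ 27 μm at 225 μm defocus, close to
the textbook beam radius of 32 μm there). The textbook form
`w(z) = w₀ sqrt(1+ζ²)` with `exp(−2τ²/w²)` is available via
`width_convention="squared"` on `BeamParameters`.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `numerical_aperture` | 0.14 | detection objective NA |
| `wavelength` | 0.6 μm | single design wavelength of the white LED |
| `medium_index` | 1.0 | immersion index; 1.0 reproduces the printed z_r |
| `focal_offset_z0` | 0 μm | waist position along the beam (the studied error) |
| `stretch_cS` | 1 | Rayleigh-range stretch of the SGBM |
| `beta1, beta2` | 1e-10 | edge-jump and norm regularization weights |
| `n_iterations` | 3 | outer reweighted steps |
| noise | 0.01 | σ relative to the max noiseless data entry |

## Kernel rasterization

Kernels are rasterized at the image pixel pitch on a centered
(depth × transverse) grid whose axial extent covers the image diagonal
plus the focal offset. Values are point samples at pixel centers, with one
correction: near the waist the beam is narrower than a pixel, so raw
center sampling overweights the focal plane (its pitch-weighted integral
reaches 1.34 at the study pitch). Because the kernel is by definition a
normalized intensity profile, each depth row is renormalized to a unit
pitch-weighted integral. The `e⁻²` hard threshold (entries below `e⁻²` of
the same depth's on-axis value are zeroed, support `|τ| ≤ √w(z)`) is
evaluated on the raw profile so renormalization cannot move the envelope;
thresholded kernels are not renormalized afterwards (the discarded tail is
the intended compression). The Dirac stamp is a single transverse bin of
value 1/pitch, matching the Gaussian rows' normalization. Multifocal
kernels average component stamps on a shared grid; components are
thresholded individually (the envelope is defined per beam) before
averaging.

## Operator discretization

System rows place the kernel stamp along each detection line: a sample at
depth `z_i` and transverse offset `τ_j` contributes
`K_ij · Δτ · Δz` at the physical point of `(α, s+τ_j, z_i)`, splatted onto
the image grid with bilinear weights; mass falling outside the grid is
truncated (a documented boundary effect). Two equivalent back ends exist:

* `assemble_system_matrix` builds the explicit sparse matrix (rows below
  1e-14 pruned) — convenient at small grid sizes and used for the direct
  small-scale tests;
* `BeamProjector` is matrix-free: a cached sparse bilinear warp into
  beam-aligned coordinates, per-depth FFT convolutions with precomputed
  kernel transforms, and an axial sum. Its adjoint is exact (the warp is
  applied by transpose; the convolution adjoint is the full correlation),
  and it is the only representation that fits in memory at the study
  scale, where the explicit Gaussian system would exceed several GB.

Both are built from the same quadrature and agree to rounding error; the
test suite asserts ≤ 1e-6 relative agreement and a 1e-10 adjoint identity.
A `dtype=float32` option halves memory traffic for large runs (≈ 1e-6
relative operator accuracy — ample for reconstructions solved to 1e-3).
With the Dirac stamp the operator reproduces scikit-image's `radon` to
machine precision on circle-supported images.

## Inversion

**FBP**: scikit-image `iradon` (linear interpolation) with a Hamming-
windowed ramp filter; sinogram values are divided by the pixel pitch so
the output is on the attenuation scale (a noiseless self-test recovers a
unit disk's amplitude within 5 %). **TV iteration**: the regularization
matrix is `D = β₁ (I − A/4) + β₂ I` with `A` the 4-neighbor adjacency —
the edge term's diagonal is the pixel perimeter normalized to one and each
neighbor carries the shared-edge fraction 1/4, so interior rows of the
edge term sum to zero. The reweighted update starts from `Γ₀ = I` (a
Tikhonov-like first solve), then reweights with
`γ_i = 1/max(|Df|_i, ε)`, `ε = 1e-8 · max_i |Df|_i` (guard on flat
regions); three outer steps by default. Inner systems
`(LᵀL + DΓD) f = Lᵀy` are solved by conjugate gradients, warm-started
from the previous iterate.

Inner-solver effort is the one genuinely free numerical parameter. The
default is a relative tolerance of 1e-6 with a 2000-iteration cap (float64
CG on these nearly unregularized normal systems stagnates around 5e-7, so
a tighter tolerance is unreachable). At the study scale the systems are
*underdetermined* (200·256 measurements vs 256² unknowns, as the
full-scale protocol also is), so a fully converged CG would fit noise;
the study therefore runs deliberately inexact inner solves (tolerance
1e-3, cap 10 per outer step, warm-started), mirroring the lightly
converged three-step descent of the original algorithm. Sensitivity: REM
*ratios* between offset and in-focus runs move by roughly ±20 % as the cap
varies over 5–20, and the cap-10/20 region is a plateau for the 225 μm
ratio; absolute REM values are considerably more sensitive. Raising the
cap sharpens reconstructions but deepens negative undershoot, which the
min-max normalization in REM amplifies.

## Synthetic data

The phantom is a sparse population of 40 binary disks (attenuation 1 on
background 0), non-overlapping, uniformly placed inside the inscribed
circle, seeded. **Disk size**: the source description is internally
inconsistent — "10 μm diameter" vs "approximately 19 pixels" on the
1 mm / 512 px grid (10 μm is 5 px there). We follow the printed pixel
count (19 px = 37.1 μm): the published error table is only consistent
with ~19 px disks (with 5 px disks the published dynamic ranges alone
would force a zero-offset FBP REM near 400 %, not the printed 180 %), so
the pixel count is taken as what the deposited phantom actually contained,
and "10 μm" as the physical bead size it nominally emulates. With this
choice our zero-offset absolute REM values land close to the published
ones (e.g. 187 % vs 180 % for FBP at matched protocol, half scale).

Projection data use the *unthresholded* zero-stretch kernel at the chosen
forward offsets — inversions always use thresholded kernels, so no
inverse crime is committed (a provenance check warns if it would be).
Noise is elementwise Gaussian with σ = 0.01 of the maximal noiseless
entry. Acquisition: full turn, equal angular steps ending at 360°
(400 × 0.9° at full scale; 200 × 1.8° at the default study scale).

What the generator does **not** emulate: polychromatic spectra (the
Rayleigh range varies ±25 % over a white LED's band), refraction and
scattering in the sample, camera noise beyond additive Gaussian, 3D beam
geometry, and any particular bead layout of the original deposited
phantom. Passing tests therefore validate the operator algebra and the
qualitative reconstruction behavior, not instrument-level accuracy.

## Study scale and known limitations

The default experiment grid runs at 256² with 200 angles (the full
512²/400 protocol exceeds a single-machine memory budget for the Gaussian
system). Two published patterns do not survive the 2× downscaling, and
are reported honestly rather than forced:

* the FBP degradation ratios between offset and in-focus data
  (published 1.3× at 75 μm and 4.9× at 225 μm) compress to ≈ 1.0× and
  ≈ 1.4×: at a 3.9 μm pitch the additional blur of a 75 μm offset
  (half-support 9 μm ≈ 2.3 px) sits at the resolution floor, and the
  sharp in-focus peak whose collapse drives the published 4.9× does not
  exist at half resolution (dynamic max ≈ 0.67 vs the published 0.25 at
  225 μm);
* for the same reason the GBM ratios land below the published values
  (≈ 1.1–1.2 vs 1.6 at 75 μm; ≈ 1.7–2.2 vs 2.6 at 225 μm).

The orderings that do reproduce at half scale: REM grows with offset for
the GBM inversion; at 225 μm offset REM decreases monotonically along
K₁ > K₅ > K₁₀ > K₂₀ > K_δ; multifocal reconstructions sit in the lower
half of the REM scale. Because single phantom realizations scatter the
ratios by ±20 %, the acceptance script reports the median over three
replicates.

## Metrics

REM min-max-normalizes the reconstruction (minimum to 0, maximum to 1) —
the literal printed normalization formula (`f/(max−min) − min`) conflicts
with its own verbal description and is kept only behind a flag. TVE uses
the isotropic gradient magnitude with forward differences and replicate
boundaries. Both are pure functions; REM is invariant under positive
affine maps of the reconstruction and scale-sensitive in the phantom.

## Preprocessing

Raw intensity stacks are affinely scaled to [1e-10, 1] (per stack by
default, per image optionally) and mapped through −log₁₀ to attenuation
in [0, 10]. Center-of-rotation correction shifts the detector axis with
linear interpolation and edge padding. The automated stand-in for the
manual "least circular artifacts" judgement maximizes reconstruction
sharpness (total variation of the FBP image) over candidate offsets;
minimizing outside-support variance — the obvious alternative — selects
wrong offsets, because a correctly centered reconstruction is *sharper*
and has more, not less, edge energy. Detector downscaling is an exact
non-overlapping block mean (2048 → 512 with factor 4), multiplying the
pitch accordingly.

## Determinism

Every stochastic step (phantom placement, noise) is driven by explicit
integer seeds; experiment presets derive per-acquisition noise seeds from
the study seed with fixed salts, so any subset of presets sees identical
data and repeated runs are bit-identical.
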