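# optgauss

Forward modeling and reconstruction for **brightfield optical projection
tomography (OPT)** with a depth-dependent Gaussian detection beam.

OPT images mesoscopic, semi-transparent samples (embryos, organoids,
hydrogel bead phantoms) by recording attenuation shadowgrams from many
angles, like an optical X-ray CT. Unlike X-rays, the detection optics
focus at one plane: features away from the focal plane are blurred with a
transverse Gaussian profile whose width grows with defocus. The classical
inverse Radon transform ignores this, which blurs reconstructions
tangentially and makes them sensitive to the *focal offset* — the unknown
distance between the focal plane and the sample's rotation axis.

`optgauss` implements

* the **Gaussian beam model (GBM)**: the normalized transverse kernel
  `K(τ, z) = sqrt(2/(π w(z))) · exp(−2τ²/w(z))` with the width profile
  `w(z) = w₀ (1 + ((z − z₀)/z_r)²)`, Rayleigh range `z_r = λ/(π NA²)` and
  waist `w₀ = NA·z_r` (all lengths in micrometers);
* the **stretched GBM (SGBM)**: `z_r → c_S z_r` with `w₀` unchanged, a
  deliberately narrower surrogate beam that robustifies the inversion
  against focal-offset error, with the closed form
  `c_S = sqrt( ((z−z₀)/z_r)² / (w(z)/w₀ − 1) )` for choosing the stretch;
* the combined forward operator `y = R ∘ B_K f + n` (depth-dependent blur
  followed by the parallel-beam Radon transform — the two do **not**
  commute), available as an explicit sparse matrix or a matrix-free
  operator with an exact adjoint;
* `e⁻²` hard thresholding of kernels (support `|τ| ≤ √w(z)`), the Dirac
  limit (plain Radon), and multifocal kernel averaging `K* = (1/N) Σ K⁽ⁱ⁾`;
* two inversions: filtered backprojection (Hamming-windowed ramp) and the
  TV-regularized reweighted iteration
  `f_{ℓ+1} = (LᵀL + D Γ_ℓ D)⁻¹ Lᵀ y`, `Γ_ℓ = diag(1/|D f_ℓ|)`, which
  descends `F(x) = ‖Lx − y‖₂² + 2‖Dx‖₁`;
* a seeded sparse-bead phantom generator, the simulated focal-offset /
  multifocal experiment grid (presets A–N), the experimental-data
  preprocessing chain (−log₁₀ linearization, center-of-rotation shift,
  detector downscaling), and the REM / TVE quality metrics.

## Worked example

```python
import optgauss as og

print(og.rayleigh_range(0.14, 0.6))        # NA 0.14, 600 nm -> 9.744... um
print(og.stretching_factor(225, 9.7, 2))   # stretch for w(225 um) = 2 w0

from optgauss.experiments import Study
study = Study(grid_size=128, n_angles=100, seed=7)
for pid in ("A", "B", "G"):
    report, _ = study.run_preset(pid)
    print(f"({pid}) REM {report.rem_percent:.1f}%  TVE {report.tve_percent:.1f}  "
          f"range [{report.dynamic_min:.3f}, {report.dynamic_max:.3f}]")
```

prints

```
9.744180189299714
23.195876288659797
(A) REM 179.8%  TVE 187.0  range [-0.038, 0.969]
(B) REM 338.1%  TVE 116.5  range [-0.190, 1.253]
(G) REM 315.2%  TVE 155.7  range [-0.086, 0.740]
```

`9.744 μm` is the Rayleigh range of the 0.14-NA detection objective;
`23.2` is the stretch that lets the beam width only double across a
225 μm focal uncertainty. The three lines are quality reports for a
128-pixel dry run of three experiment presets: (A) FBP of in-focus data,
(B) the TV/GBM inversion of the same data, and (G) the TV/SGBM (c_S = 5)
inversion of data simulated with a 225 μm focal offset. REM is the
1-norm error of the min-max-normalized reconstruction against the binary
phantom in percent (large values are normal — it integrates background
artifacts over the whole field); TVE is the relative total-variation
error, and `range` is the reconstruction's dynamic range.

The same experiments are available from the shell:

```sh
optgauss run --preset A --preset B --scale 256 --seed 7 --out runs/
```

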