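"""Synthetic bead phantoms and simulated mono-/multifocal projection data.

The study phantom emulates a hydrogel bead sample: a sparse population of
binary disks (attenuation 1) on an empty background (attenuation 0) inside
the inscribed circle of a square field of view.  Projection data are
simulated with the *unthresholded* Gaussian beam so that inversions, which
use thresholded kernels, never see their own discrete forward model (an
inverse-crime guard), and perturbed with additive Gaussian noise scaled to
the maximal noiseless entry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .beams import BeamParameters, KernelStamp, make_kernel_stamp
from .projection import BeamProjector, ScanGeometry, Sinogram, forward_project

__all__ = [
    "PhantomSpec",
    "generate_phantom",
    "forward_stamp",
    "simulate_sinogram",
    "flatten_multifocal",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Sparse disk phantom: sizes in micrometers, values binary."""

    grid_size: int = 512
    side_length: float = 1000.0
    # 19 px at the 512-pixel grid; see the methods note on disk size
    particle_diameter: float = 19 * 1000.0 / 512
    particle_count: int = 40
    background_value: float = 0.0
    particle_value: float = 1.0
    seed: int = 0
    max_retries: int = 10_000


def generate_phantom(spec: PhantomSpec) -> np.ndarray:
    """Draw non-overlapping disks at uniformly random centers.

    Disks lie fully inside the inscribed circle of the square; centers are
    rejection-sampled until non-overlapping.  Reproducible under ``seed``.
    """
    if spec.particle_count < 0:
        raise ValueError("particle_count must be non-negative")
    if spec.particle_diameter >= spec.side_length:
        raise ValueError("particles must be smaller than the field of view")
    rng = np.random.default_rng(spec.seed)
    r = spec.particle_diameter / 2.0
    R = spec.side_length / 2.0 - r  # center must keep the disk inside
    centers: list[tuple[float, float]] = []
    tries = 0
    while len(centers) < spec.particle_count:
        if tries >= spec.max_retries:
            raise RuntimeError(
                f"could not place {spec.particle_count} non-overlapping "
                f"particles after {spec.max_retries} attempts")
        tries += 1
        x, y = rng.uniform(-R, R, size=2)
        if x * x + y * y > R * R:
            continue
        if any((x - cx) ** 2 + (y - cy) ** 2 < (2 * r) ** 2 for cx, cy in centers):
            continue
        centers.append((x, y))

    N = spec.grid_size
    pitch = spec.side_length / N
    c = N // 2
    cols = (np.arange(N) - c) * pitch
    rows = (c - np.arange(N)) * pitch
    image = np.full((N, N), spec.background_value, dtype=float)
    for cx, cy in centers:
        mask = (cols[None, :] - cx) ** 2 + (rows[:, None] - cy) ** 2 <= r * r
        image[mask] = spec.particle_value
    return image


def forward_stamp(params: BeamParameters, geometry: ScanGeometry) -> KernelStamp:
    """Unthresholded kernel stamp sized for simulation with this geometry.

    Axial extent defaults to the image diagonal plus the focal offset so the
    beam covers the full field of view at every angle.
    """
    extent = geometry.diagonal + abs(params.focal_offset_z0) + geometry.pixel_pitch
    return make_kernel_stamp(params, geometry.pixel_pitch, extent,
                             apply_threshold=False)


def simulate_sinogram(
    phantom: np.ndarray,
    params: BeamParameters | Sequence[BeamParameters],
    geometry: ScanGeometry,
    noise_sigma_rel: float = 0.01,
    seed: int = 0,
) -> list[Sinogram]:
    """Simulate ``y = L f + n`` for each beam parameter set.

    ``n`` is elementwise independent Gaussian with standard deviation
    ``noise_sigma_rel`` times the maximal noiseless data entry of that
    acquisition; the forward kernels are never thresholded.
    """
    if isinstance(params, BeamParameters):
        params = [params]
    if noise_sigma_rel < 0:
        raise ValueError("noise_sigma_rel must be non-negative")
    if noise_sigma_rel > 0 and not np.any(phantom):
        raise ValueError("relative noise scale undefined for an all-zero phantom")
    rng = np.random.default_rng(seed)
    out = []
    for i, p in enumerate(params):
        stamp = forward_stamp(p, geometry)
        sino = _chunked_forward(phantom, stamp, geometry)
        if noise_sigma_rel > 0:
            sigma = noise_sigma_rel * float(np.max(sino.values))
            sino.values = sino.values + rng.normal(0.0, sigma, size=sino.values.shape)
        sino.meta.update({
            "focal_offset": p.focal_offset_z0,
            "noise_sigma_rel": noise_sigma_rel,
            "seed": seed,
            "forward_thresholded": False,
        })
        out.append(sino)
    return out


def _chunked_forward(image: np.ndarray, stamp: KernelStamp,
                     geometry: ScanGeometry, chunk: int = 25) -> Sinogram:
    """One-shot forward projection in angle blocks.

    The unthresholded simulation kernels are wide; building the cached
    operator for all angles at once would need several GB, so the warp is
    built and discarded per block of angles.
    """
    ns = geometry.detector_bins
    values = np.empty((ns, geometry.n_angles))
    for start in range(0, geometry.n_angles, chunk):
        sub = ScanGeometry(geometry.grid_size, geometry.field_of_view,
                           geometry.angles[start:start + chunk], ns)
        proj = BeamProjector(sub, stamp)
        y = proj.matvec(image.ravel()).reshape(sub.n_angles, ns)
        values[:, start:start + chunk] = y.T
    return Sinogram(values, geometry.angles.copy(), geometry.pixel_pitch,
                    meta={"kernel": stamp.kind,
                          "focal_offsets": list(stamp.focal_offsets)})


def flatten_multifocal(sinograms: Sequence[Sinogram]) -> Sinogram:
    """Average the acquisitions of each angle into one projection."""
    if len(sinograms) == 0:
        raise ValueError("need at least one sinogram")
    first = sinograms[0]
    for s in sinograms[1:]:
        if (s.values.shape != first.values.shape
                or not np.allclose(s.angles, first.angles)
                or s.pixel_pitch != first.pixel_pitch):
            raise ValueError("sinograms must share a geometry")
    values = np.mean([s.values for s in sinograms], axis=0)
    offsets = [s.meta.get("focal_offset") for s in sinograms]
    return Sinogram(values, first.angles.copy(), first.pixel_pitch,
                    meta={"multifocal": True, "focal_offsets": offsets})


def check_inverse_crime(forward_stamp: KernelStamp, inversion_stamp: KernelStamp) -> None:
    """Warn when data and inversion share one thresholded discrete kernel."""
    if (forward_stamp.threshold_applied and inversion_stamp.threshold_applied
            and forward_stamp.values.shape == inversion_stamp.values.shape
            and np.array_equal(forward_stamp.values, inversion_stamp.values)):
        warnings.warn("forward and inversion kernels are the same thresholded "
                      "stamp: this commits an inverse crime", stacklevel=2)
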