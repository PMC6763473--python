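"""Gaussian-beam algebra for brightfield OPT forward modeling.

The detection optics of a brightfield optical projection tomograph focus at a
fixed plane; light collected away from that plane is blurred with a transverse
Gaussian intensity profile whose width grows with the distance to the focus.
This module holds all of the beam physics: the Rayleigh range, the width
profile ``w(z)``, the normalized transverse kernel ``K(tau, z)``, the
"stretched" variant in which the Rayleigh range is multiplied by a constant
``c_S >= 1`` (SGBM), the hard ``e^-2`` thresholding used to sparsify kernels,
the Dirac limit (plain Radon beam), multifocal kernel averaging, and the
rasterization of all of these onto the image pixel pitch.

Unit convention
---------------
All lengths in this package are expressed in **micrometers**.  The width
profile is evaluated literally as printed in the source model,

    w(z) = w0 * (1 + ((z - z0) / (c_S * z_r))**2),
    K(tau, z) = sqrt(2 / (pi * w(z))) * exp(-2 * tau**2 / w(z)),

which places a length (not a squared length) in the exponent denominator and
therefore fixes a unit convention; micrometers reproduce the published worked
values.  The textbook form ``I ~ exp(-2 tau^2 / w(z)^2)`` with
``w(z) = w0 sqrt(1 + ((z-z0)/zr)^2)`` is available through
``width_convention="squared"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "BeamParameters",
    "KernelStamp",
    "rayleigh_range",
    "beam_width",
    "kernel_value",
    "stretching_factor",
    "make_kernel_stamp",
    "multifocal_kernel",
]

#: hard threshold relative to the on-axis value, applied along propagation
E2_THRESHOLD = math.exp(-2.0)

#: relative tail cutoff used when rasterizing unthresholded kernels
_TAIL_CUTOFF = 1e-14


def rayleigh_range(na: float, wavelength: float, medium_index: float = 1.0) -> float:
    """Rayleigh range ``z_r = (lambda / n) / (pi * NA^2)`` in micrometers.

    Consistent with ``z_r = pi w0^2 / lambda`` together with ``NA = w0 / z_r``.

    Parameters
    ----------
    na : numerical aperture of the detection objective (dimensionless).
    wavelength : wavelength in micrometers (in vacuum/air).
    medium_index : refractive index of the immersion medium (>= 1).
    """
    if na <= 0 or wavelength <= 0:
        raise ValueError("numerical aperture and wavelength must be positive")
    if medium_index < 1:
        raise ValueError("medium_index must be >= 1")
    return (wavelength / medium_index) / (math.pi * na**2)


@dataclass(frozen=True)
class BeamParameters:
    """Physics of one detection beam.

    Lengths are micrometers.  ``rayleigh_range_zr`` and ``waist_w0`` are
    derived from ``numerical_aperture`` and ``wavelength`` when not given,
    via ``z_r = (lambda/n)/(pi NA^2)`` and ``w0 = NA * z_r``.
    """

    numerical_aperture: float = 0.14
    wavelength: float = 0.6
    medium_index: float = 1.0
    waist_w0: float | None = None
    rayleigh_range_zr: float | None = None
    focal_offset_z0: float = 0.0
    stretch_cS: float = 1.0
    dirac: bool = False
    width_convention: str = "literal"

    def __post_init__(self) -> None:
        zr = self.rayleigh_range_zr
        if zr is None:
            zr = rayleigh_range(self.numerical_aperture, self.wavelength, self.medium_index)
            object.__setattr__(self, "rayleigh_range_zr", zr)
        if self.waist_w0 is None:
            object.__setattr__(self, "waist_w0", self.numerical_aperture * zr)
        if self.stretch_cS < 1:
            raise ValueError("stretch_cS must be >= 1")
        if self.waist_w0 <= 0 or zr <= 0:
            raise ValueError("waist and Rayleigh range must be positive")
        if self.width_convention not in ("literal", "squared"):
            raise ValueError("width_convention must be 'literal' or 'squared'")

    def with_offset(self, z0: float) -> "BeamParameters":
        return replace(self, focal_offset_z0=z0)

    def with_stretch(self, c_s: float) -> "BeamParameters":
        return replace(self, stretch_cS=c_s)


def beam_width(z, params: BeamParameters):
    """Beam width profile ``w(z)`` (micrometers), stretched by ``c_S``.

    Stretching substitutes ``z_r -> c_S z_r`` while keeping ``w0``; in the
    limit ``c_S -> inf`` the width is constant at the waist.
    """
    z = np.asarray(z, dtype=float)
    w0 = params.waist_w0
    if math.isinf(params.stretch_cS):
        zeta2 = np.zeros_like(z)
    else:
        zeta2 = ((z - params.focal_offset_z0) / (params.stretch_cS * params.rayleigh_range_zr)) ** 2
    if params.width_convention == "squared":
        w = w0 * np.sqrt(1.0 + zeta2)
    else:
        w = w0 * (1.0 + zeta2)
    return w if w.ndim else float(w)


def kernel_value(tau, z, params: BeamParameters):
    """Normalized transverse intensity ``K(tau, z)`` of the detection beam.

    For every fixed depth ``z`` the profile integrates to 1 over ``tau``
    (units 1/micrometer).
    """
    tau = np.asarray(tau, dtype=float)
    w = np.asarray(beam_width(z, params), dtype=float)
    if params.width_convention == "squared":
        k = np.sqrt(2.0 / math.pi) / w * np.exp(-2.0 * tau**2 / w**2)
    else:
        k = np.sqrt(2.0 / (math.pi * w)) * np.exp(-2.0 * tau**2 / w)
    return k if k.ndim else float(k)


def stretching_factor(z_minus_z0: float, zr: float, width_ratio: float) -> float:
    """Stretching constant ``c_S`` that fixes the width ratio at a given depth.

    Solves ``w(z)/w0 = width_ratio`` for ``c_S`` in the stretched width
    profile:  ``c_S = sqrt( ((z-z0)/z_r)^2 / (width_ratio - 1) )``.

    ``width_ratio`` close to 1 forces a large stretch (the beam approaches
    the straight Radon line); ``width_ratio <= 1`` has no finite solution.
    """
    if zr <= 0:
        raise ValueError("Rayleigh range must be positive")
    if width_ratio <= 1:
        raise ValueError("width_ratio must exceed 1 for a finite stretch")
    return math.sqrt((z_minus_z0 / zr) ** 2 / (width_ratio - 1.0))


@dataclass
class KernelStamp:
    """A blurring kernel rasterized on the image pixel pitch.

    ``values`` has shape ``(n_axial, n_transverse)``: row ``i`` is the
    transverse profile at depth ``z_centers[i]`` along the propagation axis,
    column ``j`` the transverse offset ``tau_centers[j]``.  Unthresholded
    Gaussian rows integrate (pitch-weighted) to 1.
    """

    values: np.ndarray
    pixel_pitch: float
    axial_extent: float
    kind: str = "gaussian"
    threshold_applied: bool = False
    focal_offsets: tuple = (0.0,)
    params: BeamParameters | None = field(default=None, repr=False)

    @property
    def n_axial(self) -> int:
        return self.values.shape[0]

    @property
    def n_transverse(self) -> int:
        return self.values.shape[1]

    @property
    def z_centers(self) -> np.ndarray:
        n = self.n_axial
        return (np.arange(n) - (n - 1) / 2.0) * self.pixel_pitch

    @property
    def tau_centers(self) -> np.ndarray:
        n = self.n_transverse
        return (np.arange(n) - (n - 1) / 2.0) * self.pixel_pitch

    @property
    def nnz(self) -> int:
        return int(np.count_nonzero(self.values))

    def column_integrals(self) -> np.ndarray:
        """Pitch-weighted transverse integral at every depth."""
        return self.values.sum(axis=1) * self.pixel_pitch


def _axial_grid(axial_extent: float, pitch: float) -> int:
    if axial_extent < pitch:
        raise ValueError("axial_extent must cover at least one pixel")
    n = int(math.ceil(axial_extent / pitch))
    return n | 1  # odd, symmetric about z = 0


def _transverse_halfwidth(params: BeamParameters, z: np.ndarray, thresholded: bool) -> float:
    """Largest |tau| that can carry a nonzero rasterized value."""
    w_max = float(np.max(beam_width(z, params)))
    if params.width_convention == "squared":
        # exp(-2 tau^2 / w^2) = cutoff  ->  tau = w sqrt(-ln(cutoff)/2)
        cut = E2_THRESHOLD if thresholded else _TAIL_CUTOFF
        return w_max * math.sqrt(-math.log(cut) / 2.0)
    cut = E2_THRESHOLD if thresholded else _TAIL_CUTOFF
    return math.sqrt(-math.log(cut) * w_max / 2.0)


def make_kernel_stamp(
    params: BeamParameters,
    pixel_pitch: float,
    axial_extent: float,
    apply_threshold: bool = False,
    n_transverse: int | None = None,
    n_axial: int | None = None,
) -> KernelStamp:
    """Rasterize the beam kernel of ``params`` onto a centered pixel grid.

    Values are point samples of ``kernel_value`` at pixel centers.  With
    ``apply_threshold``, entries below ``e^-2`` times the on-axis value at the
    same depth are zeroed (hard envelope).  A Dirac beam (``params.dirac``)
    yields a single transverse bin of value ``1/pitch``, i.e. the plain Radon
    line with the same pitch-weighted normalization as the Gaussian rows.

    ``n_transverse``/``n_axial`` (odd) force the grid, e.g. so that stamps of
    different focal offsets share a grid for multifocal averaging.
    """
    if pixel_pitch <= 0:
        raise ValueError("pixel_pitch must be positive")
    nz = n_axial if n_axial is not None else _axial_grid(axial_extent, pixel_pitch)
    if nz % 2 == 0:
        raise ValueError("n_axial must be odd")
    z = (np.arange(nz) - (nz - 1) / 2.0) * pixel_pitch

    if params.dirac:
        if n_transverse is None:
            n_transverse = 1
        values = np.zeros((nz, n_transverse))
        values[:, (n_transverse - 1) // 2] = 1.0 / pixel_pitch
        return KernelStamp(values, pixel_pitch, axial_extent, kind="dirac",
                           threshold_applied=apply_threshold,
                           focal_offsets=(params.focal_offset_z0,), params=params)

    if n_transverse is None:
        half = _transverse_halfwidth(params, z, apply_threshold)
        n_transverse = 2 * int(math.ceil(half / pixel_pitch)) + 1
    if n_transverse % 2 == 0:
        raise ValueError("n_transverse must be odd")
    tau = (np.arange(n_transverse) - (n_transverse - 1) / 2.0) * pixel_pitch

    raw = kernel_value(tau[None, :], z[:, None], params)
    # The beam profile is a *normalized* intensity distribution; near the
    # waist the profile is narrower than the pixel pitch and center-point
    # sampling overweights it, so each depth row is renormalized to unit
    # pitch-weighted integral.  The e^-2 envelope is evaluated on the raw
    # profile so the renormalization cannot shift the threshold boundary.
    values = raw / (raw.sum(axis=1, keepdims=True) * pixel_pitch)
    if apply_threshold:
        on_axis = kernel_value(0.0, z, params)
        values = np.where(raw < E2_THRESHOLD * on_axis[:, None], 0.0, values)

    kind = "gaussian" if params.stretch_cS == 1 else "stretched"
    return KernelStamp(values, pixel_pitch, axial_extent, kind=kind,
                       threshold_applied=apply_threshold,
                       focal_offsets=(params.focal_offset_z0,), params=params)


def multifocal_kernel(stamps: Sequence[KernelStamp]) -> KernelStamp:
    """Elementwise mean of kernel stamps on identical grids (kernel ``K*``).

    Models a multifocal acquisition in which the projections recorded at
    several focal planes are averaged into one all-in-focus projection: by
    linearity the effective beam is the mean of the individual beams.
    """
    if len(stamps) == 0:
        raise ValueError("need at least one stamp")
    first = stamps[0]
    for s in stamps[1:]:
        if s.values.shape != first.values.shape or s.pixel_pitch != first.pixel_pitch:
            raise ValueError("stamps must share an identical grid")
    values = np.mean([s.values for s in stamps], axis=0)
    offsets = tuple(off for s in stamps for off in s.focal_offsets)
    return KernelStamp(values, first.pixel_pitch, first.axial_extent,
                       kind="multifocal",
                       threshold_applied=any(s.threshold_applied for s in stamps),
                       focal_offsets=offsets, params=first.params)
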