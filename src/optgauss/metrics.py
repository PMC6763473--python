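"""Reconstruction quality measures: relative error (REM) and TV error (TVE).

REM compares the min-max normalized reconstruction with the phantom in the
1-norm (in percent of the phantom's 1-norm); it measures general image
quality without penalizing a change of dynamic range.  TVE compares the
total variation of the residual against the total variation of the
reconstruction and is sensitive to dynamic accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["QualityReport", "rem", "tve", "total_variation", "quality_report"]


def _normalize(recon: np.ndarray, mode: str) -> np.ndarray:
    fmin = float(recon.min())
    fmax = float(recon.max())
    if fmax == fmin:
        raise ValueError("constant reconstruction cannot be normalized")
    if mode == "minmax":
        return (recon - fmin) / (fmax - fmin)
    if mode == "printed":
        # archaic variant: f/(max-min) - min, kept for comparison purposes
        return recon / (fmax - fmin) - fmin
    raise ValueError(f"unknown normalization {mode!r}")


def rem(reconstruction: np.ndarray, phantom: np.ndarray,
        normalization: str = "minmax") -> float:
    """Relative error measure in percent.

    ``100 * ||f_rel - f_phantom||_1 / ||f_phantom||_1`` where ``f_rel`` is
    the reconstruction with its minimum shifted to zero and maximum scaled
    to one.  Invariant under positive affine maps of the reconstruction.
    """
    reconstruction = np.asarray(reconstruction, dtype=float)
    phantom = np.asarray(phantom, dtype=float)
    if reconstruction.shape != phantom.shape:
        raise ValueError("shape mismatch")
    denom = np.abs(phantom).sum()
    if denom == 0:
        raise ValueError("phantom has zero 1-norm")
    f_rel = _normalize(reconstruction, normalization)
    return 100.0 * float(np.abs(f_rel - phantom).sum() / denom)


def total_variation(image: np.ndarray, pixel_area: float = 1.0) -> float:
    """Isotropic TV: sum of forward-difference gradient magnitudes.

    Replicate boundary handling (zero gradient on the last row/column).
    """
    image = np.asarray(image, dtype=float)
    fx = np.zeros_like(image)
    fy = np.zeros_like(image)
    fx[:, :-1] = image[:, 1:] - image[:, :-1]
    fy[:-1, :] = image[1:, :] - image[:-1, :]
    return float(np.sqrt(fx * fx + fy * fy).sum() * pixel_area)


def tve(reconstruction: np.ndarray, phantom: np.ndarray) -> float:
    """Total variation error in percent: ``100 TV(f_rec - f_ph) / TV(f_rec)``."""
    reconstruction = np.asarray(reconstruction, dtype=float)
    phantom = np.asarray(phantom, dtype=float)
    if reconstruction.shape != phantom.shape:
        raise ValueError("shape mismatch")
    denom = total_variation(reconstruction)
    if denom == 0:
        raise ValueError("reconstruction has zero total variation")
    return 100.0 * total_variation(reconstruction - phantom) / denom


@dataclass
class QualityReport:
    """Per-reconstruction metrics row (Table-style record)."""

    experiment_id: str
    rem_percent: float
    tve_percent: float
    dynamic_min: float
    dynamic_max: float

    def as_dict(self) -> dict:
        return {
            "id": self.experiment_id,
            "min": self.dynamic_min,
            "max": self.dynamic_max,
            "rem_percent": self.rem_percent,
            "tve_percent": self.tve_percent,
        }


def quality_report(reconstruction: np.ndarray, phantom: np.ndarray,
                   experiment_id: str = "") -> QualityReport:
    return QualityReport(
        experiment_id=experiment_id,
        rem_percent=rem(reconstruction, phantom),
        tve_percent=tve(reconstruction, phantom),
        dynamic_min=float(np.min(reconstruction)),
        dynamic_max=float(np.max(reconstruction)),
    )
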