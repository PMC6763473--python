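"""Inversion paths: filtered backprojection and TV-regularized iteration.

The baseline is standard parallel-beam FBP (ramp filter windowed by a
Hamming taper, linear-interpolation backprojection).  The model-based path
minimizes

    F(x) = ||L x - y||_2^2 + 2 ||D x||_1

by an iteratively reweighted least-squares scheme: with
``Gamma_l = diag(1 / |D f_l|)``, each step solves the symmetric
positive-definite system

    (L^T L + D Gamma_l D) f_{l+1} = L^T y .

``D`` is a 4-neighbor edge-jump penalty (weight ``beta1``) plus a norm
penalty (``beta2``) that keeps the iteration well defined on flat regions.
The inner systems are solved by conjugate gradients, warm-started from the
previous iterate; with the very small weights used in the experiments the
systems are nearly unregularized and the (capped) CG iteration itself acts
as the descent method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import LinearOperator, cg
from skimage.transform import iradon

from .projection import Sinogram

__all__ = [
    "RegularizationSpec",
    "fbp_reconstruct",
    "build_reg_matrix",
    "tv_reconstruct",
    "objective",
]

_FBP_FILTERS = {"ramp", "shepp-logan", "cosine", "hamming", "hann"}


@dataclass(frozen=True)
class RegularizationSpec:
    """Weights and solver controls for the TV iteration.

    ``epsilon_reweight`` guards the reweighting against division by zero;
    it is relative to ``max_i |D f|_i``.  With ``inexact_ok`` the inner CG
    may stop at its iteration cap without raising (used for large grids,
    where the capped iteration doubles as early-stopping regularization).
    """

    beta1: float = 1e-10
    beta2: float = 1e-10
    n_iterations: int = 3
    epsilon_reweight: float = 1e-8
    solver_tolerance: float = 1e-6
    solver_maxiter: int = 2000
    inexact_ok: bool = False

    def __post_init__(self) -> None:
        if self.beta1 < 0 or self.beta2 < 0:
            raise ValueError("regularization weights must be non-negative")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


def fbp_reconstruct(sinogram: Sinogram, filter_name: str = "hamming",
                    output_size: int | None = None) -> np.ndarray:
    """Filtered backprojection on the reconstruction grid.

    The sinogram carries physical (pitch-weighted) line integrals; they are
    converted to pixel-sum units before the standard inversion so that the
    output is on the attenuation scale of the imaged object.
    """
    if filter_name not in _FBP_FILTERS:
        raise ValueError(f"unknown FBP filter {filter_name!r}")
    n = output_size or sinogram.values.shape[0]
    return iradon(sinogram.values / sinogram.pixel_pitch,
                  theta=sinogram.angles, filter_name=filter_name,
                  interpolation="linear", circle=True, output_size=n)


def build_reg_matrix(grid_size: int, spec: RegularizationSpec) -> sp.csr_matrix:
    """Regularization matrix D on the flattened image grid.

    ``D = beta1 (I - A/4) + beta2 I`` with ``A`` the 4-neighbor adjacency:
    the diagonal carries the pixel's own boundary (perimeter, normalized to
    1), off-diagonals the shared-edge fraction (1/4 of the perimeter) with
    negative sign, so interior rows of the edge term sum to zero.
    """
    if grid_size < 2:
        raise ValueError("grid_size must be >= 2")
    n = grid_size
    ones = np.ones(n - 1)
    T = sp.diags([ones, ones], offsets=[-1, 1], shape=(n, n))
    eye = sp.identity(n)
    adj = sp.kron(eye, T) + sp.kron(T, eye)
    D = spec.beta1 * (sp.identity(n * n) - adj / 4.0) + spec.beta2 * sp.identity(n * n)
    return D.tocsr()


def _sinogram_vector(y) -> np.ndarray:
    if isinstance(y, Sinogram):
        return y.values.T.ravel()
    return np.asarray(y, dtype=float).ravel()


def tv_reconstruct(system, D: sp.spmatrix, y, spec: RegularizationSpec,
                   return_info: bool = False):
    """Reweighted TV iteration; returns the final image.

    ``system`` is any operator with ``matvec``/``rmatvec`` and ``shape``
    (explicit :class:`~optgauss.projection.SystemMatrix` or matrix-free
    :class:`~optgauss.projection.BeamProjector`).  The first step uses
    ``Gamma_0 = I`` (a Tikhonov-like solve); subsequent steps reweight with
    the current edge jumps.
    """
    yv = _sinogram_vector(y)
    m, n = system.shape
    if len(yv) != m:
        raise ValueError("sinogram size does not match the system")
    if D.shape != (n, n):
        raise ValueError("regularization matrix size does not match the image")
    grid = int(round(np.sqrt(n)))

    b = system.rmatvec(yv)
    gamma = np.ones(n)
    f = np.zeros(n)
    info: dict = {"cg_iterations": [], "residuals": []}

    for _ in range(spec.n_iterations):
        def apply_normal(v, g=gamma):
            return system.rmatvec(system.matvec(v)) + D @ (g * (D @ v))

        A = LinearOperator((n, n), matvec=apply_normal, rmatvec=apply_normal,
                           dtype=float)
        iters = 0

        def count(_):
            nonlocal iters
            iters += 1

        f, flag = cg(A, b, x0=f, rtol=spec.solver_tolerance, atol=0.0,
                     maxiter=spec.solver_maxiter, callback=count)
        res = float(np.linalg.norm(b - apply_normal(f)) / np.linalg.norm(b))
        info["cg_iterations"].append(iters)
        info["residuals"].append(res)
        if flag > 0 and not spec.inexact_ok:
            raise RuntimeError(
                f"inner CG did not reach tolerance {spec.solver_tolerance:g} "
                f"within {spec.solver_maxiter} iterations "
                f"(relative residual {res:.3e})")
        if flag < 0:
            raise RuntimeError("inner CG failed (illegal input or breakdown)")
        if return_info:
            info.setdefault("objective", []).append(objective(f, system, D, yv))
        df = np.abs(D @ f)
        top = df.max()
        if top > 0:
            gamma = 1.0 / np.maximum(df, spec.epsilon_reweight * top)
        else:
            gamma = np.ones(n)

    image = f.reshape(grid, grid)
    return (image, info) if return_info else image


def objective(x: np.ndarray, system, D: sp.spmatrix, y) -> float:
    """Regularized objective ``||Lx - y||_2^2 + 2 ||Dx||_1``."""
    xv = np.asarray(x, dtype=float).ravel()
    yv = _sinogram_vector(y)
    misfit = system.matvec(xv) - yv
    return float(misfit @ misfit + 2.0 * np.abs(D @ xv).sum())
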