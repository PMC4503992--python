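"""Elastic half-space mechanics for traction force microscopy.

Forward problem: surface displacements of a semi-infinite, linearly elastic
substrate produced by a tangential surface traction field (Boussinesq
solution). Inverse problem: regularized Fourier-space deconvolution (FTTC),
optionally constrained so that tractions vanish outside a traced cell
contour.

Unit conventions used throughout the package:

* lengths and displacements in micrometres (µm),
* tractions in pascal (Pa),
* forces in piconewton (pN); note 1 Pa·µm² = 1 pN,
* Young's modulus in Pa.

Grids are node-centred with ``x`` increasing to the right (columns) and
``y`` increasing upward (rows); arrays are indexed ``[iy, ix]`` and vector
fields carry the component axis last (``..., 0`` = x, ``..., 1`` = y).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import shapely

__all__ = [
    "GelSubstrate",
    "GridSpec",
    "DisplacementField",
    "TractionField",
    "CellMask",
    "InversionInfo",
    "boussinesq_greens_tensor",
    "forward_solve",
    "fttc_inverse",
    "select_lambda",
    "constrained_inverse",
]


@dataclass(frozen=True)
class GelSubstrate:
    """Elastic substrate parameters.

    Parameters
    ----------
    youngs_modulus : float
        Young's modulus in Pa (e.g. 1e3, 11e3, 26e3 for soft/medium/stiff
        polyacrylamide gels).
    poisson_ratio : float
        Poisson ratio in (0, 0.5]; defaults to the incompressible limit.
    """

    youngs_modulus: float
    poisson_ratio: float = 0.5

    def __post_init__(self) -> None:
        if not self.youngs_modulus > 0:
            raise ValueError("youngs_modulus must be positive")
        if not (0 < self.poisson_ratio <= 0.5):
            raise ValueError("poisson_ratio must lie in (0, 0.5]")


@dataclass(frozen=True)
class GridSpec:
    """Regular node grid in the substrate plane.

    ``origin`` is the (x, y) position of node ``[0, 0]`` in µm; ``shape``
    is (ny, nx).
    """

    origin: tuple[float, float]
    spacing: float
    shape: tuple[int, int]

    def __post_init__(self) -> None:
        if not self.spacing > 0:
            raise ValueError("spacing must be positive")
        ny, nx = self.shape
        if ny < 2 or nx < 2:
            raise ValueError("grid must be at least 2x2 nodes")
        object.__setattr__(self, "origin", (float(self.origin[0]), float(self.origin[1])))
        object.__setattr__(self, "shape", (int(ny), int(nx)))

    @property
    def x(self) -> np.ndarray:
        return self.origin[0] + self.spacing * np.arange(self.shape[1])

    @property
    def y(self) -> np.ndarray:
        return self.origin[1] + self.spacing * np.arange(self.shape[0])

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        """Node coordinate arrays (X, Y), each of shape (ny, nx)."""
        return np.meshgrid(self.x, self.y)

    @property
    def cell_area(self) -> float:
        """Area element dA associated with one node, µm²."""
        return self.spacing ** 2


def _as_vector_field(grid: GridSpec, values: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.shape != (*grid.shape, 2):
        raise ValueError(f"{name} must have shape {(*grid.shape, 2)}, got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass
class DisplacementField:
    """Gridded substrate displacement vectors in µm."""

    grid: GridSpec
    u: np.ndarray

    def __post_init__(self) -> None:
        self.u = _as_vector_field(self.grid, self.u, "displacement")


@dataclass
class TractionField:
    """Gridded traction vectors in Pa."""

    grid: GridSpec
    t: np.ndarray

    def __post_init__(self) -> None:
        self.t = _as_vector_field(self.grid, self.t, "traction")

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.t[..., 0], self.t[..., 1])


@dataclass
class CellMask:
    """Cell footprint: a simple polygon and/or its rasterization on a grid."""

    polygon: np.ndarray | None = None
    raster: np.ndarray | None = None
    area: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.polygon is None and self.raster is None:
            raise ValueError("CellMask needs a polygon and/or a raster")
        if self.polygon is not None:
            poly = np.asarray(self.polygon, dtype=float)
            if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
                raise ValueError("polygon must be an (n>=3, 2) vertex array")
            shp = shapely.Polygon(poly)
            if not shp.is_valid:
                raise ValueError("polygon is not simple (self-intersecting?)")
            self.polygon = poly
            if self.area == 0.0:
                self.area = float(shp.area)
        if self.raster is not None:
            self.raster = np.asarray(self.raster, dtype=bool)
        if not self.area > 0:
            raise ValueError("mask area must be positive")

    @classmethod
    def from_polygon(cls, polygon: np.ndarray, grid: GridSpec | None = None) -> "CellMask":
        """Build a mask from a vertex list, rasterizing onto ``grid`` if given."""
        mask = cls(polygon=np.asarray(polygon, dtype=float))
        if grid is not None:
            mask.rasterize(grid)
        return mask

    def rasterize(self, grid: GridSpec) -> np.ndarray:
        """Rasterize the polygon: nodes strictly inside or on the boundary."""
        if self.polygon is None:
            raise ValueError("no polygon to rasterize")
        shp = shapely.Polygon(self.polygon)
        X, Y = grid.meshgrid()
        inside = shapely.contains_xy(shp, X.ravel(), Y.ravel()).reshape(grid.shape)
        boundary = shapely.intersects_xy(shp, X.ravel(), Y.ravel()).reshape(grid.shape)
        self.raster = inside | boundary
        return self.raster

    def raster_on(self, grid: GridSpec) -> np.ndarray:
        """Boolean node mask aligned with ``grid``."""
        if self.raster is not None and self.raster.shape == grid.shape:
            return self.raster
        return self.rasterize(grid)


@dataclass
class InversionInfo:
    """Diagnostics attached to a constrained inversion."""

    misfit: float
    n_iter: int
    converged: bool
    reg_lambda: float


def boussinesq_greens_tensor(r: np.ndarray, gel: GelSubstrate) -> np.ndarray:
    """Surface Green's tensor of the elastic half-space at offset ``r`` (µm).

    G_ij(r) = (1+ν)/(π E |r|) · [(1−ν) δ_ij + ν r_i r_j / |r|²]

    Returns a symmetric 2×2 array in µm per unit point force (µm/pN, since
    1 pN = 1 Pa·µm²). The tensor is even, G(r) = G(−r), and decays as 1/|r|.
    """
    r = np.asarray(r, dtype=float)
    norm = float(np.hypot(r[0], r[1]))
    if norm == 0.0:
        raise ValueError("Green's tensor is singular at r = 0")
    E, nu = gel.youngs_modulus, gel.poisson_ratio
    pref = (1.0 + nu) / (np.pi * E * norm)
    rr = np.outer(r, r) / norm ** 2
    return pref * ((1.0 - nu) * np.eye(2) + nu * rr)


def _kernel_ffts(
    shape: tuple[int, int], spacing: float, gel: GelSubstrate
) -> tuple[np.ndarray, np.ndarray, np.ndarray, tuple[int, int]]:
    """FFTs of the discrete Boussinesq kernel on the 2×-padded grid.

    The kernel entry at wrapped offset r is G(r)·dA; the singular r = 0
    cell is integrated analytically over an equal-area disc.
    """
    return _kernel_ffts_cached(shape, float(spacing), gel.youngs_modulus, gel.poisson_ratio)


@lru_cache(maxsize=32)
def _kernel_ffts_cached(
    shape: tuple[int, int], spacing: float, E: float, nu: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, tuple[int, int]]:
    ny, nx = shape
    pny, pnx = 2 * ny, 2 * nx
    # integer offsets wrapped in FFT order: 0..n/2-1, -n/2..-1
    offx = np.fft.fftfreq(pnx, d=1.0 / pnx) * spacing
    offy = np.fft.fftfreq(pny, d=1.0 / pny) * spacing
    X, Y = np.meshgrid(offx, offy)
    R = np.hypot(X, Y)
    dA = spacing ** 2
    pref = (1.0 + nu) / (np.pi * E)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_r = np.where(R > 0, 1.0 / R, 0.0)
        inv_r3 = inv_r ** 3
        Kxx = pref * ((1.0 - nu) * inv_r + nu * X * X * inv_r3) * dA
        Kyy = pref * ((1.0 - nu) * inv_r + nu * Y * Y * inv_r3) * dA
        Kxy = pref * (nu * X * Y * inv_r3) * dA
    # singular cell: integrate G over an equal-area disc (radius h/sqrt(pi));
    # the angular average of r_i r_j / r² is δ_ij / 2
    a = spacing / np.sqrt(np.pi)
    Kxx[0, 0] = Kyy[0, 0] = a * (1.0 + nu) * (2.0 - nu) / E
    Kxy[0, 0] = 0.0
    # even grids have an unpaired -n/2 offset; Kxy is odd in each coordinate,
    # so zero it there (the ± average) to keep the kernel rotation-symmetric
    Kxy[pny // 2, :] = 0.0
    Kxy[:, pnx // 2] = 0.0
    FKxx = np.fft.rfft2(Kxx).real
    FKxy = np.fft.rfft2(Kxy).real
    FKyy = np.fft.rfft2(Kyy).real
    return FKxx, FKxy, FKyy, (pny, pnx)


def forward_solve(traction: TractionField, gel: GelSubstrate) -> DisplacementField:
    """Displacement field produced by a traction field (forward Boussinesq).

    Discrete convolution of the Green's tensor with t·dA, evaluated in
    Fourier space on a 2×-zero-padded grid (linear, not circular,
    convolution over the node grid). Linear in the traction.
    """
    grid = traction.grid
    FKxx, FKxy, FKyy, pad = _kernel_ffts(grid.shape, grid.spacing, gel)
    ny, nx = grid.shape
    Tx = np.zeros(pad)
    Ty = np.zeros(pad)
    Tx[:ny, :nx] = traction.t[..., 0]
    Ty[:ny, :nx] = traction.t[..., 1]
    FTx = np.fft.rfft2(Tx)
    FTy = np.fft.rfft2(Ty)
    ux = np.fft.irfft2(FKxx * FTx + FKxy * FTy, s=pad)[:ny, :nx]
    uy = np.fft.irfft2(FKxy * FTx + FKyy * FTy, s=pad)[:ny, :nx]
    return DisplacementField(grid, np.stack([ux, uy], axis=-1))


def _operator_norm(FKxx: np.ndarray, FKxy: np.ndarray, FKyy: np.ndarray) -> float:
    mean = 0.5 * (FKxx + FKyy)
    rad = np.sqrt((0.5 * (FKxx - FKyy)) ** 2 + FKxy ** 2)
    return float(np.max(np.abs(mean) + rad))


def _taper_pad(u: np.ndarray, pad: tuple[int, int]) -> np.ndarray:
    """Extend a displacement field into the pad region with a cosine taper.

    Zero-padding the measured field leaves a discontinuity at the crop
    boundary that the inverse filter amplifies into edge artifacts; a
    raised-cosine interpolation between opposite edges (periodic topology)
    removes the jump. The construction is separable and bilinear in the
    corner block, hence exactly symmetric under grid flips/rotations.
    """
    ny, nx = u.shape[:2]
    pny, pnx = pad
    out = np.zeros((pny, pnx, u.shape[2]))
    out[:ny, :nx] = u
    wy, wx = pny - ny, pnx - nx
    ramp_y = 0.5 * (1.0 + np.cos(np.pi * np.arange(1, wy + 1) / (wy + 1)))
    ramp_x = 0.5 * (1.0 + np.cos(np.pi * np.arange(1, wx + 1) / (wx + 1)))
    out[ny:, :nx] = (
        ramp_y[:, None, None] * u[ny - 1 : ny, :, :]
        + (1.0 - ramp_y)[:, None, None] * u[0:1, :, :]
    )
    out[:, nx:] = (
        ramp_x[None, :, None] * out[:, nx - 1 : nx, :]
        + (1.0 - ramp_x)[None, :, None] * out[:, 0:1, :]
    )
    return out


def fttc_inverse(
    displacement: DisplacementField, gel: GelSubstrate, reg_lambda: float = 0.0
) -> TractionField:
    """Fourier-transform traction cytometry: regularized deconvolution.

    Solves, mode by mode, the Tikhonov-regularized normal equations
    (K² + (λ s)² I) t = K u with K the 2×2 Fourier symbol of the forward
    kernel and s its largest singular value over all modes, so that
    ``reg_lambda`` is dimensionless. ``reg_lambda = 0`` is the plain
    inverse filter. The measured field is continued into the pad region
    with a cosine taper (see :func:`_taper_pad`) before deconvolution.
    """
    if reg_lambda < 0:
        raise ValueError("reg_lambda must be >= 0")
    grid = displacement.grid
    if min(grid.shape) < 8:
        raise ValueError("grid too small for Fourier inversion (need >= 8 nodes/axis)")
    FKxx, FKxy, FKyy, pad = _kernel_ffts(grid.shape, grid.spacing, gel)
    ny, nx = grid.shape
    U = _taper_pad(displacement.u, pad)
    FUx = np.fft.rfft2(U[..., 0])
    FUy = np.fft.rfft2(U[..., 1])
    mu = (reg_lambda * _operator_norm(FKxx, FKxy, FKyy)) ** 2
    # normal equations for the symmetric 2x2 symbol per mode
    Axx = FKxx * FKxx + FKxy * FKxy + mu
    Axy = FKxy * (FKxx + FKyy)
    Ayy = FKyy * FKyy + FKxy * FKxy + mu
    bx = FKxx * FUx + FKxy * FUy
    by = FKxy * FUx + FKyy * FUy
    det = Axx * Ayy - Axy * Axy
    with np.errstate(divide="ignore", invalid="ignore"):
        FTx = (Ayy * bx - Axy * by) / det
        FTy = (Axx * by - Axy * bx) / det
    FTx[~np.isfinite(FTx)] = 0.0
    FTy[~np.isfinite(FTy)] = 0.0
    tx = np.fft.irfft2(FTx, s=pad)[:ny, :nx]
    ty = np.fft.irfft2(FTy, s=pad)[:ny, :nx]
    return TractionField(grid, np.stack([tx, ty], axis=-1))


def select_lambda(
    displacement: DisplacementField,
    gel: GelSubstrate,
    lambdas: np.ndarray | None = None,
) -> tuple[float, dict]:
    """Pick a regularization weight by the L-curve corner criterion.

    Scans a log-spaced grid of λ values, records residual norm
    ‖forward(t_λ) − u‖ against solution norm ‖t_λ‖, and returns the λ of
    maximum Menger curvature of the log-log L-curve (endpoints excluded).
    """
    if lambdas is None:
        lambdas = np.logspace(-5.0, -0.5, 20)
    lambdas = np.asarray(lambdas, dtype=float)
    rho = np.empty(lambdas.size)
    eta = np.empty(lambdas.size)
    for i, lam in enumerate(lambdas):
        t = fttc_inverse(displacement, gel, reg_lambda=lam)
        resid = forward_solve(t, gel).u - displacement.u
        rho[i] = np.linalg.norm(resid)
        eta[i] = np.linalg.norm(t.t)
    lr = np.log10(np.maximum(rho, 1e-300))
    le = np.log10(np.maximum(eta, 1e-300))
    curv = np.zeros(lambdas.size)
    for i in range(1, lambdas.size - 1):
        p0 = np.array([lr[i - 1], le[i - 1]])
        p1 = np.array([lr[i], le[i]])
        p2 = np.array([lr[i + 1], le[i + 1]])
        cross = (p1[0] - p0[0]) * (p2[1] - p0[1]) - (p1[1] - p0[1]) * (p2[0] - p0[0])
        denom = (
            np.linalg.norm(p1 - p0) * np.linalg.norm(p2 - p1) * np.linalg.norm(p2 - p0)
        )
        curv[i] = 2.0 * cross / denom if denom > 0 else 0.0
    best = int(np.argmax(curv[1:-1])) + 1
    return float(lambdas[best]), {
        "lambdas": lambdas,
        "residual_norm": rho,
        "solution_norm": eta,
        "curvature": curv,
    }


def constrained_inverse(
    displacement: DisplacementField,
    mask: CellMask,
    gel: GelSubstrate,
    reg_lambda: float = 1e-4,
    tol: float = 1e-4,
    max_iter: int = 60,
) -> tuple[TractionField, InversionInfo]:
    """Traction inversion with tractions forced to zero outside the cell.

    Iterative projection scheme: invert, zero tractions outside the mask,
    forward-solve, and correct by the inverse of the displacement residual,
    re-projecting after every correction. Stops when the relative misfit
    improvement per iteration drops below ``tol`` or at ``max_iter``; the
    lowest-misfit iterate is returned. A non-converged run is returned with
    a warning and ``converged = False``.
    """
    grid = displacement.grid
    m = mask.raster_on(grid)
    if not m.any():
        raise ValueError("cell mask does not overlap the grid")
    proj = m[..., None].astype(float)
    u = displacement.u
    unorm = np.linalg.norm(u)
    if unorm == 0:
        return TractionField(grid, np.zeros_like(u)), InversionInfo(0.0, 0, True, reg_lambda)
    if m.all():
        # constraint is vacuous: delegate to the unconstrained solver
        t_free = fttc_inverse(displacement, gel, reg_lambda)
        resid = u - forward_solve(t_free, gel).u
        return t_free, InversionInfo(
            misfit=float(np.linalg.norm(resid) / unorm),
            n_iter=0,
            converged=True,
            reg_lambda=reg_lambda,
        )

    t = fttc_inverse(displacement, gel, reg_lambda).t * proj
    best_t = t
    best_misfit = np.inf
    prev_misfit = np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        resid = u - forward_solve(TractionField(grid, t), gel).u
        misfit = np.linalg.norm(resid) / unorm
        if misfit < best_misfit:
            best_misfit = misfit
            best_t = t
        if prev_misfit - misfit < tol * max(prev_misfit, 1e-300):
            converged = True
            break
        prev_misfit = misfit
        dt = fttc_inverse(DisplacementField(grid, resid), gel, reg_lambda).t
        t = (t + dt) * proj
    if not converged:
        warnings.warn(
            f"constrained inversion did not converge in {max_iter} iterations "
            f"(misfit {best_misfit:.3g})",
            RuntimeWarning,
            stacklevel=2,
        )
    return TractionField(grid, best_t), InversionInfo(
        misfit=float(best_misfit), n_iter=n_iter, converged=converged, reg_lambda=reg_lambda
    )
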