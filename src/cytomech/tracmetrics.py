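"""Per-cell scalar read-outs of a traction field.

RMS traction, the first-order moment matrix and its trace (net contractile
moment), and the polarity ellipse derived from the moment-matrix
eigensystem.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .elastics import CellMask, GridSpec, TractionField

__all__ = [
    "TractionSummary",
    "rms_traction",
    "moment_matrix",
    "net_contractile_moment",
    "polarity_ellipse",
    "summarize_cell",
]


@dataclass
class TractionSummary:
    """Scalar mechanics read-outs for one cell.

    ``polarity`` is |λ1| / (|λ1| + |λ2|) with eigenvalues sorted by
    magnitude, so it lies in [0.5, 1]: 0.5 for isotropic traction, 1 for a
    pure uniaxial dipole. ``orientation`` is the principal-eigenvector
    angle folded to [0, π). Both are NaN when the moment matrix vanishes.
    """

    rms_traction: float
    net_force: np.ndarray
    moment_matrix: np.ndarray
    net_contractile_moment: float
    eigenvalues: tuple[float, float]
    orientation: float
    polarity: float
    spread_area: float


def _masked_nodes(
    traction: TractionField, mask: CellMask
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    grid = traction.grid
    m = mask.raster_on(grid)
    if not m.any():
        raise ValueError("mask selects no grid nodes")
    X, Y = grid.meshgrid()
    xy = np.stack([X[m], Y[m]], axis=-1)
    return traction.t[m], xy, m


def rms_traction(traction: TractionField, mask: CellMask) -> float:
    """Root-mean-square traction magnitude (Pa) over in-mask nodes."""
    t, _, _ = _masked_nodes(traction, mask)
    return float(np.sqrt(np.mean(t[:, 0] ** 2 + t[:, 1] ** 2)))


def moment_matrix(traction: TractionField, mask: CellMask) -> np.ndarray:
    """First-order moment matrix M (pN·µm), symmetrized.

    M_ij = ½ Σ (x_i t_j + x_j t_i) dA over in-mask nodes, with node
    coordinates taken relative to the traction-magnitude-weighted centroid.
    Negative trace indicates contraction under this sign convention.
    """
    t, xy, _ = _masked_nodes(traction, mask)
    dA = traction.grid.cell_area
    w = np.hypot(t[:, 0], t[:, 1])
    wsum = w.sum()
    if wsum > 0:
        centroid = (w[:, None] * xy).sum(axis=0) / wsum
    else:
        centroid = xy.mean(axis=0)
    rel = xy - centroid
    raw = np.einsum("ni,nj->ij", rel, t) * dA
    return 0.5 * (raw + raw.T)


def net_contractile_moment(M: np.ndarray) -> float:
    """Trace of the moment matrix (pN·µm); negative for contractile cells."""
    M = np.asarray(M, dtype=float)
    if not np.allclose(M, M.T):
        raise ValueError("moment matrix must be symmetric")
    return float(np.trace(M))


def polarity_ellipse(M: np.ndarray) -> tuple[tuple[float, float], float, float]:
    """Polarity ellipse of the moment matrix.

    Returns ``(semi_axes, orientation, polarity)``: semi-axes are the
    eigenvalue magnitudes sorted descending, orientation the principal
    eigenvector angle in [0, π), polarity |λ1| / (|λ1| + |λ2|).
    """
    M = np.asarray(M, dtype=float)
    if not np.allclose(M, M.T):
        raise ValueError("moment matrix must be symmetric")
    if np.allclose(M, 0.0):
        raise ValueError("zero moment matrix has no defined orientation")
    evals, evecs = np.linalg.eigh(M)
    order = np.argsort(-np.abs(evals))
    evals = evals[order]
    evecs = evecs[:, order]
    a1, a2 = abs(evals[0]), abs(evals[1])
    orientation = float(np.arctan2(evecs[1, 0], evecs[0, 0])) % np.pi
    polarity = a1 / (a1 + a2)
    return (float(a1), float(a2)), orientation, float(polarity)


def summarize_cell(traction: TractionField, mask: CellMask) -> TractionSummary:
    """Compose all per-cell metrics into a :class:`TractionSummary`.

    For an all-zero traction field the polarity ellipse is undefined;
    orientation, polarity and eigenvalues are reported as NaN with a
    warning instead of raising.
    """
    t, _, m = _masked_nodes(traction, mask)
    dA = traction.grid.cell_area
    rms = rms_traction(traction, mask)
    net_force = t.sum(axis=0) * dA
    M = moment_matrix(traction, mask)
    ncm = net_contractile_moment(M)
    area = mask.area if mask.area > 0 else m.sum() * dA
    try:
        _, orientation, polarity = polarity_ellipse(M)
        evals = np.linalg.eigvalsh(M)
        evals = evals[np.argsort(-np.abs(evals))]
        l1, l2 = float(evals[0]), float(evals[1])
    except ValueError:
        warnings.warn("zero moment matrix: polarity undefined", RuntimeWarning, stacklevel=2)
        l1 = l2 = orientation = polarity = float("nan")
    return TractionSummary(
        rms_traction=rms,
        net_force=net_force,
        moment_matrix=M,
        net_contractile_moment=ncm,
        eigenvalues=(l1, l2),
        orientation=orientation,
        polarity=polarity,
        spread_area=float(area),
    )
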