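"""Synthetic inputs with known ground truth for every pipeline stage.

Generators:

* contractile traction-dipole scenes on elastic gels, with the matching
  noiseless forward displacements plus optional bead-tracking noise;
* microtubule length traces with tunable dynamicity (multiplicative
  log-normal random walk, reflected at a positive floor);
* two-channel confocal stacks with an ellipsoidal nucleus, a perinuclear
  intensity-enriched shell, and a quadratic detector-gain distortion;
* two-arm survival cohorts with expression-dependent exponential hazard;
* bait/control intensity tables with a prescribed number of truly
  enriched proteins.

Everything is seeded and deterministic: identical seeds give identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

from .elastics import (
    CellMask,
    DisplacementField,
    GelSubstrate,
    GridSpec,
    TractionField,
    forward_solve,
)
from .mtdyn import MTLengthTrace
from .quant3d import GainCurve, VoxelStack, apply_gain

__all__ = [
    "DipoleSpec",
    "MTSimParams",
    "StackSimParams",
    "simulate_traction_scene",
    "simulate_mt_traces",
    "simulate_confocal_stack",
    "simulate_cohort",
    "simulate_intensity_table",
]


@dataclass(frozen=True)
class DipoleSpec:
    """A contractile force dipole: two equal-and-opposite Gaussian traction
    patches pulling toward their common center.

    ``force_magnitude`` is the force per pole in pN, ``separation`` the
    pole-to-pole distance in µm, ``patch_radius`` the Gaussian sd of the
    patch over which each pole's traction is spread.
    """

    center: tuple[float, float]
    axis_angle: float
    force_magnitude: float
    separation: float
    patch_radius: float

    def __post_init__(self) -> None:
        if not self.separation > 0:
            raise ValueError("separation must be positive")
        if self.force_magnitude < 0:
            raise ValueError("force_magnitude must be >= 0")
        if not self.patch_radius > 0:
            raise ValueError("patch_radius must be positive")

    @property
    def poles(self) -> tuple[np.ndarray, np.ndarray]:
        """Positions of the two poles (µm)."""
        e = np.array([np.cos(self.axis_angle), np.sin(self.axis_angle)])
        c = np.asarray(self.center, dtype=float)
        half = 0.5 * self.separation * e
        return c + half, c - half


def simulate_traction_scene(
    dipoles: list[DipoleSpec],
    gel: GelSubstrate,
    grid: GridSpec,
    noise_sd: float = 0.0,
    seed: int = 0,
    mask_margin: float | None = None,
) -> tuple[TractionField, DisplacementField, CellMask]:
    """Build a ground-truth traction field and its noisy displacement image.

    Each dipole pole contributes a Gaussian traction patch normalized to
    unit discrete integral, so the per-pole force is exact and the net
    force of the scene is exactly zero by construction. The displacement
    is ``forward_solve`` of the ground truth plus i.i.d. zero-mean
    Gaussian noise of sd ``noise_sd`` (µm). The cell mask is the convex
    hull of all poles buffered by ``mask_margin`` (default
    3 × max patch_radius).

    Zero dipoles give all-zero fields and a small central placeholder mask.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    X, Y = grid.meshgrid()
    dA = grid.cell_area
    t = np.zeros((*grid.shape, 2))
    x_lo, x_hi = grid.x[0], grid.x[-1]
    y_lo, y_hi = grid.y[0], grid.y[-1]
    pole_points = []
    for dip in dipoles:
        e = np.array([np.cos(dip.axis_angle), np.sin(dip.axis_angle)])
        for pole, direction in zip(dip.poles, (-e, +e)):
            # contractile: the force at each pole points toward the center
            if not (x_lo <= pole[0] <= x_hi and y_lo <= pole[1] <= y_hi):
                raise ValueError(f"dipole pole {pole} lies outside the grid")
            g = np.exp(
                -((X - pole[0]) ** 2 + (Y - pole[1]) ** 2) / (2.0 * dip.patch_radius ** 2)
            )
            norm = g.sum() * dA  # discrete unit integral => exact pole force
            t += dip.force_magnitude * direction[None, None, :] * (g / norm)[..., None]
            pole_points.append(pole)
    truth = TractionField(grid, t)
    disp = forward_solve(truth, gel)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        disp = DisplacementField(grid, disp.u + rng.normal(0.0, noise_sd, disp.u.shape))
    if pole_points:
        if mask_margin is None:
            mask_margin = 3.0 * max(d.patch_radius for d in dipoles)
        hull = shapely.MultiPoint(pole_points).convex_hull.buffer(mask_margin)
        polygon = np.asarray(hull.exterior.coords)
    else:
        cx = 0.5 * (x_lo + x_hi)
        cy = 0.5 * (y_lo + y_hi)
        r = 2.0 * grid.spacing
        theta = np.linspace(0, 2 * np.pi, 17)
        polygon = np.stack([cx + r * np.cos(theta), cy + r * np.sin(theta)], axis=-1)
    mask = CellMask.from_polygon(polygon, grid)
    return truth, disp, mask


@dataclass(frozen=True)
class MTSimParams:
    """Parameters of the microtubule length-trace generator."""

    n_traces: int
    base_length: float = 10.0
    dynamicity: float = 0.05
    n_frames: int = 10
    frame_interval: float = 3.0
    mts_per_cell: int = 2
    floor: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.n_traces < 1:
            raise ValueError("n_traces must be >= 1")
        if self.dynamicity < 0:
            raise ValueError("dynamicity must be >= 0")
        if not 0 < self.floor < self.base_length:
            raise ValueError("floor must be in (0, base_length)")


def simulate_mt_traces(params: MTSimParams) -> list[MTLengthTrace]:
    """Generate MT length traces as a reflected log-normal random walk.

    Per frame the length is multiplied by exp(dynamicity · z), z standard
    normal; lengths dipping below the floor are reflected in log space
    (L -> floor²/L), so every length stays positive. ``dynamicity = 0``
    gives constant traces.
    """
    rng = np.random.default_rng(params.seed)
    traces = []
    for i in range(params.n_traces):
        cell = f"cell{i // params.mts_per_cell:03d}"
        lengths = np.empty(params.n_frames)
        # small seeded spread of starting lengths around the base
        lengths[0] = params.base_length * np.exp(0.1 * params.dynamicity * rng.standard_normal())
        for k in range(1, params.n_frames):
            nxt = lengths[k - 1] * np.exp(params.dynamicity * rng.standard_normal())
            if nxt < params.floor:
                nxt = params.floor ** 2 / nxt
            lengths[k] = nxt
        traces.append(
            MTLengthTrace(
                cell_id=cell,
                mt_id=f"mt{i:03d}",
                lengths=lengths,
                frame_interval=params.frame_interval,
            )
        )
    return traces


@dataclass(frozen=True)
class StackSimParams:
    """Parameters of the two-channel confocal-stack generator."""

    shape: tuple[int, int, int] = (72, 72, 72)
    voxel_size: tuple[float, float, float] = (0.3, 0.3, 0.3)
    nucleus_radius: float = 8.0
    perinuclear_enrichment: float = 2.0
    shell_fraction: float = 0.25
    base_intensity: float = 100.0
    dapi_intensity: float = 200.0
    gain_coeffs: tuple[float, float, float] = (0.0, 1.0, 0.0)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.perinuclear_enrichment < 1:
            raise ValueError("perinuclear_enrichment must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        extent = [n * v for n, v in zip(self.shape, self.voxel_size)]
        outer = self.nucleus_radius * (1.0 + self.shell_fraction)
        if any(outer * 2.0 >= e for e in extent):
            raise ValueError("nucleus (plus shell) does not fit inside the stack")


def simulate_confocal_stack(
    params: StackSimParams,
) -> tuple[VoxelStack, VoxelStack, dict[str, np.ndarray]]:
    """Generate (raw stack, true-intensity stack, ground-truth masks).

    The DAPI channel is a solid sphere of radius ``nucleus_radius`` at the
    stack center; the tubulin channel is ``base_intensity`` outside the
    nucleus, multiplied by ``perinuclear_enrichment`` inside the true
    shell (surface distance in (0, shell_fraction · radius]). The raw
    stack applies the quadratic gain polynomial to the true intensities
    and adds Gaussian noise. Non-monotonic gain on the generated intensity
    range is rejected.

    Ground-truth masks (``nuclear``, ``shell``, ``cytoplasm``) are
    pairwise disjoint; the cytoplasm excludes the shell.
    """
    nz, ny, nx = params.shape
    vz, vy, vx = params.voxel_size
    z = (np.arange(nz) - (nz - 1) / 2.0) * vz
    y = (np.arange(ny) - (ny - 1) / 2.0) * vy
    x = (np.arange(nx) - (nx - 1) / 2.0) * vx
    Z, Y, X = np.meshgrid(z, y, x, indexing="ij")
    r = np.sqrt(Z ** 2 + Y ** 2 + X ** 2)
    nuclear = r <= params.nucleus_radius
    thickness = params.shell_fraction * params.nucleus_radius
    shell = (r > params.nucleus_radius) & (r <= params.nucleus_radius + thickness)
    cytoplasm = r > params.nucleus_radius + thickness

    dapi_true = np.where(nuclear, params.dapi_intensity, 0.0)
    tub_true = np.where(nuclear, 0.0, params.base_intensity)
    tub_true[shell] = params.base_intensity * params.perinuclear_enrichment

    a0, a1, a2 = params.gain_coeffs
    lo = 0.0
    hi = float(max(tub_true.max(), dapi_true.max(), 1.0))
    curve = GainCurve(a0=a0, a1=a1, a2=a2, valid_range=(lo, hi))  # raises if non-monotonic
    rng = np.random.default_rng(params.seed)
    raw_channels = {}
    for name, true in (("dapi", dapi_true), ("tubulin", tub_true)):
        raw = apply_gain(true, curve)
        if params.noise_sd > 0:
            raw = raw + rng.normal(0.0, params.noise_sd, raw.shape)
        raw_channels[name] = raw
    truth = VoxelStack({"dapi": dapi_true, "tubulin": tub_true}, params.voxel_size)
    raw_stack = VoxelStack(raw_channels, params.voxel_size)
    masks = {"nuclear": nuclear, "shell": shell, "cytoplasm": cytoplasm}
    return raw_stack, truth, masks


def simulate_cohort(
    n: int,
    hazard_ratio_low_vs_high: float = 1.0,
    censor_rate: float = 0.0,
    seed: int = 0,
    baseline_hazard: float = 0.02,
) -> pd.DataFrame:
    """Two-arm survival cohort with expression-dependent hazard.

    Expression values are standard normal; subjects below their 25th
    percentile form the "low" arm, whose exponential event hazard is
    ``baseline_hazard × hazard_ratio_low_vs_high`` (per month). Each
    subject is independently censored with probability ``censor_rate`` at
    a uniform fraction of its event time, so ``censor_rate = 0`` leaves
    every subject an event.
    """
    if n < 8:
        raise ValueError("n must be >= 8")
    if not hazard_ratio_low_vs_high > 0:
        raise ValueError("hazard ratio must be positive")
    if not 0 <= censor_rate < 1:
        raise ValueError("censor_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    expression = rng.standard_normal(n)
    low = expression < np.percentile(expression, 25.0, method="linear")
    hazard = np.where(low, baseline_hazard * hazard_ratio_low_vs_high, baseline_hazard)
    event_time = rng.exponential(1.0 / hazard)
    censored = rng.random(n) < censor_rate
    time = np.where(censored, event_time * rng.random(n), event_time)
    return pd.DataFrame(
        {
            "subject_id": [f"s{i:04d}" for i in range(n)],
            "expression": expression,
            "time_months": time,
            "event": ~censored,
        }
    )


def simulate_intensity_table(
    n_proteins: int = 417,
    n_enriched: int = 130,
    threshold: float = 2.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Bait/control intensity table with an exact number of enriched rows.

    Enriched proteins carry true fold > threshold with margin, the rest
    sit well below it, so the default pseudo-count filter recovers exactly
    ``n_enriched`` proteins in the noiseless case. Categories mimic a
    cytoskeleton pulldown (tubulins and friends for the enriched set).
    """
    if not 0 <= n_enriched <= n_proteins:
        raise ValueError("n_enriched must be within [0, n_proteins]")
    rng = np.random.default_rng(seed)
    control = rng.uniform(100.0, 500.0, n_proteins)
    fold = np.empty(n_proteins)
    fold[:n_enriched] = rng.uniform(threshold + 0.5, 4.0 * threshold, n_enriched)
    fold[n_enriched:] = rng.uniform(0.3, 0.75 * threshold, n_proteins - n_enriched)
    bait = control * fold
    enriched_cats = ["tubulin", "MT-associated", "motor", "chaperone"]
    other_cats = ["ribosomal", "metabolic", "membrane", "other"]
    category = np.where(
        np.arange(n_proteins) < n_enriched,
        rng.choice(enriched_cats, n_proteins),
        rng.choice(other_cats, n_proteins),
    )
    return pd.DataFrame(
        {
            "protein_id": [f"P{i:05d}" for i in range(n_proteins)],
            "bait_intensity": bait,
            "control_intensity": control,
            "category": category,
            "true_enriched": np.arange(n_proteins) < n_enriched,
        }
    )
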