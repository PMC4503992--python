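"""3-D intensity quantitation with detector-gain normalization.

Pipeline pieces: fit a quadratic detector gain curve from calibration
pairs, invert it voxel-wise to map raw intensities back to a common
reference gain, segment nuclear / cytoplasmic / perinuclear-shell masks
from a two-channel confocal stack, and report per-cell mean intensities.
Also houses the simple ratio read-outs used alongside the imaging
quantitation (densitometric fold-change, fluorescence-per-protein and
viability normalization).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label

__all__ = [
    "VoxelStack",
    "GainCurve",
    "ShellMasks",
    "DensitometryRecord",
    "fit_gain_curve",
    "apply_gain",
    "normalize_intensity",
    "segment_masks",
    "shell_and_cytoplasm_means",
    "msa_fold_change",
    "ratio_normalize",
]


@dataclass
class VoxelStack:
    """Named 3-D intensity channels with a shared physical voxel size.

    ``voxel_size`` is (z, y, x) in µm; all channels must share one shape.
    """

    channels: dict[str, np.ndarray]
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("stack needs at least one channel")
        shapes = {np.asarray(c).shape for c in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError("all channels must share one shape")
        shape = shapes.pop()
        if len(shape) != 3:
            raise ValueError("channels must be 3-D (z, y, x)")
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError("voxel_size must be three positive values (z, y, x)")
        self.voxel_size = vs

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))


@dataclass(frozen=True)
class GainCurve:
    """Quadratic detector response y = a2·x² + a1·x + a0.

    ``x`` is the input (true) intensity, ``y`` the recorded output.
    ``valid_range`` is the input-intensity interval on which the curve is
    used; the curve must be strictly increasing there.
    """

    a0: float
    a1: float
    a2: float
    valid_range: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.valid_range
        if not lo < hi:
            raise ValueError("valid_range must be a non-empty interval")
        if not self.is_monotonic():
            raise ValueError("gain curve is not strictly increasing on valid_range")

    def is_monotonic(self) -> bool:
        lo, hi = self.valid_range
        # derivative a1 + 2 a2 x is linear: check the endpoints
        return min(self.a1 + 2 * self.a2 * lo, self.a1 + 2 * self.a2 * hi) > 0

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.a2 * x ** 2 + self.a1 * x + self.a0


def apply_gain(x: np.ndarray, curve: GainCurve) -> np.ndarray:
    """Forward application of the gain polynomial (true -> recorded)."""
    return curve(x)


def fit_gain_curve(
    calibration: np.ndarray | list[tuple[float, float]],
    valid_range: tuple[float, float] | None = None,
) -> GainCurve:
    """Least-squares quadratic through (input, output) calibration pairs.

    Exactly three distinct pairs give the interpolating quadratic. Fewer
    than three pairs, or duplicated inputs, are rejected. A warning is
    emitted if the fitted curve is not monotonic on the data range.
    """
    pairs = np.asarray(calibration, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] < 3:
        raise ValueError("need at least 3 (input, output) calibration pairs")
    x, y = pairs[:, 0], pairs[:, 1]
    if np.unique(x).size != x.size:
        raise ValueError("calibration inputs must be distinct")
    a2, a1, a0 = np.polyfit(x, y, 2)
    if valid_range is None:
        valid_range = (float(x.min()), float(x.max()))
    deriv_lo = a1 + 2 * a2 * valid_range[0]
    deriv_hi = a1 + 2 * a2 * valid_range[1]
    if min(deriv_lo, deriv_hi) <= 0:
        warnings.warn(
            "fitted gain curve is not monotonic on the calibration range",
            UserWarning,
            stacklevel=2,
        )
        # widen derivative tolerance by returning an unvalidated curve
        curve = object.__new__(GainCurve)
        object.__setattr__(curve, "a0", float(a0))
        object.__setattr__(curve, "a1", float(a1))
        object.__setattr__(curve, "a2", float(a2))
        object.__setattr__(curve, "valid_range", valid_range)
        return curve
    return GainCurve(a0=float(a0), a1=float(a1), a2=float(a2), valid_range=valid_range)


def normalize_intensity(channel: np.ndarray, curve: GainCurve) -> np.ndarray:
    """Invert the gain polynomial per voxel (recorded -> true intensity).

    For each recorded value y the root of a2·x² + a1·x + (a0 − y) lying in
    ``curve.valid_range`` is selected. Voxels with no real root in range
    are set to NaN and thereby excluded from downstream means.
    """
    y = np.asarray(channel, dtype=float)
    lo, hi = curve.valid_range
    if abs(curve.a2) < 1e-300:
        x = (y - curve.a0) / curve.a1
    else:
        disc = curve.a1 ** 2 - 4.0 * curve.a2 * (curve.a0 - y)
        bad = disc < 0
        sqrt_disc = np.sqrt(np.where(bad, 0.0, disc))
        r1 = (-curve.a1 + sqrt_disc) / (2.0 * curve.a2)
        r2 = (-curve.a1 - sqrt_disc) / (2.0 * curve.a2)
        # prefer the root inside the valid range; monotonic-increasing
        # curves put it on the +sqrt branch for a2 > 0
        eps = 1e-9 * max(1.0, abs(hi - lo))
        in1 = (r1 >= lo - eps) & (r1 <= hi + eps)
        x = np.where(in1, r1, r2)
        in_range = in1 | ((r2 >= lo - eps) & (r2 <= hi + eps))
        x = np.where(bad | ~in_range, np.nan, x)
    return x


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels = label(mask, connectivity=1)
    if labels.max() == 0:
        return mask
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == counts.argmax()


@dataclass
class ShellMasks:
    """Nuclear, cytoplasmic and perinuclear-shell voxel masks.

    The shell is the hollow region just outside the nuclear surface, up to
    a fixed physical distance (a fraction of the nuclear radius) away. The
    three masks are pairwise disjoint; the cytoplasm excludes both the
    nucleus and the shell so the two intensity read-outs are independent.
    """

    nuclear: np.ndarray
    cytoplasm: np.ndarray
    perinuclear_shell: np.ndarray
    nuclear_radius_estimate: float

    def __post_init__(self) -> None:
        shapes = {self.nuclear.shape, self.cytoplasm.shape, self.perinuclear_shell.shape}
        if len(shapes) != 1:
            raise ValueError("masks must share one shape")
        if np.any(self.nuclear & self.perinuclear_shell):
            raise ValueError("shell and nuclear masks must be disjoint")


def segment_masks(
    stack: VoxelStack,
    dapi_channel: str = "dapi",
    tubulin_channel: str = "tubulin",
    shell_fraction: float = 0.25,
    shell_thickness_um: float | None = None,
) -> ShellMasks:
    """Derive nuclear / cytoplasm / perinuclear-shell masks from a stack.

    Nuclear mask: Otsu threshold on the DAPI channel, largest connected
    component, holes filled. The nuclear radius is estimated from the mask
    volume as the equivalent-sphere radius (3V/4π)^(1/3). The shell is the
    set of voxels whose anisotropy-aware Euclidean distance d to the
    nuclear mask satisfies 0 < d <= shell_fraction · radius (or an explicit
    ``shell_thickness_um``, for cohort-wide thickness). The cytoplasm is
    the Otsu-thresholded tubulin channel minus nucleus and shell.
    """
    for ch in (dapi_channel, tubulin_channel):
        if ch not in stack.channels:
            raise KeyError(f"channel {ch!r} not in stack")
    dapi = stack.channels[dapi_channel]
    tub = stack.channels[tubulin_channel]
    nuclear = dapi > threshold_otsu(dapi)
    if not nuclear.any():
        raise ValueError("empty nuclear mask")
    nuclear = _largest_component(nuclear)
    nuclear = ndimage.binary_fill_holes(nuclear)
    volume = nuclear.sum() * stack.voxel_volume
    radius = float((3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0))
    thickness = shell_thickness_um if shell_thickness_um is not None else shell_fraction * radius
    dist = ndimage.distance_transform_edt(~nuclear, sampling=stack.voxel_size)
    shell = (dist > 0) & (dist <= thickness)
    cytoplasm = (tub > threshold_otsu(tub)) & ~nuclear & ~shell
    return ShellMasks(
        nuclear=nuclear,
        cytoplasm=cytoplasm,
        perinuclear_shell=shell,
        nuclear_radius_estimate=radius,
    )


def shell_and_cytoplasm_means(
    stack: VoxelStack,
    masks: ShellMasks,
    curve: GainCurve | None = None,
    tubulin_channel: str = "tubulin",
) -> tuple[float, float]:
    """(cytoplasm mean, shell mean) of gain-normalized tubulin intensity.

    Voxels flagged NaN by the gain inversion are excluded. Raises on an
    empty mask.
    """
    tub = stack.channels[tubulin_channel]
    if curve is not None:
        tub = normalize_intensity(tub, curve)
    if not masks.cytoplasm.any() or not masks.perinuclear_shell.any():
        raise ValueError("empty cytoplasm or shell mask")
    cyto_mean = float(np.nanmean(tub[masks.cytoplasm]))
    shell_mean = float(np.nanmean(tub[masks.perinuclear_shell]))
    return cyto_mean, shell_mean


@dataclass(frozen=True)
class DensitometryRecord:
    """One immunoblot band pair (marker and loading-control intensities)."""

    condition: str
    ac_tubulin: float
    beta_tubulin: float
    treated: bool

    def __post_init__(self) -> None:
        if self.ac_tubulin <= 0 or self.beta_tubulin <= 0:
            raise ValueError("band intensities must be positive")


def msa_fold_change(treated: DensitometryRecord, untreated: DensitometryRecord) -> float:
    """Treatment-induced fold change of loading-normalized band intensity.

    fold = (marker/control)_treated / (marker/control)_untreated
    """
    if not treated.treated or untreated.treated:
        raise ValueError("records must be one treated and one untreated")
    num = treated.ac_tubulin / treated.beta_tubulin
    den = untreated.ac_tubulin / untreated.beta_tubulin
    return num / den


def ratio_normalize(signal: float, reference: float) -> float:
    """Plain ratio normalization (e.g. fluorescence per µg protein,
    viability relative to vehicle)."""
    if reference <= 0:
        raise ValueError("reference must be positive")
    return signal / reference
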