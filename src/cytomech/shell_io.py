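"""Shared I/O, configuration and the end-to-end pipeline driver.

CSV dialects
------------
All tabular artifacts are plain CSV with unit-suffixed column names
(``x_um``, ``tx_Pa``, ...). Files written by this package start with
provenance comment lines (``# key: value``: tool version, config hash,
seed); readers skip ``#`` lines.

Stacks are multi-channel TIFF with channel names and voxel size stored as
JSON in the image description.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .elastics import (
    CellMask,
    DisplacementField,
    GelSubstrate,
    GridSpec,
    TractionField,
    constrained_inverse,
    select_lambda,
)
from .quant3d import VoxelStack
from .tracmetrics import summarize_cell

log = logging.getLogger("cytomech")

DISPLACEMENT_COLUMNS = ("x_um", "y_um", "ux_um", "uy_um")
TRACTION_COLUMNS = ("x_um", "y_um", "tx_Pa", "ty_Pa")


def provenance_header(seed: int | None = None, config_hash: str | None = None) -> str:
    lines = [f"# tool: cytomech {__version__}"]
    if config_hash is not None:
        lines.append(f"# config_hash: {config_hash}")
    if seed is not None:
        lines.append(f"# seed: {seed}")
    return "\n".join(lines) + "\n"


def write_table_csv(
    path: str | Path,
    frame: pd.DataFrame,
    seed: int | None = None,
    config_hash: str | None = None,
) -> None:
    """Write a DataFrame as CSV with a provenance comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(provenance_header(seed=seed, config_hash=config_hash))
        frame.to_csv(fh, index=False)


def read_table_csv(path: str | Path, required: tuple[str, ...] = ()) -> pd.DataFrame:
    frame = pd.read_csv(path, comment="#")
    for col in required:
        if col not in frame.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    if frame.empty:
        raise ValueError(f"{path}: no data rows")
    return frame


def _vector_field_frame(grid: GridSpec, vec: np.ndarray, cols: tuple[str, ...]) -> pd.DataFrame:
    X, Y = grid.meshgrid()
    return pd.DataFrame(
        {
            cols[0]: X.ravel(),
            cols[1]: Y.ravel(),
            cols[2]: vec[..., 0].ravel(),
            cols[3]: vec[..., 1].ravel(),
        }
    )


def write_displacement_csv(path: str | Path, disp: DisplacementField, **prov) -> None:
    write_table_csv(path, _vector_field_frame(disp.grid, disp.u, DISPLACEMENT_COLUMNS), **prov)


def write_traction_csv(path: str | Path, trac: TractionField, **prov) -> None:
    write_table_csv(path, _vector_field_frame(trac.grid, trac.t, TRACTION_COLUMNS), **prov)


def _grid_from_points(x: np.ndarray, y: np.ndarray) -> GridSpec | None:
    """Recover a GridSpec if the points form a complete regular grid."""
    ux = np.unique(x)
    uy = np.unique(y)
    if ux.size < 2 or uy.size < 2 or ux.size * uy.size != x.size:
        return None
    dx = np.diff(ux)
    dy = np.diff(uy)
    if not (np.allclose(dx, dx[0]) and np.allclose(dy, dy[0]) and np.isclose(dx[0], dy[0])):
        return None
    # verify every (y, x) combination is present exactly once
    order = np.lexsort((x, y))
    Xs = x[order].reshape(uy.size, ux.size)
    Ys = y[order].reshape(uy.size, ux.size)
    if not (np.allclose(Xs, ux[None, :]) and np.allclose(Ys, uy[:, None])):
        return None
    return GridSpec(origin=(float(ux[0]), float(uy[0])), spacing=float(dx[0]),
                    shape=(uy.size, ux.size))


def read_displacement_csv(path: str | Path) -> DisplacementField | pd.DataFrame:
    """Read a displacement table.

    Gridded data come back as a :class:`DisplacementField`; scattered bead
    measurements are returned as the raw DataFrame, flagged for
    interpolation (see :func:`interpolate_to_grid`). Rejects missing
    columns and non-numeric cells with the offending row number.
    """
    frame = read_table_csv(path, required=DISPLACEMENT_COLUMNS)
    for col in DISPLACEMENT_COLUMNS:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if bad.any():
            raise ValueError(f"{path}: non-numeric value in {col!r} at row {int(bad.idxmax())}")
        if coerced.isna().any():
            raise ValueError(f"{path}: empty cell in {col!r} at row {int(coerced.isna().idxmax())}")
        frame[col] = coerced
    grid = _grid_from_points(frame["x_um"].to_numpy(), frame["y_um"].to_numpy())
    if grid is None:
        frame.attrs["scattered"] = True
        return frame
    order = np.lexsort((frame["x_um"].to_numpy(), frame["y_um"].to_numpy()))
    u = np.stack(
        [
            frame["ux_um"].to_numpy()[order].reshape(grid.shape),
            frame["uy_um"].to_numpy()[order].reshape(grid.shape),
        ],
        axis=-1,
    )
    return DisplacementField(grid, u)


def read_traction_csv(path: str | Path) -> TractionField:
    frame = read_table_csv(path, required=TRACTION_COLUMNS)
    grid = _grid_from_points(frame["x_um"].to_numpy(), frame["y_um"].to_numpy())
    if grid is None:
        raise ValueError(f"{path}: traction tables must be gridded")
    order = np.lexsort((frame["x_um"].to_numpy(), frame["y_um"].to_numpy()))
    t = np.stack(
        [
            frame["tx_Pa"].to_numpy()[order].reshape(grid.shape),
            frame["ty_Pa"].to_numpy()[order].reshape(grid.shape),
        ],
        axis=-1,
    )
    return TractionField(grid, t)


def interpolate_to_grid(points: pd.DataFrame, grid: GridSpec) -> DisplacementField:
    """Linear triangulation-based interpolation of scattered beads to a grid.

    Nodes outside the bead convex hull (where linear interpolation would
    extrapolate) are set to zero.
    """
    from scipy.interpolate import griddata

    xy = points[["x_um", "y_um"]].to_numpy()
    X, Y = grid.meshgrid()
    u = np.stack(
        [
            griddata(xy, points[c].to_numpy(), (X, Y), method="linear", fill_value=0.0)
            for c in ("ux_um", "uy_um")
        ],
        axis=-1,
    )
    return DisplacementField(grid, u)


def write_polygon_csv(path: str | Path, mask: CellMask, **prov) -> None:
    if mask.polygon is None:
        raise ValueError("mask carries no polygon")
    poly = np.asarray(mask.polygon)
    if not np.allclose(poly[0], poly[-1]):
        poly = np.vstack([poly, poly[0]])  # close the ring on disk
    write_table_csv(path, pd.DataFrame({"x_um": poly[:, 0], "y_um": poly[:, 1]}), **prov)


def read_polygon_csv(path: str | Path) -> CellMask:
    frame = read_table_csv(path, required=("x_um", "y_um"))
    poly = frame[["x_um", "y_um"]].to_numpy()
    if np.allclose(poly[0], poly[-1]):
        poly = poly[:-1]
    return CellMask(polygon=poly)


def write_stack_tiff(path: str | Path, stack: VoxelStack, **_prov) -> None:
    """Write a multi-channel stack as TIFF, axes (C, Z, Y, X)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    names = list(stack.channels)
    data = np.stack([stack.channels[n] for n in names], axis=0).astype(np.float32)
    meta = {"channels": names, "voxel_size_um": list(stack.voxel_size), "axes": "CZYX"}
    tifffile.imwrite(path, data, description=json.dumps(meta), photometric="minisblack")


def read_stack_tiff(
    path: str | Path,
    channel_names: list[str] | None = None,
    voxel_size: tuple[float, float, float] | None = None,
) -> VoxelStack:
    """Read a multi-channel TIFF stack written by :func:`write_stack_tiff`.

    ``voxel_size`` overrides any size found in metadata; with neither the
    file is rejected. A 2-D image is rejected as non-stack.
    """
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        desc = tf.pages[0].description
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    if data.ndim == 2:
        raise ValueError(f"{path}: 2-D TIFF is not a stack")
    if data.ndim == 3:
        data = data[None, ...]  # single channel
    names = meta.get("channels") or [f"ch{i}" for i in range(data.shape[0])]
    if channel_names is not None:
        missing = [c for c in channel_names if c not in names]
        if missing:
            raise ValueError(f"{path}: missing channels {missing}")
    vs = voxel_size or meta.get("voxel_size_um")
    if vs is None:
        raise ValueError(f"{path}: no voxel size in metadata and no override given")
    channels = {n: data[i] for i, n in enumerate(names)}
    if channel_names is not None:
        channels = {n: channels[n] for n in channel_names}
    return VoxelStack(channels, tuple(vs))


# ---------------------------------------------------------------------------
# pipeline configuration and driver

_SCENE_KEYS = {"n_cells", "force_pn", "separation_um", "patch_radius_um",
               "n_dipoles", "noise_sd_um"}
_GEL_KEYS = {"youngs_modulus_pa", "poisson_ratio"}
_GRID_KEYS = {"origin", "spacing_um", "shape"}
_INVERT_KEYS = {"reg_lambda", "tol", "max_iter"}
_TOP_KEYS = {"seed", "outdir", "gel", "grid", "scene", "invert", "stages"}


@dataclass
class PipelineConfig:
    """Validated configuration of the simulate -> invert -> metrics pipeline.

    Unknown keys anywhere in the mapping are rejected up front so that a
    typo cannot silently fall back to a default.
    """

    seed: int = 0
    outdir: Path = Path("cytomech_out")
    stages: list[str] = dc_field(default_factory=lambda: ["simulate", "invert", "metrics"])
    gel: dict = dc_field(default_factory=lambda: {"youngs_modulus_pa": 11e3, "poisson_ratio": 0.5})
    grid: dict = dc_field(
        default_factory=lambda: {"origin": [0.0, 0.0], "spacing_um": 1.0, "shape": [64, 64]}
    )
    scene: dict = dc_field(
        default_factory=lambda: {
            "n_cells": 3,
            "force_pn": 300.0,
            "separation_um": 16.0,
            "patch_radius_um": 2.5,
            "n_dipoles": 1,
            "noise_sd_um": 0.0,
        }
    )
    invert: dict = dc_field(
        default_factory=lambda: {"reg_lambda": "auto", "tol": 1e-4, "max_iter": 60}
    )

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        unknown = set(mapping) - _TOP_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for block, allowed in (("gel", _GEL_KEYS), ("grid", _GRID_KEYS),
                               ("scene", _SCENE_KEYS), ("invert", _INVERT_KEYS)):
            extra = set(mapping.get(block, {})) - allowed
            if extra:
                raise ValueError(f"unknown keys in {block!r} block: {sorted(extra)}")
        cfg = cls()
        for key, value in mapping.items():
            if key in ("gel", "grid", "scene", "invert"):
                getattr(cfg, key).update(value)
            elif key == "outdir":
                cfg.outdir = Path(value)
            elif key == "seed":
                if not isinstance(value, int):
                    raise ValueError("seed must be an integer")
                cfg.seed = value
            else:
                setattr(cfg, key, value)
        return cfg

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            mapping = yaml.safe_load(fh)  # YAML is a superset of JSON
        if not isinstance(mapping, dict):
            raise ValueError(f"{path}: config must be a mapping")
        return cls.from_mapping(mapping)

    def digest(self) -> str:
        payload = {
            "seed": self.seed,
            "stages": self.stages,
            "gel": self.gel,
            "grid": self.grid,
            "scene": self.scene,
            "invert": self.invert,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the configured stages in order; returns the per-cell summary CSV.

    Any stage failure aborts with the failing stage named. Output CSVs
    carry provenance headers (tool version, config hash, seed).
    """
    from . import synthio  # deferred: synthio imports from elastics

    chash = config.digest()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    rows = []
    stage = "simulate"
    try:
        gel = GelSubstrate(config.gel["youngs_modulus_pa"], config.gel.get("poisson_ratio", 0.5))
        grid = GridSpec(
            origin=tuple(config.grid["origin"]),
            spacing=config.grid["spacing_um"],
            shape=tuple(config.grid["shape"]),
        )
        scene = config.scene
        cells = []
        extent = grid.spacing * (min(grid.shape) - 1)
        center = (
            grid.origin[0] + 0.5 * grid.spacing * (grid.shape[1] - 1),
            grid.origin[1] + 0.5 * grid.spacing * (grid.shape[0] - 1),
        )
        for i in range(int(scene["n_cells"])):
            dipoles = [
                synthio.DipoleSpec(
                    center=center,
                    axis_angle=float(rng.uniform(0, np.pi)),
                    force_magnitude=float(scene["force_pn"]),
                    separation=min(float(scene["separation_um"]), 0.4 * extent),
                    patch_radius=float(scene["patch_radius_um"]),
                )
                for _ in range(int(scene.get("n_dipoles", 1)))
            ]
            truth, disp, mask = synthio.simulate_traction_scene(
                dipoles, gel, grid,
                noise_sd=float(scene.get("noise_sd_um", 0.0)),
                seed=int(rng.integers(2 ** 31)),
            )
            cells.append((f"cell{i:03d}", truth, disp, mask))
            write_displacement_csv(
                outdir / f"cell{i:03d}_displacement.csv", disp,
                seed=config.seed, config_hash=chash,
            )
            write_polygon_csv(outdir / f"cell{i:03d}_contour.csv", mask,
                              seed=config.seed, config_hash=chash)
        log.info("simulate: %d cells on %s grid", len(cells), grid.shape)

        recovered = {}
        if "invert" in config.stages:
            stage = "invert"
            lam_cfg = config.invert.get("reg_lambda", "auto")
            for cell_id, _, disp, mask in cells:
                lam = (
                    select_lambda(disp, gel)[0]
                    if lam_cfg == "auto"
                    else float(lam_cfg)
                )
                trac, info = constrained_inverse(
                    disp, mask, gel, reg_lambda=lam,
                    tol=float(config.invert.get("tol", 1e-4)),
                    max_iter=int(config.invert.get("max_iter", 60)),
                )
                recovered[cell_id] = trac
                write_traction_csv(outdir / f"{cell_id}_traction.csv", trac,
                                   seed=config.seed, config_hash=chash)
                log.info("invert %s: lambda=%.3g misfit=%.3g iters=%d",
                         cell_id, lam, info.misfit, info.n_iter)

        if "metrics" in config.stages:
            stage = "metrics"
            for cell_id, truth, _, mask in cells:
                trac = recovered.get(cell_id, truth)
                s = summarize_cell(trac, mask)
                rows.append(
                    {
                        "cell_id": cell_id,
                        "rms_Pa": s.rms_traction,
                        "ncm_pNum": s.net_contractile_moment,
                        "polarity": s.polarity,
                        "orientation_rad": s.orientation,
                        "area_um2": s.spread_area,
                        "stiffness_kPa": gel.youngs_modulus / 1e3,
                    }
                )
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    summary = outdir / "cell_summary.csv"
    write_table_csv(summary, pd.DataFrame(rows), seed=config.seed, config_hash=chash)
    log.info("pipeline complete: %s", summary)
    return summary
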