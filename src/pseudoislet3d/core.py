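"""Domain types, acquisition geometry, and file IO for pseudoislet stacks.

All physical quantities are micrometres (µm). Voxel indices are 0-based
``(z, y, x)``; the physical position of a voxel is its centre. Conversion
between µm and voxel counts goes through :class:`VoxelGeometry` only, which
carries the two calibration factors of a spinning-disk z-stack: the xy pixel
size and the z step.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "CHANNEL_ROLES",
    "CELL_TYPES",
    "REGIONS",
    "ConfigError",
    "StackFormatError",
    "VoxelGeometry",
    "Length",
    "ChannelStack",
    "LabelMap",
    "OBJECT_TABLE_COLUMNS",
    "GROUND_TRUTH_COLUMNS",
    "BENCHMARK_REPORT_COLUMNS",
    "make_object_table",
    "validate_object_table",
    "validate_ground_truth",
    "read_table",
    "write_table",
    "PipelineConfig",
    "preset",
    "PRESET_NAMES",
    "load_config",
    "save_config",
    "read_stack",
    "write_stack",
]

#: Channel roles of a pseudoislet acquisition: all nuclei (Sytox-orange-like),
#: INS1E cytoplasm (mNeonGreen2-like), alpha-cell cytoplasm (BFP2-like), and
#: the collagen-IV ECM channel.
CHANNEL_ROLES = ("nuclei", "insle", "alpha", "ecm")

#: Constituent cell types at the 1:9:5 seeding ratio.
CELL_TYPES = ("alpha", "insle", "huvec")

REGIONS = ("core", "mantle", "unassigned")


class ConfigError(ValueError):
    """A pipeline or simulation configuration violates its invariants."""


class StackFormatError(ValueError):
    """An image file does not match the expected multi-page layout."""


# ---------------------------------------------------------------------------
# Geometry and calibrated lengths
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VoxelGeometry:
    """Physical calibration of a z-stack.

    Parameters
    ----------
    pixel_size_xy : float
        Lateral pixel size, µm/pixel. Must be > 0.
    z_step : float
        Axial slice spacing, µm/slice. Must be > 0.
    """

    pixel_size_xy: float
    z_step: float

    def __post_init__(self) -> None:
        if not (self.pixel_size_xy > 0 and self.z_step > 0):
            raise ConfigError(
                "VoxelGeometry requires strictly positive pixel_size_xy and "
                f"z_step, got ({self.pixel_size_xy}, {self.z_step})"
            )

    @property
    def spacing_zyx(self) -> tuple[float, float, float]:
        """Per-axis voxel extents in µm, ordered (z, y, x)."""
        return (self.z_step, self.pixel_size_xy, self.pixel_size_xy)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in µm³."""
        return self.pixel_size_xy**2 * self.z_step

    @property
    def pixel_area(self) -> float:
        """In-plane area of one pixel in µm²."""
        return self.pixel_size_xy**2

    def length_to_voxels(self, length_um: float, axis: str = "xy") -> int:
        """Convert a physical length to a voxel count, rounding half-up.

        ``axis`` is ``"xy"`` or ``"z"``; anisotropic stacks convert
        differently per axis.
        """
        if axis == "xy":
            step = self.pixel_size_xy
        elif axis == "z":
            step = self.z_step
        else:
            raise ValueError(f"axis must be 'xy' or 'z', got {axis!r}")
        return int(math.floor(length_um / step + 0.5))

    def voxel_centre_um(self, index_zyx: Sequence[float]) -> np.ndarray:
        """Physical (x, y, z) µm position of a voxel index (z, y, x)."""
        z, y, x = index_zyx
        return np.array(
            [x * self.pixel_size_xy, y * self.pixel_size_xy, z * self.z_step]
        )


@dataclass(frozen=True)
class Length:
    """A length with an explicit unit tag, either ``"um"`` or ``"px"``.

    The unit tag exists because published pipelines mix pixel-denominated
    parameters (Fiji's rolling ball of 50 pixels) with µm-denominated ones
    (GA3's 27 µm); converting through :meth:`to_pixels` makes the
    interpretation explicit.
    """

    value: float
    unit: str  # "um" | "px"

    def __post_init__(self) -> None:
        if self.unit not in ("um", "px"):
            raise ConfigError(f"Length unit must be 'um' or 'px', got {self.unit!r}")
        if not self.value > 0:
            raise ConfigError(f"Length must be positive, got {self.value}")

    def to_pixels(self, geometry: VoxelGeometry, axis: str = "xy") -> float:
        if self.unit == "px":
            return float(self.value)
        step = geometry.pixel_size_xy if axis == "xy" else geometry.z_step
        return float(self.value) / step

    def __str__(self) -> str:  # round-trips through parse_length
        return f"{self.value:g} {self.unit}"


def parse_length(text: str | Length | float) -> Length:
    """Parse ``"50 px"`` / ``"27 um"``; a bare number means µm."""
    if isinstance(text, Length):
        return text
    if isinstance(text, (int, float)):
        return Length(float(text), "um")
    parts = str(text).split()
    if len(parts) == 1:
        return Length(float(parts[0]), "um")
    if len(parts) == 2:
        return Length(float(parts[0]), parts[1])
    raise ConfigError(f"cannot parse length {text!r}")


# ---------------------------------------------------------------------------
# Voxel containers
# ---------------------------------------------------------------------------


@dataclass
class ChannelStack:
    """A named set of 3D intensity grids sharing one geometry.

    ``channels`` maps a role from :data:`CHANNEL_ROLES` to a 3D array with
    axes (z, y, x). All grids must share dimensions and hold finite,
    non-negative intensities.
    """

    channels: dict[str, np.ndarray]
    geometry: VoxelGeometry

    def __post_init__(self) -> None:
        if not self.channels:
            raise StackFormatError("ChannelStack requires at least one channel")
        shapes = set()
        for role, grid in self.channels.items():
            if role not in CHANNEL_ROLES:
                raise StackFormatError(
                    f"unknown channel role {role!r}; expected one of {CHANNEL_ROLES}"
                )
            grid = np.asarray(grid)
            if grid.ndim != 3:
                raise StackFormatError(f"channel {role!r} is not a 3D grid")
            if not np.all(np.isfinite(grid)):
                raise StackFormatError(f"channel {role!r} has non-finite values")
            if np.any(grid < 0):
                raise StackFormatError(f"channel {role!r} has negative intensities")
            self.channels[role] = grid
            shapes.add(grid.shape)
        if len(shapes) != 1:
            raise StackFormatError(f"channel grids differ in shape: {sorted(shapes)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def roles(self) -> tuple[str, ...]:
        return tuple(self.channels)

    def __getitem__(self, role: str) -> np.ndarray:
        return self.channels[role]


@dataclass
class LabelMap:
    """Integer-labelled 3D voxel grid; 0 is background, objects are 1..K."""

    labels: np.ndarray
    geometry: VoxelGeometry

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("LabelMap requires a 3D grid")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("LabelMap requires an integer dtype")
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("LabelMap labels must be non-negative")

    @property
    def n_objects(self) -> int:
        return len(self.label_values())

    def label_values(self) -> np.ndarray:
        vals = np.unique(self.labels)
        return vals[vals > 0]


# ---------------------------------------------------------------------------
# Tabular records (pandas-backed, fixed documented headers)
# ---------------------------------------------------------------------------

OBJECT_TABLE_COLUMNS = (
    "object_id",
    "channel",
    "centroid_x_um",
    "centroid_y_um",
    "centroid_z_um",
    "voxel_count",
    "volume_um3",
    "max_slice_area_um2",
    "mean_intensity",
    "region",
)

GROUND_TRUTH_COLUMNS = (
    "cell_id",
    "cell_type",
    "centre_x_um",
    "centre_y_um",
    "centre_z_um",
    "nucleus_radius_um",
    "cell_radius_um",
    "region",
    "ecm_contact",
)

BENCHMARK_REPORT_COLUMNS = (
    "dataset_id",
    "preset_name",
    "channel",
    "count",
    "reference_count",
    "relative_change_pct",
    "core_count",
    "mantle_count",
    "ecm_contact_count",
)


def make_object_table(rows: Sequence[Mapping] | None = None) -> pd.DataFrame:
    """Return an object table with the canonical column order."""
    df = pd.DataFrame(list(rows) if rows else [], columns=list(OBJECT_TABLE_COLUMNS))
    return df


def validate_object_table(
    table: pd.DataFrame, geometry: VoxelGeometry | None = None,
    shape: tuple[int, int, int] | None = None,
) -> pd.DataFrame:
    """Check the object-table invariants; returns the table unchanged.

    Volume must equal ``voxel_count × pixel_size_xy² × z_step`` and, when a
    grid shape is supplied, centroids must lie inside the physical bounds.
    """
    missing = set(OBJECT_TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"object table missing columns: {sorted(missing)}")
    if geometry is not None and len(table):
        expected = table["voxel_count"].to_numpy() * geometry.voxel_volume
        if not np.allclose(table["volume_um3"].to_numpy(), expected, rtol=1e-6):
            raise ValueError("volume_um3 inconsistent with voxel_count × voxel volume")
        if shape is not None:
            nz, ny, nx = shape
            bounds = (nx * geometry.pixel_size_xy, ny * geometry.pixel_size_xy,
                      nz * geometry.z_step)
            for col, hi in zip(("centroid_x_um", "centroid_y_um", "centroid_z_um"), bounds):
                v = table[col].to_numpy(dtype=float)
                if np.any(v < -geometry.pixel_size_xy) or np.any(v > hi):
                    raise ValueError(f"{col} outside physical bounds [0, {hi:g}]")
    return table


def validate_ground_truth(truth: pd.DataFrame) -> pd.DataFrame:
    missing = set(GROUND_TRUTH_COLUMNS) - set(truth.columns)
    if missing:
        raise ValueError(f"ground truth missing columns: {sorted(missing)}")
    if len(truth):
        bad = set(truth["cell_type"]) - set(CELL_TYPES)
        if bad:
            raise ValueError(f"unknown cell types: {sorted(bad)}")
    return truth


def write_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a table as CSV with its documented header, no index column."""
    table.to_csv(path, index=False)


def read_table(path: str | os.PathLike, columns: Sequence[str]) -> pd.DataFrame:
    """Read a CSV table and verify its header matches ``columns`` exactly."""
    df = pd.read_csv(path)
    if list(df.columns) != list(columns):
        raise ValueError(
            f"{path}: header {list(df.columns)} does not match expected {list(columns)}"
        )
    return df


# ---------------------------------------------------------------------------
# Pipeline configuration and the four software-emulating presets
# ---------------------------------------------------------------------------

PRESET_NAMES = ("fiji", "cellprofiler", "ga3", "imaris")


@dataclass
class PipelineConfig:
    """Every tunable of the segmentation presets, in one validated record.

    Each preset fixes the subset of fields its emulated software exposes;
    unused fields keep neutral defaults. Lengths are µm unless held in a
    :class:`Length` with a ``px`` tag.
    """

    preset_name: str = "custom"
    rescale: bool = False
    rolling_ball_radius: Length | None = None
    median_size: int | None = None
    log_sigma: float | None = None
    z_equalize: bool = False
    bg_gauss_length: dict[str, float] | None = None
    otsu_mode: str | None = "global"  # "global" | "adaptive" | None
    adaptive_block: int = 50
    manual_threshold: float | None = None
    min_voxels: int = 0
    min_area: float = 0.0  # µm², max single-slice cross-section
    spot_diameter: float | None = None  # µm
    surface_smoothness: float | None = None  # µm
    surface_bg_diameter: float | None = None  # µm
    split_diameter: float | None = None  # µm
    core_fraction: float = 0.8
    contact_max_distance: float = 0.0  # µm
    connectivity: int = 26

    def validate(self) -> "PipelineConfig":
        problems: list[str] = []
        if self.preset_name not in PRESET_NAMES + ("custom",):
            problems.append(f"preset_name: unknown {self.preset_name!r}")
        if not (0.0 < self.core_fraction < 1.0):
            problems.append(f"core_fraction: {self.core_fraction} not in (0, 1)")
        if (self.manual_threshold is None) == (self.otsu_mode is None):
            problems.append(
                "exactly one of manual_threshold and otsu_mode must drive binarization"
            )
        if self.otsu_mode not in (None, "global", "adaptive"):
            problems.append(f"otsu_mode: unknown {self.otsu_mode!r}")
        if self.connectivity not in (6, 18, 26):
            problems.append(f"connectivity: {self.connectivity} not in {{6, 18, 26}}")
        if self.median_size is not None and (
            self.median_size < 1 or self.median_size % 2 == 0
        ):
            problems.append(f"median_size: {self.median_size} must be odd and >= 1")
        for name in ("log_sigma", "spot_diameter", "surface_smoothness",
                     "surface_bg_diameter", "split_diameter"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                problems.append(f"{name}: {v} must be > 0")
        if self.adaptive_block < 2:
            problems.append(f"adaptive_block: {self.adaptive_block} must be >= 2")
        if self.min_voxels < 0:
            problems.append(f"min_voxels: {self.min_voxels} must be >= 0")
        if self.min_area < 0:
            problems.append(f"min_area: {self.min_area} must be >= 0")
        if self.contact_max_distance < 0:
            problems.append(f"contact_max_distance: {self.contact_max_distance} must be >= 0")
        if self.bg_gauss_length is not None:
            for role, v in self.bg_gauss_length.items():
                if role not in CHANNEL_ROLES:
                    problems.append(f"bg_gauss_length: unknown role {role!r}")
                elif not v > 0:
                    problems.append(f"bg_gauss_length[{role}]: {v} must be > 0")
        if problems:
            raise ConfigError("invalid PipelineConfig: " + "; ".join(problems))
        return self


def preset(name: str) -> PipelineConfig:
    """Return the parameterisation emulating one published software pipeline.

    ``fiji``          rolling ball 50 px, 3D object counter, voxel filter > 250.
    ``cellprofiler``  rescale to [0, 1], median filter 5, adaptive two-class Otsu.
    ``ga3``           rolling ball 27 µm, z equalisation, Laplacian-of-Gaussian
                      (sigma 2 px), 60 % core volume.
    ``imaris``        Gaussian background 60 µm (20 µm for ECM), 6 µm spots,
                      surfaces with 0.6 µm smoothness / 16 µm background
                      diameter / 8 µm split, 353 µm² size filter, 80 % core,
                      0 µm contact distance.
    """
    if name == "fiji":
        cfg = PipelineConfig(
            preset_name="fiji",
            rolling_ball_radius=Length(50, "px"),
            otsu_mode="global",
            min_voxels=250,
            connectivity=26,
        )
    elif name == "cellprofiler":
        cfg = PipelineConfig(
            preset_name="cellprofiler",
            rescale=True,
            median_size=5,
            otsu_mode="adaptive",
            adaptive_block=50,
        )
    elif name == "ga3":
        cfg = PipelineConfig(
            preset_name="ga3",
            rolling_ball_radius=Length(27, "um"),
            z_equalize=True,
            log_sigma=2.0,
            otsu_mode="global",
            core_fraction=0.60,
            contact_max_distance=0.0,
        )
    elif name == "imaris":
        cfg = PipelineConfig(
            preset_name="imaris",
            bg_gauss_length={"nuclei": 60.0, "insle": 60.0, "alpha": 60.0, "ecm": 20.0},
            z_equalize=True,
            otsu_mode="global",
            spot_diameter=6.0,
            surface_smoothness=0.6,
            surface_bg_diameter=16.0,
            split_diameter=8.0,
            min_area=353.0,
            core_fraction=0.80,
            contact_max_distance=0.0,
        )
    else:
        raise ConfigError(f"unknown preset {name!r}; expected one of {PRESET_NAMES}")
    return cfg.validate()


_LENGTH_FIELDS = {"rolling_ball_radius"}
_CONFIG_FIELDS = {f.name for f in PipelineConfig.__dataclass_fields__.values()}


def load_config(path: str | os.PathLike) -> PipelineConfig:
    """Load a flat key:value config file (YAML syntax) into a PipelineConfig.

    A ``preset_name`` key seeds the record from that preset; remaining keys
    override individual fields. Unknown keys are an error, not a warning.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a flat key:value mapping")
    unknown = set(raw) - _CONFIG_FIELDS
    if unknown:
        raise ConfigError(f"{path}: unknown config keys: {sorted(unknown)}")
    base_name = raw.get("preset_name", "custom")
    cfg = preset(base_name) if base_name in PRESET_NAMES else PipelineConfig()
    overrides = {}
    for key, value in raw.items():
        if key == "preset_name":
            overrides[key] = value
        elif key in _LENGTH_FIELDS and value is not None:
            overrides[key] = parse_length(value)
        else:
            overrides[key] = value
    return replace(cfg, **overrides).validate()


def save_config(cfg: PipelineConfig, path: str | os.PathLike) -> None:
    """Write a PipelineConfig as a flat key:value file readable by load_config."""
    out = {}
    for name in _CONFIG_FIELDS:
        value = getattr(cfg, name)
        if isinstance(value, Length):
            value = str(value)
        out[name] = value
    with open(path, "w") as fh:
        yaml.safe_dump(out, fh, default_flow_style=False, sort_keys=True)


# ---------------------------------------------------------------------------
# Stack IO (multi-page TIFF, one page per z-slice, channels interleaved)
# ---------------------------------------------------------------------------


def write_stack(stack: ChannelStack, path: str | os.PathLike) -> None:
    """Write a ChannelStack as a multi-page TIFF.

    Pages are ordered slice-major with channels fastest (z0/c0, z0/c1,
    z1/c0, ...), the ImageJ hyperstack convention. Integer dtypes
    round-trip bit-exactly through :func:`read_stack`; float dtypes to
    their native precision. Pixel-size metadata is stored as ImageJ-style
    resolution tags.
    """
    if not isinstance(stack, ChannelStack):
        raise TypeError("write_stack expects a ChannelStack")
    arr = np.stack([stack.channels[r] for r in stack.roles], axis=1)  # (Z, C, Y, X)
    g = stack.geometry
    tifffile.imwrite(
        path,
        arr,
        imagej=arr.dtype in (np.dtype("uint8"), np.dtype("uint16"), np.dtype("float32")),
        resolution=(1.0 / g.pixel_size_xy, 1.0 / g.pixel_size_xy),
        metadata={"spacing": g.z_step, "unit": "um", "axes": "ZCYX",
                  "channel_roles": ",".join(stack.roles)},
    )


def read_stack(
    path: str | os.PathLike | Sequence[str | os.PathLike],
    channel_roles: Sequence[str],
    geometry: VoxelGeometry,
) -> ChannelStack:
    """Read a multi-page TIFF (or one file per channel) into a ChannelStack.

    For a single file the page count must be divisible by the number of
    roles; pages are interpreted slice-major with channels fastest. The
    supplied geometry is stored as-is (TIFF metadata is not trusted for
    calibration).
    """
    roles = list(channel_roles)
    if not roles:
        raise StackFormatError("channel_roles must be non-empty")
    if isinstance(path, (str, os.PathLike)):
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(p)
        arr = tifffile.imread(p)
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim == 3:
            n_pages = arr.shape[0]
            if n_pages % len(roles) != 0:
                raise StackFormatError(
                    f"{p}: {n_pages} pages not divisible by {len(roles)} channels; "
                    "expected slice-major pages with channels interleaved"
                )
            arr = arr.reshape(n_pages // len(roles), len(roles), *arr.shape[1:])
        if arr.ndim != 4 or arr.shape[1] != len(roles):
            raise StackFormatError(
                f"{p}: array shape {arr.shape} does not match {len(roles)} channels"
            )
        channels = {role: np.ascontiguousarray(arr[:, i]) for i, role in enumerate(roles)}
    else:
        paths = [Path(q) for q in path]
        if len(paths) != len(roles):
            raise StackFormatError(
                f"{len(paths)} files supplied for {len(roles)} channel roles"
            )
        channels = {}
        for role, q in zip(roles, paths):
            if not q.exists():
                raise FileNotFoundError(q)
            grid = tifffile.imread(q)
            if grid.ndim == 2:
                grid = grid[None]
            if grid.ndim != 3:
                raise StackFormatError(f"{q}: expected a single-channel z-stack")
            channels[role] = grid
    return ChannelStack(channels=channels, geometry=geometry)
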