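"""Synthetic pseudoislet generator with exact ground truth.

Emulates the composition and imaging artifacts of a microwell-grown
pseudoislet: ~1500 cells at an Alpha TC1:INS1E:HUVEC seeding ratio of
1:9:5 packed into a spherical aggregate with touching cells and ~6 µm
nuclei, imaged as a four-channel z-stack with depth-dependent signal
attenuation, an anisotropic Gaussian PSF, a smooth low-frequency
background, and Poisson-then-Gaussian camera noise. HUVEC cells appear
in the nuclei channel only (they carry no cytoplasmic label), so the
nucleus count exceeds the labelled-cell count, as in the real assay.

Ground-truth centres are expressed in an aggregate-centred frame
(aggregate centre at the origin); :func:`truth_in_grid_frame` shifts
them into the physical frame of a rendered grid for comparison with
detected centroids.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from .core import (
    CELL_TYPES,
    ChannelStack,
    ConfigError,
    GROUND_TRUTH_COLUMNS,
    VoxelGeometry,
    validate_ground_truth,
)

__all__ = [
    "SimulationConfig",
    "apportion",
    "place_cells",
    "assign_truth_regions",
    "synthesize_ecm",
    "render",
    "simulate_dataset",
    "truth_in_grid_frame",
    "default_shape",
]

log = logging.getLogger(__name__)

#: Densest effective hard-sphere packing the placement algorithm attempts;
#: requests beyond it raise with the maximum feasible cell count.
PACKING_LIMIT = 0.45


@dataclass
class SimulationConfig:
    """Study conditions of one synthetic pseudoislet.

    Defaults emulate the seeding protocol (1500 cells at 1:9:5) and the
    imaging regime: 6 µm nuclei in ~7 µm cells packed to touching inside
    a 55 µm-radius aggregate, exponential depth attenuation, a mildly
    anisotropic PSF, a smooth background at 10 % of peak signal, and
    shot noise at ~200 photons per unit intensity.
    """

    n_cells: int = 1500
    type_ratio: tuple[int, int, int] = (1, 9, 5)  # alpha : insle : huvec
    aggregate_radius: float = 55.0  # µm
    nucleus_radius: float = 3.0  # µm (6 µm diameter)
    cell_radius: float = 3.5  # µm
    contact_fraction: float = 0.8  # centres >= fraction × (sum of radii)
    mantle_layers: int = 2
    ecm_fibre_count: int = 40
    fibre_radius: float = 0.5  # µm
    attenuation_length: float = 50.0  # µm; inf disables
    psf_sigma_xy: float = 0.4  # µm; 0 disables
    psf_sigma_z: float = 1.0  # µm
    background_amplitude: float = 0.1  # fraction of peak signal
    noise_photons: float = 200.0  # Poisson scale; 0 disables
    noise_read_sigma: float = 0.01  # Gaussian read noise; 0 disables
    seed: int = 0

    def __post_init__(self) -> None:
        problems = []
        if self.n_cells < 0:
            problems.append("n_cells must be >= 0")
        if len(self.type_ratio) != 3 or any(
            int(r) != r or r <= 0 for r in self.type_ratio
        ):
            problems.append("type_ratio must be three positive integers")
        if not self.nucleus_radius <= self.cell_radius:
            problems.append("nucleus_radius must not exceed cell_radius")
        for name in ("aggregate_radius", "nucleus_radius", "cell_radius",
                     "fibre_radius", "attenuation_length"):
            if not getattr(self, name) > 0:
                problems.append(f"{name} must be > 0")
        if not (0.0 < self.contact_fraction <= 1.0):
            problems.append("contact_fraction must be in (0, 1]")
        if self.mantle_layers < 0 or self.ecm_fibre_count < 0:
            problems.append("mantle_layers and ecm_fibre_count must be >= 0")
        for name in ("psf_sigma_xy", "psf_sigma_z", "background_amplitude",
                     "noise_photons", "noise_read_sigma"):
            if getattr(self, name) < 0:
                problems.append(f"{name} must be >= 0")
        if problems:
            raise ConfigError("invalid SimulationConfig: " + "; ".join(problems))


def apportion(n: int, ratio: tuple[int, ...]) -> list[int]:
    """Apportion ``n`` into parts proportional to ``ratio`` (largest remainder)."""
    total = sum(ratio)
    quotas = [n * r / total for r in ratio]
    counts = [math.floor(q) for q in quotas]
    remainders = [q - c for q, c in zip(quotas, counts)]
    for i in sorted(range(len(ratio)), key=lambda i: -remainders[i])[: n - sum(counts)]:
        counts[i] += 1
    return counts


# ---------------------------------------------------------------------------
# Cell placement
# ---------------------------------------------------------------------------


def _random_in_sphere(rng: np.random.Generator, radius: float, size: int) -> np.ndarray:
    pts = rng.normal(size=(size, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    r = radius * rng.random(size) ** (1.0 / 3.0)
    return pts * r[:, None]


def place_cells(cfg: SimulationConfig) -> pd.DataFrame:
    """Pack ``cfg.n_cells`` cell centres into the aggregate sphere.

    Dart-throwing (random sequential placement with a minimum separation
    of ``contact_fraction × 2 × cell_radius``) with a repulsion-relaxation
    fallback when darts alone stall; deterministic given ``cfg.seed``.
    Cell types are apportioned by ``type_ratio`` with largest-remainder
    rounding and assigned to positions in a seeded shuffle. Raises when
    the requested count exceeds the feasible packing, naming the maximum
    feasible count.
    """
    rng = np.random.default_rng([cfg.seed, 101])
    n = cfg.n_cells
    columns = list(GROUND_TRUTH_COLUMNS)
    if n == 0:
        return pd.DataFrame([], columns=columns)
    r_min = cfg.contact_fraction * 2.0 * cfg.cell_radius
    r_avail = cfg.aggregate_radius - cfg.nucleus_radius
    if r_avail <= 0:
        raise ConfigError("aggregate_radius too small to hold a nucleus")
    packing = n * (r_min / 2.0) ** 3 / r_avail**3
    if packing > PACKING_LIMIT:
        n_max = int(PACKING_LIMIT * (r_avail / (r_min / 2.0)) ** 3)
        raise ConfigError(
            f"infeasible packing: {n} cells at effective packing {packing:.2f} "
            f"exceeds {PACKING_LIMIT}; at most {n_max} cells fit this aggregate"
        )
    centres = _dart_throw(rng, n, r_min, r_avail)
    if centres is None:
        centres = _relax(rng, n, r_min, r_avail)
    counts = apportion(n, tuple(cfg.type_ratio))
    types = np.repeat(np.array(CELL_TYPES), counts)
    rng.shuffle(types)
    truth = pd.DataFrame({
        "cell_id": np.arange(1, n + 1),
        "cell_type": types,
        "centre_x_um": centres[:, 0],
        "centre_y_um": centres[:, 1],
        "centre_z_um": centres[:, 2],
        "nucleus_radius_um": cfg.nucleus_radius,
        "cell_radius_um": cfg.cell_radius,
        "region": "core",
        "ecm_contact": False,
    })[columns]
    return validate_ground_truth(truth)


def _dart_throw(
    rng: np.random.Generator, n: int, r_min: float, r_avail: float,
    max_attempts_per_cell: int = 300,
) -> np.ndarray | None:
    cell = r_min  # hash-grid pitch: only neighbouring bins can conflict
    grid: dict[tuple[int, int, int], list[int]] = {}
    placed = np.empty((n, 3))
    k = 0
    budget = n * max_attempts_per_cell
    while k < n and budget > 0:
        p = _random_in_sphere(rng, r_avail, 1)[0]
        budget -= 1
        key = tuple((p // cell).astype(int))
        ok = True
        for dz in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    for idx in grid.get((key[0] + dz, key[1] + dy, key[2] + dx), ()):
                        if np.sum((placed[idx] - p) ** 2) < r_min**2:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            placed[k] = p
            grid.setdefault(key, []).append(k)
            k += 1
    if k == n:
        return placed
    log.debug("dart throwing stalled at %d/%d cells; relaxing", k, n)
    return None


def _relax(
    rng: np.random.Generator, n: int, r_min: float, r_avail: float,
    max_iter: int = 400,
) -> np.ndarray:
    """Lloyd-style fallback: push overlapping centres apart iteratively."""
    pts = _random_in_sphere(rng, r_avail, n)
    for it in range(max_iter):
        tree = cKDTree(pts)
        pairs = tree.query_pairs(r_min, output_type="ndarray")
        if len(pairs) == 0:
            return pts
        shift = np.zeros_like(pts)
        vec = pts[pairs[:, 0]] - pts[pairs[:, 1]]
        d = np.linalg.norm(vec, axis=1)
        zero = d < 1e-12
        if zero.any():
            vec[zero] = rng.normal(size=(int(zero.sum()), 3))
            d[zero] = np.linalg.norm(vec[zero], axis=1)
        push = (r_min - d) / 2.0 * 1.05 / d
        np.add.at(shift, pairs[:, 0], vec * push[:, None])
        np.add.at(shift, pairs[:, 1], -vec * push[:, None])
        pts = pts + shift
        norms = np.linalg.norm(pts, axis=1)
        outside = norms > r_avail
        pts[outside] *= (r_avail / norms[outside])[:, None]
    raise ConfigError(
        f"infeasible packing: relaxation failed to separate {n} cells at "
        f"minimum distance {r_min:.2f} µm inside radius {r_avail:.2f} µm"
    )


# ---------------------------------------------------------------------------
# Region and ECM ground truth
# ---------------------------------------------------------------------------


def assign_truth_regions(truth: pd.DataFrame, cfg: SimulationConfig) -> pd.DataFrame:
    """Label each cell core/mantle from its depth below the aggregate surface.

    A cell is mantle iff its centre lies within ``mantle_layers × 2 ×
    cell_radius`` µm of the aggregate surface (the peripheral-cell-layer
    convention); deeper cells are core. Operates in the aggregate-centred
    frame.
    """
    if len(truth) == 0:
        return truth.copy()
    out = truth.copy()
    centres = out[["centre_x_um", "centre_y_um", "centre_z_um"]].to_numpy(float)
    depth = cfg.aggregate_radius - np.linalg.norm(centres, axis=1)
    shell = cfg.mantle_layers * 2.0 * cfg.cell_radius
    out["region"] = np.where(depth <= shell, "mantle", "core")
    return out


def _fibre_polylines(cfg: SimulationConfig, rng: np.random.Generator) -> list[np.ndarray]:
    """Random-walk polylines confined to the aggregate sphere."""
    fibres = []
    r_conf = 0.95 * cfg.aggregate_radius
    step = max(cfg.aggregate_radius / 3.0, 4.0)
    for _ in range(cfg.ecm_fibre_count):
        p = _random_in_sphere(rng, 0.8 * cfg.aggregate_radius, 1)[0]
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        pts = [p]
        for _ in range(6):
            d = d + 0.6 * rng.normal(size=3)
            d /= np.linalg.norm(d)
            q = pts[-1] + step * d
            if np.linalg.norm(q) > r_conf:  # reflect back toward the centre
                d = -q / np.linalg.norm(q)
                q = pts[-1] + step * d
            pts.append(q)
        fibres.append(np.array(pts))
    return fibres


def _grid_centre_um(shape: tuple[int, int, int], geometry: VoxelGeometry) -> np.ndarray:
    """Physical (x, y, z) of the grid centre."""
    nz, ny, nx = shape
    return np.array([nx * geometry.pixel_size_xy,
                     ny * geometry.pixel_size_xy,
                     nz * geometry.z_step]) / 2.0


def default_shape(cfg: SimulationConfig, geometry: VoxelGeometry,
                  margin_um: float = 4.0) -> tuple[int, int, int]:
    """Grid shape (z, y, x) covering the aggregate plus a margin."""
    extent = 2.0 * (cfg.aggregate_radius + margin_um)
    return (int(math.ceil(extent / geometry.z_step)),
            int(math.ceil(extent / geometry.pixel_size_xy)),
            int(math.ceil(extent / geometry.pixel_size_xy)))


def synthesize_ecm(
    truth: pd.DataFrame,
    cfg: SimulationConfig,
    geometry: VoxelGeometry,
    shape: tuple[int, int, int] | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Voxelize random collagen-like fibres and set per-cell contact flags.

    Fibres are random polyline tubes of radius ``fibre_radius`` inside
    the aggregate, deterministic given the seed. A cell's
    ``ecm_contact`` flag is true iff its cell sphere contains at least
    one fibre voxel centre (surface distance <= 0, the 0 µm overlap
    criterion).
    """
    rng = np.random.default_rng([cfg.seed, 202])
    if shape is None:
        shape = default_shape(cfg, geometry)
    grid = np.zeros(shape, dtype=np.float64)
    offset = _grid_centre_um(shape, geometry)
    fibres = _fibre_polylines(cfg, rng)
    spacing = np.array([geometry.z_step, geometry.pixel_size_xy, geometry.pixel_size_xy])
    for poly in fibres:
        for a, b in zip(poly[:-1], poly[1:]):
            _rasterize_segment(grid, a + offset, b + offset, cfg.fibre_radius, spacing)
    out = truth.copy()
    if len(out):
        fibre_vox = np.argwhere(grid > 0)
        if len(fibre_vox):
            # voxel-centre physical coordinates, (x, y, z)
            fibre_xyz = np.stack([
                fibre_vox[:, 2] * geometry.pixel_size_xy,
                fibre_vox[:, 1] * geometry.pixel_size_xy,
                fibre_vox[:, 0] * geometry.z_step,
            ], axis=1)
            tree = cKDTree(fibre_xyz)
            centres = out[["centre_x_um", "centre_y_um", "centre_z_um"]].to_numpy(float)
            d, _ = tree.query(centres + offset[None, :])
            out["ecm_contact"] = d <= out["cell_radius_um"].to_numpy(float)
        else:
            out["ecm_contact"] = False
    return grid, out


def _rasterize_segment(
    grid: np.ndarray, a_xyz: np.ndarray, b_xyz: np.ndarray,
    radius: float, spacing_zyx: np.ndarray,
) -> None:
    """Set to 1 all voxels whose centre is within ``radius`` of segment ab."""
    a = a_xyz[::-1] / spacing_zyx  # to (z, y, x) voxel coordinates
    b = b_xyz[::-1] / spacing_zyx
    r_vox = radius / spacing_zyx
    lo = np.maximum(np.floor(np.minimum(a, b) - r_vox - 1).astype(int), 0)
    hi = np.minimum(np.ceil(np.maximum(a, b) + r_vox + 2).astype(int),
                    np.array(grid.shape))
    if np.any(lo >= hi):
        return
    zz, yy, xx = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij")
    pts = np.stack([zz, yy, xx], axis=-1) * spacing_zyx  # µm, (z, y, x)
    a_um, b_um = a * spacing_zyx, b * spacing_zyx
    ab = b_um - a_um
    denom = float(ab @ ab)
    if denom < 1e-12:
        t = np.zeros(pts.shape[:-1])
    else:
        t = np.clip(((pts - a_um) @ ab) / denom, 0.0, 1.0)
    closest = a_um + t[..., None] * ab
    d2 = np.sum((pts - closest) ** 2, axis=-1)
    sub = grid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    sub[d2 <= radius**2] = 1.0


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _add_sphere_shell(
    grid: np.ndarray, centre_xyz_um: np.ndarray, r_inner: float, r_outer: float,
    geometry: VoxelGeometry, amplitude: float = 1.0,
) -> None:
    """Add an (anti-aliased) spherical shell ``r_inner <= d <= r_outer``."""
    spacing = np.array(geometry.spacing_zyx)
    c = centre_xyz_um[::-1] / spacing  # (z, y, x) voxel coordinates
    r_vox = r_outer / spacing
    lo = np.maximum(np.floor(c - r_vox - 1).astype(int), 0)
    hi = np.minimum(np.ceil(c + r_vox + 2).astype(int), np.array(grid.shape))
    if np.any(lo >= hi):
        return
    zz, yy, xx = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij")
    pts = np.stack([zz, yy, xx], axis=-1) * spacing
    d = np.sqrt(np.sum((pts - c * spacing) ** 2, axis=-1))
    w = float(min(spacing)) / 2.0  # anti-aliasing edge half-width
    outer = np.clip((r_outer - d) / (2 * w) + 0.5, 0.0, 1.0)
    if r_inner > 0:
        inner = np.clip((d - r_inner) / (2 * w) + 0.5, 0.0, 1.0)
        val = outer * inner
    else:
        val = outer
    sub = grid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    np.maximum(sub, amplitude * val, out=sub)


def render(
    truth: pd.DataFrame,
    cfg: SimulationConfig,
    geometry: VoxelGeometry,
    shape: tuple[int, int, int] | None = None,
    ecm_grid: np.ndarray | None = None,
) -> ChannelStack:
    """Render ground truth into a four-channel stack with imaging artifacts.

    Channels: ``nuclei`` holds a spherical nucleus kernel for every cell;
    ``insle`` and ``alpha`` hold cytoplasmic shells for cells of that
    type only (HUVECs are unlabelled); ``ecm`` is the fibre grid. Each
    channel is attenuated by ``exp(-depth / attenuation_length)``,
    convolved with the anisotropic Gaussian PSF, offset by a smooth
    low-frequency background, and corrupted by Poisson-then-Gaussian
    noise. Deterministic given ``cfg.seed``.
    """
    if cfg.nucleus_radius < geometry.pixel_size_xy or cfg.nucleus_radius < geometry.z_step:
        raise ConfigError(
            f"geometry too coarse: nucleus radius {cfg.nucleus_radius} µm is "
            f"below one voxel ({geometry.pixel_size_xy} × {geometry.z_step} µm)"
        )
    if shape is None:
        shape = default_shape(cfg, geometry)
    if ecm_grid is None:
        ecm_grid, truth = synthesize_ecm(truth, cfg, geometry, shape)
    offset = _grid_centre_um(shape, geometry)
    channels = {role: np.zeros(shape, dtype=np.float64)
                for role in ("nuclei", "insle", "alpha")}
    for _, row in truth.iterrows():
        centre = np.array([row["centre_x_um"], row["centre_y_um"],
                           row["centre_z_um"]]) + offset
        _add_sphere_shell(channels["nuclei"], centre, 0.0,
                          row["nucleus_radius_um"], geometry)
        if row["cell_type"] in ("insle", "alpha"):
            _add_sphere_shell(channels[row["cell_type"]], centre,
                              row["nucleus_radius_um"], row["cell_radius_um"],
                              geometry)
    channels["ecm"] = np.asarray(ecm_grid, dtype=np.float64).copy()
    rng = np.random.default_rng([cfg.seed, 303])
    if math.isfinite(cfg.attenuation_length):
        depth = np.arange(shape[0]) * geometry.z_step
        decay = np.exp(-depth / cfg.attenuation_length)[:, None, None]
    else:
        decay = None
    psf_vox = (cfg.psf_sigma_z / geometry.z_step,
               cfg.psf_sigma_xy / geometry.pixel_size_xy,
               cfg.psf_sigma_xy / geometry.pixel_size_xy)
    background = _smooth_background(shape, cfg.background_amplitude, rng)
    for role in ("nuclei", "insle", "alpha", "ecm"):
        g = channels[role]
        if decay is not None:
            g *= decay
        if max(psf_vox) > 0:
            g = ndi.gaussian_filter(g, sigma=psf_vox, mode="constant")
        if background is not None:
            g = g + background
        if cfg.noise_photons > 0:
            g = rng.poisson(np.clip(g, 0, None) * cfg.noise_photons) / cfg.noise_photons
        if cfg.noise_read_sigma > 0:
            g = g + rng.normal(0.0, cfg.noise_read_sigma, size=shape)
        channels[role] = np.clip(g, 0.0, None).astype(np.float32)
    return ChannelStack(channels=channels, geometry=geometry)


def _smooth_background(
    shape: tuple[int, int, int], amplitude: float, rng: np.random.Generator
) -> np.ndarray | None:
    """z-constant haze: low-order polynomial in (x, y), scaled to [0, amplitude]."""
    if amplitude <= 0:
        return None
    ny, nx = shape[1], shape[2]
    y = np.linspace(-1, 1, ny)[:, None]
    x = np.linspace(-1, 1, nx)[None, :]
    c = rng.normal(size=6)
    p = c[0] + c[1] * x + c[2] * y + c[3] * x * y + c[4] * x**2 + c[5] * y**2
    p = (p - p.min()) / max(p.max() - p.min(), 1e-12)
    return np.broadcast_to(amplitude * p, shape).copy()


def truth_in_grid_frame(
    truth: pd.DataFrame, shape: tuple[int, int, int], geometry: VoxelGeometry
) -> pd.DataFrame:
    """Shift aggregate-centred truth centres into a grid's physical frame."""
    out = truth.copy()
    offset = _grid_centre_um(shape, geometry)
    for col, off in zip(("centre_x_um", "centre_y_um", "centre_z_um"), offset):
        out[col] = out[col] + off
    return out


def simulate_dataset(
    cfg: SimulationConfig,
    geometry: VoxelGeometry,
    shape: tuple[int, int, int] | None = None,
) -> tuple[ChannelStack, pd.DataFrame]:
    """Full simulation: placement, regions, ECM, rendering.

    Returns the rendered stack and the ground truth with centres in the
    grid frame (directly comparable to detected centroids).
    """
    truth = place_cells(cfg)
    truth = assign_truth_regions(truth, cfg)
    if shape is None:
        shape = default_shape(cfg, geometry)
    ecm_grid, truth = synthesize_ecm(truth, cfg, geometry, shape)
    stack = render(truth, cfg, geometry, shape=shape, ecm_grid=ecm_grid)
    return stack, truth_in_grid_frame(truth, shape, geometry)
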