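"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately naive (loops, exhaustive enumeration)
and shares no code path with the package implementation it checks.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np

_OFFSETS = {
    6: [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
        if abs(dz) + abs(dy) + abs(dx) == 1],
    18: [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
         if 0 < abs(dz) + abs(dy) + abs(dx) <= 2],
    26: [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
         if (dz, dy, dx) != (0, 0, 0)],
}


def flood_fill_label(binary: np.ndarray, connectivity: int) -> np.ndarray:
    """Connected-component labelling by breadth-first flood fill."""
    binary = np.asarray(binary, dtype=bool)
    labels = np.zeros(binary.shape, dtype=np.int32)
    offsets = _OFFSETS[connectivity]
    next_label = 0
    for start in zip(*np.nonzero(binary)):
        if labels[start]:
            continue
        next_label += 1
        labels[start] = next_label
        queue = deque([start])
        while queue:
            z, y, x = queue.popleft()
            for dz, dy, dx in offsets:
                nz, ny, nx = z + dz, y + dy, x + dx
                if (0 <= nz < binary.shape[0] and 0 <= ny < binary.shape[1]
                        and 0 <= nx < binary.shape[2]
                        and binary[nz, ny, nx] and not labels[nz, ny, nx]):
                    labels[nz, ny, nx] = next_label
                    queue.append((nz, ny, nx))
    return labels


def same_partition(a: np.ndarray, b: np.ndarray) -> bool:
    """True iff two label maps agree up to a relabelling of object ids."""
    if (a > 0).tolist() != (b > 0).tolist():
        return False
    mapping: dict[int, int] = {}
    reverse: dict[int, int] = {}
    for va, vb in zip(a.ravel(), b.ravel()):
        if va == 0:
            continue
        if mapping.setdefault(int(va), int(vb)) != vb:
            return False
        if reverse.setdefault(int(vb), int(va)) != va:
            return False
    return True


def exhaustive_otsu_discrete(grid: np.ndarray) -> float:
    """Otsu threshold of an integer-valued grid by trying every level."""
    values = np.asarray(grid, dtype=float).ravel()
    candidates = np.unique(values)
    best_thr, best_var = candidates[0], -1.0
    for thr in candidates:
        below = values[values <= thr]
        above = values[values > thr]
        if below.size == 0 or above.size == 0:
            continue
        w0, w1 = below.size / values.size, above.size / values.size
        var = w0 * w1 * (below.mean() - above.mean()) ** 2
        if var > best_var + 1e-15:
            best_var = var
            best_thr = thr
    return float(best_thr)


def brute_median(grid: np.ndarray, size: int) -> np.ndarray:
    """Cubic-neighbourhood median with reflected edges, voxel by voxel."""
    r = size // 2
    padded = np.pad(grid, r, mode="symmetric")  # edge-repeating reflection
    out = np.empty_like(np.asarray(grid, dtype=float))
    for z in range(grid.shape[0]):
        for y in range(grid.shape[1]):
            for x in range(grid.shape[2]):
                out[z, y, x] = np.median(
                    padded[z:z + size, y:y + size, x:x + size]
                )
    return out


def ball_opening_2d(img: np.ndarray, radius: float) -> np.ndarray:
    """Grayscale opening with a non-flat ball element by exhaustive min-max."""
    r = int(np.ceil(radius))
    ys, xs = np.mgrid[-r:r + 1, -r:r + 1]
    inside = ys**2 + xs**2 <= radius**2
    height = np.where(
        inside, np.sqrt(np.maximum(radius**2 - ys**2 - xs**2, 0.0)), np.nan
    )
    offs = [(dy, dx, height[dy + r, dx + r])
            for dy in range(-r, r + 1) for dx in range(-r, r + 1)
            if inside[dy + r, dx + r]]
    h, w = img.shape
    eroded = np.empty_like(np.asarray(img, dtype=float))
    for y in range(h):
        for x in range(w):
            vals = [img[y + dy, x + dx] - hv for dy, dx, hv in offs
                    if 0 <= y + dy < h and 0 <= x + dx < w]
            eroded[y, x] = min(vals)
    opened = np.empty_like(eroded)
    for y in range(h):
        for x in range(w):
            vals = [eroded[y + dy, x + dx] + hv for dy, dx, hv in offs
                    if 0 <= y + dy < h and 0 <= x + dx < w]
            opened[y, x] = max(vals)
    return opened


def log_kernel_2d(sigma: float, half_size: int) -> np.ndarray:
    """Sampled negated Laplacian-of-Gaussian kernel (impulse response)."""
    import scipy.ndimage as _ndi

    size = 2 * half_size + 1
    impulse = np.zeros((size, size))
    impulse[half_size, half_size] = 1.0
    return -_ndi.gaussian_laplace(impulse, sigma=sigma, mode="constant")


def brute_measurements(labels: np.ndarray, intensity: np.ndarray, spacing_zyx):
    """Per-object centroid/size/intensity stats by per-voxel accumulation."""
    sz, sy, sx = spacing_zyx
    out = {}
    for lab in np.unique(labels):
        if lab == 0:
            continue
        voxels = np.argwhere(labels == lab)
        weights = np.array([intensity[tuple(v)] for v in voxels], dtype=float)
        if weights.sum() > 0:
            centroid_vox = (voxels * weights[:, None]).sum(0) / weights.sum()
        else:
            centroid_vox = voxels.mean(0)
        slice_counts = {}
        for v in voxels:
            slice_counts[v[0]] = slice_counts.get(v[0], 0) + 1
        out[int(lab)] = {
            "voxel_count": len(voxels),
            "volume": len(voxels) * sz * sy * sx,
            "centroid_xyz": (centroid_vox[2] * sx, centroid_vox[1] * sy,
                             centroid_vox[0] * sz),
            "max_slice_area": max(slice_counts.values()) * sy * sx,
            "mean_intensity": float(weights.mean()),
        }
    return out


def brute_contacts(
    child_labels: np.ndarray, parent_labels: np.ndarray, spacing_zyx,
    max_distance: float, touching_counts: bool = True,
):
    """Interacting child ids by all-pairs voxel-centre distances."""
    spacing = np.asarray(spacing_zyx, dtype=float)
    parents = np.argwhere(parent_labels > 0) * spacing
    interacting = set()
    for cid in np.unique(child_labels):
        if cid == 0:
            continue
        child_vox = np.argwhere(child_labels == cid)
        if len(parents) == 0:
            continue
        child = child_vox * spacing
        d = np.sqrt(((child[:, None, :] - parents[None, :, :]) ** 2).sum(-1))
        d_min = d.min()
        if max_distance == 0:
            if touching_counts:
                # overlap or 26-adjacency in voxel index space
                parent_idx = np.argwhere(parent_labels > 0)
                diff = np.abs(child_vox[:, None, :] - parent_idx[None, :, :]).max(-1)
                if (diff <= 1).any():
                    interacting.add(int(cid))
            elif d_min == 0:
                interacting.add(int(cid))
        elif d_min <= max_distance:
            interacting.add(int(cid))
    return interacting


def brute_match(det_xyz: np.ndarray, truth_xyz: np.ndarray, radius: float):
    """Optimal matching by enumerating every injective assignment.

    Returns (best_n_pairs, best_total_distance). Feasible only for
    min(n_det, n_truth) <= 8.
    """
    n_d, n_t = len(det_xyz), len(truth_xyz)
    if n_d == 0 or n_t == 0:
        return 0, 0.0
    dist = np.sqrt(((det_xyz[:, None, :] - truth_xyz[None, :, :]) ** 2).sum(-1))
    best = (0, 0.0)
    swap = n_d > n_t
    small, big = (n_t, n_d) if swap else (n_d, n_t)
    for perm in itertools.permutations(range(big), small):
        pairs = [(i, perm[i]) for i in range(small)]
        if swap:
            pairs = [(j, i) for i, j in pairs]
        admissible = [(i, j) for i, j in pairs if dist[i, j] <= radius]
        total = sum(dist[i, j] for i, j in admissible)
        key = (len(admissible), -total)
        if key > (best[0], -best[1]):
            best = (len(admissible), total)
    return best
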