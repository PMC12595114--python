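"""Independent brute-force oracles used to verify the fast implementations.

Everything here is written for clarity, not speed: exhaustive neighbourhood
enumeration, all-pairs minima, breadth-first flood fill. These never share
code with the package.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def disk_offsets(radius: int) -> list[tuple[int, int]]:
    return [
        (dy, dx)
        for dy in range(-radius, radius + 1)
        for dx in range(-radius, radius + 1)
        if dy * dy + dx * dx <= radius * radius
    ]


def brute_median_slicewise(data: np.ndarray, radius: int) -> np.ndarray:
    """Per-voxel median over the 2D disk in its own z-slice (reflect border)."""
    r = radius
    # scipy's "reflect" boundary duplicates the edge sample = numpy "symmetric"
    pad = np.pad(data, ((0, 0), (r, r), (r, r)), mode="symmetric")
    offs = disk_offsets(r)
    out = np.empty_like(data)
    for z in range(data.shape[0]):
        for y in range(data.shape[1]):
            for x in range(data.shape[2]):
                vals = [pad[z, y + r + dy, x + r + dx] for dy, dx in offs]
                out[z, y, x] = np.median(vals)
    return out


def brute_opening_slicewise(data: np.ndarray, radius: int) -> np.ndarray:
    """Greyscale opening (erosion then dilation) with a flat disk, per slice."""
    r = radius
    offs = disk_offsets(r)

    def erode(plane):
        pad = np.pad(plane, r, mode="reflect")
        out = np.empty_like(plane)
        for y in range(plane.shape[0]):
            for x in range(plane.shape[1]):
                out[y, x] = min(pad[y + r + dy, x + r + dx] for dy, dx in offs)
        return out

    def dilate(plane):
        pad = np.pad(plane, r, mode="reflect")
        out = np.empty_like(plane)
        for y in range(plane.shape[0]):
            for x in range(plane.shape[1]):
                out[y, x] = max(pad[y + r + dy, x + r + dx] for dy, dx in offs)
        return out

    return np.stack([dilate(erode(data[z])) for z in range(data.shape[0])])


_CONN_OFFSETS = {
    6: [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
        if abs(dz) + abs(dy) + abs(dx) == 1],
    18: [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
         if 0 < abs(dz) + abs(dy) + abs(dx) <= 2],
    26: [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
         if (dz, dy, dx) != (0, 0, 0)],
}


def flood_fill_labels(mask: np.ndarray, connectivity: int = 26) -> np.ndarray:
    """Breadth-first connected-component labelling."""
    offs = _CONN_OFFSETS[connectivity]
    labels = np.zeros(mask.shape, dtype=np.int32)
    next_label = 0
    for seed in zip(*np.nonzero(mask)):
        if labels[seed]:
            continue
        next_label += 1
        labels[seed] = next_label
        queue = deque([seed])
        while queue:
            z, y, x = queue.popleft()
            for dz, dy, dx in offs:
                n = (z + dz, y + dy, x + dx)
                if (0 <= n[0] < mask.shape[0] and 0 <= n[1] < mask.shape[1]
                        and 0 <= n[2] < mask.shape[2] and mask[n] and not labels[n]):
                    labels[n] = next_label
                    queue.append(n)
    return labels


def same_partition(a: np.ndarray, b: np.ndarray) -> bool:
    """Whether two label maps induce the same partition of the foreground."""
    if not np.array_equal(a > 0, b > 0):
        return False
    pairs = set(zip(a[a > 0].ravel(), b[a > 0].ravel()))
    return len(pairs) == len({p[0] for p in pairs}) == len({p[1] for p in pairs})


def brute_distance_map(mask: np.ndarray, spacing) -> np.ndarray:
    """All-pairs minimum physical distance from every voxel to the foreground."""
    sp = np.asarray(spacing, dtype=float)
    coords = np.argwhere(mask) * sp
    out = np.empty(mask.shape, dtype=float)
    for idx in np.ndindex(mask.shape):
        p = np.asarray(idx) * sp
        out[idx] = np.sqrt(((coords - p) ** 2).sum(axis=1)).min()
    return out


def brute_local_thickness(mask: np.ndarray, spacing) -> np.ndarray:
    """Exhaustive inscribed-sphere local thickness.

    r(c) = distance from a foreground voxel centre c to the nearest
    background voxel centre; thickness(p) = 2·max{r(c) : |p − c|² ≤ r(c)² + ε}.
    """
    sp = np.asarray(spacing, dtype=float)
    fg = np.argwhere(mask)
    bg = np.argwhere(~mask)
    out = np.zeros(mask.shape, dtype=float)
    if fg.size == 0:
        return out
    fg_um = fg * sp
    bg_um = bg * sp
    r = np.empty(len(fg))
    for i, c in enumerate(fg_um):
        r[i] = np.sqrt(((bg_um - c) ** 2).sum(axis=1)).min() if len(bg_um) else np.inf
    for i, p in enumerate(fg_um):
        d2 = ((fg_um - p) ** 2).sum(axis=1)
        contains = d2 <= r * r + 1e-9
        out[tuple(fg[i])] = 2.0 * r[contains].max()
    return out


def brute_contact_area(obj: np.ndarray, ves: np.ndarray, spacing) -> float:
    """Exhaustive enumeration of object faces adjacent to vessel-only voxels."""
    dz, dy, dx = spacing
    areas = {0: dy * dx, 1: dz * dx, 2: dz * dy}
    ves_only = (ves != 0) & ~(obj != 0)
    total = 0.0
    for z, y, x in zip(*np.nonzero(obj)):
        for axis, (oz, oy, ox) in enumerate([(1, 0, 0), (0, 1, 0), (0, 0, 1)]):
            for s in (-1, 1):
                n = (z + s * oz, y + s * oy, x + s * ox)
                if (0 <= n[0] < obj.shape[0] and 0 <= n[1] < obj.shape[1]
                        and 0 <= n[2] < obj.shape[2] and ves_only[n]):
                    total += areas[axis]
    return total
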