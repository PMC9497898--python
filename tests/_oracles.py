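"""Independent brute-force oracles for texture matrices and ICC.

Deliberately naive O(N * directions) implementations — plain Python loops,
flood fills and pair enumeration — sharing no code with the package's
vectorized versions.
"""

from __future__ import annotations

import numpy as np


def brute_glcm(levels: np.ndarray, direction, symmetric: bool = True) -> np.ndarray:
    """Co-occurrence counts by explicit pair enumeration (level 0 = outside)."""
    G = int(levels.max())
    counts = np.zeros((G, G), dtype=np.int64)
    shape = levels.shape
    dx, dy, dz = direction
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                a = levels[x, y, z]
                if a == 0:
                    continue
                nx, ny, nz = x + dx, y + dy, z + dz
                if not (0 <= nx < shape[0] and 0 <= ny < shape[1] and 0 <= nz < shape[2]):
                    continue
                b = levels[nx, ny, nz]
                if b == 0:
                    continue
                counts[a - 1, b - 1] += 1
    if symmetric:
        counts = counts + counts.T
    return counts


def brute_glrlm(levels: np.ndarray, direction) -> np.ndarray:
    """Run counts by walking every line voxel by voxel."""
    G = int(levels.max())
    shape = levels.shape
    maxlen = max(shape)
    counts = np.zeros((G, maxlen), dtype=np.int64)
    d = np.array(direction)

    def in_bounds(p):
        return all(0 <= p[i] < shape[i] for i in range(3))

    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                p = np.array([x, y, z])
                if in_bounds(p - d):
                    continue  # not a line start
                run_level, run_len = 0, 0
                while in_bounds(p):
                    v = levels[tuple(p)]
                    if v == run_level:
                        run_len += 1
                    else:
                        if run_level > 0:
                            counts[run_level - 1, run_len - 1] += 1
                        run_level, run_len = v, 1
                    p = p + d
                if run_level > 0:
                    counts[run_level - 1, run_len - 1] += 1
    return counts


def brute_glszm(levels: np.ndarray) -> np.ndarray:
    """Zone counts by BFS flood fill with 26-connectivity."""
    shape = levels.shape
    G = int(levels.max())
    visited = np.zeros(shape, dtype=bool)
    zones = []
    neigh = [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
             for dz in (-1, 0, 1) if (dx, dy, dz) != (0, 0, 0)]
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if visited[x, y, z] or levels[x, y, z] == 0:
                    continue
                g = levels[x, y, z]
                stack = [(x, y, z)]
                visited[x, y, z] = True
                size = 0
                while stack:
                    cx, cy, cz = stack.pop()
                    size += 1
                    for dx, dy, dz in neigh:
                        nx, ny, nz = cx + dx, cy + dy, cz + dz
                        if (0 <= nx < shape[0] and 0 <= ny < shape[1]
                                and 0 <= nz < shape[2]
                                and not visited[nx, ny, nz]
                                and levels[nx, ny, nz] == g):
                            visited[nx, ny, nz] = True
                            stack.append((nx, ny, nz))
                zones.append((g, size))
    max_size = max(s for _, s in zones)
    counts = np.zeros((G, max_size), dtype=np.int64)
    for g, s in zones:
        counts[g - 1, s - 1] += 1
    return counts


def anova_icc2(matrix: np.ndarray) -> float:
    """ICC(2,1) via explicit two-way ANOVA sums of squares."""
    x = np.asarray(matrix, dtype=float)
    n, k = x.shape
    grand = x.mean()
    ss_rows = k * sum((x[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = n * sum((x[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = ((x - grand) ** 2).sum()
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))
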