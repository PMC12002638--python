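"""Independent brute-force implementations used as oracles by the tests.

These are written naively (explicit loops, sets, heaps) and share no code
with the package's vectorized implementations.
"""

from __future__ import annotations

import heapq
import math


def flood_fill_components(mask) -> list[set[tuple[int, int]]]:
    """8-connected components of a 2D bool mask, by explicit flood fill."""
    h, w = mask.shape
    seen = set()
    comps = []
    for r in range(h):
        for c in range(w):
            if not mask[r, c] or (r, c) in seen:
                continue
            comp = set()
            stack = [(r, c)]
            while stack:
                y, x = stack.pop()
                if (y, x) in seen or not (0 <= y < h and 0 <= x < w) or not mask[y, x]:
                    continue
                seen.add((y, x))
                comp.add((y, x))
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        if dy or dx:
                            stack.append((y + dy, x + dx))
            comps.append(comp)
    return comps


def pairwise_overlaps(sets_a, sets_b, min_overlap):
    """All (i, j, n_shared) with >= min_overlap shared pixels (exhaustive)."""
    out = []
    for i, sa in enumerate(sets_a):
        for j, sb in enumerate(sets_b):
            n = len(sa & sb)
            if n >= min_overlap:
                out.append((i, j, n))
    return out


def brute_nearest_distances(points_a, points_b):
    out = []
    for pa in points_a:
        best = math.inf
        for pb in points_b:
            d = math.sqrt(sum((u - v) ** 2 for u, v in zip(pa, pb)))
            best = min(best, d)
        out.append(best)
    return out


def _neighbors26(k, j, i, shape):
    for dk in (-1, 0, 1):
        for dj in (-1, 0, 1):
            for di in (-1, 0, 1):
                if dk == dj == di == 0:
                    continue
                nk, nj, ni = k + dk, j + dj, i + di
                if 0 <= nk < shape[0] and 0 <= nj < shape[1] and 0 <= ni < shape[2]:
                    yield nk, nj, ni


def brute_segment(image, spacing, rxy, rz, global_k, gauss_sd, max_radius,
                  min_vox, max_vox):
    """Naive reference of the 3D segmentation rules (no smoothing):

    global threshold mean + k*SD (sample SD); seeds = strict ellipsoidal
    maxima above it with ties to the lower linear index; priority-flood
    (descending intensity) assignment of admissible voxels from the seeds;
    per-seed pruning at max(T, peak*exp(-sd^2/2)) within the anisotropic
    radius box, keeping the 26-connected component that contains the seed;
    size gate. Returns a set of frozensets of voxel index triples.
    """
    nz, ny, nx = image.shape
    vals = [float(v) for v in image.ravel()]
    n = len(vals)
    mean = sum(vals) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / (n - 1))
    thr = mean + global_k * sd

    def lin(k, j, i):
        return (k * ny + j) * nx + i

    # seeds
    seeds = []
    for k in range(nz):
        for j in range(ny):
            for i in range(nx):
                v = image[k, j, i]
                if v <= thr:
                    continue
                is_seed = True
                for dk in range(-rz, rz + 1):
                    for dj in range(-rxy, rxy + 1):
                        for di in range(-rxy, rxy + 1):
                            if dk == dj == di == 0:
                                continue
                            if (dk / rz) ** 2 + (dj / rxy) ** 2 + (di / rxy) ** 2 > 1 + 1e-12:
                                continue
                            nk, nj, ni = k + dk, j + dj, i + di
                            if not (0 <= nk < nz and 0 <= nj < ny and 0 <= ni < nx):
                                continue
                            u = image[nk, nj, ni]
                            if u > v or (u == v and lin(nk, nj, ni) < lin(k, j, i)):
                                is_seed = False
                if is_seed:
                    seeds.append((k, j, i))

    # marker flooding on descending intensity: a voxel is claimed by the
    # first basin whose flood front reaches it (front ordered by intensity,
    # ties by push age)
    label_of = {}
    heap = []
    age = 0
    for lbl, s in enumerate(seeds, start=1):
        label_of[s] = lbl
        heapq.heappush(heap, (-image[s], age, s))
        age += 1
    while heap:
        _, _, vox = heapq.heappop(heap)
        for nb in _neighbors26(*vox, image.shape):
            if image[nb] > thr and nb not in label_of:
                label_of[nb] = label_of[vox]
                heapq.heappush(heap, (-image[nb], age, nb))
                age += 1

    rad_z = max(1, round(max_radius * spacing[2] / spacing[0]))
    frac = math.exp(-0.5 * gauss_sd**2)
    out = set()
    for lbl, seed in enumerate(seeds, start=1):
        level = max(thr, image[seed] * frac)
        allowed = {
            v for v, l in label_of.items()
            if l == lbl and image[v] > level
            and abs(v[0] - seed[0]) <= rad_z
            and abs(v[1] - seed[1]) <= max_radius
            and abs(v[2] - seed[2]) <= max_radius
        }
        if seed not in allowed:
            continue
        comp = set()
        stack = [seed]
        while stack:
            v = stack.pop()
            if v in comp or v not in allowed:
                continue
            comp.add(v)
            stack.extend(_neighbors26(*v, image.shape))
        if min_vox <= len(comp) <= max_vox:
            out.add(frozenset(comp))
    return out
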