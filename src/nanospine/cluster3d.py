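"""3D STED nanocluster segmentation and object-based distance analysis.

Segmentation follows the local-maxima-plus-threshold scheme used for
DiAna-style cluster analysis:

1. a global threshold ``T_g`` = frame mean + ``global_k``*SD;
2. seed voxels above ``T_g`` that are strict maxima within an ellipsoidal
   neighborhood (``maxima_radius_xy`` voxels laterally, ``maxima_radius_z``
   axially), ties broken toward the lower linear index;
3. per-seed region growth over 26-connected voxels brighter than
   ``max(T_g, L_s)`` with the per-seed level ``L_s = peak * exp(-sd^2/2)``
   (a Gaussian evaluated ``gaussfit_sd`` standard deviations from its peak),
   constrained to ``max_radius`` voxels laterally (scaled by dx/dz axially);
   voxels reachable from several seeds go to the seed with the higher
   intensity path (marker watershed on inverted intensity);
4. components outside [min_voxels, max_voxels] are discarded.

The per-seed level formula and the contested-voxel rule are this package's
interpretation of the (unpublished) plugin internals; both are configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import maximum_filter
from scipy.spatial import cKDTree
from skimage.measure import label as cc_label
from skimage.segmentation import watershed

from .grid import VoxelGrid

__all__ = [
    "SegmentationParams",
    "Nanocluster",
    "NanomodulePair",
    "segment_nanoclusters",
    "nearest_neighbor_distances",
    "trans_synaptic_pairs",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Segmentation settings; defaults are the published analysis values
    (5 px / 2 px maxima radii, mean + 2 SD threshold, Gaussian-fit SD 1.5,
    20 px maximum radius, 3-20,000 voxel size gate)."""

    maxima_radius_xy: int = 5
    maxima_radius_z: int = 2
    global_k: float = 2.0
    gaussfit_sd: float = 1.5
    max_radius: int = 20
    min_voxels: int = 3
    max_voxels: int = 20000
    smooth_sigma_px: float = 0.8  # in-plane Gaussian blur applied before analysis

    def __post_init__(self) -> None:
        if min(self.maxima_radius_xy, self.maxima_radius_z, self.max_radius) <= 0:
            raise ValueError("radii must be positive")
        if self.global_k < 0 or self.gaussfit_sd <= 0:
            raise ValueError("global_k must be >= 0 and gaussfit_sd > 0")
        if not 0 < self.min_voxels <= self.max_voxels:
            raise ValueError("need 0 < min_voxels <= max_voxels")
        if self.smooth_sigma_px < 0:
            raise ValueError("smooth_sigma_px must be >= 0")

    @property
    def local_level_fraction(self) -> float:
        """Per-seed threshold as a fraction of the seed peak."""
        return math.exp(-0.5 * self.gaussfit_sd**2)


@dataclass(frozen=True)
class Nanocluster:
    """One segmented 3D object."""

    id: int
    channel: str
    grid: VoxelGrid
    voxels: np.ndarray  # (n, 3) int indices (k, j, i)
    voxel_count: int
    volume_um3: float
    centroid_nm: tuple[float, float, float]  # intensity-weighted, (z, y, x)
    peak_intensity: float
    peak_index: tuple[int, int, int]


@dataclass(frozen=True)
class NanomodulePair:
    """A trans-synaptically aligned cross-channel NC pair (>=1 voxel overlap)."""

    id_a: int
    id_b: int
    overlap_voxels: int
    distance_nm: float
    orientation: str  # "A" (XY-dominant) | "B" (Z-dominant)


def _ellipsoid_offsets(rxy: int, rz: int) -> np.ndarray:
    """Integer offsets (dk, dj, di) inside the ellipsoid, center excluded."""
    ks, js, is_ = np.mgrid[-rz:rz + 1, -rxy:rxy + 1, -rxy:rxy + 1]
    inside = (ks / rz) ** 2 + (js / rxy) ** 2 + (is_ / rxy) ** 2 <= 1.0 + 1e-12
    inside[rz, rxy, rxy] = False
    return np.stack([ks[inside], js[inside], is_[inside]], axis=1)


def _find_seeds(image: np.ndarray, threshold: float, params: SegmentationParams,
                mask: np.ndarray | None) -> np.ndarray:
    """Linear indices of seed voxels (strict ellipsoidal maxima above threshold,
    ties resolved toward the lower linear index)."""
    nz, ny, nx = image.shape
    admissible = image > threshold
    if mask is not None:
        admissible &= mask
    rxy, rz = params.maxima_radius_xy, params.maxima_radius_z
    # cheap prefilter: any seed must equal the maximum over the part of its
    # 3x3x3 neighborhood that lies inside the ellipsoid
    ks, js, is_ = np.mgrid[-1:2, -1:2, -1:2]
    foot = (ks / rz) ** 2 + (js / rxy) ** 2 + (is_ / rxy) ** 2 <= 1.0 + 1e-12
    foot[1, 1, 1] = True
    cand = admissible & (image >= maximum_filter(image, footprint=foot,
                                                 mode="constant", cval=-np.inf))
    cand_idx = np.flatnonzero(cand)
    if cand_idx.size == 0:
        return cand_idx
    pad = ((rz, rz), (rxy, rxy), (rxy, rxy))
    padded = np.pad(image, pad, mode="constant", constant_values=-np.inf)
    pnz, pny, pnx = padded.shape
    k0, j0, i0 = np.unravel_index(cand_idx, image.shape)
    keep = np.ones(cand_idx.size, dtype=bool)
    own = image.reshape(-1)[cand_idx]
    for dk, dj, di in _ellipsoid_offsets(rxy, rz):
        neigh = padded[k0 + rz + dk, j0 + rxy + dj, i0 + rxy + di]
        nk, nj, ni = k0 + dk, j0 + dj, i0 + di
        nlin = (nk * ny + nj) * nx + ni  # only meaningful in-bounds; -inf guards OOB
        keep &= (own > neigh) | ((own == neigh) & (cand_idx < nlin))
        if not keep.any():
            break
    return cand_idx[keep]


def segment_nanoclusters(
    stack3d: np.ndarray,
    grid: VoxelGrid,
    params: SegmentationParams | None = None,
    channel: str = "",
    mask: np.ndarray | None = None,
    threshold: float | None = None,
) -> list[Nanocluster]:
    """Segment nanoclusters in a 3D stack.

    ``mask``/``threshold`` restrict the analysis to a region of interest with
    an externally computed threshold (used by the per-spine re-thresholding
    step); by default statistics are taken over the entire frame. An empty or
    all-background stack yields an empty list.
    """
    params = params or SegmentationParams()
    image = np.asarray(stack3d, dtype=np.float64)
    if image.ndim != 3:
        raise ValueError("expected a 3D (z, y, x) stack")
    if image.shape != grid.shape:
        raise ValueError(f"stack shape {image.shape} != grid shape {grid.shape}")
    if image.size == 0:
        return []
    if params.smooth_sigma_px > 0:
        from scipy.ndimage import gaussian_filter

        image = gaussian_filter(image, sigma=(0.0, params.smooth_sigma_px,
                                              params.smooth_sigma_px))
    if threshold is None:
        stat_vals = image[mask] if mask is not None else image
        ddof = 1 if stat_vals.size > 1 else 0
        threshold = float(stat_vals.mean() + params.global_k * stat_vals.std(ddof=ddof))

    seeds = _find_seeds(image, threshold, params, mask)
    if seeds.size == 0:
        return []

    admissible = image > threshold
    if mask is not None:
        admissible &= mask
    markers = np.zeros(image.shape, dtype=np.int32)
    markers.reshape(-1)[seeds] = np.arange(1, seeds.size + 1)
    ws = watershed(-image, markers=markers, mask=admissible,
                   connectivity=np.ones((3, 3, 3), dtype=bool))

    nz, ny, nx = image.shape
    rad_xy = params.max_radius
    rad_z = max(1, int(round(params.max_radius * grid.spacing[2] / grid.spacing[0])))
    frac = params.local_level_fraction
    out: list[Nanocluster] = []
    for lbl, lin in enumerate(seeds, start=1):
        k0, j0, i0 = np.unravel_index(lin, image.shape)
        peak = image[k0, j0, i0]
        level = max(threshold, peak * frac)
        sl = (slice(max(0, k0 - rad_z), min(nz, k0 + rad_z + 1)),
              slice(max(0, j0 - rad_xy), min(ny, j0 + rad_xy + 1)),
              slice(max(0, i0 - rad_xy), min(nx, i0 + rad_xy + 1)))
        sub = (ws[sl] == lbl) & (image[sl] > level)
        comp = cc_label(sub, connectivity=3)
        seed_local = (k0 - sl[0].start, j0 - sl[1].start, i0 - sl[2].start)
        comp_id = comp[seed_local]
        if comp_id == 0:
            continue
        sel = comp == comp_id
        count = int(sel.sum())
        if not params.min_voxels <= count <= params.max_voxels:
            continue
        kk, jj, ii = np.nonzero(sel)
        kk = kk + sl[0].start
        jj = jj + sl[1].start
        ii = ii + sl[2].start
        weights = image[kk, jj, ii]
        wsum = weights.sum()
        centroid_idx = np.array([
            (kk * weights).sum(), (jj * weights).sum(), (ii * weights).sum()
        ]) / wsum
        centroid = grid.index_to_physical(centroid_idx)
        pk = int(np.argmax(weights))
        out.append(Nanocluster(
            id=len(out) + 1,
            channel=channel,
            grid=grid,
            voxels=np.stack([kk, jj, ii], axis=1),
            voxel_count=count,
            volume_um3=count * grid.voxel_volume_um3,
            centroid_nm=tuple(float(c) for c in centroid),
            peak_intensity=float(weights[pk]),
            peak_index=(int(kk[pk]), int(jj[pk]), int(ii[pk])),
        ))
    return out


def nearest_neighbor_distances(centers_a: np.ndarray, centers_b: np.ndarray) -> np.ndarray:
    """For each physical-nm point in A, the distance to its nearest point in B.

    Asymmetric by design (A -> B). Raises if either set is empty.
    """
    centers_a = np.atleast_2d(np.asarray(centers_a, dtype=float))
    centers_b = np.atleast_2d(np.asarray(centers_b, dtype=float))
    if centers_a.size == 0 or centers_b.size == 0:
        raise ValueError("nearest-neighbor analysis needs non-empty point sets")
    dist, _ = cKDTree(centers_b).query(centers_a)
    return np.asarray(dist, dtype=float)


def trans_synaptic_pairs(
    ncs_a: list[Nanocluster],
    ncs_b: list[Nanocluster],
    min_overlap_vox: int = 1,
) -> tuple[list[NanomodulePair], float]:
    """Cross-channel NC pairs sharing >= ``min_overlap_vox`` voxels.

    Returns the pair list plus the percentage of channel-A NCs with at least
    one partner. Orientation is "A" when the lateral component of the
    center-to-center offset is at least as large as the axial component,
    else "B".
    """
    if ncs_a and ncs_b and ncs_a[0].grid != ncs_b[0].grid:
        raise ValueError("NC lists live on different grids")
    if not ncs_a:
        return [], float("nan")
    if not ncs_b:
        return [], 0.0
    grid = ncs_a[0].grid
    occ_b = np.zeros(grid.shape, dtype=np.int32)
    for nc in ncs_b:
        occ_b[nc.voxels[:, 0], nc.voxels[:, 1], nc.voxels[:, 2]] = nc.id
    by_id_b = {nc.id: nc for nc in ncs_b}
    pairs: list[NanomodulePair] = []
    matched_a: set[int] = set()
    for nca in ncs_a:
        hits = occ_b[nca.voxels[:, 0], nca.voxels[:, 1], nca.voxels[:, 2]]
        hits = hits[hits > 0]
        if hits.size == 0:
            continue
        ids, counts = np.unique(hits, return_counts=True)
        for bid, cnt in zip(ids, counts):
            if cnt < min_overlap_vox:
                continue
            ncb = by_id_b[int(bid)]
            delta = np.asarray(nca.centroid_nm) - np.asarray(ncb.centroid_nm)
            lateral = math.hypot(delta[1], delta[2])
            pairs.append(NanomodulePair(
                id_a=nca.id,
                id_b=int(bid),
                overlap_voxels=int(cnt),
                distance_nm=float(np.linalg.norm(delta)),
                orientation="A" if lateral >= abs(delta[0]) else "B",
            ))
            matched_a.add(nca.id)
    percent = 100.0 * len(matched_a) / len(ncs_a)
    return pairs, percent
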