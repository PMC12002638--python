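"""Confocal puncta co-clustering analysis (2D, on maximum-intensity projections).

Each channel is max-projected, thresholded to the frame mean + k*SD
(k = 2 by default), and binarized. Puncta are 8-connected components of
3-100 pixels; co-clusters are cross-channel punctum pairs overlapping by
more than one pixel. Densities are reported per 10 um of dendrite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.measure import label, regionprops

from .grid import VoxelGrid

__all__ = [
    "Punctum",
    "CoCluster",
    "max_project",
    "threshold_mask",
    "extract_puncta",
    "cocluster",
    "linear_density",
]

MIN_PUNCTUM_PX = 3
MAX_PUNCTUM_PX = 100
MIN_COCLUSTER_OVERLAP_PX = 2  # "> 1-pixel overlap"
MIN_DENDRITE_LENGTH_UM = 50.0


@dataclass(frozen=True)
class Punctum:
    """One 2D synaptic punctum on the max-projection grid."""

    id: int
    channel: str
    rows: np.ndarray  # pixel row indices (y)
    cols: np.ndarray  # pixel column indices (x)
    pixel_count: int
    area_um2: float
    centroid_nm: tuple[float, float]  # (y, x), intensity-weighted
    mean_intensity: float

    def pixel_set(self) -> set[tuple[int, int]]:
        return set(zip(self.rows.tolist(), self.cols.tolist()))


@dataclass(frozen=True)
class CoCluster:
    id_a: int
    id_b: int
    overlap_px: int


def max_project(stack3d: np.ndarray) -> np.ndarray:
    """Maximum-intensity projection along z of a (nz, ny, nx) stack."""
    stack3d = np.asarray(stack3d)
    if stack3d.ndim != 3 or stack3d.shape[0] < 1:
        raise ValueError("expected a non-empty 3D (z, y, x) stack")
    return stack3d.max(axis=0)


def threshold_mask(image2d: np.ndarray, k: float = 2.0) -> tuple[np.ndarray, float]:
    """Binarize at mean + k*SD of the full frame (strict '>').

    Returns (mask, threshold). A constant frame has SD 0 and yields an empty
    mask, not an error. SD uses the sample convention (ddof=1) when the frame
    has more than one pixel.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    image2d = np.asarray(image2d, dtype=float)
    ddof = 1 if image2d.size > 1 else 0
    thr = float(image2d.mean() + k * image2d.std(ddof=ddof))
    return image2d > thr, thr


def extract_puncta(
    mask: np.ndarray,
    grid: VoxelGrid,
    channel: str = "",
    intensity: np.ndarray | None = None,
    min_px: int = MIN_PUNCTUM_PX,
    max_px: int = MAX_PUNCTUM_PX,
) -> list[Punctum]:
    """8-connected components of a binary mask, kept if min_px <= size <= max_px.

    Area is pixel count times the grid pixel area; centroids are
    intensity-weighted when an intensity image is given, else geometric.
    """
    mask = np.asarray(mask, dtype=bool)
    lab = label(mask, connectivity=2)
    dy, dx = grid.spacing[1], grid.spacing[2]
    out: list[Punctum] = []
    for rp in regionprops(lab, intensity_image=intensity):
        if not (min_px <= rp.area <= max_px):
            continue
        rows = rp.coords[:, 0].astype(np.int64)
        cols = rp.coords[:, 1].astype(np.int64)
        if intensity is not None:
            cy, cx = rp.centroid_weighted
            mean_int = float(rp.intensity_mean)
        else:
            cy, cx = rp.centroid
            mean_int = 1.0
        out.append(Punctum(
            id=len(out) + 1,
            channel=channel,
            rows=rows,
            cols=cols,
            pixel_count=int(rp.area),
            area_um2=float(rp.area) * grid.pixel_area_um2,
            centroid_nm=(grid.origin[1] + cy * dy, grid.origin[2] + cx * dx),
            mean_intensity=mean_int,
        ))
    return out


def cocluster(
    puncta_a: list[Punctum],
    puncta_b: list[Punctum],
    shape: tuple[int, int],
    min_overlap_px: int = MIN_COCLUSTER_OVERLAP_PX,
) -> tuple[list[CoCluster], float]:
    """Cross-channel punctum pairs sharing at least ``min_overlap_px`` pixels.

    Returns the pair list and the colocalized fraction of channel A
    (% of A puncta with >= 1 partner). A punctum may appear in several pairs.
    """
    occ_b = np.zeros(shape, dtype=np.int32)
    for p in puncta_b:
        if np.any(p.rows >= shape[0]) or np.any(p.cols >= shape[1]):
            raise ValueError("puncta lie outside the stated grid: grid mismatch")
        occ_b[p.rows, p.cols] = p.id
    pairs: list[CoCluster] = []
    matched_a: set[int] = set()
    for pa in puncta_a:
        if np.any(pa.rows >= shape[0]) or np.any(pa.cols >= shape[1]):
            raise ValueError("puncta lie outside the stated grid: grid mismatch")
        hit_ids = occ_b[pa.rows, pa.cols]
        hit_ids = hit_ids[hit_ids > 0]
        if hit_ids.size == 0:
            continue
        ids, counts = np.unique(hit_ids, return_counts=True)
        for bid, cnt in zip(ids, counts):
            if cnt >= min_overlap_px:
                pairs.append(CoCluster(pa.id, int(bid), int(cnt)))
                matched_a.add(pa.id)
    fraction = 100.0 * len(matched_a) / len(puncta_a) if puncta_a else float("nan")
    return pairs, fraction


def linear_density(n_objects: int, dendrite_length_um: float,
                   per_um: float = 10.0) -> float:
    """Objects per ``per_um`` (default 10) um of dendrite.

    Analysis is meant for stretches of at least 50 um; shorter lengths are
    accepted with a warning.
    """
    if dendrite_length_um <= 0:
        raise ValueError("dendrite length must be positive")
    if dendrite_length_um < MIN_DENDRITE_LENGTH_UM:
        warnings.warn(
            f"dendrite length {dendrite_length_um:.1f} um is below the "
            f"{MIN_DENDRITE_LENGTH_UM:.0f} um analysis minimum",
            stacklevel=2,
        )
    return n_objects / dendrite_length_um * per_um
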