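"""Per-spine analysis: NC-to-spine assignment, nanomodule counting,
VGluT1/VGluT2 input classification, and spine volume metrics.

Assignment rules follow the per-spine protocol: spine ROIs come from a
mean + 2*SD morphology mask (or provided labels / generator truth); PSD-95
NCs are assigned to a spine only when their thresholded voxel set lies
entirely within the spine head ROI, while Bassoon NCs associate on partial
overlap or proximity (0.15-0.2 um); discrete NCs within a spine must exceed
the ROI-local mean + 1.5*SD level; a nanomodule is an assigned PSD-95 NC
with at least one trans-synaptically aligned Bassoon partner; spines are
classed CC/TC by VGluT1/VGluT2 overlap (>1 pixel) with nanomodule
colocalization breaking dual-innervation ties.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree
from skimage.measure import label as cc_label

from .cluster3d import Nanocluster, NanomodulePair, SegmentationParams, \
    segment_nanoclusters, trans_synaptic_pairs
from .grid import VoxelGrid
from .puncta import Punctum, extract_puncta, max_project, threshold_mask

__all__ = [
    "SpineRecord",
    "derive_spine_rois",
    "identify_spine_ncs",
    "assign_psd95",
    "assign_bassoon",
    "count_nanomodules",
    "classify_input",
    "spine_metrics",
    "analyze_spines",
]

DEFAULT_BASSOON_PROXIMITY_NM = 200.0
ROI_LOCAL_K = 1.5
MIN_ROI_VOXELS = 10


@dataclass
class SpineRecord:
    """One dendritic spine and its per-spine analysis results."""

    id: int
    grid: VoxelGrid  # morphology grid the mask lives on
    mask: np.ndarray  # 3D bool
    head_roi: np.ndarray  # 3D bool, subset of mask (default: the full mask)
    volume_um3: float
    orientation: str  # "A" (XY-projecting) | "B" (Z-projecting)
    input_class: str = "unclassified"
    assigned_psd95: list[int] = field(default_factory=list)
    associated_bassoon: list[int] = field(default_factory=list)
    nanomodule_count: int = 0
    total_psd95_volume_um3: float | None = None
    mean_nc_volume_um3: float | None = None
    dual_innervated: bool = False  # both VGluT markers contacted the spine


def _principal_orientation(mask: np.ndarray, grid: VoxelGrid) -> str:
    """Class A if the spine's principal axis is XY-dominant, else B."""
    coords = np.argwhere(mask).astype(float) * np.asarray(grid.spacing)
    if len(coords) < 2:
        return "A"
    cov = np.cov((coords - coords.mean(axis=0)).T)
    vec = np.linalg.eigh(cov)[1][:, -1]
    return "A" if np.hypot(vec[1], vec[2]) >= abs(vec[0]) else "B"


def derive_spine_rois(
    morphology: np.ndarray | None,
    grid: VoxelGrid,
    k: float = 2.0,
    provided_labels: np.ndarray | None = None,
    truth=None,
) -> list[SpineRecord]:
    """Build per-spine binary masks.

    Modes, in order of precedence: generator ``truth`` (masks rasterized
    from the ground-truth geometry), ``provided_labels`` (a spine label
    image, intersected with the mean + k*SD morphology mask when a
    morphology stack is given), or plain thresholding of the morphology
    channel into 26-connected components (which merges touching structures).
    """
    records: list[SpineRecord] = []

    def _emit(mask: np.ndarray, sid: int) -> None:
        volume = float(mask.sum()) * grid.voxel_volume_um3
        records.append(SpineRecord(
            id=sid, grid=grid, mask=mask, head_roi=mask, volume_um3=volume,
            orientation=_principal_orientation(mask, grid),
        ))

    if truth is not None:
        from .synth import rasterize_spines

        labels = rasterize_spines(truth, grid)
        for sp in truth.spines:
            _emit(labels == sp.id, sp.id)
        return records

    if morphology is not None:
        morphology = np.asarray(morphology, dtype=float)
        ddof = 1 if morphology.size > 1 else 0
        thr = morphology.mean() + k * morphology.std(ddof=ddof)
        binary = morphology > thr
    else:
        binary = None

    if provided_labels is not None:
        for sid in np.unique(provided_labels):
            if sid == 0:
                continue
            mask = provided_labels == sid
            if binary is not None:
                mask = mask & binary
            if not mask.any():
                warnings.warn(f"spine label {sid} empty after thresholding", stacklevel=2)
                continue
            _emit(mask, int(sid))
        return records

    if binary is None:
        raise ValueError("need a morphology stack, provided labels, or truth")
    comps = cc_label(binary, connectivity=3)
    for sid in range(1, comps.max() + 1):
        _emit(comps == sid, sid)
    if not records:
        warnings.warn("no spines found in morphology channel", stacklevel=2)
    return records


def _map_roi_to_grid(spine: SpineRecord, target: VoxelGrid) -> tuple[np.ndarray, tuple[slice, slice, slice]]:
    """Nearest-neighbor upsampling of the spine head ROI onto ``target``;
    returns the bool ROI restricted to its bounding box plus the box slices."""
    src = spine.grid
    occ = np.argwhere(spine.head_roi)
    if occ.size == 0:
        return np.zeros((0, 0, 0), dtype=bool), (slice(0, 0),) * 3
    lo_nm = src.index_to_physical(occ.min(axis=0)) - np.asarray(src.spacing) / 2
    hi_nm = src.index_to_physical(occ.max(axis=0)) + np.asarray(src.spacing) / 2
    lo = np.maximum(np.floor(target.physical_to_index(lo_nm)).astype(int), 0)
    hi = np.minimum(np.ceil(target.physical_to_index(hi_nm)).astype(int) + 1,
                    np.asarray(target.shape))
    if np.any(lo >= hi):
        return np.zeros((0, 0, 0), dtype=bool), (slice(0, 0),) * 3
    axes_idx = []
    for ax in range(3):
        coords = target.axis_coordinates(ax)[lo[ax]:hi[ax]]
        src_idx = np.rint((coords - src.origin[ax]) / src.spacing[ax]).astype(int)
        axes_idx.append(np.clip(src_idx, 0, src.shape[ax] - 1))
    roi = spine.head_roi[np.ix_(axes_idx[0], axes_idx[1], axes_idx[2])]
    return roi, tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))


def identify_spine_ncs(
    stack3d: np.ndarray,
    grid: VoxelGrid,
    spine: SpineRecord,
    params: SegmentationParams | None = None,
    k_local: float = ROI_LOCAL_K,
    channel: str = "",
) -> list[Nanocluster]:
    """Discrete NCs within one spine ROI, re-thresholded at the ROI-local
    mean + ``k_local``*SD (segmented over the spine's bounding box; global
    segmentation remains the source of NC geometry in the full pipeline).
    """
    params = params or SegmentationParams()
    if spine.head_roi.sum() < MIN_ROI_VOXELS:
        warnings.warn(f"spine {spine.id}: ROI below {MIN_ROI_VOXELS} voxels, skipped",
                      stacklevel=2)
        return []
    roi, box = _map_roi_to_grid(spine, grid)
    if not roi.any():
        return []
    sub = np.asarray(stack3d, dtype=float)[box]
    sub_grid = VoxelGrid(
        shape=sub.shape, spacing=grid.spacing,
        origin=tuple(grid.origin[ax] + box[ax].start * grid.spacing[ax] for ax in range(3)),
    )
    local = replace(params, global_k=k_local)
    return segment_nanoclusters(sub, sub_grid, local, channel=channel, mask=roi)


def roi_local_threshold(stack3d: np.ndarray, grid: VoxelGrid, spine: SpineRecord,
                        params: SegmentationParams | None = None,
                        k_local: float = ROI_LOCAL_K) -> float | None:
    """ROI-local discrimination level: mean + k*SD of the (smoothed) channel
    within the spine ROI; None if the ROI has fewer than 10 voxels."""
    params = params or SegmentationParams()
    if spine.head_roi.sum() < MIN_ROI_VOXELS:
        return None
    roi, box = _map_roi_to_grid(spine, grid)
    if not roi.any():
        return None
    sub = np.asarray(stack3d, dtype=float)[box]
    if params.smooth_sigma_px > 0:
        sub = gaussian_filter(sub, sigma=(0.0, params.smooth_sigma_px, params.smooth_sigma_px))
    vals = sub[roi]
    return float(vals.mean() + k_local * vals.std(ddof=1 if vals.size > 1 else 0))


def _voxel_centers_inside(spine: SpineRecord, nc: Nanocluster) -> np.ndarray:
    """Bool per NC voxel: does its physical center fall inside the head ROI
    (nearest-voxel lookup on the morphology grid)?"""
    centers = nc.grid.index_to_physical(nc.voxels)
    idx = spine.grid.physical_to_nearest(centers)
    inside = spine.grid.contains_index(idx)
    out = np.zeros(len(idx), dtype=bool)
    if inside.any():
        ii = idx[inside]
        out[inside] = spine.head_roi[ii[:, 0], ii[:, 1], ii[:, 2]]
    return out


def assign_psd95(spine: SpineRecord, ncs: list[Nanocluster]) -> list[int]:
    """IDs of NCs whose voxel centers fall *entirely* inside the head ROI
    (an NC straddling the boundary is not assigned)."""
    return [nc.id for nc in ncs if len(nc.voxels) and _voxel_centers_inside(spine, nc).all()]


def assign_bassoon(
    spine: SpineRecord,
    ncs: list[Nanocluster],
    proximity_nm: float = DEFAULT_BASSOON_PROXIMITY_NM,
) -> list[int]:
    """IDs of NCs overlapping the head ROI by >= 1 voxel center, or whose
    centroid lies within ``proximity_nm`` of the ROI (nearest ROI voxel
    center), covering presynaptic clusters abutting the spine."""
    roi_pts = np.argwhere(spine.head_roi).astype(float)
    tree = cKDTree(roi_pts * np.asarray(spine.grid.spacing)
                   + np.asarray(spine.grid.origin)) if len(roi_pts) else None
    out: list[int] = []
    for nc in ncs:
        if len(nc.voxels) and _voxel_centers_inside(spine, nc).any():
            out.append(nc.id)
            continue
        if tree is not None:
            d, _ = tree.query(np.asarray(nc.centroid_nm))
            if d <= proximity_nm:
                out.append(nc.id)
    return out


def count_nanomodules(spine: SpineRecord, pairs: list[NanomodulePair]) -> int:
    """Number of assigned PSD-95 NCs with >= 1 aligned Bassoon partner.

    Counting is keyed on PSD-95: one Bassoon shared by two PSD-95 NCs
    yields a count of 2.
    """
    assigned = set(spine.assigned_psd95)
    associated = set(spine.associated_bassoon)
    counted = {p.id_a for p in pairs if p.id_a in assigned and p.id_b in associated}
    spine.nanomodule_count = len(counted)
    return spine.nanomodule_count


def _project_mask_2d(spine: SpineRecord) -> np.ndarray:
    return spine.mask.any(axis=0)


def _nc_projection_pixels(ncs: list[Nanocluster], grid2d: VoxelGrid) -> set[tuple[int, int]]:
    pts: set[tuple[int, int]] = set()
    for nc in ncs:
        centers = nc.grid.index_to_physical(nc.voxels)
        rows = np.rint((centers[:, 1] - grid2d.origin[1]) / grid2d.spacing[1]).astype(int)
        cols = np.rint((centers[:, 2] - grid2d.origin[2]) / grid2d.spacing[2]).astype(int)
        ok = (rows >= 0) & (rows < grid2d.shape[1]) & (cols >= 0) & (cols < grid2d.shape[2])
        pts.update(zip(rows[ok].tolist(), cols[ok].tolist()))
    return pts


def classify_input(
    spine: SpineRecord,
    vg1_puncta: list[Punctum],
    vg2_puncta: list[Punctum],
    nanomodule_ncs: list[Nanocluster] | None = None,
    min_overlap_px: int = 2,
) -> str:
    """Classify a spine as CC (VGluT1), TC (VGluT2) or unclassified.

    A marker "contacts" the spine when one of its puncta overlaps the
    z-projected spine mask by more than one pixel. With dual contact the
    class follows the marker colocalizing with the spine's aligned
    nanomodule(s); a residual tie goes to the marker with the larger total
    overlap (and to CC if exactly equal). The VGluT grids must match the
    morphology grid laterally.
    """
    proj = _project_mask_2d(spine)

    def _overlap(puncta: list[Punctum]) -> tuple[bool, int]:
        total = 0
        contact = False
        for p in puncta:
            ok = (p.rows < proj.shape[0]) & (p.cols < proj.shape[1])
            cnt = int(proj[p.rows[ok], p.cols[ok]].sum())
            total += cnt
            if cnt >= min_overlap_px:
                contact = True
        return contact, total

    has1, tot1 = _overlap(vg1_puncta)
    has2, tot2 = _overlap(vg2_puncta)
    spine.dual_innervated = has1 and has2
    if not has1 and not has2:
        spine.input_class = "unclassified"
    elif has1 != has2:
        spine.input_class = "CC" if has1 else "TC"
    else:  # dual innervation: use the aligned nanomodules, then overlap size
        mod1 = mod2 = 0
        if nanomodule_ncs:
            pix = _nc_projection_pixels(nanomodule_ncs, spine.grid)
            for puncta, which in ((vg1_puncta, 1), (vg2_puncta, 2)):
                hits = sum(len(pix & p.pixel_set()) for p in puncta)
                if which == 1:
                    mod1 = hits
                else:
                    mod2 = hits
        if mod1 != mod2:
            spine.input_class = "CC" if mod1 > mod2 else "TC"
        else:
            spine.input_class = "TC" if tot2 > tot1 else "CC"
    return spine.input_class


def spine_metrics(spine: SpineRecord, ncs_by_id: dict[int, Nanocluster]) -> SpineRecord:
    """Total and mean assigned PSD-95 NC volume; null (None) when nothing is
    assigned, never zero."""
    vols = [ncs_by_id[i].volume_um3 for i in spine.assigned_psd95 if i in ncs_by_id]
    if vols:
        spine.total_psd95_volume_um3 = float(np.sum(vols))
        spine.mean_nc_volume_um3 = float(np.mean(vols))
    else:
        spine.total_psd95_volume_um3 = None
        spine.mean_nc_volume_um3 = None
    return spine


def analyze_spines(
    stacks: dict[str, np.ndarray],
    grids: dict[str, VoxelGrid],
    truth=None,
    provided_labels: np.ndarray | None = None,
    params: SegmentationParams | None = None,
    proximity_nm: float = DEFAULT_BASSOON_PROXIMITY_NM,
    k_morphology: float = 2.0,
    k_local: float = ROI_LOCAL_K,
) -> dict:
    """Run the full per-spine pipeline on a rendered or loaded scene.

    Returns a dict with the spine records, the global PSD-95/Bassoon NC
    lists, all trans-synaptic pairs, and the per-spine pair lists.
    """
    params = params or SegmentationParams()
    psd = segment_nanoclusters(stacks["psd95"], grids["psd95"], params, channel="psd95")
    bas = segment_nanoclusters(stacks["bassoon"], grids["bassoon"], params, channel="bassoon")
    pairs, percent_aligned = trans_synaptic_pairs(psd, bas)
    psd_by_id = {nc.id: nc for nc in psd}

    morph = stacks.get("yfp")
    spines = derive_spine_rois(morph, grids["yfp"], k=k_morphology,
                               provided_labels=provided_labels, truth=truth)

    vg_puncta: dict[str, list[Punctum]] = {}
    for ch in ("vglut1", "vglut2"):
        if ch in stacks:
            img = max_project(stacks[ch])
            mask, _ = threshold_mask(img, k=2.0)
            vg_puncta[ch] = extract_puncta(mask, grids[ch], channel=ch, intensity=img)
        else:
            vg_puncta[ch] = []

    spine_pairs: dict[int, list[NanomodulePair]] = {}
    for spine in spines:
        assigned = assign_psd95(spine, psd)
        thr_psd = roi_local_threshold(stacks["psd95"], grids["psd95"], spine,
                                      params, k_local)
        if thr_psd is not None:
            assigned = [i for i in assigned if psd_by_id[i].peak_intensity > thr_psd]
        spine.assigned_psd95 = assigned
        spine.associated_bassoon = assign_bassoon(spine, bas, proximity_nm)
        sp_pairs = [p for p in pairs
                    if p.id_a in set(assigned) and p.id_b in set(spine.associated_bassoon)]
        spine_pairs[spine.id] = sp_pairs
        count_nanomodules(spine, sp_pairs)
        aligned_ids = {p.id_a for p in sp_pairs}
        classify_input(spine, vg_puncta["vglut1"], vg_puncta["vglut2"],
                       nanomodule_ncs=[psd_by_id[i] for i in aligned_ids])
        spine_metrics(spine, psd_by_id)

    return {
        "spines": spines,
        "psd95_ncs": psd,
        "bassoon_ncs": bas,
        "pairs": pairs,
        "percent_aligned": percent_aligned,
        "spine_pairs": spine_pairs,
        "vglut_puncta": vg_puncta,
    }
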