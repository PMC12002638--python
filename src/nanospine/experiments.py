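"""Parameter-recovery experiments: run the full pipeline on synthetic scenes
generated at the study conditions and measure how well the known inputs are
returned. Shared by the test suite and ``scripts/acceptance.py``.

Large spine populations are processed as batches of moderate fields of view
(about 50 spines per ~15 x 15 um frame) so each batch segments quickly on a
single CPU; batch seeds are spawned from one master seed.
"""

from __future__ import annotations

import math

import numpy as np

from .cluster3d import SegmentationParams, segment_nanoclusters, trans_synaptic_pairs
from .profiles import fit_fwhm, line_profile, peak_separation, \
    pooled_axial_separation, principal_axis_2d
from .puncta import extract_puncta, max_project, threshold_mask
from .spines import analyze_spines, classify_input, derive_spine_rois
from .synth import CC_BASAL_PMF, TC_BASAL_PMF, RULER_OPTICS, SceneConfig, \
    _effective_sigma_nm, build_nanoruler_phantom, build_scene, build_spot_phantom, \
    render_channels

__all__ = [
    "run_spine_population",
    "nanomodule_fraction_recovery",
    "tc_fraction_recovery",
    "trans_synaptic_distance_recovery",
    "axial_ruler_recovery",
    "lateral_ruler_recovery",
    "fwhm_recovery",
]

FIG2D_NANOBODY_FWHM_NM = 126.0  # tau-STED nanobody-labeled PSD-95 cluster FWHM
STED_PSF_LATERAL_NM = 50.0


def _batch_sizes(n: int, batch: int) -> list[int]:
    full, rem = divmod(n, batch)
    return [batch] * full + ([rem] if rem else [])


def _spawn_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31)) for s in
            np.random.SeedSequence(int(seed)).spawn(n)]


def run_spine_population(
    n_spines: int,
    seed: int,
    p_tc: float = 0.0,
    pmfs: dict | None = None,
    exact: bool = True,
    batch: int = 50,
    confocal_only: bool = False,
    config_overrides: dict | None = None,
    params: SegmentationParams | None = None,
):
    """Generate + analyze a spine population in batches; returns the pooled
    spine records (and per-batch results for the STED pipeline).

    With ``exact=True`` class and nanomodule-count compositions follow the
    configured proportions exactly (largest remainder, per batch; TC counts
    are apportioned across batches so the run total matches ``p_tc``).
    """
    pmfs = pmfs or {"CC": CC_BASAL_PMF, "TC": TC_BASAL_PMF}
    sizes = _batch_sizes(n_spines, batch)
    seeds = _spawn_seeds(seed, len(sizes))
    # apportion the exact TC total across batches
    if exact and n_spines:
        total_tc = int(round(n_spines * p_tc))
        raw = np.asarray(sizes) * total_tc / n_spines
        tc_counts = np.floor(raw).astype(int)
        order = np.argsort(-(raw - tc_counts), kind="stable")
        tc_counts[order[: total_tc - tc_counts.sum()]] += 1
    else:
        tc_counts = [None] * len(sizes)

    all_spines, all_results = [], []
    for bn, bseed, btc in zip(sizes, seeds, tc_counts):
        cfg = SceneConfig(
            n_spines=bn,
            p_tc=(btc / bn if btc is not None else p_tc),
            nanomodule_count_pmf=pmfs,
            exact_fractions=exact,
            seed=bseed,
            **(config_overrides or {}),
        )
        scene = build_scene(cfg)
        grids = scene.default_grids()
        channels = ["vglut1", "vglut2"] if confocal_only else \
            ["psd95", "bassoon", "vglut1", "vglut2"]
        stacks = render_channels(scene, {ch: grids[ch] for ch in channels})
        if confocal_only:
            spines = derive_spine_rois(None, grids["yfp"], truth=scene)
            vg = {}
            for ch in ("vglut1", "vglut2"):
                img = max_project(stacks[ch])
                mask, _ = threshold_mask(img, k=2.0)
                vg[ch] = extract_puncta(mask, grids[ch], channel=ch, intensity=img)
            for sp in spines:
                classify_input(sp, vg["vglut1"], vg["vglut2"])
            result = {"spines": spines, "truth": scene}
        else:
            result = analyze_spines(stacks, grids, truth=scene, params=params)
            result["truth"] = scene
        all_spines.extend(result["spines"])
        all_results.append(result)
    return all_spines, all_results


def nanomodule_fraction_recovery(seed: int, n_spines: int = 500) -> dict:
    """Fraction (%) of VGluT1+ spines recovered with exactly one aligned
    PSD-95/Bassoon nanomodule, with counts drawn from the basal VGluT1
    distribution (spines with zero recovered nanomodules are excluded from
    the denominator, as in the published fractions)."""
    spines, _ = run_spine_population(n_spines, seed, p_tc=0.0)
    counts = np.array([s.nanomodule_count for s in spines])
    denom = int((counts >= 1).sum())
    value = 100.0 * int((counts == 1).sum()) / denom if denom else math.nan
    return {"value": value, "n": n_spines}


def tc_fraction_recovery(seed: int, n_spines: int = 507) -> dict:
    """Percent of spines classified TC by VGluT2 overlap when identities are
    drawn at the basal proportions (68 TC of 507)."""
    spines, _ = run_spine_population(n_spines, seed, p_tc=68 / 507,
                                     confocal_only=True, batch=80)
    n_tc = sum(1 for s in spines if s.input_class == "TC")
    return {"value": 100.0 * n_tc / len(spines), "n": n_spines}


def trans_synaptic_distance_recovery(
    seed: int,
    offset_nm: float = 140.0,
    min_pairs: int = 200,
    axis_mix: float = 0.5,
) -> dict:
    """Pooled mean center-to-center distance (nm) over all >=1-voxel-overlap
    PSD-95/Bassoon pairs in scenes generated at a fixed cleft offset (spine
    nanomodules plus fully paired neuropil synapses). Also reports the
    distance SD and the fraction of XY-dominant (type A) pairs."""
    distances: list[float] = []
    orientations: list[str] = []
    seeds = _spawn_seeds(seed, 8)
    for bseed in seeds:
        cfg = SceneConfig(
            n_spines=49,
            p_tc=0.0,
            nanomodule_count_pmf={"CC": (1.0, 0, 0, 0), "TC": (1.0, 0, 0, 0)},
            cleft_offset_nm=offset_nm,
            cleft_axis_mix=axis_mix,
            neuropil_paired_fraction=1.0,
            exact_fractions=True,
            seed=bseed,
        )
        scene = build_scene(cfg)
        grids = scene.default_grids()
        stacks = render_channels(scene, {ch: grids[ch] for ch in ("psd95", "bassoon")})
        psd = segment_nanoclusters(stacks["psd95"], grids["psd95"], channel="psd95")
        bas = segment_nanoclusters(stacks["bassoon"], grids["bassoon"], channel="bassoon")
        pairs, _ = trans_synaptic_pairs(psd, bas)
        distances.extend(p.distance_nm for p in pairs)
        orientations.extend(p.orientation for p in pairs)
        if len(distances) >= min_pairs:
            break
    return {
        "value": float(np.mean(distances)),
        "n": len(distances),
        "sd": float(np.std(distances, ddof=1)),
        "percent_type_a": 100.0 * orientations.count("A") / len(orientations),
    }


def _match_to_truth(ncs, truth_centers, max_nm=400.0):
    """Detected NC nearest each true site (bookkeeping only; measurements come
    from the image). Returns one NC per truth site or None."""
    from scipy.spatial import cKDTree

    if not ncs:
        return [None] * len(truth_centers)
    centers = np.array([nc.centroid_nm for nc in ncs])
    tree = cKDTree(centers)
    out = []
    for tc in truth_centers:
        d, j = tree.query(np.asarray(tc))
        out.append(ncs[int(j)] if d <= max_nm else None)
    return out


def axial_ruler_recovery(seed: int, n_pairs: int = 120, spacing_nm: float = 90.0) -> dict:
    """Separation (nm) of axially spaced nano-ruler bead pairs on the 150 nm
    z-grid: pairs are detected as merged spots by segmentation, then the
    shared spacing is recovered by the matched-filter profile likelihood
    pooled over pairs (the per-pair split is below the information limit at
    this z-sampling)."""
    image, grid, pairs = build_nanoruler_phantom(spacing_nm, "axial", n_pairs, seed=seed)
    ncs = segment_nanoclusters(image, grid, channel="rulers")
    sigma = _effective_sigma_nm(0.0, RULER_OPTICS)
    centers = [nc.centroid_nm for nc in
               _match_to_truth(ncs, [p.center_nm for p in pairs]) if nc is not None]
    s_hat, _, _ = pooled_axial_separation(image, grid, centers, sigma)
    return {"value": s_hat, "n": len(centers)}


def lateral_ruler_recovery(seed: int, n_pairs: int = 43, spacing_nm: float = 50.0) -> dict:
    """Mean fitted peak-to-peak distance (nm) and Rayleigh dip (%) of
    laterally spaced nano-ruler pairs, from line profiles along each merged
    spot's principal axis."""
    image, grid, pairs = build_nanoruler_phantom(spacing_nm, "lateral", n_pairs, seed=seed)
    ncs = segment_nanoclusters(image, grid, channel="rulers")
    dists, dips = [], []
    for nc in _match_to_truth(ncs, [p.center_nm for p in pairs]):
        if nc is None:
            continue
        plane = image[nc.peak_index[0]]
        center2d = (nc.centroid_nm[1], nc.centroid_nm[2])
        axis = principal_axis_2d(plane, grid, center2d)
        try:
            prof = line_profile(plane, grid, center2d, axis, length_nm=500.0)
        except ValueError:
            continue
        res = peak_separation(prof)
        if res.resolved:
            dists.append(res.distance_nm)
            dips.append(res.dip_percent)
    return {
        "value": float(np.mean(dists)) if dists else math.nan,
        "dip_percent": float(np.mean(dips)) if dips else math.nan,
        "n": len(dists),
    }


def fwhm_recovery(seed: int, n_spots: int = 160,
                  target_fwhm_nm: float = FIG2D_NANOBODY_FWHM_NM) -> dict:
    """Mean fitted FWHM (nm) of isolated clusters rendered so their true
    image-domain FWHM equals ``target_fwhm_nm`` (intrinsic size deconvolved
    from the 50 nm PSF in quadrature), at the tissue photon budget."""
    intrinsic = math.sqrt(target_fwhm_nm**2 - STED_PSF_LATERAL_NM**2)
    image, grid, emitters = build_spot_phantom(n_spots, intrinsic, seed=seed)
    ncs = segment_nanoclusters(image, grid, channel="spots")
    fwhms = []
    for nc in _match_to_truth(ncs, [e.center_nm for e in emitters]):
        if nc is None:
            continue
        plane = image[nc.peak_index[0]]
        center2d = (nc.centroid_nm[1], nc.centroid_nm[2])
        axis = principal_axis_2d(plane, grid, center2d)
        try:
            prof = line_profile(plane, grid, center2d, axis, length_nm=1000.0)
        except ValueError:
            continue
        fit = fit_fwhm(prof)
        if fit.ok:
            fwhms.append(fit.fwhm_nm)
    return {"value": float(np.mean(fwhms)) if fwhms else math.nan, "n": len(fwhms)}
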