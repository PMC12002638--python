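"""Synthetic scene generation and rendering.

Builds ground-truth scenes of dendritic spines carrying trans-synaptically
aligned PSD-95/Bassoon nanocluster (NC) pairs ("nanomodules"), plus VGluT1
or VGluT2 presynaptic puncta marking corticocortical (CC) vs thalamocortical
(TC) input, and renders them into noisy multi-channel confocal/STED stacks.
Every downstream stage of the pipeline can then be validated by parameter
recovery against the recorded truth.

The imaging model: each fluorescent object is an isotropic Gaussian of
intrinsic FWHM ``size_nm`` convolved (in quadrature, per axis) with a
separable Gaussian PSF, sampled on an anisotropic voxel grid, scaled so the
expected photon count at the emitter peak is ``peak_photons * amplitude``,
with a constant expected background per voxel, then Poisson-sampled
(photon-counting detection; no read noise).

Frames also contain "neuropil" synapse units outside the labeled spines, so
that frame-statistics thresholds (mean + k*SD over the whole field) are set
by real structure, as they are in dense tissue images.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import gaussian_filter

from .grid import VoxelGrid, STED_GRID_SPACING, CONFOCAL_GRID_SPACING

__all__ = [
    "FWHM_TO_SIGMA",
    "OpticsModel",
    "SceneConfig",
    "Emitter",
    "SpineTruth",
    "RulerPair",
    "GroundTruthScene",
    "DEFAULT_OPTICS",
    "CC_BASAL_PMF",
    "TC_BASAL_PMF",
    "CC_APICAL_PMF",
    "TC_APICAL_PMF",
    "build_scene",
    "scene_from_json",
    "render_channels",
    "build_nanoruler_phantom",
    "build_spot_phantom",
    "rasterize_spines",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))  # sigma = FWHM * this

STED_CHANNELS = ("psd95", "bassoon")
CONFOCAL_CHANNELS = ("yfp", "vglut1", "vglut2")

# Nanomodule-count distributions over counts 1..4 (fractions of spines).
# Basal CC follows the per-category spine counts (308/107/20/4 of 439);
# basal TC follows the stated 68%/32% single/multiple split.
CC_BASAL_PMF = (308 / 439, 107 / 439, 20 / 439, 4 / 439)
TC_BASAL_PMF = (0.68, 0.28, 0.04, 0.0)
CC_APICAL_PMF = (329 / 507, 133 / 507, 31 / 507, 14 / 507)
TC_APICAL_PMF = (49 / 99, 39 / 99, 8 / 99, 3 / 99)


@dataclass(frozen=True)
class OpticsModel:
    """Per-channel imaging parameters.

    lateral_fwhm / axial_fwhm : PSF full widths at half maximum, nm.
    peak_photons : expected photons in the peak voxel of a unit-amplitude emitter.
    background_photons : expected photons per voxel away from any emitter.
    """

    lateral_fwhm: float
    axial_fwhm: float
    peak_photons: float
    background_photons: float = 0.0

    def __post_init__(self) -> None:
        if self.lateral_fwhm <= 0 or self.axial_fwhm <= 0:
            raise ValueError("PSF FWHMs must be positive")
        if self.peak_photons <= 0:
            raise ValueError("peak_photons must be positive")
        if self.background_photons < 0:
            raise ValueError("background_photons must be non-negative")

    @property
    def sigma_nm(self) -> tuple[float, float, float]:
        s_lat = self.lateral_fwhm * FWHM_TO_SIGMA
        return (self.axial_fwhm * FWHM_TO_SIGMA, s_lat, s_lat)


# STED: ~50 nm lateral resolution; the axial FWHM is not pinned down by a
# bead-separability figure alone, so the default (130 nm) is this package's
# choice for 3D STED at 20% z-depletion power -- see docs/methods.md.
# Tissue STED channels run at ~8 expected peak photons (photon-counting
# regime); the confocal channels are brighter. Calibration phantoms use
# RULER_OPTICS (bright GATTA slides).
DEFAULT_OPTICS: dict[str, OpticsModel] = {
    "yfp": OpticsModel(250.0, 600.0, peak_photons=30.0, background_photons=1.0),
    "vglut1": OpticsModel(250.0, 600.0, peak_photons=15.0, background_photons=0.5),
    "vglut2": OpticsModel(250.0, 600.0, peak_photons=15.0, background_photons=0.5),
    "psd95": OpticsModel(50.0, 130.0, peak_photons=8.0, background_photons=0.05),
    "bassoon": OpticsModel(50.0, 130.0, peak_photons=8.0, background_photons=0.05),
}

RULER_OPTICS = OpticsModel(50.0, 130.0, peak_photons=100.0, background_photons=0.05)


@dataclass(frozen=True)
class Emitter:
    """A single fluorescent object: Gaussian of intrinsic FWHM ``size_nm``."""

    channel: str
    center_nm: tuple[float, float, float]  # (z, y, x)
    size_nm: float
    amplitude: float = 1.0
    spine_id: int | None = None  # owning spine, or None for neuropil/phantom


@dataclass
class SpineTruth:
    """Ground truth for one dendritic spine."""

    id: int
    input_class: str  # "CC" or "TC"
    nanomodule_count: int
    head_center_nm: tuple[float, float, float]
    head_radius_nm: float
    volume_um3: float  # target volume of the analytic head + neck
    psd95_centers_nm: list[tuple[float, float, float]] = field(default_factory=list)
    bassoon_centers_nm: list[tuple[float, float, float]] = field(default_factory=list)

    NECK_LENGTH_NM = 350.0
    NECK_RADIUS_NM = 100.0


@dataclass(frozen=True)
class RulerPair:
    """One nano-ruler: two point emitters at a designed spacing."""

    id: int
    designed_nm: float
    realized_nm: float
    axis: str  # "lateral" | "axial"
    center_nm: tuple[float, float, float]
    unit_vector: tuple[float, float, float]


# Geometric margins for placing PSD-95 emitters inside the spine head so
# that, after rendering + thresholding + mask discretization, their voxel
# sets remain entirely inside the head ROI (the paper's assignment rule).
_PSD_LATERAL_MARGIN_NM = 200.0
_PSD_AXIAL_MARGIN_NM = 280.0
_PSD_MIN_SEP_NM = 300.0
_PSD_MIN_LATERAL_SEP_NM = 220.0
_NC_SIZE_CLIP_NM = (100.0, 200.0)
_SHAFT_RADIUS_NM = 250.0


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of a synthetic spine scene.

    Defaults follow the basal-dendrite study conditions: 13.4% of spines
    receive TC (VGluT2+) input; nanomodule counts per spine are drawn from
    class-specific distributions over 1..4; trans-synaptic PSD-95/Bassoon
    centers are separated by ~140 nm, oriented axially or laterally per
    ``cleft_axis_mix``; NC sizes ~150 +/- 25 nm; spine volume grows linearly
    with nanomodule count (~0.36 um^3 per module) with lognormal scatter.
    """

    n_spines: int
    p_tc: float = 68 / 507
    nanomodule_count_pmf: dict = field(
        default_factory=lambda: {"CC": CC_BASAL_PMF, "TC": TC_BASAL_PMF}
    )
    cleft_offset_nm: float = 140.0
    cleft_axis_mix: float = 0.5  # fraction of pairs oriented axially
    nc_size_mean_nm: float = 150.0
    nc_size_sd_nm: float = 25.0
    spine_volume_base_um3: float = 0.05
    spine_volume_per_module_um3: float = 0.36
    spine_volume_sigma_log: float = 0.25
    min_spine_separation_nm: float = 500.0
    neuropil_density_um2: float = 2.0
    neuropil_paired_fraction: float = 0.6
    vglut_neuropil_density_um2: float = 0.05
    vglut_size_nm: float = 350.0
    stack_depth_nm: float = 2100.0
    exact_fractions: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_spines < 0:
            raise ValueError("n_spines must be >= 0")
        if not 0.0 <= self.p_tc <= 1.0:
            raise ValueError("p_tc must lie in [0, 1]")
        if self.cleft_offset_nm < 0:
            raise ValueError("cleft_offset_nm must be >= 0")
        if not 0.0 <= self.cleft_axis_mix <= 1.0:
            raise ValueError("cleft_axis_mix must lie in [0, 1]")
        for cls in ("CC", "TC"):
            pmf = np.asarray(self.nanomodule_count_pmf[cls], dtype=float)
            if pmf.shape != (4,) or np.any(pmf < 0) or abs(pmf.sum() - 1.0) > 1e-9:
                raise ValueError(f"{cls} nanomodule pmf must be 4 non-negative values summing to 1")


@dataclass
class GroundTruthScene:
    """The generator's truth: the recovery oracle for every pipeline stage."""

    config: SceneConfig
    box_nm: tuple[float, float, float]  # physical extent (z, y, x)
    spines: list[SpineTruth]
    emitters: list[Emitter]
    shaft_rows: list[tuple[float, float]]  # (y, z) of each shaft axis (along x)
    rulers: list[RulerPair] | None = None

    def default_grids(self) -> dict[str, VoxelGrid]:
        grids = {}
        for ch in CONFOCAL_CHANNELS:
            grids[ch] = _grid_for_box(self.box_nm, CONFOCAL_GRID_SPACING)
        for ch in STED_CHANNELS:
            grids[ch] = _grid_for_box(self.box_nm, STED_GRID_SPACING)
        return grids

    def emitters_in(self, channel: str) -> list[Emitter]:
        return [e for e in self.emitters if e.channel == channel]

    def to_json(self) -> str:
        """Serialize the truth (deterministically) for audit / comparison."""
        payload = {
            "config": {**asdict(self.config), "nanomodule_count_pmf": {
                k: list(v) for k, v in self.config.nanomodule_count_pmf.items()}},
            "box_nm": list(self.box_nm),
            "spines": [
                {
                    "id": s.id,
                    "input_class": s.input_class,
                    "nanomodule_count": s.nanomodule_count,
                    "head_center_nm": list(s.head_center_nm),
                    "head_radius_nm": s.head_radius_nm,
                    "volume_um3": s.volume_um3,
                    "psd95_centers_nm": [list(c) for c in s.psd95_centers_nm],
                    "bassoon_centers_nm": [list(c) for c in s.bassoon_centers_nm],
                }
                for s in self.spines
            ],
            "emitters": [
                {
                    "channel": e.channel,
                    "center_nm": list(e.center_nm),
                    "size_nm": e.size_nm,
                    "amplitude": e.amplitude,
                    "spine_id": e.spine_id,
                }
                for e in self.emitters
            ],
            "rulers": None if self.rulers is None else [asdict(r) for r in self.rulers],
        }
        return json.dumps(payload, sort_keys=True)


def _grid_for_box(box_nm, spacing) -> VoxelGrid:
    shape = tuple(max(1, int(math.floor(b / s)) + 1) for b, s in zip(box_nm, spacing))
    return VoxelGrid(shape=shape, spacing=tuple(spacing))


def scene_from_json(text: str) -> GroundTruthScene:
    """Rebuild a GroundTruthScene from its ``to_json`` serialization."""
    raw = json.loads(text)
    cfg_raw = dict(raw["config"])
    cfg_raw["nanomodule_count_pmf"] = {
        k: tuple(v) for k, v in cfg_raw["nanomodule_count_pmf"].items()}
    cfg = SceneConfig(**cfg_raw)
    spines = [
        SpineTruth(
            id=s["id"], input_class=s["input_class"],
            nanomodule_count=s["nanomodule_count"],
            head_center_nm=tuple(s["head_center_nm"]),
            head_radius_nm=s["head_radius_nm"], volume_um3=s["volume_um3"],
            psd95_centers_nm=[tuple(c) for c in s["psd95_centers_nm"]],
            bassoon_centers_nm=[tuple(c) for c in s["bassoon_centers_nm"]],
        )
        for s in raw["spines"]
    ]
    emitters = [
        Emitter(e["channel"], tuple(e["center_nm"]), e["size_nm"], e["amplitude"],
                e["spine_id"])
        for e in raw["emitters"]
    ]
    rulers = None if raw["rulers"] is None else [
        RulerPair(**{**r, "center_nm": tuple(r["center_nm"]),
                     "unit_vector": tuple(r["unit_vector"])})
        for r in raw["rulers"]
    ]
    # shaft rows are re-derived from the spine layout (one per head row)
    shaft_rows = []
    if spines:
        max_r = max(s.head_radius_nm for s in spines)
        ys = sorted({round(s.head_center_nm[1], -2) for s in spines})
        zs = float(np.mean([s.head_center_nm[0] for s in spines]))
        merged: list[float] = []
        for y in ys:
            if not merged or y - merged[-1] > 1000.0:
                merged.append(y)
        shaft_rows = [(y - max_r - SpineTruth.NECK_LENGTH_NM - _SHAFT_RADIUS_NM, zs)
                      for y in merged]
    return GroundTruthScene(config=cfg, box_nm=tuple(raw["box_nm"]), spines=spines,
                            emitters=emitters, shaft_rows=shaft_rows, rulers=rulers)


# ---------------------------------------------------------------------------
# scene construction
# ---------------------------------------------------------------------------


def _exact_counts(pmf: np.ndarray, n: int) -> np.ndarray:
    """Integer composition of n items matching pmf by largest remainder."""
    raw = pmf * n
    base = np.floor(raw).astype(int)
    short = n - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:short]] += 1
    return base


def _draw_counts(rng, pmf, n, exact):
    values = np.arange(1, 5)
    pmf = np.asarray(pmf, dtype=float)
    if n == 0:
        return np.empty(0, dtype=int)
    if exact:
        counts = np.repeat(values, _exact_counts(pmf, n))
        rng.shuffle(counts)
        return counts
    return rng.choice(values, size=n, p=pmf)


def _sample_offset_direction(rng, axis_mix: float) -> np.ndarray:
    """Unit offset vector: axial (+-z) with probability axis_mix, else lateral."""
    if rng.random() < axis_mix:
        return np.array([rng.choice([-1.0, 1.0]), 0.0, 0.0])
    phi = rng.uniform(0.0, 2.0 * math.pi)
    return np.array([0.0, math.sin(phi), math.cos(phi)])


def _place_psd_centers(rng, count, head_center, radius):
    """PSD-95 centers inside the head with lateral/axial margins and minimum
    pairwise separation (so distinct nanomodules stay resolvable)."""
    lat_max = radius - _PSD_LATERAL_MARGIN_NM
    z_max = min(100.0, max(0.0, radius - _PSD_AXIAL_MARGIN_NM))
    if lat_max <= 0:
        raise ValueError(f"spine head radius {radius:.0f} nm too small for NC placement")
    for _ in range(4000):
        pts = []
        ok = True
        for _ in range(count):
            for _ in range(200):
                r = lat_max * math.sqrt(rng.random())
                phi = rng.uniform(0, 2 * math.pi)
                dz = rng.uniform(-z_max, z_max)
                cand = np.array([head_center[0] + dz,
                                 head_center[1] + r * math.sin(phi),
                                 head_center[2] + r * math.cos(phi)])
                good = True
                for p in pts:
                    d = cand - p
                    if np.linalg.norm(d) < _PSD_MIN_SEP_NM or np.hypot(d[1], d[2]) < _PSD_MIN_LATERAL_SEP_NM:
                        good = False
                        break
                if good:
                    pts.append(cand)
                    break
            else:
                ok = False
                break
        if ok:
            return pts
    raise ValueError("could not place nanomodules inside spine head")


def _nc_size(rng, cfg) -> float:
    s = rng.normal(cfg.nc_size_mean_nm, cfg.nc_size_sd_nm)
    return float(np.clip(s, *_NC_SIZE_CLIP_NM))


def _nc_amplitude(rng) -> float:
    return float(np.clip(rng.lognormal(mean=0.0, sigma=0.25), 0.5, 2.0))


def build_scene(config: SceneConfig) -> GroundTruthScene:
    """Generate a ground-truth scene of spines (plus neuropil) from ``config``.

    Spines sit on a jittered 2D lattice (head rows above/below short dendrite
    shafts) with center-to-center pitch large enough that neighboring heads
    stay at least ``min_spine_separation_nm`` apart. Identical (config, seed)
    yields bit-identical truth.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0x5C33]))
    n = config.n_spines
    cfg = config

    # -- per-spine draws ------------------------------------------------
    if n > 0:
        if cfg.exact_fractions:
            n_tc = int(round(n * cfg.p_tc))
            classes = np.array(["TC"] * n_tc + ["CC"] * (n - n_tc))
            rng.shuffle(classes)
        else:
            classes = np.where(rng.random(n) < cfg.p_tc, "TC", "CC")
        counts = np.empty(n, dtype=int)
        for cls in ("CC", "TC"):
            idx = np.flatnonzero(classes == cls)
            counts[idx] = _draw_counts(rng, cfg.nanomodule_count_pmf[cls], len(idx),
                                       cfg.exact_fractions)
        # unit-mean lognormal scatter (clipped at +-2 sigma in log space) so
        # E[volume | count] stays linear in the count
        log_sd = cfg.spine_volume_sigma_log
        noise = np.exp(np.clip(rng.normal(0.0, log_sd, size=n), -2 * log_sd, 2 * log_sd)
                       - log_sd**2 / 2)
        volumes = (cfg.spine_volume_base_um3
                   + cfg.spine_volume_per_module_um3 * counts) * noise
    else:
        classes = np.empty(0, dtype=object)
        counts = np.empty(0, dtype=int)
        volumes = np.empty(0)

    neck_vol = math.pi * SpineTruth.NECK_RADIUS_NM**2 * SpineTruth.NECK_LENGTH_NM * 1e-9
    head_radii = np.array([
        (max(v - neck_vol, 0.05) * 3 / (4 * math.pi) * 1e9) ** (1 / 3) for v in volumes
    ])

    # -- layout ---------------------------------------------------------
    max_r = float(head_radii.max()) if n else 500.0
    pitch = 2 * max_r + cfg.min_spine_separation_nm + 200.0
    n_cols = max(1, math.ceil(math.sqrt(n))) if n else 1
    n_rows = max(1, math.ceil(n / n_cols)) if n else 1
    margin = max_r + 700.0
    box = (
        cfg.stack_depth_nm,
        2 * margin + (n_rows - 1) * pitch,
        2 * margin + (n_cols - 1) * pitch,
    )
    z_mid = box[0] / 2.0

    spines: list[SpineTruth] = []
    emitters: list[Emitter] = []
    shaft_rows: list[tuple[float, float]] = []
    for i in range(n):
        row, col = divmod(i, n_cols)
        r = float(head_radii[i])
        center = np.array([
            z_mid + rng.uniform(-100.0, 100.0),
            margin + row * pitch + rng.uniform(-80.0, 80.0),
            margin + col * pitch + rng.uniform(-80.0, 80.0),
        ])
        sp = SpineTruth(
            id=i + 1,
            input_class=str(classes[i]),
            nanomodule_count=int(counts[i]),
            head_center_nm=tuple(center),
            head_radius_nm=r,
            volume_um3=float(volumes[i]),
        )
        psd_pts = _place_psd_centers(rng, sp.nanomodule_count, center, r)
        for p in psd_pts:
            direction = _sample_offset_direction(rng, cfg.cleft_axis_mix)
            b = p + cfg.cleft_offset_nm * direction
            sp.psd95_centers_nm.append(tuple(p))
            sp.bassoon_centers_nm.append(tuple(b))
            emitters.append(Emitter("psd95", tuple(p), _nc_size(rng, cfg),
                                    _nc_amplitude(rng), spine_id=sp.id))
            emitters.append(Emitter("bassoon", tuple(b), _nc_size(rng, cfg),
                                    _nc_amplitude(rng), spine_id=sp.id))
        # presynaptic VGluT bouton abutting the head, on the side away from the neck
        vg_channel = "vglut2" if sp.input_class == "TC" else "vglut1"
        vg_pos = center + np.array([0.0, r + 100.0, 0.0])
        emitters.append(Emitter(vg_channel, tuple(vg_pos), cfg.vglut_size_nm,
                                1.0, spine_id=sp.id))
        spines.append(sp)
    for row in range(n_rows if n else 0):
        shaft_rows.append((margin + row * pitch - max_r - SpineTruth.NECK_LENGTH_NM
                           - _SHAFT_RADIUS_NM, z_mid))

    _add_neuropil(rng, cfg, box, spines, emitters)
    return GroundTruthScene(config=cfg, box_nm=box, spines=spines,
                            emitters=emitters, shaft_rows=shaft_rows)


def _add_neuropil(rng, cfg, box, spines, emitters) -> None:
    """Scatter non-spine synapse units (paired or single NCs) and VGluT
    puncta through the field, away from labeled spine heads."""
    area_um2 = (box[1] * box[2]) * 1e-6
    heads = np.array([s.head_center_nm for s in spines]).reshape(-1, 3)
    radii = np.array([s.head_radius_nm for s in spines]).reshape(-1)
    placed: list[np.ndarray] = []

    def _try_place(min_head_clear: float, min_unit_sep: float):
        for _ in range(60):
            pos = np.array([
                rng.uniform(300.0, box[0] - 300.0),
                rng.uniform(300.0, box[1] - 300.0),
                rng.uniform(300.0, box[2] - 300.0),
            ])
            if len(heads) and np.any(np.linalg.norm(heads - pos, axis=1) < radii + min_head_clear):
                continue
            if placed and min_unit_sep > 0:
                d = np.linalg.norm(np.asarray(placed) - pos, axis=1)
                if np.any(d < min_unit_sep):
                    continue
            return pos
        return None

    n_units = rng.poisson(cfg.neuropil_density_um2 * area_um2)
    kinds = rng.random(n_units)
    for k in kinds:
        pos = _try_place(min_head_clear=250.0, min_unit_sep=350.0)
        if pos is None:
            continue
        placed.append(pos)
        paired = k < cfg.neuropil_paired_fraction
        psd_only = cfg.neuropil_paired_fraction <= k < cfg.neuropil_paired_fraction + 0.5 * (1 - cfg.neuropil_paired_fraction)
        if paired or psd_only:
            emitters.append(Emitter("psd95", tuple(pos), _nc_size(rng, cfg), _nc_amplitude(rng)))
        if paired:
            b = pos + cfg.cleft_offset_nm * _sample_offset_direction(rng, cfg.cleft_axis_mix)
            emitters.append(Emitter("bassoon", tuple(b), _nc_size(rng, cfg), _nc_amplitude(rng)))
        elif not psd_only:
            emitters.append(Emitter("bassoon", tuple(pos), _nc_size(rng, cfg), _nc_amplitude(rng)))

    n_vg = rng.poisson(cfg.vglut_neuropil_density_um2 * area_um2)
    for _ in range(n_vg):
        pos = _try_place(min_head_clear=350.0, min_unit_sep=0.0)
        if pos is None:
            continue
        ch = "vglut1" if rng.random() < 0.85 else "vglut2"
        emitters.append(Emitter(ch, tuple(pos), cfg.vglut_size_nm, 1.0))


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _effective_sigma_nm(size_nm: float, optics: OpticsModel) -> np.ndarray:
    """Per-axis sigma (z, y, x) of intrinsic size convolved with the PSF."""
    s_int = size_nm * FWHM_TO_SIGMA
    return np.sqrt(np.asarray(optics.sigma_nm) ** 2 + s_int**2)


def _add_gaussian(image: np.ndarray, grid: VoxelGrid, center_nm, sigma_nm,
                  peak: float) -> None:
    """Accumulate a separable Gaussian into ``image`` over a +-4.5 sigma window."""
    idx_c = grid.physical_to_index(center_nm)
    slices = []
    axes_vals = []
    for ax in range(3):
        half = int(math.ceil(4.5 * sigma_nm[ax] / grid.spacing[ax])) + 1
        lo = max(0, int(math.floor(idx_c[ax])) - half)
        hi = min(grid.shape[ax], int(math.ceil(idx_c[ax])) + half + 1)
        if lo >= hi:
            return
        coords = grid.axis_coordinates(ax)[lo:hi]
        axes_vals.append(np.exp(-0.5 * ((coords - center_nm[ax]) / sigma_nm[ax]) ** 2))
        slices.append(slice(lo, hi))
    image[tuple(slices)] += peak * (
        axes_vals[0][:, None, None] * axes_vals[1][None, :, None] * axes_vals[2][None, None, :]
    )


def _check_footprint(sigma_nm, grid: VoxelGrid) -> None:
    fwhm = np.asarray(sigma_nm) / FWHM_TO_SIGMA
    for ax in range(3):
        if fwhm[ax] < grid.spacing[ax] / 2.0:
            raise ValueError(
                f"emitter footprint (FWHM {fwhm[ax]:.0f} nm on axis {ax}) is below "
                f"half the voxel spacing ({grid.spacing[ax]:.0f} nm): grid too coarse"
            )


def render_channels(
    scene: GroundTruthScene,
    grids: dict[str, VoxelGrid] | None = None,
    optics: dict[str, OpticsModel] | None = None,
    noise: bool = True,
) -> dict[str, np.ndarray]:
    """Render every channel of ``scene`` into a photon-count stack.

    With ``noise=False`` the expected (noiseless) photon image is returned;
    otherwise each channel is an independent Poisson sample seeded from the
    scene seed, so identical (scene, grids, optics) render bit-identically.
    """
    grids = scene.default_grids() if grids is None else grids
    optics = DEFAULT_OPTICS if optics is None else optics
    out: dict[str, np.ndarray] = {}
    channel_names = sorted(grids)
    seeds = np.random.SeedSequence([int(scene.config.seed), 0xA11CE]).spawn(len(channel_names))
    for ch, sseq in zip(channel_names, seeds):
        if ch not in optics:
            raise KeyError(f"no optics entry for channel '{ch}'")
        grid, opt = grids[ch], optics[ch]
        image = np.full(grid.shape, float(opt.background_photons))
        if ch == "yfp":
            _render_morphology(image, scene, grid, opt)
        for em in scene.emitters_in(ch):
            sigma = _effective_sigma_nm(em.size_nm, opt)
            _check_footprint(sigma, grid)
            _add_gaussian(image, grid, em.center_nm, sigma, opt.peak_photons * em.amplitude)
        if noise:
            image = np.random.default_rng(sseq).poisson(image).astype(np.float64)
        out[ch] = image
    return out


def _render_morphology(image, scene, grid, opt) -> None:
    labels = rasterize_spines(scene, grid)
    vol = (labels > 0).astype(float)
    for y0, z0 in scene.shaft_rows:
        zz = grid.axis_coordinates(0)[:, None]
        yy = grid.axis_coordinates(1)[None, :]
        inside = ((zz - z0) ** 2 + (yy - y0) ** 2) <= _SHAFT_RADIUS_NM**2
        vol += inside[:, :, None].astype(float)
    np.clip(vol, 0.0, 1.0, out=vol)
    sig_vox = np.asarray(opt.sigma_nm) / np.asarray(grid.spacing)
    image += opt.peak_photons * gaussian_filter(vol, sigma=sig_vox)


def rasterize_spines(scene: GroundTruthScene, grid: VoxelGrid) -> np.ndarray:
    """Label volume of the analytic spine masks (head sphere + neck cylinder)
    on ``grid``: 0 = background, i = spine id. Masks never overlap."""
    labels = np.zeros(grid.shape, dtype=np.int32)
    for sp in scene.spines:
        c = np.asarray(sp.head_center_nm)
        r = sp.head_radius_nm
        lo_nm = c - np.array([r, r + SpineTruth.NECK_LENGTH_NM, r])
        hi_nm = c + r
        lo = np.maximum(np.floor(grid.physical_to_index(lo_nm)).astype(int) - 1, 0)
        hi = np.minimum(np.ceil(grid.physical_to_index(hi_nm)).astype(int) + 2,
                        np.asarray(grid.shape))
        if np.any(lo >= hi):
            continue
        zz = grid.axis_coordinates(0)[lo[0]:hi[0], None, None]
        yy = grid.axis_coordinates(1)[None, lo[1]:hi[1], None]
        xx = grid.axis_coordinates(2)[None, None, lo[2]:hi[2]]
        head = ((zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2) <= r**2
        neck = (((zz - c[0]) ** 2 + (xx - c[2]) ** 2) <= SpineTruth.NECK_RADIUS_NM**2) & \
               (yy <= c[1]) & (yy >= c[1] - r - SpineTruth.NECK_LENGTH_NM)
        region = labels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        region[head | neck] = sp.id
    return labels


def expected_total_photons(scene: GroundTruthScene, grid: VoxelGrid,
                           optics: OpticsModel, channel: str) -> float:
    """Analytic expected photon sum of a noiseless render of one channel
    (per-axis Gaussian sample sums on the actual grid + background)."""
    total = optics.background_photons * float(np.prod(grid.shape))
    for em in scene.emitters_in(channel):
        sigma = _effective_sigma_nm(em.size_nm, optics)
        s = optics.peak_photons * em.amplitude
        for ax in range(3):
            coords = grid.axis_coordinates(ax)
            s *= float(np.sum(np.exp(-0.5 * ((coords - em.center_nm[ax]) / sigma[ax]) ** 2)))
        total += s
    return total


# ---------------------------------------------------------------------------
# calibration phantoms
# ---------------------------------------------------------------------------


def _phantom_grid(n_sites: int, pitch_nm: float, spacing, depth_nm: float) -> VoxelGrid:
    n_cols = max(1, math.ceil(math.sqrt(n_sites)))
    n_rows = max(1, math.ceil(n_sites / n_cols))
    box = (depth_nm, 1600.0 + (n_rows - 1) * pitch_nm, 1600.0 + (n_cols - 1) * pitch_nm)
    return _grid_for_box(box, spacing)


def build_nanoruler_phantom(
    spacing_nm: float,
    axis: str,
    n_pairs: int,
    grid: VoxelGrid | None = None,
    optics: OpticsModel = RULER_OPTICS,
    seed: int = 0,
    jitter_sd_nm: float = 2.5,
    noise: bool = True,
    pitch_nm: float = 1500.0,
) -> tuple[np.ndarray, VoxelGrid, list[RulerPair]]:
    """Render a field of GATTA-style nano-ruler bead pairs.

    Each pair is two point emitters exactly ``spacing_nm`` apart (plus
    Gaussian manufacturing jitter of SD ``jitter_sd_nm``) along the requested
    axis: ``lateral`` pairs lie in the focal plane at a random azimuth;
    ``axial`` pairs are stacked along z and placed so the pair straddles at
    least one z-plane boundary (as a mounted 3D ruler imaged in focus does).
    Pairs sit >= 1 um apart. Truth records designed and realized spacings.
    """
    if spacing_nm < 0:
        raise ValueError("spacing_nm must be >= 0")
    if axis not in ("lateral", "axial"):
        raise ValueError("axis must be 'lateral' or 'axial'")
    if pitch_nm < 1000.0:
        raise ValueError("ruler pairs must be placed >= 1 um apart")
    if grid is None:
        grid = _phantom_grid(n_pairs, pitch_nm, STED_GRID_SPACING, depth_nm=1500.0)
    if axis == "axial" and grid.shape[0] < 5:
        raise ValueError("axial phantoms need a grid with at least 5 z-planes")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xBEAD]))
    dz = grid.spacing[0]
    n_cols = max(1, math.ceil(math.sqrt(n_pairs)))
    z_mid = (grid.shape[0] - 1) * dz / 2.0
    pairs: list[RulerPair] = []
    image = np.full(grid.shape, float(optics.background_photons))
    for i in range(n_pairs):
        row, col = divmod(i, n_cols)
        center = np.array([
            z_mid,
            800.0 + row * pitch_nm + rng.uniform(-100.0, 100.0),
            800.0 + col * pitch_nm + rng.uniform(-100.0, 100.0),
        ])
        realized = max(0.0, spacing_nm + rng.normal(0.0, jitter_sd_nm)) if jitter_sd_nm > 0 else spacing_nm
        if axis == "lateral":
            phi = rng.uniform(0, 2 * math.pi)
            u = np.array([0.0, math.sin(phi), math.cos(phi)])
            center[0] += rng.uniform(-dz / 2, dz / 2)
        else:
            u = np.array([1.0, 0.0, 0.0])
            # z-phase such that [z - s/2, z + s/2] contains a plane boundary
            if realized > 0:
                boundary = (math.floor(z_mid / dz) + 0.5) * dz
                half = min(realized / 2.0, dz / 2.0)
                center[0] = boundary + rng.uniform(-half, half)
        half_vec = 0.5 * realized * u
        amp = _nc_amplitude(rng)
        for sgn in (-1.0, 1.0):
            pos = center + sgn * half_vec
            sigma = _effective_sigma_nm(0.0, optics)
            _check_footprint(sigma, grid)
            _add_gaussian(image, grid, pos, sigma, optics.peak_photons * amp)
        pairs.append(RulerPair(id=i + 1, designed_nm=spacing_nm, realized_nm=realized,
                               axis=axis, center_nm=tuple(center), unit_vector=tuple(u)))
    if noise:
        image = np.random.default_rng(np.random.SeedSequence([int(seed), 0xD1CE])).poisson(
            image).astype(np.float64)
    return image, grid, pairs


def build_spot_phantom(
    n_spots: int,
    intrinsic_fwhm_nm: float,
    grid: VoxelGrid | None = None,
    optics: OpticsModel | None = None,
    seed: int = 0,
    noise: bool = True,
    pitch_nm: float = 1500.0,
) -> tuple[np.ndarray, VoxelGrid, list[Emitter]]:
    """Render a field of isolated clusters of a fixed intrinsic FWHM
    (image-domain FWHM = sqrt(intrinsic^2 + PSF^2)); used for FWHM-estimator
    calibration."""
    optics = DEFAULT_OPTICS["psd95"] if optics is None else optics
    if grid is None:
        grid = _phantom_grid(n_spots, pitch_nm, STED_GRID_SPACING, depth_nm=1800.0)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5B07]))
    n_cols = max(1, math.ceil(math.sqrt(n_spots)))
    z_mid = (grid.shape[0] - 1) * grid.spacing[0] / 2.0
    image = np.full(grid.shape, float(optics.background_photons))
    emitters: list[Emitter] = []
    for i in range(n_spots):
        row, col = divmod(i, n_cols)
        pos = (
            z_mid + rng.uniform(-grid.spacing[0] / 2, grid.spacing[0] / 2),
            800.0 + row * pitch_nm + rng.uniform(-100.0, 100.0),
            800.0 + col * pitch_nm + rng.uniform(-100.0, 100.0),
        )
        em = Emitter("spots", pos, float(intrinsic_fwhm_nm), 1.0)
        sigma = _effective_sigma_nm(em.size_nm, optics)
        _check_footprint(sigma, grid)
        _add_gaussian(image, grid, pos, sigma, optics.peak_photons)
        emitters.append(em)
    if noise:
        image = np.random.default_rng(np.random.SeedSequence([int(seed), 0xF00D])).poisson(
            image).astype(np.float64)
    return image, grid, emitters
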