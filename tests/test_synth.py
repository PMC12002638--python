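import math

import numpy as np
import pytest

from nanospine import (
    DEFAULT_OPTICS,
    OpticsModel,
    SceneConfig,
    VoxelGrid,
    build_nanoruler_phantom,
    build_scene,
    build_spot_phantom,
    rasterize_spines,
    render_channels,
    scene_from_json,
)
from nanospine.profiles import fit_fwhm, line_profile, peak_separation
from nanospine.cluster3d import segment_nanoclusters
from nanospine.synth import expected_total_photons, _effective_sigma_nm


def _quiet_config(**kw):
    kw.setdefault("neuropil_density_um2", 0.0)
    kw.setdefault("vglut_neuropil_density_um2", 0.0)
    return SceneConfig(**kw)


class TestSceneTruth:
    def test_empty_scene_has_no_spines_or_emitters(self):
        scene = build_scene(_quiet_config(n_spines=0, seed=1))
        assert scene.spines == [] and scene.emitters == []

    def test_degenerate_pmf_gives_single_module_tc_spines(self):
        cfg = _quiet_config(
            n_spines=6, seed=2, p_tc=1.0,
            nanomodule_count_pmf={"CC": (1, 0, 0, 0), "TC": (1, 0, 0, 0)},
        )
        scene = build_scene(cfg)
        assert all(s.input_class == "TC" for s in scene.spines)
        assert all(s.nanomodule_count == 1 for s in scene.spines)
        assert all(len(s.psd95_centers_nm) == 1 for s in scene.spines)

    def test_identical_seed_is_bit_identical_and_seeds_differ(self):
        a = build_scene(SceneConfig(n_spines=8, seed=7)).to_json()
        b = build_scene(SceneConfig(n_spines=8, seed=7)).to_json()
        c = build_scene(SceneConfig(n_spines=8, seed=8)).to_json()
        assert a == b
        assert a != c

    def test_truth_serialization_round_trip(self):
        scene = build_scene(SceneConfig(n_spines=5, seed=3))
        back = scene_from_json(scene.to_json())
        assert back.to_json() == scene.to_json()

    def test_psd_emitters_lie_in_exactly_one_spine_mask(self, small_scene):
        scene, grids, _ = small_scene
        labels = rasterize_spines(scene, grids["yfp"])
        for sp in scene.spines:
            for c in sp.psd95_centers_nm:
                idx = grids["yfp"].physical_to_nearest(np.asarray(c))
                assert labels[tuple(idx)] == sp.id

    def test_pair_separation_equals_cleft_offset(self, small_scene):
        scene, _, _ = small_scene
        off = scene.config.cleft_offset_nm
        for sp in scene.spines:
            for p, b in zip(sp.psd95_centers_nm, sp.bassoon_centers_nm):
                d = np.linalg.norm(np.asarray(p) - np.asarray(b))
                assert d == pytest.approx(off, abs=1e-6)

    def test_exact_fractions_realize_composition(self):
        cfg = SceneConfig(n_spines=50, seed=9, p_tc=0.2, exact_fractions=True)
        scene = build_scene(cfg)
        assert sum(s.input_class == "TC" for s in scene.spines) == 10


class TestRendering:
    def test_render_is_deterministic_per_seed(self):
        cfg = SceneConfig(n_spines=4, seed=5)
        scene = build_scene(cfg)
        grids = {"psd95": scene.default_grids()["psd95"]}
        a = render_channels(scene, grids)["psd95"]
        b = render_channels(scene, grids)["psd95"]
        assert np.array_equal(a, b)

    def test_photon_conservation_against_dense_oracle(self):
        cfg = _quiet_config(n_spines=3, seed=6)
        scene = build_scene(cfg)
        grid = scene.default_grids()["psd95"]
        opt = DEFAULT_OPTICS["psd95"]
        image = render_channels(scene, {"psd95": grid}, noise=False)["psd95"]
        zz = grid.axis_coordinates(0)[:, None, None]
        yy = grid.axis_coordinates(1)[None, :, None]
        xx = grid.axis_coordinates(2)[None, None, :]
        dense = np.full(grid.shape, opt.background_photons)
        for em in scene.emitters_in("psd95"):
            s = _effective_sigma_nm(em.size_nm, opt)
            dense += opt.peak_photons * em.amplitude * np.exp(
                -0.5 * (((zz - em.center_nm[0]) / s[0]) ** 2
                        + ((yy - em.center_nm[1]) / s[1]) ** 2
                        + ((xx - em.center_nm[2]) / s[2]) ** 2))
        assert image.sum() == pytest.approx(dense.sum(), rel=1e-3)
        assert expected_total_photons(scene, grid, opt, "psd95") == pytest.approx(
            dense.sum(), rel=1e-3)

    def test_poisson_mean_matches_noiseless_render(self):
        grid = VoxelGrid(shape=(5, 31, 31), spacing=(150.0, 20.0, 20.0))
        noiseless, _, _ = build_spot_phantom(1, 150.0, grid=grid, seed=0, noise=False)
        totals = [build_spot_phantom(1, 150.0, grid=grid, seed=s, noise=True)[0].sum()
                  for s in range(60)]
        se = math.sqrt(noiseless.sum() / 60)  # Poisson: var(total) = expected total
        assert abs(np.mean(totals) - noiseless.sum()) < 3 * se
        assert not np.array_equal(
            build_spot_phantom(1, 150.0, grid=grid, seed=1)[0],
            build_spot_phantom(1, 150.0, grid=grid, seed=2)[0])

    def test_point_source_reproduces_psf_fwhm(self):
        image, grid, ems = build_spot_phantom(1, 0.0, seed=0, noise=False)
        prof = line_profile(image[int(round(
            (ems[0].center_nm[0] - grid.origin[0]) / grid.spacing[0]))],
            grid, ems[0].center_nm[1:], (0.0, 1.0), length_nm=600.0)
        fit = fit_fwhm(prof)
        assert fit.ok
        assert fit.fwhm_nm == pytest.approx(DEFAULT_OPTICS["psd95"].lateral_fwhm,
                                            abs=grid.spacing[2])

    def test_quadrature_law_across_sizes(self, rng):
        psf = DEFAULT_OPTICS["psd95"].lateral_fwhm
        for size in rng.uniform(80.0, 250.0, size=10):
            image, grid, ems = build_spot_phantom(1, float(size), seed=0, noise=False)
            k = int(round((ems[0].center_nm[0] - grid.origin[0]) / grid.spacing[0]))
            prof = line_profile(image[k], grid, ems[0].center_nm[1:], (0.0, 1.0),
                                length_nm=1400.0)
            fit = fit_fwhm(prof)
            assert fit.ok
            assert fit.fwhm_nm == pytest.approx(math.hypot(size, psf),
                                                abs=grid.spacing[2] / 2)

    def test_too_coarse_grid_rejected(self):
        coarse = VoxelGrid(shape=(5, 10, 10), spacing=(150.0, 200.0, 200.0))
        with pytest.raises(ValueError, match="too coarse"):
            build_spot_phantom(1, 0.0, grid=coarse, seed=0)


class TestNanorulerPhantom:
    def test_lateral_truth_lists_all_pairs_with_jittered_spacing(self):
        _, _, pairs = build_nanoruler_phantom(50.0, "lateral", 43, seed=1)
        assert len(pairs) == 43
        realized = np.array([p.realized_nm for p in pairs])
        assert np.all(np.abs(realized - 50.0) < 12.0)
        assert realized.std() > 0

    def test_axial_pairs_straddle_a_zplane_boundary(self):
        _, grid, pairs = build_nanoruler_phantom(90.0, "axial", 10, seed=2)
        dz = grid.spacing[0]
        for p in pairs:
            z1 = p.center_nm[0] - p.realized_nm / 2
            z2 = p.center_nm[0] + p.realized_nm / 2
            assert math.floor(z1 / dz - 0.5) != math.floor(z2 / dz - 0.5)

    def test_axial_phantom_needs_five_zplanes(self):
        grid = VoxelGrid(shape=(4, 64, 64), spacing=(150.0, 20.0, 20.0))
        with pytest.raises(ValueError, match="z-planes"):
            build_nanoruler_phantom(90.0, "axial", 3, grid=grid, seed=0)

    def test_coincident_pair_is_one_unresolved_spot(self):
        image, grid, pairs = build_nanoruler_phantom(
            0.0, "lateral", 1, seed=3, jitter_sd_nm=0.0, noise=False)
        ncs = segment_nanoclusters(image, grid)
        assert len(ncs) == 1
        nc = ncs[0]
        prof = line_profile(image[nc.peak_index[0]], grid,
                            (nc.centroid_nm[1], nc.centroid_nm[2]), (0.0, 1.0),
                            length_nm=500.0)
        assert not peak_separation(prof).resolved

    def test_pairs_closer_than_one_micron_rejected(self):
        with pytest.raises(ValueError, match="1 um"):
            build_nanoruler_phantom(50.0, "lateral", 4, seed=0, pitch_nm=800.0)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        SceneConfig(n_spines=-1)
    with pytest.raises(ValueError):
        SceneConfig(n_spines=1, p_tc=1.5)
    with pytest.raises(ValueError):
        SceneConfig(n_spines=1, nanomodule_count_pmf={"CC": (0.5, 0, 0, 0),
                                                      "TC": (1, 0, 0, 0)})
    with pytest.raises(ValueError):
        OpticsModel(0.0, 90.0, 5.0)
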