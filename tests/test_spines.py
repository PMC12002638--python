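import numpy as np
import pytest

from nanospine import (
    Nanocluster,
    NanomodulePair,
    VoxelGrid,
    assign_bassoon,
    assign_psd95,
    classify_input,
    count_nanomodules,
    derive_spine_rois,
    extract_puncta,
    identify_spine_ncs,
    rasterize_spines,
    spine_metrics,
)
from nanospine.spines import SpineRecord, _principal_orientation

MORPH = VoxelGrid(shape=(7, 60, 60), spacing=(300.0, 100.0, 100.0))
STED = VoxelGrid(shape=(14, 300, 300), spacing=(150.0, 20.0, 20.0))


def _ball_mask(grid, center_nm, radius_nm):
    zz = grid.axis_coordinates(0)[:, None, None]
    yy = grid.axis_coordinates(1)[None, :, None]
    xx = grid.axis_coordinates(2)[None, None, :]
    return ((zz - center_nm[0]) ** 2 + (yy - center_nm[1]) ** 2
            + (xx - center_nm[2]) ** 2) <= radius_nm**2


def _spine(mask, grid=MORPH, sid=1):
    return SpineRecord(id=sid, grid=grid, mask=mask, head_roi=mask,
                       volume_um3=float(mask.sum()) * grid.voxel_volume_um3,
                       orientation="A")


def _nc(id_, voxels, grid=STED, channel="psd95", peak=10.0):
    vox = np.asarray(voxels, dtype=int)
    w = np.ones(len(vox))
    centroid = tuple(grid.index_to_physical(vox.astype(float)).T @ (w / w.sum()))
    return Nanocluster(id=id_, channel=channel, grid=grid, voxels=vox,
                       voxel_count=len(vox),
                       volume_um3=len(vox) * grid.voxel_volume_um3,
                       centroid_nm=centroid, peak_intensity=peak,
                       peak_index=tuple(vox[0]))


class TestDeriveRois:
    def test_truth_masks_are_generator_masks(self, small_scene):
        scene, grids, _ = small_scene
        labels = rasterize_spines(scene, grids["yfp"])
        records = derive_spine_rois(None, grids["yfp"], truth=scene)
        assert [r.id for r in records] == [s.id for s in scene.spines]
        for r in records:
            assert np.array_equal(r.mask, labels == r.id)
            assert r.volume_um3 == pytest.approx(
                (labels == r.id).sum() * grids["yfp"].voxel_volume_um3)

    def test_threshold_rule_mean_plus_2sd(self):
        morph = np.zeros(MORPH.shape)
        morph[3, 10:13, 10:13] = 100.0
        records = derive_spine_rois(morph, MORPH, k=2.0)
        assert len(records) == 1
        assert records[0].mask.sum() == 9

    def test_orientation_classes_from_principal_axis(self):
        z_spine = np.zeros(MORPH.shape, bool)
        z_spine[1:6, 30, 30] = True  # 1500 nm along z, 100 nm lateral
        xy_spine = np.zeros(MORPH.shape, bool)
        xy_spine[3, 20:35, 30] = True  # 1500 nm along y, single plane
        assert _principal_orientation(z_spine, MORPH) == "B"
        assert _principal_orientation(xy_spine, MORPH) == "A"

    def test_no_spines_warns(self):
        with pytest.warns(UserWarning, match="no spines"):
            assert derive_spine_rois(np.zeros(MORPH.shape), MORPH) == []


class TestIdentifySpineNcs:
    def test_uniform_roi_has_no_discrete_ncs(self):
        spine = _spine(_ball_mask(MORPH, (900, 3000, 3000), 500.0))
        stack = np.full(STED.shape, 5.0)
        assert identify_spine_ncs(stack, STED, spine) == []

    def test_two_ncs_300nm_apart_found(self):
        center = np.array([900.0, 3000.0, 3000.0])
        spine = _spine(_ball_mask(MORPH, center, 500.0))
        zz = STED.axis_coordinates(0)[:, None, None]
        yy = STED.axis_coordinates(1)[None, :, None]
        xx = STED.axis_coordinates(2)[None, None, :]
        stack = np.zeros(STED.shape)
        for c in (center + (0, 0, -150), center + (0, 0, 150)):
            stack += 40.0 * np.exp(-0.5 * (((zz - c[0]) / 60) ** 2
                                           + ((yy - c[1]) / 45) ** 2
                                           + ((xx - c[2]) / 45) ** 2))
        ncs = identify_spine_ncs(stack, STED, spine)
        assert len(ncs) == 2

    def test_tiny_roi_skipped_with_warning(self):
        mask = np.zeros(MORPH.shape, bool)
        mask[3, 30, 30] = True
        with pytest.warns(UserWarning, match="ROI"):
            assert identify_spine_ncs(np.ones(STED.shape), STED, _spine(mask)) == []


class TestAssignment:
    def setup_method(self):
        self.center = np.array([900.0, 3000.0, 3000.0])
        self.spine = _spine(_ball_mask(MORPH, self.center, 500.0))

    def _interior_voxels(self, offset_nm=(0, 0, 0), n=3):
        base = STED.physical_to_nearest(self.center + np.asarray(offset_nm, float))
        return [tuple(base + (0, 0, d)) for d in range(n)]

    def test_fully_interior_nc_assigned(self):
        nc = _nc(1, self._interior_voxels())
        assert assign_psd95(self.spine, [nc]) == [1]

    def test_one_voxel_outside_not_assigned(self):
        vox = self._interior_voxels()
        far = STED.physical_to_nearest(self.center + np.array([0, 0, 700.0]))
        nc = _nc(2, vox + [tuple(far)])
        assert assign_psd95(self.spine, [nc]) == []

    def test_matches_containment_oracle_on_random_layouts(self, rng):
        ncs = []
        for i in range(30):
            off = rng.uniform(-700, 700, size=3)
            base = STED.physical_to_nearest(self.center + off)
            vox = [tuple(base + (0, dj, di)) for dj in range(2) for di in range(2)]
            ncs.append(_nc(i + 1, vox))
        got = set(assign_psd95(self.spine, ncs))
        want = set()
        for nc in ncs:
            centers = nc.grid.index_to_physical(nc.voxels)
            inside = []
            for c in centers:
                idx = tuple(int(round((c[a] - MORPH.origin[a]) / MORPH.spacing[a]))
                            for a in range(3))
                ok = all(0 <= idx[a] < MORPH.shape[a] for a in range(3))
                inside.append(ok and bool(self.spine.head_roi[idx]))
            if all(inside):
                want.add(nc.id)
        assert got == want

    def test_bassoon_partial_overlap_associates(self):
        edge = self.center + np.array([0, 480.0, 0])  # straddles the surface
        base = STED.physical_to_nearest(edge)
        nc = _nc(1, [tuple(base + (0, dj, 0)) for dj in range(-2, 3)], channel="bassoon")
        assert assign_bassoon(self.spine, [nc]) == [1]

    def test_bassoon_within_proximity_associates(self):
        pos = self.center + np.array([0, 500.0 + 180.0, 0])
        base = STED.physical_to_nearest(pos)
        nc = _nc(2, [tuple(base + (0, 0, di)) for di in range(3)], channel="bassoon")
        assert assign_bassoon(self.spine, [nc], proximity_nm=200.0) == [2]

    def test_bassoon_far_away_not_associated(self):
        pos = self.center + np.array([0, 500.0 + 500.0, 0])
        base = STED.physical_to_nearest(pos)
        nc = _nc(3, [tuple(base + (0, 0, di)) for di in range(3)], channel="bassoon")
        assert assign_bassoon(self.spine, [nc]) == []


class TestCounting:
    def _spine_with(self, psd, bas):
        sp = _spine(np.ones(MORPH.shape, bool))
        sp.assigned_psd95 = psd
        sp.associated_bassoon = bas
        return sp

    def test_one_aligned_pair_counts_one(self):
        sp = self._spine_with([1], [7])
        pairs = [NanomodulePair(1, 7, 3, 140.0, "A")]
        assert count_nanomodules(sp, pairs) == 1

    def test_count_keyed_on_psd95_for_shared_bassoon(self):
        sp = self._spine_with([1, 2], [7])
        pairs = [NanomodulePair(1, 7, 2, 120.0, "A"),
                 NanomodulePair(2, 7, 2, 150.0, "A")]
        assert count_nanomodules(sp, pairs) == 2

    def test_pairs_outside_assignment_ignored(self):
        sp = self._spine_with([1], [7])
        pairs = [NanomodulePair(9, 7, 2, 140.0, "A")]
        assert count_nanomodules(sp, pairs) == 0


def _punctum_over(spine, n_px, channel, grid=MORPH, shift=0):
    proj = spine.mask.any(axis=0)
    rows, cols = np.nonzero(proj)
    mask2 = np.zeros(proj.shape, bool)
    mask2[rows[:n_px] + shift, cols[:n_px]] = True
    return extract_puncta(mask2, grid, channel=channel, min_px=1, max_px=10**6)


class TestClassifyInput:
    def setup_method(self):
        self.spine = _spine(_ball_mask(MORPH, (900, 3000, 3000), 500.0))

    def test_only_vglut2_overlap_is_tc(self):
        vg2 = _punctum_over(self.spine, 4, "vglut2")
        assert classify_input(self.spine, [], vg2) == "TC"
        assert not self.spine.dual_innervated

    def test_single_pixel_overlap_does_not_count(self):
        vg2 = _punctum_over(self.spine, 1, "vglut2")
        assert classify_input(self.spine, [], vg2) == "unclassified"

    def test_dual_innervation_tiebreak_by_nanomodule(self):
        vg1 = _punctum_over(self.spine, 4, "vglut1")
        vg2 = _punctum_over(self.spine, 4, "vglut2", shift=2)
        # a nanomodule NC projecting onto the vg2 punctum pixels
        p = vg2[0]
        vox = []
        for r, c in list(p.pixel_set())[:3]:
            pos = np.array([900.0, MORPH.origin[1] + r * 100.0,
                            MORPH.origin[2] + c * 100.0])
            vox.append(tuple(STED.physical_to_nearest(pos)))
        module = _nc(1, vox)
        cls = classify_input(self.spine, vg1, vg2, nanomodule_ncs=[module])
        assert cls == "TC"
        assert self.spine.dual_innervated

    def test_no_marker_unclassified(self):
        assert classify_input(self.spine, [], []) == "unclassified"


class TestSpineMetrics:
    def test_sum_and_mean_of_assigned_volumes(self):
        sp = _spine(np.ones(MORPH.shape, bool))
        sp.assigned_psd95 = [1, 2]
        ncs = {1: _nc(1, [(0, 0, 0)] ), 2: _nc(2, [(1, 1, 1)])}
        object.__setattr__(ncs[1], "volume_um3", 0.01)
        object.__setattr__(ncs[2], "volume_um3", 0.02)
        spine_metrics(sp, ncs)
        assert sp.total_psd95_volume_um3 == pytest.approx(0.03)
        assert sp.mean_nc_volume_um3 == pytest.approx(0.015)

    def test_no_assignment_gives_null_not_zero(self):
        sp = _spine(np.ones(MORPH.shape, bool))
        spine_metrics(sp, {})
        assert sp.total_psd95_volume_um3 is None
        assert sp.mean_nc_volume_um3 is None
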