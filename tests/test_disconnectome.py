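"""Lesion-tractogram intersection and disconnection probability maps."""

import numpy as np
import pytest

import praxmap as pm
from praxmap.disconnectome import rasterise_tractogram


def make_lesion(space, centre_vox, radius):
    centre = space.voxel_to_world(np.array([centre_vox], dtype=float))[0]
    return pm.generate_lesion(space, centre, radius)


def full_grid_lesion(space):
    return pm.LesionMask(volume=np.ones(space.shape, np.uint8),
                         affine=space.affine.copy())


class TestRasteriseStreamline:
    def test_axis_aligned_segment(self, space):
        # from the centre of voxel (4,16,16) to the centre of voxel (8,16,16)
        a = space.voxel_to_world(np.array([[4, 16, 16]], float))[0]
        b = space.voxel_to_world(np.array([[8, 16, 16]], float))[0]
        vox = pm.rasterise_streamline(np.array([a, b]), space)
        expected = [
            np.ravel_multi_index((i, 16, 16), space.shape) for i in range(4, 9)
        ]
        assert sorted(vox.tolist()) == expected

    def test_outside_grid_is_empty(self, space):
        poly = np.array([[200.0, 0, 0], [210.0, 0, 0]])
        assert pm.rasterise_streamline(poly, space).size == 0

    def test_single_point_errors(self, space):
        with pytest.raises(ValueError, match="2 points"):
            pm.rasterise_streamline(np.array([[1.0, 1, 1]]), space)

    @staticmethod
    def _segment_hits_box(a, b, lo, hi, eps=1e-9):
        """Exact slab test: does segment [a, b] intersect the AABB [lo, hi]?"""
        d = b - a
        t0, t1 = 0.0, 1.0
        for ax in range(3):
            if abs(d[ax]) < eps:
                if a[ax] < lo[ax] - eps or a[ax] > hi[ax] + eps:
                    return False
            else:
                ta = (lo[ax] - a[ax]) / d[ax]
                tb = (hi[ax] - a[ax]) / d[ax]
                t0 = max(t0, min(ta, tb))
                t1 = min(t1, max(ta, tb))
        return t0 <= t1 + eps

    @pytest.mark.parametrize("seed", range(5))
    def test_step_size_soundness_and_refinement(self, space, seed):
        rng = np.random.default_rng(seed)
        poly = rng.uniform(5, 58, size=(6, 3))
        coarse = pm.rasterise_streamline(poly, space, step_fraction=0.5)
        fine = pm.rasterise_streamline(poly, space, step_fraction=0.02)

        # soundness: every reported voxel's cell truly intersects the
        # polyline (independent exact segment/box oracle)
        half = space.voxel_size / 2.0
        for flat in coarse:
            ijk = np.unravel_index(flat, space.shape)
            centre = space.voxel_to_world(np.array([ijk], float))[0]
            assert any(
                self._segment_hits_box(poly[k], poly[k + 1],
                                       centre - half, centre + half)
                for k in range(len(poly) - 1)
            ), f"voxel {ijk} not on the polyline"

        # refinement only adds boundary-grazing voxels, never removes any
        assert set(coarse.tolist()) <= set(fine.tolist())

        # every vertex's own voxel is always found
        vert = np.round(space.world_to_voxel(poly)).astype(int)
        vert_flat = np.ravel_multi_index(vert.T, space.shape)
        assert set(vert_flat.tolist()) <= set(coarse.tolist())


class TestStreamlinesThroughMask:
    def test_whole_grid_selects_all(self, space):
        tract = pm.generate_tractogram(
            space,
            [pm.BundleSpec("b", np.array([[10.0, 32, 32], [54.0, 32, 32]]),
                           n_streamlines=20, jitter_sd=1.0)],
            seed=1,
        )
        hit = pm.streamlines_through_mask(tract, full_grid_lesion(space), space)
        assert len(hit) == len(tract)

    def test_disjoint_lesion_selects_none(self, space):
        tract = pm.generate_tractogram(
            space,
            [pm.BundleSpec("b", np.array([[10.0, 32, 32], [54.0, 32, 32]]),
                           n_streamlines=20, jitter_sd=0.5)],
            seed=1,
        )
        lesion = make_lesion(space, (16, 4, 4), radius=4.0)
        assert pm.streamlines_through_mask(tract, lesion, space) == []

    def test_count_matches_point_in_sphere_oracle(self, space):
        tract = pm.generate_tractogram(
            space,
            [pm.BundleSpec("b", np.array([[6.0, 32, 32], [58.0, 32, 32]]),
                           n_streamlines=200, jitter_sd=2.0)],
            seed=4,
        )
        centre = np.array([32.0, 32.0, 32.0])
        radius = 6.0
        lesion = pm.generate_lesion(space, centre, radius)
        selected = pm.streamlines_through_mask(tract, lesion, space)
        # oracle: a straight streamline intersects the lesioned voxel ball
        # iff some densely sampled point lies in a lesioned voxel
        lesion_flat = lesion.volume.ravel().astype(bool)
        expected = 0
        for sl in tract.streamlines:
            t = np.linspace(0, 1, 2000)[:, None]
            pts = sl[0] + t * (sl[-1] - sl[0])
            vox = np.round(space.world_to_voxel(pts)).astype(int)
            ok = np.all((vox >= 0) & (vox < np.array(space.shape)), axis=1)
            flat = np.ravel_multi_index(vox[ok].T, space.shape)
            expected += lesion_flat[flat].any()
        assert len(selected) == expected

    def test_affine_mismatch_errors(self, space):
        tract = pm.generate_tractogram(
            space,
            [pm.BundleSpec("b", np.array([[10.0, 32, 32], [54.0, 32, 32]]))],
            seed=1,
        )
        other = pm.PhantomSpace(shape=(16, 16, 16), voxel_size=4.0)
        lesion = pm.LesionMask(np.ones((16, 16, 16), np.uint8),
                               other.affine.copy())
        with pytest.raises(ValueError, match="grid"):
            pm.streamlines_through_mask(tract, lesion, space)


class TestSubjectVolume:
    def test_empty_subset_is_zero(self, space):
        vol = pm.subject_disconnection_volume([], space)
        assert vol.sum() == 0

    def test_single_streamline_exact(self, space):
        a = space.voxel_to_world(np.array([[4, 16, 16]], float))[0]
        b = space.voxel_to_world(np.array([[8, 16, 16]], float))[0]
        sl = np.array([a, b])
        vol = pm.subject_disconnection_volume([sl], space)
        assert np.array_equal(
            np.flatnonzero(vol.ravel()), pm.rasterise_streamline(sl, space)
        )

    def test_union_property(self, space):
        rng = np.random.default_rng(6)
        sls = [rng.uniform(5, 58, size=(4, 3)) for _ in range(8)]
        va = pm.subject_disconnection_volume(sls[:4], space)
        vb = pm.subject_disconnection_volume(sls[4:], space)
        vab = pm.subject_disconnection_volume(sls, space)
        assert np.array_equal(vab, np.logical_or(va, vb).astype(np.uint8))


class TestDisconnectionMap:
    def test_values_are_control_fractions(self, space):
        # 10 controls; jitter-free bundle so every control is identical:
        # a lesion on the bundle disconnects it in all 10 -> values 1
        bundle = pm.BundleSpec("b", np.array([[10.0, 32, 32], [54.0, 32, 32]]),
                               jitter_sd=0.0, n_streamlines=5)
        tracts = [pm.generate_tractogram(space, [bundle], seed=s)
                  for s in range(10)]
        lesion = make_lesion(space, (16, 16, 16), radius=4.0)
        dmap = pm.disconnection_probability_map(lesion, tracts, space)
        vals = np.unique(dmap.volume)
        scaled = vals * dmap.n_controls
        assert np.allclose(scaled, np.round(scaled))
        assert dmap.volume.min() >= 0 and dmap.volume.max() <= 1

    def test_jitter_free_support_is_bundle_mask(self, space):
        bundle = pm.BundleSpec("b", np.array([[10.0, 32, 32], [54.0, 32, 32]]),
                               jitter_sd=0.0, n_streamlines=5)
        tracts = [pm.generate_tractogram(space, [bundle], seed=s)
                  for s in range(4)]
        dmap = pm.disconnection_probability_map(
            full_grid_lesion(space), tracts, space
        )
        bundle_vox = pm.rasterise_streamline(bundle.centreline, space)
        assert np.array_equal(np.flatnonzero(dmap.volume.ravel()), bundle_vox)
        assert np.allclose(dmap.volume.ravel()[bundle_vox], 1.0)

    def test_monotone_in_lesion_growth(self, space, small_cohort):
        tracts = small_cohort.tractograms
        inner = make_lesion(space, (16, 16, 16), radius=5.0)
        outer = make_lesion(space, (16, 16, 16), radius=10.0)
        m_in = pm.disconnection_probability_map(inner, tracts, space)
        m_out = pm.disconnection_probability_map(outer, tracts, space)
        assert (m_out.volume >= m_in.volume - 1e-12).all()

    def test_permutation_invariance(self, space, small_cohort):
        lesion = small_cohort.lesions[0]
        tracts = small_cohort.tractograms
        a = pm.disconnection_probability_map(lesion, tracts, space)
        b = pm.disconnection_probability_map(lesion, tracts[::-1], space)
        assert np.array_equal(a.volume, b.volume)

    def test_empty_tractogram_list_errors(self, space):
        lesion = make_lesion(space, (16, 16, 16), radius=4.0)
        with pytest.raises(ValueError, match="at least one"):
            pm.disconnection_probability_map(lesion, [], space)

    def test_precomputed_rasters_match_direct(self, space, small_cohort):
        lesion = small_cohort.lesions[1]
        tracts = small_cohort.tractograms
        rasters = [rasterise_tractogram(t, space) for t in tracts]
        a = pm.disconnection_probability_map(lesion, tracts, space)
        b = pm.disconnection_probability_map(lesion, tracts, space, rasters)
        assert np.array_equal(a.volume, b.volume)
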