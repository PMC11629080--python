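"""MTV segmentation: reference stats, detection, exclusion, refinement."""

import numpy as np
import pytest
from scipy import ndimage

from petrad.grids import Modality, VolumeGrid
from petrad.phantom import LesionSpec, PhantomSpec, render_phantom
from petrad.segmentation import (
    LesionSet,
    ReferenceStats,
    detect_candidates,
    exclude_physiologic,
    largest_lesion_per_compartment,
    reference_stats,
    refine_41pct,
    refine_all,
    total_mtv,
)


def suv_volume(values, spacing=1.0):
    return VolumeGrid(np.asarray(values, dtype=float), (spacing,) * 3,
                      modality=Modality.PET_SUV)


def put_ball(arr, center, radius, value):
    idx = np.indices(arr.shape).astype(float)
    d2 = sum((idx[a] - center[a]) ** 2 for a in range(3))
    arr[d2 <= radius**2] = value
    return d2 <= radius**2


class TestReferenceStats:
    def test_uniform_volume(self):
        vol = suv_volume(np.full((30, 30, 30), 2.0))
        ref = reference_stats(vol, (15, 15, 15), radius=10.0)
        assert ref.mean == pytest.approx(2.0)
        assert ref.sd == 0.0
        assert ref.threshold == pytest.approx(2.0)

    def test_planted_normal_recovered_within_3_se(self):
        rng = np.random.default_rng(0)
        vol = suv_volume(rng.normal(2.0, 0.3, (30, 30, 30)))
        ref = reference_stats(vol, (15, 15, 15), radius=10.0)
        assert abs(ref.mean - 2.0) <= 3 * 0.3 / np.sqrt(ref.n_voxels)

    def test_voxel_count_matches_rasterization_oracle(self, ball_mask):
        _, oracle = ball_mask
        vol = suv_volume(np.zeros((25, 25, 25)))
        ref = reference_stats(vol, (12.0, 12.0, 12.0), radius=10.0)
        assert ref.n_voxels == oracle

    def test_clipped_sphere_rejected_with_overlap(self):
        vol = suv_volume(np.zeros((30, 30, 30)))
        with pytest.raises(ValueError, match="clipped"):
            reference_stats(vol, (3, 15, 15), radius=10.0)


class TestDetectCandidates:
    def ref(self, mean=2.0, sd=0.25):
        return ReferenceStats(mean=mean, sd=sd, n_voxels=500, seed_point=(0, 0, 0))

    def test_uniform_below_threshold_no_candidates(self):
        vol = suv_volume(np.full((20, 20, 20), 2.4))
        out = detect_candidates(vol, self.ref())  # threshold 2.5
        assert out.n_lesions == 0

    def test_two_hot_spheres_match_flood_fill_oracle(self):
        arr = np.full((40, 40, 40), 1.0)
        m1 = put_ball(arr, (10, 10, 10), 6, 5.0)
        m2 = put_ball(arr, (28, 28, 28), 5, 6.0)
        vol = suv_volume(arr)
        out = detect_candidates(vol, self.ref(), min_voxels=10)
        assert out.n_lesions == 2
        # oracle: brute-force threshold + 26-connected flood fill
        oracle_lab, oracle_n = ndimage.label(arr > 2.5, structure=np.ones((3, 3, 3)))
        assert oracle_n == 2
        det = np.asarray(out.label_volume.voxels)
        for planted in (m1, m2):
            ids = np.unique(det[planted])
            ids = ids[ids > 0]
            assert len(ids) == 1
            assert np.array_equal(det == ids[0], planted)

    def test_subthreshold_lesion_not_detected(self):
        arr = np.full((30, 30, 30), 1.0)
        put_ball(arr, (15, 15, 15), 6, 2.4)  # below threshold 2.5
        out = detect_candidates(suv_volume(arr), self.ref())
        assert out.n_lesions == 0

    def test_min_voxels_suppresses_specks(self):
        arr = np.full((20, 20, 20), 1.0)
        arr[5, 5, 5] = 9.0
        out = detect_candidates(suv_volume(arr), self.ref(), min_voxels=64)
        assert out.n_lesions == 0
        out2 = detect_candidates(suv_volume(arr), self.ref(), min_voxels=0)
        assert out2.n_lesions == 1

    def test_zero_sd_warns(self):
        arr = np.full((10, 10, 10), 1.0)
        arr[4:6, 4:6, 4:6] = 3.0
        with pytest.warns(UserWarning, match="reference SD"):
            detect_candidates(suv_volume(arr), self.ref(sd=0.0), min_voxels=0)

    def test_percist_form_uses_higher_threshold(self):
        arr = np.full((20, 20, 20), 1.0)
        put_ball(arr, (10, 10, 10), 5, 2.8)  # above 2.5, below 1.5*2+0.5=3.5
        assert detect_candidates(suv_volume(arr), self.ref()).n_lesions == 1
        assert detect_candidates(suv_volume(arr), self.ref(),
                                 use_percist_form=True).n_lesions == 0


class TestExcludePhysiologic:
    def build(self, overlap_frac):
        arr = np.full((30, 30, 30), 1.0)
        put_ball(arr, (10, 10, 10), 5, 5.0)
        vol = suv_volume(arr)
        cands = detect_candidates(vol, ReferenceStats(2.0, 0.25, 500, (0, 0, 0)),
                                  min_voxels=10)
        lesion = np.asarray(cands.label_volume.voxels) == 1
        n = lesion.sum()
        excl = np.zeros_like(lesion)
        flat = np.flatnonzero(lesion.ravel())[: int(round(overlap_frac * n))]
        excl.ravel()[flat] = True
        return vol, cands, excl

    def test_empty_masks_identity(self):
        vol, cands, _ = self.build(0.0)
        out = exclude_physiologic(cands, [], vol)
        assert out.n_lesions == cands.n_lesions

    def test_full_overlap_removed(self):
        vol, cands, _ = self.build(0.0)
        full = np.asarray(cands.label_volume.voxels) > 0
        out = exclude_physiologic(cands, [full], vol)
        assert out.n_lesions == 0

    def test_overlap_threshold_boundary(self):
        vol, cands, excl = self.build(0.30)
        kept = exclude_physiologic(cands, [excl], vol, overlap_threshold=0.5)
        removed = exclude_physiologic(cands, [excl], vol, overlap_threshold=0.25)
        assert kept.n_lesions == 1
        assert removed.n_lesions == 0

    def test_labels_renumbered_contiguously(self):
        arr = np.full((40, 40, 40), 1.0)
        put_ball(arr, (8, 8, 8), 4, 5.0)
        put_ball(arr, (20, 20, 20), 4, 5.0)
        put_ball(arr, (32, 32, 32), 4, 5.0)
        vol = suv_volume(arr)
        cands = detect_candidates(vol, ReferenceStats(2.0, 0.25, 500, (0, 0, 0)),
                                  min_voxels=10)
        excl = np.zeros(arr.shape, dtype=bool)
        put_ball(excl.view(np.uint8).reshape(excl.shape), (20, 20, 20), 6, 1)
        out = exclude_physiologic(cands, [excl], vol)
        assert out.n_lesions == 2
        assert sorted(out.table["lesion_id"]) == [1, 2]


class TestRefine41pct:
    def test_uniform_lesion_unchanged(self):
        arr = np.full((20, 20, 20), 0.5)
        mask = put_ball(arr, (10, 10, 10), 6, 4.0)
        out = refine_41pct(suv_volume(arr), mask)
        assert np.array_equal(out, mask)

    def test_core_rim_two_level(self):
        # rim at SUV 3 < 0.41*10 = 4.1 -> only the core survives
        arr = np.full((24, 24, 24), 0.2)
        rim = put_ball(arr, (12, 12, 12), 8, 3.0)
        core = put_ball(arr, (12, 12, 12), 4, 10.0)
        out = refine_41pct(suv_volume(arr), rim | core)
        assert np.array_equal(out, core)
        assert out.sum() == core.sum()

    def test_fraction_monotonicity(self):
        rng = np.random.default_rng(3)
        arr = np.full((20, 20, 20), 0.1)
        mask = put_ball(arr, (10, 10, 10), 7, 1.0)
        arr[mask] = rng.uniform(2.0, 8.0, mask.sum())
        vol = suv_volume(arr)
        m41 = refine_41pct(vol, mask, fraction=0.41)
        m60 = refine_41pct(vol, mask, fraction=0.60)
        assert m60.sum() <= m41.sum()
        assert np.all(mask[m41])  # contractive
        assert m60.any()  # SUVmax voxel always kept

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            refine_41pct(suv_volume(np.ones((5, 5, 5))), np.zeros((5, 5, 5), dtype=bool))


class TestTotalMtvAndCompartments:
    @staticmethod
    def lesion_set(volumes_nodal):
        """LesionSet with synthetic table only."""
        import pandas as pd

        rows = [
            {"lesion_id": i + 1, "suv_max": 5.0, "volume_ml": v, "site_label": "abdomen",
             "nodal": nodal, "centroid_mm": (0, 0, 0)}
            for i, (v, nodal) in enumerate(volumes_nodal)
        ]
        grid = VolumeGrid(np.zeros((4, 4, 4), dtype=np.int32), (1, 1, 1),
                          modality=Modality.MASK)
        return LesionSet(label_volume=grid, table=pd.DataFrame(rows))

    def test_zero_lesions(self):
        assert total_mtv(self.lesion_set([])) == 0.0

    def test_additivity(self):
        ls = self.lesion_set([(12.0, True), (30.5, False)])
        assert total_mtv(ls) == pytest.approx(42.5)

    def test_counting_oracle_on_refined_phantom(self):
        spec = PhantomSpec(
            grid_shape=(64, 64, 64), spacing=(1.0, 1.0, 1.0),
            liver_center=(15.0, 15.0, 15.0), liver_radii=(10.0, 8.0, 8.0),
            noise_sd=0.0, ct_noise_sd=0.0,
            lesions=(LesionSpec(center=(45.0, 45.0, 45.0), base_radius=8.0,
                                suv_peak=6.0, texture_amp=0.0),),
        )
        _, pet, (labels, table), _ = render_phantom(spec)
        ref = reference_stats(pet, spec.liver_center)
        cands = detect_candidates(pet, ref, min_voxels=10)
        refined = refine_all(pet, cands)
        brute = int((np.asarray(pet.voxels) > ref.threshold).sum())
        assert total_mtv(refined) == pytest.approx(brute * 0.001)
        assert total_mtv(refined) == pytest.approx(table["true_volume_ml"].sum())

    def test_largest_per_compartment(self):
        ls = self.lesion_set([(10.0, True), (25.0, True), (3.0, True)])
        nodal, extra = largest_lesion_per_compartment(ls)
        assert nodal == 2 and extra is None

    def test_tie_breaks_to_lower_id(self):
        ls = self.lesion_set([(10.0, False), (10.0, False)])
        _, extra = largest_lesion_per_compartment(ls)
        assert extra == 1


class TestRecoveryOnPhantom:
    def test_noise_free_detection_exact_and_volumes_within_surface_band(self):
        from petrad.phantom import make_phantom_spec

        spec = make_phantom_spec(21, n_lesions=3, lesion_texture_amp=0.0, noise_sd=0.0,
                                 ct_noise_sd=0.0)
        _, pet, (labels, table), organs = render_phantom(spec)
        ref = reference_stats(pet, spec.liver_center)
        cands = detect_candidates(pet, ref)
        excl = [organs[k] for k in organs if k.startswith("physiologic")]
        kept = exclude_physiologic(cands, excl, pet)
        refined = refine_all(pet, kept)
        assert refined.n_lesions == len(table)
        truth = np.asarray(labels.voxels)
        det = np.asarray(refined.label_volume.voxels)
        for _, row in table.iterrows():
            tmask = truth == row["lesion_id"]
            ids = np.unique(det[tmask])
            ids = ids[ids > 0]
            assert len(ids) == 1
            dmask = det == ids[0]
            surface = tmask & ~ndimage.binary_erosion(tmask, np.ones((3, 3, 3)))
            assert abs(int(dmask.sum()) - int(tmask.sum())) <= int(surface.sum())
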