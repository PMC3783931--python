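"""Contralateral-reference construction and lesion delineation."""

import numpy as np
import pytest

from strokemismatch.image_io import VolumeImage
from strokemismatch.lesion_segmentation import (
    SegmentationParams,
    mirror_reference,
    segment_dwi_lesion,
    segment_ttp_lesion,
)
from strokemismatch.param_maps import compute_adc, compute_ttp, signal_to_concentration
from strokemismatch.phantom import PhantomConfig, generate_stroke_phantom
from strokemismatch.preprocess import (
    BrainMask,
    Laterality,
    LateralityError,
    compute_brain_mask,
)

from conftest import dice

RIGHT = Laterality(side="right", asymmetry_score=1.0)


def _brain_of(arr, spacing=(1.0, 1.0, 1.0)):
    vol = VolumeImage(arr.astype(bool), spacing, is_mask=True)
    return BrainMask(mask=vol, n_voxels=int(arr.sum()))


class TestMirrorReference:
    def test_neighborhood_stats_match_brute_force(self):
        """Reference mean/SD equal explicit loops over the mirrored cube."""
        rng = np.random.default_rng(8)
        shape = (12, 7, 7)
        data = rng.normal(100, 10, shape)
        brain_arr = np.zeros(shape, dtype=bool)
        brain_arr[1:11, 1:6, 1:6] = True
        vol = VolumeImage(data, (1, 1, 1))
        brain = _brain_of(brain_arr)
        nb = 3
        ref_mean, ref_sd = mirror_reference(vol, brain, RIGHT, neighborhood=nb)

        lo, hi = 1, 10  # brain bounds along LR axis
        half = nb // 2
        checked = 0
        for i in range(shape[0]):
            for j in range(shape[1]):
                for k in range(shape[2]):
                    if not np.isfinite(ref_mean[i, j, k]):
                        continue
                    mi = lo + hi - i  # mirrored index
                    vals = []
                    for di in range(-half, half + 1):
                        for dj in range(-half, half + 1):
                            for dk in range(-half, half + 1):
                                a, b, c = mi + di, j + dj, k + dk
                                if 0 <= a < shape[0] and 0 <= b < shape[1] and 0 <= c < shape[2] \
                                        and brain_arr[a, b, c]:
                                    vals.append(data[a, b, c])
                    assert ref_mean[i, j, k] == pytest.approx(np.mean(vals))
                    assert ref_sd[i, j, k] == pytest.approx(np.std(vals), abs=1e-9)
                    checked += 1
        assert checked > 100

    def test_symmetric_volume_reference_matches_own_neighborhood(self, symmetric_phantom):
        ph = symmetric_phantom
        brain = compute_brain_mask(ph.b0)
        side = Laterality(side="right", asymmetry_score=0.0)
        ref_mean, _ = mirror_reference(ph.b0, brain, side)
        inside = np.isfinite(ref_mean)
        # noiseless construction is LR-symmetric: mirrored mean tracks local signal
        assert np.nanmedian(np.abs(ref_mean[inside] - ph.b0.data[inside])) < 50.0

    def test_mirror_outside_brain_is_nan(self):
        # asymmetric brain: one slab exists only on the affected side, so its
        # mirrored positions fall outside the mask
        shape = (11, 6, 6)
        brain_arr = np.zeros(shape, dtype=bool)
        brain_arr[2:9, 2:5, 1:5] = True
        brain_arr[6:9, 1, 1:5] = True  # right-only slab at y=1
        vol = VolumeImage(np.ones(shape), (1, 1, 1))
        ref_mean, _ = mirror_reference(vol, _brain_of(brain_arr), RIGHT)
        # lo+hi = 2+8: voxel (7, 1, k) mirrors to (3, 1, k), outside the brain
        assert np.all(np.isnan(ref_mean[6:9, 1, 1:5]))
        # symmetric part of the brain has a defined reference
        assert np.all(np.isfinite(ref_mean[6:8, 2:5, 1:5]))

    def test_undetermined_side_refused(self, default_phantom):
        brain = compute_brain_mask(default_phantom.b0)
        with pytest.raises(LateralityError):
            mirror_reference(default_phantom.b0, brain, Laterality(None, 0.0))


@pytest.fixture(scope="module")
def segmented(default_phantom):
    ph = default_phantom
    brain = compute_brain_mask(ph.b0)
    adc = compute_adc(ph.b0, ph.b1000)
    ttp = compute_ttp(signal_to_concentration(ph.dsc), ph.dsc.tr, template=ph.b0)
    return ph, brain, adc, ttp


class TestDWISegmentation:
    def test_core_recovered_within_tolerance(self, segmented):
        ph, brain, adc, ttp = segmented
        lesion = segment_dwi_lesion(ph.b1000, adc, brain, RIGHT)
        truth = ph.truth.core_volume_mL
        assert abs(lesion.volume_mL - truth) / truth <= 0.10
        assert dice(lesion.mask.data, ph.truth.core.data) >= 0.8

    def test_mask_inside_brain_and_hemisphere(self, segmented):
        ph, brain, adc, ttp = segmented
        lesion = segment_dwi_lesion(ph.b1000, adc, brain, RIGHT)
        assert not (lesion.mask.data & ~brain.mask.data).any()
        # right side = increasing index half (left_positive=False)
        mid = ph.b0.shape[0] // 2
        assert not lesion.mask.data[:mid].any()

    def test_infinite_k_gives_empty_mask(self, segmented):
        ph, brain, adc, ttp = segmented
        lesion = segment_dwi_lesion(
            ph.b1000, adc, brain, RIGHT, SegmentationParams(k=1e9)
        )
        assert lesion.volume_mL == 0.0

    def test_volume_monotone_in_k_and_adc_max(self, segmented):
        ph, brain, adc, ttp = segmented
        vols = [
            segment_dwi_lesion(ph.b1000, adc, brain, RIGHT, SegmentationParams(k=k)).volume_mL
            for k in (1.0, 2.0, 4.0)
        ]
        assert vols[0] >= vols[1] >= vols[2]
        loose = segment_dwi_lesion(
            ph.b1000, adc, brain, RIGHT, SegmentationParams(adc_max=700e-6)
        ).volume_mL
        tight = segment_dwi_lesion(
            ph.b1000, adc, brain, RIGHT, SegmentationParams(adc_max=550e-6)
        ).volume_mL
        assert tight <= loose

    def test_lesion_free_phantom_gives_empty_mask(self, symmetric_phantom):
        ph = symmetric_phantom
        brain = compute_brain_mask(ph.b0)
        adc = compute_adc(ph.b0, ph.b1000)
        lesion = segment_dwi_lesion(ph.b1000, adc, brain, RIGHT)
        assert lesion.volume_mL == 0.0


class TestTTPSegmentation:
    def test_hypoperfusion_recovered_within_tolerance(self, segmented):
        ph, brain, adc, ttp = segmented
        lesion = segment_ttp_lesion(ttp, brain, RIGHT)
        truth = ph.truth.hypo_volume_mL
        assert abs(lesion.volume_mL - truth) / truth <= 0.10
        assert dice(lesion.mask.data, ph.truth.hypoperfusion.data) >= 0.8

    def test_subthreshold_delay_gives_empty_mask(self):
        ph = generate_stroke_phantom(
            PhantomConfig(seed=31, ttp_delay_s=2.0)  # below tau = 4 s
        )
        brain = compute_brain_mask(ph.b0)
        ttp = compute_ttp(signal_to_concentration(ph.dsc), ph.dsc.tr, template=ph.b0)
        lesion = segment_ttp_lesion(ttp, brain, RIGHT)
        assert lesion.volume_mL == 0.0

    def test_volume_monotone_in_tau(self, segmented):
        ph, brain, adc, ttp = segmented
        vols = [
            segment_ttp_lesion(ttp, brain, RIGHT, SegmentationParams(tau_s=t)).volume_mL
            for t in (1.0, 4.0, 7.0)
        ]
        assert vols[0] >= vols[1] >= vols[2]

    def test_near_zero_tau_approaches_hypoperfused_hemisphere_region(self, segmented):
        # every delayed voxel clears a vanishing threshold
        ph, brain, adc, ttp = segmented
        lesion = segment_ttp_lesion(ttp, brain, RIGHT, SegmentationParams(tau_s=1e-6))
        assert lesion.volume_mL >= ph.truth.hypo_volume_mL * 0.95

    def test_mirror_equivariance_of_lesion_mask(self, segmented):
        ph, brain, adc, ttp = segmented
        lesion = segment_ttp_lesion(ttp, brain, RIGHT)

        def mirror_vol(vol, is_mask=False):
            return VolumeImage(
                np.flip(vol.data, axis=vol.lr_axis).copy(), vol.spacing,
                lr_axis=vol.lr_axis, left_positive=vol.left_positive, is_mask=is_mask,
            )

        brain_m = BrainMask(mask=mirror_vol(brain.mask, is_mask=True), n_voxels=brain.n_voxels)
        left = Laterality(side="left", asymmetry_score=1.0)
        lesion_m = segment_ttp_lesion(mirror_vol(ttp), brain_m, left)
        np.testing.assert_array_equal(
            lesion_m.mask.data, np.flip(lesion.mask.data, axis=0)
        )
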