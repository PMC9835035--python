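"""PSNR, SSIM, Dice, SIS and the induced-swap counting protocol."""

import numpy as np
import pytest

from dixonsep import (
    ScalarField3D,
    count_induced_swaps,
    dice,
    psnr,
    sis,
    ssim,
)
from dixonsep.metrics import segment_structure


def field(values, spacing=(1.0, 1.0, 1.0)):
    return ScalarField3D(np.asarray(values, dtype=float), spacing)


class TestPSNR:
    def test_twenty_db_closed_form(self, rng):
        ref = rng.uniform(0, 1, (8, 8, 8))
        ref.flat[0] = 1.0  # pin MPI to 1
        err = np.full_like(ref, 0.1)  # MSE = 0.01
        assert psnr(field(ref), field(ref + err)) == pytest.approx(20.0)

    def test_zero_db_when_mse_equals_mpi_squared(self):
        ref = np.ones((4, 4, 4))
        test = np.zeros((4, 4, 4))  # MSE = 1 = MPI^2
        assert psnr(field(ref), field(test)) == pytest.approx(0.0)

    def test_identical_volumes_signalled_as_infinite(self, rng):
        ref = rng.uniform(0, 2, (5, 5, 5))
        assert psnr(field(ref), field(ref)) == np.inf

    def test_monotone_in_noise(self, rng):
        ref = rng.uniform(0, 1, (10, 10, 10))
        ref.flat[0] = 1.0
        values = [
            psnr(field(ref), field(np.abs(ref + rng.normal(0, s, ref.shape))))
            for s in (0.01, 0.05, 0.2)
        ]
        assert values[0] > values[1] > values[2]


class TestSSIM:
    def test_self_identity_is_one(self, rng):
        x = field(rng.uniform(0, 1, (32, 32, 32)))
        assert ssim(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_constant_fields_closed_form(self):
        """Constant 0 vs constant L: SSIM = C1 / (L^2 + C1) with C1=(0.01 L)^2."""
        zero = field(np.zeros((12, 12, 12)))
        one = field(np.ones((12, 12, 12)))
        expected = 1e-4 / (1 + 1e-4)
        assert ssim(zero, one, dynamic_range=1.0) == pytest.approx(expected, rel=1e-9)

    def test_symmetry(self, rng):
        x = field(rng.uniform(0, 1, (16, 16, 16)))
        y = field(rng.uniform(0, 1, (16, 16, 16)))
        assert ssim(x, y, dynamic_range=1.0) == pytest.approx(
            ssim(y, x, dynamic_range=1.0), rel=1e-12
        )

    def test_matches_reference_implementation(self, rng):
        """Cross-check the uniform-window implementation against the
        established image-metrics library on random volumes."""
        skimage_metrics = pytest.importorskip("skimage.metrics")
        x = rng.uniform(0, 1, (20, 20, 20))
        y = np.clip(x + rng.normal(0, 0.1, x.shape), 0, 1)
        ours = ssim(field(x), field(y), dynamic_range=1.0)
        theirs = skimage_metrics.structural_similarity(
            x, y, win_size=11, data_range=1.0, gaussian_weights=False,
            use_sample_covariance=False,
        )
        assert ours == pytest.approx(theirs, abs=1e-9)

    def test_decreases_with_noise(self, rng):
        x = rng.uniform(0, 1, (24, 24, 24))
        vals = [
            ssim(field(x), field(np.clip(x + rng.normal(0, s, x.shape), 0, 1)),
                 dynamic_range=1.0)
            for s in (0.02, 0.08, 0.3)
        ]
        assert vals[0] > vals[1] > vals[2]

    def test_volume_smaller_than_window_rejected(self, rng):
        x = field(rng.uniform(0, 1, (8, 8, 8)))
        with pytest.raises(ValueError, match="window"):
            ssim(x, x)


class TestDice:
    def test_identical_nonempty_is_one(self):
        a = np.zeros((4, 4, 4), dtype=bool)
        a[:2] = True
        assert dice(a, a) == 1.0

    def test_disjoint_is_zero(self):
        a = np.zeros((4, 4, 4), dtype=bool)
        b = np.zeros((4, 4, 4), dtype=bool)
        a[0], b[3] = True, True
        assert dice(a, b) == 0.0

    def test_half_overlap(self):
        a = np.zeros((4, 4, 4), dtype=bool)
        b = np.zeros((4, 4, 4), dtype=bool)
        a.flat[:8] = True
        b.flat[4:12] = True
        assert dice(a, b) == pytest.approx(0.5)

    def test_both_empty_convention(self):
        empty = np.zeros((3, 3, 3), dtype=bool)
        assert dice(empty, empty) == 1.0

    def test_jaccard_relation(self, rng):
        """Dice = 2J / (1 + J) for Jaccard J — independent cross-check."""
        a = rng.random((6, 6, 6)) > 0.5
        b = rng.random((6, 6, 6)) > 0.5
        jaccard = (a & b).sum() / (a | b).sum()
        assert dice(a, b) == pytest.approx(2 * jaccard / (1 + jaccard))

    def test_symmetric(self, rng):
        a = rng.random((5, 5, 5)) > 0.4
        b = rng.random((5, 5, 5)) > 0.6
        assert dice(a, b) == dice(b, a)


class TestSIS:
    @pytest.mark.parametrize(
        "d, base, expected", [(0.85, 0.85, 1.0), (0.9, 0.8, 1.125), (0.0, 0.5, 0.0)]
    )
    def test_ratio(self, d, base, expected):
        assert sis(d, base) == pytest.approx(expected)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            sis(0.5, 0.0)


class TestCountInducedSwaps:
    def _setup(self, rng):
        fat = rng.uniform(5, 10, (24, 24, 24))
        water = rng.uniform(20, 30, (24, 24, 24))
        body = np.ones(fat.shape, dtype=bool)
        return fat, water, body

    def test_identical_prediction_counts_nothing(self, rng):
        fat, water, body = self._setup(rng)
        out = count_induced_swaps(
            field(fat), field(fat), field(water), field(water), body
        )
        assert out == (0, 0, 0.0)

    def test_single_blob_with_volume(self, rng):
        fat, water, body = self._setup(rng)
        fat_hat, water_hat = fat.copy(), water.copy()
        blob = np.zeros_like(body)
        blob[4:9, 4:9, 4:8] = True  # 5*5*4 = 100 voxels
        fat_hat[blob], water_hat[blob] = water[blob], fat[blob]
        spacing = (0.0158e3) ** (1 / 3)  # voxel of 0.0158 ml
        count, voxels, ml = count_induced_swaps(
            field(fat, (spacing,) * 3), field(fat_hat, (spacing,) * 3),
            field(water, (spacing,) * 3), field(water_hat, (spacing,) * 3), body,
        )
        assert (count, voxels) == (1, 100)
        assert ml == pytest.approx(1.58, rel=1e-6)

    def test_two_disjoint_blobs(self, rng):
        fat, water, body = self._setup(rng)
        fat_hat, water_hat = fat.copy(), water.copy()
        for sl in (np.s_[2:6, 2:6, 2:6], np.s_[14:19, 14:19, 14:19]):
            blob = np.zeros_like(body)
            blob[sl] = True
            fat_hat[blob], water_hat[blob] = water[blob], fat[blob]
        count, *_ = count_induced_swaps(
            field(fat), field(fat_hat), field(water), field(water_hat), body
        )
        assert count == 2

    def test_exact_on_phantom_injected_swap(self, small_phantom):
        from dixonsep import inject_swap, realize_swap_mask, SwapSpec

        _, channels, labels = small_phantom
        mask = realize_swap_mask(SwapSpec(kind="region_label", label=2), labels)
        fat_s, water_s = inject_swap(channels.fat, channels.water, mask)
        body = labels.labels > 0
        count, voxels, _ = count_induced_swaps(
            channels.fat, fat_s, channels.water, water_s, body
        )
        assert count == 1
        assert voxels == int(mask.sum())

    def test_empty_body_mask_rejected(self, rng):
        fat, water, _ = self._setup(rng)
        with pytest.raises(ValueError, match="body mask"):
            count_induced_swaps(
                field(fat), field(fat), field(water), field(water),
                np.zeros(fat.shape, dtype=bool),
            )


class TestStandInSegmenter:
    def test_recovers_structure_on_clean_channels(self, small_phantom):
        _, channels, labels = small_phantom
        annotation = labels.labels == 2  # water-dominant core, fat fraction 0.1
        seg = segment_structure(
            channels.fat, channels.water, annotation, fat_fraction_window=(0.0, 0.3)
        )
        assert dice(seg, annotation) > 0.95

    def test_swap_destroys_segmentation(self, small_phantom):
        from dixonsep import inject_swap

        _, channels, labels = small_phantom
        annotation = labels.labels == 2
        fat_s, water_s = inject_swap(channels.fat, channels.water, annotation)
        seg = segment_structure(
            fat_s, water_s, annotation, fat_fraction_window=(0.0, 0.3)
        )
        assert dice(seg, annotation) < 0.5
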