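"""Synthetic phantom generation and swap-artifact injection."""

import numpy as np
import pytest

from dixonsep import (
    PhantomSpec,
    SwapSpec,
    TissueRegion,
    analytic_separation,
    default_template,
    generate_phantom,
    inject_swap,
    make_dataset,
    realize_swap_mask,
)
from dixonsep.phantom import LabelMap


class TestGeneratePhantom:
    def test_region_fat_fraction_and_total_signal(self):
        region = TissueRegion(
            geometry="ellipsoid", center=(15.5, 15.5, 15.5), semi_axes=(10, 10, 10),
            fat_fraction=0.9, intensity=100.0,
        )
        spec = PhantomSpec(shape=(32, 32, 32), regions=(region,), noise_sigma=0.0)
        channels, labels = generate_phantom(spec)
        inside = labels.labels == 1
        total = channels.fat.values + channels.water.values
        np.testing.assert_allclose(channels.ip.values[inside], 100.0)
        np.testing.assert_allclose(
            (channels.fat.values[inside] / total[inside]), 0.9
        )
        assert np.all(channels.ip.values[~inside] == 0)

    def test_deterministic_under_seed(self):
        spec = default_template(24)
        a, la = generate_phantom(spec)
        b, lb = generate_phantom(spec)
        np.testing.assert_array_equal(a.stack(), b.stack())
        np.testing.assert_array_equal(la.labels, lb.labels)

    def test_noise_free_channels_satisfy_forward_model(self, small_phantom):
        _, channels, _ = small_phantom
        np.testing.assert_array_equal(
            channels.op.values, np.abs(channels.water.values - channels.fat.values)
        )
        np.testing.assert_array_equal(
            channels.ip.values, channels.water.values + channels.fat.values
        )

    def test_region_outside_grid_rejected(self):
        region = TissueRegion(
            geometry="ellipsoid", center=(100, 100, 100), semi_axes=(3, 3, 3),
            fat_fraction=0.5, intensity=10.0,
        )
        with pytest.raises(ValueError, match="outside the grid"):
            generate_phantom(PhantomSpec(shape=(16, 16, 16), regions=(region,)))

    def test_empty_region_list_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            PhantomSpec(shape=(8, 8, 8), regions=())

    def test_fat_dominance_marks_exactly_the_analytic_swap_set(self, small_phantom):
        """Voxels where fat dominates are exactly those the analytic
        inversion returns exchanged — the phantom exercises the ambiguity."""
        _, channels, _ = small_phantom
        w_hat, f_hat = analytic_separation(channels.ip, channels.op)
        swapped = ~np.isclose(w_hat.values, channels.water.values)
        fat_dominant = channels.fat.values > channels.water.values
        np.testing.assert_array_equal(swapped, fat_dominant)


class TestSwapMasks:
    def test_full_volume(self, small_phantom):
        *_, labels = small_phantom
        assert realize_swap_mask(SwapSpec(kind="full_volume"), labels).all()

    def test_region_label_equals_support(self, small_phantom):
        *_, labels = small_phantom
        mask = realize_swap_mask(SwapSpec(kind="region_label", label=2), labels)
        np.testing.assert_array_equal(mask, labels.labels == 2)

    def test_absent_label_rejected(self, small_phantom):
        *_, labels = small_phantom
        with pytest.raises(ValueError, match="label 9"):
            realize_swap_mask(SwapSpec(kind="region_label", label=9), labels)

    def test_slab_spans_full_cross_section(self):
        labels = LabelMap(np.zeros((16, 16, 16), dtype=np.int32))
        mask = realize_swap_mask(SwapSpec(kind="slab", axis=2, lo=0, hi=8), labels)
        assert mask.sum() == 16 * 16 * 8
        assert mask[:, :, :8].all() and not mask[:, :, 8:].any()

    def test_boundary_shell_touches_all_faces(self):
        labels = LabelMap(np.zeros((12, 12, 12), dtype=np.int32))
        mask = realize_swap_mask(SwapSpec(kind="boundary_shell", thickness=2), labels)
        for axis in range(3):
            assert np.take(mask, 0, axis=axis).all()
            assert np.take(mask, -1, axis=axis).all()
        assert not mask[6, 6, 6]

    def test_blob_is_ball_subset(self):
        labels = LabelMap(np.zeros((20, 20, 20), dtype=np.int32))
        mask = realize_swap_mask(
            SwapSpec(kind="blob", center=(10, 10, 10), radius=4), labels
        )
        assert mask[10, 10, 10]
        assert 0 < mask.sum() < mask.size
        assert not mask[0, 0, 0]

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown swap kind"):
            SwapSpec(kind="spiral")


class TestInjectSwap:
    def test_empty_mask_is_identity(self, small_phantom):
        _, channels, _ = small_phantom
        mask = np.zeros(channels.shape, dtype=bool)
        f2, w2 = inject_swap(channels.fat, channels.water, mask)
        np.testing.assert_array_equal(f2.values, channels.fat.values)
        np.testing.assert_array_equal(w2.values, channels.water.values)

    def test_full_mask_exchanges_channels(self, small_phantom):
        _, channels, _ = small_phantom
        mask = np.ones(channels.shape, dtype=bool)
        f2, w2 = inject_swap(channels.fat, channels.water, mask)
        np.testing.assert_array_equal(f2.values, channels.water.values)
        np.testing.assert_array_equal(w2.values, channels.fat.values)

    def test_involution(self, small_phantom, rng):
        _, channels, _ = small_phantom
        mask = rng.random(channels.shape) > 0.5
        f1, w1 = inject_swap(channels.fat, channels.water, mask)
        f2, w2 = inject_swap(f1, w1, mask)
        np.testing.assert_array_equal(f2.values, channels.fat.values)
        np.testing.assert_array_equal(w2.values, channels.water.values)

    def test_conserves_voxelwise_sum(self, small_phantom, rng):
        _, channels, _ = small_phantom
        mask = rng.random(channels.shape) > 0.7
        f1, w1 = inject_swap(channels.fat, channels.water, mask)
        np.testing.assert_allclose(
            f1.values + w1.values, channels.fat.values + channels.water.values
        )


class TestMakeDataset:
    def test_no_swaps_means_scanner_equals_clean(self):
        data = make_dataset(4, default_template(24), swap_fraction=0.0, seed=1)
        for s in data:
            np.testing.assert_array_equal(s.scanner.fat.values, s.clean.fat.values)
            assert not s.swap_mask.any()

    def test_all_slab_swaps_differ_on_a_slab(self):
        data = make_dataset(4, default_template(24), swap_fraction=1.0,
                            swap_kinds=("slab",), seed=1)
        for s in data:
            assert s.swap_mask.any()
            changed = s.scanner.fat.values != s.clean.fat.values
            assert changed.any()
            # swap only alters voxels inside the mask (and only where F != W)
            assert not changed[~s.swap_mask].any()

    def test_deterministic_under_seed(self):
        a = make_dataset(3, default_template(24), seed=9)
        b = make_dataset(3, default_template(24), seed=9)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.clean.stack(), sb.clean.stack())
            np.testing.assert_array_equal(sa.swap_mask, sb.swap_mask)

    def test_subjects_vary(self):
        data = make_dataset(2, default_template(24), seed=3)
        assert not np.array_equal(data[0].clean.ip.values, data[1].clean.ip.values)

    def test_invalid_jitter_rejected(self):
        with pytest.raises(ValueError, match="jitter"):
            make_dataset(2, default_template(24), jitter=0.9)
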