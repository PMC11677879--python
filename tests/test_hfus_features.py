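"""HFUS descriptor contracts: morphology, echogenicity, scattering, unions."""

import dataclasses

import numpy as np
import pytest

from akstage.features.hfus import (
    EchogenicityBands,
    HFUSFeatureConfig,
    combined_layer_features,
    echogenicity_features,
    extract_hfus_features,
    morphological_features,
    perimeter_edge_count,
    thickness_profile,
)
from akstage.features.scattering import scattering_stats
from akstage.synthetic import PhantomParams, generate_hfus_phantom
from akstage.types import HFUSScan, LayerMaskSet
from tests.oracles import boundary_edge_oracle


def _band_masks(h=96, w=96, entry_rows=(10, 20), sleb_rows=(20, 40),
                dermis_rows=(40, 70)):
    def band(rows):
        m = np.zeros((h, w), bool)
        m[rows[0]:rows[1]] = True
        return m

    return LayerMaskSet(
        entry_echo=band(entry_rows),
        sleb=band(sleb_rows),
        dermis_reference=band(dermis_rows),
    )


class TestThicknessProfile:
    def test_uniform_band(self):
        mask = np.zeros((30, 8), bool)
        mask[5:15] = True
        assert (thickness_profile(mask) == 10).all()

    def test_two_level_band_order_statistics(self):
        mask = np.zeros((30, 10), bool)
        mask[0:5, :5] = True
        mask[0:15, 5:] = True
        prof = thickness_profile(mask)
        assert np.median(prof) == 10
        assert np.percentile(prof, 75) == 15

    def test_single_pixel(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 3] = True
        assert list(thickness_profile(mask)) == [1.0]

    def test_empty_mask_is_missing(self):
        assert thickness_profile(np.zeros((5, 5), bool)).size == 0


class TestPerimeter:
    @pytest.mark.parametrize("n", [1, 2, 3, 5, 8])
    def test_solid_square_edges(self, n):
        mask = np.zeros((n + 4, n + 4), bool)
        mask[2 : 2 + n, 2 : 2 + n] = True
        assert perimeter_edge_count(mask) == 4 * n
        assert perimeter_edge_count(mask) / mask.sum() == pytest.approx(4 / n)

    def test_random_shapes_match_enumeration(self, rng):
        for _ in range(10):
            mask = rng.random((9, 9)) < 0.4
            assert perimeter_edge_count(mask) == boundary_edge_oracle(mask)

    def test_border_pixels_count_image_edge(self):
        mask = np.ones((3, 3), bool)  # touches all image borders
        assert perimeter_edge_count(mask) == boundary_edge_oracle(mask) == 12


class TestMorphology:
    def test_band_statistics(self):
        masks = _band_masks()
        feats = morphological_features(masks)
        assert feats["hfus.morphology.entry_echo.thickness_mean"] == 10
        assert feats["hfus.morphology.sleb.thickness_mean"] == 20
        assert feats["hfus.morphology.sleb.depth_max"] == 40
        assert feats["hfus.morphology.sleb.depth_mean"] == 40

    def test_sleb_absent_gives_missing(self):
        masks = _band_masks()
        masks = LayerMaskSet(
            entry_echo=masks.entry_echo,
            sleb=np.zeros_like(masks.sleb),
            dermis_reference=masks.dermis_reference,
        )
        feats = morphological_features(masks)
        assert np.isnan(feats["hfus.morphology.sleb.thickness_mean"])
        assert np.isnan(feats["hfus.morphology.sleb.depth_max"])

    def test_empty_entry_echo_rejected(self):
        masks = _band_masks()
        with pytest.raises(ValueError, match="entry-echo"):
            morphological_features(
                LayerMaskSet(
                    entry_echo=np.zeros_like(masks.entry_echo),
                    sleb=masks.sleb,
                    dermis_reference=masks.dermis_reference,
                )
            )


class TestEchogenicity:
    def test_band_partition_is_exact(self, rng):
        """LEP + MEP + HEP = 1 on random regions, always."""
        for _ in range(50):
            img = rng.integers(0, 256, (64, 64)).astype(np.uint8)
            mask = rng.random((64, 64)) < 0.5
            if not mask.any():
                continue
            masks = LayerMaskSet(
                entry_echo=mask,
                sleb=np.zeros_like(mask),
                dermis_reference=np.zeros_like(mask),
            )
            feats = echogenicity_features(HFUSScan(pixels=img), masks)
            total = (
                feats["hfus.echogenicity.entry_echo.lep"]
                + feats["hfus.echogenicity.entry_echo.mep"]
                + feats["hfus.echogenicity.entry_echo.hep"]
            )
            assert total == 1.0

    def test_all_zero_region(self):
        img = np.zeros((64, 64), np.uint8)
        mask = np.zeros((64, 64), bool)
        mask[:10] = True
        masks = LayerMaskSet(
            entry_echo=mask,
            sleb=np.zeros_like(mask),
            dermis_reference=np.zeros_like(mask),
        )
        feats = echogenicity_features(HFUSScan(pixels=img), masks)
        assert feats["hfus.echogenicity.entry_echo.lep"] == 1.0
        assert feats["hfus.echogenicity.entry_echo.mep"] == 0.0
        assert feats["hfus.echogenicity.entry_echo.hep"] == 0.0

    def test_counted_fractions(self):
        img = np.zeros((64, 64), np.uint8)
        mask = np.zeros((64, 64), bool)
        mask[0, :10] = True
        img[0, :3] = 10    # below low cut (30)
        img[0, 3:8] = 100  # mid band
        img[0, 8:10] = 200 # above high cut (150)
        masks = LayerMaskSet(
            entry_echo=mask,
            sleb=np.zeros_like(mask),
            dermis_reference=np.zeros_like(mask),
        )
        feats = echogenicity_features(HFUSScan(pixels=img), masks)
        assert feats["hfus.echogenicity.entry_echo.lep"] == pytest.approx(0.3)
        assert feats["hfus.echogenicity.entry_echo.mep"] == pytest.approx(0.5)
        assert feats["hfus.echogenicity.entry_echo.hep"] == pytest.approx(0.2)

    def test_identical_distributions_ratio_near_one(self, rng):
        """SLEB/dermis ratios ~ 1 when both regions share one distribution."""
        img = rng.normal(110, 18, (200, 100)).clip(0, 255).astype(np.uint8)
        masks = _band_masks(h=200, w=100, entry_rows=(5, 15),
                            sleb_rows=(20, 120), dermis_rows=(120, 200))
        feats = echogenicity_features(HFUSScan(pixels=img), masks)
        assert feats["hfus.echogenicity.sleb.mean_over_dermis"] == pytest.approx(
            1.0, abs=0.02
        )
        assert feats["hfus.echogenicity.sleb.mep_over_dermis"] == pytest.approx(
            1.0, abs=0.02
        )

    def test_invalid_bands_rejected(self):
        with pytest.raises(ValueError):
            EchogenicityBands(low_cut=200, high_cut=100)


class TestScattering:
    def test_zero_patch_all_zero(self):
        img = np.zeros((40, 40))
        mask = np.ones((40, 40), bool)
        assert all(v == 0 for v in scattering_stats(img, mask).values())

    def test_order_ge_one_nonnegative(self, rng):
        img = rng.normal(100, 30, (48, 48))
        vals = scattering_stats(img, np.ones((48, 48), bool))
        for name, v in vals.items():
            if name != "order0":
                assert v >= 0

    def test_translation_stability(self, rng):
        """Shifting the texture under a fixed window moves pooled
        coefficients by < 5% relative norm."""
        big = rng.normal(120, 25, (80, 120))
        mask = np.zeros((80, 120), bool)
        mask[8:72, 8:72] = True
        a = np.array(list(scattering_stats(big, mask).values()))
        shifted = np.roll(big, 4, axis=1)
        b = np.array(list(scattering_stats(shifted, mask).values()))
        rel = np.linalg.norm(a - b) / np.linalg.norm(a)
        assert rel < 0.05

    def test_small_bbox_is_missing(self):
        mask = np.zeros((32, 32), bool)
        mask[4:8, 4:8] = True  # 4 px < minimum side
        out = scattering_stats(np.ones((32, 32)), mask)
        assert all(np.isnan(v) for v in out.values())


class TestCombinedLayers:
    def test_union_equals_entry_when_sleb_empty(self):
        params = PhantomParams(sleb_presence_prob=0.0)
        scan, masks = generate_hfus_phantom(params, 2, seed=5)
        assert not masks.sleb.any()
        combined = combined_layer_features(scan, masks)
        full = extract_hfus_features(scan, masks)
        for name, v in combined.items():
            entry_name = name.replace(".combined.", ".entry_echo.")
            ref = full[entry_name]
            if np.isnan(v):
                assert np.isnan(ref)
            else:
                assert v == pytest.approx(ref)

    def test_union_area_is_sum_of_areas(self, params):
        _, masks = generate_hfus_phantom(params, 2, seed=7)
        assert masks.combined().sum() == masks.entry_echo.sum() + masks.sleb.sum()


class TestPaddingInvariance:
    def test_features_ignore_pixels_outside_mask(self, params):
        scan, masks = generate_hfus_phantom(params, 2, seed=3)
        feats_a = extract_hfus_features(scan, masks)
        outside = ~(masks.entry_echo | masks.sleb | masks.dermis_reference)
        pixels = scan.pixels.copy()
        pixels[outside] = 251  # clobber background
        feats_b = extract_hfus_features(HFUSScan(pixels=pixels), masks)
        for name in feats_a:
            a, b = feats_a[name], feats_b[name]
            if np.isnan(a):
                assert np.isnan(b)
            else:
                assert a == pytest.approx(b, rel=1e-9), name
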