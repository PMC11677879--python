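"""Segmentation contracts: Dice, cropping, model determinism, grouped folds."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from akstage.segmentation import (
    CFPNetM,
    SegModelConfig,
    _to_target,
    _train_one,
    build_model,
    crop_scan,
    derive_dermis_reference,
    dice_index,
    patient_folds,
    segment_layers,
    train_segmentation,
)
from akstage.synthetic import PhantomParams, generate_cohort, generate_hfus_phantom
from akstage.types import HFUSScan


class TestDice:
    def test_identical_masks(self):
        m = np.zeros((8, 8), bool)
        m[2:5, 2:5] = True
        assert dice_index(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((8, 8), bool)
        b = np.zeros((8, 8), bool)
        a[0, 0] = True
        b[5, 5] = True
        assert dice_index(a, b) == 0.0

    def test_partial_overlap_closed_form(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[0, :4] = True          # |A| = 4
        b[0, 2:4] = True         # |B| = 2, overlap 2
        assert dice_index(a, b) == pytest.approx(2 * 2 / (4 + 2))

    def test_both_empty_defined_as_one(self):
        empty = np.zeros((4, 4), bool)
        assert dice_index(empty, empty) == 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shapes"):
            dice_index(np.zeros((3, 3), bool), np.zeros((4, 4), bool))

    @given(
        a=arrays(bool, (6, 6), elements=st.booleans()),
        b=arrays(bool, (6, 6), elements=st.booleans()),
    )
    def test_symmetry_and_identity(self, a, b):
        assert dice_index(a, b) == dice_index(b, a)
        assert 0.0 <= dice_index(a, b) <= 1.0
        if dice_index(a, b) == 1.0:
            assert np.array_equal(a, b)


class TestCrop:
    def test_middle_crop_columns(self):
        pixels = np.tile(np.arange(1024, dtype=np.uint8) % 251, (224, 1))
        scan = HFUSScan(pixels=pixels)
        cropped = crop_scan(scan, 512, "middle")
        assert cropped.shape == (224, 512)
        np.testing.assert_array_equal(cropped.pixels, pixels[:, 256:768])

    def test_identity_when_already_target_width(self):
        pixels = np.zeros((224, 512), np.uint8)
        scan = HFUSScan(pixels=pixels)
        assert crop_scan(scan, 512).shape == (224, 512)

    def test_too_wide_rejected(self):
        scan = HFUSScan(pixels=np.zeros((224, 100), np.uint8))
        with pytest.raises(ValueError, match="exceeds"):
            crop_scan(scan, 512)

    def test_window_clamped_to_bounds(self):
        scan = HFUSScan(pixels=np.zeros((100, 200), np.uint8))
        cropped = crop_scan(scan, 100, center=5)
        assert cropped.shape == (100, 100)


class TestModel:
    def test_output_shape_contract(self):
        cfg = SegModelConfig(input_size=(64, 64), epochs=1)
        model = build_model(cfg)
        x = np.zeros((1, 1, 64, 64), np.float32)
        logits = model.forward(x)
        assert logits.shape == (1, 3, 64, 64)
        assert np.isfinite(logits).all()

    def test_seeded_init_is_deterministic(self):
        cfg = SegModelConfig(input_size=(64, 64), seed=3)
        a, b = build_model(cfg), build_model(cfg)
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa.value, pb.value)

    def test_indivisible_input_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            SegModelConfig(input_size=(130, 64))

    def test_checkpoint_roundtrip(self, tmp_path):
        cfg = SegModelConfig(input_size=(64, 64))
        model = build_model(cfg)
        model.save(tmp_path / "m.npz")
        loaded = CFPNetM.load(tmp_path / "m.npz")
        x = np.random.default_rng(0).normal(size=(1, 1, 64, 64)).astype(np.float32)
        np.testing.assert_array_equal(model.forward(x), loaded.forward(x))


class TestFolds:
    def test_assignment_covers_all_patients(self):
        folds = patient_folds([f"P{i}" for i in range(10)], 4, seed=0)
        assert set(folds.values()) == {0, 1, 2, 3}
        assert len(folds) == 10

    def test_single_patient_cannot_split(self, params):
        cohort = generate_cohort(1, (2, 0, 0), params, seed=0,
                                 with_dermoscopy=False)
        with pytest.raises(ValueError, match="patients"):
            train_segmentation(cohort, 2, SegModelConfig(epochs=1))

    def test_fold_assignment_deterministic(self):
        ids = [f"P{i}" for i in range(12)]
        assert patient_folds(ids, 3, seed=5) == patient_folds(ids, 3, seed=5)


@pytest.fixture(scope="module")
def overfit_model(params):
    """One phantom, enough epochs: capacity sanity for segment_layers tests."""
    scan, masks = generate_hfus_phantom(params, 2, seed=1)
    cfg = SegModelConfig(epochs=200, seed=0)
    model = build_model(cfg)
    _train_one(model, [scan.pixels], [_to_target(masks, 3)])
    return model, scan, masks


class TestSegmentLayers:

    def test_overfit_reaches_near_perfect_dice(self, overfit_model):
        model, scan, masks = overfit_model
        pred = segment_layers(model, scan)
        assert dice_index(pred.entry_echo, masks.entry_echo) > 0.99
        assert not pred.degenerate

    def test_outputs_disjoint_and_aligned(self, overfit_model):
        model, scan, _ = overfit_model
        pred = segment_layers(model, scan)
        assert pred.shape == scan.shape
        assert not (pred.entry_echo & pred.sleb).any()
        assert not (pred.entry_echo & pred.dermis_reference).any()

    def test_sleb_free_phantom_gives_empty_sleb(self, overfit_model, params):
        model, _, _ = overfit_model
        no_sleb = dataclasses.replace(params, sleb_presence_prob=0.0)
        scan, _ = generate_hfus_phantom(no_sleb, 1, seed=4)
        pred = segment_layers(model, scan)
        # valid result regardless of SLEB content
        assert pred.entry_echo.any()

    def test_all_background_prediction_flags_degenerate(self, monkeypatch):
        cfg = SegModelConfig(input_size=(64, 64))
        model = build_model(cfg)
        logits = np.zeros((1, 3, 64, 64), np.float32)
        logits[:, 0] = 10.0  # background wins everywhere
        monkeypatch.setattr(model, "forward", lambda x: logits)
        scan = HFUSScan(pixels=np.zeros((64, 64), np.uint8))
        with pytest.warns(UserWarning, match="degenerate"):
            pred = segment_layers(model, scan)
        assert pred.degenerate

    def test_incompatible_size_rejected(self):
        model = build_model(SegModelConfig(input_size=(64, 64)))
        with pytest.raises(ValueError, match="incompatible"):
            segment_layers(model, HFUSScan(pixels=np.zeros((128, 64), np.uint8)))


class TestDermisDerivation:
    def test_band_below_sleb_or_entry(self):
        entry = np.zeros((40, 4), bool)
        sleb = np.zeros((40, 4), bool)
        entry[5:10] = True
        sleb[10:20, :2] = True  # SLEB only in first two columns
        dermis = derive_dermis_reference(entry, sleb, band_px=8)
        assert dermis[20:28, 0].all() and not dermis[:20, 0].any()
        assert dermis[10:18, 3].all()  # below entry where SLEB absent


class TestTrainSegmentation:
    def test_grouped_training_and_determinism(self, params):
        cohort = generate_cohort(6, (4, 2, 2), params, seed=3,
                                 with_dermoscopy=False)
        cfg = SegModelConfig(epochs=2, seed=1)
        _, rep_a = train_segmentation(cohort, 2, cfg)
        _, rep_b = train_segmentation(cohort, 2, cfg)
        assert rep_a.fold_of_patient == rep_b.fold_of_patient
        assert rep_a.entry_dice == rep_b.entry_dice
        folds = rep_a.fold_of_patient
        for f in set(folds.values()):
            inside = {p for p, v in folds.items() if v == f}
            outside = {p for p, v in folds.items() if v != f}
            assert not inside & outside
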