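"""Staging-classifier building blocks and the agreement metrics."""

import numpy as np
import pandas as pd
import pytest

from akstage.classify import (
    ClassifierConfig,
    cohen_kappa,
    confusion_and_accuracy,
    impute_missing,
    interpret_kappa,
    loo_patient_folds,
    mrmr_rank,
    select_and_classify,
    smote_oversample,
    zscore_fit_apply,
)


class TestZScore:
    def test_sample_sd_closed_form(self):
        train = pd.DataFrame({"f": [1.0, 2.0, 3.0]})
        test = pd.DataFrame({"f": [2.0]})
        tr, te = zscore_fit_apply(train, test)
        np.testing.assert_allclose(tr["f"], [-1.0, 0.0, 1.0])
        assert te["f"].iloc[0] == 0.0  # test value equal to train mean

    def test_constant_column_zeroed_with_warning(self):
        train = pd.DataFrame({"f": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="constant"):
            tr, _ = zscore_fit_apply(train, train)
        assert (tr["f"] == 0).all()

    def test_single_row_rejected(self):
        one = pd.DataFrame({"f": [1.0]})
        with pytest.raises(ValueError, match="2 training rows"):
            zscore_fit_apply(one, one)

    def test_test_statistics_never_used(self):
        train = pd.DataFrame({"f": [0.0, 2.0]})
        test_a = pd.DataFrame({"f": [1.0]})
        test_b = pd.DataFrame({"f": [100.0]})
        _, ta = zscore_fit_apply(train, test_a)
        tr_a, _ = zscore_fit_apply(train, test_a)
        tr_b, _ = zscore_fit_apply(train, test_b)
        pd.testing.assert_frame_equal(tr_a, tr_b)
        assert ta["f"].iloc[0] == 0.0


class TestImpute:
    def test_identity_without_missing(self):
        t = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0]})
        tr, te = impute_missing(t, t)
        pd.testing.assert_frame_equal(tr, t)
        pd.testing.assert_frame_equal(te, t)

    def test_median_fill_from_train_only(self):
        train = pd.DataFrame({"a": [1.0, 5.0, 9.0]})
        test = pd.DataFrame({"a": [np.nan]})
        _, te = impute_missing(train, test)
        assert te["a"].iloc[0] == 5.0

    def test_all_missing_column_dropped(self):
        train = pd.DataFrame({"a": [np.nan, np.nan], "b": [1.0, 2.0]})
        test = pd.DataFrame({"a": [3.0], "b": [np.nan]})
        tr, te = impute_missing(train, test)
        assert list(tr.columns) == ["b"]
        assert te["b"].iloc[0] == 1.5


class TestMRMR:
    def test_class_indicator_ranked_first(self, rng):
        n = 60
        labels = np.repeat([1, 2, 3], n // 3)
        table = pd.DataFrame(
            {f"noise{i}": rng.normal(size=n) for i in range(8)}
        )
        table["indicator"] = labels.astype(float)
        ranking = mrmr_rank(table, labels)
        assert ranking[0][0] == "indicator"

    def test_duplicate_of_top_feature_penalized(self, rng):
        n = 60
        labels = np.repeat([1, 2, 3], n // 3)
        # two complementary informative features and an exact duplicate
        is_one = (labels == 1).astype(float) + 0.01 * rng.normal(size=n)
        is_three = (labels == 3).astype(float) + 0.01 * rng.normal(size=n)
        table = pd.DataFrame(
            {
                "ind1": is_one,
                "ind1_copy": is_one.copy(),
                "ind3": is_three,
                "noise": rng.normal(size=n),
            }
        )
        names = [name for name, _ in mrmr_rank(table, labels)]
        assert names[0] in ("ind1", "ind1_copy")
        # the duplicate carries maximal redundancy: the complementary
        # informative feature outranks it
        copy_rank = max(names.index("ind1"), names.index("ind1_copy"))
        assert copy_rank > names.index("ind3")

    def test_full_ranking_returned(self, rng):
        labels = np.repeat([1, 2], 10)
        table = pd.DataFrame(
            {"a": labels.astype(float), "b": rng.normal(size=20)}
        )
        assert len(mrmr_rank(table, labels)) == 2

    def test_degenerate_inputs_rejected(self, rng):
        table = pd.DataFrame({"a": rng.normal(size=10), "b": rng.normal(size=10)})
        with pytest.raises(ValueError, match="classes"):
            mrmr_rank(table, np.ones(10))


class TestSMOTE:
    def test_clinical_counts_balanced(self, rng):
        x = rng.normal(size=(161, 4))
        y = np.repeat([1, 2, 3], [92, 42, 27])
        xs, ys = smote_oversample(x, y, seed=1)
        assert [int((ys == s).sum()) for s in (1, 2, 3)] == [92, 92, 92]
        # original rows preserved
        np.testing.assert_array_equal(xs[:161], x)

    def test_balanced_input_unchanged(self, rng):
        x = rng.normal(size=(30, 3))
        y = np.repeat([1, 2, 3], 10)
        xs, ys = smote_oversample(x, y, seed=0)
        np.testing.assert_array_equal(xs, x)
        np.testing.assert_array_equal(ys, y)

    def test_synthetic_points_on_segments(self, rng):
        """Every synthetic sample is a coordinate-wise convex combination
        of two original same-class points."""
        x = rng.normal(size=(12, 2))
        y = np.array([1] * 9 + [2] * 3)
        xs, ys = smote_oversample(x, y, k_neighbors=2, seed=3)
        originals = x[y == 2]
        for row in xs[12:]:
            on_segment = False
            for i in range(len(originals)):
                for j in range(len(originals)):
                    if i == j:
                        continue
                    a, b = originals[i], originals[j]
                    denom = b - a
                    with np.errstate(divide="ignore", invalid="ignore"):
                        u = (row - a) / denom
                    u = u[np.isfinite(u)]
                    if len(u) and np.allclose(u, u[0], atol=1e-9) and -1e-9 <= u[0] <= 1 + 1e-9:
                        on_segment = True
            assert on_segment

    def test_singleton_class_advises_fallback(self, rng):
        x = rng.normal(size=(4, 2))
        y = np.array([1, 1, 1, 2])
        with pytest.raises(ValueError, match="duplicate_singletons"):
            smote_oversample(x, y, seed=0)
        xs, ys = smote_oversample(x, y, seed=0, duplicate_singletons=True)
        assert (ys == 2).sum() == 3


class TestFoldsAndMetrics:
    def test_loo_by_patient(self):
        ids = ["A", "A", "B", "C", "C", "C"]
        folds = loo_patient_folds(ids)
        assert len(folds) == 3
        sizes = [ids.count(p) for p in folds]
        assert sorted(sizes) == [1, 2, 3]

    def test_single_patient_rejected(self):
        with pytest.raises(ValueError, match="2 patients"):
            loo_patient_folds(["A", "A"])

    def test_confusion_perfect_and_degenerate(self):
        m, acc = confusion_and_accuracy([1, 2, 3], [1, 2, 3])
        assert acc == 1.0
        assert np.array_equal(m, np.eye(3, dtype=int))
        m, acc = confusion_and_accuracy([1, 2, 3], [1, 1, 1])
        assert acc == pytest.approx(1 / 3)
        assert m.sum() == 3

    def test_label_outside_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            confusion_and_accuracy([1, 4], [1, 1])

    def test_kappa_closed_forms(self):
        assert cohen_kappa(np.diag([10, 10, 10])) == 1.0
        assert cohen_kappa(np.array([[5, 5], [5, 5]])) == 0.0
        # p_o = 0.7, p_e = 0.5 -> kappa 0.4
        assert cohen_kappa(np.array([[20, 5], [10, 15]])) == pytest.approx(0.4)

    def test_kappa_degenerate_cases(self):
        # every lesion truly 1 but predicted 2: zero chance agreement
        assert cohen_kappa(np.array([[0, 3], [0, 0]])) == 0.0
        # unanimous truth and prediction: chance agreement 1, observed 1
        assert cohen_kappa(np.array([[7, 0], [0, 0]])) == 1.0
        with pytest.raises(ValueError, match="empty"):
            cohen_kappa(np.zeros((3, 3)))

    @pytest.mark.parametrize(
        "value,label",
        [
            (-0.1, "no agreement"),
            (0.1, "none to slight"),
            (0.3, "fair"),
            (0.5, "moderate"),
            (0.73, "substantial"),
            (0.85, "almost perfect"),
        ],
    )
    def test_kappa_interpretation_bands(self, value, label):
        assert interpret_kappa(value) == label

    def test_kappa_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            interpret_kappa(1.5)


def _toy_table(seed, informative=False, n_patients=12):
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_patients):
        for l in range(3):
            stage = (p + l) % 3 + 1
            row = {
                "patient_id": f"P{p:02d}",
                "lesion_id": f"L{p:02d}_{l}",
                "stage": stage,
            }
            for j in range(10):
                row[f"hfus.histogram.entry_echo.n{j:02d}"] = rng.normal()
            row["hfus.histogram.entry_echo.canary"] = rng.normal()
            if informative:
                row["hfus.morphology.entry_echo.sig"] = stage + 0.05 * rng.normal()
            rows.append(row)
    return pd.DataFrame(rows)


_FAST = ClassifierConfig(
    feature_counts=(2, 5, 10), c_grid=(1.0, 10.0), gamma_factors=(1.0,)
)


class TestSelectAndClassify:
    def test_informative_feature_reaches_ceiling(self):
        rep = select_and_classify(
            _toy_table(2, informative=True), "hfus_hand", config=_FAST, seed=0
        )
        assert rep.accuracy == 1.0
        assert rep.kappa == 1.0
        assert rep.confusion.sum() == 36

    def test_end_to_end_determinism(self):
        a = select_and_classify(
            _toy_table(2, informative=True), "hfus_hand", config=_FAST, seed=0
        )
        b = select_and_classify(
            _toy_table(2, informative=True), "hfus_hand", config=_FAST, seed=0
        )
        assert a.accuracy == b.accuracy
        assert np.array_equal(a.confusion, b.confusion)
        assert a.n_features_per_fold == b.n_features_per_fold

    def test_report_bookkeeping(self):
        rep = select_and_classify(
            _toy_table(2, informative=True), "hfus_hand", config=_FAST, seed=0
        )
        assert rep.confusion.sum() == len(rep.predictions)
        assert rep.accuracy == pytest.approx(
            np.trace(rep.confusion) / rep.confusion.sum()
        )
        assert rep.n_features_mode in rep.n_features_per_fold

    def test_unknown_combination_rejected(self):
        with pytest.raises(ValueError, match="combination"):
            select_and_classify(_toy_table(1), "bogus", config=_FAST)
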