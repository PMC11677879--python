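"""Three-class AK staging from fused feature tables.

The pipeline inside every training fold: median imputation -> z-score
normalization -> minimum-redundancy maximum-relevance (MRMR) feature
ranking -> joint inner grouped-CV search over the feature-count cutoff
and SVM hyperparameters -> SMOTE oversampling of the minority stages ->
RBF-SVM fit -> prediction of the held-out patient.  The outer loop is
leave-one-out over patients (every patient is one fold), so no patient
ever appears on both sides of a split.  Reported: confusion matrix,
accuracy, unweighted Cohen's kappa and the selected feature count per
feature-set combination.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import GroupKFold
from sklearn.svm import SVC

from akstage.features.table import select_features, validate_table

logger = logging.getLogger(__name__)

VALID_STAGES = (1, 2, 3)

#: feature-set combinations mirroring the modality ablation
COMBINATIONS: dict[str, dict[str, tuple[str, ...] | None]] = {
    "hfus_hand": {"modalities": ("hfus",), "families": None},
    "derm_hand": {
        "modalities": ("derm",),
        "families": ("histogram", "glcm", "lbp", "scattering"),
    },
    "derm_nn": {"modalities": ("derm",), "families": ("nn",)},
    "derm_hand_nn": {"modalities": ("derm",), "families": None},
    "hfus_derm_hand": {
        "modalities": ("hfus", "derm"),
        "families": (
            "morphology", "echogenicity", "histogram", "glcm", "lbp", "scattering",
        ),
    },
    "hfus_derm_nn": {
        "modalities": ("hfus", "derm"),
        "families": (
            "morphology", "echogenicity", "histogram", "glcm", "lbp",
            "scattering", "nn",
        ),
    },
    "all": {"modalities": ("hfus", "derm"), "families": None},
}


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def zscore_fit_apply(
    train: pd.DataFrame, test: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Z-score both tables using mean and sample (n-1) SD of ``train`` only.

    Constant training columns (SD 0) are mapped to all-zeros with a
    warning; a single-row training table is an error.
    """
    if len(train) < 2:
        raise ValueError("z-score normalization needs at least 2 training rows")
    mean = train.mean()
    sd = train.std(ddof=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant feature(s) mapped to zero: "
            f"{list(sd.index[constant])[:5]}...",
            stacklevel=2,
        )
    sd = sd.replace(0, 1.0)
    return (train - mean) / sd, (test - mean) / sd


def impute_missing(
    train: pd.DataFrame, test: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fill missing values with training-fold medians.

    Columns missing in every training row are dropped from both tables
    (logged); everything else keeps its observed values.
    """
    medians = train.median()
    all_missing = medians.isna()
    if all_missing.any():
        dropped = list(medians.index[all_missing])
        logger.info("dropping all-missing feature(s): %s", dropped)
        train = train.drop(columns=dropped)
        test = test.drop(columns=dropped)
        medians = medians.drop(index=dropped)
    return train.fillna(medians), test.fillna(medians)


def mrmr_rank(
    features: pd.DataFrame, labels: np.ndarray
) -> list[tuple[str, float]]:
    """Greedy MRMR ranking (difference criterion) of all feature columns.

    Relevance is the correlation ratio (one-way ANOVA eta squared) of
    each feature against the class label — bounded in [0, 1], hence
    commensurate with the redundancy term, the mean absolute Pearson
    correlation with the already-selected features.  The first feature
    maximizes relevance, each next maximizes relevance minus redundancy,
    so a duplicate of an already-selected feature (redundancy 1) falls
    behind every informative feature that adds new information.
    Zero-variance features are excluded before ranking.  Returns the
    full ranking as (name, score) pairs.
    """
    labels = np.asarray(labels)
    if features.shape[1] < 2:
        raise ValueError("need at least 2 features to rank")
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least 2 classes present")
    variances = features.var(ddof=0)
    cols = [c for c in features.columns if variances[c] > 0]
    if not cols:
        return []
    x = features[cols].to_numpy(dtype=float)

    # eta^2 = 1 - SS_within / SS_total, per feature
    ss_total = ((x - x.mean(axis=0)) ** 2).sum(axis=0)
    ss_within = np.zeros_like(ss_total)
    for cls in np.unique(labels):
        member = x[labels == cls]
        ss_within += ((member - member.mean(axis=0)) ** 2).sum(axis=0)
    relevance = 1.0 - ss_within / np.where(ss_total > 0, ss_total, 1.0)
    corr = np.abs(np.corrcoef(x, rowvar=False))
    np.nan_to_num(corr, copy=False, nan=0.0)

    n = len(cols)
    selected: list[int] = []
    scores: list[float] = []
    remaining = set(range(n))
    redundancy = np.zeros(n)
    while remaining:
        rem = np.fromiter(remaining, dtype=int)
        crit = relevance[rem] - (
            redundancy[rem] / len(selected) if selected else 0.0
        )
        best_pos = int(np.argmax(crit))
        best = int(rem[best_pos])
        selected.append(best)
        scores.append(float(crit[best_pos]))
        remaining.discard(best)
        redundancy += corr[:, best]
    return [(cols[i], s) for i, s in zip(selected, scores)]


def smote_oversample(
    features: np.ndarray,
    labels: np.ndarray,
    k_neighbors: int = 5,
    seed: int = 0,
    duplicate_singletons: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """SMOTE: upsample minority classes to the majority count.

    Synthetic samples are convex combinations ``x + u * (x_nn - x)``
    with ``u ~ U(0, 1)`` and ``x_nn`` one of the ``k`` nearest
    same-class neighbours (k reduced to class size - 1 when smaller).
    Original rows are always preserved.  A single-member class raises
    unless ``duplicate_singletons`` allows plain duplication.
    """
    from sklearn.neighbors import NearestNeighbors

    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)
    majority = counts.max()
    out_x, out_y = [x], [y]
    for cls, count in zip(classes, counts):
        deficit = int(majority - count)
        if deficit == 0:
            continue
        members = x[y == cls]
        if count == 1:
            if not duplicate_singletons:
                raise ValueError(
                    f"class {cls} has a single member; SMOTE needs >= 2 "
                    "(pass duplicate_singletons=True to fall back to "
                    "duplication)"
                )
            synth = np.repeat(members, deficit, axis=0)
        else:
            k = min(k_neighbors, count - 1)
            nn = NearestNeighbors(n_neighbors=k + 1).fit(members)
            _, idx = nn.kneighbors(members)  # col 0 is the point itself
            base = rng.integers(0, count, size=deficit)
            pick = idx[base, rng.integers(1, k + 1, size=deficit)]
            u = rng.uniform(0, 1, size=(deficit, 1))
            synth = members[base] + u * (members[pick] - members[base])
        out_x.append(synth)
        out_y.append(np.full(deficit, cls, dtype=y.dtype))
    return np.concatenate(out_x), np.concatenate(out_y)


def loo_patient_folds(patient_ids: list[str]) -> dict[str, int]:
    """Leave-one-patient-out fold assignment: fold i tests patient i."""
    unique = list(dict.fromkeys(patient_ids))
    if len(unique) < 2:
        raise ValueError("leave-one-out needs at least 2 patients")
    return {p: i for i, p in enumerate(unique)}


def confusion_and_accuracy(
    y_true: np.ndarray, y_pred: np.ndarray
) -> tuple[np.ndarray, float]:
    """3x3 confusion matrix (rows = true stage, cols = predicted) and
    accuracy = trace / total."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors differ in length")
    for arr, which in ((y_true, "true"), (y_pred, "predicted")):
        bad = ~np.isin(arr, VALID_STAGES)
        if bad.any():
            raise ValueError(f"{which} labels outside {VALID_STAGES}: "
                             f"{sorted(set(arr[bad]))}")
    matrix = np.zeros((3, 3), dtype=int)
    for t, p in zip(y_true, y_pred):
        matrix[t - 1, p - 1] += 1
    return matrix, float(np.trace(matrix) / matrix.sum())


def cohen_kappa(matrix: np.ndarray) -> float:
    """Unweighted Cohen's kappa of a square confusion matrix.

    ``kappa = (p_o - p_e) / (1 - p_e)`` with observed agreement
    ``p_o = trace/n`` and chance agreement
    ``p_e = sum_i row_i * col_i / n^2``.  Degenerate ``p_e = 1`` is
    defined as 1.0 when observed agreement is also perfect, else 0.0
    with a warning.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("confusion matrix must be square")
    n = matrix.sum()
    if n == 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(matrix) / n
    p_e = float((matrix.sum(axis=1) * matrix.sum(axis=0)).sum()) / n**2
    if p_e >= 1.0 - 1e-12:
        if p_o >= 1.0 - 1e-12:
            return 1.0
        warnings.warn("chance agreement is 1; kappa undefined, returning 0.0",
                      stacklevel=2)
        return 0.0
    return float((p_o - p_e) / (1 - p_e))


_KAPPA_BANDS = (
    (0.20, "none to slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.00, "almost perfect"),
)


def interpret_kappa(value: float) -> str:
    """Qualitative agreement band of a kappa value in [-1, 1]."""
    if not -1.0 <= value <= 1.0:
        raise ValueError(f"kappa must lie in [-1, 1], got {value}")
    if value < 0:
        return "no agreement"
    for upper, label in _KAPPA_BANDS:
        if value <= upper:
            return label
    return "almost perfect"


# ---------------------------------------------------------------------------
# end-to-end staging experiment
# ---------------------------------------------------------------------------


@dataclass
class ClassifierConfig:
    """Search grid and pipeline knobs of the staging experiment."""

    c_grid: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
    gamma_factors: tuple[float, ...] = (0.1, 1.0, 10.0)
    feature_counts: tuple[int, ...] = (5, 10, 20, 40)
    inner_folds: int = 5
    smote_k: int = 5
    duplicate_singletons: bool = True


@dataclass
class StagingReport:
    """Aggregated leave-one-out staging result for one combination."""

    combination: str
    confusion: np.ndarray
    accuracy: float
    kappa: float
    kappa_label: str
    n_features_mode: int
    n_features_per_fold: list[int]
    predictions: pd.DataFrame
    hyperparams_per_fold: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "combination": self.combination,
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "kappa": self.kappa,
            "kappa_label": self.kappa_label,
            "n_features_mode": self.n_features_mode,
            "n_features_per_fold": self.n_features_per_fold,
            "hyperparams_per_fold": self.hyperparams_per_fold,
        }


def _fit_svm(
    x: np.ndarray,
    y: np.ndarray,
    c: float,
    gamma_factor: float,
    smote_k: int,
    seed: int,
    duplicate_singletons: bool,
) -> SVC | None:
    """SMOTE the training set, then fit a one-vs-one RBF SVM."""
    if len(np.unique(y)) < 2:
        return None
    xs, ys = smote_oversample(
        x, y, k_neighbors=smote_k, seed=seed,
        duplicate_singletons=duplicate_singletons,
    )
    var = xs.var()
    gamma = gamma_factor / (xs.shape[1] * var) if var > 0 else "scale"
    clf = SVC(C=c, kernel="rbf", gamma=gamma, decision_function_shape="ovo")
    clf.fit(xs, ys)
    return clf


def select_and_classify(
    table: pd.DataFrame,
    combination: str = "all",
    config: ClassifierConfig | None = None,
    seed: int = 0,
    leakage_canary: str | None = None,
) -> StagingReport:
    """The full staging experiment for one feature-set combination.

    Outer loop: leave-one-patient-out.  Per fold everything is fitted on
    the training rows only — imputation medians, z-score statistics,
    MRMR ranking, the joint (feature count, C, gamma) search via inner
    patient-grouped CV, SMOTE, and the SVM.  Tie-breaking prefers the
    smallest feature count, then the smallest C, then gamma.

    ``leakage_canary`` names a feature column that is overwritten with
    the true stage label on the held-out rows (only) at the start of
    each fold — a leak-free pipeline never sees those values during
    fitting, so accuracy must stay at chance; any leak shows up as
    inflated accuracy.
    """
    config = config or ClassifierConfig()
    validate_table(table)
    if combination not in COMBINATIONS:
        raise ValueError(
            f"unknown combination {combination!r}; "
            f"options: {sorted(COMBINATIONS)}"
        )
    sel = COMBINATIONS[combination]
    feat_cols = select_features(
        table, modalities=sel["modalities"], families=sel["families"]
    )
    if not feat_cols:
        raise ValueError(f"no features in table for combination {combination!r}")
    if leakage_canary is not None and leakage_canary not in feat_cols:
        raise ValueError(f"canary column {leakage_canary!r} not in combination")

    folds = loo_patient_folds(list(table["patient_id"]))
    rng = np.random.default_rng(seed)
    fold_seeds = rng.integers(0, 2**31, size=len(folds))

    all_true: list[int] = []
    all_pred: list[int] = []
    rows: list[dict] = []
    counts_per_fold: list[int] = []
    hypers_per_fold: list[dict] = []

    for patient, fold in folds.items():
        test_mask = (table["patient_id"] == patient).to_numpy()
        work = table[feat_cols].copy()
        if leakage_canary is not None:
            work.loc[test_mask, leakage_canary] = table.loc[
                test_mask, "stage"
            ].astype(float)
        train_x_raw = work[~test_mask]
        test_x_raw = work[test_mask]
        train_y = table.loc[~test_mask, "stage"].to_numpy()
        test_y = table.loc[test_mask, "stage"].to_numpy()
        train_groups = table.loc[~test_mask, "patient_id"].to_numpy()

        train_x_raw, test_x_raw = impute_missing(train_x_raw, test_x_raw)
        train_x, test_x = zscore_fit_apply(train_x_raw, test_x_raw)
        ranking = [name for name, _ in mrmr_rank(train_x, train_y)]

        best = None  # (score, m, c, gf)
        n_groups = len(np.unique(train_groups))
        inner = GroupKFold(n_splits=min(config.inner_folds, n_groups))
        splits = list(inner.split(train_x, train_y, groups=train_groups))
        counts = sorted({min(m, len(ranking)) for m in config.feature_counts})
        for m in counts:
            xm = train_x[ranking[:m]].to_numpy()
            for c in config.c_grid:
                for gf in config.gamma_factors:
                    scores = []
                    for tr_idx, va_idx in splits:
                        clf = _fit_svm(
                            xm[tr_idx], train_y[tr_idx], c, gf,
                            config.smote_k, int(fold_seeds[fold]),
                            config.duplicate_singletons,
                        )
                        if clf is None:
                            logger.debug(
                                "degenerate inner fold (single class) skipped"
                            )
                            continue
                        scores.append(
                            float(
                                (clf.predict(xm[va_idx]) == train_y[va_idx]).mean()
                            )
                        )
                    if not scores:
                        continue
                    cand = (np.mean(scores), m, c, gf)
                    # maximize score; tie-break: small m, small C, small gamma
                    if best is None or (
                        cand[0] > best[0] + 1e-12
                        or (
                            abs(cand[0] - best[0]) <= 1e-12
                            and (cand[1], cand[2], cand[3])
                            < (best[1], best[2], best[3])
                        )
                    ):
                        best = cand
        if best is None:
            raise RuntimeError("no valid hyperparameter candidate in fold")
        _, m, c, gf = best
        clf = _fit_svm(
            train_x[ranking[:m]].to_numpy(), train_y, c, gf,
            config.smote_k, int(fold_seeds[fold]), config.duplicate_singletons,
        )
        pred = clf.predict(test_x[ranking[:m]].to_numpy())
        counts_per_fold.append(m)
        hypers_per_fold.append({"n_features": m, "C": c, "gamma_factor": gf})
        all_true.extend(int(v) for v in test_y)
        all_pred.extend(int(v) for v in pred)
        for lid, t, p in zip(table.loc[test_mask, "lesion_id"], test_y, pred):
            rows.append(
                {"patient_id": patient, "lesion_id": lid,
                 "stage": int(t), "predicted": int(p)}
            )

    matrix, accuracy = confusion_and_accuracy(
        np.array(all_true), np.array(all_pred)
    )
    kappa = cohen_kappa(matrix)
    mode = int(pd.Series(counts_per_fold).mode().iloc[0])
    return StagingReport(
        combination=combination,
        confusion=matrix,
        accuracy=accuracy,
        kappa=kappa,
        kappa_label=interpret_kappa(kappa),
        n_features_mode=mode,
        n_features_per_fold=counts_per_fold,
        predictions=pd.DataFrame(rows),
        hyperparams_per_fold=hypers_per_fold,
    )
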