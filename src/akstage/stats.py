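"""Nonparametric group-difference statistics for stage-labelled features.

Stage groups are compared with the Kruskal–Wallis rank test (tie
corrected), the rank-based eta-squared effect size
``(H - k + 1) / (n - k)``, and Dunn's post-hoc pairwise test with
Bonferroni correction inside each feature's pairwise family.  No
multiplicity correction is applied across features at the screening
stage; each feature is reported with its own raw Kruskal–Wallis p value.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

DEFAULT_ALPHA = 0.05

#: conventional eta-squared bands: small / medium / large
ETA_SQUARED_BANDS = ((0.01, "small"), (0.06, "medium"), (0.14, "large"))

#: feature families regarded as medically interpretable
INTERPRETABLE_FAMILIES = ("morphology", "echogenicity", "histogram", "glcm")


@dataclass
class GroupStatResult:
    """Group-difference statistics for one feature across stages."""

    feature: str
    h_statistic: float
    p_value: float
    eta_squared: float
    dunn_z: dict[tuple[int, int], float] = field(default_factory=dict)
    dunn_p_adjusted: dict[tuple[int, int], float] = field(default_factory=dict)
    alpha: float = DEFAULT_ALPHA

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    def significant_pairs(self) -> list[tuple[int, int]]:
        return [
            pair
            for pair, p in self.dunn_p_adjusted.items()
            if p < self.alpha
        ]


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Kruskal–Wallis H and p value for ``k`` independent samples.

    H is tie-corrected; p comes from the chi-squared approximation with
    ``k - 1`` degrees of freedom.  All pooled values identical gives
    ``H = 0, p = 1``.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 1 for g in groups):
        raise ValueError("every group needs at least one value")
    n_total = sum(len(g) for g in groups)
    if n_total < 3:
        raise ValueError("need at least three values in total")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def eta_squared(h: float, k: int, n: int) -> float:
    """Rank-based effect size ``(H - k + 1) / (n - k)``, floored at 0."""
    if n <= k:
        raise ValueError(f"need n > k groups, got n={n}, k={k}")
    return max(0.0, (h - k + 1) / (n - k))


def eta_squared_label(value: float) -> str:
    """Qualitative band for an eta-squared effect size."""
    if value < 0:
        raise ValueError("eta squared cannot be negative")
    label = "negligible"
    for cut, name in ETA_SQUARED_BANDS:
        if value >= cut:
            label = name
    return label


def dunn_posthoc(
    groups: list[np.ndarray],
    labels: list[int] | None = None,
) -> tuple[dict[tuple[int, int], float], dict[tuple[int, int], float]]:
    """Dunn's post-hoc pairwise comparisons with Bonferroni correction.

    Pairwise z statistics are computed from mean ranks of the pooled
    sample with the standard tie correction; two-sided p values are
    Bonferroni-adjusted by the number of pairs (capped at 1).

    Returns ``(z_by_pair, adjusted_p_by_pair)`` keyed by group-label
    pairs (defaults to 1-based group indices).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    if labels is None:
        labels = list(range(1, len(groups) + 1))

    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    # tie correction term: sum over tie groups of (t^3 - t)
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts**3 - counts))
    tie_term = tie_sum / (12.0 * (n - 1)) if n > 1 else 0.0

    mean_ranks = []
    start = 0
    for g in groups:
        mean_ranks.append(float(np.mean(ranks[start : start + len(g)])))
        start += len(g)

    n_pairs = len(groups) * (len(groups) - 1) // 2
    z_by_pair: dict[tuple[int, int], float] = {}
    p_by_pair: dict[tuple[int, int], float] = {}
    for i, j in itertools.combinations(range(len(groups)), 2):
        ni, nj = len(groups[i]), len(groups[j])
        sigma_sq = (n * (n + 1) / 12.0 - tie_term) * (1.0 / ni + 1.0 / nj)
        pair = (labels[i], labels[j])
        if sigma_sq <= 0:  # fully tied data
            z = 0.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / np.sqrt(sigma_sq)
        p_raw = 2.0 * sps.norm.sf(abs(z))
        z_by_pair[pair] = float(z)
        p_by_pair[pair] = float(min(1.0, p_raw * n_pairs))
    return z_by_pair, p_by_pair


def analyze_feature(
    values_by_stage: dict[int, np.ndarray],
    feature_name: str = "",
    alpha: float = DEFAULT_ALPHA,
) -> GroupStatResult:
    """Full Kruskal–Wallis + eta-squared + Dunn analysis of one feature."""
    stages = sorted(values_by_stage)
    groups = [np.asarray(values_by_stage[s], dtype=float) for s in stages]
    h, p = kruskal_wallis(groups)
    n = sum(len(g) for g in groups)
    eta2 = eta_squared(h, k=len(groups), n=n)
    z, p_adj = dunn_posthoc(groups, labels=stages)
    return GroupStatResult(
        feature=feature_name,
        h_statistic=h,
        p_value=p,
        eta_squared=eta2,
        dunn_z=z,
        dunn_p_adjusted=p_adj,
        alpha=alpha,
    )


def feature_screen(
    table: pd.DataFrame,
    families: tuple[str, ...] = INTERPRETABLE_FAMILIES,
    alpha: float = DEFAULT_ALPHA,
    stage_column: str = "stage",
) -> list[GroupStatResult]:
    """Screen interpretable features for stage-group differences.

    ``table`` is a feature table (one row per lesion) whose feature
    columns follow the ``modality.family.region.stat`` naming scheme.
    Only columns whose family tag is in ``families`` are screened; rows
    with missing values are dropped per feature.  Results are sorted by
    p value.
    """
    from akstage.features.table import feature_columns, parse_feature_name

    stages = sorted(table[stage_column].unique())
    if len(stages) < 2:
        raise ValueError("need at least two stages present")

    results: list[GroupStatResult] = []
    for col in feature_columns(table):
        tags = parse_feature_name(col)
        if families and tags.family not in families:
            continue
        sub = table[[stage_column, col]].dropna()
        groups = {
            int(s): sub.loc[sub[stage_column] == s, col].to_numpy()
            for s in stages
        }
        if any(len(g) == 0 for g in groups.values()):
            continue
        results.append(analyze_feature(groups, feature_name=col, alpha=alpha))
    results.sort(key=lambda r: r.p_value)
    return results


def results_to_frame(results: list[GroupStatResult]) -> pd.DataFrame:
    """Flatten screen results to a tidy DataFrame (one row per feature)."""
    rows = []
    for r in results:
        row: dict[str, object] = {
            "feature": r.feature,
            "H": r.h_statistic,
            "p": r.p_value,
            "eta_squared": r.eta_squared,
            "effect_size_label": eta_squared_label(r.eta_squared),
            "significant": r.significant,
        }
        for pair, p in r.dunn_p_adjusted.items():
            row[f"dunn_p_{pair[0]}v{pair[1]}"] = p
        rows.append(row)
    return pd.DataFrame(rows)
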