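"""Feature-table conventions.

A feature table is a pandas DataFrame with one row per lesion, key
columns ``patient_id``, ``lesion_id``, ``stage``, and one column per
named feature.  Feature names encode their tags in four dot-separated
parts::

    <modality>.<family>.<region>.<stat>

e.g. ``hfus.glcm.sleb.contrast`` or ``derm.histogram.R.mean``.
``modality`` is ``hfus`` or ``derm``; ``family`` is one of morphology,
echogenicity, histogram, glcm, lbp, scattering, nn; ``region`` is a
skin layer (entry_echo / sleb / dermis / combined) for HFUS or a
channel name (R, G, B, H, S, V) or ``image`` for dermatoscopy.
Missing values (e.g. SLEB features of SLEB-free lesions) are NaN.
"""

from __future__ import annotations

from typing import NamedTuple

import pandas as pd

KEY_COLUMNS = ("patient_id", "lesion_id", "stage")

MODALITIES = ("hfus", "derm")
FAMILIES = (
    "morphology",
    "echogenicity",
    "histogram",
    "glcm",
    "lbp",
    "scattering",
    "nn",
)


class FeatureTags(NamedTuple):
    modality: str
    family: str
    region: str
    stat: str


def make_name(modality: str, family: str, region: str, stat: str) -> str:
    """Compose a feature name from its tags (validating tag vocabulary)."""
    if modality not in MODALITIES:
        raise ValueError(f"unknown modality {modality!r}")
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    for part in (region, stat):
        if "." in part or not part:
            raise ValueError(f"invalid tag part {part!r}")
    return f"{modality}.{family}.{region}.{stat}"


def parse_feature_name(name: str) -> FeatureTags:
    parts = name.split(".", 3)
    if len(parts) != 4 or parts[0] not in MODALITIES:
        raise ValueError(f"not a feature name: {name!r}")
    return FeatureTags(*parts)


def is_feature_name(name: str) -> bool:
    try:
        parse_feature_name(name)
        return True
    except ValueError:
        return False


def feature_columns(table: pd.DataFrame) -> list[str]:
    """All columns of ``table`` that are tagged feature names."""
    return [c for c in table.columns if is_feature_name(str(c))]


def select_features(
    table: pd.DataFrame,
    modalities: tuple[str, ...] | None = None,
    families: tuple[str, ...] | None = None,
) -> list[str]:
    """Feature columns restricted to the given modality/family tags."""
    cols = []
    for c in feature_columns(table):
        t = parse_feature_name(c)
        if modalities is not None and t.modality not in modalities:
            continue
        if families is not None and t.family not in families:
            continue
        cols.append(c)
    return cols


def validate_table(table: pd.DataFrame) -> None:
    """Check feature-table invariants; raise ValueError on violation."""
    for key in KEY_COLUMNS:
        if key not in table.columns:
            raise ValueError(f"missing key column {key!r}")
    dup = table.duplicated(subset=["patient_id", "lesion_id"])
    if dup.any():
        raise ValueError(
            f"duplicate (patient, lesion) keys in rows {list(table.index[dup])}"
        )
    bad = ~table["stage"].isin((1, 2, 3))
    if bad.any():
        raise ValueError(
            f"stage labels outside {{1,2,3}} in rows {list(table.index[bad])}"
        )
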