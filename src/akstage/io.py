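"""Readers and writers: images, indexed masks, manifests, cohorts, configs.

Images travel as 8-bit PNG (grayscale HFUS, RGB dermatoscopy); layer
masks as indexed PNG with the palette 0 = background, 1 = entry echo,
2 = SLEB, 3 = dermis reference; feature tables as CSV with the
``modality.family.region.stat`` header scheme; reports as JSON; run
configuration as YAML (JSON is a YAML subset and loads too).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from akstage.types import (
    Cohort,
    DermoscopyImage,
    HFUSScan,
    LayerMaskSet,
    Lesion,
    VALID_STAGES,
)

MANIFEST_COLUMNS = ("patient_id", "lesion_id", "stage", "hfus_path", "derm_path")

_MASK_PALETTE = [
    0, 0, 0,        # background
    255, 80, 80,    # entry echo
    80, 160, 255,   # SLEB
    120, 220, 120,  # dermis reference
]


def write_image(path: str | Path, array: np.ndarray) -> None:
    Image.fromarray(array).save(path)


def read_gray_image(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("L"))


def read_rgb_image(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def write_mask(path: str | Path, masks: LayerMaskSet) -> None:
    img = Image.fromarray(masks.to_label_image(), mode="P")
    img.putpalette(_MASK_PALETTE)
    img.save(path)


def read_mask(path: str | Path) -> LayerMaskSet:
    label = np.asarray(Image.open(path))
    return LayerMaskSet.from_label_image(label)


# ---------------------------------------------------------------------------
# manifests and cohorts
# ---------------------------------------------------------------------------


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Load and validate a cohort manifest CSV.

    Required columns: patient_id, lesion_id, stage, hfus_path, derm_path
    (optionally mask_path).  Paths are resolved relative to the manifest
    location; every problem row is reported in one error message.
    """
    path = Path(path)
    try:
        table = pd.read_csv(path, dtype={"patient_id": str, "lesion_id": str})
    except pd.errors.EmptyDataError:
        raise ValueError(f"manifest {path} is empty") from None
    missing_cols = [c for c in MANIFEST_COLUMNS if c not in table.columns]
    if missing_cols:
        raise ValueError(f"manifest missing columns: {missing_cols}")
    if len(table) == 0:
        raise ValueError(f"manifest {path} has no rows")

    problems: list[str] = []
    base = path.parent
    dup = table.duplicated(subset=["patient_id", "lesion_id"], keep=False)
    for i in table.index[dup]:
        problems.append(f"row {i}: duplicate (patient, lesion) key")
    for i, row in table.iterrows():
        if row["stage"] not in VALID_STAGES:
            problems.append(f"row {i}: stage {row['stage']!r} not in 1..3")
        for col in ("hfus_path", "derm_path", "mask_path"):
            if col in table.columns and isinstance(row.get(col), str):
                if not (base / row[col]).exists():
                    problems.append(f"row {i}: missing file {row[col]}")
    if problems:
        raise ValueError(
            "invalid manifest:\n  " + "\n  ".join(problems)
        )
    return table


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Persist a cohort as a directory tree with a manifest CSV."""
    out = Path(out_dir)
    for sub in ("hfus", "derm", "masks"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    rows = []
    for les in cohort:
        rec: dict[str, object] = {
            "patient_id": les.patient_id,
            "lesion_id": les.lesion_id,
            "stage": les.stage,
        }
        hfus_path = f"hfus/{les.lesion_id}.png"
        write_image(out / hfus_path, les.scan.pixels)
        rec["hfus_path"] = hfus_path
        if les.dermoscopy is not None:
            derm_path = f"derm/{les.lesion_id}.png"
            write_image(out / derm_path, les.dermoscopy.rgb)
            rec["derm_path"] = derm_path
        else:
            rec["derm_path"] = ""
        if les.masks is not None:
            mask_path = f"masks/{les.lesion_id}.png"
            write_mask(out / mask_path, les.masks)
            rec["mask_path"] = mask_path
        rows.append(rec)
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cohort(manifest_path: str | Path) -> Cohort:
    """Rebuild a cohort from a manifest written by :func:`write_cohort`."""
    manifest_path = Path(manifest_path)
    table = read_manifest(manifest_path)
    base = manifest_path.parent
    lesions = []
    for _, row in table.iterrows():
        scan = HFUSScan(
            pixels=read_gray_image(base / row["hfus_path"]),
            patient_id=row["patient_id"],
            lesion_id=row["lesion_id"],
        )
        derm = None
        if isinstance(row.get("derm_path"), str) and row["derm_path"]:
            derm = DermoscopyImage(
                rgb=read_rgb_image(base / row["derm_path"]),
                patient_id=row["patient_id"],
                lesion_id=row["lesion_id"],
            )
        masks = None
        if isinstance(row.get("mask_path"), str) and row["mask_path"]:
            masks = read_mask(base / row["mask_path"])
        lesions.append(
            Lesion(
                patient_id=row["patient_id"],
                lesion_id=row["lesion_id"],
                stage=int(row["stage"]),
                scan=scan,
                dermoscopy=derm,
                masks=masks,
            )
        )
    return Cohort(lesions=lesions)


# ---------------------------------------------------------------------------
# feature tables and reports
# ---------------------------------------------------------------------------


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    from akstage.features.table import validate_table

    table = pd.read_csv(path, dtype={"patient_id": str, "lesion_id": str})
    validate_table(table)
    return table


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default))


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

#: every configurable section and its allowed keys
_CONFIG_SCHEMA: dict[str, tuple[str, ...]] = {
    "global": ("seed", "out_dir"),
    "cohort": ("n_patients", "class_counts", "with_dermoscopy"),
    "phantom": (),       # validated against PhantomParams fields dynamically
    "segmentation": (),  # validated against SegModelConfig fields
    "classifier": (),    # validated against ClassifierConfig fields
    "features": (),      # validated against HFUSFeatureConfig fields
    "stats": ("alpha", "families"),
    "pipeline": ("n_folds", "combinations", "use_predicted_masks",
                 "extractor_epochs", "extractor_n_per_class"),
}


def load_config(path: str | Path | None) -> dict:
    """Load a YAML/JSON run config, rejecting unknown sections and keys."""
    from dataclasses import fields

    from akstage.classify import ClassifierConfig
    from akstage.features.hfus import HFUSFeatureConfig
    from akstage.segmentation import SegModelConfig
    from akstage.synthetic import PhantomParams

    raw = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")

    dynamic = {
        "phantom": {f.name for f in fields(PhantomParams)},
        "segmentation": {f.name for f in fields(SegModelConfig)},
        "classifier": {f.name for f in fields(ClassifierConfig)},
        "features": {f.name for f in fields(HFUSFeatureConfig)},
    }
    for section, content in raw.items():
        if section not in _CONFIG_SCHEMA:
            raise ValueError(f"unknown config section {section!r}")
        allowed = dynamic.get(section, set(_CONFIG_SCHEMA[section]))
        if not isinstance(content, dict):
            raise ValueError(f"config section {section!r} must be a mapping")
        unknown = set(content) - set(allowed)
        if unknown:
            raise ValueError(
                f"unknown key(s) {sorted(unknown)} in config section "
                f"{section!r}; allowed: {sorted(allowed)}"
            )
    return raw


def dump_config(config: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=True))
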