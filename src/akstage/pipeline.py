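"""End-to-end orchestration: simulate -> segment -> extract -> classify -> stats.

Library counterpart of the ``akstage run-all`` command.  Every stage is
callable on its own; :func:`run_pipeline` wires them in the canonical
order, persists every intermediate artifact under the output directory,
and derives per-stage random seeds from the single global seed via
named substreams.
"""

from __future__ import annotations

import dataclasses
import logging
import time
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from akstage import io as akio
from akstage import stats as akstats
from akstage.classify import ClassifierConfig, StagingReport, select_and_classify
from akstage.dermoscopy import (
    SmallCNNExtractor,
    extract_derm_features,
    train_small_cnn_extractor,
)
from akstage.features.hfus import (
    EchogenicityBands,
    HFUSFeatureConfig,
    extract_hfus_features,
)
from akstage.segmentation import (
    SegModelConfig,
    SegmentationReport,
    segment_layers,
    train_segmentation,
)
from akstage.synthetic import PhantomParams, generate_cohort
from akstage.types import Cohort

logger = logging.getLogger(__name__)

#: the five feature-set combinations of the modality ablation
DEFAULT_COMBINATIONS = (
    "hfus_derm_hand",
    "derm_nn",
    "derm_hand_nn",
    "hfus_derm_nn",
    "all",
)


def substream(seed: int, name: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    tag = zlib.crc32(name.encode("utf-8"))  # stable across processes
    h = np.random.SeedSequence([seed, tag])
    return int(h.generate_state(1)[0] % (2**31))


def build_hfus_table(
    cohort: Cohort,
    masks_by_lesion: dict[str, object] | None = None,
    config: HFUSFeatureConfig | None = None,
) -> pd.DataFrame:
    """HFUS handcrafted feature table, one row per lesion.

    ``masks_by_lesion`` (lesion id -> LayerMaskSet) supplies predicted
    masks; the cohort's ground-truth masks are used when absent.
    """
    rows = []
    for les in cohort:
        masks = (
            masks_by_lesion[les.lesion_id]
            if masks_by_lesion is not None
            else les.masks
        )
        row = {
            "patient_id": les.patient_id,
            "lesion_id": les.lesion_id,
            "stage": les.stage,
        }
        row.update(extract_hfus_features(les.scan, masks, config))
        rows.append(row)
    return pd.DataFrame(rows)


def build_derm_table(
    cohort: Cohort,
    extractor: SmallCNNExtractor | None = None,
    config: HFUSFeatureConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Dermatoscopy feature table (preprocessing + handcrafted + CNN)."""
    rows = []
    for les in cohort:
        if les.dermoscopy is None:
            raise ValueError(f"lesion {les.lesion_id} has no dermatoscopy image")
        row = {
            "patient_id": les.patient_id,
            "lesion_id": les.lesion_id,
            "stage": les.stage,
        }
        row.update(
            extract_derm_features(les.dermoscopy, extractor, config, seed=seed)
        )
        rows.append(row)
    return pd.DataFrame(rows)


def merge_feature_tables(*tables: pd.DataFrame) -> pd.DataFrame:
    """Outer-join feature tables on the lesion key columns."""
    out = tables[0]
    for t in tables[1:]:
        out = out.merge(t, on=["patient_id", "lesion_id", "stage"], how="outer")
    return out


def _config_obj(cls, overrides: dict):
    if cls is HFUSFeatureConfig and "bands" in overrides:
        overrides = dict(overrides)
        overrides["bands"] = EchogenicityBands(**overrides["bands"])
    known = {f.name for f in dataclasses.fields(cls)}
    bad = set(overrides) - known
    if bad:
        raise ValueError(f"unknown {cls.__name__} key(s): {sorted(bad)}")
    converted = {}
    for key, value in overrides.items():
        converted[key] = tuple(value) if isinstance(value, list) else value
    return cls(**converted)


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Execute the full framework on a freshly simulated phantom cohort.

    Stages: simulate -> patient-grouped segmentation training ->
    held-out segmentation of every scan -> HFUS feature extraction from
    the predicted masks -> dermatoscopy preprocessing and feature
    extraction (handcrafted + desk-scale CNN) -> staging classification
    for every requested feature-set combination -> group statistics on
    the interpretable features.  Raises with the stage name on failure;
    returns the collected reports.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("global", {}).get("seed", 0))
    akio.dump_config(config, out / "resolved_config.yaml")

    cohort_cfg = config.get("cohort", {})
    pipe_cfg = config.get("pipeline", {})
    params = _config_obj(PhantomParams, config.get("phantom", {}))
    seg_cfg = _config_obj(SegModelConfig, config.get("segmentation", {}))
    feat_cfg = _config_obj(HFUSFeatureConfig, config.get("features", {}))
    clf_cfg = _config_obj(ClassifierConfig, config.get("classifier", {}))
    alpha = float(config.get("stats", {}).get("alpha", 0.05))

    timings: dict[str, float] = {}
    results: dict[str, object] = {}

    def stage(name: str):
        class _Timer:
            def __enter__(self_inner):
                logger.info("stage %s ...", name)
                self_inner.t0 = time.time()

            def __exit__(self_inner, exc_type, exc, tb):
                timings[name] = round(time.time() - self_inner.t0, 2)
                if exc is not None:
                    logger.error(
                        "stage %s failed; artifacts so far are under %s",
                        name, out,
                    )
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}")

        return _Timer()

    with stage("simulate"):
        cohort = generate_cohort(
            n_patients=int(cohort_cfg.get("n_patients", 12)),
            class_counts=tuple(cohort_cfg.get("class_counts", (6, 4, 2))),
            params=params,
            seed=substream(seed, "simulate"),
            with_dermoscopy=bool(cohort_cfg.get("with_dermoscopy", True)),
        )
        akio.write_cohort(cohort, out / "cohort")

    with stage("segment"):
        n_folds = int(pipe_cfg.get("n_folds", 2))
        seg_cfg = dataclasses.replace(
            seg_cfg,
            seed=substream(seed, "segment"),
            input_size=(params.height, params.width),
        )
        models, seg_report = train_segmentation(cohort, n_folds, seg_cfg)
        akio.write_json(seg_report.to_dict(), out / "segmentation_report.json")
        results["segmentation"] = seg_report
        # each lesion is segmented by the model that never saw its patient
        predicted = {}
        (out / "predicted_masks").mkdir(exist_ok=True)
        for les in cohort:
            fold = seg_report.fold_of_patient[les.patient_id]
            masks = segment_layers(models[fold], les.scan)
            predicted[les.lesion_id] = masks
            akio.write_mask(out / "predicted_masks" / f"{les.lesion_id}.png", masks)

    with stage("extract-hfus"):
        use_pred = bool(pipe_cfg.get("use_predicted_masks", True))
        hfus_table = build_hfus_table(
            cohort, predicted if use_pred else None, feat_cfg
        )
        akio.write_feature_table(hfus_table, out / "features_hfus.csv")

    with_derm = any(l.dermoscopy is not None for l in cohort)
    combos = tuple(pipe_cfg.get("combinations", DEFAULT_COMBINATIONS))
    if with_derm:
        with stage("extract-derm"):
            extractor = train_small_cnn_extractor(
                n_per_class=int(pipe_cfg.get("extractor_n_per_class", 60)),
                params=params,
                seed=substream(seed, "extractor"),
                epochs=int(pipe_cfg.get("extractor_epochs", 25)),
            )
            extractor.save(out / "extractor.npz")
            derm_table = build_derm_table(
                cohort, extractor, feat_cfg, seed=substream(seed, "derm")
            )
            akio.write_feature_table(derm_table, out / "features_derm.csv")
            table = merge_feature_tables(hfus_table, derm_table)
    else:
        table = hfus_table
        combos = ("hfus_hand",)  # the only modality available
    akio.write_feature_table(table, out / "features_all.csv")

    with stage("classify"):
        staging: dict[str, StagingReport] = {}
        for combo in combos:
            report = select_and_classify(
                table, combination=combo, config=clf_cfg,
                seed=substream(seed, f"classify-{combo}"),
            )
            staging[combo] = report
            logger.info(
                "combination %s: accuracy %.4f kappa %.4f (%s), %d features",
                combo, report.accuracy, report.kappa, report.kappa_label,
                report.n_features_mode,
            )
        akio.write_json(
            {c: r.to_dict() for c, r in staging.items()},
            out / "staging_reports.json",
        )
        results["staging"] = staging

    with stage("stats"):
        screen = akstats.feature_screen(
            table,
            families=tuple(
                config.get("stats", {}).get(
                    "families", akstats.INTERPRETABLE_FAMILIES
                )
            ),
            alpha=alpha,
        )
        frame = akstats.results_to_frame(screen)
        frame.to_csv(out / "group_stats.csv", index=False)
        results["stats"] = screen

    akio.write_json({"timings_s": timings}, out / "timings.json")
    results["timings"] = timings
    return results
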