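"""Handcrafted HFUS descriptors computed from a scan and its layer masks.

Three families: morphology (per-column thickness statistics,
perimeter-to-area ratio, boundary roughness, SLEB depth), echogenicity
(fractions of low/medium/high echogenic pixels — LEP/MEP/HEP — and mean
intensity, with SLEB values additionally referenced to the dermis), and
texture (histogram, GLCM, LBP, scattering) per layer and for the
combined entry-echo + SLEB region.

Perimeter convention: the perimeter is the number of exposed 4-neighbour
pixel edges (mask pixel to background/image-border incidences), so a
solid ``n x n`` square has perimeter ``4n`` and a single pixel ``4``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from akstage.features import scattering as scat
from akstage.features import texture as tex
from akstage.features.table import make_name
from akstage.types import HFUSScan, LayerMaskSet

THICKNESS_STATS = ("mean", "sd", "min", "median", "q1", "q3")


@dataclass(frozen=True)
class EchogenicityBands:
    """Cut points splitting [0, 255] into low/medium/high echogenicity.

    LEP: intensity < ``low_cut``; MEP: ``low_cut <= v < high_cut``;
    HEP: intensity >= ``high_cut``.  The three bands partition the scale.
    """

    low_cut: int = 30
    high_cut: int = 150

    def __post_init__(self) -> None:
        if not (0 <= self.low_cut < self.high_cut <= 255):
            raise ValueError(
                f"need 0 <= low_cut < high_cut <= 255, got "
                f"({self.low_cut}, {self.high_cut})"
            )


@dataclass
class HFUSFeatureConfig:
    """Tunable parameters of the HFUS feature extractor."""

    bands: EchogenicityBands = field(default_factory=EchogenicityBands)
    glcm_levels: int = tex.DEFAULT_GLCM_LEVELS
    glcm_distance: int = 1
    lbp_radius: int = 1
    lbp_points: int = 8
    scattering_patch: int = scat.DEFAULT_PATCH_SIZE
    scattering_scales: int = scat.DEFAULT_N_SCALES
    scattering_orientations: int = scat.DEFAULT_N_ORIENTATIONS
    include_scattering: bool = True


def thickness_profile(mask: np.ndarray) -> np.ndarray:
    """Per-column mask thickness in pixels.

    For each image column that intersects the mask, the count of mask
    pixels in that column; columns without mask pixels are excluded.
    An empty mask yields an empty array (missing-value result).
    """
    mask = np.asarray(mask, dtype=bool)
    counts = mask.sum(axis=0)
    return counts[counts > 0].astype(float)


def perimeter_edge_count(mask: np.ndarray) -> int:
    """Number of exposed 4-neighbour edges of the mask (see module note)."""
    m = np.asarray(mask, dtype=bool)
    padded = np.pad(m, 1, constant_values=False)
    edges = 0
    for shift, axis in (((1, 0), 0), ((-1, 0), 0), ((0, 1), 1), ((0, -1), 1)):
        neighbour = np.roll(padded, shift, axis=(0, 1))
        edges += int((padded & ~neighbour).sum())
    return edges


def _thickness_stats(mask: np.ndarray) -> dict[str, float]:
    prof = thickness_profile(mask)
    if prof.size == 0:
        return {k: float("nan") for k in THICKNESS_STATS}
    return {
        "mean": float(prof.mean()),
        "sd": float(prof.std()),
        "min": float(prof.min()),
        "median": float(np.median(prof)),
        "q1": float(np.percentile(prof, 25)),
        "q3": float(np.percentile(prof, 75)),
    }


def _boundary_roughness(mask: np.ndarray) -> float:
    """SD of the per-column lower-boundary row index (waviness proxy)."""
    m = np.asarray(mask, dtype=bool)
    cols = np.flatnonzero(m.any(axis=0))
    if cols.size == 0:
        return float("nan")
    depth = np.array([np.flatnonzero(m[:, c])[-1] for c in cols], dtype=float)
    return float(depth.std())


def morphological_features(
    masks: LayerMaskSet, pixel_size_mm: float | None = None
) -> dict[str, float]:
    """Morphology descriptors of the entry echo and SLEB layers.

    Per layer: thickness mean/sd/min/median/Q1/Q3, perimeter-to-area
    ratio, boundary roughness; for the SLEB additionally the depth of
    its lower boundary below the image top (per-column max and mean).
    SLEB features are NaN when the SLEB is absent.  Lengths are in
    pixels; ``*_mm`` variants are added when a pixel size is known.
    """
    if not masks.entry_echo.any():
        raise ValueError("entry-echo mask is empty")
    out: dict[str, float] = {}
    for region, mask in (("entry_echo", masks.entry_echo), ("sleb", masks.sleb)):
        stats = _thickness_stats(mask)
        for stat, v in stats.items():
            out[make_name("hfus", "morphology", region, f"thickness_{stat}")] = v
        area = int(mask.sum())
        pa = perimeter_edge_count(mask) / area if area else float("nan")
        out[make_name("hfus", "morphology", region, "perimeter_to_area")] = pa
        out[make_name("hfus", "morphology", region, "boundary_roughness")] = (
            _boundary_roughness(mask)
        )

    sleb = masks.sleb
    if sleb.any():
        cols = np.flatnonzero(sleb.any(axis=0))
        lower = np.array(
            [np.flatnonzero(sleb[:, c])[-1] + 1 for c in cols], dtype=float
        )
        depth_max, depth_mean = float(lower.max()), float(lower.mean())
    else:
        depth_max = depth_mean = float("nan")
    out[make_name("hfus", "morphology", "sleb", "depth_max")] = depth_max
    out[make_name("hfus", "morphology", "sleb", "depth_mean")] = depth_mean

    if pixel_size_mm is not None:
        for name, v in list(out.items()):
            stat = name.rsplit(".", 1)[-1]
            if stat.startswith(("thickness_", "depth_")):
                out[f"{name}_mm"] = v * pixel_size_mm
    return out


def _band_fractions(
    values: np.ndarray, bands: EchogenicityBands
) -> dict[str, float]:
    n = values.size
    lep = float((values < bands.low_cut).sum() / n)
    hep = float((values >= bands.high_cut).sum() / n)
    mep = 1.0 - lep - hep
    # the three fractions partition the region: nudge MEP by the float
    # rounding residual so ``lep + mep + hep`` sums to exactly 1.0
    for _ in range(3):
        residual = 1.0 - (lep + mep + hep)
        if residual == 0.0:
            break
        mep += residual
    return {"lep": lep, "mep": mep, "hep": hep, "mean": float(values.mean())}


def echogenicity_features(
    scan: HFUSScan,
    masks: LayerMaskSet,
    bands: EchogenicityBands | None = None,
) -> dict[str, float]:
    """LEP/MEP/HEP fractions and mean intensity per layer.

    SLEB values are additionally referenced to the dermis: each SLEB
    statistic is divided by the corresponding dermis statistic
    (``*_over_dermis`` features); a zero dermis denominator yields NaN
    with a warning.  SLEB features are NaN when the SLEB is absent.
    """
    bands = bands or EchogenicityBands()
    img = scan.pixels.astype(float)
    out: dict[str, float] = {}
    per_region: dict[str, dict[str, float]] = {}
    for region, mask in (
        ("entry_echo", masks.entry_echo),
        ("sleb", masks.sleb),
        ("dermis", masks.dermis_reference),
    ):
        if mask.any():
            stats = _band_fractions(img[mask], bands)
        else:
            stats = {k: float("nan") for k in ("lep", "mep", "hep", "mean")}
        per_region[region] = stats
        for stat, v in stats.items():
            out[make_name("hfus", "echogenicity", region, stat)] = v

    if masks.sleb.any() and not masks.dermis_reference.any():
        raise ValueError("dermis reference required when SLEB is present")
    for stat in ("lep", "mep", "hep", "mean"):
        num = per_region["sleb"][stat]
        den = per_region["dermis"][stat]
        if np.isnan(num) or np.isnan(den):
            ratio = float("nan")
        elif den == 0:
            warnings.warn(
                f"dermis {stat} is zero; SLEB/dermis ratio undefined",
                stacklevel=2,
            )
            ratio = float("nan")
        else:
            ratio = num / den
        out[make_name("hfus", "echogenicity", "sleb", f"{stat}_over_dermis")] = ratio
    return out


def _texture_features(
    img: np.ndarray,
    mask: np.ndarray,
    region: str,
    config: HFUSFeatureConfig,
    modality: str = "hfus",
) -> dict[str, float]:
    out: dict[str, float] = {}
    for stat, v in tex.histogram_stats(img, mask).items():
        out[make_name(modality, "histogram", region, stat)] = v
    for stat, v in tex.glcm_stats(
        img, mask, levels=config.glcm_levels, distance=config.glcm_distance
    ).items():
        out[make_name(modality, "glcm", region, stat)] = v
    for stat, v in tex.lbp_stats(
        img, mask, radius=config.lbp_radius, n_points=config.lbp_points
    ).items():
        out[make_name(modality, "lbp", region, stat)] = v
    if config.include_scattering:
        for stat, v in scat.scattering_stats(
            img,
            mask,
            patch_size=config.scattering_patch,
            n_scales=config.scattering_scales,
            n_orientations=config.scattering_orientations,
        ).items():
            out[make_name(modality, "scattering", region, stat)] = v
    return out


def combined_layer_features(
    scan: HFUSScan,
    masks: LayerMaskSet,
    config: HFUSFeatureConfig | None = None,
) -> dict[str, float]:
    """Texture features on the union region entry echo + SLEB."""
    if not masks.entry_echo.any():
        raise ValueError("entry-echo mask is empty")
    config = config or HFUSFeatureConfig()
    return _texture_features(
        scan.pixels.astype(float), masks.combined(), "combined", config
    )


def extract_hfus_features(
    scan: HFUSScan,
    masks: LayerMaskSet,
    config: HFUSFeatureConfig | None = None,
) -> dict[str, float]:
    """The full handcrafted HFUS feature vector of one lesion."""
    config = config or HFUSFeatureConfig()
    img = scan.pixels.astype(float)
    feats = morphological_features(masks, pixel_size_mm=scan.pixel_size_mm)
    feats.update(echogenicity_features(scan, masks, config.bands))
    for region, mask in (("entry_echo", masks.entry_echo), ("sleb", masks.sleb)):
        feats.update(_texture_features(img, mask, region, config))
    feats.update(combined_layer_features(scan, masks, config))
    return feats
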