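"""Seeded phantom generator for HFUS / dermatoscopy lesion pairs.

HFUS phantoms are layered speckle images: an echo-free gel zone, a
bright entry-echo band whose thickness, boundary waviness and speckle
heterogeneity grow with AK stage, an optional hypoechoic subepidermal
band (SLEB) whose echogenicity falls and speckle heterogeneity rises
with stage, and dermis below.  Speckle is multiplicative Rayleigh noise
on per-layer mean intensities with 8-bit clipping — a first-order
B-mode texture proxy, not an acoustic simulation.

Dermatoscopy phantoms are a stage-coloured lesion disk on skin
background (pink pseudonetwork; "strawberry" follicles; bright
white-yellow keratotic scale, so lesion brightness rises with stage)
composited with the artifacts real dermatoscopes leave: a dark
round-corner frame, ruler ticks, and dark/light hairs.  Exact artifact
masks and the clean image are returned as ground truth so the
preprocessing stages can be scored.

Every generator is a pure function of (params, stage, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import binary_dilation, gaussian_filter
from skimage.draw import disk as disk_coords

from akstage.types import (
    Cohort,
    DermoscopyGroundTruth,
    DermoscopyImage,
    HFUSScan,
    LayerMaskSet,
    Lesion,
    VALID_STAGES,
)

logger = logging.getLogger(__name__)

#: the clinical per-stage lesion counts used as default cohort composition
DEFAULT_CLASS_COUNTS = (92, 42, 27)
DEFAULT_N_PATIENTS = 54

_STAGES = (1, 2, 3)


def _stage_map(values) -> dict[int, float]:
    return {s: float(v) for s, v in zip(_STAGES, values)}


@dataclass
class PhantomParams:
    """All tunable knobs of the phantom generators.

    Per-stage values are dicts keyed by stage 1–3.  Defaults encode the
    stage trends the downstream analysis is meant to recover: entry-echo
    thickness, boundary roughness and speckle heterogeneity (hence
    entropy) increase with stage; SLEB echogenicity falls and SLEB
    speckle heterogeneity rises (hence GLCM homogeneity falls) with
    stage.
    """

    # --- HFUS geometry (pixels) ---
    height: int = 256
    width: int = 128
    surface_depth: float = 18.0
    entry_thickness_mean: dict[int, float] = field(
        default_factory=lambda: _stage_map((12.0, 16.0, 22.0))
    )
    entry_thickness_sd: dict[int, float] = field(
        default_factory=lambda: _stage_map((2.5, 2.5, 3.0))
    )
    entry_roughness: dict[int, float] = field(
        default_factory=lambda: _stage_map((1.5, 3.0, 5.0))
    )
    sleb_presence_prob: float = 0.9
    sleb_thickness_mean: float = 30.0
    sleb_thickness_sd: float = 8.0
    dermis_band_px: int = 50

    # --- HFUS intensities (0-255) and multiplicative speckle weights ---
    gel_mean: float = 4.0
    entry_mean: float = 200.0
    sleb_mean: dict[int, float] = field(
        default_factory=lambda: _stage_map((56.0, 46.0, 38.0))
    )
    dermis_mean: float = 120.0
    gel_noise: float = 0.1
    entry_noise: dict[int, float] = field(
        default_factory=lambda: _stage_map((0.22, 0.34, 0.46))
    )
    # the spread is wide because the simultaneous drop in SLEB mean
    # echogenicity shrinks the absolute speckle amplitude: a narrower
    # spread would not yield a monotone stage trend in quantized
    # co-occurrence statistics
    sleb_noise: dict[int, float] = field(
        default_factory=lambda: _stage_map((0.15, 0.40, 0.65))
    )
    dermis_noise: float = 0.30
    speckle_smooth_sigma: float = 0.7

    # --- dermatoscopy ---
    derm_size: int = 512
    derm_skin_rgb: tuple[float, float, float] = (219.0, 178.0, 158.0)
    derm_lesion_rgb: dict[int, tuple[float, float, float]] = field(
        default_factory=lambda: {
            1: (205.0, 132.0, 126.0),  # pink-red pseudonetwork
            2: (198.0, 122.0, 112.0),  # erythematous strawberry pattern
            3: (228.0, 208.0, 162.0),  # white-yellow keratotic scale
        }
    )
    derm_texture_amp: dict[int, float] = field(
        default_factory=lambda: _stage_map((6.0, 13.0, 28.0))
    )
    derm_follicle_count: dict[int, float] = field(
        default_factory=lambda: _stage_map((0, 25, 45))
    )
    derm_hair_count_range: tuple[int, int] = (4, 12)
    derm_hair_width_range: tuple[int, int] = (3, 7)
    derm_light_hair_prob: float = 0.35
    derm_frame: bool = True
    derm_frame_corner_frac: float = 0.35
    derm_ruler: bool = True

    def __post_init__(self) -> None:
        for name, d in (
            ("entry_thickness_mean", self.entry_thickness_mean),
            ("entry_thickness_sd", self.entry_thickness_sd),
            ("entry_roughness", self.entry_roughness),
        ):
            for s in _STAGES:
                if d[s] <= 0:
                    raise ValueError(f"{name}[{s}] must be strictly positive")
        if self.sleb_thickness_mean <= 0 or self.surface_depth <= 0:
            raise ValueError("thicknesses must be strictly positive")
        for v in (self.gel_mean, self.entry_mean, self.dermis_mean, *self.sleb_mean.values()):
            if not 0 <= v <= 255:
                raise ValueError("echogenicity means must lie in [0, 255]")
        if not self.entry_thickness_mean[3] > self.entry_thickness_mean[1]:
            raise ValueError(
                "stage-3 entry-echo thickness mean must exceed stage-1"
            )
        if not all(v < self.dermis_mean for v in self.sleb_mean.values()):
            raise ValueError("SLEB must be less echogenic than dermis")

    def at_full_scale(self) -> "PhantomParams":
        """Clinical-resolution variant (512x224 HFUS, 3024-px dermoscopy)."""
        return replace(self, height=224, width=512, derm_size=3024)


def _check_stage(stage: int) -> None:
    if stage not in VALID_STAGES:
        raise ValueError(f"stage must be in {VALID_STAGES}, got {stage}")


def _smooth_curve(rng: np.random.Generator, n: int, wavelength: float) -> np.ndarray:
    """Zero-mean, unit-amplitude smooth random curve of length ``n``."""
    raw = rng.standard_normal(n)
    sm = gaussian_filter(raw, sigma=wavelength, mode="wrap")
    peak = np.abs(sm).max()
    return sm / peak if peak > 0 else sm


def _speckle(
    rng: np.random.Generator,
    shape: tuple[int, int],
    weight: np.ndarray,
    smooth_sigma: float,
) -> np.ndarray:
    """Multiplicative noise field ``(1 - w) + w * R`` with mean-1 Rayleigh R."""
    r = rng.rayleigh(scale=np.sqrt(2.0 / np.pi), size=shape)
    if smooth_sigma > 0:
        r = gaussian_filter(r, sigma=smooth_sigma, mode="reflect")
    return (1.0 - weight) + weight * r


def generate_hfus_phantom(
    params: PhantomParams, stage: int, seed: int
) -> tuple[HFUSScan, LayerMaskSet]:
    """One layered speckle B-scan phantom plus its ground-truth masks.

    Layer geometry is drawn first (rejection-resampled at most 100 times
    if the stack would exceed the image height), then per-layer mean
    intensities are modulated by multiplicative Rayleigh speckle and
    clipped to 8 bits.  Identical (params, stage, seed) give bit-identical
    output.
    """
    _check_stage(stage)
    rng = np.random.default_rng(seed)
    h, w = params.height, params.width

    top_curve = _smooth_curve(rng, w, wavelength=w / 6)
    rough_curve = _smooth_curve(rng, w, wavelength=w / 10)
    sleb_curve = _smooth_curve(rng, w, wavelength=w / 8)

    for attempt in range(100):
        thickness = rng.normal(
            params.entry_thickness_mean[stage], params.entry_thickness_sd[stage]
        )
        has_sleb = rng.random() < params.sleb_presence_prob
        sleb_thickness = (
            rng.normal(params.sleb_thickness_mean, params.sleb_thickness_sd)
            if has_sleb
            else 0.0
        )
        if thickness < 3 or (has_sleb and sleb_thickness < 4):
            continue
        total = (
            params.surface_depth
            + 3
            + thickness
            + params.entry_roughness[stage]
            + sleb_thickness
            + params.dermis_band_px
        )
        if total < h - 4:
            break
    else:
        raise RuntimeError(
            "could not draw a layer stack fitting the image height "
            "after 100 attempts"
        )

    top = params.surface_depth + 3.0 * top_curve
    lower = top + thickness + params.entry_roughness[stage] * rough_curve
    lower = np.maximum(lower, top + 1.0)
    sleb_lower = lower + sleb_thickness + (2.0 * sleb_curve if has_sleb else 0.0)

    rows = np.arange(h, dtype=float)[:, None]
    entry = (rows >= top[None, :]) & (rows < lower[None, :])
    sleb = (
        (rows >= lower[None, :]) & (rows < sleb_lower[None, :])
        if has_sleb
        else np.zeros((h, w), dtype=bool)
    )
    dermis_ref = (rows >= sleb_lower[None, :]) & (
        rows < sleb_lower[None, :] + params.dermis_band_px
    )
    dermis_all = rows >= sleb_lower[None, :]

    mean_map = np.full((h, w), params.gel_mean)
    mean_map[dermis_all] = params.dermis_mean
    mean_map[sleb] = params.sleb_mean[stage]
    mean_map[entry] = params.entry_mean

    weight = np.full((h, w), params.gel_noise)
    weight[dermis_all] = params.dermis_noise
    weight[sleb] = params.sleb_noise[stage]
    weight[entry] = params.entry_noise[stage]

    noise = _speckle(rng, (h, w), weight, params.speckle_smooth_sigma)
    img = np.clip(np.rint(mean_map * noise), 0, 255).astype(np.uint8)

    scan = HFUSScan(pixels=img)
    masks = LayerMaskSet(entry_echo=entry, sleb=sleb, dermis_reference=dermis_ref)
    return scan, masks


# ---------------------------------------------------------------------------
# dermatoscopy phantoms
# ---------------------------------------------------------------------------


def _rounded_rect_valid(size: int, corner_frac: float) -> np.ndarray:
    """True inside a rounded-corner rectangle covering the image."""
    r = corner_frac * size / 2
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    cy = np.clip(yy, r, size - 1 - r)
    cx = np.clip(xx, r, size - 1 - r)
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


def _draw_hair(
    rng: np.random.Generator, size: int, width_range: tuple[int, int]
) -> np.ndarray:
    """Boolean stroke of one hair: a quadratic Bezier-like curve dilated
    to a random width."""
    pts = rng.uniform(0, size, size=(3, 2))
    # stretch endpoints to opposite borders so hairs span the field
    pts[0] = pts[0] * np.array([1.0, 0.15])
    pts[2] = size - pts[2] * np.array([1.0, 0.15])
    t = np.linspace(0, 1, 4 * size)[:, None]
    curve = ((1 - t) ** 2) * pts[0] + 2 * (1 - t) * t * pts[1] + t**2 * pts[2]
    ij = np.clip(np.rint(curve).astype(int), 0, size - 1)
    stroke = np.zeros((size, size), dtype=bool)
    stroke[ij[:, 0], ij[:, 1]] = True
    halfwidth = int(rng.integers(width_range[0], width_range[1] + 1)) // 2
    if halfwidth > 0:
        yy, xx = np.mgrid[-halfwidth : halfwidth + 1, -halfwidth : halfwidth + 1]
        stroke = binary_dilation(stroke, yy**2 + xx**2 <= halfwidth**2)
    return stroke


def generate_dermoscopy_phantom(
    params: PhantomParams,
    stage: int,
    seed: int,
    n_hairs: int | None = None,
    frame: bool | None = None,
    ruler: bool | None = None,
    lesion: bool = True,
) -> tuple[DermoscopyImage, DermoscopyGroundTruth]:
    """One dermatoscopy phantom plus exact artifact ground truth.

    The composite is clean stage-textured image + round-corner frame +
    hairs/ruler marks; the returned ground truth holds the clean image
    and masks exactly covering each injected artifact.  ``lesion=False``
    renders artifact-free healthy skin (used to train the desk-scale
    AK-vs-non-AK feature extractor).
    """
    _check_stage(stage)
    if n_hairs is None:
        lo, hi = params.derm_hair_count_range
        n_hairs_eff = None
    else:
        if n_hairs < 0:
            raise ValueError("hair count must be non-negative")
        n_hairs_eff = n_hairs
    frame = params.derm_frame if frame is None else frame
    ruler = params.derm_ruler if ruler is None else ruler

    rng = np.random.default_rng(seed)
    s = params.derm_size
    if n_hairs_eff is None:
        n_hairs_eff = int(rng.integers(lo, hi + 1))

    # --- clean skin + lesion ---
    base = np.empty((s, s, 3), dtype=float)
    base[:] = params.derm_skin_rgb
    skin_tex = gaussian_filter(rng.standard_normal((s, s)), sigma=s / 40)
    skin_tex /= max(np.abs(skin_tex).max(), 1e-9)
    base += 8.0 * skin_tex[:, :, None]

    lesion_mask = np.zeros((s, s), dtype=bool)
    if lesion:
        cy, cx = s / 2 + rng.uniform(-s / 16, s / 16, size=2)
        radius = s * rng.uniform(0.28, 0.36)
        yy, xx = np.mgrid[0:s, 0:s].astype(float)
        dist = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
        lesion_mask = dist <= radius
        blend = np.clip((radius - dist) / (0.12 * radius), 0, 1)

        lesion_rgb = np.array(params.derm_lesion_rgb[stage])
        tex = gaussian_filter(rng.standard_normal((s, s)), sigma=s / 80)
        tex /= max(np.abs(tex).max(), 1e-9)
        lesion_img = lesion_rgb[None, None, :] + (
            params.derm_texture_amp[stage] * tex
        )[:, :, None]

        # keratinized follicle dots (strawberry pattern, stages 2-3)
        n_follicles = int(params.derm_follicle_count[stage])
        for _ in range(n_follicles):
            ang = rng.uniform(0, 2 * np.pi)
            rad = radius * np.sqrt(rng.uniform(0, 0.9))
            fy, fx = cy + rad * np.sin(ang), cx + rad * np.cos(ang)
            fr = rng.uniform(0.008, 0.02) * s
            rr, cc = disk_coords((fy, fx), fr, shape=(s, s))
            lesion_img[rr, cc] = (235.0, 220.0, 150.0)  # yellow keratin plug

        base = base * (1 - blend[:, :, None]) + lesion_img * blend[:, :, None]
    clean = np.clip(np.rint(base), 0, 255).astype(np.uint8)

    # --- artifacts ---
    composite = clean.astype(float).copy()
    if frame:
        valid = _rounded_rect_valid(s, params.derm_frame_corner_frac)
        frame_mask = ~valid
        frame_shade = 12.0 + 6.0 * rng.random((s, s))
        composite[frame_mask] = frame_shade[frame_mask, None]
    else:
        frame_mask = np.zeros((s, s), dtype=bool)

    hair_mask = np.zeros((s, s), dtype=bool)
    if ruler:
        # dark tick marks along the right edge, inside the valid region
        x0 = int(s * 0.94)
        for k, y in enumerate(range(int(s * 0.1), int(s * 0.9), max(s // 24, 4))):
            ln = int(s * (0.03 if k % 5 else 0.05))
            tick = np.zeros((s, s), dtype=bool)
            tick[y : y + 2, x0 : x0 + ln] = True
            tick &= ~frame_mask
            hair_mask |= tick
    if hair_mask.any():  # ruler ticks are dark
        composite[hair_mask] = 35.0
    for _ in range(n_hairs_eff):
        stroke = _draw_hair(rng, s, params.derm_hair_width_range) & ~frame_mask
        dark = rng.random() >= params.derm_light_hair_prob
        shade = rng.uniform(20, 55) if dark else rng.uniform(228, 250)
        composite[stroke] = shade
        hair_mask |= stroke
    img = np.clip(np.rint(composite), 0, 255).astype(np.uint8)

    truth = DermoscopyGroundTruth(
        clean_rgb=clean,
        frame_mask=frame_mask,
        hair_mask=hair_mask,
        lesion_mask=lesion_mask,
    )
    return DermoscopyImage(rgb=img), truth


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


def generate_cohort(
    n_patients: int,
    class_counts: tuple[int, int, int] = DEFAULT_CLASS_COUNTS,
    params: PhantomParams | None = None,
    seed: int = 0,
    with_dermoscopy: bool = True,
) -> Cohort:
    """A multi-patient phantom cohort with the given per-stage counts.

    Lesions (``n1`` stage-1, ``n2`` stage-2, ``n3`` stage-3) are dealt to
    patients round-robin, so single patients hold lesions of different
    stages.  Fully seeded: identical arguments give identical cohorts.

    The default per-stage counts are the clinical ones (92/42/27); note
    they sum to 161 while the source dataset's printed total is 162 —
    the discrepancy is logged, not resolved.
    """
    if any(c < 0 for c in class_counts):
        raise ValueError("class counts must be non-negative")
    total = sum(class_counts)
    if not (total >= n_patients >= 1):
        raise ValueError(
            f"need sum(class_counts) >= n_patients >= 1, got {total} lesions "
            f"for {n_patients} patients"
        )
    if tuple(class_counts) == DEFAULT_CLASS_COUNTS:
        logger.info(
            "using clinical per-stage counts 92/42/27 (sum 161; the printed "
            "dataset total is 162 — known discrepancy, not resolved here)"
        )
    params = params or PhantomParams()

    stages = [s for s, c in zip(_STAGES, class_counts) for _ in range(c)]
    rng = np.random.default_rng(seed)
    lesions: list[Lesion] = []
    for i, stage in enumerate(stages):
        patient = f"P{i % n_patients:03d}"
        hfus_seed = int(rng.integers(2**31))
        derm_seed = int(rng.integers(2**31))
        scan, masks = generate_hfus_phantom(params, stage, hfus_seed)
        lesion_id = f"L{i:04d}"
        scan.patient_id, scan.lesion_id = patient, lesion_id
        derm = truth = None
        if with_dermoscopy:
            derm, truth = generate_dermoscopy_phantom(params, stage, derm_seed)
            derm.patient_id, derm.lesion_id = patient, lesion_id
        lesions.append(
            Lesion(
                patient_id=patient,
                lesion_id=lesion_id,
                stage=stage,
                scan=scan,
                dermoscopy=derm,
                masks=masks,
                dermoscopy_truth=truth,
            )
        )
    return Cohort(lesions=lesions)
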