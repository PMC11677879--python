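"""Core in-memory containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: palette indices used when masks are written as indexed PNG
MASK_BACKGROUND = 0
MASK_ENTRY_ECHO = 1
MASK_SLEB = 2
MASK_DERMIS_REF = 3

VALID_STAGES = (1, 2, 3)


@dataclass
class HFUSScan:
    """One grayscale HFUS B-scan (rows = depth, columns = lateral position).

    Parameters
    ----------
    pixels : uint8 array, shape (depth, width)
        8-bit echo intensities.
    patient_id, lesion_id : str
        Identity of the imaged lesion.
    pixel_size_mm : float, optional
        Physical pixel size; when absent all depth/thickness features are
        reported in pixels.
    """

    pixels: np.ndarray
    patient_id: str = ""
    lesion_id: str = ""
    pixel_size_mm: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("HFUS scan must be a 2-D array")
        if self.pixels.shape[0] < 64 or self.pixels.shape[1] < 64:
            raise ValueError(
                f"HFUS scan must be at least 64x64 px, got {self.pixels.shape}"
            )
        if self.pixels.dtype != np.uint8:
            arr = np.asarray(self.pixels)
            if arr.min() < 0 or arr.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            self.pixels = arr.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class LayerMaskSet:
    """Disjoint binary masks of the skin layers in one HFUS scan.

    ``entry_echo`` is the bright superficial band, ``sleb`` the optional
    hypoechoic band beneath it (may be empty), and ``dermis_reference`` a
    dermis band used to normalize SLEB echogenicity.
    """

    entry_echo: np.ndarray
    sleb: np.ndarray
    dermis_reference: np.ndarray
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.entry_echo = np.asarray(self.entry_echo, dtype=bool)
        self.sleb = np.asarray(self.sleb, dtype=bool)
        self.dermis_reference = np.asarray(self.dermis_reference, dtype=bool)
        shapes = {
            self.entry_echo.shape,
            self.sleb.shape,
            self.dermis_reference.shape,
        }
        if len(shapes) != 1:
            raise ValueError(f"mask shapes differ: {shapes}")
        if (
            (self.entry_echo & self.sleb).any()
            or (self.entry_echo & self.dermis_reference).any()
            or (self.sleb & self.dermis_reference).any()
        ):
            raise ValueError("layer masks must be pairwise disjoint")

    @property
    def shape(self) -> tuple[int, int]:
        return self.entry_echo.shape

    def combined(self) -> np.ndarray:
        """Union of entry echo and SLEB (the 'combined layers' region)."""
        return self.entry_echo | self.sleb

    def to_label_image(self) -> np.ndarray:
        """Encode as a single indexed image (palette constants above)."""
        lab = np.zeros(self.shape, dtype=np.uint8)
        lab[self.dermis_reference] = MASK_DERMIS_REF
        lab[self.sleb] = MASK_SLEB
        lab[self.entry_echo] = MASK_ENTRY_ECHO
        return lab

    @classmethod
    def from_label_image(cls, label: np.ndarray) -> "LayerMaskSet":
        label = np.asarray(label)
        return cls(
            entry_echo=label == MASK_ENTRY_ECHO,
            sleb=label == MASK_SLEB,
            dermis_reference=label == MASK_DERMIS_REF,
        )


@dataclass
class DermoscopyImage:
    """One RGB dermatoscopic photograph with an optional valid-region mask.

    The valid-region mask marks pixels that carry skin information, i.e.
    excludes the dark round-corner frame, blurred background and
    measurement marks.
    """

    rgb: np.ndarray
    patient_id: str = ""
    lesion_id: str = ""
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.rgb = np.asarray(self.rgb)
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise ValueError("dermoscopy image must be (H, W, 3)")
        if self.rgb.dtype != np.uint8:
            self.rgb = np.clip(self.rgb, 0, 255).astype(np.uint8)
        if self.valid_mask is not None:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != self.rgb.shape[:2]:
                raise ValueError("valid mask must match image shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.rgb.shape[:2]


@dataclass
class DermoscopyGroundTruth:
    """Generator-side ground truth for the injected dermoscopy artifacts."""

    clean_rgb: np.ndarray
    frame_mask: np.ndarray
    hair_mask: np.ndarray
    lesion_mask: np.ndarray


@dataclass
class Lesion:
    """One lesion: an HFUS/dermatoscopy image pair plus its stage label."""

    patient_id: str
    lesion_id: str
    stage: int
    scan: HFUSScan | None = None
    dermoscopy: DermoscopyImage | None = None
    masks: LayerMaskSet | None = None
    dermoscopy_truth: DermoscopyGroundTruth | None = None

    def __post_init__(self) -> None:
        if self.stage not in VALID_STAGES:
            raise ValueError(f"stage must be in {VALID_STAGES}, got {self.stage}")


@dataclass
class Cohort:
    """A multi-patient collection of staged lesions.

    A patient may hold lesions of different stages; every lesion belongs
    to exactly one patient.
    """

    lesions: list[Lesion] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.lesions)

    def __iter__(self):
        return iter(self.lesions)

    @property
    def patient_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for les in self.lesions:
            seen.setdefault(les.patient_id, None)
        return list(seen)

    def lesions_of(self, patient_id: str) -> list[Lesion]:
        return [l for l in self.lesions if l.patient_id == patient_id]

    def stage_counts(self) -> dict[int, int]:
        counts = {s: 0 for s in VALID_STAGES}
        for les in self.lesions:
            counts[les.stage] += 1
        return counts
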