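"""HFUS skin-layer segmentation with a CFPNet-style encoder/decoder.

The network is U-shaped: a convolutional stem at full resolution, two
encoder stages of contextual-feature-pyramid (CFP) blocks — parallel
dilated convolutions whose outputs are concatenated and fused — with
2x downsampling between them, and a decoder that upsamples and
concatenates the encoder skip connections.  It predicts background,
entry echo and SLEB per pixel (optionally a dermis class); the dermis
reference band is otherwise derived geometrically below the deepest
segmented layer.  Training minimizes cross-entropy plus soft Dice,
cross-validated with patient-grouped folds.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from skimage.measure import label as cc_label

from akstage import nn
from akstage.types import Cohort, HFUSScan, LayerMaskSet

logger = logging.getLogger(__name__)


def dice_index(pred: np.ndarray, ref: np.ndarray) -> float:
    """Dice overlap ``2|A∩B| / (|A|+|B|)`` of two binary masks.

    Two empty masks agree on absence and score 1.0 (logged when it
    happens).  Shapes must match.
    """
    pred = np.asarray(pred, dtype=bool)
    ref = np.asarray(ref, dtype=bool)
    if pred.shape != ref.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {ref.shape}")
    total = int(pred.sum()) + int(ref.sum())
    if total == 0:
        logger.info("dice_index: both masks empty, defined as 1.0")
        return 1.0
    return 2.0 * int((pred & ref).sum()) / total


def crop_scan(
    scan: HFUSScan, target_width: int, center: int | str = "middle"
) -> HFUSScan:
    """Crop a scan laterally to ``target_width`` columns.

    ``center`` is the lateral index of the crop-window centre or
    ``"middle"``; the window is clamped to the image bounds.  Depth is
    unchanged.
    """
    h, w = scan.pixels.shape
    if target_width > w:
        raise ValueError(f"target width {target_width} exceeds scan width {w}")
    c = w // 2 if center == "middle" else int(center)
    start = int(np.clip(c - target_width // 2, 0, w - target_width))
    return HFUSScan(
        pixels=scan.pixels[:, start : start + target_width],
        patient_id=scan.patient_id,
        lesion_id=scan.lesion_id,
        pixel_size_mm=scan.pixel_size_mm,
    )


@dataclass
class SegModelConfig:
    """Architecture and training hyperparameters of the segmenter.

    ``channels`` are the encoder stage widths (stem, /2 stage, /4
    stage); ``dilations`` the dilation rates of the parallel branches in
    each CFP block.  ``n_classes`` is 3 (background / entry echo / SLEB)
    or 4 when the dermis reference is predicted too.
    """

    input_size: tuple[int, int] = (256, 128)
    channels: tuple[int, int, int] = (8, 16, 32)
    dilations: tuple[int, ...] = (1, 2, 4)
    n_classes: int = 3
    epochs: int = 20
    batch_size: int = 4
    learning_rate: float = 2e-3
    loss: str = "ce_dice"
    seed: int = 0
    dermis_band_px: int = 50

    def __post_init__(self) -> None:
        if self.n_classes not in (3, 4):
            raise ValueError("n_classes must be 3 or 4")
        if self.input_size[0] % 4 or self.input_size[1] % 4:
            raise ValueError(
                "input size must be divisible by the total downsampling "
                f"factor 4, got {self.input_size}"
            )


class CFPNetM:
    """The segmentation network (see module docstring)."""

    def __init__(self, config: SegModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        c0, c1, c2 = config.channels
        dil = config.dilations
        self.stem = nn.Conv2D(rng, 1, c0, kernel=3)
        self.stem_relu = nn.ReLU()
        self.pool1 = nn.AvgPool2()
        self.enc1 = nn.CFPBlock(rng, c0, c1, dilations=dil)
        self.pool2 = nn.AvgPool2()
        self.enc2 = nn.CFPBlock(rng, c1, c2, dilations=dil)
        self.up1 = nn.Upsample2()
        # cheap 1x1 projections keep the 3x3 decoder convolutions narrow
        self.dec1_proj = nn.Conv2D(rng, c2 + c1, c1, kernel=1)
        self.dec1 = nn.Conv2D(rng, c1, c1, kernel=3)
        self.dec1_relu = nn.ReLU()
        self.up2 = nn.Upsample2()
        self.dec2_proj = nn.Conv2D(rng, c1 + c0, c0, kernel=1)
        self.dec2 = nn.Conv2D(rng, c0, c0, kernel=3)
        self.dec2_relu = nn.ReLU()
        self.head = nn.Conv2D(rng, c0, config.n_classes, kernel=1)
        self._layers = [
            self.stem, self.enc1, self.enc2,
            self.dec1_proj, self.dec1, self.dec2_proj, self.dec2, self.head,
        ]
        n_params = sum(p.value.size for l in self._layers for p in l.params())
        logger.info("CFPNetM built: %d trainable parameters", n_params)

    def parameters(self) -> list[nn.Param]:
        return [p for l in self._layers for p in l.params()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        s = self.stem_relu.forward(self.stem.forward(x))
        e1 = self.enc1.forward(self.pool1.forward(s))
        e2 = self.enc2.forward(self.pool2.forward(e1))
        cat1 = np.concatenate([self.up1.forward(e2), e1], axis=1)
        d1 = self.dec1_relu.forward(self.dec1.forward(self.dec1_proj.forward(cat1)))
        cat2 = np.concatenate([self.up2.forward(d1), s], axis=1)
        d2 = self.dec2_relu.forward(self.dec2.forward(self.dec2_proj.forward(cat2)))
        return self.head.forward(d2)

    def backward(self, dlogits: np.ndarray) -> None:
        c0, c1, c2 = self.config.channels
        dd2 = self.head.backward(dlogits)
        dcat2 = self.dec2_proj.backward(
            self.dec2.backward(self.dec2_relu.backward(dd2))
        )
        dd1 = self.up2.backward(dcat2[:, :c1])
        ds_skip = dcat2[:, c1:]
        dcat1 = self.dec1_proj.backward(
            self.dec1.backward(self.dec1_relu.backward(dd1))
        )
        de2 = self.up1.backward(dcat1[:, :c2])
        de1_skip = dcat1[:, c2:]
        de1 = self.pool2.backward(self.enc2.backward(de2)) + de1_skip
        ds = self.pool1.backward(self.enc1.backward(de1)) + ds_skip
        self.stem.backward(self.stem_relu.backward(ds))

    # -- persistence -------------------------------------------------
    def state(self) -> list[np.ndarray]:
        return nn.state_dict(self._layers)

    def load_state(self, state: list[np.ndarray]) -> None:
        nn.load_state_dict(self._layers, state)

    def save(self, path: str | Path) -> None:
        arrays = {f"p{i:03d}": a for i, a in enumerate(self.state())}
        np.savez(path, config=json.dumps(asdict(self.config)), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "CFPNetM":
        data = np.load(path, allow_pickle=False)
        cfg_raw = json.loads(str(data["config"]))
        for key in ("input_size", "channels", "dilations"):
            cfg_raw[key] = tuple(cfg_raw[key])
        model = cls(SegModelConfig(**cfg_raw))
        keys = sorted(k for k in data.files if k.startswith("p"))
        model.load_state([data[k] for k in keys])
        return model


def build_model(config: SegModelConfig) -> CFPNetM:
    """Build a segmenter with deterministic initialization from its seed."""
    return CFPNetM(config)


def _to_input(pixels: np.ndarray) -> np.ndarray:
    return (pixels.astype(nn.F32) / 255.0 - 0.5)[None, :, :]


def _to_target(masks: LayerMaskSet, n_classes: int) -> np.ndarray:
    target = np.zeros(masks.shape, dtype=np.int64)
    target[masks.entry_echo] = 1
    target[masks.sleb] = 2
    if n_classes == 4:
        target[masks.dermis_reference] = 3
    return target


def derive_dermis_reference(
    entry: np.ndarray, sleb: np.ndarray, band_px: int
) -> np.ndarray:
    """Dermis band of ``band_px`` rows directly below the lower SLEB
    boundary (or below the entry echo where the SLEB is absent)."""
    h, w = entry.shape
    out = np.zeros((h, w), dtype=bool)
    rows = np.arange(h)
    for c in range(w):
        col = sleb[:, c] if sleb[:, c].any() else entry[:, c]
        nz = np.flatnonzero(col)
        if nz.size == 0:
            continue
        lo = nz[-1] + 1
        out[(rows >= lo) & (rows < lo + band_px), c] = True
    return out


def _largest_component(mask: np.ndarray) -> np.ndarray:
    if not mask.any():
        return mask
    lab = cc_label(mask, connectivity=2)
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    return lab == sizes.argmax()


def segment_layers(model: CFPNetM, scan: HFUSScan) -> LayerMaskSet:
    """Segment one scan into entry-echo / SLEB / dermis-reference masks.

    The argmax class map is post-processed: the largest connected
    component is kept per layer, entry echo takes priority over SLEB
    where they would overlap, and the dermis reference band is derived
    geometrically when the model does not predict it.  An empty
    entry-echo prediction flags the result as degenerate (never silent).
    """
    h, w = scan.pixels.shape
    if (h, w) != tuple(model.config.input_size):
        raise ValueError(
            f"scan size {(h, w)} incompatible with model input "
            f"{model.config.input_size}"
        )
    logits = model.forward(_to_input(scan.pixels)[None])
    classes = logits[0].argmax(axis=0)
    entry = _largest_component(classes == 1)
    sleb = _largest_component(classes == 2) & ~entry
    if model.config.n_classes == 4:
        dermis = _largest_component(classes == 3) & ~entry & ~sleb
    else:
        dermis = derive_dermis_reference(
            entry, sleb, model.config.dermis_band_px
        ) & ~entry & ~sleb
    degenerate = not entry.any()
    if degenerate:
        warnings.warn(
            f"degenerate segmentation: empty entry-echo prediction for "
            f"lesion {scan.lesion_id!r}",
            stacklevel=2,
        )
    return LayerMaskSet(
        entry_echo=entry, sleb=sleb, dermis_reference=dermis, degenerate=degenerate
    )


@dataclass
class SegmentationReport:
    """Per-fold held-out Dice for both layers of interest."""

    fold_of_patient: dict[str, int]
    entry_dice: list[float] = field(default_factory=list)
    sleb_dice: list[float] = field(default_factory=list)

    @property
    def mean_entry_dice(self) -> float:
        return float(np.mean(self.entry_dice))

    @property
    def mean_sleb_dice(self) -> float:
        return float(np.mean(self.sleb_dice))

    def to_dict(self) -> dict:
        return {
            "fold_of_patient": self.fold_of_patient,
            "entry_dice_per_fold": self.entry_dice,
            "sleb_dice_per_fold": self.sleb_dice,
            "mean_entry_dice": self.mean_entry_dice,
            "mean_sleb_dice": self.mean_sleb_dice,
        }


def patient_folds(
    patient_ids: list[str], n_folds: int, seed: int
) -> dict[str, int]:
    """Deterministic patient-grouped fold assignment (round-robin after a
    seeded shuffle)."""
    unique = list(dict.fromkeys(patient_ids))
    if len(unique) < n_folds:
        raise ValueError(
            f"cannot split {len(unique)} patients into {n_folds} folds"
        )
    order = np.random.default_rng(seed).permutation(len(unique))
    return {unique[j]: i % n_folds for i, j in enumerate(order)}


def _train_one(
    model: CFPNetM, scans: list[np.ndarray], targets: list[np.ndarray]
) -> None:
    cfg = model.config
    rng = np.random.default_rng(cfg.seed + 1)
    x = np.stack([_to_input(s) for s in scans])
    y = np.stack(targets)
    opt = nn.Adam(model.parameters(), lr=cfg.learning_rate)
    n = len(scans)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            opt.zero_grad()
            logits = model.forward(x[idx])
            loss, dlogits = nn.ce_dice_loss(logits, y[idx], cfg.n_classes)
            model.backward(dlogits)
            opt.step()
            epoch_loss += loss * len(idx)
        logger.debug("epoch %d loss %.4f", epoch, epoch_loss / n)


def train_segmentation(
    cohort: Cohort,
    n_folds: int,
    config: SegModelConfig,
    pretrained: CFPNetM | None = None,
) -> tuple[list[CFPNetM], SegmentationReport]:
    """Patient-grouped ``n_folds``-fold cross-validated training.

    One model per fold is trained only on its training split (folds
    never share patients — asserted) and evaluated on its held-out
    patients; the report holds per-fold mean Dice for entry echo and
    SLEB.  ``pretrained`` optionally provides initial weights for every
    fold (the phantom pre-training hook; externally trained checkpoints
    load via :meth:`CFPNetM.load`).
    """
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    for les in cohort:
        if les.masks is None or les.scan is None:
            raise ValueError("cohort must carry scans and ground-truth masks")
    folds = patient_folds([l.patient_id for l in cohort], n_folds, config.seed)

    models: list[CFPNetM] = []
    report = SegmentationReport(fold_of_patient=folds)
    for fold in range(n_folds):
        train = [l for l in cohort if folds[l.patient_id] != fold]
        val = [l for l in cohort if folds[l.patient_id] == fold]
        assert not {l.patient_id for l in train} & {l.patient_id for l in val}
        model = build_model(config)
        if pretrained is not None:
            model.load_state(pretrained.state())
        _train_one(
            model,
            [l.scan.pixels for l in train],
            [_to_target(l.masks, config.n_classes) for l in train],
        )
        entry_scores, sleb_scores = [], []
        for les in val:
            pred = segment_layers(model, les.scan)
            entry_scores.append(dice_index(pred.entry_echo, les.masks.entry_echo))
            sleb_scores.append(dice_index(pred.sleb, les.masks.sleb))
        report.entry_dice.append(float(np.mean(entry_scores)))
        report.sleb_dice.append(float(np.mean(sleb_scores)))
        models.append(model)
        logger.info(
            "fold %d: entry Dice %.3f, SLEB Dice %.3f",
            fold, report.entry_dice[-1], report.sleb_dice[-1],
        )
    return models, report
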