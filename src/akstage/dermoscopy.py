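"""Dermatoscopic image preprocessing and feature extraction.

Preprocessing removes what carries no skin information: the dark
round-corner frame and blurred background (intensity adjustment +
thresholding + fuzzy c-means on intensity/sharpness), then dark and
light hairs and ruler marks (a dual-polarity DullRazor: directional
grayscale closing detects dark elongated structures, directional
opening the light ones, an elongation filter drops compact blobs), and
finally neighbourhood-diffusion inpainting smooths the removed pixels.

Features come from two sources: the handcrafted texture families
(histogram, GLCM, LBP, scattering) computed per R, G, B, H, S, V
channel inside the valid region, and the activations of the last fully
connected layer of a pluggable CNN extractor.  The bundled desk-scale
extractor is a small CNN trained in-repo to separate AK from lesion-free
skin phantoms; externally trained checkpoints load through the same
interface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from skimage.color import rgb2gray, rgb2hsv
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import closing, dilation, disk, opening, reconstruction
from skimage.transform import resize

from akstage import nn
from akstage.features import texture as tex
from akstage.features.hfus import HFUSFeatureConfig, _texture_features
from akstage.features.table import make_name
from akstage.types import DermoscopyImage

logger = logging.getLogger(__name__)

CHANNEL_NAMES = ("R", "G", "B", "H", "S", "V")


# ---------------------------------------------------------------------------
# frame / background removal
# ---------------------------------------------------------------------------


def _fuzzy_cmeans(
    data: np.ndarray, n_clusters: int = 2, m: float = 2.0, n_iter: int = 30,
    seed: int = 0,
) -> np.ndarray:
    """Plain fuzzy c-means; returns cluster centres (n_clusters, n_dims)."""
    rng = np.random.default_rng(seed)
    centres = data[rng.choice(len(data), size=n_clusters, replace=False)]
    power = 2.0 / (m - 1.0)
    for _ in range(n_iter):
        d = np.linalg.norm(data[:, None, :] - centres[None], axis=2) + 1e-9
        u = 1.0 / ((d[:, :, None] / d[:, None, :]) ** power).sum(axis=2)
        um = u**m
        centres = (um.T @ data) / um.sum(axis=0)[:, None]
    return centres


def _fcm_membership(data: np.ndarray, centres: np.ndarray, m: float = 2.0):
    d = np.linalg.norm(data[:, None, :] - centres[None], axis=2) + 1e-9
    power = 2.0 / (m - 1.0)
    return 1.0 / ((d[:, :, None] / d[:, None, :]) ** power).sum(axis=2)


def _contrast_stretch(gray: np.ndarray) -> np.ndarray:
    lo, hi = np.percentile(gray, (2, 98))
    if hi <= lo:
        return np.zeros_like(gray)
    return np.clip((gray - lo) / (hi - lo), 0, 1)


def remove_frame_and_background(
    image: DermoscopyImage,
    dark_threshold: float = 0.22,
    blob_radius: int = 5,
    sharpness_ratio: float = 0.35,
    sharpness_floor: float = 0.015,
    seed: int = 0,
) -> np.ndarray:
    """Valid-region mask: drops the dark frame and blurred background.

    Pipeline: percentile contrast stretch -> threshold of dark pixels,
    morphologically opened so thin dark hairs are not mistaken for frame
    -> 2-cluster fuzzy c-means on (intensity, local sharpness), dropping
    the low-sharpness cluster only when it is markedly blurrier than the
    other (ratio below ``sharpness_ratio``) AND essentially structureless
    (mean sharpness below ``sharpness_floor``), so sharp frameless images
    survive intact -> largest connected component containing the image
    centre, holes filled.  Raises if nothing remains.
    """
    gray = rgb2gray(image.rgb)
    stretched = _contrast_stretch(gray)

    # frame pixels are dark both relative to the stretched dynamic range
    # and in absolute terms (lesion borders may be relatively dark but
    # are never near-black)
    dark = (stretched < dark_threshold) & (gray < 0.25)
    frame = opening(dark, disk(blob_radius))
    valid = ~frame

    # sharpness: local deviation from a smoothed copy
    smooth = ndi.gaussian_filter(stretched, 4.0)
    sharpness = ndi.gaussian_filter(np.abs(stretched - smooth), 8.0)
    feats = np.stack([stretched[valid], sharpness[valid]], axis=1)
    if len(feats) > 4000:
        step = len(feats) // 4000
        sample = feats[::step]
    else:
        sample = feats
    if len(sample) >= 4:
        centres = _fuzzy_cmeans(sample, seed=seed)
        blur_c = int(np.argmin(centres[:, 1]))
        if (
            centres[blur_c, 1] < sharpness_ratio * centres[1 - blur_c, 1]
            and centres[blur_c, 1] < sharpness_floor
        ):
            u = _fcm_membership(feats, centres)
            drop = u[:, blur_c] > 0.5
            vv = valid.copy()
            vv[valid] = ~drop
            valid = vv

    valid = ndi.binary_fill_holes(valid)
    if not valid.any():
        raise ValueError("no valid region after frame/background removal")
    lab = cc_label(valid)
    h, w = valid.shape
    centre_label = lab[h // 2, w // 2]
    if centre_label == 0:
        sizes = np.bincount(lab.ravel())
        sizes[0] = 0
        centre_label = sizes.argmax()
    valid = lab == centre_label
    if not valid.any():
        raise ValueError("no valid region after frame/background removal")
    return valid


# ---------------------------------------------------------------------------
# hair / ruler removal (dual-polarity DullRazor)
# ---------------------------------------------------------------------------


def _line_footprints(length: int) -> list[np.ndarray]:
    """Linear structuring elements at 0, 45, 90 and 135 degrees."""
    horiz = np.ones((1, length), dtype=bool)
    vert = np.ones((length, 1), dtype=bool)
    diag = np.eye(length, dtype=bool)
    return [horiz, diag, vert, diag[::-1]]


def diffusion_inpaint(
    rgb: np.ndarray, mask: np.ndarray, n_iter: int = 60
) -> np.ndarray:
    """Neighbourhood-diffusion inpainting of masked pixels (per channel).

    Masked pixels are relaxed toward the mean of their 3x3
    neighbourhood, keeping unmasked pixels fixed — a Jacobi solve of the
    Laplace equation with the surrounding image as boundary condition.
    Converges quickly for the thin structures hairs leave behind.
    """
    mask = np.asarray(mask, dtype=bool)
    out = rgb.astype(float).copy()
    if not mask.any():
        return rgb.copy()
    # initialize holes from the nearest valid pixel
    _, (iy, ix) = ndi.distance_transform_edt(mask, return_indices=True)
    out[mask] = out[iy[mask], ix[mask]]
    for _ in range(n_iter):
        blurred = ndi.uniform_filter(out, size=(3, 3, 1))
        out[mask] = blurred[mask]
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def remove_hairs(
    image: DermoscopyImage,
    se_length: int = 15,
    diff_threshold: float = 10.0,
    min_elongation: float = 4.0,
    max_hair_halfwidth: float = 5.0,
    dilate_px: int = 2,
) -> tuple[np.ndarray, DermoscopyImage]:
    """Detect dark/light hairs and ruler marks; return mask + inpainted image.

    Dark structures respond to directional grayscale closing, light ones
    to opening; a pixel is a candidate where the strongest directional
    response exceeds ``diff_threshold`` intensity units.  A candidate
    component is kept when it is elongated (major/minor axis ratio at
    least ``min_elongation``) — single hairs and ruler ticks — or when
    it is long but everywhere thin (maximum inscribed radius at most
    ``max_hair_halfwidth``), which catches networks of crossing hairs
    whose merged component is not elongated; compact structures such as
    keratotic follicles fail both tests.  The union mask, slightly
    dilated to cover anti-aliased hair borders, is diffusion-inpainted.
    A hairless image returns an empty mask and the untouched image.
    """
    gray = rgb2gray(image.rgb) * 255.0
    valid = (
        image.valid_mask
        if image.valid_mask is not None
        else np.ones(gray.shape, dtype=bool)
    )

    dark_resp = np.zeros_like(gray)
    light_resp = np.zeros_like(gray)
    for fp in _line_footprints(se_length):
        np.maximum(dark_resp, closing(gray, fp) - gray, out=dark_resp)
        np.maximum(light_resp, gray - opening(gray, fp), out=light_resp)
    candidates = ((dark_resp > diff_threshold) | (light_resp > diff_threshold)) & valid

    # directional closing also fills the space between nearby hairs, so
    # the raw candidate blob is thicker than the hairs themselves: strip
    # its thick cores, filter the remaining thin segments by shape, then
    # grow the accepted segments back inside the candidate mask
    cores = opening(candidates, disk(int(max_hair_halfwidth) + 1))
    thin = candidates & ~cores
    kept = np.zeros_like(candidates)
    lab = cc_label(thin, connectivity=2)
    for region in regionprops(lab):
        if region.area < 2 * se_length:
            continue
        elong = region.axis_major_length / max(region.axis_minor_length, 1.0)
        if elong >= min_elongation or region.axis_major_length >= 2 * se_length:
            kept[lab == region.label] = True
    hair_mask = reconstruction(kept, candidates, method="dilation").astype(bool)
    if dilate_px > 0 and hair_mask.any():
        hair_mask = dilation(hair_mask, disk(dilate_px)) & valid

    if not hair_mask.any():
        cleaned = image.rgb.copy()
    else:
        cleaned = diffusion_inpaint(image.rgb, hair_mask)
    return hair_mask, DermoscopyImage(
        rgb=cleaned,
        patient_id=image.patient_id,
        lesion_id=image.lesion_id,
        valid_mask=image.valid_mask,
    )


def preprocess(image: DermoscopyImage, seed: int = 0) -> tuple[DermoscopyImage, dict]:
    """Frame removal followed by hair removal; returns the cleaned image
    (valid mask attached) and the intermediate masks."""
    valid = remove_frame_and_background(image, seed=seed)
    with_mask = DermoscopyImage(
        rgb=image.rgb, patient_id=image.patient_id,
        lesion_id=image.lesion_id, valid_mask=valid,
    )
    hair_mask, cleaned = remove_hairs(with_mask)
    return cleaned, {"valid_mask": valid, "hair_mask": hair_mask}


# ---------------------------------------------------------------------------
# channels + handcrafted features
# ---------------------------------------------------------------------------


def decompose_channels(image: DermoscopyImage) -> dict[str, np.ndarray]:
    """R, G, B plus H, S, V channels, each scaled to the 8-bit range.

    Hue is circular and mapped linearly from [0, 1) to [0, 255]."""
    rgb = image.rgb
    hsv = rgb2hsv(rgb)
    return {
        "R": rgb[:, :, 0].astype(float),
        "G": rgb[:, :, 1].astype(float),
        "B": rgb[:, :, 2].astype(float),
        "H": hsv[:, :, 0] * 255.0,
        "S": hsv[:, :, 1] * 255.0,
        "V": hsv[:, :, 2] * 255.0,
    }


def dermoscopy_handcrafted_features(
    channels: dict[str, np.ndarray],
    valid_mask: np.ndarray,
    config: HFUSFeatureConfig | None = None,
) -> dict[str, float]:
    """Texture families per channel, restricted to the valid region."""
    if not valid_mask.any():
        raise ValueError("valid mask is empty")
    config = config or HFUSFeatureConfig()
    out: dict[str, float] = {}
    for name, channel in channels.items():
        out.update(
            _texture_features(channel, valid_mask, name, config, modality="derm")
        )
    return out


# ---------------------------------------------------------------------------
# CNN feature extraction
# ---------------------------------------------------------------------------


@dataclass
class ExtractorInfo:
    name: str
    input_size: int
    output_dim: int
    provenance: str


class SmallCNNExtractor:
    """Desk-scale CNN feature extractor (AK vs lesion-free phantom skin).

    Three convolution stages, global average pooling and two fully
    connected layers; :meth:`extract` returns the activations of the
    last fully connected hidden layer.  Deterministic at inference:
    the same image always maps to the same vector.
    """

    def __init__(self, input_size: int = 32, hidden_dim: int = 24, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.info = ExtractorInfo(
            name="small-cnn-phantom",
            input_size=input_size,
            output_dim=hidden_dim,
            provenance="trained in-repo on synthetic AK / lesion-free phantoms",
        )
        self.conv1 = nn.Conv2D(rng, 3, 8, kernel=3)
        self.relu1 = nn.ReLU()
        self.pool1 = nn.AvgPool2()
        self.conv2 = nn.Conv2D(rng, 8, 16, kernel=3)
        self.relu2 = nn.ReLU()
        self.pool2 = nn.AvgPool2()
        self.conv3 = nn.Conv2D(rng, 16, 32, kernel=3)
        self.relu3 = nn.ReLU()
        self.fc1 = nn.Dense(rng, 32, hidden_dim)
        self.fc_relu = nn.ReLU()
        self.fc2 = nn.Dense(rng, hidden_dim, 2)
        self._layers = [self.conv1, self.conv2, self.conv3, self.fc1, self.fc2]

    def parameters(self) -> list[nn.Param]:
        return [p for l in self._layers for p in l.params()]

    def _features_and_logits(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        h = self.pool1.forward(self.relu1.forward(self.conv1.forward(x)))
        h = self.pool2.forward(self.relu2.forward(self.conv2.forward(h)))
        h = self.relu3.forward(self.conv3.forward(h))
        self._gap_shape = h.shape
        pooled = h.mean(axis=(2, 3))
        feats = self.fc_relu.forward(self.fc1.forward(pooled))
        return feats, self.fc2.forward(feats)

    def _backward(self, dlogits: np.ndarray) -> None:
        dfeats = self.fc2.backward(dlogits)
        dpooled = self.fc1.backward(self.fc_relu.backward(dfeats))
        n, c, h, w = self._gap_shape
        dh = np.broadcast_to(
            dpooled[:, :, None, None] / (h * w), (n, c, h, w)
        ).astype(nn.F32)
        dh = self.conv3.backward(self.relu3.backward(dh))
        dh = self.conv2.backward(self.relu2.backward(self.pool2.backward(dh)))
        self.conv1.backward(self.relu1.backward(self.pool1.backward(dh)))

    def prepare(self, image: DermoscopyImage) -> np.ndarray:
        s = self.info.input_size
        small = resize(
            image.rgb.astype(float) / 255.0, (s, s, 3), anti_aliasing=True
        )
        return (small.transpose(2, 0, 1) - 0.5).astype(nn.F32)

    def extract(self, image: DermoscopyImage) -> np.ndarray:
        feats, _ = self._features_and_logits(self.prepare(image)[None])
        return feats[0].astype(float)

    def classify(self, image: DermoscopyImage) -> int:
        _, logits = self._features_and_logits(self.prepare(image)[None])
        return int(logits[0].argmax())

    def save(self, path: str | Path) -> None:
        arrays = {
            f"p{i:03d}": p.value
            for i, p in enumerate(self.parameters())
        }
        np.savez(
            path,
            input_size=self.info.input_size,
            hidden_dim=self.info.output_dim,
            **arrays,
        )

    @classmethod
    def load(cls, path: str | Path) -> "SmallCNNExtractor":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(
                f"extractor checkpoint not found: {path}. Train one with "
                "akstage.dermoscopy.train_small_cnn_extractor and save() it, "
                "or point the config at an existing .npz checkpoint."
            )
        data = np.load(path, allow_pickle=False)
        model = cls(
            input_size=int(data["input_size"]), hidden_dim=int(data["hidden_dim"])
        )
        keys = sorted(k for k in data.files if k.startswith("p"))
        params = model.parameters()
        if len(keys) != len(params):
            raise ValueError("checkpoint does not match extractor architecture")
        for k, p in zip(keys, params):
            p.value[...] = data[k].astype(nn.F32)
        return model


def train_small_cnn_extractor(
    n_per_class: int = 100,
    params=None,
    seed: int = 0,
    epochs: int = 30,
    batch_size: int = 16,
    learning_rate: float = 2e-3,
) -> SmallCNNExtractor:
    """Train the desk-scale extractor on AK vs lesion-free phantoms.

    Phantoms are rendered small (the extractor ingests 32x32 anyway) and
    without artifacts — the extractor sees cleaned images in the
    pipeline.  Stages are cycled 1-2-3 for the AK class.
    """
    from dataclasses import replace

    from akstage.synthetic import PhantomParams, generate_dermoscopy_phantom

    params = params or PhantomParams()
    params = replace(params, derm_size=96)
    rng = np.random.default_rng(seed)
    model = SmallCNNExtractor(seed=seed)

    images, labels = [], []
    for i in range(n_per_class):
        stage = (i % 3) + 1
        img, _ = generate_dermoscopy_phantom(
            params, stage, seed=int(rng.integers(2**31)),
            n_hairs=0, frame=False, ruler=False,
        )
        images.append(model.prepare(img))
        labels.append(1)
        img0, _ = generate_dermoscopy_phantom(
            params, stage, seed=int(rng.integers(2**31)),
            n_hairs=0, frame=False, ruler=False, lesion=False,
        )
        images.append(model.prepare(img0))
        labels.append(0)
    x = np.stack(images)
    y = np.array(labels)

    opt = nn.Adam(model.parameters(), lr=learning_rate)
    n = len(y)
    for epoch in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            opt.zero_grad()
            _, logits = model._features_and_logits(x[idx])
            loss, dlogits = nn.ce_loss_classifier(logits, y[idx])
            model._backward(dlogits)
            opt.step()
    return model


def cnn_features(
    image: DermoscopyImage, extractor: SmallCNNExtractor
) -> dict[str, float]:
    """Named activations of the extractor's last fully connected layer."""
    vec = extractor.extract(image)
    if vec.shape[0] != extractor.info.output_dim:
        raise RuntimeError("extractor returned unexpected dimensionality")
    return {
        make_name("derm", "nn", "image", f"f{i:03d}"): float(v)
        for i, v in enumerate(vec)
    }


def extract_derm_features(
    image: DermoscopyImage,
    extractor: SmallCNNExtractor | None = None,
    config: HFUSFeatureConfig | None = None,
    seed: int = 0,
) -> dict[str, float]:
    """Preprocess one dermatoscopy image and extract all its features."""
    cleaned, masks = preprocess(image, seed=seed)
    channels = decompose_channels(cleaned)
    feats = dermoscopy_handcrafted_features(channels, masks["valid_mask"], config)
    if extractor is not None:
        feats.update(cnn_features(cleaned, extractor))
    return feats
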