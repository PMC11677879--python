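"""Region-restricted texture primitives: histogram, GLCM and LBP statistics.

All operations take a grayscale image and a binary region mask and
depend only on pixels inside the mask: GLCM pairs are counted only when
both pixels lie in the mask, and LBP codes are histogrammed only at
pixels whose full circular neighbourhood lies inside the mask.  A region
too small to support an operation yields NaN statistics rather than an
error, so that SLEB-free lesions carry explicit missing values.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from skimage.feature import graycomatrix, local_binary_pattern
from skimage.morphology import erosion, footprint_rectangle

HISTOGRAM_STATS = ("mean", "sd", "skewness", "kurtosis", "entropy")
GLCM_STATS = ("contrast", "homogeneity", "correlation", "energy")

#: default GLCM setup: 32 levels, distance 1, four offsets averaged
DEFAULT_GLCM_LEVELS = 32
DEFAULT_GLCM_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)


def _masked_values(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape:
        raise ValueError("image and mask shapes differ")
    return image[mask].astype(float)


def histogram_stats(
    image: np.ndarray,
    mask: np.ndarray,
    n_bins: int = 256,
    value_range: tuple[float, float] = (0, 256),
) -> dict[str, float]:
    """First-order statistics of in-mask intensities.

    Entropy is Shannon entropy in bits over an ``n_bins`` histogram of
    the 8-bit range; skewness and kurtosis are the usual standardized
    moments (Fisher kurtosis, 0 for a normal sample).  A constant region
    has entropy 0 and undefined (NaN) skewness/kurtosis.
    """
    vals = _masked_values(image, mask)
    if vals.size == 0:
        return {k: float("nan") for k in HISTOGRAM_STATS}
    counts, _ = np.histogram(vals, bins=n_bins, range=value_range)
    p = counts[counts > 0] / vals.size
    entropy = float(-(p * np.log2(p)).sum())
    sd = float(np.std(vals))
    if sd == 0:
        skew = kurt = float("nan")
    else:
        skew = float(sps.skew(vals))
        kurt = float(sps.kurtosis(vals))
    return {
        "mean": float(np.mean(vals)),
        "sd": sd,
        "skewness": skew,
        "kurtosis": kurt,
        "entropy": entropy,
    }


def _quantize(
    image: np.ndarray,
    mask: np.ndarray,
    levels: int,
    value_range: tuple[float, float],
) -> np.ndarray:
    """Quantize in-mask pixels to ``0..levels-1``; out-of-mask pixels get
    the sentinel level ``levels`` so co-occurrence with them can be
    discarded."""
    lo, hi = value_range
    scaled = (np.asarray(image, dtype=float) - lo) * levels / (hi - lo)
    q = np.clip(np.floor(scaled), 0, levels - 1).astype(np.uint16)
    q[~np.asarray(mask, dtype=bool)] = levels
    return q


def glcm_stats(
    image: np.ndarray,
    mask: np.ndarray,
    levels: int = DEFAULT_GLCM_LEVELS,
    distance: int = 1,
    angles: tuple[float, ...] = DEFAULT_GLCM_ANGLES,
    value_range: tuple[float, float] = (0, 256),
) -> dict[str, float]:
    """GLCM contrast, homogeneity, correlation and energy within a mask.

    The co-occurrence matrix is symmetric and normalized, built only
    from pixel pairs that both lie inside the mask, with intensities
    quantized to ``levels`` gray levels over ``value_range``.  Each
    statistic is computed per offset and averaged over the offsets that
    produced at least one valid pair; if no offset does, all statistics
    are NaN.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != np.asarray(image).shape:
        raise ValueError("image and mask shapes differ")
    nan = {k: float("nan") for k in GLCM_STATS}
    if mask.sum() < 2:
        return nan

    q = _quantize(image, mask, levels, value_range)
    # sentinel row/column collects pairs touching out-of-mask pixels
    glcm = graycomatrix(
        q,
        distances=[distance],
        angles=list(angles),
        levels=levels + 1,
        symmetric=True,
        normed=False,
    ).astype(float)
    glcm = glcm[:levels, :levels, 0, :]  # drop sentinel, one distance

    i = np.arange(levels, dtype=float)
    diff_sq = (i[:, None] - i[None, :]) ** 2
    per_angle: dict[str, list[float]] = {k: [] for k in GLCM_STATS}
    for a in range(glcm.shape[-1]):
        total = glcm[:, :, a].sum()
        if total == 0:
            continue
        p = glcm[:, :, a] / total
        contrast = float((p * diff_sq).sum())
        homogeneity = float((p / (1.0 + diff_sq)).sum())
        energy = float(np.sqrt((p**2).sum()))
        pi = p.sum(axis=1)
        pj = p.sum(axis=0)
        mu_i = float((i * pi).sum())
        mu_j = float((i * pj).sum())
        var_i = float(((i - mu_i) ** 2 * pi).sum())
        var_j = float(((i - mu_j) ** 2 * pj).sum())
        if var_i <= 1e-15 or var_j <= 1e-15:
            correlation = 1.0  # constant region: perfectly correlated
        else:
            cov = float(((i[:, None] - mu_i) * (i[None, :] - mu_j) * p).sum())
            correlation = cov / np.sqrt(var_i * var_j)
        per_angle["contrast"].append(contrast)
        per_angle["homogeneity"].append(homogeneity)
        per_angle["correlation"].append(correlation)
        per_angle["energy"].append(energy)

    if not per_angle["contrast"]:
        return nan
    return {k: float(np.mean(v)) for k, v in per_angle.items()}


def lbp_stats(
    image: np.ndarray,
    mask: np.ndarray,
    radius: int = 1,
    n_points: int = 8,
) -> dict[str, float]:
    """Normalized histogram of uniform LBP codes within a mask.

    Codes are computed with the rotation-robust 'uniform' mapping
    (``n_points + 2`` bins) and histogrammed only at pixels whose full
    circular neighbourhood lies inside the mask (mask eroded by the
    neighbourhood radius).  No interior pixel at the given radius yields
    NaN for every bin.
    """
    mask = np.asarray(mask, dtype=bool)
    image = np.asarray(image, dtype=float)
    if mask.shape != image.shape:
        raise ValueError("image and mask shapes differ")
    n_bins = n_points + 2
    names = [f"u{b:02d}" for b in range(n_bins)]

    margin = int(np.ceil(radius))
    side = 2 * margin + 1
    # pad with background first: the full neighbourhood must lie inside
    # both the mask and the image
    padded = np.pad(mask, margin, constant_values=False)
    interior = erosion(padded, footprint_rectangle((side, side)))[
        margin:-margin, margin:-margin
    ]
    if not interior.any():
        return {k: float("nan") for k in names}

    filled = image.copy()
    filled[~mask] = image[mask].mean()  # neutral fill, unused by interior codes
    # intensities are 8-bit; integer codes avoid float-comparison artifacts
    filled = np.rint(filled).astype(np.int64)
    codes = local_binary_pattern(filled, P=n_points, R=radius, method="uniform")
    counts, _ = np.histogram(
        codes[interior], bins=n_bins, range=(0, n_bins)
    )
    hist = counts / counts.sum()
    return {name: float(h) for name, h in zip(names, hist)}


def lbp_bin_names(n_points: int = 8) -> list[str]:
    return [f"u{b:02d}" for b in range(n_points + 2)]
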