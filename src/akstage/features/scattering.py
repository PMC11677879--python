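"""Translation-stable scattering-wavelet texture coefficients.

A compact 2-D scattering transform: the image patch is convolved with a
Morlet filter bank (``n_scales`` dyadic scales x ``n_orientations``
orientations), the complex modulus is taken, and the cascade is repeated
once more for scale-increasing paths.  Spatially averaged outputs give
one coefficient per path:

* order 0 — patch mean (1 path),
* order 1 — ``mean(|x * psi_{j,t}|)`` (``n_scales * n_orientations``),
* order 2 — ``mean(||x * psi_{j1,t1}| * psi_{j2,t2}|)`` for ``j1 < j2``.

Global averaging makes the coefficients stable to small translations
of the texture.  The region of interest is cut out by its mask bounding
box, out-of-mask pixels are replaced by the in-mask mean, and the patch
is resampled to a fixed dyadic size so coefficients are comparable
across lesions of different extent.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from skimage.transform import resize

DEFAULT_PATCH_SIZE = 64
DEFAULT_N_SCALES = 2
DEFAULT_N_ORIENTATIONS = 6
MIN_BBOX_SIDE = 8


@lru_cache(maxsize=8)
def _filter_bank(
    size: int, n_scales: int, n_orientations: int
) -> np.ndarray:
    """Morlet filters in the Fourier domain, shape (n_filters, size, size).

    Each filter is a Gaussian envelope centred at a scale-dependent
    frequency ``xi_j = 3*pi/4 / 2**j`` along its orientation, minus a
    DC-centred Gaussian scaled to give an exactly zero-mean wavelet.
    """
    freqs = 2 * np.pi * np.fft.fftfreq(size)
    wy = freqs[:, None]
    wx = freqs[None, :]
    filters = []
    sigma0 = 0.8  # envelope width at scale 0, in pixels
    for j in range(n_scales):
        sigma = sigma0 * 2**j
        xi = 3 * np.pi / 4 / 2**j
        for t in range(n_orientations):
            theta = np.pi * t / n_orientations
            cy, cx = xi * np.sin(theta), xi * np.cos(theta)
            gab = np.exp(-(sigma**2) * ((wy - cy) ** 2 + (wx - cx) ** 2) / 2)
            gauss = np.exp(-(sigma**2) * (wy**2 + wx**2) / 2)
            beta = gab[0, 0] / gauss[0, 0]  # zero response at DC
            filters.append(gab - beta * gauss)
    return np.stack(filters)


def scattering_path_names(
    n_scales: int = DEFAULT_N_SCALES,
    n_orientations: int = DEFAULT_N_ORIENTATIONS,
) -> list[str]:
    """Stable names for every scattering path, in output order."""
    names = ["order0"]
    for j in range(n_scales):
        for t in range(n_orientations):
            names.append(f"o1_j{j}t{t}")
    for j1 in range(n_scales):
        for j2 in range(j1 + 1, n_scales):
            for t1 in range(n_orientations):
                for t2 in range(n_orientations):
                    names.append(f"o2_j{j1}t{t1}_j{j2}t{t2}")
    return names


def _wavelet_moduli(patch_f: np.ndarray, filters: np.ndarray) -> np.ndarray:
    """|patch * psi| for every filter; input is the patch's 2-D FFT."""
    prod = patch_f[None, :, :] * filters
    return np.abs(np.fft.ifft2(prod, axes=(-2, -1)))


def scattering_stats(
    image: np.ndarray,
    mask: np.ndarray,
    patch_size: int = DEFAULT_PATCH_SIZE,
    n_scales: int = DEFAULT_N_SCALES,
    n_orientations: int = DEFAULT_N_ORIENTATIONS,
) -> dict[str, float]:
    """Spatially averaged scattering coefficients of a masked region.

    Returns one value per path (see :func:`scattering_path_names`);
    all values are NaN when the mask bounding box is smaller than
    ``MIN_BBOX_SIDE`` in either direction.  Intensities are scaled to
    [0, 1] so coefficients are device-gain comparable.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape:
        raise ValueError("image and mask shapes differ")
    names = scattering_path_names(n_scales, n_orientations)
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0 or cols.size == 0:
        return {k: float("nan") for k in names}
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    if (r1 - r0) < MIN_BBOX_SIDE or (c1 - c0) < MIN_BBOX_SIDE:
        return {k: float("nan") for k in names}

    patch = image[r0:r1, c0:c1].copy() / 255.0
    sub = mask[r0:r1, c0:c1]
    patch[~sub] = patch[sub].mean()
    patch = resize(
        patch, (patch_size, patch_size), order=1, anti_aliasing=True
    )

    filters = _filter_bank(patch_size, n_scales, n_orientations)
    per_scale = n_orientations

    values = [float(patch.mean())]
    u1 = _wavelet_moduli(np.fft.fft2(patch), filters)
    values.extend(float(v) for v in u1.mean(axis=(-2, -1)))
    for j1 in range(n_scales):
        for j2 in range(j1 + 1, n_scales):
            band2 = filters[j2 * per_scale : (j2 + 1) * per_scale]
            for t1 in range(n_orientations):
                u1f = np.fft.fft2(u1[j1 * per_scale + t1])
                u2 = _wavelet_moduli(u1f, band2)
                values.extend(float(v) for v in u2.mean(axis=(-2, -1)))
    return dict(zip(names, values))
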