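"""Independent brute-force oracles used by the texture and stats tests.

Everything here is deliberately naive — explicit pair enumeration,
per-pixel neighbourhood sampling, textbook rank formulas — and shares no
code with the package implementation it checks.
"""

import numpy as np

GLCM_OFFSETS = {
    0.0: (0, 1),
    np.pi / 4: (1, 1),
    np.pi / 2: (1, 0),
    3 * np.pi / 4: (1, -1),
}


def glcm_oracle(levels_img, mask, n_levels, offset):
    """GLCM statistics by explicit enumeration of in-mask pixel pairs.

    ``levels_img`` already holds integer gray levels; ``offset`` is a
    (dy, dx) displacement.  The symmetric normalized co-occurrence
    distribution is accumulated pair by pair.  Returns None when no
    valid pair exists.
    """
    h, w = levels_img.shape
    dy, dx = offset
    pairs = []
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dy, c + dx
            if 0 <= r2 < h and 0 <= c2 < w and mask[r, c] and mask[r2, c2]:
                pairs.append((levels_img[r, c], levels_img[r2, c2]))
    if not pairs:
        return None
    p = np.zeros((n_levels, n_levels))
    for a, b in pairs:
        p[a, b] += 1
        p[b, a] += 1  # symmetric
    p /= p.sum()
    i = np.arange(n_levels)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    contrast = float((p * (ii - jj) ** 2).sum())
    homogeneity = float((p / (1 + (ii - jj) ** 2)).sum())
    energy = float(np.sqrt((p**2).sum()))
    pi = p.sum(axis=1)
    mu_i = float((i * pi).sum())
    pj = p.sum(axis=0)
    mu_j = float((i * pj).sum())
    var_i = float(((i - mu_i) ** 2 * pi).sum())
    var_j = float(((i - mu_j) ** 2 * pj).sum())
    if var_i <= 1e-15 or var_j <= 1e-15:
        correlation = 1.0
    else:
        correlation = float(
            (((ii - mu_i) * (jj - mu_j) * p).sum()) / np.sqrt(var_i * var_j)
        )
    return {
        "contrast": contrast,
        "homogeneity": homogeneity,
        "correlation": correlation,
        "energy": energy,
    }


def lbp_oracle_histogram(img, mask, n_points=8, radius=1.0):
    """Uniform-LBP histogram by direct per-pixel neighbourhood sampling.

    Bilinear sampling at ``(r - R sin a, c + R cos a)`` (interpolated
    value rounded to 8 decimals), threshold ``neighbour >= centre``,
    uniform mapping: number of set bits when the circular bit string has
    at most two 0-1 transitions, else ``n_points + 1``.  Histogrammed
    over pixels whose full neighbourhood lies inside the mask.
    """
    h, w = img.shape
    margin = int(np.ceil(radius))
    counts = np.zeros(n_points + 2)
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            block = mask[
                max(r - margin, 0) : r + margin + 1,
                max(c - margin, 0) : c + margin + 1,
            ]
            if (
                r - margin < 0 or c - margin < 0
                or r + margin >= h or c + margin >= w
                or not block.all()
            ):
                continue
            bits = []
            for k in range(n_points):
                ang = 2 * np.pi * k / n_points
                rr = r - radius * np.sin(ang)
                cc = c + radius * np.cos(ang)
                r0 = min(int(np.floor(rr)), h - 2)
                c0 = min(int(np.floor(cc)), w - 2)
                fr, fc = rr - r0, cc - c0
                v = (
                    img[r0, c0] * (1 - fr) * (1 - fc)
                    + img[r0, c0 + 1] * (1 - fr) * fc
                    + img[r0 + 1, c0] * fr * (1 - fc)
                    + img[r0 + 1, c0 + 1] * fr * fc
                )
                bits.append(1 if round(v, 8) - img[r, c] >= 0 else 0)
            trans = sum(
                bits[k] != bits[(k + 1) % n_points] for k in range(n_points)
            )
            code = sum(bits) if trans <= 2 else n_points + 1
            counts[code] += 1
    total = counts.sum()
    return counts / total if total else None


def boundary_edge_oracle(mask):
    """Exposed 4-neighbour edge count by per-pixel enumeration."""
    h, w = mask.shape
    edges = 0
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                r2, c2 = r + dr, c + dc
                if not (0 <= r2 < h and 0 <= c2 < w) or not mask[r2, c2]:
                    edges += 1
    return edges


def kruskal_oracle(groups):
    """Textbook tie-corrected Kruskal-Wallis H from mean ranks."""
    pooled = np.concatenate(groups)
    n = len(pooled)
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(n)
    sorted_vals = pooled[order]
    i = 0
    while i < n:
        j = i
        while j < n and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0  # mid-rank for ties
        i = j
    grand = (n + 1) / 2.0
    h_stat = 0.0
    start = 0
    for g in groups:
        r_mean = ranks[start : start + len(g)].mean()
        h_stat += len(g) * (r_mean - grand) ** 2
        start += len(g)
    h_stat *= 12.0 / (n * (n + 1))
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    return h_stat / correction if correction > 0 else 0.0


def dunn_z_oracle(groups):
    """Dunn pairwise z statistics from mean ranks, tie corrected."""
    pooled = np.concatenate(groups)
    n = len(pooled)
    from scipy.stats import rankdata

    ranks = rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    ties = (counts**3 - counts).sum() / (12.0 * (n - 1))
    means, sizes, start = [], [], 0
    for g in groups:
        means.append(ranks[start : start + len(g)].mean())
        sizes.append(len(g))
        start += len(g)
    out = {}
    for a in range(len(groups)):
        for b in range(a + 1, len(groups)):
            sigma = np.sqrt(
                (n * (n + 1) / 12.0 - ties) * (1.0 / sizes[a] + 1.0 / sizes[b])
            )
            out[(a + 1, b + 1)] = (means[a] - means[b]) / sigma
    return out
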