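"""Naive reference implementations used as independent test oracles.

Everything here is written as literal per-pixel / per-cluster Python
loops following the algorithmic definitions, deliberately sharing no
code with the package's vectorized implementation.  Intended only for
tiny inputs (images of at most a few hundred pixels).
"""

import math

import numpy as np
from skimage.color import rgb2lab


def naive_quantize(img, levels=8):
    m, n, _ = img.shape
    out = np.zeros((m, n), dtype=int)
    for i in range(m):
        for j in range(n):
            b = [min(int(img[i, j, c]) * levels // 256, levels - 1) for c in range(3)]
            out[i, j] = b[0] * levels * levels + b[1] * levels + b[2] + 1
    return out


def naive_chc(img, n_param=0.5, levels=8):
    """Cluster table + pixel saliency map via literal double loops.

    Returns a dict with every per-cluster quantity plus the saliency
    map, all computed from scratch.
    """
    m, n, _ = img.shape
    idx = naive_quantize(img, levels)
    constant = all(
        (img[i, j] == img[0, 0]).all() for i in range(m) for j in range(n)
    )
    if constant:  # degenerate joint rescale: defined as all-zero
        lab = np.zeros((m, n, 3))
    else:
        lab = rgb2lab(img)
        lo = lab.min()
        hi = lab.max()
        lab = (lab - lo) / (hi - lo)

    n_bins = levels**3
    sums = {z: [0.0] * 5 for z in range(1, n_bins + 1)}  # L, a, b, x, y
    counts = {z: 0 for z in range(1, n_bins + 1)}
    for x in range(1, m + 1):
        for y in range(1, n + 1):
            z = idx[x - 1, y - 1]
            counts[z] += 1
            for c in range(3):
                sums[z][c] += lab[x - 1, y - 1, c]
            sums[z][3] += x
            sums[z][4] += y

    bin_of, mean_lab, mean_x, mean_y, count = [], [], [], [], []
    label_of_bin = {}
    for z in range(1, n_bins + 1):
        if counts[z] > 0:
            label_of_bin[z] = len(bin_of) + 1
            bin_of.append(z)
            mean_lab.append([sums[z][c] / counts[z] for c in range(3)])
            mean_x.append((sums[z][3] / m) / counts[z])
            mean_y.append((sums[z][4] / n) / counts[z])
            count.append(counts[z])
    k = len(bin_of)
    w = [count[i] / (m * n) for i in range(k)]

    ccc = []
    for x in range(k):
        acc = 0.0
        for y in range(k):
            d = math.sqrt(sum((mean_lab[x][c] - mean_lab[y][c]) ** 2 for c in range(3)))
            acc += w[y] * d
        ccc.append(acc)

    pdc = [0.0] * k
    for x in range(1, m + 1):
        for y in range(1, n + 1):
            z = label_of_bin[idx[x - 1, y - 1]]
            pdc[z - 1] += (x / m - 0.5) ** 2 + (y / n - 0.5) ** 2
    for z in range(k):
        pdc[z] = pdc[z] / (n_param * n_param * count[z])

    css = []
    for x in range(k):
        acc = 0.0
        for y in range(k):
            ds = math.sqrt((mean_x[x] - mean_x[y]) ** 2 + (mean_y[x] - mean_y[y]) ** 2)
            phi = (ccc[x] + 0.05) / (ccc[y] + 0.05)
            acc += w[y] * phi * math.exp(-ds)
        css.append(math.exp(-pdc[x]) * (w[x] * ccc[x] + acc))
    lo, hi = min(css), max(css)
    if hi == lo:
        css = [0.0] * k
    else:
        css = [(v - lo) / (hi - lo) for v in css]

    sal = np.zeros((m, n))
    for x in range(m):
        for y in range(n):
            sal[x, y] = css[label_of_bin[idx[x, y]] - 1]

    return {
        "index": idx,
        "bin_index": np.array(bin_of),
        "mean_lab": np.array(mean_lab),
        "mean_x": np.array(mean_x),
        "mean_y": np.array(mean_y),
        "pixel_count": np.array(count),
        "weight": np.array(w),
        "color_contrast": np.array(ccc),
        "center_dist": np.array(pdc),
        "saliency": np.array(css),
        "saliency_map": sal,
    }


def naive_otsu(values, bins=256):
    """Exhaustive-scan Otsu threshold over bin-boundary cuts.

    Returns the boundary (t+1)/bins of the first cut maximizing the
    between-class variance, or None if the histogram is flat.
    """
    flat = np.asarray(values, dtype=float).ravel()
    which = [min(int(v * bins), bins - 1) for v in flat]
    occupied = set(which)
    if len(occupied) < 2:
        return None
    centers = [(b + 0.5) / bins for b in range(bins)]
    best_var, best_t = -1.0, None
    for t in range(bins - 1):
        g0 = [centers[b] for b in which if b <= t]
        g1 = [centers[b] for b in which if b > t]
        if not g0 or not g1:
            continue
        w0, w1 = len(g0), len(g1)
        mu0 = sum(g0) / w0
        mu1 = sum(g1) / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var + 1e-15:
            best_var, best_t = var, t
    return (best_t + 1) / bins
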