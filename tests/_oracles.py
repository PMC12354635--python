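"""Independent brute-force oracles used to verify the package's operations.

Everything here is deliberately naive (python loops, scalar math, bisection)
and shares no code with the implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage

from danioscope.phenotypes import PhenotypeClass

# ---------------------------------------------------------------------------
# CBAM: scalar-arithmetic attention oracle
# ---------------------------------------------------------------------------

def _sigmoid(v: float) -> float:
    return 1.0 / (1.0 + math.exp(-v))


def _mlp_scalar(desc, p):
    """Two-layer perceptron on a per-channel descriptor, scalar loops."""
    hidden = []
    for j in range(p.w1.shape[1]):
        acc = p.b1[j]
        for c in range(p.w1.shape[0]):
            acc += desc[c] * p.w1[c, j]
        hidden.append(max(acc, 0.0))
    out = []
    for c in range(p.w2.shape[1]):
        acc = p.b2[c]
        for j in range(p.w2.shape[0]):
            acc += hidden[j] * p.w2[j, c]
        out.append(acc)
    return out


def channel_attention_oracle(x: np.ndarray, params) -> np.ndarray:
    h, w, nc = x.shape
    avg = [float(np.mean(x[:, :, c])) for c in range(nc)]
    mx = [float(np.max(x[:, :, c])) for c in range(nc)]
    s_avg = _mlp_scalar(avg, params)
    s_max = _mlp_scalar(mx, params)
    return np.array([_sigmoid(a + b) for a, b in zip(s_avg, s_max)])


def spatial_attention_oracle(x: np.ndarray, params) -> np.ndarray:
    h, w, nc = x.shape
    k = params.spatial_kernel.shape[0]
    pad = k // 2
    mean_map = x.mean(axis=2)
    max_map = x.max(axis=2)
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            acc = float(params.spatial_bias[0])
            for di in range(k):
                for dj in range(k):
                    ii, jj = i + di - pad, j + dj - pad
                    if 0 <= ii < h and 0 <= jj < w:
                        acc += mean_map[ii, jj] * params.spatial_kernel[di, dj, 0, 0]
                        acc += max_map[ii, jj] * params.spatial_kernel[di, dj, 1, 0]
            out[i, j] = _sigmoid(acc)
    return out


def cbam_refine_oracle(x: np.ndarray, params) -> np.ndarray:
    cw = channel_attention_oracle(x, params)
    x1 = x * cw[None, None, :]
    sw = spatial_attention_oracle(x1, params)
    return x1 * sw[:, :, None]


# ---------------------------------------------------------------------------
# Image oracles: clot detection and a trivial pixel-statistics classifier
# ---------------------------------------------------------------------------

#: Fixture constants for the clot detector (documented detection contract).
CLOT_MARGIN = 40
CLOT_MIN_PIXELS = 5


def count_clots(pixels: np.ndarray) -> int:
    """Connected components whose red channel exceeds max(G, B) by the margin."""
    px = pixels.astype(int)
    mask = (px[..., 0] - np.maximum(px[..., 1], px[..., 2])) >= CLOT_MARGIN
    labels, n = ndimage.label(mask)
    if n == 0:
        return 0
    sizes = ndimage.sum(mask, labels, range(1, n + 1))
    return int(np.sum(np.asarray(sizes) >= CLOT_MIN_PIXELS))


def interior_mean(pixels: np.ndarray) -> float:
    """Mean intensity of the central half-crop (covers the embryo body)."""
    s = pixels.shape[0]
    return float(pixels[s // 4 : 3 * s // 4, s // 4 : 3 * s // 4].mean())


def pixel_statistic_classifier(pixels: np.ndarray) -> PhenotypeClass:
    """Hand-rolled decision rules on simple pixel statistics.

    Thresholds are fixture constants calibrated once against the generator's
    nominal parameter ranges (not scientific claims): red clot components
    identify blood stasis; the dark fraction of the central crop separates
    dead (opaque mass) from necrosed yolk (localised dark ball); a count of
    pale-blue pixels (fluid-filled sac) identifies edema.  Area thresholds
    scale with the squared image size.
    """
    px = pixels.astype(int)
    s = px.shape[0]
    if count_clots(pixels) >= 1:
        return PhenotypeClass.BLOOD_STASIS
    center = px[s // 4 : 3 * s // 4, s // 4 : 3 * s // 4]
    dark_fraction = (center.mean(axis=2) < 120).mean()
    if dark_fraction > 0.30:
        return PhenotypeClass.DEAD
    if dark_fraction > 0.08:
        return PhenotypeClass.NECROSED_YOLK_SAC
    pale_blue = ((px[..., 2] - px[..., 0] > 30) & (px[..., 2] > 200)).sum()
    if pale_blue >= 50 * (s / 64) ** 2:
        return PhenotypeClass.EDEMA
    return PhenotypeClass.NORMAL


# ---------------------------------------------------------------------------
# Top-k metrics: exhaustive counting oracle
# ---------------------------------------------------------------------------

def report_oracle(ranked: list[list[int]], truths: list[int], k: int) -> dict:
    """Tally TP/FP/FN per class with explicit loops under the documented
    attribution rule, then compute the metrics from their definitions."""
    n_classes = 5
    tp = [0] * n_classes
    fp = [0] * n_classes
    fn = [0] * n_classes
    confusion = [[0] * n_classes for _ in range(n_classes)]
    for ranks, truth in zip(ranked, truths):
        if truth in ranks[:k]:
            tp[truth] += 1
            confusion[truth][truth] += 1
        else:
            fn[truth] += 1
            fp[ranks[0]] += 1
            confusion[truth][ranks[0]] += 1
    precision, recall, f1 = [], [], []
    for c in range(n_classes):
        p = tp[c] / (tp[c] + fp[c]) if tp[c] + fp[c] else 0.0
        r = tp[c] / (tp[c] + fn[c]) if tp[c] + fn[c] else 0.0
        precision.append(p)
        recall.append(r)
        f1.append(2 * p * r / (p + r) if p + r else 0.0)
    return {
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "macro_precision": sum(precision) / n_classes,
        "macro_recall": sum(recall) / n_classes,
        "macro_f1": sum(f1) / n_classes,
        "accuracy": sum(tp) / len(truths),
        "confusion": confusion,
    }


# ---------------------------------------------------------------------------
# Normal quantile via bisection on the erf-based CDF
# ---------------------------------------------------------------------------

def normal_quantile_oracle(p: float, tol: float = 1e-10) -> float:
    """Phi^-1 by bisection, independent of scipy's ppf implementation."""
    cdf = lambda z: 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))
    lo, hi = -10.0, 10.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if cdf(mid) < p:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
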