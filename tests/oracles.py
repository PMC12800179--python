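"""Independent brute-force reference implementations used only by tests.

These are deliberately naive (pair enumeration, exhaustive sign assignment,
per-pixel histogram accumulation) so they can serve as oracles for the
package's faster implementations.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def auc_by_pair_counting(labels: np.ndarray, scores: np.ndarray) -> float:
    """AUC as the fraction of correctly ordered positive/negative pairs.

    Ties contribute one half, per the rank-statistic convention.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def wilcoxon_exact_by_enumeration(a: np.ndarray, b: np.ndarray):
    """Two-sided exact Wilcoxon signed-rank p over all 2^n sign assignments.

    Midranks for tied magnitudes; zero differences dropped; statistic
    W = min(W+, W-). Returns (W, p); all-zero differences give (None, 1.0).
    """
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return None, 1.0
    abs_d = np.abs(d)
    order = np.argsort(abs_d, kind="stable")
    ranks = np.empty(n)
    sorted_abs = abs_d[order]
    i = 0
    while i < n:
        j = i
        while j < n and sorted_abs[j] == sorted_abs[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0  # midrank of positions i..j-1 (1-based)
        i = j
    w_plus = ranks[d > 0].sum()
    w_minus = ranks[d < 0].sum()
    w = min(w_plus, w_minus)
    total = ranks.sum()
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        s = sum(r for r, bit in zip(ranks, signs) if bit)
        if s <= w + 1e-9 or s >= total - w - 1e-9:
            count += 1
    return w, count / 2.0**n


def disc_area(radius: float) -> int:
    """Pixels inside an origin-centered rasterized disc of given radius."""
    r = int(math.ceil(radius)) + 1
    count = 0
    for y in range(-r, r + 1):
        for x in range(-r, r + 1):
            if (y / radius) ** 2 + (x / radius) ** 2 <= 1.0:
                count += 1
    return count


def orientation_histogram(image: np.ndarray, n_bins: int = 9) -> np.ndarray:
    """Unsigned gradient-orientation histogram by per-pixel accumulation.

    Central differences, orientations folded to [0, 180); magnitude-weighted
    votes to the containing bin (no interpolation). A deliberately crude
    global reference for checking which orientation dominates.
    """
    img = np.asarray(image, dtype=float)
    gy, gx = np.gradient(img)
    mag = np.hypot(gx, gy)
    ang = np.rad2deg(np.arctan2(gy, gx)) % 180.0
    hist = np.zeros(n_bins)
    width = 180.0 / n_bins
    for m, a in zip(mag.ravel(), ang.ravel()):
        hist[min(int(a // width), n_bins - 1)] += m
    return hist
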