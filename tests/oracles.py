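"""Independent brute-force oracles used across the test suite.

Each oracle is written long-hand, from the textbook definition, and shares
no code with the implementation it checks.
"""

from fractions import Fraction
from math import comb

import numpy as np


def naive_median_filter(image, radius):
    """Per-pixel sorted-window median, circular window truncated at edges."""
    h, w = image.shape
    out = np.empty_like(image, dtype=float)
    r = int(np.ceil(radius))
    for y in range(h):
        for x in range(w):
            vals = []
            for dy in range(-r, r + 1):
                for dx in range(-r, r + 1):
                    if dy * dy + dx * dx <= radius * radius:
                        yy, xx = y + dy, x + dx
                        if 0 <= yy < h and 0 <= xx < w:
                            vals.append(image[yy, xx])
            out[y, x] = np.median(vals)
    return out


def naive_huang_bin(hist):
    """Exhaustive scan of the Huang–Wang fuzzy-entropy objective."""
    nb = len(hist)
    C = nb - 1
    best_t, best_s = None, np.inf
    for t in range(nb - 1):
        w0 = sum(hist[: t + 1])
        w1 = sum(hist[t + 1:])
        if w0 == 0 or w1 == 0:
            continue
        mu0 = sum(g * hist[g] for g in range(t + 1)) / w0
        mu1 = sum(g * hist[g] for g in range(t + 1, nb)) / w1
        s = 0.0
        for g in range(nb):
            if hist[g] == 0:
                continue
            mu = 1.0 / (1.0 + abs(g - (mu0 if g <= t else mu1)) / C)
            for m in (mu, 1.0 - mu):
                if 0.0 < m < 1.0:
                    s -= hist[g] * m * np.log(m)
        if s < best_s:
            best_s, best_t = s, t
    return best_t


def definitional_pearson(a, b):
    """Two-pass textbook Pearson correlation on plain Python floats."""
    a = [float(x) for x in a]
    b = [float(x) for x in b]
    n = len(a)
    am = sum(a) / n
    bm = sum(b) / n
    num = sum((x - am) * (y - bm) for x, y in zip(a, b))
    den = (sum((x - am) ** 2 for x in a) * sum((y - bm) ** 2 for y in b)) ** 0.5
    return num / den


def fisher_enumeration(a, b, c, d):
    """Two-sided Fisher p by exact rational hypergeometric enumeration."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    denom = comb(n, c1)
    probs = {}
    for x in range(max(0, c1 - (c + d)), min(r1, c1) + 1):
        probs[x] = Fraction(comb(r1, x) * comb(n - r1, c1 - x), denom)
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs))
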