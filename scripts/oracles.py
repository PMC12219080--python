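"""Brute-force reference implementations used by the acceptance script.

These are deliberately naive (double loops, exhaustive searches) so they are
independent of the vectorised implementations they check.
"""

import numpy as np

OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def brute_glcm(levels, Ng, direction, symmetric):
    dr, dc = OFFSETS[direction]
    h, w = levels.shape
    counts = np.zeros((Ng, Ng))
    for i in range(h):
        for j in range(w):
            i2, j2 = i + dr, j + dc
            if 0 <= i2 < h and 0 <= j2 < w:
                counts[levels[i, j] - 1, levels[i2, j2] - 1] += 1
                if symmetric:
                    counts[levels[i2, j2] - 1, levels[i, j] - 1] += 1
    return counts / counts.sum()


def brute_glrlm(levels, Ng, direction):
    h, w = levels.shape
    if direction == 0:
        lines = [levels[i, :] for i in range(h)]
    elif direction == 90:
        lines = [levels[:, j] for j in range(w)]
    elif direction == 135:
        lines = [np.diagonal(levels, k) for k in range(-(h - 1), w)]
    else:
        flipped = levels[::-1]
        lines = [np.diagonal(flipped, k) for k in range(-(h - 1), w)]
    lmax = {0: w, 90: h}.get(direction, min(h, w))
    R = np.zeros((Ng, lmax), dtype=int)
    for line in lines:
        run_val, run_len = None, 0
        for v in list(line) + [None]:
            if v == run_val:
                run_len += 1
            else:
                if run_val is not None:
                    R[run_val - 1, run_len - 1] += 1
                run_val, run_len = v, 1
    return R


def brute_force_otsu(pixels, max_value=255):
    hist = np.bincount(pixels.reshape(-1), minlength=max_value + 1).astype(float)
    total = hist.sum()
    best_t, best_score = None, -1.0
    for t in range(max_value + 1):
        w0 = hist[:t + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[:t + 1] * np.arange(t + 1)).sum() / w0
        mu1 = (hist[t + 1:] * np.arange(t + 1, max_value + 1)).sum() / w1
        score = w0 * w1 * (mu0 - mu1) ** 2
        if score > best_score + 1e-9:
            best_score, best_t = score, t
    return best_t
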