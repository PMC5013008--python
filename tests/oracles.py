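"""Independent brute-force reference implementations used by the tests.

Deliberately written as plain nested loops over pixels, neighbors and
candidate displacements, with no shared code paths with the package's
vectorized operators.
"""

import numpy as np

from hystsum.saliency import quantize


def entropy_oracle(gray, params):
    """Per-pixel histogram entropy by direct windowed counting."""
    w = params.entropy_window
    pad = w // 2
    g_levels = params.gray_levels
    q = quantize(gray, g_levels)
    qp = np.pad(q, pad, mode="reflect")
    n = float(w * w)
    out = np.zeros(gray.shape)
    for y in range(gray.shape[0]):
        for x in range(gray.shape[1]):
            hist = np.bincount(qp[y : y + w, x : x + w].ravel(), minlength=g_levels)
            e = 0.0
            for k in range(g_levels):
                c = hist[k]
                if c:
                    p = c / n
                    e -= p * np.log2(p)
            out[y, x] = e / np.log2(g_levels)
    return out


def contrast_oracle(img, params):
    """Nested-loop sum of squared differences over the contrast window."""
    img = np.asarray(img, dtype=np.float64)
    if np.issubdtype(np.asarray(img).dtype, np.integer):
        img = img / 255.0
    k = params.contrast_neighborhood
    pad = k // 2
    padded = np.pad(img, ((pad, pad), (pad, pad), (0, 0)), mode="reflect")
    h, w = img.shape[:2]
    out = np.zeros((h, w))
    for y in range(h):
        for x in range(w):
            total = 0.0
            for c in range(3):
                center = img[y, x, c]
                for dy in range(k):
                    for dx in range(k):
                        if dy == pad and dx == pad:
                            continue
                        total += (center - padded[y + dy, x + dx, c]) ** 2
            out[y, x] = total
    return out


def motion_oracle(prev, cur, params):
    """Exhaustive per-block SAD search; returns (dy, dx) per block origin."""
    prev = np.asarray(prev, dtype=np.float64)
    cur = np.asarray(cur, dtype=np.float64)
    r, b = params.search_radius, params.block_size
    padded = np.pad(prev, r, mode="reflect")
    h, w = cur.shape
    result = {}
    for by in range(0, h, b):
        for bx in range(0, w, b):
            block = cur[by : by + b, bx : bx + b]
            bh, bw = block.shape
            best_key = None
            best_d = None
            for dy in range(-r, r + 1):
                for dx in range(-r, r + 1):
                    sad = 0.0
                    for yy in range(bh):
                        for xx in range(bw):
                            sad += abs(
                                block[yy, xx]
                                - padded[by - dy + r + yy, bx - dx + r + xx]
                            )
                    key = (sad, dy * dy + dx * dx, dy, dx)
                    if best_key is None or key < best_key:
                        best_key, best_d = key, (dy, dx)
            result[(by, bx)] = best_d
    return result


def nkf_oracle(values, nkf):
    """Shot partition + per-shot argmax by direct recomputation."""
    n = len(values)
    k = min(nkf, n)
    base, rem = n // k, n % k
    picks = []
    start = 0
    for s in range(k):
        stop = start + base + (1 if s < rem else 0)
        best, best_i = None, None
        for i in range(start, stop):
            if best is None or values[i] > best:
                best, best_i = values[i], i
        picks.append(best_i)
        start = stop
    return picks


def optimal_matching_oracle(extracted, truth, tolerance):
    """Maximum one-to-one matching count by exhaustive recursion."""
    ext = sorted(extracted)
    tru = sorted(truth)

    def best_from(i, used):
        if i == len(tru):
            return 0
        best = best_from(i + 1, used)  # leave truth i unmatched
        for j, e in enumerate(ext):
            if not used & (1 << j) and abs(e - tru[i]) <= tolerance:
                best = max(best, 1 + best_from(i + 1, used | (1 << j)))
        return best

    return best_from(0, 0)
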