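"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately naive — explicit loops, flood fill,
O(n^2) pair counting — and shares no code with the package implementation.
"""

import numpy as np


def brute_glcm(levels, n_bins, directions, distance=1):
    """Exhaustive pair enumeration, symmetrized and normalized."""
    lv = np.asarray(levels)
    counts = np.zeros((n_bins, n_bins))
    nr, nc = lv.shape
    for r in range(nr):
        for c in range(nc):
            if lv[r, c] == 0:
                continue
            for dr, dc in directions:
                r2, c2 = r + dr * distance, c + dc * distance
                if 0 <= r2 < nr and 0 <= c2 < nc and lv[r2, c2] > 0:
                    counts[lv[r, c] - 1, lv[r2, c2] - 1] += 1
                    counts[lv[r2, c2] - 1, lv[r, c] - 1] += 1
    total = counts.sum()
    return counts / total if total else counts


def brute_glrlm(levels, n_bins, directions):
    """Maximal-run enumeration by walking each lattice line."""
    lv = np.asarray(levels)
    nr, nc = lv.shape
    maxlen = max(nr, nc)
    counts = np.zeros((n_bins, maxlen))
    for dr, dc in directions:
        starts = []
        for r in range(nr):
            for c in range(nc):
                # a line start has no in-grid predecessor
                if not (0 <= r - dr < nr and 0 <= c - dc < nc):
                    starts.append((r, c))
        for r0, c0 in starts:
            seq = []
            r, c = r0, c0
            while 0 <= r < nr and 0 <= c < nc:
                seq.append(lv[r, c])
                r, c = r + dr, c + dc
            run_level, run_len = 0, 0
            for v in seq + [0]:
                if v == run_level:
                    run_len += 1
                else:
                    if run_level > 0:
                        counts[run_level - 1, run_len - 1] += 1
                    run_level, run_len = v, 1
    return counts


def brute_glszm(levels, n_bins):
    """8-connected zone enumeration by flood fill."""
    lv = np.asarray(levels)
    nr, nc = lv.shape
    seen = np.zeros_like(lv, dtype=bool)
    zones = []
    for r in range(nr):
        for c in range(nc):
            if lv[r, c] == 0 or seen[r, c]:
                continue
            level = lv[r, c]
            stack, size = [(r, c)], 0
            seen[r, c] = True
            while stack:
                rr, cc = stack.pop()
                size += 1
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        r2, c2 = rr + dr, cc + dc
                        if (0 <= r2 < nr and 0 <= c2 < nc and not seen[r2, c2]
                                and lv[r2, c2] == level):
                            seen[r2, c2] = True
                            stack.append((r2, c2))
            zones.append((level, size))
    maxsize = max((s for _, s in zones), default=1)
    counts = np.zeros((n_bins, maxsize))
    for level, size in zones:
        counts[level - 1, size - 1] += 1
    return counts


def brute_ngtdm(levels, n_bins):
    """Per-pixel neighborhood averages with explicit loops.

    Returns (p, s, n_valid) over pixels having >= 1 in-mask neighbour.
    """
    lv = np.asarray(levels)
    nr, nc = lv.shape
    p = np.zeros(n_bins)
    s = np.zeros(n_bins)
    n_valid = 0
    for r in range(nr):
        for c in range(nc):
            if lv[r, c] == 0:
                continue
            neigh = []
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    r2, c2 = r + dr, c + dc
                    if 0 <= r2 < nr and 0 <= c2 < nc and lv[r2, c2] > 0:
                        neigh.append(lv[r2, c2])
            if not neigh:
                continue
            n_valid += 1
            p[lv[r, c] - 1] += 1
            s[lv[r, c] - 1] += abs(lv[r, c] - float(np.mean(neigh)))
    return p / n_valid if n_valid else p, s, n_valid


def brute_auc(scores, labels):
    """O(n^2) concordance count, ties = 1/2."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    pos = s[y == 1]
    neg = s[y == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


def random_roi(rng, max_side=8, max_levels=4):
    """Random small discretized ROI with at least a few in-mask pixels."""
    nr = rng.integers(2, max_side + 1)
    nc = rng.integers(2, max_side + 1)
    levels = rng.integers(1, max_levels + 1, size=(nr, nc))
    mask = rng.random((nr, nc)) < 0.8
    while mask.sum() < 3:
        mask = rng.random((nr, nc)) < 0.8
    return np.where(mask, levels, 0).astype(np.int32), int(max_levels)
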