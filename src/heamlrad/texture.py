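"""Per-channel 47-feature texture panel.

Seven first-order histogram statistics plus forty texture-matrix features:
9 gray-level co-occurrence (GLCM), 13 run-length (GLRLM), 13 size-zone
(GLSZM) and 5 neighborhood gray-tone difference (NGTDM) features, computed
on a discretized ROI. Definitions follow the classical sources (Haralick;
Galloway/Chu/Dasarathy; Thibault; Amadasun-King) in their 2-D,
distance-1, four-direction, direction-summed form, with fixed conventions
for degenerate (constant) ROIs where the formulas are undefined.

All entropies are log base 2. Epsilon guards (1e-6) protect the NGTDM
coarseness/busyness/strength denominators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .preprocess import DiscretizedRoi

EPS = 1e-6

#: distance-1 offsets: 0, 90, 45, 135 degrees — closed under 90-degree rotation
DIRECTIONS: tuple[tuple[int, int], ...] = ((0, 1), (1, 0), (1, 1), (1, -1))

FIRST_ORDER_NAMES = ("mean", "variance", "skewness", "kurtosis",
                     "energy", "entropy", "uniformity")
GLCM_NAMES = ("contrast", "correlation", "energy", "entropy", "homogeneity",
              "variance", "sum_average", "dissimilarity", "cluster_shade")
GLRLM_NAMES = ("sre", "lre", "gln", "rln", "rp", "lglre", "hglre",
               "srlgle", "srhgle", "lrlgle", "lrhgle", "glv", "rlv")
GLSZM_NAMES = ("sze", "lze", "gln", "zsn", "zp", "lglze", "hglze",
               "szlgle", "szhgle", "lzlgle", "lzhgle", "glv", "zsv")
NGTDM_NAMES = ("coarseness", "contrast", "busyness", "complexity", "strength")


# ---------------------------------------------------------------------------
# First order
# ---------------------------------------------------------------------------

def first_order_features(roi: DiscretizedRoi) -> dict[str, float]:
    """Histogram statistics of the in-mask gray levels.

    skewness and kurtosis (non-excess) of a constant ROI are defined as 0;
    energy is the mean squared gray level (size-invariant convention);
    uniformity is the sum of squared level probabilities.
    """
    v = roi.in_mask().astype(float)
    if v.size == 0:
        raise ValueError("empty ROI")
    mu = v.mean()
    var = v.var()
    sd = np.sqrt(var)
    if sd > 0:
        skew = float(np.mean((v - mu) ** 3) / sd**3)
        kurt = float(np.mean((v - mu) ** 4) / sd**4)
    else:
        skew = kurt = 0.0
    _, counts = np.unique(v, return_counts=True)
    p = counts / v.size
    return {
        "mean": float(mu),
        "variance": float(var),
        "skewness": skew,
        "kurtosis": kurt,
        "energy": float(np.mean(v**2)),
        "entropy": float(-np.sum(p * np.log2(p))),
        "uniformity": float(np.sum(p**2)),
    }


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

@dataclass
class GlcmMatrix:
    """Symmetric, direction-summed, sum-1 normalized co-occurrence matrix."""

    p: np.ndarray  # (n_bins, n_bins)
    distance: int = 1
    directions: tuple[tuple[int, int], ...] = DIRECTIONS


def compute_glcm(
    roi: DiscretizedRoi,
    distance: int = 1,
    directions: tuple[tuple[int, int], ...] = DIRECTIONS,
) -> GlcmMatrix:
    lv = roi.levels
    nb = roi.n_bins
    counts = np.zeros((nb, nb), dtype=float)
    for dr, dc in directions:
        dr, dc = dr * distance, dc * distance
        # overlapping views shifted by (dr, dc)
        r0, r1 = max(0, -dr), min(lv.shape[0], lv.shape[0] - dr)
        c0, c1 = max(0, -dc), min(lv.shape[1], lv.shape[1] - dc)
        a = lv[r0:r1, c0:c1]
        b = lv[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        ok = (a > 0) & (b > 0)
        if ok.any():
            np.add.at(counts, (a[ok] - 1, b[ok] - 1), 1.0)
    counts = counts + counts.T  # symmetrize
    total = counts.sum()
    if total == 0:
        raise ValueError("no in-mask pixel pairs for GLCM")
    return GlcmMatrix(p=counts / total, distance=distance, directions=tuple(directions))


def glcm_features(m: GlcmMatrix) -> dict[str, float]:
    """Nine Haralick-style features; correlation of a constant ROI is 1."""
    p = m.p
    nb = p.shape[0]
    i = np.arange(1, nb + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    mu = float(np.sum(ii * p))  # marginal means coincide (symmetric matrix)
    sigma2 = float(np.sum((ii - mu) ** 2 * p))
    nz = p > 0
    corr = (
        float((np.sum(ii * jj * p) - mu * mu) / sigma2) if sigma2 > 0 else 1.0
    )
    return {
        "contrast": float(np.sum((ii - jj) ** 2 * p)),
        "correlation": corr,
        "energy": float(np.sum(p**2)),
        "entropy": float(-np.sum(p[nz] * np.log2(p[nz]))),
        "homogeneity": float(np.sum(p / (1.0 + (ii - jj) ** 2))),
        "variance": sigma2,
        "sum_average": float(np.sum((ii + jj) * p)),
        "dissimilarity": float(np.sum(np.abs(ii - jj) * p)),
        "cluster_shade": float(np.sum((ii + jj - 2 * mu) ** 3 * p)),
    }


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

@dataclass
class GlrlmMatrix:
    counts: np.ndarray  # (n_bins, max_run_length)
    n_directions: int
    n_pixels: int  # in-mask pixel count


def _lines(shape: tuple[int, int], direction: tuple[int, int]):
    """Index arrays for every maximal lattice line along ``direction``."""
    nr, nc = shape
    dr, dc = direction
    if (dr, dc) == (0, 1):
        for r in range(nr):
            yield np.full(nc, r), np.arange(nc)
    elif (dr, dc) == (1, 0):
        for c in range(nc):
            yield np.arange(nr), np.full(nr, c)
    elif (dr, dc) == (1, 1):
        for off in range(-(nr - 1), nc):
            r = np.arange(max(0, -off), min(nr, nc - off))
            yield r, r + off
    elif (dr, dc) == (1, -1):
        for s in range(nr + nc - 1):
            r = np.arange(max(0, s - nc + 1), min(nr, s + 1))
            yield r, s - r
    else:
        raise ValueError(f"unsupported direction {direction}")


def compute_glrlm(
    roi: DiscretizedRoi,
    directions: tuple[tuple[int, int], ...] = DIRECTIONS,
) -> GlrlmMatrix:
    lv = roi.levels
    npix = int((lv > 0).sum())
    if npix == 0:
        raise ValueError("empty ROI")
    maxlen = max(lv.shape)
    counts = np.zeros((roi.n_bins, maxlen), dtype=float)
    for d in directions:
        # concatenate every lattice line with a 0 separator, then one
        # vectorized run-length pass (level 0 = out of mask breaks runs)
        pieces = []
        for r, c in _lines(lv.shape, d):
            pieces.append(lv[r, c])
            pieces.append([0])
        seq = np.concatenate(pieces)
        change = np.flatnonzero(np.diff(seq) != 0)
        starts = np.concatenate(([0], change + 1))
        ends = np.concatenate((change + 1, [seq.size]))
        levels = seq[starts]
        keep = levels > 0
        np.add.at(counts, (levels[keep] - 1, (ends - starts)[keep] - 1), 1.0)
    return GlrlmMatrix(counts=counts, n_directions=len(directions), n_pixels=npix)


def _rl_style_features(counts: np.ndarray, names: tuple[str, ...],
                       n_total: float) -> dict[str, float]:
    """Shared run-length / size-zone feature formulas.

    ``counts[i, j]`` is the number of runs (zones) of gray level i+1 and
    length (size) j+1; ``n_total`` is the normalizer for RP/ZP (pixel count
    per direction for GLRLM, pixel count for GLSZM).
    """
    n_runs = counts.sum()
    if n_runs == 0:
        raise ValueError("empty matrix")
    gl = np.arange(1, counts.shape[0] + 1, dtype=float)[:, None]
    ln = np.arange(1, counts.shape[1] + 1, dtype=float)[None, :]
    pr = counts / n_runs
    mu_g = float(np.sum(pr * gl))
    mu_l = float(np.sum(pr * ln))
    feats = {
        names[0]: float(np.sum(counts / ln**2) / n_runs),          # SRE / SZE
        names[1]: float(np.sum(counts * ln**2) / n_runs),          # LRE / LZE
        names[2]: float(np.sum(counts.sum(axis=1) ** 2) / n_runs),  # GLN
        names[3]: float(np.sum(counts.sum(axis=0) ** 2) / n_runs),  # RLN / ZSN
        names[4]: float(n_runs / n_total),                          # RP / ZP
        names[5]: float(np.sum(counts / gl**2) / n_runs),
        names[6]: float(np.sum(counts * gl**2) / n_runs),
        names[7]: float(np.sum(counts / (gl**2 * ln**2)) / n_runs),
        names[8]: float(np.sum(counts * gl**2 / ln**2) / n_runs),
        names[9]: float(np.sum(counts * ln**2 / gl**2) / n_runs),
        names[10]: float(np.sum(counts * gl**2 * ln**2) / n_runs),
        names[11]: float(np.sum(pr * (gl - mu_g) ** 2)),            # GLV
        names[12]: float(np.sum(pr * (ln - mu_l) ** 2)),            # RLV / ZSV
    }
    return feats


def glrlm_features(m: GlrlmMatrix) -> dict[str, float]:
    return _rl_style_features(m.counts, GLRLM_NAMES,
                              n_total=m.n_pixels * m.n_directions)


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

@dataclass
class GlszmMatrix:
    counts: np.ndarray  # (n_bins, max_zone_size)
    n_pixels: int


_EIGHT = np.ones((3, 3), dtype=int)


def compute_glszm(roi: DiscretizedRoi, connectivity: int = 8) -> GlszmMatrix:
    lv = roi.levels
    npix = int((lv > 0).sum())
    if npix == 0:
        raise ValueError("empty ROI")
    structure = _EIGHT if connectivity == 8 else None
    zones: list[tuple[int, int]] = []
    for level in np.unique(lv[lv > 0]):
        lab, nlab = ndimage.label(lv == level, structure=structure)
        sizes = np.bincount(lab.ravel())[1:]
        zones.extend((int(level), int(s)) for s in sizes)
    maxsize = max(s for _, s in zones)
    counts = np.zeros((roi.n_bins, maxsize), dtype=float)
    for level, size in zones:
        counts[level - 1, size - 1] += 1
    return GlszmMatrix(counts=counts, n_pixels=npix)


def glszm_features(m: GlszmMatrix) -> dict[str, float]:
    return _rl_style_features(m.counts, GLSZM_NAMES, n_total=m.n_pixels)


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------

@dataclass
class NgtdmTable:
    p: np.ndarray  # occurrence probability per level (length n_bins)
    s: np.ndarray  # summed |level - neighborhood mean| per level
    n_valid: int   # pixels with at least one in-mask neighbour


def compute_ngtdm(roi: DiscretizedRoi) -> NgtdmTable:
    """Amadasun-King table with mask-restricted 3x3 neighborhoods.

    A pixel contributes if it is in-mask and has >= 1 in-mask neighbour; its
    neighborhood average excludes the center and out-of-mask pixels.
    """
    lv = roi.levels.astype(float)
    inm = roi.mask.astype(float)
    ksum = ndimage.convolve(lv * inm, _EIGHT.astype(float), mode="constant") - lv * inm
    kcnt = ndimage.convolve(inm, _EIGHT.astype(float), mode="constant") - inm
    valid = roi.mask & (kcnt > 0)
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("no pixel has an in-mask neighbour")
    avg = np.zeros_like(lv)
    avg[valid] = ksum[valid] / kcnt[valid]
    diffs = np.abs(lv - avg)
    p = np.zeros(roi.n_bins)
    s = np.zeros(roi.n_bins)
    levels_valid = roi.levels[valid]
    np.add.at(p, levels_valid - 1, 1.0)
    np.add.at(s, levels_valid - 1, diffs[valid])
    return NgtdmTable(p=p / n_valid, s=s, n_valid=n_valid)


def ngtdm_features(t: NgtdmTable) -> dict[str, float]:
    p, s = t.p, t.s
    i = np.arange(1, p.size + 1, dtype=float)
    occ = p > 0
    ng = int(occ.sum())
    n = t.n_valid
    psi = float(np.sum(p * s))
    coarseness = 1.0 / (EPS + psi)
    if ng > 1:
        io, po = i[occ], p[occ]
        dif2 = (io[:, None] - io[None, :]) ** 2
        contrast = float(
            np.sum(po[:, None] * po[None, :] * dif2) / (ng * (ng - 1))
            * (s.sum() / n)
        )
        busy_den = float(np.sum(np.abs(io[:, None] * po[:, None]
                                       - io[None, :] * po[None, :])))
        busyness = psi / (EPS + busy_den)
        ps_o = (p * s)[occ]
        pij = po[:, None] + po[None, :]
        complexity = float(
            np.sum(np.abs(io[:, None] - io[None, :])
                   * (ps_o[:, None] + ps_o[None, :]) / pij) / n
        )
        strength = float(np.sum(pij * dif2) / (EPS + s.sum()))
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "coarseness": coarseness,
        "contrast": contrast,
        "busyness": busyness,
        "complexity": complexity,
        "strength": strength,
    }


# ---------------------------------------------------------------------------
# Channel panel
# ---------------------------------------------------------------------------

def channel_feature_set(roi: DiscretizedRoi, channel_name: str | None = None) -> dict[str, float]:
    """All 47 features of one channel, namespaced ``<channel>.<family>.<name>``.

    Ordering is fixed: first_order (7), glcm (9), glrlm (13), glszm (13),
    ngtdm (5).
    """
    ch = channel_name if channel_name is not None else roi.channel
    # crop to the mask bounding box (plus a 1-px guard ring): every family is
    # mask-restricted, so this is exact and just removes dead background
    m = roi.mask
    rows = np.flatnonzero(m.any(axis=1))
    cols = np.flatnonzero(m.any(axis=0))
    if rows.size and (rows[0] > 0 or rows[-1] < m.shape[0] - 1
                      or cols[0] > 0 or cols[-1] < m.shape[1] - 1):
        roi = DiscretizedRoi(
            levels=roi.levels[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1],
            n_bins=roi.n_bins, channel=roi.channel,
        )
    out: dict[str, float] = {}
    for name, val in first_order_features(roi).items():
        out[f"{ch}.firstorder.{name}"] = val
    for name, val in glcm_features(compute_glcm(roi)).items():
        out[f"{ch}.glcm.{name}"] = val
    for name, val in glrlm_features(compute_glrlm(roi)).items():
        out[f"{ch}.glrlm.{name}"] = val
    for name, val in glszm_features(compute_glszm(roi)).items():
        out[f"{ch}.glszm.{name}"] = val
    for name, val in ngtdm_features(compute_ngtdm(roi)).items():
        out[f"{ch}.ngtdm.{name}"] = val
    assert len(out) == 47
    return out


def feature_dictionary() -> dict[str, str]:
    """name -> formula-family reference, for the serialized feature dictionary."""
    d = {}
    for n in FIRST_ORDER_NAMES:
        d[f"firstorder.{n}"] = "histogram statistic of in-mask gray levels"
    for n in GLCM_NAMES:
        d[f"glcm.{n}"] = "Haralick co-occurrence feature (distance 1, 4 directions, symmetric)"
    for n in GLRLM_NAMES:
        d[f"glrlm.{n}"] = "Galloway/Chu/Dasarathy run-length feature (4 directions, summed)"
    for n in GLSZM_NAMES:
        d[f"glszm.{n}"] = "Thibault size-zone feature (8-connected zones)"
    for n in NGTDM_NAMES:
        d[f"ngtdm.{n}"] = "Amadasun-King gray-tone difference feature (3x3 neighborhood)"
    return d
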