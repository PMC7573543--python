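"""Stationary Haar wavelet channels and the 376-feature wavelet panel.

Each case image is decomposed by a two-level undecimated (stationary) 2-D
Haar transform. Every one of the eight sub-bands (LL/LH/HL/HH at levels 1
and 2) is inverse-reconstructed alone — all other sub-bands zeroed — back to
the original grid, yielding eight channel images the same size as the input.
Each channel is then discretized within the lesion mask and run through the
47-feature texture panel: 8 x 47 = 376 wavelet features, which together with
the 47 original-channel features complete the 423-feature vector.

A single-level 2-D transform has only four sub-bands; the two-level
stationary scheme is the natural reading of an "eight reconstructed images,
same size as the original" protocol for single-slice ROIs, and its level-1
sub-band reconstructions still sum exactly to the input (linearity of the
filter bank).
"""

from __future__ import annotations

import numpy as np
import pywt

from .preprocess import PhantomImage, RoiMask, discretize
from .texture import channel_feature_set

#: fixed, versioned channel order
CHANNEL_NAMES = ("L1.LL", "L1.LH", "L1.HL", "L1.HH",
                 "L2.LL", "L2.LH", "L2.HL", "L2.HH")


def _pad_to_multiple(arr: np.ndarray, m: int) -> tuple[np.ndarray, tuple[int, int]]:
    pr = (-arr.shape[0]) % m
    pc = (-arr.shape[1]) % m
    if pr or pc:
        arr = np.pad(arr, ((0, pr), (0, pc)), mode="symmetric")
    return arr, (pr, pc)


def haar_channels(image: PhantomImage | np.ndarray) -> dict[str, np.ndarray]:
    """Eight single-sub-band reconstructions of the two-level stationary
    Haar transform, each shape-equal to the input.

    The stationary transform needs dimensions divisible by 4; the image is
    symmetrically padded and the reconstructions cropped back.
    """
    pixels = image.pixels if isinstance(image, PhantomImage) else np.asarray(image, float)
    if pixels.ndim != 2 or min(pixels.shape) < 4:
        raise ValueError("haar_channels needs a 2-D image of at least 4x4")
    padded, (pr, pc) = _pad_to_multiple(pixels, 4)
    coeffs = pywt.swt2(padded, "haar", level=2, norm=True)
    # pywt returns the coarsest level first: coeffs[0] = level 2, coeffs[1] = level 1
    (a2, d2), (a1, d1) = coeffs
    z = np.zeros_like(padded)

    def recon(lvl2, lvl1):
        return pywt.iswt2([lvl2, lvl1], "haar", norm=True)

    zero3 = (z, z, z)
    out = {
        # L1.LL: smooth part = everything except the level-1 details
        "L1.LL": recon((a2, d2), (z, zero3)),
        "L1.LH": recon((z, zero3), (z, (d1[0], z, z))),
        "L1.HL": recon((z, zero3), (z, (z, d1[1], z))),
        "L1.HH": recon((z, zero3), (z, (z, z, d1[2]))),
        "L2.LL": recon((a2, zero3), (z, zero3)),
        "L2.LH": recon((z, (d2[0], z, z)), (z, zero3)),
        "L2.HL": recon((z, (z, d2[1], z)), (z, zero3)),
        "L2.HH": recon((z, (z, z, d2[2])), (z, zero3)),
    }
    nr, nc = pixels.shape
    return {k: v[:nr, :nc] for k, v in out.items()}


def wavelet_feature_set(
    channels: dict[str, np.ndarray],
    mask: RoiMask | np.ndarray,
    n_bins: int = 64,
) -> dict[str, float]:
    """376 features: each channel independently discretized within the mask
    (same range-relative rule as the original channel) then run through the
    47-feature panel."""
    maskarr = mask.data if isinstance(mask, RoiMask) else np.asarray(mask, bool)
    out: dict[str, float] = {}
    for name in CHANNEL_NAMES:
        ch = channels[name]
        if ch.shape != maskarr.shape:
            raise ValueError("channel and mask shapes differ")
        roi = discretize(ch, maskarr, n_bins=n_bins, channel=name)
        out.update(channel_feature_set(roi, name))
    assert len(out) == 376
    return out


def full_feature_vector(
    image: PhantomImage,
    mask: RoiMask,
    n_bins: int = 64,
) -> dict[str, float]:
    """The complete 423-feature vector for one preprocessed case:
    47 original-channel features + 376 wavelet features, in stable order."""
    roi = discretize(image.pixels, mask.data, n_bins=n_bins, channel="original")
    feats = channel_feature_set(roi, "original")
    feats.update(wavelet_feature_set(haar_channels(image), mask, n_bins=n_bins))
    assert len(feats) == 423
    return feats
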