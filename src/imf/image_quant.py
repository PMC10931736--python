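"""Staining-area and colocalization quantification for micrographs.

Positive-staining quantification (immunohistochemistry / Oil-red-O) is a
single-channel threshold: the fraction of pixels above (or below) an
intensity cutoff, optionally within a foreground mask. Colocalization of a
two-channel immunofluorescence pair is summarized by the Pearson
correlation Rr of pixel intensities and the Manders overlap coefficient
R = sum(S1*S2) / sqrt(sum(S1^2) * sum(S2^2)); R lies in [0, 1] by
Cauchy-Schwarz (1 iff the channels are proportional) and is invariant to
positive rescaling of either channel, while Rr is invariant to affine
rescaling. By default both coefficients are computed over a foreground
mask — the union of each channel's Otsu-thresholded pixels — so empty
background does not inflate the correlation; pass ``mask=False`` for
whole-image statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from skimage.filters import threshold_otsu

__all__ = ["ImagePair", "positive_area_fraction", "pearson_rr", "overlap_r", "default_mask"]


@dataclass
class ImagePair:
    """Two same-shape single-channel intensity rasters with an optional
    boolean foreground mask."""

    channel1: np.ndarray
    channel2: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.channel1 = np.asarray(self.channel1)
        self.channel2 = np.asarray(self.channel2)
        if self.channel1.shape != self.channel2.shape:
            raise ValueError("channels must have identical dimensions")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.channel1.shape:
                raise ValueError("mask must match the image shape")


def positive_area_fraction(
    image: np.ndarray,
    threshold: float,
    polarity: Literal["above", "below"] = "above",
    mask: np.ndarray | None = None,
) -> float:
    """Fraction of (masked) pixels strictly above/below the intensity cutoff."""
    image = np.asarray(image)
    if polarity not in ("above", "below"):
        raise ValueError(f"unknown polarity {polarity!r}")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != image.shape:
            raise ValueError("mask must match the image shape")
        if not mask.any():
            raise ValueError("empty mask")
        pixels = image[mask]
    else:
        pixels = image.ravel()
    positive = pixels > threshold if polarity == "above" else pixels < threshold
    return float(positive.mean())


def default_mask(pair: ImagePair) -> np.ndarray:
    """Foreground = union of each channel's Otsu-thresholded pixels."""
    mask = np.zeros(pair.channel1.shape, dtype=bool)
    for ch in (pair.channel1, pair.channel2):
        vals = np.asarray(ch, dtype=float)
        if np.ptp(vals) == 0:
            continue
        mask |= vals > threshold_otsu(vals)
    if not mask.any():
        raise ValueError("both channels are constant; no foreground")
    return mask


def _masked_pixels(pair: ImagePair, mask) -> tuple[np.ndarray, np.ndarray]:
    if mask is False or mask is None and pair.mask is None:
        m = np.ones(pair.channel1.shape, dtype=bool)
    elif mask is None:
        m = pair.mask
    elif mask is True:
        m = pair.mask if pair.mask is not None else default_mask(pair)
    else:
        m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("empty mask")
    return (
        np.asarray(pair.channel1, dtype=float)[m],
        np.asarray(pair.channel2, dtype=float)[m],
    )


def pearson_rr(pair: ImagePair, mask=True) -> float:
    """Pearson correlation of pixel intensities over the mask.

    ``mask=True`` uses the pair's mask (or the Otsu default); ``mask=False``
    uses every pixel; an explicit boolean array overrides. A constant
    channel has no defined correlation and raises.
    """
    a, b = _masked_pixels(pair, mask)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant channel: Pearson Rr undefined")
    a = a - a.mean()
    b = b - b.mean()
    return float((a * b).sum() / np.sqrt((a * a).sum() * (b * b).sum()))


def overlap_r(pair: ImagePair, mask=True) -> float:
    """Manders overlap coefficient over the mask; all-zero channels error."""
    a, b = _masked_pixels(pair, mask)
    energy1 = (a * a).sum()
    energy2 = (b * b).sum()
    if energy1 == 0 or energy2 == 0:
        raise ValueError("all-zero channel: overlap coefficient undefined")
    return float((a * b).sum() / np.sqrt(energy1 * energy2))
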