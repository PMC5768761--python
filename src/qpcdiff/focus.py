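"""Entropy-based autofocus: pick the sharpest plane of a focal stack.

Focused images carry more fine texture, hence higher local gray-level
entropy, than defocused ones; the best plane is the one maximising the mean
of a local Shannon-entropy filter (9 x 9 neighbourhood by default).

Implementation notes: the image is quantized to ``n_bins`` gray levels over
its min-max range before histogramming (the filter is defined on discrete
levels); borders use replicate padding so the entropy map keeps the full
image size; counts are accumulated with integer-exact summed-area tables,
so the map agrees bit-for-bit with a naive per-pixel histogram.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .config import FocalStack, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class FocusResult:
    best_index: int
    mean_entropies: list[float]


def quantize(image: np.ndarray, n_bins: int) -> np.ndarray:
    """Map an image to integer gray levels 0..n_bins-1 over its min-max range."""
    img = np.asarray(image, dtype=float)
    lo, hi = img.min(), img.max()
    if hi == lo:
        return np.zeros(img.shape, dtype=np.int64)
    idx = np.floor((img - lo) / (hi - lo) * n_bins).astype(np.int64)
    return np.clip(idx, 0, n_bins - 1)


def local_entropy_map(image: np.ndarray, window: int = 9,
                      n_bins: int = 256) -> np.ndarray:
    """Shannon entropy (bits) of the gray-level histogram around each pixel.

    Values lie in [0, log2(min(n_bins, window^2))]; a constant image maps
    to zero everywhere.
    """
    if window % 2 == 0 or window < 3:
        raise ValidationError("window must be odd and >= 3")
    if n_bins < 2:
        raise ValidationError("n_bins must be >= 2")
    levels = quantize(image, n_bins)
    pad = window // 2
    padded = np.pad(levels, pad, mode="edge")
    h, w = levels.shape
    n = window * window
    entropy = np.zeros((h, w))
    # one summed-area table per gray level actually present; counts are
    # integers so the float64 cumulative sums are exact
    for lvl in np.unique(levels):
        ind = (padded == lvl).astype(np.float64)
        sat = ind.cumsum(0).cumsum(1)
        sat = np.pad(sat, ((1, 0), (1, 0)))
        counts = (sat[window:, window:] - sat[:-window, window:]
                  - sat[window:, :-window] + sat[:-window, :-window])
        p = counts / n
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(p > 0, -p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
        entropy += term
    return entropy


def best_focus(stack: FocalStack, window: int = 9,
               n_bins: int = 256) -> FocusResult:
    """Select the plane with the highest mean local entropy.

    Ties are broken in favour of the lowest index (and logged).
    """
    if len(stack) == 0:
        raise ValidationError("empty focal stack")
    means = [float(local_entropy_map(img, window, n_bins).mean())
             for img in stack.images]
    best = int(np.argmax(means))
    if sum(np.isclose(m, means[best]) for m in means) > 1:
        logger.info("mean-entropy tie at planes %s; keeping lowest index",
                    [i for i, m in enumerate(means)
                     if np.isclose(m, means[best])])
    return FocusResult(best_index=best, mean_entropies=means)
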