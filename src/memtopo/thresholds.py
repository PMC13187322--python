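"""Automatic histogram thresholds.

Otsu comes from scikit-image; the moment-preserving ("Moments") method is
implemented here following Tsai's bilevel construction on a 256-bin
histogram, matching the ImageJ auto-threshold dialect: the threshold is the
first bin whose cumulative normalised histogram exceeds the preserved
background fraction p0.  Thresholds are returned in image intensity units
and are applied with a strict ``>`` comparison.
"""

from __future__ import annotations

import numpy as np
from skimage.filters import threshold_otsu

__all__ = ["moments_threshold", "moments_threshold_bin", "auto_threshold"]

N_BINS = 256


def histogram_256(image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """256-bin histogram of an image plus bin upper edges."""
    image = np.asarray(image, dtype=np.float64)
    lo, hi = float(image.min()), float(image.max())
    if hi <= lo:
        hi = lo + 1.0
    counts, edges = np.histogram(image, bins=N_BINS, range=(lo, hi))
    return counts.astype(np.float64), edges


def moments_threshold_bin(counts: np.ndarray) -> int:
    """Tsai moment-preserving threshold bin for a histogram of counts.

    Finds the bilevel image (fractions p0/p1 at grey values z0/z1) whose
    first three moments match the histogram's, then returns the first bin
    index at which the cumulative fraction exceeds p0.
    """
    counts = np.asarray(counts, dtype=np.float64)
    total = counts.sum()
    if total <= 0:
        raise ValueError("empty histogram")
    p = counts / total
    levels = np.arange(counts.size, dtype=np.float64)
    m1 = float(np.sum(p * levels))
    m2 = float(np.sum(p * levels**2))
    m3 = float(np.sum(p * levels**3))
    cd = m2 - m1 * m1
    if cd <= 0:  # degenerate (single-level) histogram
        return int(np.argmax(counts))
    c0 = (-m2 * m2 + m1 * m3) / cd
    c1 = (-m3 + m2 * m1) / cd
    disc = max(c1 * c1 - 4.0 * c0, 0.0)
    z0 = 0.5 * (-c1 - np.sqrt(disc))
    z1 = 0.5 * (-c1 + np.sqrt(disc))
    if z1 == z0:
        return int(np.argmax(counts))
    p0 = (z1 - m1) / (z1 - z0)
    csum = np.cumsum(p)
    # tie tolerance: an exactly two-level histogram yields csum == p0 at the
    # background bin and must still split there
    above = np.nonzero(csum > p0 - 1e-9)[0]
    return int(above[0]) if above.size else counts.size - 1


def moments_threshold(image: np.ndarray) -> float:
    """Moments threshold of an image, in intensity units (mask: image > t)."""
    counts, edges = histogram_256(image)
    t_bin = moments_threshold_bin(counts)
    return float(edges[t_bin + 1])


def auto_threshold(image: np.ndarray, method: str, fixed: float | None = None) -> float:
    """Dispatch to the configured threshold method; returns intensity value."""
    if method not in ("otsu", "moments", "fixed"):
        raise ValueError(f"unknown threshold method {method!r}")
    image = np.asarray(image, dtype=np.float64)
    if method == "fixed":
        if fixed is None:
            raise ValueError("fixed threshold requested but no value configured")
        return float(fixed)
    if image.max() <= image.min():
        return float(image.max())  # constant image: nothing above threshold
    if method == "otsu":
        return float(threshold_otsu(image, nbins=N_BINS))
    return moments_threshold(image)
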