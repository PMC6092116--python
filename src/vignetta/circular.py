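"""Circular statistics for axial (orientation, mod-180) data."""

from __future__ import annotations

import numpy as np

__all__ = [
    "axial_difference_deg",
    "median_absolute_axial_difference",
    "circular_correlation",
]


def axial_difference_deg(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Signed orientation difference a - b wrapped to (-90, 90] degrees."""
    d = (np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 180.0
    return np.where(d > 90.0, d - 180.0, d)


def median_absolute_axial_difference(a: np.ndarray, b: np.ndarray) -> float:
    """Median of |a - b| on the axial circle, in [0, 90] degrees."""
    return float(np.median(np.abs(axial_difference_deg(a, b))))


def circular_correlation(a_deg: np.ndarray, b_deg: np.ndarray) -> float:
    """Fisher-Lee circular correlation of two orientation samples.

    Orientations (degrees, mod 180) are doubled onto the full circle before
    applying the Fisher-Lee statistic

        T = sum_{i<j} sin(ai - aj) sin(bi - bj)
            / sqrt(sum_{i<j} sin^2(ai - aj) * sum_{i<j} sin^2(bi - bj))

    which is invariant to rotating either sample by a constant.
    """
    a = np.deg2rad(2.0 * np.asarray(a_deg, dtype=float))
    b = np.deg2rad(2.0 * np.asarray(b_deg, dtype=float))
    if a.shape != b.shape:
        raise ValueError("samples must have equal length")
    if a.size < 3:
        raise ValueError("need at least 3 observations")
    sa = np.sin(a[:, None] - a[None, :])
    sb = np.sin(b[:, None] - b[None, :])
    num = np.sum(np.triu(sa * sb, k=1))
    den = np.sqrt(np.sum(np.triu(sa**2, k=1)) * np.sum(np.triu(sb**2, k=1)))
    if den == 0:
        raise ValueError("degenerate sample (all angles equal)")
    return float(num / den)
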