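"""Small shared numerics helpers."""

from __future__ import annotations

import numpy as np


def fwhm_1d(profile: np.ndarray, spacing: float = 1.0) -> float:
    """Full width at half maximum of a 1D profile, linearly interpolated."""
    p = np.asarray(profile, dtype=float)
    p = p - p.min()
    peak = p.argmax()
    half = p[peak] / 2.0
    if p[peak] <= 0:
        return np.nan

    def cross(idx_range):
        prev = peak
        for i in idx_range:
            if p[i] < half:
                # linear interpolation between i and prev
                frac = (p[prev] - half) / (p[prev] - p[i])
                return prev + frac * (i - prev)
            prev = i
        return idx_range[-1]

    left = cross(range(peak, -1, -1))
    right = cross(range(peak, len(p)))
    return abs(right - left) * spacing


def volume_fwhm(volume: np.ndarray, spacing: float = 1.0):
    """FWHM along each axis through the global maximum; (z, y, x) order."""
    v = np.asarray(volume, dtype=float)
    zc, yc, xc = np.unravel_index(v.argmax(), v.shape)
    return (
        fwhm_1d(v[:, yc, xc], spacing),
        fwhm_1d(v[zc, :, xc], spacing),
        fwhm_1d(v[zc, yc, :], spacing),
    )
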