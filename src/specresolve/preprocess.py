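"""Smoothing and differentiation shared by both resolution methods.

Every spectrum is first Savitzky–Golay smoothed (raw S′ → S) so that the
gradient reflects genuine spectral structure rather than single-channel
detector noise, then differentiated channel-by-channel (Δpixel = 1), and
the gradient itself is smoothed again with the same filter, yielding the
gradient signal Δ used by both methods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

__all__ = ["SmoothingParams", "smooth", "gradient", "smooth_gradient"]


@dataclass(frozen=True)
class SmoothingParams:
    """Savitzky–Golay filter settings.

    The defaults (window 9 channels, quadratic) preserve lines whose FWHM
    spans at least a handful of channels — the narrow-band probes targeted
    here (FWHM < 20 nm, i.e. tens of channels on a typical grating) are far
    wider — while flattening single-channel noise.
    """

    window_length: int = 9
    poly_order: int = 2

    def __post_init__(self) -> None:
        if self.window_length < 1 or self.window_length % 2 == 0:
            raise ValueError("window_length must be a positive odd integer")
        if not 0 <= self.poly_order < self.window_length:
            raise ValueError("poly_order must satisfy 0 <= poly_order < window_length")


def smooth(spectrum: np.ndarray, params: SmoothingParams = SmoothingParams()) -> np.ndarray:
    """Savitzky–Golay smoothing, S′ → S.

    Length-preserving; edges are handled by evaluating the local polynomial
    fit (no padding), so polynomials of degree ≤ poly_order pass through
    unchanged at interior points.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    if spectrum.ndim != 1:
        raise ValueError("spectrum must be 1-D")
    if spectrum.size < params.window_length:
        raise ValueError(
            f"too short to smooth: length {spectrum.size} < window {params.window_length}"
        )
    return savgol_filter(spectrum, params.window_length, params.poly_order, mode="interp")


def gradient(spectrum: np.ndarray) -> np.ndarray:
    """Per-channel slope Δcounts/Δpixel with Δpixel = 1.

    Central differences at interior channels, one-sided at the two ends;
    the output has the same length as the input.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    if spectrum.size < 2:
        raise ValueError("too short: need at least 2 channels to differentiate")
    return np.gradient(spectrum)


def smooth_gradient(
    spectrum_raw: np.ndarray, params: SmoothingParams = SmoothingParams()
) -> tuple[np.ndarray, np.ndarray]:
    """Return (S, Δ): the smoothed spectrum and the smoothed gradient.

    Δ = smooth(gradient(smooth(S′))) — the same filter settings are applied
    before and after differentiation.
    """
    s = smooth(spectrum_raw, params)
    return s, smooth(gradient(s), params)
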