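"""Images, profiles and signal-to-background metrics.

Per-pixel signals (raw S, comparator X, gradient contrast L(I), resolved
L(II), baseline B) become intensity images by integrating over the whole
spectral range or inside a spectral gate keyed to one probe's emission
band. Signal-to-background is the max/min of an intensity profile; a zero
background with nonzero signal is reported as infinite contrast via an
explicit flag, never as a floating-point infinity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectral_io import SpectralCube, WavelengthCalibration

__all__ = [
    "SpectralGate",
    "IntensityImage",
    "RGBComposite",
    "SignalToBackground",
    "integrate_image",
    "threshold_subtract",
    "experimental_background",
    "intensity_profile",
    "diagonal_profile",
    "signal_to_background",
    "rgb_composite",
]


@dataclass(frozen=True)
class SpectralGate:
    """Wavelength window [lo_nm, hi_nm] keyed to one emission band."""

    label: str
    lo_nm: float
    hi_nm: float

    def __post_init__(self) -> None:
        if not self.lo_nm < self.hi_nm:
            raise ValueError("gate requires lo_nm < hi_nm")

    def channel_indices(self, calibration: WavelengthCalibration) -> np.ndarray:
        """0-based channels whose wavelength lies in [lo, hi] (bounds included)."""
        wl = calibration.wavelength_nm
        if self.hi_nm < wl[0] or self.lo_nm > wl[-1]:
            raise ValueError(
                f"gate out of range: [{self.lo_nm}, {self.hi_nm}] nm outside "
                f"calibration [{wl[0]:.1f}, {wl[-1]:.1f}] nm"
            )
        return calibration.channels_in_band(self.lo_nm, self.hi_nm)


@dataclass
class IntensityImage:
    """One non-negative scalar per pixel plus provenance (signal and gate)."""

    values: np.ndarray  # (H, W)
    signal: str = ""
    gate: SpectralGate | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("image values must be 2-D")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError("image values must be finite and >= 0")
        self.values = v

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]


def integrate_image(
    signal_cube: np.ndarray | SpectralCube,
    gate: SpectralGate | None = None,
    calibration: WavelengthCalibration | None = None,
    signal: str = "",
) -> IntensityImage:
    """Per-pixel sum over the gated channels (whole range when no gate).

    ``signal_cube`` is an (H, W, N) array of any per-pixel signal, or a
    :class:`SpectralCube` (whose calibration is then used for gating).
    """
    if isinstance(signal_cube, SpectralCube):
        calibration = signal_cube.calibration
        data = signal_cube.counts
    else:
        data = np.asarray(signal_cube, dtype=float)
    if gate is None:
        vals = data.sum(axis=2)
    else:
        if calibration is None:
            raise ValueError("gating requires a calibration")
        idx = gate.channel_indices(calibration)
        vals = data[:, :, idx].sum(axis=2)
    # derived signals (e.g. the baseline B) may undershoot zero by a hair
    # from the smoothing; an intensity image is non-negative by definition
    return IntensityImage(values=np.maximum(vals, 0.0), signal=signal, gate=gate)


def threshold_subtract(spectrum_raw: np.ndarray, threshold: float) -> np.ndarray:
    """Comparator X = max(S′ − T, 0), channel by channel.

    The plain constant-threshold subtraction found in any imaging software.
    It cannot remove structured background — broad fluorophore emission
    above T survives — and is provided only as a baseline of comparison for
    the gradient methods.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return np.maximum(np.asarray(spectrum_raw, dtype=float) - threshold, 0.0)


def experimental_background(cube: SpectralCube, region: list[tuple[int, int]]) -> np.ndarray:
    """Mean spectrum B_exp over a probe-free pixel region [(x, y), …]."""
    if len(region) == 0:
        raise ValueError("experimental background region is empty")
    spectra = [cube.pixel(x, y) for x, y in region]
    return np.mean(spectra, axis=0)


def intensity_profile(
    image: IntensityImage, line: list[tuple[int, int]]
) -> np.ndarray:
    """Image values sampled along an ordered pixel path [(x, y), …]."""
    vals = np.empty(len(line), dtype=float)
    for k, (x, y) in enumerate(line):
        if not (0 <= x < image.width and 0 <= y < image.height):
            raise IndexError(f"profile coordinate ({x}, {y}) out of bounds")
        vals[k] = image.values[y, x]
    return vals


def diagonal_profile(image: IntensityImage) -> np.ndarray:
    """Main-diagonal preset, pixels (i, i), for square images."""
    n = min(image.width, image.height)
    return intensity_profile(image, [(i, i) for i in range(n)])


@dataclass(frozen=True)
class SignalToBackground:
    """Signal = profile maximum, background = profile minimum.

    ``infinite`` is True when the background is exactly zero while signal
    is positive; ``ratio`` is None in that case.
    """

    signal: float
    background: float
    infinite: bool
    ratio: float | None

    def __str__(self) -> str:  # report form: "2.37e+04:0 (infinite)"
        tail = " (infinite contrast)" if self.infinite else ""
        return f"{self.signal:.3g}:{self.background:.3g}{tail}"


def signal_to_background(profile: np.ndarray) -> SignalToBackground:
    """Max/min of an intensity profile, with explicit infinite-contrast flag."""
    profile = np.asarray(profile, dtype=float)
    if profile.size == 0:
        raise ValueError("profile is empty")
    sig = float(profile.max())
    bg = float(profile.min())
    if bg == 0.0:
        return SignalToBackground(sig, bg, infinite=sig > 0, ratio=None)
    return SignalToBackground(sig, bg, infinite=False, ratio=sig / bg)


@dataclass
class RGBComposite:
    """Three intensity images merged after independent min–max scaling."""

    rgb: np.ndarray  # (H, W, 3) in [0, 1]
    normalization: dict = field(default_factory=dict)  # slot -> (min, max)


def rgb_composite(
    red: IntensityImage | None = None,
    green: IntensityImage | None = None,
    blue: IntensityImage | None = None,
) -> RGBComposite:
    """Merge up to three images; each slot is min–max normalized on its own
    so dim channels (e.g. the background B in green) remain visible next to
    bright probe channels. Empty slots are zero."""
    imgs = {"red": red, "green": green, "blue": blue}
    shapes = {im.values.shape for im in imgs.values() if im is not None}
    if not shapes:
        raise ValueError("at least one image required")
    if len(shapes) > 1:
        raise ValueError("geometry mismatch between composite channels")
    h, w = shapes.pop()
    out = np.zeros((h, w, 3), dtype=float)
    norms: dict[str, tuple[float, float]] = {}
    for k, (slot, im) in enumerate(imgs.items()):
        if im is None:
            continue
        lo, hi = float(im.values.min()), float(im.values.max())
        norms[slot] = (lo, hi)
        if hi > lo:
            out[:, :, k] = (im.values - lo) / (hi - lo)
    return RGBComposite(rgb=out, normalization=norms)
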