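"""Spectral-cube containers and on-disk dialects.

A spectral cube is a raster of W×H pixels in which every pixel holds a full
emission spectrum of ``channel_count`` detector channels. Two interchange
dialects are supported:

* a text container — UTF-8 CSV with header ``x,y,c1..cN`` (one pixel per
  row) plus a JSON sidecar ``<path>.meta.json`` holding the wavelength
  calibration and acquisition metadata;
* a multi-page grayscale TIFF, one page per spectral channel, with the same
  JSON sidecar.

Both dialects round-trip integer counts losslessly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "WavelengthCalibration",
    "SpectralCube",
    "default_calibration",
    "read_cube",
    "write_cube",
    "read_signal_cube",
    "write_signal_cube",
    "write_spectrum_csv",
    "MalformedCubeError",
    "CalibrationError",
]

#: wavelength span assumed when no calibration is supplied: linear
#: 500–760 nm, the region selected by a 300 g/mm grating centred at 500 nm.
DEFAULT_WAVELENGTH_SPAN_NM = (500.0, 760.0)
DEFAULT_CHANNEL_COUNT = 1340


class MalformedCubeError(ValueError):
    """Raised when an on-disk cube violates the dialect contract."""


class CalibrationError(ValueError):
    """Raised for missing, mismatched or non-monotonic calibrations."""


@dataclass(frozen=True)
class WavelengthCalibration:
    """Monotonic map from detector channel to emission wavelength.

    Parameters
    ----------
    wavelength_nm:
        Strictly increasing wavelengths, one per channel, in nanometres.

    Channel indices are 1-based in all user-facing output; internally the
    array is addressed 0-based.
    """

    wavelength_nm: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelength_nm, dtype=float)
        object.__setattr__(self, "wavelength_nm", wl)
        if wl.ndim != 1 or wl.size < 8:
            raise CalibrationError(
                "bad calibration: need at least 8 channels to smooth and "
                f"differentiate meaningfully, got {wl.size}"
            )
        if not np.all(np.isfinite(wl)) or np.any(np.diff(wl) <= 0):
            raise CalibrationError(
                "bad calibration: wavelengths must be finite and strictly increasing"
            )
        if wl[0] <= 0:
            raise CalibrationError("bad calibration: wavelengths must be positive")

    @property
    def channel_count(self) -> int:
        return int(self.wavelength_nm.size)

    @property
    def wavenumber_cm1(self) -> np.ndarray:
        """Per-channel wavenumber 1e7 / λ(nm), in cm⁻¹ (strictly decreasing)."""
        return 1e7 / self.wavelength_nm

    def channels_in_band(self, lo_nm: float, hi_nm: float) -> np.ndarray:
        """0-based channel indices whose wavelength lies in [lo_nm, hi_nm]."""
        wl = self.wavelength_nm
        return np.flatnonzero((wl >= lo_nm) & (wl <= hi_nm))


def default_calibration(channel_count: int = DEFAULT_CHANNEL_COUNT) -> WavelengthCalibration:
    """Linear 500–760 nm calibration over ``channel_count`` channels."""
    lo, hi = DEFAULT_WAVELENGTH_SPAN_NM
    return WavelengthCalibration(np.linspace(lo, hi, channel_count))


@dataclass
class SpectralCube:
    """W×H raster of emission spectra (the raw data S′ of every pixel).

    ``counts`` has shape (height, width, channel_count) and is finite and
    non-negative. ``integration_time_s`` is carried as acquisition metadata.
    """

    counts: np.ndarray
    calibration: WavelengthCalibration
    integration_time_s: float = 1.0
    extra_metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 3:
            raise MalformedCubeError(
                f"malformed cube: counts must be (height, width, channels), got shape {c.shape}"
            )
        if c.shape[2] != self.calibration.channel_count:
            raise CalibrationError(
                "calibration mismatch: cube has "
                f"{c.shape[2]} channels, calibration {self.calibration.channel_count}"
            )
        if not np.all(np.isfinite(c)) or np.any(c < 0):
            raise MalformedCubeError("malformed cube: counts must be finite and >= 0")
        self.counts = c

    @property
    def height(self) -> int:
        return self.counts.shape[0]

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def channel_count(self) -> int:
        return self.counts.shape[2]

    def pixel(self, x: int, y: int) -> np.ndarray:
        """Spectrum at pixel column x, row y (0-based)."""
        return self.counts[y, x]

    def as_matrix(self) -> np.ndarray:
        """Flatten to (n_pixels, channel_count), row-major over (y, x)."""
        return self.counts.reshape(-1, self.channel_count)


# ---------------------------------------------------------------------------
# sidecar


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def _write_sidecar(cube: SpectralCube, path: Path) -> None:
    meta = {
        "channel_count": cube.channel_count,
        "wavelength_nm": cube.calibration.wavelength_nm.tolist(),
        "integration_time_s": cube.integration_time_s,
        "width": cube.width,
        "height": cube.height,
        **cube.extra_metadata,
    }
    _sidecar_path(path).write_text(json.dumps(meta), encoding="utf-8")


def _read_sidecar(path: Path, n_channels: int) -> tuple[WavelengthCalibration, float, dict]:
    sc = _sidecar_path(path)
    if not sc.exists():
        return default_calibration(n_channels), 1.0, {}
    meta = json.loads(sc.read_text(encoding="utf-8"))
    declared = int(meta.get("channel_count", n_channels))
    if declared != n_channels:
        raise CalibrationError(
            f"calibration mismatch: sidecar declares {declared} channels, data has {n_channels}"
        )
    wl = meta.get("wavelength_nm")
    cal = (
        WavelengthCalibration(np.asarray(wl, dtype=float))
        if wl is not None
        else default_calibration(n_channels)
    )
    if cal.channel_count != n_channels:
        raise CalibrationError(
            "calibration mismatch: sidecar wavelength_nm length "
            f"{cal.channel_count} != channel count {n_channels}"
        )
    t = float(meta.get("integration_time_s", 1.0))
    extra = {
        k: v
        for k, v in meta.items()
        if k not in {"channel_count", "wavelength_nm", "integration_time_s", "width", "height"}
    }
    return cal, t, extra


# ---------------------------------------------------------------------------
# readers / writers


def write_cube(cube: SpectralCube, path: str | Path, format: str = "text") -> Path:
    """Serialize a cube; lossless for integer counts in both dialects."""
    return write_signal_cube(
        cube.counts, cube.calibration, path, format, cube.integration_time_s, cube.extra_metadata
    )


def write_signal_cube(
    values: np.ndarray,
    calibration: WavelengthCalibration,
    path: str | Path,
    format: str = "text",
    integration_time_s: float = 1.0,
    extra_metadata: dict | None = None,
) -> Path:
    """Serialize any per-pixel signal array (H, W, N) in the cube dialects.

    Unlike :func:`write_cube` this accepts derived signals (baselines,
    gradients) that may dip below zero.
    """
    values = np.asarray(values)
    path = Path(path)
    if values.ndim != 3 or values.shape[2] != calibration.channel_count:
        raise CalibrationError("calibration mismatch: array channels != calibration")
    h, w, n = values.shape
    if format == "text":
        header = ["x", "y"] + [f"c{i}" for i in range(1, n + 1)]
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(",".join(header) + "\n")
            for y in range(h):
                for x in range(w):
                    vals = ",".join(_fmt(v) for v in values[y, x])
                    fh.write(f"{x},{y},{vals}\n")
    elif format == "tiff":
        # page-per-channel grayscale stack
        pages = np.moveaxis(values, 2, 0)
        if (
            np.issubdtype(pages.dtype, np.integer)
            and pages.min(initial=0) >= 0
            and pages.max(initial=0) < 2**16
        ):
            pages = pages.astype(np.uint16)
        else:
            pages = pages.astype(np.float32)
        tifffile.imwrite(path, pages, photometric="minisblack")
    else:
        raise ValueError(f"unknown cube format {format!r}")
    meta_cube = SpectralCube.__new__(SpectralCube)  # bypass >=0 validation
    meta_cube.counts = values
    meta_cube.calibration = calibration
    meta_cube.integration_time_s = integration_time_s
    meta_cube.extra_metadata = extra_metadata or {}
    _write_sidecar(meta_cube, path)
    return path


def read_signal_cube(path: str | Path, format: str | None = None):
    """Read a signal array written by :func:`write_signal_cube` without the
    raw-cube non-negativity validation. Returns (values, calibration)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "tiff" if path.suffix.lower() in {".tif", ".tiff"} else "text"
    if format == "text":
        values = _read_text_counts(path)
    elif format == "tiff":
        pages = tifffile.imread(path)
        if pages.ndim == 2:
            pages = pages[None]
        values = np.moveaxis(np.asarray(pages), 0, 2)
    else:
        raise ValueError(f"unknown cube format {format!r}")
    cal, _, _ = _read_sidecar(path, values.shape[2])
    return values, cal


def _fmt(v) -> str:
    f = float(v)
    if f.is_integer() and abs(f) < 2**53:
        return str(int(f))
    return repr(f)


def read_cube(path: str | Path, format: str | None = None) -> SpectralCube:
    """Read a cube in either dialect; ``format`` is inferred from the suffix
    when not given (.tif/.tiff → TIFF, otherwise text container)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "tiff" if path.suffix.lower() in {".tif", ".tiff"} else "text"
    if format == "text":
        counts = _read_text_counts(path)
    elif format == "tiff":
        pages = tifffile.imread(path)
        if pages.ndim == 2:
            pages = pages[None]
        counts = np.moveaxis(np.asarray(pages), 0, 2)
    else:
        raise ValueError(f"unknown cube format {format!r}")
    cal, t, extra = _read_sidecar(path, counts.shape[2])
    return SpectralCube(counts=counts, calibration=cal, integration_time_s=t, extra_metadata=extra)


def _read_text_counts(path: Path) -> np.ndarray:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas message varies
        raise MalformedCubeError(f"malformed cube: {exc}") from exc
    if df.shape[1] < 3 or list(df.columns[:2]) != ["x", "y"]:
        raise MalformedCubeError("malformed cube: expected header x,y,c1..cN")
    if df.isna().any().any():
        raise MalformedCubeError("malformed cube: missing or short rows")
    n = df.shape[1] - 2
    xs = df["x"].to_numpy(dtype=int)
    ys = df["y"].to_numpy(dtype=int)
    w, h = xs.max() + 1, ys.max() + 1
    if len(df) != w * h or len(set(zip(xs.tolist(), ys.tolist()))) != w * h:
        raise MalformedCubeError("malformed cube: pixel rows do not tile a full raster")
    counts = np.empty((h, w, n), dtype=float)
    body = df.iloc[:, 2:].to_numpy(dtype=float)
    counts[ys, xs] = body
    return counts


def write_spectrum_csv(
    path: str | Path, calibration: WavelengthCalibration, counts: np.ndarray
) -> Path:
    """Export a single spectrum as two-column CSV (wavelength_nm, counts)."""
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (calibration.channel_count,):
        raise CalibrationError("calibration mismatch: spectrum length != channel count")
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("wavelength_nm,counts\n")
        for wl, c in zip(calibration.wavelength_nm, counts):
            fh.write(f"{_fmt(wl)},{_fmt(c)}\n")
    return path
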