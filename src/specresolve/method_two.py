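"""Method II: anchor-point baseline construction and non-negative residual
extraction — the zero-background ("infinite contrast") resolver.

Per pixel, the smoothed gradient Δ is thresholded at ±T1 to locate the
onsets and ends of sharp spectral features (narrow-band probe lines). The
coding pipeline d1 → d2 → d3 converts the thresholded gradient into
onset/end markers; close end→onset pairs (< T2 cm⁻¹ apart) are merged so a
multiplet of vibrational sub-bands counts as one feature; the long-pass
filter edge is recognised and discarded with the width threshold T3; the
first and last channels are added as terminal anchors. The baseline B then
equals the smoothed data S between features and a straight line under each
feature, and the resolved signal is L = max(S − B, 0) — photons that can be
attributed exclusively to the narrow-band probe. Two optional cleanups:
spectra whose total resolved counts fall below T4 are zeroed, and features
whose gradient exceeds ``cosmicthres`` are treated as cosmic rays and
absorbed into the baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .preprocess import SmoothingParams, smooth_gradient
from .spectral_io import SpectralCube, WavelengthCalibration, default_calibration

__all__ = [
    "MethodIIParams",
    "AnchorSet",
    "ResolvedPixel",
    "ResolvedCube",
    "AnchorBaselineResolver",
    "code_d1",
    "code_d2",
    "code_d3",
    "dedupe_anchors",
    "prune_close_pairs",
    "extract_anchors",
    "build_baseline",
    "resolve_method2",
    "resolve_cube",
]

ONSET = 2
END = -2


@dataclass(frozen=True)
class MethodIIParams:
    """Threshold bundle for Method II.

    t1 : gradient threshold, Δcounts/Δpixel. Too low converts noise into
        false features; too high misses band onsets. 5 is robust for
        count levels around a 1 s CCD integration; scale with the photon
        noise (√signal) for much brighter data.
    t2 : minimum end→onset gap in wavenumber (cm⁻¹). Anchor pairs closer
        than this are eliminated, merging vibrational sub-bands of one
        electronic transition into a single feature. Default 200.
    t3 : filter-feature width threshold in channels (None disables). A
        first feature narrower than t3 is the long-pass filter onset and
        is discarded; a wider first feature is a band overlapping the
        filter edge and its onset anchor is relocated. Default 40.
    t4 : optional minimum total resolved counts; spectra with sum(L) below
        it are zeroed (kills residual cosmic-ray fragments). Default 2000.
    cosmicthres : optional gradient threshold (must exceed t1) above which
        a feature is treated as a cosmic-ray spike and dropped from the
        anchor set, absorbing the spike into the baseline. Default 500.
    """

    t1: float = 5.0
    t2: float = 200.0
    t3: int | None = 40
    t4: float | None = 2000.0
    cosmicthres: float | None = 500.0
    smoothing: SmoothingParams = field(default_factory=SmoothingParams)

    def __post_init__(self) -> None:
        if self.t1 <= 0:
            raise ValueError("T1 must be > 0")
        if self.t2 < 0:
            raise ValueError("T2 must be >= 0")
        if self.t3 is not None and self.t3 < 0:
            raise ValueError("T3 must be >= 0 when enabled")
        if self.t4 is not None and self.t4 < 0:
            raise ValueError("T4 must be >= 0 when enabled")
        if self.cosmicthres is not None and self.cosmicthres <= self.t1:
            raise ValueError("cosmicthres must exceed T1 when enabled")


@dataclass(frozen=True)
class AnchorSet:
    """Ordered anchor channel positions (1-based) delimiting sharp features.

    Anchors alternate end/onset starting with the added terminal "end" at
    channel 1 and finishing with the added terminal "onset" at the last
    channel: [end, onset, end, onset, …]. Feature (interpolated) intervals
    are the (onset, end) pairs at positions (2, 3), (4, 5), …; background
    intervals (baseline = data) are the (end, onset) pairs in between. A
    feature still rising at the spectrum end yields an odd-length set whose
    terminal anchor closes the feature.
    """

    positions: tuple[int, ...]
    channel_count: int

    def __post_init__(self) -> None:
        p = self.positions
        if len(p) < 2 or p[0] != 1 or p[-1] != self.channel_count:
            raise ValueError("anchors must start at channel 1 and end at the last channel")
        if any(b <= a for a, b in zip(p, p[1:])):
            raise ValueError("anchor positions must be strictly increasing")

    @property
    def roles(self) -> tuple[str, ...]:
        """Role per anchor: odd list positions are ends, even are onsets."""
        return tuple("end" if i % 2 == 0 else "onset" for i in range(len(self.positions)))

    def feature_intervals(self) -> list[tuple[int, int]]:
        """Closed 1-based (onset, end) intervals interpolated by the baseline."""
        p = self.positions
        return [(p[i], p[i + 1]) for i in range(1, len(p) - 1, 2)]

    def background_intervals(self) -> list[tuple[int, int]]:
        """Closed 1-based (end, onset) intervals where the baseline equals S."""
        p = self.positions
        return [(p[i], p[i + 1]) for i in range(0, len(p) - 1, 2)]


@dataclass
class ResolvedPixel:
    """Aligned per-pixel signals: raw S′, smoothed S, gradient Δ, baseline B
    and resolved L = max(S − B, 0), plus the anchor set used."""

    raw: np.ndarray
    smoothed: np.ndarray
    grad: np.ndarray
    baseline: np.ndarray
    resolved: np.ndarray
    anchors: AnchorSet
    zeroed_by_t4: bool = False
    warnings: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# coding pipeline (gradient → onset/end markers)


def code_d1(delta: np.ndarray, t1: float) -> np.ndarray:
    """Threshold coding: +1 where Δ > T1, −1 where Δ < −T1, else 0.

    Comparisons are strict, so Δ = ±T1 exactly codes to 0.
    """
    delta = np.asarray(delta, dtype=float)
    d1 = np.zeros(delta.shape, dtype=int)
    d1[delta > t1] = 1
    d1[delta < -t1] = -1
    return d1


def code_d2(d1: np.ndarray) -> np.ndarray:
    """Mark the flanks: every 0 adjacent to a ±1 becomes 2."""
    d1 = np.asarray(d1, dtype=int)
    d2 = d1.copy()
    nz = d1 != 0
    near = np.zeros_like(nz)
    near[:-1] |= nz[1:]
    near[1:] |= nz[:-1]
    d2[(d1 == 0) & near] = 2
    return d2


def code_d3(d2: np.ndarray) -> np.ndarray:
    """First difference of d2 (0 prepended), keeping only ±2.

    +2 marks a feature onset, −2 a feature end; everything else is zeroed.
    """
    d2 = np.asarray(d2, dtype=int)
    d3 = np.concatenate(([0], np.diff(d2)))
    d3[(d3 != ONSET) & (d3 != END)] = 0
    return d3


def dedupe_anchors(d3: np.ndarray) -> np.ndarray:
    """Collapse runs of equal markers: of consecutive +2s keep the leftmost,
    of consecutive −2s the rightmost, so surviving markers alternate in sign."""
    d3 = np.asarray(d3, dtype=int).copy()
    idx = np.flatnonzero(d3)
    prev_sign = 0
    prev_pos = -1
    for i in idx:
        s = d3[i]
        if s == prev_sign:
            if s == ONSET:
                d3[i] = 0  # keep the leftmost onset
            else:
                d3[prev_pos] = 0  # keep the rightmost end
                prev_pos = i
        else:
            prev_sign, prev_pos = s, i
    return d3


def prune_close_pairs(
    d3: np.ndarray, calibration: WavelengthCalibration, t2: float
) -> np.ndarray:
    """Eliminate end→onset anchor pairs closer than T2 in wavenumber.

    Merges the two flanking features into one, which removes anchors at
    peak maxima and between the vibrational sub-bands of a multiplet.
    Applied left-to-right with re-evaluation until no pair violates T2.
    """
    d3 = np.asarray(d3, dtype=int).copy()
    wn = calibration.wavenumber_cm1
    changed = True
    while changed:
        changed = False
        idx = np.flatnonzero(d3)
        for a, b in zip(idx, idx[1:]):
            if d3[a] == END and d3[b] == ONSET and abs(wn[a] - wn[b]) < t2:
                d3[a] = 0
                d3[b] = 0
                changed = True
                break
    return d3


# ---------------------------------------------------------------------------
# anchor extraction


def extract_anchors(
    smoothed: np.ndarray,
    delta: np.ndarray,
    params: MethodIIParams = MethodIIParams(),
    calibration: WavelengthCalibration | None = None,
) -> tuple[AnchorSet, list[str]]:
    """Run the full coding pipeline and return the anchor set for one pixel.

    Returns (anchors, warnings). On a degenerate anchor structure the pixel
    falls back to the no-feature anchors [1, N] (baseline = data, L = 0)
    and a warning is recorded.
    """
    smoothed = np.asarray(smoothed, dtype=float)
    n = smoothed.size
    if calibration is None:
        calibration = default_calibration(n)
    if calibration.channel_count != n:
        raise ValueError("calibration mismatch: calibration does not cover the spectrum")

    warn: list[str] = []
    d3 = code_d3(code_d2(code_d1(delta, params.t1)))
    d3 = dedupe_anchors(d3)
    d3 = prune_close_pairs(d3, calibration, params.t2)

    idx = np.flatnonzero(d3)
    markers = [(int(i), int(d3[i])) for i in idx]
    # feature truncated at the spectrum start: its end marker has no onset
    while markers and markers[0][1] == END:
        warn.append("leading end marker dropped (feature truncated at channel 1)")
        markers.pop(0)
    # terminal channels are reserved for the added anchors
    markers = [(i, s) for i, s in markers if 0 < i < n - 1]
    if any(a[1] == b[1] for a, b in zip(markers, markers[1:])):
        warn.append("degenerate anchor structure; falling back to no-feature anchors")
        markers = []

    positions = [1] + [i + 1 for i, _ in markers] + [n]

    if params.t3 is not None and len(markers) >= 2:
        a2, a3 = positions[1], positions[2]
        if a3 - a2 < params.t3:
            # narrow first feature = the long-pass filter onset; discard it
            del positions[1:3]
        else:
            # band overlapping the filter edge: move the onset anchor to the
            # channel before the band maximum where S comes closest to (but
            # stays above) S at the band's end, making the baseline under
            # this band as close to horizontal as possible.
            new_a2 = _relocate_onset(smoothed, a2, a3)
            if new_a2 is not None:
                positions[1] = new_a2

    if params.cosmicthres is not None and len(positions) > 2:
        positions = _drop_cosmic_features(positions, np.abs(delta), params.cosmicthres, warn)

    anchors = AnchorSet(tuple(positions), n)
    return anchors, warn


def _relocate_onset(s: np.ndarray, a2: int, a3: int) -> int | None:
    """P = S − S(Anchor(3)); pick the channel before the band maximum where
    P is minimal but positive (rightmost on ties). 1-based in and out."""
    lo, hi = a2 - 1, a3 - 1  # 0-based
    peak = lo + int(np.argmax(s[lo : hi + 1]))
    p = s[lo:peak] - s[hi]
    pos = np.flatnonzero(p > 0)
    if pos.size == 0:
        return None
    best = pos[p[pos] <= p[pos].min()][-1]
    return int(lo + best + 1)


def _drop_cosmic_features(
    positions: list[int], absdelta: np.ndarray, cosmicthres: float, warn: list[str]
) -> list[int]:
    """Drop (onset, end) pairs whose interval contains |Δ| > cosmicthres."""
    keep = list(positions)
    i = 1
    while i + 1 <= len(keep) - 1:
        on, end = keep[i], keep[i + 1]
        if np.any(absdelta[on - 1 : end] > cosmicthres):
            warn.append(f"cosmic-ray feature dropped at channels {on}-{end}")
            if end == keep[-1]:  # trailing feature closed by the terminal anchor
                del keep[i]
            else:
                del keep[i : i + 2]
        else:
            i += 2
    return keep


# ---------------------------------------------------------------------------
# baseline and resolution


def build_baseline(smoothed: np.ndarray, anchors: AnchorSet) -> np.ndarray:
    """Baseline B: equal to S on end→onset intervals, straight line joining
    S at the anchors across each onset→end feature interval."""
    s = np.asarray(smoothed, dtype=float)
    if anchors.channel_count != s.size:
        raise ValueError("anchors do not match spectrum length")
    b = s.copy()
    for on, end in anchors.feature_intervals():
        lo, hi = on - 1, end - 1
        if hi - lo >= 2:  # line on the open interval; B = S at the anchors
            idx = np.arange(lo + 1, hi)
            b[idx] = s[lo] + ((idx - lo) / (hi - lo)) * (s[hi] - s[lo])
    return b


def resolve_method2(
    spectrum_raw: np.ndarray,
    params: MethodIIParams = MethodIIParams(),
    calibration: WavelengthCalibration | None = None,
) -> ResolvedPixel:
    """Full Method II resolution of one raw spectrum.

    Smooths, differentiates, extracts anchors, builds the baseline and
    returns L = max(S − B, 0); applies the optional cosmic-ray feature
    exclusion and, afterwards, the optional T4 zeroing of dim spectra.
    """
    raw = np.asarray(spectrum_raw, dtype=float)
    s, delta = smooth_gradient(raw, params.smoothing)
    anchors, warn = extract_anchors(s, delta, params, calibration)
    b = build_baseline(s, anchors)
    l = np.maximum(s - b, 0.0)
    zeroed = False
    if params.t4 is not None and l.sum() < params.t4:
        l = np.zeros_like(l)
        zeroed = True
    return ResolvedPixel(
        raw=raw,
        smoothed=s,
        grad=delta,
        baseline=b,
        resolved=l,
        anchors=anchors,
        zeroed_by_t4=zeroed,
        warnings=tuple(warn),
    )


@dataclass
class ResolvedCube:
    """Per-pixel resolution of a whole cube; geometry matches the input."""

    resolved: np.ndarray  # L (method 2) or L(I) (method 1), (H, W, N)
    baseline: np.ndarray | None  # B for method 2, None for method 1
    zeroed_by_t4: np.ndarray | None  # boolean (H, W) mask, method 2 only
    anchors: list[list[AnchorSet]] | None
    warnings: list[tuple[int, int, str]]  # (x, y, message)


def resolve_cube(
    cube: SpectralCube,
    params: MethodIIParams | None = None,
    method: int = 2,
    method1_params=None,
) -> ResolvedCube:
    """Apply Method I or II pixel-by-pixel; pixels are independent.

    Per-pixel failures are recorded as warnings (the pixel's output is
    zeroed) and processing continues.
    """
    from .method_one import MethodIParams, resolve_method1

    h, w, n = cube.counts.shape
    res = np.zeros((h, w, n), dtype=float)
    warn: list[tuple[int, int, str]] = []
    if method == 1:
        p1 = method1_params if method1_params is not None else MethodIParams()
        for y in range(h):
            for x in range(w):
                try:
                    res[y, x] = resolve_method1(cube.counts[y, x], p1)
                except Exception as exc:
                    warn.append((x, y, str(exc)))
        return ResolvedCube(res, None, None, None, warn)
    if method != 2:
        raise ValueError("method must be 1 or 2")
    p2 = params if params is not None else MethodIIParams()
    base = np.zeros((h, w, n), dtype=float)
    zeroed = np.zeros((h, w), dtype=bool)
    anchors: list[list[AnchorSet]] = [[None] * w for _ in range(h)]  # type: ignore[list-item]
    for y in range(h):
        for x in range(w):
            try:
                px = resolve_method2(cube.counts[y, x], p2, cube.calibration)
            except Exception as exc:
                warn.append((x, y, str(exc)))
                base[y, x] = cube.counts[y, x]
                anchors[y][x] = AnchorSet((1, n), n)
                continue
            res[y, x] = px.resolved
            base[y, x] = px.baseline
            zeroed[y, x] = px.zeroed_by_t4
            anchors[y][x] = px.anchors
            for msg in px.warnings:
                warn.append((x, y, msg))
    return ResolvedCube(res, base, zeroed, anchors, warn)


# ---------------------------------------------------------------------------
# estimator front end


class AnchorBaselineResolver(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer applying Method II row-wise.

    ``transform`` maps a matrix of raw spectra, shape
    (n_spectra, n_channels), to the resolved signals L of the same shape;
    :meth:`baselines` returns the per-spectrum baselines B.

    Parameters mirror :class:`MethodIIParams` (pass ``t3=None`` /
    ``t4=None`` / ``cosmicthres=None`` to disable the optional steps);
    ``wavelength_nm`` supplies the channel→wavelength calibration, and
    defaults to the documented linear 500–760 nm map when omitted.
    """

    def __init__(
        self,
        t1: float = 5.0,
        t2: float = 200.0,
        t3: int | None = 40,
        t4: float | None = 2000.0,
        cosmicthres: float | None = 500.0,
        window_length: int = 9,
        poly_order: int = 2,
        wavelength_nm=None,
    ) -> None:
        self.t1 = t1
        self.t2 = t2
        self.t3 = t3
        self.t4 = t4
        self.cosmicthres = cosmicthres
        self.window_length = window_length
        self.poly_order = poly_order
        self.wavelength_nm = wavelength_nm

    def _params(self) -> MethodIIParams:
        return MethodIIParams(
            t1=self.t1,
            t2=self.t2,
            t3=self.t3,
            t4=self.t4,
            cosmicthres=self.cosmicthres,
            smoothing=SmoothingParams(self.window_length, self.poly_order),
        )

    def fit(self, X, y=None):
        X = self._validate(X)
        self._params()
        self.n_features_in_ = X.shape[1]
        self.calibration_ = (
            WavelengthCalibration(np.asarray(self.wavelength_nm, dtype=float))
            if self.wavelength_nm is not None
            else default_calibration(X.shape[1])
        )
        if self.calibration_.channel_count != X.shape[1]:
            raise ValueError("calibration mismatch: wavelength_nm length != n_channels")
        return self

    def transform(self, X) -> np.ndarray:
        return np.vstack([px.resolved for px in self.resolve(X)])

    def baselines(self, X) -> np.ndarray:
        return np.vstack([px.baseline for px in self.resolve(X)])

    def resolve(self, X) -> list[ResolvedPixel]:
        """Full :class:`ResolvedPixel` per row (S′, S, Δ, B, L, anchors)."""
        X = self._validate(X)
        if not hasattr(self, "n_features_in_"):
            raise AttributeError("AnchorBaselineResolver is not fitted; call fit first")
        if X.shape[1] != self.n_features_in_:
            raise ValueError(f"X has {X.shape[1]} channels, expected {self.n_features_in_}")
        p = self._params()
        return [resolve_method2(row, p, self.calibration_) for row in X]

    @staticmethod
    def _validate(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.ndim != 2:
            raise ValueError("X must be (n_spectra, n_channels)")
        if not np.all(np.isfinite(X)):
            raise ValueError("X must be finite")
        return X
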