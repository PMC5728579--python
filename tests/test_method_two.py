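import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import specresolve as sr
from specresolve.method_two import (
    AnchorSet,
    MethodIIParams,
    build_baseline,
    code_d1,
    code_d2,
    code_d3,
    dedupe_anchors,
    extract_anchors,
    prune_close_pairs,
    resolve_cube,
    resolve_method2,
)

NO_OPTIONS = MethodIIParams(t3=None, t4=None, cosmicthres=None)


# ---------------------------------------------------------------------------
# coding pipeline


class TestCoding:
    def test_d1_worked_example(self, printed_gradient):
        expected = [0, 0, 0, 1, 1, 1, 0, 0, -1, -1, -1, 0, 0, 0, 1, 1, 1]
        assert code_d1(printed_gradient, 5).tolist() == expected

    def test_d1_zero_gradient(self):
        assert not code_d1(np.zeros(10), 5).any()

    def test_d1_boundary_is_strict(self):
        """Δ = ±T1 exactly codes to 0 (greater-than / lower-than)."""
        assert code_d1(np.array([5.0, -5.0, 5.0001, -5.0001]), 5).tolist() == [0, 0, 1, -1]

    def test_d2_worked_example(self, printed_gradient):
        expected = [0, 0, 2, 1, 1, 1, 2, 2, -1, -1, -1, 2, 0, 2, 1, 1, 1]
        assert code_d2(code_d1(printed_gradient, 5)).tolist() == expected

    def test_d2_no_markers(self):
        assert not code_d2(np.zeros(8, dtype=int)).any()

    def test_d2_adjacency_rule(self):
        assert code_d2(np.array([1, 0, 0, 0, 1])).tolist() == [1, 2, 0, 2, 1]

    def test_d3_worked_example(self, printed_gradient):
        d2 = code_d2(code_d1(printed_gradient, 5))
        raw_diff = np.concatenate(([0], np.diff(d2)))
        assert raw_diff.tolist() == [0, 0, 2, -1, 0, 0, 1, 0, -3, 0, 0, 3, -2, 2, -1, 0, 0]
        expected = [0, 0, 2, 0, 0, 0, 0, 0, 0, 0, 0, 0, -2, 2, 0, 0, 0]
        assert code_d3(d2).tolist() == expected

    def test_d3_zero(self):
        assert not code_d3(np.zeros(6, dtype=int)).any()

    def test_d3_hand_example(self):
        assert code_d3(np.array([0, 2, 1, 2, 0])).tolist() == [0, 2, 0, 0, -2]


class TestDedupe:
    def test_keeps_leftmost_onset(self):
        d3 = np.zeros(30, dtype=int)
        d3[[5, 9]] = 2
        d3[20] = -2
        out = dedupe_anchors(d3)
        assert np.flatnonzero(out).tolist() == [5, 20]
        assert out[5] == 2 and out[20] == -2

    def test_keeps_rightmost_end(self):
        d3 = np.zeros(12, dtype=int)
        d3[[4, 8]] = -2
        out = dedupe_anchors(d3)
        assert np.flatnonzero(out).tolist() == [8]

    def test_alternating_markers_unchanged(self):
        d3 = np.zeros(20, dtype=int)
        d3[3], d3[7], d3[12], d3[16] = 2, -2, 2, -2
        np.testing.assert_array_equal(dedupe_anchors(d3), d3)
        np.testing.assert_array_equal(dedupe_anchors(dedupe_anchors(d3)), dedupe_anchors(d3))


class TestPrune:
    # 1 nm channel spacing around 600 nm
    cal = sr.WavelengthCalibration(np.arange(590.0, 621.0))

    def _d3(self, end_nm, onset_nm):
        d3 = np.zeros(31, dtype=int)
        wl = self.cal.wavelength_nm
        d3[int(np.flatnonzero(wl == end_nm)[0])] = -2
        d3[int(np.flatnonzero(wl == onset_nm)[0])] = 2
        return d3

    def test_close_pair_removed(self):
        """600 -> 603 nm is ~83 cm^-1, below the 200 cm^-1 merge distance."""
        out = prune_close_pairs(self._d3(600.0, 603.0), self.cal, 200.0)
        assert not out.any()

    def test_distant_pair_kept(self):
        """600 -> 612 nm is ~327 cm^-1, so both anchors survive."""
        d3 = self._d3(600.0, 612.0)
        np.testing.assert_array_equal(prune_close_pairs(d3, self.cal, 200.0), d3)

    def test_t2_zero_is_identity(self):
        d3 = self._d3(600.0, 601.0)
        np.testing.assert_array_equal(prune_close_pairs(d3, self.cal, 0.0), d3)


# ---------------------------------------------------------------------------
# anchors


class TestExtractAnchors:
    def test_worked_example_onset_at_three(self, printed_gradient, fine17_cal):
        """After the full coding pipeline the only feature starts at
        position 3 and the terminal anchors frame it."""
        anchors, warn = extract_anchors(
            np.zeros(17), printed_gradient, NO_OPTIONS, fine17_cal
        )
        assert anchors.positions[:2] == (1, 3)
        assert anchors.positions[-1] == 17
        assert anchors.roles[0] == "end" and anchors.roles[1] == "onset"
        assert not warn

    def test_flat_spectrum_has_terminal_anchors_only(self):
        cal = sr.default_calibration(64)
        anchors, _ = extract_anchors(np.full(64, 5.0), np.zeros(64), NO_OPTIONS, cal)
        assert anchors.positions == (1, 64)
        assert anchors.roles == ("end", "onset")

    def test_filter_edge_only_discarded(self):
        """A sharp rise narrower than T3 with no band leaves no features,
        so the resolved signal is zero up to the first real band."""
        i = np.arange(256, dtype=float)
        raw = 200.0 / (1.0 + np.exp(-(i - 60) / 2.0))
        px = resolve_method2(raw, MethodIIParams(t4=None), sr.default_calibration(256))
        assert px.anchors.positions == (1, 256)
        assert not px.resolved.any()

    def test_early_onset_relocation(self):
        """A band overlapping the filter edge keeps its feature but the
        onset anchor moves to the band's own onset, giving a near-horizontal
        chord under the band."""
        i = np.arange(256, dtype=float)
        edge = 200.0 / (1.0 + np.exp(-(i - 60) / 2.0))
        band = 400 * np.exp(-0.5 * ((i - 75) / 6) ** 2)
        px = resolve_method2(edge + band, MethodIIParams(t4=None), sr.default_calibration(256))
        on, end = px.anchors.feature_intervals()[0]
        assert on > 60  # moved past the raw filter-edge onset
        chord = abs(px.smoothed[on - 1] - px.smoothed[end - 1])
        assert chord < 30  # close to horizontal

    def test_anchor_set_invariants(self):
        with pytest.raises(ValueError):
            AnchorSet((2, 10), 10)  # must start at 1
        with pytest.raises(ValueError):
            AnchorSet((1, 9), 10)  # must end at channel_count
        with pytest.raises(ValueError):
            AnchorSet((1, 5, 5, 10), 10)  # strictly increasing


class TestParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"t1": 0.0},
            {"t2": -1.0},
            {"t3": -5},
            {"t4": -1.0},
            {"cosmicthres": 4.0},  # must exceed T1
        ],
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            MethodIIParams(**kwargs)


# ---------------------------------------------------------------------------
# baseline


class TestBaseline:
    def test_no_features_baseline_is_data(self):
        s = np.sin(np.arange(32) / 3.0) + 2
        np.testing.assert_array_equal(build_baseline(s, AnchorSet((1, 32), 32)), s)

    def test_line_over_a_ramp_is_the_ramp(self):
        s = np.arange(10, dtype=float)
        b = build_baseline(s, AnchorSet((1, 3, 8, 10), 10))
        np.testing.assert_allclose(b, s, rtol=1e-12)

    def test_triangle_on_flat_background(self):
        s = np.full(40, 10.0)
        s[15:26] += np.concatenate([np.linspace(0, 100, 6), np.linspace(100, 0, 6)[1:]])
        b = build_baseline(s, AnchorSet((1, 15, 26, 40), 40))
        np.testing.assert_array_equal(b, np.full(40, 10.0))

    def test_baseline_consistency(self, noiseless_resolved, noiseless_phantom):
        """B equals S on background intervals, is affine across features and
        continuous at every anchor."""
        _, cube, truth = noiseless_phantom
        y, x = 2, 2  # inside the emitter disc
        px = resolve_method2(cube.counts[y, x], MethodIIParams(), cube.calibration)
        assert len(px.anchors.feature_intervals()) >= 1
        for a, b in px.anchors.background_intervals():
            np.testing.assert_array_equal(
                px.baseline[a - 1 : b], px.smoothed[a - 1 : b]
            )
        for on, end in px.anchors.feature_intervals():
            seg = px.baseline[on - 1 : end]
            if seg.size > 2:  # affine: second differences vanish
                np.testing.assert_allclose(np.diff(seg, 2), 0, atol=1e-8)
            assert px.baseline[on - 1] == px.smoothed[on - 1]
            assert px.baseline[end - 1] == px.smoothed[end - 1]


# ---------------------------------------------------------------------------
# full resolution


class TestResolve:
    def test_flat_noiseless_spectrum(self):
        px = resolve_method2(np.full(64, 100.0), NO_OPTIONS, sr.default_calibration(64))
        assert not px.resolved.any()
        np.testing.assert_array_equal(px.baseline, px.smoothed)

    def test_line_area_recovered_within_ten_percent(self):
        """A sharp line (FWHM 6 channels) on a curved background resolves to
        its analytic Gaussian area within 10%."""
        n = 256
        i = np.arange(n, dtype=float)
        line = 500 * np.exp(-0.5 * ((i - 128) / (6 / 2.3548)) ** 2)
        background = 100 + 0.5 * i - 0.001 * i**2
        px = resolve_method2(background + line, NO_OPTIONS, sr.default_calibration(n))
        analytic = 500 * 6 * np.sqrt(np.pi / np.log(16))
        assert px.resolved.sum() == pytest.approx(analytic, rel=0.10)

    def test_subthreshold_line_not_resolved(self):
        """A 1-count line is below the gradient threshold and contributes
        no anchors and no resolved signal."""
        n = 256
        i = np.arange(n, dtype=float)
        line = 1.0 * np.exp(-0.5 * ((i - 128) / (6 / 2.3548)) ** 2)
        px = resolve_method2(100 + line, NO_OPTIONS, sr.default_calibration(n))
        assert px.anchors.positions == (1, n)
        assert not px.resolved.any()

    def test_t4_zeroes_dim_spectra(self):
        n = 256
        i = np.arange(n, dtype=float)
        line = 100 * np.exp(-0.5 * ((i - 128) / 3) ** 2)  # ~750 resolved counts
        params = MethodIIParams(t3=None, t4=2000.0, cosmicthres=None)
        px = resolve_method2(10 + line, params, sr.default_calibration(n))
        assert px.zeroed_by_t4
        assert not px.resolved.any()
        no_t4 = resolve_method2(10 + line, NO_OPTIONS, sr.default_calibration(n))
        assert no_t4.resolved.sum() > 0

    def test_cosmicthres_drops_spike_feature(self):
        n = 256
        raw = np.full(n, 50.0)
        raw[100] = 40000.0
        params = MethodIIParams(t3=None, t4=None, cosmicthres=500.0)
        px = resolve_method2(raw, params, sr.default_calibration(n))
        assert not px.resolved.any()  # spike absorbed into the baseline
        keep = resolve_method2(raw, NO_OPTIONS, sr.default_calibration(n))
        assert keep.resolved.sum() > 1000  # without the option it leaks into L

    def test_doubling_amplitude_doubles_resolved_area(self):
        """Above the resolution onset L is linear in line amplitude (5%)."""
        n = 512
        i = np.arange(n, dtype=float)

        def area(amp):
            line = amp * np.exp(-0.5 * ((i - 250) / (8 / 2.3548)) ** 2)
            px = resolve_method2(80 + line, NO_OPTIONS, sr.default_calibration(n))
            return px.resolved.sum()

        assert area(1000.0) / area(500.0) == pytest.approx(2.0, rel=0.05)

    def test_resolution_onset_nonlinearity(self):
        """Below the gradient threshold the amplitude-response curve is flat
        zero; it switches on only once the line's gradient exceeds T1."""
        n = 256
        i = np.arange(n, dtype=float)

        def area(amp):
            line = amp * np.exp(-0.5 * ((i - 128) / (8 / 2.3548)) ** 2)
            px = resolve_method2(80 + line, NO_OPTIONS, sr.default_calibration(n))
            return px.resolved.sum()

        amps = [0.5, 1, 2, 5, 10, 50, 200]
        curve = [area(a) for a in amps]
        assert curve[0] == 0.0 and curve[1] == 0.0
        assert curve[-1] > 0


@settings(derandomize=True, max_examples=25)
@given(st.integers(0, 2**31 - 1))
def test_resolved_signal_never_negative(seed):
    """L >= 0 for arbitrary non-negative spectra."""
    rng = np.random.default_rng(seed)
    raw = np.abs(np.cumsum(rng.normal(0, rng.uniform(0.5, 30), 96))) + rng.uniform(0, 100)
    px = resolve_method2(raw, MethodIIParams(t4=None), sr.default_calibration(96))
    assert np.all(px.resolved >= 0)


def test_zero_background_for_smooth_inputs():
    """Any noiseless sum of smooth components with |Δ| <= T1 everywhere
    resolves to exactly zero."""
    n = 512
    i = np.arange(n, dtype=float)
    raw = (
        300 * np.exp(-0.5 * ((i - 150) / 120) ** 2)
        + 120 * np.exp(-0.5 * ((i - 380) / 90) ** 2)
        + 40
    )
    px = resolve_method2(raw, MethodIIParams(t4=None), sr.default_calibration(n))
    assert np.abs(px.grad).max() <= 5.0
    assert not px.resolved.any()


class TestResolveCube:
    def test_flat_cube_resolves_to_zero(self):
        cal = sr.default_calibration(32)
        cube = sr.SpectralCube(np.full((2, 2, 32), 10.0), cal)
        rc = resolve_cube(cube, NO_OPTIONS, method=2)
        assert not rc.resolved.any()

    def test_pixel_independence(self, noiseless_phantom):
        """Permuting pixels permutes outputs identically."""
        _, cube, _ = noiseless_phantom
        rc = resolve_cube(cube, MethodIIParams(), method=2)
        flipped = sr.SpectralCube(cube.counts[::-1, ::-1].copy(), cube.calibration)
        rc_f = resolve_cube(flipped, MethodIIParams(), method=2)
        np.testing.assert_array_equal(rc_f.resolved, rc.resolved[::-1, ::-1])

    def test_signal_confined_to_disc_footprint(self, noiseless_phantom, noiseless_resolved):
        """L is nonzero only inside the emitter disc, zero in every
        pure-background pixel."""
        _, _, truth = noiseless_phantom
        recovered = noiseless_resolved.resolved.sum(axis=2)
        assert not recovered[truth.background_mask()].any()
        assert np.all(recovered[truth.masks["Eu"]] > 0)

    def test_method1_route(self, noiseless_phantom):
        _, cube, truth = noiseless_phantom
        rc = resolve_cube(cube, method=1)
        assert rc.baseline is None
        img = rc.resolved.sum(axis=2)
        assert img[truth.masks["Eu"]].min() > img[truth.background_mask()].max()
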