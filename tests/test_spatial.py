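import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage

from photorf import (
    HillFit,
    RFComponentTruth,
    RecordingTrace,
    SpatialSensitivityMap,
    average_fwhm,
    delay_difference,
    detect_coupling,
    extract_raw_map,
    fit_rf,
    simulate_grid_scan,
    smooth_map,
    to_sensitivity,
)
from photorf.errors import DataError, InputError, NotEstimableError
from photorf.recording import Marker
from photorf.spatial import FWHM_FACTOR, RFComponent, RFModel, _fit_k_components
from photorf.synth import spatial_profile
from conftest import make_cell


def sens_map_from(values, protocol):
    return SpatialSensitivityMap(stage="sensitivity",
                                 values=values / values.max(),
                                 az_deg=protocol.az_deg, el_deg=protocol.el_deg)


def pipeline_sens(cell, protocol, hill, seed=0, smoothing=None, baseline="none"):
    tr = simulate_grid_scan(cell, protocol, seed=seed)
    raw = extract_raw_map(tr, protocol)
    m = smooth_map(raw, sigma_deg=smoothing) if smoothing else raw
    return to_sensitivity(m, hill, baseline=baseline)


class TestExtractRawMap:
    def test_flat_zero_trace(self, protocol):
        cell = make_cell()
        tr = simulate_grid_scan(cell, protocol, seed=0, i0_factor=0.0)
        raw = extract_raw_map(tr, protocol)
        np.testing.assert_array_equal(raw.values, 0.0)
        assert raw.stage == "raw"

    def test_peak_at_true_center_node(self, protocol):
        cell = make_cell(az=3.0, el=-2.0, sigma=2.0)
        tr = simulate_grid_scan(cell, protocol, seed=0)
        raw = extract_raw_map(tr, protocol)
        r, c = np.unravel_index(np.argmax(raw.values), raw.values.shape)
        assert protocol.az_deg[c] == 3.0
        assert protocol.el_deg[r] == -2.0

    def test_baseline_invariance(self, protocol):
        # max - min per epoch ignores any constant resting potential
        cell = make_cell(sigma=2.0)
        tr = simulate_grid_scan(cell, protocol, seed=0)
        shifted = RecordingTrace(samples=tr.samples - 50.0,
                                 sampling_rate=tr.sampling_rate,
                                 markers=tr.markers)
        np.testing.assert_allclose(extract_raw_map(tr, protocol).values,
                                   extract_raw_map(shifted, protocol).values,
                                   atol=1e-12)

    def test_missing_epochs(self, protocol):
        cell = make_cell()
        tr = simulate_grid_scan(cell, protocol, seed=0)
        truncated = RecordingTrace(samples=tr.samples,
                                   sampling_rate=tr.sampling_rate,
                                   markers=tr.markers[:-5])
        with pytest.raises(InputError, match="missing epochs"):
            extract_raw_map(truncated, protocol)


class TestSmoothMap:
    def _raw(self, values, protocol):
        return SpatialSensitivityMap(stage="raw", values=values,
                                     az_deg=protocol.az_deg,
                                     el_deg=protocol.el_deg)

    def test_identity_limit(self, protocol):
        rng = np.random.default_rng(0)
        raw = self._raw(rng.random((21, 21)), protocol)
        out = smooth_map(raw, sigma_deg=1e-6)
        np.testing.assert_allclose(out.values, raw.values, atol=1e-6)

    def test_impulse_matches_direct_convolution(self, protocol):
        # oracle: explicit truncated separable kernel, built independently
        values = np.zeros((21, 21))
        values[10, 10] = 1.0
        out = smooth_map(self._raw(values, protocol), sigma_deg=1.0)
        i = np.arange(-4, 5)  # scipy radius = int(4*sigma + 0.5) = 4
        g = np.exp(-i**2 / 2.0)
        g /= g.sum()
        expected = np.zeros((21, 21))
        expected[6:15, 6:15] = np.outer(g, g)
        np.testing.assert_allclose(out.values, expected, atol=1e-12)

    def test_dc_preservation(self, protocol):
        raw = self._raw(np.full((21, 21), 3.3), protocol)
        out = smooth_map(raw, sigma_deg=1.0)
        np.testing.assert_allclose(out.values, 3.3, atol=1e-12)

    def test_requires_raw_stage(self, protocol):
        raw = self._raw(np.ones((21, 21)), protocol)
        smoothed = smooth_map(raw)
        with pytest.raises(InputError):
            smooth_map(smoothed)

    def test_sigma_positive(self, protocol):
        with pytest.raises(InputError):
            smooth_map(self._raw(np.ones((21, 21)), protocol), sigma_deg=0.0)


class TestToSensitivity:
    def test_max_is_one(self, protocol, hill_unit):
        cell = make_cell(sigma=2.5)
        sens = pipeline_sens(cell, protocol, hill_unit, smoothing=1.0,
                             baseline="min")
        assert sens.values.max() == pytest.approx(1.0)
        assert sens.stage == "sensitivity"

    def test_ratio_closed_form(self, protocol, hill_unit):
        # responses at 0.5 and 0.9 of V_max: sensitivities 1 : 9 (n = 1)
        values = np.zeros((21, 21))
        values[10, 10] = 0.9 * hill_unit.v_max
        values[10, 12] = 0.5 * hill_unit.v_max
        raw = SpatialSensitivityMap(stage="raw", values=values,
                                    az_deg=protocol.az_deg,
                                    el_deg=protocol.el_deg)
        sens = to_sensitivity(raw, hill_unit, baseline="none")
        assert sens.values[10, 12] / sens.values[10, 10] == pytest.approx(1 / 9)

    def test_recovers_profile_noiseless(self, protocol):
        # simulator oracle: the full voltage->sensitivity chain inverts the
        # Hill nonlinearity exactly
        cell = make_cell(az=1.0, el=2.0, sigma=3.0, v_max=18.0, k_half=0.7, n=1.3)
        hill = HillFit(18.0, 0.7, 1.3)
        sens = pipeline_sens(cell, protocol, hill, baseline="none")
        az2, el2 = np.meshgrid(protocol.az_deg, protocol.el_deg)
        np.testing.assert_allclose(sens.values,
                                   spatial_profile(cell, az2, el2), atol=1e-6)

    def test_all_zero_map(self, protocol, hill_unit):
        raw = SpatialSensitivityMap(stage="raw", values=np.zeros((21, 21)),
                                    az_deg=protocol.az_deg,
                                    el_deg=protocol.el_deg)
        with pytest.raises(DataError):
            to_sensitivity(raw, hill_unit)


class TestFitRF:
    def test_single_isotropic_gaussian(self, protocol, hill_unit):
        cell = make_cell(az=0.3, el=-0.4, sigma=2.0)
        sens = pipeline_sens(cell, protocol, hill_unit)
        model = fit_rf(sens)
        assert len(model.components) == 1
        expected = FWHM_FACTOR * 2.0  # 4.7096 deg
        assert model.main.fwhm_circ == pytest.approx(expected, rel=0.01)
        assert model.main.center_az == pytest.approx(0.3, abs=0.05)
        assert model.main.center_el == pytest.approx(-0.4, abs=0.05)

    def test_two_component_weights(self, protocol, hill_unit):
        comps = [RFComponentTruth(-4.0, 0.0, 1.5, 1.5, weight=1.0),
                 RFComponentTruth(4.0, 0.0, 1.5, 1.5, weight=0.6)]
        cell = make_cell(components=comps)
        sens = pipeline_sens(cell, protocol, hill_unit)
        model = fit_rf(sens)
        assert len(model.components) == 2
        assert model.main.weight == 1.0
        assert model.components[1].weight == pytest.approx(0.6, abs=1e-3)
        assert model.components[1].role == "coupled"

    def test_fwhm_circ_equal_area(self):
        comp = RFComponent(center_az=0, center_el=0,
                           sigma_major=9.0 / FWHM_FACTOR,
                           sigma_minor=4.0 / FWHM_FACTOR,
                           orientation=30.0, amplitude=1.0)
        assert comp.fwhm_major == pytest.approx(9.0)
        assert comp.fwhm_minor == pytest.approx(4.0)
        assert comp.fwhm_circ == pytest.approx(6.0, abs=1e-12)

    def test_elliptical_recovery(self, protocol, hill_unit):
        cell = make_cell(sigma=3.0, sigma_minor=1.5, orientation=40.0)
        sens = pipeline_sens(cell, protocol, hill_unit)
        model = fit_rf(sens)
        assert model.main.sigma_major == pytest.approx(3.0, rel=0.02)
        assert model.main.sigma_minor == pytest.approx(1.5, rel=0.02)
        assert model.main.orientation == pytest.approx(40.0, abs=2.0)

    def test_flat_map_no_rf(self, protocol):
        values = np.full((21, 21), 0.5)
        values[0, 0] = 1.0  # max=1 for the invariant; still < 3x median
        smap = SpatialSensitivityMap(stage="sensitivity", values=values,
                                     az_deg=protocol.az_deg,
                                     el_deg=protocol.el_deg)
        with pytest.raises(NotEstimableError):
            fit_rf(smap)

    def test_model_selection_rss_monotone(self, protocol, hill_unit):
        comps = [RFComponentTruth(-4.0, 0.0, 1.5, 1.5, weight=1.0),
                 RFComponentTruth(4.0, 0.0, 1.5, 1.5, weight=0.6)]
        cell = make_cell(components=comps)
        sens = pipeline_sens(cell, protocol, hill_unit)
        m1 = fit_rf(sens, max_components=1)
        m2 = fit_rf(sens, max_components=2)
        assert len(m1.components) == 1 and len(m2.components) == 2
        assert m1.rss > m2.rss

    def test_requires_sensitivity_stage(self, protocol):
        raw = SpatialSensitivityMap(stage="raw", values=np.ones((21, 21)),
                                    az_deg=protocol.az_deg,
                                    el_deg=protocol.el_deg)
        with pytest.raises(InputError):
            fit_rf(raw)

    @given(s_maj=st.floats(min_value=0.5, max_value=8.0),
           s_min=st.floats(min_value=0.5, max_value=8.0))
    @settings(max_examples=50, deadline=None)
    def test_fwhm_identities(self, s_maj, s_min):
        comp = RFComponent(center_az=0, center_el=0, sigma_major=s_maj,
                           sigma_minor=s_min, orientation=0.0, amplitude=1.0)
        assert comp.fwhm_major == pytest.approx(
            FWHM_FACTOR * max(s_maj, s_min), rel=1e-12)
        assert comp.fwhm_minor == pytest.approx(
            FWHM_FACTOR * min(s_maj, s_min), rel=1e-12)
        assert comp.fwhm_circ == pytest.approx(
            np.sqrt(comp.fwhm_major * comp.fwhm_minor), rel=1e-12)


def two_peak_map(protocol, peak_b=0.7, valley=0.1, sep=10.0):
    """Synthetic two-lobe sensitivity map with a controllable valley floor."""
    az2, el2 = np.meshgrid(protocol.az_deg, protocol.el_deg)
    sig = 1.5
    a = 0.9 * np.exp(-((az2 + sep / 2) ** 2 + el2**2) / (2 * sig**2))
    b = peak_b * np.exp(-((az2 - sep / 2) ** 2 + el2**2) / (2 * sig**2))
    values = np.maximum(np.maximum(a, b), valley * 0.9)
    return sens_map_from(values, protocol)


def two_comp_model(sep=10.0, amp_b=0.7):
    comps = [
        RFComponent(center_az=-sep / 2, center_el=0.0, sigma_major=1.5,
                    sigma_minor=1.5, orientation=0.0, amplitude=0.9),
        RFComponent(center_az=sep / 2, center_el=0.0, sigma_major=1.5,
                    sigma_minor=1.5, orientation=0.0, amplitude=amp_b),
    ]
    return RFModel(components=comps, offset=0.0, rss=0.0)


class TestDetectCoupling:
    def test_single_component_false(self, protocol, hill_unit):
        cell = make_cell(sigma=2.0)
        sens = pipeline_sens(cell, protocol, hill_unit)
        model = fit_rf(sens)
        assert not detect_coupling(model, sens).coupled

    def test_two_peaks_low_valley_true(self, protocol):
        smap = two_peak_map(protocol, peak_b=0.7, valley=0.1)
        res = detect_coupling(two_comp_model(), smap)
        assert res.coupled
        assert res.pairs[0]["valley"] < 0.45
        assert len(res.pairs[0]["profile"]) > 0

    def test_two_peaks_high_valley_false(self, protocol):
        # overlapping lobes, one rhabdom
        smap = two_peak_map(protocol, peak_b=0.7, valley=0.6)
        assert not detect_coupling(two_comp_model(), smap).coupled

    def test_weak_secondary_false(self, protocol):
        smap = two_peak_map(protocol, peak_b=0.2, valley=0.05)
        assert not detect_coupling(two_comp_model(amp_b=0.2), smap).coupled

    def test_thresholds_configurable(self, protocol):
        smap = two_peak_map(protocol, peak_b=0.7, valley=0.3)
        assert detect_coupling(two_comp_model(), smap).coupled
        assert not detect_coupling(two_comp_model(), smap,
                                   valley_threshold=0.2).coupled


class TestDelayDifference:
    def _coupled_cell(self, latency):
        comps = [RFComponentTruth(-4.0, 0.0, 1.3, 1.3, weight=1.0,
                                  latency_ms=0.0),
                 RFComponentTruth(4.0, 0.0, 1.3, 1.3, weight=0.7,
                                  latency_ms=latency)]
        return make_cell(components=comps)

    def _fit(self, cell, protocol, hill):
        tr = simulate_grid_scan(cell, protocol, seed=0)
        sens = pipeline_sens(cell, protocol, hill)
        return tr, fit_rf(sens)

    def test_constructed_offset(self, protocol, hill_unit):
        cell = self._coupled_cell(3.0)
        tr, model = self._fit(cell, protocol, hill_unit)
        deltas = delay_difference(tr, protocol, model)
        assert len(deltas) == 1
        assert deltas[0] == pytest.approx(-3.0, abs=1e-6)

    def test_identical_latencies(self, protocol, hill_unit):
        cell = self._coupled_cell(0.0)
        tr, model = self._fit(cell, protocol, hill_unit)
        assert delay_difference(tr, protocol, model)[0] == pytest.approx(
            0.0, abs=1e-6)

    def test_needs_two_components(self, protocol, hill_unit):
        cell = make_cell(sigma=2.0)
        tr = simulate_grid_scan(cell, protocol, seed=0)
        sens = pipeline_sens(cell, protocol, hill_unit)
        model = fit_rf(sens)
        with pytest.raises(InputError):
            delay_difference(tr, protocol, model)


class TestAverageFwhm:
    def _model(self, fwhm, quality="high"):
        comp = RFComponent(center_az=0, center_el=0,
                           sigma_major=fwhm / FWHM_FACTOR,
                           sigma_minor=fwhm / FWHM_FACTOR,
                           orientation=0.0, amplitude=1.0)
        return RFModel(components=[comp], offset=0.0, rss=0.0, quality=quality)

    def test_singleton(self):
        assert average_fwhm([self._model(6.0)]) == pytest.approx(6.0)

    def test_mean(self):
        assert average_fwhm([self._model(6.0), self._model(8.0)]) \
            == pytest.approx(7.0)

    def test_low_quality_filtered(self):
        models = [self._model(6.0), self._model(8.0),
                  self._model(100.0, quality="low")]
        assert average_fwhm(models) == pytest.approx(7.0)

    def test_none_high_quality(self):
        with pytest.raises(NotEstimableError):
            average_fwhm([self._model(6.0, quality="low")])


class TestRFModelInvariants:
    def test_sorted_and_roles(self):
        comps = [
            RFComponent(center_az=0, center_el=0, sigma_major=1, sigma_minor=1,
                        orientation=0, amplitude=0.4),
            RFComponent(center_az=5, center_el=0, sigma_major=1, sigma_minor=1,
                        orientation=0, amplitude=0.9),
        ]
        model = RFModel(components=comps, offset=0.0, rss=0.0)
        amps = [c.amplitude for c in model.components]
        assert amps == sorted(amps, reverse=True)
        assert model.main.role == "main" and model.main.weight == 1.0
        assert model.components[1].role == "coupled"
        assert model.components[1].weight == pytest.approx(0.4 / 0.9)

    def test_axis_ordering_normalized(self):
        comp = RFComponent(center_az=0, center_el=0, sigma_major=1.0,
                           sigma_minor=3.0, orientation=10.0, amplitude=1.0)
        assert comp.sigma_major == 3.0 and comp.sigma_minor == 1.0
        assert comp.orientation == pytest.approx(100.0)
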