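"""Generators: seeded determinism, forward-model identity, noise calibration."""

import numpy as np
import pytest

import photocyclekit as pk
from photocyclekit.synth import (
    biphasic_dip_time,
    default_time_grid,
    default_wavelength_grid,
    pyranine_model,
)


class TestTransientSurface:
    def test_seeded_determinism_bit_identical(self):
        gt = pk.PhotocycleGroundTruth(noise_sigma=0.05, seed=7)
        a = pk.generate_transient_surface(gt)
        b = pk.generate_transient_surface(gt)
        np.testing.assert_array_equal(a.delta_A, b.delta_A)

    def test_different_seed_differs(self):
        a = pk.generate_transient_surface(pk.PhotocycleGroundTruth(seed=0))
        b = pk.generate_transient_surface(pk.PhotocycleGroundTruth(seed=1))
        assert np.any(a.delta_A != b.delta_A)

    def test_earliest_time_shows_only_first_intermediate(self):
        gt = pk.PhotocycleGroundTruth(noise_sigma=0.0, excited_fraction=0.8)
        t = np.array([1e-5, 1.0])  # 1e-5 ms << tau_K = 0.015 ms
        surf = pk.generate_transient_surface(gt, time_grid=t)
        wl = surf.wavelengths
        expected = 0.8 * gt.sads_matrix(wl)[0]
        np.testing.assert_allclose(surf.delta_A[:, 0], expected, atol=1e-3)

    def test_noiseless_output_equals_forward_model_exactly(self, noiseless_surface):
        """Identity with an independently assembled occupancy x SADS product."""
        gt = pk.PhotocycleGroundTruth(noise_sigma=0.0)
        wl, t = default_wavelength_grid(), default_time_grid()
        occ, _ = pk.sequential_occupancies(
            pk.SequentialModel(np.array(gt.decay_taus), labels=gt.intermediate_labels), t
        )
        manual = gt.sads_matrix(wl).T @ occ
        np.testing.assert_allclose(noiseless_surface.delta_A, manual, atol=1e-12)

    def test_noise_sd_calibrated_to_sigma(self):
        clean = pk.generate_transient_surface(pk.PhotocycleGroundTruth(noise_sigma=0.0))
        noisy = pk.generate_transient_surface(
            pk.PhotocycleGroundTruth(noise_sigma=0.05, seed=3)
        )
        resid = noisy.delta_A - clean.delta_A
        target = 0.05 * np.max(np.abs(clean.delta_A))
        assert resid.size >= 10_000
        assert abs(np.std(resid) / target - 1) < 0.05

    def test_invalid_ground_truth_rejected(self):
        with pytest.raises(ValueError):
            pk.PhotocycleGroundTruth(decay_taus=(1.0, -1.0, 2.0))
        with pytest.raises(ValueError):
            pk.PhotocycleGroundTruth(excited_fraction=0.0)
        with pytest.raises(ValueError):
            pk.generate_transient_surface(
                pk.PhotocycleGroundTruth(), wavelength_grid=[]
            )


class TestTitrationSeries:
    def test_high_pH_limit_is_deprotonated_end_member(self):
        gt = pk.TitrationGroundTruth(noise_sigma=0.0, pH_list=(13.0, 7.1), reference_pH=7.1)
        series = pk.generate_titration_series(gt)
        end_member = gt.state_spectra(series.wavelengths)[0]
        np.testing.assert_allclose(series.spectra[0], end_member, atol=1e-9)

    def test_half_protonation_at_pka1(self):
        gt = pk.TitrationGroundTruth(
            pka_values=(5.0, 0.5), noise_sigma=0.0, pH_list=(7.1, 5.0), reference_pH=7.1
        )
        series = pk.generate_titration_series(gt)
        states = gt.state_spectra(series.wavelengths)
        np.testing.assert_allclose(
            series.spectra[1], 0.5 * states[0] + 0.5 * states[1], atol=2e-4
        )

    def test_state_weights_match_hand_evaluated_fractions(self):
        # direct evaluation of the two-site formula at pH 2.0, pKa (3.0, 1.5)
        p1 = 1 / (1 + 10 ** (2.0 - 3.0))       # 0.909090...
        p2 = 1 / (1 + 10 ** (2.0 - 1.5))       # 0.240253...
        w = pk.protonation_state_weights(2.0, 3.0, 1.5)[:, 0]
        np.testing.assert_allclose(w, [1 - p1, p1 - p2, p2], rtol=1e-12)
        assert w.sum() == pytest.approx(1.0)

    def test_equal_pkas_rejected(self):
        with pytest.raises(ValueError, match="ambiguous"):
            pk.TitrationGroundTruth(pka_values=(2.0, 2.0))

    def test_reference_must_be_sampled(self):
        with pytest.raises(ValueError):
            pk.TitrationGroundTruth(pH_list=(5.0, 3.0), reference_pH=7.1)


class TestChromatogram:
    def test_single_peak_area_is_gaussian_area(self):
        gt = pk.ChromatogramGroundTruth(
            isomer_fractions={"all-trans": 1.0},
            syn_anti_split={"all-trans": 1.0},
            retention_times={"Ts": 10.0},
            oxime_map={"Ts": ("all-trans", "syn")},
            peak_widths={"Ts": 0.2},
            extinction_table={"Ts": 50000.0},
            noise_sigma=0.0,
        )
        chrom = pk.generate_chromatogram(gt)
        areas = pk.integrate_peaks(chrom)
        expected = 1.0 * 50000.0 * gt.amount_scale  # amount * eps * scale
        assert areas["Ts"] == pytest.approx(expected, rel=1e-3)

    def test_area_ratio_follows_fractions(self):
        gt = pk.ChromatogramGroundTruth(
            isomer_fractions={"all-trans": 0.95, "13-cis": 0.05},
            syn_anti_split={"all-trans": 1.0, "13-cis": 1.0},
            retention_times={"Ts": 10.5, "13s": 8.7},
            oxime_map={"Ts": ("all-trans", "syn"), "13s": ("13-cis", "syn")},
            peak_widths={"Ts": 0.15, "13s": 0.15},
            extinction_table={"Ts": 50000.0, "13s": 50000.0},
            noise_sigma=0.0,
        )
        areas = pk.integrate_peaks(pk.generate_chromatogram(gt))
        assert areas["Ts"] / areas["13s"] == pytest.approx(19.0, rel=1e-2)

    def test_seeded_determinism(self):
        gt = pk.ChromatogramGroundTruth(seed=5)
        np.testing.assert_array_equal(
            pk.generate_chromatogram(gt).a360, pk.generate_chromatogram(gt).a360
        )

    def test_overlapping_peaks_warn(self):
        gt = pk.ChromatogramGroundTruth(
            retention_times={"13s": 8.7, "Ts": 8.75, "13a": 12.3, "Ta": 14.0},
        )
        with pytest.warns(RuntimeWarning, match="closer than one width"):
            with pytest.raises(ValueError):  # windows overlap too
                pk.generate_chromatogram(gt)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            pk.ChromatogramGroundTruth(
                isomer_fractions={"all-trans": 0.9, "13-cis": 0.05}
            )


class TestPumpAssay:
    def test_cccp_abolishes_light_response(self):
        gt = pk.PumpAssayGroundTruth(cccp=True, seed=11)
        trace = pk.generate_pump_assay(gt)
        light = (trace.times >= gt.illumination_window[0]) & (
            trace.times <= gt.illumination_window[1]
        )
        model = gt.baseline_pH + gt.drift_rate * trace.times
        assert np.max(np.abs(trace.pH - model)[light]) <= 3.5 * gt.noise_sigma

    def test_empty_vector_same_flat_contract(self):
        gt = pk.PumpAssayGroundTruth(pump_amplitude=0.0, construct="empty_vector", seed=12)
        trace = pk.generate_pump_assay(gt)
        model = gt.baseline_pH + gt.drift_rate * trace.times
        assert np.max(np.abs(trace.pH - model)) <= 4.0 * gt.noise_sigma

    def test_noiseless_minimum_matches_closed_form(self):
        gt = pk.PumpAssayGroundTruth(
            pump_amplitude=0.2, drift_rate=0.0, noise_sigma=0.0
        )
        trace = pk.generate_pump_assay(gt)
        t_on, t_off = gt.illumination_window
        expected_min = gt.baseline_pH - 0.2 * (1 - np.exp(-(t_off - t_on) / gt.tau_on))
        assert np.min(trace.pH) == pytest.approx(expected_min, abs=1e-12)

    def test_requires_pre_light_baseline(self):
        with pytest.raises(ValueError, match="60 s"):
            pk.generate_pump_assay(
                pk.PumpAssayGroundTruth(illumination_window=(10.0, 200.0))
            )


class TestPyranine:
    def test_boundaries_return_to_zero(self):
        gt = pk.PyranineGroundTruth(noise_sigma=0.0)
        t = np.geomspace(1e-4, 1e5, 200)
        trace = pk.generate_pyranine_trace(gt, time_grid=t)
        assert abs(trace.delta_a450[0]) < 1e-3 * gt.amplitude
        assert abs(trace.delta_a450[-1]) < 1e-3 * gt.amplitude
        # grid rarely hits the dip time exactly; parabolic flatness bounds the gap
        assert trace.delta_a450.min() == pytest.approx(-gt.amplitude, rel=1e-3)

    def test_analytic_dip_time_matches_numeric_minimum(self):
        tr, tu = 1.5, 47.0
        t = np.linspace(0.01, 400, 400_000)
        numeric = t[np.argmin(pyranine_model(t, tr, tu, 1.0))]
        assert biphasic_dip_time(tr, tu) == pytest.approx(numeric, abs=1e-3)

    def test_default_dip_between_1_and_10_ms(self):
        assert 1.0 < biphasic_dip_time(1.5, 47.0) < 10.0

    def test_degenerate_taus_rejected(self):
        with pytest.raises(ValueError):
            pk.PyranineGroundTruth(tau_release=5.0, tau_uptake=5.0)
        with pytest.raises(ValueError, match="degenerate"):
            biphasic_dip_time(5.0, 5.0)

    def test_seeded_determinism(self):
        gt = pk.PyranineGroundTruth(seed=2)
        np.testing.assert_array_equal(
            pk.generate_pyranine_trace(gt).delta_a450,
            pk.generate_pyranine_trace(gt).delta_a450,
        )
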